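"""End-to-end evaluation of one plate: fits, per-sample quantities, metrics.

Given a plate carrying a genomic standard dilution series, C-T indicator
dilutions, gDNA wells and converted (BS-DNA) wells, this module:

1. collapses replicate wells;
2. fits the short-C and long-Cfree standard curves (ng scale) and the
   short-T -> short-C Ct transform (from the indicator dilutions);
3. quantifies every gDNA and BS-DNA sample on all three channels;
4. pairs each converted sample with its source gDNA and computes conversion
   efficiency, degradation level and recovery, plus IPC inhibition flags.

A transform R-squared below 0.99 does not stop evaluation but marks every
result with a ``TRANSFORM_UNRELIABLE`` flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import metrics as m
from .quantify import (
    CtTransform,
    StandardCurve,
    fit_ct_transform,
    fit_standard_curve,
    quantify,
    quantify_short_t,
)
from .plate import Channel, PlateRun, SampleRole, collapse_replicates

__all__ = ["MissingRoleError", "RunFits", "EvaluationResult", "evaluate_run"]

FLAG_TRANSFORM_UNRELIABLE = "TRANSFORM_UNRELIABLE"


class MissingRoleError(ValueError):
    """The plate lacks wells of a role required for calibration or pairing."""


@dataclass
class RunFits:
    """All calibration objects fitted from one plate."""

    short_c_curve: StandardCurve
    long_curve: StandardCurve
    transform: CtTransform

    def to_dict(self) -> dict:
        return {
            "short_c_curve": self.short_c_curve.to_dict(),
            "long_cfree_curve": self.long_curve.to_dict(),
            "ct_transform": self.transform.to_dict(),
        }


@dataclass
class EvaluationResult:
    fits: RunFits
    quants: dict[str, m.SampleQuant]
    results: list[m.BisqueResult]
    ipc_flags: dict[str, bool]

    def per_sample_frame(self, kit_by_sample: dict[str, str] | None = None) -> pd.DataFrame:
        kit_by_sample = kit_by_sample or {}
        rows = []
        for r in self.results:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "kit": kit_by_sample.get(r.sample_id, ""),
                    "conversion_efficiency_pct": r.conversion_efficiency,
                    "degradation_level": r.degradation_level,
                    "recovery_pct": r.recovery,
                    "ipc_flag": self.ipc_flags.get(r.sample_id, False),
                    "flags": ";".join(sorted(r.flags)),
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, kit_by_sample: dict[str, str] | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_sample_frame(kit_by_sample).to_csv(
            out / "per_sample.tsv", sep="\t", index=False
        )
        with open(out / "fits.json", "w", encoding="utf-8") as fh:
            json.dump(self.fits.to_dict(), fh, indent=2, sort_keys=True)


def _standard_points(run: PlateRun, channel: Channel) -> list[tuple[float, float]]:
    pts = []
    for w in run.records(role=SampleRole.STANDARD, channel=channel):
        if w.ct is not None and w.known_amount is not None:
            pts.append((w.known_amount, w.ct))
    return pts


def fit_run(run: PlateRun) -> RunFits:
    """Fit both standard curves and the C-T transform from a collapsed run."""
    if not run.records(role=SampleRole.STANDARD):
        raise MissingRoleError("plate has no STANDARD dilution wells")
    indicators = run.records(role=SampleRole.CT_INDICATOR)
    if not indicators:
        raise MissingRoleError("plate has no CT_INDICATOR wells")

    short_curve = fit_standard_curve(
        _standard_points(run, Channel.SHORT_C), Channel.SHORT_C
    )
    long_curve = fit_standard_curve(
        _standard_points(run, Channel.LONG_CFREE), Channel.LONG_CFREE
    )

    by_dilution: dict[float, dict[Channel, float | None]] = {}
    for w in indicators:
        if w.known_amount is None or w.channel not in (Channel.SHORT_C, Channel.SHORT_T):
            continue
        by_dilution.setdefault(w.known_amount, {})[w.channel] = w.ct
    triples = [
        (copies, cts.get(Channel.SHORT_C), cts.get(Channel.SHORT_T))
        for copies, cts in sorted(by_dilution.items())
    ]
    transform = fit_ct_transform(triples)
    return RunFits(short_c_curve=short_curve, long_curve=long_curve, transform=transform)


def _sample_quant(
    run: PlateRun, sample_id: str, role: SampleRole, fits: RunFits
) -> m.SampleQuant:
    def ct_of(channel: Channel) -> float | None:
        recs = run.records(role=role, channel=channel, sample_id=sample_id)
        return recs[0].ct if recs else None

    q_c = quantify(ct_of(Channel.SHORT_C), fits.short_c_curve).value
    q_long = quantify(ct_of(Channel.LONG_CFREE), fits.long_curve).value
    if role == SampleRole.GDNA:
        q_t = 0.0  # untreated template carries no converted allele
    else:
        q_t = quantify_short_t(
            ct_of(Channel.SHORT_T), fits.transform, fits.short_c_curve
        ).value
    return m.SampleQuant(
        sample_id=sample_id,
        q_short_c=q_c,
        q_short_t=q_t,
        q_long=q_long,
        ipc_ct=ct_of(Channel.IPC),
    )


def evaluate_run(
    run: PlateRun, ipc_threshold: float = m.DEFAULT_IPC_THRESHOLD
) -> EvaluationResult:
    """Run the full evaluation on a (possibly replicated) plate."""
    collapsed = collapse_replicates(run)
    fits = fit_run(collapsed)
    meta = collapsed.metadata

    quants: dict[str, m.SampleQuant] = {}
    for role in (SampleRole.GDNA, SampleRole.BSDNA):
        for sid in collapsed.sample_ids(role):
            quants[sid] = _sample_quant(collapsed, sid, role, fits)

    try:
        ipc_flags = m.ipc_qc(collapsed, threshold=ipc_threshold)
    except m.ConfigurationError:
        ipc_flags = {}

    bs_ids = collapsed.sample_ids(SampleRole.BSDNA)
    if not bs_ids:
        raise MissingRoleError("plate has no BSDNA sample wells")
    results: list[m.BisqueResult] = []
    for bid in bs_ids:
        gid = meta.source_gdna_by_sample.get(bid)
        if gid is None or gid not in quants:
            raise MissingRoleError(
                f"BS-DNA sample {bid!r} has no paired gDNA sample in the run"
            )
        elution = m.ElutionCorrection(
            elution_volume=meta.elution_volume_by_sample.get(bid, m.BASELINE_ELUTION_UL)
        )
        res = m.evaluate_pair(quants[bid], quants[gid], elution)
        flags = set(res.flags)
        if ipc_flags.get(bid) or ipc_flags.get(gid):
            flags.add(m.FLAG_IPC_INHIBITED)
        if not fits.transform.reliable:
            flags.add(FLAG_TRANSFORM_UNRELIABLE)
        results.append(
            m.BisqueResult(
                sample_id=res.sample_id,
                conversion_efficiency=res.conversion_efficiency,
                degradation_level=res.degradation_level,
                recovery=res.recovery,
                flags=frozenset(flags),
            )
        )
    return EvaluationResult(fits=fits, quants=quants, results=results, ipc_flags=ipc_flags)
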