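"""The three conversion-QC metrics, IPC inhibition checks and kit summaries.

Each bisulfite-converted (BS) sample is paired with its untreated source
genomic DNA (gDNA) run in the same assay. From the quantified amounts:

* conversion efficiency (%) = 100 * T / (C + T) over the short amplicon,
* degradation level = (BS short/long ratio) / (gDNA short/long ratio),
* recovery (%) = 100 * 2 * BS short total / gDNA short-C, scaled by the
  elution volume over the 10-ul baseline.

The factor 2 in recovery accounts for only the sense strand of converted
DNA being amplifiable, while both gDNA strands serve as template. Pairing
with the source gDNA normalises individual copy-number variation: scaling
every quantity of a sample pair by a constant leaves degradation level and
recovery unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plate import Channel, PlateRun, SampleRole

__all__ = [
    "SampleQuant",
    "ElutionCorrection",
    "BisqueResult",
    "InvalidPairError",
    "ConfigurationError",
    "conversion_efficiency",
    "degradation_level",
    "recovery",
    "evaluate_pair",
    "ipc_qc",
    "summarize_kits",
    "DEFAULT_IPC_THRESHOLD",
    "FLAG_UNDEFINED_EFFICIENCY",
    "FLAG_INFINITE_DEGRADATION",
    "FLAG_IPC_INHIBITED",
]

#: a sample is flagged as inhibited when its IPC Ct exceeds the run median
#: by more than this many cycles
DEFAULT_IPC_THRESHOLD = 2.0

FLAG_UNDEFINED_EFFICIENCY = "UNDEFINED_EFFICIENCY"
FLAG_INFINITE_DEGRADATION = "INFINITE_DEGRADATION"
FLAG_IPC_INHIBITED = "IPC_INHIBITED"

BASELINE_ELUTION_UL = 10.0


class InvalidPairError(ValueError):
    """The gDNA side of a sample pair carries no usable signal."""


class ConfigurationError(ValueError):
    """The run is missing a channel or mapping the operation needs."""


@dataclass(frozen=True)
class SampleQuant:
    """Per-sample quantities (ng-equivalents per 1-ul reaction).

    gDNA samples have ``q_short_t == 0``: an untreated template carries the
    cytosine allele only, so the T probe yields no signal.
    """

    sample_id: str
    q_short_c: float
    q_short_t: float
    q_long: float
    ipc_ct: float | None = None

    @property
    def q_short_total(self) -> float:
        return self.q_short_c + self.q_short_t


@dataclass(frozen=True)
class ElutionCorrection:
    """Elution-volume correction for recovery.

    A converted sample eluted in 20 ul is twice as dilute per ul as the
    10-ul baseline, so its per-reaction amount under-reports total recovery
    by that factor.
    """

    elution_volume: float = BASELINE_ELUTION_UL
    baseline_volume: float = BASELINE_ELUTION_UL

    @property
    def factor(self) -> float:
        return self.elution_volume / self.baseline_volume


@dataclass(frozen=True)
class BisqueResult:
    """Metrics for one converted sample paired with its source gDNA."""

    sample_id: str
    conversion_efficiency: float  # percent, NaN when undefined
    degradation_level: float      # ratio; +inf for no long-amplicon signal
    recovery: float               # percent
    flags: frozenset[str] = frozenset()


def conversion_efficiency(q_short_c: float, q_short_t: float) -> float:
    """Percent of short-amplicon template carrying the converted (T) allele."""
    total = q_short_c + q_short_t
    if total <= 0:
        raise ValueError("no short-amplicon signal: efficiency undefined")
    return min(100.0, max(0.0, 100.0 * q_short_t / total))


def degradation_level(bs: SampleQuant, g: SampleQuant) -> float:
    """Size-dependent loss during conversion, normalised by the source gDNA.

    Ratio of (short total / long) in the converted sample over
    (short-C / long) in its gDNA; 1.0 means no preferential loss of long
    fragments, > 1 means the converted DNA is degraded.
    """
    if g.q_short_c <= 0 or g.q_long <= 0:
        raise InvalidPairError(
            f"gDNA {g.sample_id!r} lacks short or long signal; cannot normalise"
        )
    g_ratio = g.q_short_c / g.q_long
    if bs.q_long <= 0:
        return math.inf
    return (bs.q_short_total / bs.q_long) / g_ratio


def recovery(
    bs: SampleQuant, g: SampleQuant, elution: ElutionCorrection | None = None
) -> float:
    """Percent of amplifiable input surviving conversion and purification.

    ``100 * 2 * (BS short total / gDNA short-C) * (elution_volume / 10)``.
    The strand factor 2 compensates for only the sense strand of converted
    DNA being amplifiable.
    """
    elution = elution or ElutionCorrection()
    if g.q_short_c <= 0:
        raise InvalidPairError(f"gDNA {g.sample_id!r} has no short-C signal")
    return 100.0 * 2.0 * (bs.q_short_total / g.q_short_c) * elution.factor


def evaluate_pair(
    bs: SampleQuant, g: SampleQuant, elution: ElutionCorrection | None = None
) -> BisqueResult:
    """Compute all three metrics for one BS/gDNA pair, flagging degeneracies."""
    flags: set[str] = set()
    try:
        eff = conversion_efficiency(bs.q_short_c, bs.q_short_t)
    except ValueError:
        eff = math.nan
        flags.add(FLAG_UNDEFINED_EFFICIENCY)
    dl = degradation_level(bs, g)
    if math.isinf(dl):
        flags.add(FLAG_INFINITE_DEGRADATION)
    rec = recovery(bs, g, elution)
    return BisqueResult(
        sample_id=bs.sample_id,
        conversion_efficiency=eff,
        degradation_level=dl,
        recovery=rec,
        flags=frozenset(flags),
    )


def ipc_qc(
    run: PlateRun, threshold: float = DEFAULT_IPC_THRESHOLD
) -> dict[str, bool]:
    """Flag samples whose internal-positive-control Ct signals inhibition.

    Every quantified sample (gDNA and BS-DNA) must carry an IPC channel; a
    sample is flagged when its IPC Ct exceeds the run median IPC Ct by more
    than ``threshold`` cycles, or when its IPC failed to amplify at all.
    """
    sample_roles = (SampleRole.GDNA, SampleRole.BSDNA)
    ipc_ct: dict[str, float | None] = {}
    for role in sample_roles:
        for sid in run.sample_ids(role):
            wells = run.records(role=role, channel=Channel.IPC, sample_id=sid)
            if not wells:
                raise ConfigurationError(f"sample {sid!r} has no IPC channel")
            cts = [w.ct for w in wells if w.ct is not None]
            ipc_ct[sid] = sum(cts) / len(cts) if cts else None
    numeric = [ct for ct in ipc_ct.values() if ct is not None]
    if not numeric:
        raise ConfigurationError("no numeric IPC Ct in the run")
    med = median(numeric)
    return {
        sid: (ct is None or ct > med + threshold) for sid, ct in ipc_ct.items()
    }


def _rank(series: pd.Series, ascending: bool) -> pd.Series:
    return series.rank(ascending=ascending, method="min").astype(int)


def summarize_kits(
    results: Iterable[BisqueResult],
    kit_by_sample: Mapping[str, str],
    qubit_recovery: Mapping[str, float] | None = None,
    statistic: str = "mean",
) -> tuple[pd.DataFrame, float | None]:
    """Per-kit summary table and the qPCR-vs-fluorometric recovery correlation.

    Returns a DataFrame indexed by kit with the chosen per-kit statistic
    (``mean`` by default, ``median`` available) of each metric plus ranks
    (efficiency and recovery: high is rank 1; degradation: low is rank 1),
    and Pearson's r between per-sample qPCR recovery and Qubit recovery when
    fluorometric values are supplied (else ``None``).
    """
    if statistic not in {"mean", "median"}:
        raise ValueError(f"unsupported statistic {statistic!r}")
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "kit": kit_by_sample[r.sample_id],
                "conversion_efficiency_pct": r.conversion_efficiency,
                "degradation_level": r.degradation_level,
                "recovery_pct": r.recovery,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no results to summarise")
    agg = getattr(
        df.groupby("kit")[
            ["conversion_efficiency_pct", "degradation_level", "recovery_pct"]
        ],
        statistic,
    )()
    agg["conversion_rank"] = _rank(agg["conversion_efficiency_pct"], ascending=False)
    agg["degradation_rank"] = _rank(agg["degradation_level"], ascending=True)
    agg["recovery_rank"] = _rank(agg["recovery_pct"], ascending=False)
    agg["n_samples"] = df.groupby("kit").size()

    pearson: float | None = None
    if qubit_recovery is not None:
        paired = df[df["sample_id"].isin(qubit_recovery)]
        if len(paired) >= 2:
            qpcr = paired["recovery_pct"].to_numpy(float)
            qubit = np.array([qubit_recovery[s] for s in paired["sample_id"]], float)
            pearson = float(stats.pearsonr(qpcr, qubit).statistic)
    return agg, pearson
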