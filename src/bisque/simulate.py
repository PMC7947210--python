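"""Molecule-level simulator of the bisulfite-conversion + multiplex qPCR run.

The generative model tracks amplifiable template molecules per sample:

1. Input gDNA (default 50 ng) carries ``locus_copies_per_ng`` double-stranded
   copies of each target locus per ng, scattered lognormally across
   individuals (copy-number variation of the multicopy targets).
2. Conversion fragments DNA: each amplicon survives with probability
   ``(1 - breakage_prob_per_nt)**(length - 1)`` (independent per-nucleotide
   breakage; one break anywhere in the span kills the amplicon), so long
   amplicons are lost preferentially.
3. Purification retains each surviving molecule with ``retention_prob``.
4. The eluate (``elution_volume`` ul) donates a 1-ul aliquot to each
   reaction; template copies per well are Poisson, so low-input stochastic
   effects are representable.
5. Converted molecules are single-stranded and only the sense strand is
   amplifiable: a well with n single-stranded copies reads like n/2
   double-stranded standard copies on the calibration curves.
6. Each short-amplicon molecule is converted at the probe's discriminating
   site with probability ``true_conversion_prob`` (-> T channel), else it
   stays C.

Cts come from per-channel response curves ``ct = slope*log10(copies) + k``
plus Gaussian noise; zero copies, or a Ct beyond ``max_cycles``, is reported
as Undetermined. Standards and C-T indicators are synthesised directly from
the same curves, which is what makes the whole pipeline self-consistent:
the expected estimates equal the closed forms in :func:`expected_metrics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .plate import Channel, PlateRun, RunMetadata, SampleRole, WellRecord

__all__ = [
    "ChannelResponse",
    "SimulationConfig",
    "GroundTruth",
    "simulate_run",
    "expected_metrics",
    "amplicon_survival",
    "breakage_for_degradation_level",
]

#: standard dilution series, ng per 1-ul reaction
STANDARD_AMOUNTS_NG = (10.0, 2.0, 0.4, 0.08, 0.016)
#: indicator dilution series, copies per ul
INDICATOR_COPIES = (1e6, 1e5, 1e4, 1e3)


@dataclass(frozen=True)
class ChannelResponse:
    """Ct response of one channel: ct = slope*log10(copies) + intercept_1copy."""

    slope: float = -3.3219280948873623  # log2(10): perfect doubling
    intercept_1copy: float = 34.5

    def ct(self, copies: float) -> float:
        return self.slope * math.log10(copies) + self.intercept_1copy


def _default_curves() -> dict[Channel, ChannelResponse]:
    # small probe-specific intercept offsets; the C-T transform exists to
    # absorb exactly this kind of channel-to-channel difference
    return {
        Channel.SHORT_C: ChannelResponse(intercept_1copy=34.5),
        Channel.SHORT_T: ChannelResponse(intercept_1copy=34.8),
        Channel.LONG_CFREE: ChannelResponse(intercept_1copy=35.9),
    }


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples: int = 20
    kit: str = "SIM"
    locus_copies_per_ng: float = 1000.0
    copy_cv: float = 0.2  # lognormal CV of per-individual locus copy number
    true_conversion_prob: float = 0.99
    breakage_prob_per_nt: float = 0.003
    retention_prob: float = 0.6
    elution_volume: float = 10.0
    gdna_input_ng: float = 50.0  # mass fed into the conversion reaction
    gdna_conc_ng_per_ul: float = 5.0  # loading of the paired gDNA wells
    short_len: int = 104
    long_len: int = 238
    curve_params: Mapping[Channel, ChannelResponse] = field(
        default_factory=_default_curves
    )
    ct_noise_sd: float = 0.15
    indicator_c_fraction: float = 0.5  # degenerate Y assumed 50% C / 50% T
    ipc_ct: float = 28.0
    max_cycles: float = 40.0
    n_replicates: int = 2
    #: False replaces every molecule-count draw by its expectation, giving the
    #: exact zero-noise limit (useful with ct_noise_sd=0 for analytic checks)
    stochastic_copies: bool = True

    def __post_init__(self):
        for name in (
            "true_conversion_prob",
            "breakage_prob_per_nt",
            "retention_prob",
            "indicator_c_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        if self.short_len <= 0 or self.long_len <= 0:
            raise ValueError("amplicon lengths must be positive")
        if self.elution_volume <= 0:
            raise ValueError("elution volume must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expected metrics implied by a :class:`SimulationConfig`."""

    conversion_efficiency: float  # percent
    degradation_level: float
    recovery: float  # percent


def amplicon_survival(breakage_prob_per_nt: float, length: int) -> float:
    """P(no break within an amplicon of ``length`` nt): (1-p)^(L-1)."""
    return (1.0 - breakage_prob_per_nt) ** (length - 1)


def breakage_for_degradation_level(
    dl: float, short_len: int = 104, long_len: int = 238
) -> float:
    """Per-nt breakage probability that yields a target degradation level.

    Inverts ``dl = (1-p)**(short_len - long_len)``; dl=1 gives p=0.
    """
    if dl < 1.0:
        raise ValueError("this fragmentation model cannot produce dl < 1")
    return 1.0 - dl ** (1.0 / (short_len - long_len))


def expected_metrics(config: SimulationConfig) -> GroundTruth:
    """What an unbiased estimator should report, in closed form.

    * efficiency: 100 * conversion probability;
    * degradation level: survival_short / survival_long
      = (1-p)**(short_len - long_len);
    * recovery: 100 * retention * survival_short. The elution-volume
      correction cancels the per-ul dilution by construction, and the strand
      factor 2 cancels the single-strand signal halving, so neither appears.
    """
    surv_short = amplicon_survival(config.breakage_prob_per_nt, config.short_len)
    surv_long = amplicon_survival(config.breakage_prob_per_nt, config.long_len)
    return GroundTruth(
        conversion_efficiency=100.0 * config.true_conversion_prob,
        degradation_level=surv_short / surv_long,
        recovery=100.0 * config.retention_prob * surv_short,
    )


def _ct_or_none(
    copies: float,
    resp: ChannelResponse,
    rng: np.random.Generator,
    noise_sd: float,
    max_cycles: float,
) -> float | None:
    if copies <= 0:
        return None
    ct = resp.ct(copies) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    if ct > max_cycles or ct <= 0:
        return None
    return ct


class _WellEmitter:
    """Accumulates well records, assigning synthetic well ids."""

    def __init__(self):
        self.wells: list[WellRecord] = []
        self._n = 0

    def emit(
        self,
        sample_id: str,
        role: SampleRole,
        replicate: int,
        cts: Mapping[Channel, float | None],
        known_amount: float | None = None,
    ) -> None:
        self._n += 1
        well_id = f"W{self._n:03d}"
        for channel, ct in cts.items():
            self.wells.append(
                WellRecord(
                    well_id=well_id,
                    sample_id=sample_id,
                    role=role,
                    channel=channel,
                    ct=ct,
                    known_amount=known_amount,
                    replicate=replicate,
                )
            )


def simulate_run(config: SimulationConfig) -> tuple[PlateRun, GroundTruth]:
    """Generate one full plate (standards, indicators, gDNA + BS-DNA wells).

    Deterministic given ``config.seed``. Every well also carries the IPC
    channel. Returns the plate together with the closed-form ground truth
    from :func:`expected_metrics`.
    """
    rng = np.random.default_rng(config.seed)
    em = _WellEmitter()
    curves = dict(config.curve_params)
    nominal = config.locus_copies_per_ng
    sd = config.ct_noise_sd
    maxc = config.max_cycles

    def ipc_ct() -> float | None:
        return _ct_or_none(1.0, ChannelResponse(0.0, config.ipc_ct), rng, sd, maxc)

    # --- standards: known ng of double-stranded genomic calibrator ---------
    for amount_ng in STANDARD_AMOUNTS_NG:
        copies = amount_ng * nominal
        for rep in range(1, config.n_replicates + 1):
            em.emit(
                f"STD_{amount_ng:g}ng",
                SampleRole.STANDARD,
                rep,
                {
                    Channel.SHORT_C: _ct_or_none(
                        copies, curves[Channel.SHORT_C], rng, sd, maxc
                    ),
                    Channel.SHORT_T: None,  # genomic template has no T allele
                    Channel.LONG_CFREE: _ct_or_none(
                        copies, curves[Channel.LONG_CFREE], rng, sd, maxc
                    ),
                    Channel.IPC: ipc_ct(),
                },
                known_amount=amount_ng,
            )

    # --- C-T indicators: single-stranded oligos, Y site split C/T ----------
    cf = config.indicator_c_fraction
    for copies_per_ul in INDICATOR_COPIES:
        c_copies = copies_per_ul * cf / 2.0  # /2: ss signal vs ds calibration
        t_copies = copies_per_ul * (1.0 - cf) / 2.0
        for rep in range(1, config.n_replicates + 1):
            em.emit(
                f"IND_{copies_per_ul:g}",
                SampleRole.CT_INDICATOR,
                rep,
                {
                    Channel.SHORT_C: _ct_or_none(
                        c_copies, curves[Channel.SHORT_C], rng, sd, maxc
                    ),
                    Channel.SHORT_T: _ct_or_none(
                        t_copies, curves[Channel.SHORT_T], rng, sd, maxc
                    ),
                    Channel.LONG_CFREE: None,  # the indicator is a short oligo
                    Channel.IPC: ipc_ct(),
                },
                known_amount=copies_per_ul,
            )

    # --- samples ------------------------------------------------------------
    surv_short = amplicon_survival(config.breakage_prob_per_nt, config.short_len)
    surv_long = amplicon_survival(config.breakage_prob_per_nt, config.long_len)
    sigma = math.sqrt(math.log(1.0 + config.copy_cv**2))
    meta = RunMetadata(run_id=f"sim_seed{config.seed}", max_cycles=maxc)

    if config.stochastic_copies:
        poisson = lambda mean: float(rng.poisson(mean))
        binomial = lambda n, p: float(rng.binomial(int(n), p))
    else:
        poisson = float
        binomial = lambda n, p: float(n) * p

    for i in range(1, config.n_samples + 1):
        gid = f"S{i:02d}"
        bid = f"{gid}_{config.kit}"
        # per-individual copy-number scatter, shared by both loci
        scatter = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
        copies_per_ng = nominal * scatter

        # gDNA wells: double-stranded, loaded at gdna_conc ng/ul, 1 ul/well
        g_mean = config.gdna_conc_ng_per_ul * copies_per_ng
        for rep in range(1, config.n_replicates + 1):
            em.emit(
                gid,
                SampleRole.GDNA,
                rep,
                {
                    Channel.SHORT_C: _ct_or_none(
                        poisson(g_mean), curves[Channel.SHORT_C], rng, sd, maxc
                    ),
                    Channel.SHORT_T: None,
                    Channel.LONG_CFREE: _ct_or_none(
                        poisson(g_mean), curves[Channel.LONG_CFREE], rng, sd, maxc
                    ),
                    Channel.IPC: ipc_ct(),
                },
            )
        meta.gdna_conc_by_sample[gid] = config.gdna_conc_ng_per_ul

        # conversion + purification: thin the sense-strand pools
        n0 = poisson(config.gdna_input_ng * copies_per_ng)
        pool_short = binomial(binomial(n0, surv_short), config.retention_prob)
        n0_long = poisson(config.gdna_input_ng * copies_per_ng)
        pool_long = binomial(binomial(n0_long, surv_long), config.retention_prob)

        for rep in range(1, config.n_replicates + 1):
            # 1-ul aliquot of the eluate into each well
            n_short = poisson(pool_short / config.elution_volume)
            n_t = binomial(n_short, config.true_conversion_prob)
            n_c = n_short - n_t
            n_long = poisson(pool_long / config.elution_volume)
            em.emit(
                bid,
                SampleRole.BSDNA,
                rep,
                {
                    # /2: single-stranded template against ds calibration
                    Channel.SHORT_C: _ct_or_none(
                        n_c / 2.0, curves[Channel.SHORT_C], rng, sd, maxc
                    ),
                    Channel.SHORT_T: _ct_or_none(
                        n_t / 2.0, curves[Channel.SHORT_T], rng, sd, maxc
                    ),
                    Channel.LONG_CFREE: _ct_or_none(
                        n_long / 2.0, curves[Channel.LONG_CFREE], rng, sd, maxc
                    ),
                    Channel.IPC: ipc_ct(),
                },
            )
        meta.elution_volume_by_sample[bid] = config.elution_volume
        meta.source_gdna_by_sample[bid] = gid
        meta.kit_by_sample[bid] = config.kit

    return PlateRun(wells=em.wells, metadata=meta), expected_metrics(config)


def ground_truth_frame(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample ground-truth table (identical rows: truth is config-level)."""
    gt = expected_metrics(config)
    rows = [
        {
            "sample_id": f"S{i:02d}_{config.kit}",
            "true_conversion_efficiency_pct": gt.conversion_efficiency,
            "true_degradation_level": gt.degradation_level,
            "true_recovery_pct": gt.recovery,
        }
        for i in range(1, config.n_samples + 1)
    ]
    return pd.DataFrame(rows)
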