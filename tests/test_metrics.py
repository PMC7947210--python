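"""Conversion efficiency, degradation level, recovery, IPC QC, kit summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisque.metrics import (
    BisqueResult,
    ConfigurationError,
    DEFAULT_IPC_THRESHOLD,
    ElutionCorrection,
    FLAG_UNDEFINED_EFFICIENCY,
    InvalidPairError,
    SampleQuant,
    conversion_efficiency,
    degradation_level,
    evaluate_pair,
    ipc_qc,
    recovery,
    summarize_kits,
)
from bisque.plate import Channel, PlateRun, SampleRole, WellRecord


def sq(sid, c, t, lg, ipc=None):
    return SampleQuant(sample_id=sid, q_short_c=c, q_short_t=t, q_long=lg, ipc_ct=ipc)


class TestConversionEfficiency:
    def test_complete_conversion(self):
        assert conversion_efficiency(0.0, 1.7) == 100.0

    def test_symmetry_gives_half(self):
        assert conversion_efficiency(0.42, 0.42) == pytest.approx(50.0)

    def test_no_signal_is_undefined(self):
        with pytest.raises(ValueError):
            conversion_efficiency(0.0, 0.0)

    @given(
        c=st.floats(0.0, 1e3), t=st.floats(1e-6, 1e3),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_joint_scaling(self, c, t, k):
        base = conversion_efficiency(c, t)
        scaled = conversion_efficiency(c * k, t * k)
        assert scaled == pytest.approx(base, rel=1e-9)
        assert 0.0 <= base <= 100.0


class TestDegradationLevel:
    def test_equal_ratios_give_one(self):
        g = sq("g", 4.0, 0.0, 2.0)
        bs = sq("b", 0.8, 0.2, 0.5)  # short/long = 2.0 in both
        assert degradation_level(bs, g) == pytest.approx(1.0)

    def test_halved_long_doubles_level(self):
        g = sq("g", 4.0, 0.0, 2.0)
        bs = sq("b", 0.8, 0.2, 0.25)
        assert degradation_level(bs, g) == pytest.approx(2.0)

    def test_invariant_under_scaling_one_sample(self):
        g = sq("g", 4.0, 0.0, 2.5)
        bs = sq("b", 0.6, 0.3, 0.4)
        base = degradation_level(bs, g)
        for k in (0.01, 3.0, 250.0):
            scaled = sq("b", 0.6 * k, 0.3 * k, 0.4 * k)
            assert degradation_level(scaled, g) == pytest.approx(base)

    def test_no_long_signal_is_infinite(self):
        g = sq("g", 4.0, 0.0, 2.0)
        assert math.isinf(degradation_level(sq("b", 0.5, 0.5, 0.0), g))

    def test_dead_gdna_is_invalid_pair(self):
        with pytest.raises(InvalidPairError):
            degradation_level(sq("b", 1, 1, 1), sq("g", 0.0, 0.0, 2.0))


class TestRecovery:
    def test_quarter_input_baseline_elution(self):
        g = sq("g", 4.0, 0.0, 2.0)
        bs = sq("b", 0.2, 0.8, 0.5)  # short total = 1.0 = g/4
        assert recovery(bs, g) == pytest.approx(50.0)

    def test_strand_and_elution_doubling(self):
        g = sq("g", 4.0, 0.0, 2.0)
        bs = sq("b", 1.0, 1.0, 0.5)  # short total = g/2
        assert recovery(bs, g, ElutionCorrection(20.0)) == pytest.approx(200.0)

    def test_linear_in_elution_volume(self):
        g = sq("g", 4.0, 0.0, 2.0)
        bs = sq("b", 0.5, 0.5, 0.5)
        r10 = recovery(bs, g, ElutionCorrection(10.0))
        for v in (5.0, 15.0, 40.0):
            assert recovery(bs, g, ElutionCorrection(v)) == pytest.approx(
                r10 * v / 10.0
            )

    def test_copy_number_invariance_of_pair_metrics(self):
        # scaling the locus copy number scales all four quantities of both
        # samples; degradation level and recovery must not move
        g = sq("g", 4.0, 0.0, 2.5)
        bs = sq("b", 0.1, 1.2, 0.4)
        dl0, r0 = degradation_level(bs, g), recovery(bs, g)
        k = 7.3
        gk = sq("g", 4.0 * k, 0.0, 2.5 * k)
        bsk = sq("b", 0.1 * k, 1.2 * k, 0.4 * k)
        assert degradation_level(bsk, gk) == pytest.approx(dl0)
        assert recovery(bsk, gk) == pytest.approx(r0)


def test_evaluate_pair_flags_dead_short_channel():
    g = sq("g", 4.0, 0.0, 2.0)
    res = evaluate_pair(sq("b", 0.0, 0.0, 0.5), g)
    assert math.isnan(res.conversion_efficiency)
    assert FLAG_UNDEFINED_EFFICIENCY in res.flags


def _ipc_run(ipc_cts):
    wells = []
    for i, ct in enumerate(ipc_cts):
        sid = f"S{i}"
        wells.append(
            WellRecord(f"A{i}", sid, SampleRole.GDNA, Channel.IPC, ct)
        )
        wells.append(
            WellRecord(f"A{i}", sid, SampleRole.GDNA, Channel.SHORT_C, 22.0)
        )
    return PlateRun(wells=wells)


class TestIpcQc:
    def test_constant_ipc_no_flags(self):
        flags = ipc_qc(_ipc_run([28.0] * 6))
        assert not any(flags.values())

    def test_elevated_sample_flagged(self):
        flags = ipc_qc(_ipc_run([28.0, 28.1, 27.9, 31.0]), threshold=2.0)
        assert flags["S3"] and not flags["S0"]

    def test_infinite_threshold_never_flags(self):
        flags = ipc_qc(_ipc_run([28.0, 28.1, 40.0]), threshold=math.inf)
        assert not any(flags.values())

    def test_missing_ipc_channel_is_config_error(self):
        run = PlateRun(
            wells=[WellRecord("A1", "S1", SampleRole.GDNA, Channel.SHORT_C, 22.0)]
        )
        with pytest.raises(ConfigurationError):
            ipc_qc(run)


def _result(sid, eff, dl, rec):
    return BisqueResult(sid, eff, dl, rec)


class TestKitSummary:
    def test_single_kit_mean_and_rank(self):
        res = [_result("a", 99.0, 1.2, 40.0), _result("b", 100.0, 1.4, 50.0)]
        table, r = summarize_kits(res, {"a": "K1", "b": "K1"})
        assert table.loc["K1", "conversion_efficiency_pct"] == pytest.approx(99.5)
        assert table.loc["K1", "conversion_rank"] == 1
        assert r is None

    def test_rank_directions(self):
        res = [
            _result("a1", 99.9, 1.5, 50.0), _result("a2", 99.9, 1.5, 50.0),
            _result("b1", 94.0, 0.9, 18.0), _result("b2", 94.0, 0.9, 18.0),
        ]
        kits = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        table, _ = summarize_kits(res, kits)
        # high efficiency/recovery rank first; low degradation ranks first
        assert table.loc["A", "conversion_rank"] == 1
        assert table.loc["A", "recovery_rank"] == 1
        assert table.loc["B", "degradation_rank"] == 1

    def test_self_correlation_is_one(self):
        res = [_result(f"s{i}", 99.0, 1.2, float(20 + i)) for i in range(6)]
        kits = {f"s{i}": "K" for i in range(6)}
        qubit = {f"s{i}": float(20 + i) for i in range(6)}
        _, r = summarize_kits(res, kits, qubit_recovery=qubit)
        assert r == pytest.approx(1.0)

    def test_median_statistic_available(self):
        res = [_result("a", 90.0, 1.0, 10.0), _result("b", 100.0, 2.0, 90.0),
               _result("c", 99.0, 1.5, 20.0)]
        kits = dict.fromkeys(["a", "b", "c"], "K")
        table, _ = summarize_kits(res, kits, statistic="median")
        assert table.loc["K", "recovery_pct"] == pytest.approx(20.0)
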