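"""In-silico conversion, C-free scans, probe scans, in-silico PCR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisque.design import (
    Amplicon,
    MethylationModel,
    ReferenceSeq,
    bisulfite_convert,
    expand_degenerate,
    in_silico_pcr,
    scan_cfree_primers,
    scan_discrimination_probes,
)
from bisque.panel import IPC_ASSAY, LONG_ASSAY, PANEL, SHORT_ASSAY

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def convert_oracle(seq, model):
    """Independent per-base rule application."""
    out = []
    for i, b in enumerate(seq):
        if b == "C":
            cpg = i + 1 < len(seq) and seq[i + 1] == "G"
            keep = model == MethylationModel.CPG_METHYLATED and cpg
            out.append("C" if keep else "T")
        else:
            out.append(b)
    return "".join(out)


class TestBisulfiteConvert:
    def test_lone_c_converts(self):
        assert bisulfite_convert("ACAT", MethylationModel.UNMETHYLATED) == "ATAT"

    def test_cpg_preserved_when_methylated(self):
        assert bisulfite_convert("ACGT", MethylationModel.CPG_METHYLATED) == "ACGT"
        assert bisulfite_convert("ACGT", MethylationModel.UNMETHYLATED) == "ATGT"

    def test_none_model_is_identity(self):
        assert bisulfite_convert("ACGTC", MethylationModel.NONE) == "ACGTC"

    def test_bottom_strand_operates_on_revcomp(self):
        # bottom strand of ACGT is ACGT; of AACC it is GGTT (no C to convert)
        assert bisulfite_convert("AACC", MethylationModel.UNMETHYLATED, "bottom") == "GGTT"
        assert bisulfite_convert("TTGG", MethylationModel.UNMETHYLATED, "bottom") == "TTAA"

    @pytest.mark.parametrize(
        "model", [MethylationModel.UNMETHYLATED, MethylationModel.CPG_METHYLATED]
    )
    def test_matches_per_base_oracle_random_1kb(self, model, rng):
        seq = _random_seq(rng, 1000)
        assert bisulfite_convert(seq, model) == convert_oracle(seq, model)

    @given(dna)
    @settings(max_examples=60, deadline=None)
    def test_unmethylated_conversion_idempotent(self, seq):
        once = bisulfite_convert(seq, MethylationModel.UNMETHYLATED)
        assert "C" not in once
        assert bisulfite_convert(once, MethylationModel.UNMETHYLATED) == once

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            bisulfite_convert("ACGU")


class TestCfreeScan:
    def test_published_short_forward_primer_is_cfree(self):
        assert "C" not in SHORT_ASSAY.forward
        template = "TTTT" + SHORT_ASSAY.forward + "TTTT"
        hits = scan_cfree_primers(template, (len(SHORT_ASSAY.forward),) * 2, "forward")
        assert any(h.sequence == SHORT_ASSAY.forward for h in hits)

    def test_window_with_c_fails_forward_constraint(self):
        hits = scan_cfree_primers("AAACAAA", (7, 7), "forward")
        assert hits == []

    def test_matches_brute_force_on_random_500nt(self, rng):
        seq = _random_seq(rng, 500)
        for orientation, forbidden in (("forward", "C"), ("reverse", "G")):
            hits = scan_cfree_primers(seq, (18, 22), orientation)
            brute = {
                (s, s + L)
                for L in range(18, 23)
                for s in range(0, 500 - L + 1)
                if forbidden not in seq[s : s + L]
            }
            assert {(h.start, h.end) for h in hits} == brute

    def test_reverse_candidates_are_revcomp_of_window(self, rng):
        seq = _random_seq(rng, 300)
        for h in scan_cfree_primers(seq, (18, 20), "reverse"):
            assert h.sequence == _revcomp(seq[h.start : h.end])
            assert "G" not in seq[h.start : h.end]

    def test_cfree_primer_matches_converted_and_unconverted(self, rng):
        # the property that lets one assay quantify gDNA and BS-DNA alike
        seq = _random_seq(rng, 400)
        converted = bisulfite_convert(seq, MethylationModel.UNMETHYLATED)
        fwd = {(h.start, h.end) for h in scan_cfree_primers(seq, (18, 20), "forward")}
        for start, end in fwd:
            assert converted[start:end] == seq[start:end]


class TestProbeScan:
    def test_published_c_probe_has_single_noncpg_c(self):
        probe = SHORT_ASSAY.probes["C"]
        assert probe.count("C") == 1
        i = probe.index("C")
        assert probe[i + 1] != "G"
        hits = scan_discrimination_probes(probe, (len(probe), len(probe)))
        assert len(hits) == 1
        assert hits[0].sequence_c == probe
        assert hits[0].sequence_t == SHORT_ASSAY.probes["T"]

    def test_two_c_window_rejected(self):
        assert scan_discrimination_probes("AACAACAA", (8, 8)) == []

    def test_cpg_context_rejected(self):
        assert scan_discrimination_probes("AAACGAAA", (8, 8)) == []

    def test_matches_brute_force_on_random_sequence(self, rng):
        seq = _random_seq(rng, 500)
        hits = scan_discrimination_probes(seq, (15, 18))
        brute = set()
        for L in range(15, 19):
            for s in range(0, 500 - L + 1):
                w = seq[s : s + L]
                if w.count("C") != 1:
                    continue
                p = s + w.index("C")
                if p + 1 < len(seq) and seq[p + 1] == "G":
                    continue
                brute.add((s, s + L))
        assert {(h.start, h.end) for h in hits} == brute


class TestInSilicoPcr:
    def test_planted_construction_length(self, rng):
        f = _random_seq(rng, 22)
        r = _random_seq(rng, 22)
        template = f + _random_seq(rng, 10) + _revcomp(r)
        products = in_silico_pcr(f, r, template)
        assert len(products) == 1
        assert products[0].length == 54
        assert products[0].sequence == template

    def test_planted_sites_recovered(self, rng):
        f, r = _random_seq(rng, 20), _random_seq(rng, 20)
        insert = f + _random_seq(rng, 60) + _revcomp(r)
        template = _random_seq(rng, 100) + insert + _random_seq(rng, 100) + insert
        products = in_silico_pcr(f, r, template)
        starts = sorted(p.start for p in products)
        # two planted copies plus the long cross product between them
        assert 100 in starts and 100 + len(insert) + 100 in starts
        assert all(p.sequence == template[p.start : p.end] for p in products)

    def test_no_product_is_empty_not_error(self):
        assert in_silico_pcr("AAAA", "TTTT", "GGGGGGGG") == []

    def test_published_primer_pairs_on_synthetic_loci(self, rng):
        # references reconstructed around each published primer pair at the
        # published amplicon size (true genomic context is not distributed)
        for assay in PANEL:
            spacer_len = assay.amplicon_bp - len(assay.forward) - len(assay.reverse)
            locus = (
                _random_seq(rng, 30)
                + assay.forward
                + "A" * spacer_len
                + _revcomp(assay.reverse)
                + _random_seq(rng, 30)
            )
            products = in_silico_pcr(assay.forward, assay.reverse, locus)
            assert [p.length for p in products] == [assay.amplicon_bp]


class TestExpandDegenerate:
    def test_y_expands_to_c_and_t(self):
        assert set(expand_degenerate("AYT")) == {"ACT", "ATT"}

    def test_concrete_sequence_is_singleton(self):
        assert expand_degenerate("ACGT") == ["ACGT"]

    def test_double_y_matches_product(self):
        got = set(expand_degenerate("YY"))
        assert got == {a + b for a in "CT" for b in "CT"}

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            expand_degenerate("N" * 10, cap=1000)

    @given(st.text(alphabet="ACGTYRN", min_size=1, max_size=6))
    @settings(max_examples=40, deadline=None)
    def test_expansion_size_is_code_product(self, seq):
        sizes = {"Y": 2, "R": 2, "N": 4}
        expected = 1
        for b in seq:
            expected *= sizes.get(b, 1)
        out = expand_degenerate(seq)
        assert len(out) == len(set(out)) == expected


def test_published_probe_lengths():
    lengths = [
        len(SHORT_ASSAY.probes["C"]),
        len(SHORT_ASSAY.probes["T"]),
        len(LONG_ASSAY.probes["Cfree"]),
        len(IPC_ASSAY.probes["Probe"]),
    ]
    assert lengths == [19, 19, 21, 21]
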