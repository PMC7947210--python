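"""In-silico bisulfite conversion and cytosine-free assay design.

Bisulfite chemistry deaminates unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine, in practice CpG-context cytosine,
is protected. Primers whose annealing footprint contains no convertible
cytosine bind converted and unconverted template identically, which is what
lets a single assay quantify both genomic and converted DNA:

* forward primers must contain no C on the top strand;
* reverse primers must contain no G (their top-strand annealing target
  carries the convertible Cs as the primer's G complements).

Discrimination probes carry exactly one cytosine, at a non-CpG site, so the
C-version and T-version of the probe differ by that single base and separate
unconverted from converted template.

Coordinates are 0-based, half-open, on the top strand throughout. Amplicon
length spans the forward primer's 5' end through the reverse primer's 5' end
inclusive, matching how amplicon sizes are conventionally reported.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

__all__ = [
    "MethylationModel",
    "PrimerClass",
    "ReferenceSeq",
    "PrimerCandidate",
    "ProbeCandidate",
    "Amplicon",
    "bisulfite_convert",
    "scan_cfree_primers",
    "scan_discrimination_probes",
    "in_silico_pcr",
    "expand_degenerate",
    "melting_temp",
]

_DNA = set("ACGTN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


class MethylationModel(str, enum.Enum):
    """Which cytosines survive conversion.

    UNMETHYLATED   - every C converts (fully unmethylated template)
    CPG_METHYLATED - CpG-context Cs are protected, all others convert
    NONE           - no conversion (identity; the untreated template)
    """

    UNMETHYLATED = "UNMETHYLATED"
    CPG_METHYLATED = "CPG_METHYLATED"
    NONE = "NONE"


class PrimerClass(str, enum.Enum):
    C_FREE_FORWARD = "C_FREE_FORWARD"
    G_FREE_REVERSE = "G_FREE_REVERSE"


@dataclass(frozen=True)
class ReferenceSeq:
    """A named reference sequence over {A,C,G,T,N}, uppercase-normalised."""

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"reference {self.id!r} is empty")
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(
                f"reference {self.id!r} contains non-DNA characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerCandidate:
    """A window satisfying a cytosine-free constraint class.

    ``sequence`` is the primer as synthesised 5'->3' (the reverse complement
    of the top-strand window for reverse primers); ``start``/``end`` are the
    window's top-strand coordinates.
    """

    start: int
    end: int
    orientation: str  # "forward" | "reverse"
    sequence: str
    constraint_class: PrimerClass
    gc_fraction: float
    tm: float


@dataclass(frozen=True)
class ProbeCandidate:
    """A discrimination-probe window: exactly one C, in non-CpG context."""

    start: int
    end: int
    sequence_c: str
    sequence_t: str
    variant_position: int  # offset of the discriminating base within the probe


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def bisulfite_convert(
    seq: ReferenceSeq | str,
    model: MethylationModel = MethylationModel.UNMETHYLATED,
    strand: str = "top",
) -> str:
    """Apply in-silico bisulfite conversion to one strand of a reference.

    Top strand: every C becomes T, except that under ``CPG_METHYLATED`` a C
    immediately followed by G is preserved (an ambiguous N neighbour does not
    protect). Bottom strand: the rule is applied to the reverse complement
    and the result reported in that strand's own 5'->3' orientation.
    ``NONE`` returns the input strand unchanged.
    """
    if strand not in {"top", "bottom"}:
        raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")
    ref = seq if isinstance(seq, ReferenceSeq) else ReferenceSeq("seq", seq)
    s = ref.sequence if strand == "top" else _revcomp(ref.sequence)
    if model == MethylationModel.NONE:
        return s
    out = []
    n = len(s)
    for i, base in enumerate(s):
        if base == "C":
            protected = (
                model == MethylationModel.CPG_METHYLATED
                and i + 1 < n
                and s[i + 1] == "G"
            )
            out.append("C" if protected else "T")
        else:
            out.append(base)
    return "".join(out)


def melting_temp(seq: str) -> float:
    """Quick Tm estimate for ranking: Wallace rule up to 14 nt, GC formula above."""
    if len(seq) <= 14:
        return float(MeltingTemp.Tm_Wallace(seq))
    return float(MeltingTemp.Tm_GC(seq))


def _gc_fraction(seq: str) -> float:
    return sum(b in "GCS" for b in seq) / len(seq)


def scan_cfree_primers(
    seq: ReferenceSeq | str,
    length_range: tuple[int, int] = (18, 27),
    orientation: str = "forward",
) -> list[PrimerCandidate]:
    """Enumerate every window satisfying the cytosine-free primer constraint.

    Exhaustive by design (no heuristic pruning): forward windows with zero C,
    or reverse windows with zero G on the top strand -- each reported as the
    primer actually synthesised (reverse complement for reverse primers) with
    a GC fraction and a rough Tm for ranking.
    """
    if orientation not in {"forward", "reverse"}:
        raise ValueError(f"orientation must be forward|reverse, got {orientation!r}")
    ref = seq if isinstance(seq, ReferenceSeq) else ReferenceSeq("seq", seq)
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad length range {length_range}")
    forbidden = "C" if orientation == "forward" else "G"
    out: list[PrimerCandidate] = []
    s = ref.sequence
    for length in range(lo, hi + 1):
        for start in range(0, len(s) - length + 1):
            window = s[start : start + length]
            if forbidden in window or "N" in window:
                continue
            primer = window if orientation == "forward" else _revcomp(window)
            out.append(
                PrimerCandidate(
                    start=start,
                    end=start + length,
                    orientation=orientation,
                    sequence=primer,
                    constraint_class=(
                        PrimerClass.C_FREE_FORWARD
                        if orientation == "forward"
                        else PrimerClass.G_FREE_REVERSE
                    ),
                    gc_fraction=_gc_fraction(primer),
                    tm=melting_temp(primer),
                )
            )
    return out


def scan_discrimination_probes(
    seq: ReferenceSeq | str, length_range: tuple[int, int] = (15, 25)
) -> list[ProbeCandidate]:
    """Enumerate windows usable as C/T allele-discrimination probes.

    A qualifying window contains exactly one top-strand C, that C is in
    non-CpG context (next top-strand base is not G), and no other C. Both
    allele versions are emitted: the C probe (matches unconverted template)
    and the T probe (matches converted template).
    """
    ref = seq if isinstance(seq, ReferenceSeq) else ReferenceSeq("seq", seq)
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad length range {length_range}")
    s = ref.sequence
    out: list[ProbeCandidate] = []
    for length in range(lo, hi + 1):
        for start in range(0, len(s) - length + 1):
            window = s[start : start + length]
            if "N" in window or window.count("C") != 1:
                continue
            off = window.index("C")
            pos = start + off
            if pos + 1 < len(s) and s[pos + 1] == "G":
                continue  # CpG context: the site is methylation-dependent
            out.append(
                ProbeCandidate(
                    start=start,
                    end=start + length,
                    sequence_c=window,
                    sequence_t=window[:off] + "T" + window[off + 1 :],
                    variant_position=off,
                )
            )
    return out


def in_silico_pcr(
    forward: PrimerCandidate | str,
    reverse: PrimerCandidate | str,
    template: ReferenceSeq | str,
) -> list[Amplicon]:
    """Exact-match PCR product prediction on the top strand.

    Finds every occurrence of the forward primer and, downstream of each, of
    the reverse primer's reverse complement; the product spans the forward
    primer's 5' end through the reverse primer's 5' end inclusive. Multiple
    products are expected for multicopy targets; no product is an empty list,
    not an error. Annealing is exact-match only (no mismatch model).
    """
    fwd = forward.sequence if isinstance(forward, PrimerCandidate) else forward.upper()
    rev = reverse.sequence if isinstance(reverse, PrimerCandidate) else reverse.upper()
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    ref = template if isinstance(template, ReferenceSeq) else ReferenceSeq("t", template)
    s = ref.sequence
    rev_site = _revcomp(rev)
    products: list[Amplicon] = []
    f_start = s.find(fwd)
    while f_start != -1:
        r_start = s.find(rev_site, f_start + len(fwd))
        while r_start != -1:
            end = r_start + len(rev_site)
            products.append(Amplicon(start=f_start, end=end, sequence=s[f_start:end]))
            r_start = s.find(rev_site, r_start + 1)
        f_start = s.find(fwd, f_start + 1)
    return products


def expand_degenerate(seq: str, cap: int = 4096) -> list[str]:
    """Expand IUPAC degenerate codes into every concrete sequence.

    ``Y`` (the indicator's degenerate base) expands to {C, T}. Raises if the
    Cartesian product would exceed ``cap`` sequences.
    """
    seq = seq.upper()
    size = 1
    for base in seq:
        if base not in IUPAC:
            raise ValueError(f"not an IUPAC code: {base!r}")
        size *= len(IUPAC[base])
        if size > cap:
            raise ValueError(f"expansion of {seq!r} exceeds cap of {cap}")
    return ["".join(p) for p in itertools.product(*(IUPAC[b] for b in seq))]
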