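"""The published multiplex primer/probe panel.

Three amplicons are multiplexed: a 104-bp short target and a 238-bp long
target in multicopy intronic regions (cytosine-free primer pairs, so both
genomic and converted DNA amplify), plus a 147-bp synthetic internal
positive control (IPC) spiked into every reaction. The short target carries
two allele-discrimination probes differing at a single non-CpG base (C for
unconverted, T for converted template); the long target's probe is itself
cytosine-free; the IPC primers and probe target a random synthetic sequence
and are under no cytosine constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AssayDef", "SHORT_ASSAY", "LONG_ASSAY", "IPC_ASSAY", "PANEL"]


@dataclass(frozen=True)
class AssayDef:
    name: str
    forward: str
    reverse: str
    amplicon_bp: int
    probes: dict[str, str]  # probe label -> sequence (5'->3')
    cfree: bool  # whether the primer pair obeys the cytosine-free constraints


SHORT_ASSAY = AssayDef(
    name="short",
    forward="GAAATGGTTAAGAGAAAGGGAAA",
    reverse="CCCATTACATTTTTCATCCTCA",
    amplicon_bp=104,
    probes={
        "C": "TGGGTGAATACTTAGAATG",
        "T": "TGGGTGAATATTTAGAATG",
    },
    cfree=True,
)

LONG_ASSAY = AssayDef(
    name="long",
    forward="GGGAAAATGAGGAAGTGATGA",
    reverse="ACACAAAAAACCCTTCAAAAAA",
    amplicon_bp=238,
    probes={
        "Cfree": "AATGTTGTATGTTATTTGTGG",
    },
    cfree=True,
)

IPC_ASSAY = AssayDef(
    name="ipc",
    forward="AACTGCTAGAAAACCGCGTC",
    reverse="GAGGCAGGCTCTTGCTATGT",
    amplicon_bp=147,
    probes={
        "Probe": "TCCAGGCAGTGCGTCTGCTGT",
    },
    cfree=False,
)

PANEL = (SHORT_ASSAY, LONG_ASSAY, IPC_ASSAY)
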