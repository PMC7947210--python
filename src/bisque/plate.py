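"""qPCR plate data model and delimited-text I/O.

A multiplex run is represented as a :class:`PlateRun`: a flat collection of
:class:`WellRecord` objects (one per well *and* dye channel) plus run-level
metadata. Ct values are stored as ``float`` cycles or ``None`` for
"Undetermined" (no amplification within ``max_cycles``).

Plate exports differ between instruments only in their column headers, so
reading is driven by a :class:`PlateSchema` column mapping; the default
mirrors a generic "Sample Name / Target Name / CT" export.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Channel",
    "SampleRole",
    "WellRecord",
    "RunMetadata",
    "PlateRun",
    "PlateSchema",
    "SchemaError",
    "PlateValidationError",
    "read_plate",
    "write_plate",
    "collapse_replicates",
    "FLAG_REPLICATE_DISCORDANT",
    "FLAG_REPLICATE_DROPOUT",
]

#: duplicate wells whose numeric Cts differ by more than this get a warning flag
REPLICATE_DELTA_CT_WARN = 0.5

FLAG_REPLICATE_DISCORDANT = "REPLICATE_DISCORDANT"
FLAG_REPLICATE_DROPOUT = "REPLICATE_DROPOUT"

_METADATA_PREFIX = "#meta"


class Channel(str, enum.Enum):
    """Dye channel of the multiplex assay.

    SHORT_C  - probe for the unconverted (cytosine) allele of the short amplicon
    SHORT_T  - probe for the converted (thymine) allele of the short amplicon
    LONG_CFREE - cytosine-free probe of the long amplicon
    IPC      - internal positive control, present in every well
    """

    SHORT_C = "SHORT_C"
    SHORT_T = "SHORT_T"
    LONG_CFREE = "LONG_CFREE"
    IPC = "IPC"

    @property
    def dye(self) -> str:
        """Reporter dye label conventionally attached to this channel."""
        return _DYES[self]


_DYES = {
    Channel.SHORT_C: "FAM",
    Channel.SHORT_T: "VIC",
    Channel.LONG_CFREE: "NED",
    Channel.IPC: "CY5",
}


class SampleRole(str, enum.Enum):
    """What a well's template is: calibrator, sample, control or blank."""

    STANDARD = "STANDARD"          # genomic standard dilution, known ng/ul
    CT_INDICATOR = "CT_INDICATOR"  # synthetic C/T oligo dilution, known copies/ul
    GDNA = "GDNA"                  # untreated genomic DNA sample
    BSDNA = "BSDNA"                # bisulfite-converted sample
    CONTROL_M = "CONTROL_M"        # converted, methylated reference
    CONTROL_U = "CONTROL_U"        # converted, unmethylated reference
    NTC = "NTC"                    # no-template control


#: roles whose wells carry a known input amount
_CALIBRATOR_ROLES = {SampleRole.STANDARD, SampleRole.CT_INDICATOR}


@dataclass(frozen=True)
class WellRecord:
    """One well/channel observation.

    ``ct`` is ``None`` for "Undetermined"; ``known_amount`` is ng per reaction
    for standards and copies per ul for C-T indicators, ``None`` otherwise.
    """

    well_id: str
    sample_id: str
    role: SampleRole
    channel: Channel
    ct: float | None
    known_amount: float | None = None
    replicate: int = 1
    flags: frozenset[str] = frozenset()

    def is_undetermined(self) -> bool:
        return self.ct is None


@dataclass
class RunMetadata:
    """Run-level context that does not live in the well table."""

    run_id: str = "run"
    max_cycles: float = 40.0
    #: elution volume (ul) of each converted sample; baseline is 10 ul
    elution_volume_by_sample: dict[str, float] = field(default_factory=dict)
    #: concentration (ng/ul) at which each gDNA sample was loaded
    gdna_conc_by_sample: dict[str, float] = field(default_factory=dict)
    #: BS-DNA sample id -> its source gDNA sample id
    source_gdna_by_sample: dict[str, str] = field(default_factory=dict)
    #: sample id -> conversion-kit label (for per-kit summaries)
    kit_by_sample: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "run_id": self.run_id,
                "max_cycles": self.max_cycles,
                "elution_volume_by_sample": self.elution_volume_by_sample,
                "gdna_conc_by_sample": self.gdna_conc_by_sample,
                "source_gdna_by_sample": self.source_gdna_by_sample,
                "kit_by_sample": self.kit_by_sample,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunMetadata":
        return cls(**json.loads(text))


@dataclass
class PlateRun:
    """A parsed plate: well records plus run metadata."""

    wells: list[WellRecord]
    metadata: RunMetadata = field(default_factory=RunMetadata)

    def records(
        self,
        role: SampleRole | None = None,
        channel: Channel | None = None,
        sample_id: str | None = None,
    ) -> list[WellRecord]:
        """Filter wells by role/channel/sample."""
        out = self.wells
        if role is not None:
            out = [w for w in out if w.role == role]
        if channel is not None:
            out = [w for w in out if w.channel == channel]
        if sample_id is not None:
            out = [w for w in out if w.sample_id == sample_id]
        return out

    def sample_ids(self, role: SampleRole) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            if w.role == role:
                seen.setdefault(w.sample_id)
        return list(seen)


@dataclass(frozen=True)
class PlateSchema:
    """Column-name mapping from an instrument export to the data model."""

    well: str = "Well"
    sample: str = "Sample Name"
    role: str = "Role"
    channel: str = "Target Name"
    ct: str = "CT"
    amount: str = "Quantity"
    replicate: str = "Replicate"

    def required(self) -> tuple[str, ...]:
        return (self.well, self.sample, self.role, self.channel, self.ct)


class SchemaError(ValueError):
    """A mapped column is absent from the export."""


class PlateValidationError(ValueError):
    """A well record violates the plate invariants."""


def _parse_ct(raw, max_cycles: float, well_id: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() == "undetermined":
        return None
    try:
        ct = float(text)
    except ValueError as exc:
        raise PlateValidationError(f"well {well_id!r}: unparseable Ct {raw!r}") from exc
    if not 0.0 < ct <= max_cycles:
        raise PlateValidationError(
            f"well {well_id!r}: Ct {ct} outside (0, {max_cycles}]"
        )
    return ct


def _parse_amount(raw) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    return float(text)


def read_plate(
    path: str | Path,
    schema: PlateSchema | None = None,
    metadata: RunMetadata | None = None,
) -> PlateRun:
    """Read a delimited plate export into a validated :class:`PlateRun`.

    The delimiter is sniffed (comma or tab). Lines starting with ``#meta``
    carry run metadata as JSON and take effect unless ``metadata`` is given
    explicitly. "Undetermined" (case-insensitive) or empty Ct cells parse to
    ``None``.
    """
    schema = schema or PlateSchema()
    path = Path(path)
    file_meta: RunMetadata | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(_METADATA_PREFIX):
                file_meta = RunMetadata.from_json(line[len(_METADATA_PREFIX):].strip())
            elif line.strip():
                break
    meta = metadata or file_meta or RunMetadata(run_id=path.stem)

    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    for col in schema.required():
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")

    wells: list[WellRecord] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        well_id = str(row[schema.well]).strip()
        channel = Channel(str(row[schema.channel]).strip())
        key = (well_id, channel.value)
        if key in seen:
            raise PlateValidationError(
                f"duplicate record for well {well_id!r}, channel {channel.value}"
            )
        seen.add(key)
        amount = None
        if schema.amount in df.columns:
            amount = _parse_amount(row[schema.amount])
        rep = 1
        if schema.replicate in df.columns and not pd.isna(row[schema.replicate]):
            rep = int(float(row[schema.replicate]))
        wells.append(
            WellRecord(
                well_id=well_id,
                sample_id=str(row[schema.sample]).strip(),
                role=SampleRole(str(row[schema.role]).strip()),
                channel=channel,
                ct=_parse_ct(row[schema.ct], meta.max_cycles, well_id),
                known_amount=amount,
                replicate=rep,
            )
        )
    return PlateRun(wells=wells, metadata=meta)


def write_plate(run: PlateRun, path: str | Path, schema: PlateSchema | None = None) -> None:
    """Write a plate back to delimited text (TSV for .tsv, else CSV).

    Metadata is embedded as a ``#meta`` JSON header so the file round-trips
    through :func:`read_plate` without sidecar files.
    """
    schema = schema or PlateSchema()
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = []
    for w in run.wells:
        rows.append(
            {
                schema.well: w.well_id,
                schema.sample: w.sample_id,
                schema.role: w.role.value,
                schema.channel: w.channel.value,
                schema.ct: "Undetermined" if w.ct is None else repr(w.ct),
                schema.amount: "" if w.known_amount is None else repr(w.known_amount),
                schema.replicate: w.replicate,
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_METADATA_PREFIX} {run.metadata.to_json()}\n")
        df.to_csv(fh, sep=sep, index=False)


def collapse_replicates(run: PlateRun) -> PlateRun:
    """Average duplicate wells into one record per (sample, channel).

    The collapsed Ct is the arithmetic mean of the numeric replicate Cts.
    If every replicate is undetermined the result is undetermined. A mixed
    group (some undetermined, some numeric) keeps the numeric mean and is
    flagged ``REPLICATE_DROPOUT`` -- discarding it would silently lose
    low-copy samples. Numeric duplicates spanning more than
    ``REPLICATE_DELTA_CT_WARN`` cycles are flagged ``REPLICATE_DISCORDANT``.
    Idempotent: collapsing a collapsed run is the identity.
    """
    groups: dict[tuple[str, str, str], list[WellRecord]] = {}
    order: list[tuple[str, str, str]] = []
    for w in run.wells:
        key = (w.sample_id, w.role.value, w.channel.value)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(w)

    collapsed: list[WellRecord] = []
    for key in order:
        members = groups[key]
        cts = [w.ct for w in members if w.ct is not None]
        flags: set[str] = set()
        for w in members:
            flags |= w.flags
        if not cts:
            ct: float | None = None
        else:
            ct = sum(cts) / len(cts)
            if len(cts) < len(members):
                flags.add(FLAG_REPLICATE_DROPOUT)
            if len(cts) >= 2 and (max(cts) - min(cts)) > REPLICATE_DELTA_CT_WARN:
                flags.add(FLAG_REPLICATE_DISCORDANT)
        first = members[0]
        amounts = [w.known_amount for w in members if w.known_amount is not None]
        collapsed.append(
            replace(
                first,
                well_id="+".join(w.well_id for w in members),
                ct=ct,
                known_amount=amounts[0] if amounts else None,
                replicate=1,
                flags=frozenset(flags),
            )
        )
    return PlateRun(wells=collapsed, metadata=run.metadata)
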