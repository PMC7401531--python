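"""Reading and writing RCC (reporter code count) lane files.

RCC is the per-lane CSV-dialect export of the nCounter digital analyzer:
sections delimited by ``<SectionName>`` / ``</SectionName>`` tags, each
holding comma-separated ``key,value`` lines, plus a ``Code_Summary`` table
of ``CodeClass,Name,Accession,Count`` rows.  One file describes one
cartridge lane / one hybridised sample.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .codeset import CodeSet, RCC_CODECLASS
from .errors import ConsistencyError, RCCFormatError

REQUIRED_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes",
                     "Code_Summary")


@dataclass
class LaneAttributes:
    """Per-lane instrument attributes recorded in the RCC export.

    ``binding_density`` is reporter probe spots per square micron of lane
    surface, as recorded by the instrument; ``fov_requested`` /
    ``fov_counted`` are the imaging fields of view requested and
    successfully counted.
    """

    lane_id: str
    fov_requested: int
    fov_counted: int
    binding_density: float
    cartridge_id: str = ""

    def __post_init__(self):
        if self.fov_requested <= 0:
            raise ValueError("fov_requested must be positive")
        if self.fov_counted < 0 or self.fov_counted > self.fov_requested:
            raise ValueError("fov_counted must be in [0, fov_requested]")
        if self.binding_density < 0:
            raise ValueError("binding_density must be non-negative")


@dataclass
class LaneCounts:
    """Raw probe counts for one lane, keyed by probe name."""

    sample_id: str
    attributes: LaneAttributes
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for probe, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for probe {probe}")

    def validate_against(self, codeset: CodeSet) -> None:
        known = set(codeset.names())
        unknown = set(self.counts) - known
        if unknown:
            raise ConsistencyError(
                f"lane {self.sample_id}: counts for probes not in codeset "
                f"{codeset.name}: {sorted(unknown)}"
            )


def _parse_sections(stream: io.TextIOBase) -> dict[str, list[tuple[int, str]]]:
    """Split an RCC stream into sections of (line_number, line) pairs."""
    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append((lineno, line))
    return sections


def read_rcc(stream: str | io.TextIOBase) -> LaneCounts:
    """Parse an RCC stream into a :class:`LaneCounts`.

    Raises :class:`RCCFormatError` naming the first missing required
    section, and :class:`ValueError` with a line number for a non-integer
    count.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    sections = _parse_sections(stream)
    for sec in REQUIRED_SECTIONS:
        if sec not in sections:
            raise RCCFormatError(f"missing RCC section: {sec}")

    def kv(section):
        out = {}
        for _, line in sections[section]:
            key, _, value = line.partition(",")
            out[key] = value
        return out

    sample = kv("Sample_Attributes")
    lane = kv("Lane_Attributes")
    try:
        attrs = LaneAttributes(
            lane_id=lane.get("ID", ""),
            fov_requested=int(lane["FovCount"]),
            fov_counted=int(lane["FovCounted"]),
            binding_density=float(lane["BindingDensity"]),
            cartridge_id=lane.get("CartridgeID", ""),
        )
    except KeyError as exc:
        raise RCCFormatError(f"Lane_Attributes missing key {exc}") from exc

    counts: dict[str, int] = {}
    rows = sections["Code_Summary"]
    body = rows[1:] if rows and rows[0][1].startswith("CodeClass,") else rows
    for lineno, line in body:
        parts = line.split(",")
        if len(parts) != 4:
            raise RCCFormatError(
                f"line {lineno}: Code_Summary row needs 4 fields, got "
                f"{len(parts)}"
            )
        _, name, _, count = parts
        try:
            counts[name] = int(count)
        except ValueError:
            raise ValueError(
                f"line {lineno}: non-integer count {count!r} for probe "
                f"{name}"
            ) from None
    return LaneCounts(
        sample_id=sample.get("ID", ""), attributes=attrs, counts=counts
    )


def write_rcc(lane: LaneCounts, codeset: CodeSet) -> str:
    """Serialize a lane to RCC text; probes in codeset order.

    Inverse of :func:`read_rcc` for canonical field ordering; probes absent
    from ``lane.counts`` are written with count 0.
    """
    lane.validate_against(codeset)
    a = lane.attributes
    out = [
        "<Header>",
        "FileVersion,1.7",
        "SoftwareVersion,rccpipe",
        "</Header>",
        "<Sample_Attributes>",
        f"ID,{lane.sample_id}",
        "</Sample_Attributes>",
        "<Lane_Attributes>",
        f"ID,{a.lane_id}",
        f"FovCount,{a.fov_requested}",
        f"FovCounted,{a.fov_counted}",
        f"BindingDensity,{a.binding_density!r}",
        f"CartridgeID,{a.cartridge_id}",
        "</Lane_Attributes>",
        "<Code_Summary>",
        "CodeClass,Name,Accession,Count",
    ]
    for probe in codeset:
        out.append(
            f"{RCC_CODECLASS[probe.probe_class]},{probe.name},"
            f"{probe.accession},{lane.counts.get(probe.name, 0)}"
        )
    out.append("</Code_Summary>")
    return "\n".join(out) + "\n"
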