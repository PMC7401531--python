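"""Probe panel (CodeSet) definitions and loading.

A CodeSet is the panel of capture/reporter probe pairs carried by a single
nCounter assay: endogenous genes of interest, reference (housekeeping)
genes, and spike-in positive/negative control probes.  The packaged fixture
is a 15-gene bovine leukocyte cytokine / neuroactive ligand-receptor panel
(12 endogenous + 3 reference genes: GAPDH, GUSB, YWHAZ) together with the
standard 6-probe positive-control ladder (POS_A..POS_F at 128, 32, 8, 2,
0.5, 0.125 fM; POS_E marks the nominal limit of detection) and 6 negative
control probes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .errors import ConsistencyError

PROBE_CLASSES = ("endogenous", "reference", "positive", "negative")

#: CodeClass labels used in RCC Code_Summary sections, by probe class.
RCC_CODECLASS = {
    "endogenous": "Endogenous",
    "reference": "Housekeeping",
    "positive": "Positive",
    "negative": "Negative",
}
_RCC_CODECLASS_INV = {v: k for k, v in RCC_CODECLASS.items()}


@dataclass(frozen=True)
class ProbeDef:
    """A single probe-pair definition.

    ``target_start``/``target_end`` are the 1-based inclusive coordinates of
    the 100-nt target region on the accession; control probes carry no
    target interval.  ``concentration_fM`` is the spike-in concentration and
    is positive exactly for positive-control probes.
    """

    name: str
    probe_class: str
    accession: str = ""
    target_start: Optional[int] = None
    target_end: Optional[int] = None
    concentration_fM: float = 0.0
    category: str = ""

    def __post_init__(self):
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {self.probe_class!r}")
        if self.target_start is not None and self.target_end is not None:
            if self.target_end < self.target_start:
                raise ValueError(
                    f"probe {self.name}: target_end < target_start"
                )
        if self.concentration_fM < 0:
            raise ValueError(f"probe {self.name}: negative concentration")
        if (self.concentration_fM > 0) != (self.probe_class == "positive"):
            raise ValueError(
                f"probe {self.name}: concentration_fM > 0 must hold exactly "
                "for positive-control probes"
            )

    @property
    def target_length(self) -> Optional[int]:
        """Inclusive length of the target interval, or None for controls."""
        if self.target_start is None or self.target_end is None:
            return None
        return self.target_end - self.target_start + 1


@dataclass
class CodeSet:
    """An ordered probe panel with unique probe names."""

    name: str
    probes: list[ProbeDef] = field(default_factory=list)

    def __post_init__(self):
        names = [p.name for p in self.probes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConsistencyError(
                f"duplicate probe names in codeset: {sorted(dupes)}"
            )

    def __iter__(self):
        return iter(self.probes)

    def __len__(self):
        return len(self.probes)

    def __getitem__(self, probe_name: str) -> ProbeDef:
        for p in self.probes:
            if p.name == probe_name:
                return p
        raise KeyError(probe_name)

    def by_class(self, probe_class: str) -> list[ProbeDef]:
        return [p for p in self.probes if p.probe_class == probe_class]

    def names(self, probe_class: Optional[str] = None) -> list[str]:
        if probe_class is None:
            return [p.name for p in self.probes]
        return [p.name for p in self.by_class(probe_class)]

    @property
    def endogenous(self) -> list[str]:
        return self.names("endogenous")

    @property
    def reference(self) -> list[str]:
        return self.names("reference")

    @property
    def positives(self) -> list[ProbeDef]:
        return self.by_class("positive")

    @property
    def negatives(self) -> list[ProbeDef]:
        return self.by_class("negative")

    @property
    def gene_probes(self) -> list[ProbeDef]:
        """Endogenous plus reference probes (the assayed genes)."""
        return [p for p in self.probes
                if p.probe_class in ("endogenous", "reference")]


def load_codeset(table: str | io.TextIOBase, name: str = "codeset") -> CodeSet:
    """Parse a delimited codeset table into a :class:`CodeSet`.

    The table must be tab- or comma-delimited with a header row naming at
    least ``name``, ``probe_class``, ``accession``, ``target_start``,
    ``target_end``; optional columns ``concentration_fM`` and ``category``.
    """
    if isinstance(table, str):
        table = io.StringIO(table)
    sample = table.read(2048)
    table.seek(0)
    delim = "\t" if "\t" in sample.splitlines()[0] else ","
    reader = csv.DictReader(table, delimiter=delim)
    probes = []
    for i, row in enumerate(reader, start=2):
        try:
            start = row.get("target_start") or None
            end = row.get("target_end") or None
            probes.append(ProbeDef(
                name=row["name"].strip(),
                probe_class=row["probe_class"].strip(),
                accession=(row.get("accession") or "").strip(),
                target_start=int(start) if start is not None else None,
                target_end=int(end) if end is not None else None,
                concentration_fM=float(row.get("concentration_fM") or 0.0),
                category=(row.get("category") or "").strip(),
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"codeset line {i}: {exc}") from exc
    return CodeSet(name=name, probes=probes)


def codeset_to_tsv(codeset: CodeSet) -> str:
    """Serialize a codeset to the delimited form :func:`load_codeset` reads."""
    lines = ["name\tprobe_class\tcategory\taccession\ttarget_start\t"
             "target_end\tconcentration_fM"]
    for p in codeset:
        start = "" if p.target_start is None else str(p.target_start)
        end = "" if p.target_end is None else str(p.target_end)
        conc = f"{p.concentration_fM:g}"
        lines.append(f"{p.name}\t{p.probe_class}\t{p.category}\t"
                     f"{p.accession}\t{start}\t{end}\t{conc}")
    return "\n".join(lines) + "\n"


def default_panel() -> CodeSet:
    """The packaged bovine cytokine / neuroactive-ligand panel plus controls."""
    text = (resources.files("rccpipe") / "data" / "codeset_panel.tsv").read_text()
    return load_codeset(text, name="bovine_cytokine_panel")
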