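"""Study design and assembled run sets.

A RunSet joins the raw lanes of one experiment to its codeset and to the
study design (which animal, which group, which sampling time each lane
belongs to).  The motivating design is a randomised controlled trial:
16 animals in two groups of 8 (control vs treatment), sampled just
before an intervention and 4 and 24 h after it, i.e. 48 lanes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .codeset import CodeSet
from .errors import ConsistencyError, JoinError
from .io import LaneCounts

GROUPS = ("control", "treatment")


@dataclass
class StudyDesign:
    """Mapping sample -> (animal, group, time in hours).

    Each animal belongs to exactly one group and is measured at most once
    per time point.
    """

    rows: pd.DataFrame  # columns: sample_id, animal_id, group, time_h

    def __post_init__(self):
        required = {"sample_id", "animal_id", "group", "time_h"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ConsistencyError(f"design missing columns: {sorted(missing)}")
        df = self.rows.copy()
        df["time_h"] = df["time_h"].astype(float)
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ConsistencyError(f"unknown groups: {sorted(bad_groups)}")
        if df.duplicated(["animal_id", "time_h"]).any():
            raise ConsistencyError("duplicate (animal_id, time_h) pairs")
        if df.duplicated("sample_id").any():
            raise ConsistencyError("duplicate sample_id")
        ngroups = df.groupby("animal_id")["group"].nunique()
        if (ngroups > 1).any():
            raise ConsistencyError(
                "animals in more than one group: "
                f"{list(ngroups[ngroups > 1].index)}"
            )
        self.rows = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, source: str | io.TextIOBase) -> "StudyDesign":
        return cls(pd.read_csv(source, dtype={"sample_id": str,
                                              "animal_id": str}))

    def to_csv(self) -> str:
        return self.rows.to_csv(index=False)

    def __len__(self):
        return len(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows["sample_id"])

    @property
    def animals(self) -> list[str]:
        return sorted(self.rows["animal_id"].unique())

    @property
    def times(self) -> list[float]:
        return sorted(self.rows["time_h"].unique())

    def row_for(self, sample_id: str) -> pd.Series:
        hit = self.rows[self.rows["sample_id"] == sample_id]
        if hit.empty:
            raise KeyError(sample_id)
        return hit.iloc[0]


@dataclass
class RunSet:
    """Codeset + lanes + design, validated and deterministically ordered."""

    codeset: CodeSet
    lanes: list[LaneCounts] = field(default_factory=list)
    design: StudyDesign = None

    def lane_for(self, sample_id: str) -> LaneCounts:
        for lane in self.lanes:
            if lane.sample_id == sample_id:
                return lane
        raise KeyError(sample_id)

    def counts_frame(self) -> pd.DataFrame:
        """Raw counts as a probes x samples DataFrame in codeset order."""
        probes = self.codeset.names()
        data = {
            lane.sample_id: [lane.counts.get(p, 0) for p in probes]
            for lane in self.lanes
        }
        return pd.DataFrame(data, index=probes)

    def subset(self, sample_ids) -> "RunSet":
        keep = set(sample_ids)
        lanes = [l for l in self.lanes if l.sample_id in keep]
        design = StudyDesign(
            self.design.rows[self.design.rows["sample_id"].isin(keep)]
        )
        return RunSet(codeset=self.codeset, lanes=lanes, design=design)


def assemble_runset(lanes, codeset: CodeSet, design: StudyDesign) -> RunSet:
    """Validate and join lanes to the design; lanes sorted by (animal, time).

    Order-insensitive in its lane input: any permutation of ``lanes`` yields
    an identical RunSet.  Lanes whose sample_id has no design row raise a
    :class:`JoinError` listing every orphan.
    """
    lanes = list(lanes)
    for lane in lanes:
        lane.validate_against(codeset)
    known = set(design.sample_ids)
    orphans = [l.sample_id for l in lanes if l.sample_id not in known]
    if orphans:
        raise JoinError(sorted(orphans))
    seen = [l.sample_id for l in lanes]
    if len(set(seen)) != len(seen):
        raise ConsistencyError("duplicate lanes for the same sample_id")

    def key(lane):
        row = design.row_for(lane.sample_id)
        return (str(row["animal_id"]), float(row["time_h"]))

    lanes.sort(key=key)
    present = {l.sample_id for l in lanes}
    design = StudyDesign(
        design.rows[design.rows["sample_id"].isin(present)]
    )
    return RunSet(codeset=codeset, lanes=lanes, design=design)
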