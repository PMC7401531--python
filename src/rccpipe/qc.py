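"""Lane quality control.

The four default lane checks of the nCounter workflow:

* imaging: percentage of requested fields of view successfully counted;
  a lane fails strictly below 75%.
* binding density: reporter spots per square micron must lie inside
  [0.1, 2.25] (saturation above, underloading below).
* positive-control linearity: squared Pearson correlation between
  log2(count + 1) and log2 spike-in concentration over the positive-control
  ladder; fails strictly below 0.95.
* limit of detection: the 0.5 fM POS_E probe must exceed
  mean + k*SD (default k = 2, sample SD) of the negative-control counts.

Failing lanes are flagged, never removed here; dropping them is a
normalization-stage option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codeset import CodeSet
from .errors import InsufficientDataError
from .io import LaneAttributes, LaneCounts
from .runset import RunSet

LOD_PROBE = "POS_E"


@dataclass(frozen=True)
class QCThresholds:
    """Default thresholds mirror the platform's default QC settings."""

    fov_pct_min: float = 75.0
    binding_density_min: float = 0.1
    binding_density_max: float = 2.25
    linearity_min: float = 0.95
    lod_sd_multiplier: float = 2.0

    def __post_init__(self):
        if not 0 < self.fov_pct_min <= 100:
            raise ValueError("fov_pct_min must be in (0, 100]")
        if not self.binding_density_min < self.binding_density_max:
            raise ValueError("binding density bounds out of order")
        if not 0 < self.linearity_min <= 1:
            raise ValueError("linearity_min must be in (0, 1]")
        if self.lod_sd_multiplier < 0:
            raise ValueError("lod_sd_multiplier must be >= 0")


FLAG_COLUMNS = ["fov_pass", "binding_density_pass", "linearity_pass",
                "lod_pass"]


@dataclass
class QCReport:
    """Per-lane QC metrics and pass/fail flags."""

    table: pd.DataFrame  # indexed by sample_id
    thresholds: QCThresholds

    @property
    def passing(self) -> list[str]:
        return list(self.table.index[self.table["overall_pass"]])

    @property
    def failing(self) -> list[str]:
        return list(self.table.index[~self.table["overall_pass"]])

    def to_csv(self) -> str:
        return self.table.to_csv(index_label="sample_id")

    def log_lines(self) -> list[str]:
        lines = []
        for sid, row in self.table.iterrows():
            status = "PASS" if row["overall_pass"] else "FAIL"
            lines.append(
                f"qc lane={sid} fov_pct={row['fov_pct']:.2f} "
                f"bd={row['binding_density']:.4f} "
                f"r2={row['linearity_r2']:.4f} "
                f"lod_margin={row['lod_margin']:.2f} {status}"
            )
        return lines


def imaging_qc(attrs: LaneAttributes,
               thresholds: QCThresholds = QCThresholds()):
    """Percentage of requested FOV counted; fail strictly below threshold."""
    if attrs.fov_requested <= 0:
        raise ValueError("fov_requested must be positive")
    fov_pct = 100.0 * attrs.fov_counted / attrs.fov_requested
    return fov_pct, fov_pct >= thresholds.fov_pct_min


def binding_density_qc(attrs: LaneAttributes,
                       thresholds: QCThresholds = QCThresholds()) -> bool:
    """Pass iff binding density lies in the closed acceptance interval."""
    return (thresholds.binding_density_min
            <= attrs.binding_density
            <= thresholds.binding_density_max)


def linearity_qc(lane: LaneCounts, codeset: CodeSet,
                 thresholds: QCThresholds = QCThresholds()):
    """R^2 of log2(count+1) against log2 concentration over positives."""
    positives = codeset.positives
    concs = {p.concentration_fM for p in positives}
    if len(concs) < 3:
        raise InsufficientDataError(
            "linearity QC needs >= 3 positive probes with distinct "
            "concentrations"
        )
    x = np.log2([p.concentration_fM for p in positives])
    y = np.log2([lane.counts.get(p.name, 0) + 1.0 for p in positives])
    if np.ptp(y) == 0:  # zero variance: no correlation with the ladder
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return r2, r2 >= thresholds.linearity_min


def lod_qc(lane: LaneCounts, codeset: CodeSet,
           thresholds: QCThresholds = QCThresholds()):
    """Margin of the 0.5 fM positive probe over the negative-control cutoff.

    cutoff = mean(neg) + k * SD(neg) with sample (n-1) SD; the lane passes
    only on strict exceedance (margin > 0).
    """
    negatives = codeset.negatives
    if len(negatives) < 2:
        raise InsufficientDataError("LOD QC needs >= 2 negative probes")
    if LOD_PROBE not in lane.counts:
        raise InsufficientDataError(f"LOD QC needs the {LOD_PROBE} probe")
    neg = np.array([lane.counts.get(p.name, 0) for p in negatives], float)
    cutoff = neg.mean() + thresholds.lod_sd_multiplier * neg.std(ddof=1)
    margin = float(lane.counts[LOD_PROBE] - cutoff)
    return margin, margin > 0


def run_qc(runset: RunSet,
           thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Apply all four checks to every lane; flags, never removes."""
    records = []
    for lane in runset.lanes:
        try:
            fov_pct, fov_pass = imaging_qc(lane.attributes, thresholds)
            bd_pass = binding_density_qc(lane.attributes, thresholds)
            r2, lin_pass = linearity_qc(lane, runset.codeset, thresholds)
            margin, lod_pass = lod_qc(lane, runset.codeset, thresholds)
        except (ValueError, InsufficientDataError) as exc:
            raise type(exc)(f"lane {lane.sample_id}: {exc}") from exc
        records.append({
            "sample_id": lane.sample_id,
            "fov_pct": fov_pct,
            "binding_density": lane.attributes.binding_density,
            "linearity_r2": r2,
            "lod_margin": margin,
            "fov_pass": fov_pass,
            "binding_density_pass": bd_pass,
            "linearity_pass": lin_pass,
            "lod_pass": lod_pass,
            "overall_pass": fov_pass and bd_pass and lin_pass and lod_pass,
        })
    columns = ["sample_id", "fov_pct", "binding_density", "linearity_r2",
               "lod_margin", *FLAG_COLUMNS, "overall_pass"]
    table = pd.DataFrame(records, columns=columns)
    table = table.set_index("sample_id")
    return QCReport(table=table, thresholds=thresholds)
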