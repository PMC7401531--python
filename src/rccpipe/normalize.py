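"""Three-step count normalization.

Order is fixed: (1) background minimisation — subtract, per lane, the
highest negative-control count plus two sample SDs of the negatives from
every gene probe, clamping at zero; (2) positive-control normalization —
scale each lane by (arithmetic mean over lanes of per-lane geometric means
of the raw positive-control counts) / (this lane's geometric mean);
(3) biological normalization — the same mean-of-geometric-means
construction on the three reference genes (GAPDH, GUSB, YWHAZ), computed
on background-subtracted, positive-normalized values.

After step (3) the geometric mean of the reference genes is identical in
every lane, so per-lane technical scale differences are absorbed up to a
single global factor shared by all lanes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, PipelineOrderError, RCCPipeError
from .qc import QCThresholds, run_qc
from .runset import RunSet

STAGES = ("raw", "background_subtracted", "positive_normalized",
          "fully_normalized")


@dataclass
class NormalizationFactors:
    """Per-lane background cutoffs and scale factors, recorded as applied."""

    table: pd.DataFrame  # index sample_id; background_cutoff,
    #                      positive_factor, reference_factor

    def to_csv(self) -> str:
        return self.table.to_csv(index_label="sample_id")


@dataclass
class NormalizeOptions:
    drop_qc_failures: bool = False
    #: "max" implements highest-negative + 2 SD; "mean" the mean + 2 SD
    #: variant some workflows use instead.
    background_summary: str = "max"
    background_sd_multiplier: float = 2.0


@dataclass
class ExpressionMatrix:
    """Gene probes x samples matrix with a pipeline stage tag.

    Rows cover endogenous and reference probes; ``endogenous_values`` gives
    the genes-of-interest view used for modelling.
    """

    values: pd.DataFrame
    stage: str = "raw"
    factors: Optional[NormalizationFactors] = None
    endogenous_genes: list[str] = field(default_factory=list)
    reference_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        v = self.values.to_numpy(float)
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("expression values must be finite and >= 0")

    def _require_stage(self, expected: str, op: str) -> None:
        if self.stage != expected:
            raise PipelineOrderError(
                f"{op} requires stage {expected!r}, matrix is at "
                f"{self.stage!r}"
            )

    @property
    def endogenous_values(self) -> pd.DataFrame:
        return self.values.loc[self.endogenous_genes]

    def to_tsv(self) -> str:
        return self.values.to_csv(sep="\t", index_label="gene")

    def to_long_csv(self) -> str:
        long = (self.values.rename_axis("gene")
                .reset_index()
                .melt(id_vars="gene", var_name="sample_id",
                      value_name="value"))
        return long[["sample_id", "gene", "value"]].to_csv(index=False)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1))


def background_cutoff(neg_counts, summary: str = "max",
                      sd_multiplier: float = 2.0) -> float:
    """Per-lane background cutoff from negative-control counts.

    Default reading: highest negative control + 2 sample SDs.
    """
    neg = np.asarray(list(neg_counts), dtype=float)
    if neg.size < 2:
        raise InsufficientDataError(
            "background cutoff needs >= 2 negative-control counts"
        )
    base = neg.max() if summary == "max" else neg.mean()
    return float(base + sd_multiplier * _sd(neg))


def subtract_background(matrix: ExpressionMatrix,
                        cutoffs: pd.Series) -> ExpressionMatrix:
    """Clamp-at-zero subtraction of each lane's cutoff from its gene counts."""
    matrix._require_stage("raw", "subtract_background")
    cut = cutoffs.reindex(matrix.values.columns)
    if cut.isna().any():
        raise RCCPipeError(
            f"missing cutoffs for lanes: {list(cut.index[cut.isna()])}"
        )
    values = (matrix.values - cut).clip(lower=0.0)
    return ExpressionMatrix(
        values=values, stage="background_subtracted", factors=matrix.factors,
        endogenous_genes=matrix.endogenous_genes,
        reference_genes=matrix.reference_genes,
    )


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def _mean_of_geomeans_factors(frame: pd.DataFrame, what: str) -> pd.Series:
    """factor_i = mean_j(geomean_j) / geomean_i over the rows of ``frame``."""
    bad = frame.columns[(frame <= 0).any(axis=0)]
    if len(bad):
        rows = frame[bad[0]]
        probe = rows.index[rows <= 0][0]
        raise ValueError(
            f"nonpositive {what} value in lane {bad[0]} (probe {probe}); "
            "lane unnormalizable"
        )
    geo = frame.apply(lambda col: _geomean(col.to_numpy(float)), axis=0)
    return geo.mean() / geo


def positive_factors(runset: RunSet) -> pd.Series:
    """Per-lane positive-control factors from the raw spike-in counts."""
    pos_names = runset.codeset.names("positive")
    counts = runset.counts_frame().loc[pos_names]
    return _mean_of_geomeans_factors(counts.astype(float), "positive-control")


def reference_factors(matrix: ExpressionMatrix,
                      reference_genes=None) -> pd.Series:
    """Per-lane biological factors from the reference (housekeeping) genes."""
    matrix._require_stage("positive_normalized", "reference_factors")
    genes = list(reference_genes or matrix.reference_genes)
    if not genes:
        raise InsufficientDataError("no reference genes given")
    return _mean_of_geomeans_factors(matrix.values.loc[genes], "reference-gene")


def normalize_runset(runset: RunSet,
                     thresholds: QCThresholds = QCThresholds(),
                     options: NormalizeOptions = NormalizeOptions()
                     ) -> ExpressionMatrix:
    """Full background -> positive -> reference pipeline for a run set."""
    if options.drop_qc_failures:
        report = run_qc(runset, thresholds)
        runset = runset.subset(report.passing)
        if not runset.lanes:
            raise RCCPipeError("no lanes left after dropping QC failures")

    codeset = runset.codeset
    gene_names = [p.name for p in codeset.gene_probes]
    counts = runset.counts_frame().astype(float)
    raw = ExpressionMatrix(
        values=counts.loc[gene_names], stage="raw",
        endogenous_genes=codeset.endogenous,
        reference_genes=codeset.reference,
    )

    neg_names = codeset.names("negative")
    cutoffs = counts.loc[neg_names].apply(
        lambda col: background_cutoff(
            col, options.background_summary, options.background_sd_multiplier
        ),
        axis=0,
    )
    bg = subtract_background(raw, cutoffs)

    pos = positive_factors(runset)
    pos_norm = ExpressionMatrix(
        values=bg.values * pos, stage="positive_normalized",
        endogenous_genes=bg.endogenous_genes,
        reference_genes=bg.reference_genes,
    )

    ref = reference_factors(pos_norm)
    factors = NormalizationFactors(pd.DataFrame({
        "background_cutoff": cutoffs,
        "positive_factor": pos,
        "reference_factor": ref,
    }))
    return ExpressionMatrix(
        values=pos_norm.values * ref, stage="fully_normalized",
        factors=factors,
        endogenous_genes=pos_norm.endogenous_genes,
        reference_genes=pos_norm.reference_genes,
    )
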