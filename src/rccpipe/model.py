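"""Per-gene repeated-measures differential-transcription model.

The response is a gene's normalized count measured repeatedly on each
animal.  Fixed effects are group (control vs treatment), time, their
interaction, and optionally the animal's baseline (0 h) value as a
covariate; repeated measures within an animal are correlated via a
first-order autoregressive (AR1) structure indexed by measurement order,
with variance and correlation estimated by REML.  Estimation is
generalized least squares given the correlation, with the AR1 parameter
profiled out by a bounded scalar search on the restricted log-likelihood.

Two model variants cover the two contrast families:

* the default covariate model treats the post-baseline times as the
  repeated responses and the 0 h value as a covariate, and supplies
  between-group contrasts within each time point;
* a companion three-timepoint variant treats all times (baseline included)
  as repeated responses with no covariate, and supplies within-group
  contrasts of each post time against baseline.

Denominator degrees of freedom use a between-within partition: effects
that vary within animals are tested against the within-animal residual
df, purely between-animal effects against the between-animal df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EstimationError, InsufficientDataError
from .normalize import ExpressionMatrix
from .runset import GROUPS, StudyDesign

RHO_BOUND = 0.99


@dataclass(frozen=True)
class ModelSpec:
    """Modelling choices for :class:`GeneExpressionModel`.

    ``times_modeled`` are the post-baseline sampling times treated as
    repeated responses (default 4 and 24 h); ``baseline_as_covariate``
    adjusts for each animal's 0 h value.  ``correlation`` selects the
    within-animal structure: ``ar1`` (rho**|order gap|), ``independence``
    (rho fixed at 0) or ``compound_symmetry`` (constant rho, standing in
    for a pure random animal intercept).
    """

    response_transform: str = "identity"  # or "log2p1"
    times_modeled: tuple[float, ...] = (4.0, 24.0)
    baseline_time: float = 0.0
    baseline_as_covariate: bool = True
    correlation: str = "ar1"
    alpha: float = 0.05

    def __post_init__(self):
        if not self.times_modeled:
            raise ValueError("times_modeled must be nonempty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.correlation not in ("ar1", "independence",
                                    "compound_symmetry"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.response_transform not in ("identity", "log2p1"):
            raise ValueError(
                f"unknown transform {self.response_transform!r}"
            )


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    df: float
    t: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def as_dict(self) -> dict:
        return {
            "contrast_label": self.label, "estimate": self.estimate,
            "se": self.se, "df": self.df, "t": self.t, "p": self.p_value,
            "significant": self.significant,
        }


def _transform(y: np.ndarray, how: str) -> np.ndarray:
    return np.log2(y + 1.0) if how == "log2p1" else y


def _correlation_matrix(m: int, rho: float, structure: str) -> np.ndarray:
    idx = np.arange(m)
    if structure == "compound_symmetry":
        C = np.full((m, m), rho)
        np.fill_diagonal(C, 1.0)
        return C
    return rho ** np.abs(idx[:, None] - idx[None, :])


class GeneExpressionModel:
    """GLS/REML repeated-measures model for one gene.

    Parameters
    ----------
    values : pd.Series
        Normalized expression indexed by sample_id.
    design : StudyDesign
        Sample -> (animal, group, time) mapping.
    spec : ModelSpec
        Modelling choices.

    ``fit()`` returns a :class:`GeneFitResults`.
    """

    def __init__(self, values: pd.Series, design: StudyDesign,
                 spec: ModelSpec = ModelSpec(), gene: str = ""):
        self.spec = spec
        self.gene = gene or (values.name if values.name else "gene")
        self._build(values, design)

    # -- design construction -------------------------------------------

    def _build(self, values: pd.Series, design: StudyDesign) -> None:
        spec = self.spec
        rows = design.rows.merge(
            values.rename("y"), left_on="sample_id", right_index=True,
            how="inner",
        )
        if rows["y"].isna().any():
            raise EstimationError(f"{self.gene}: missing response values")
        times = sorted(spec.times_modeled)
        resp = rows[rows["time_h"].isin(times)].copy()

        baseline = None
        if spec.baseline_as_covariate:
            base = rows[rows["time_h"] == spec.baseline_time]
            baseline = base.set_index("animal_id")["y"]
            missing = set(resp["animal_id"]) - set(baseline.index)
            if missing:
                raise EstimationError(
                    f"{self.gene}: animals without baseline value: "
                    f"{sorted(missing)}"
                )
            resp["baseline"] = baseline.loc[resp["animal_id"]].to_numpy()

        # deterministic order: animal, then time
        resp = resp.sort_values(["animal_id", "time_h"],
                                kind="mergesort").reset_index(drop=True)
        per_group = resp.groupby("group")["animal_id"].nunique()
        for g in per_group.index:
            if per_group[g] < 2:
                raise EstimationError(
                    f"{self.gene}: group {g!r} has fewer than 2 animals"
                )

        y = _transform(resp["y"].to_numpy(float), spec.response_transform)
        group_ind = (resp["group"] == "treatment").astype(float).to_numpy()

        cols = {"Intercept": np.ones(len(resp))}
        if len(set(resp["group"])) > 1:
            cols["group[treatment]"] = group_ind
        ref_time = times[0]
        for t in times[1:]:
            d = (resp["time_h"] == t).astype(float).to_numpy()
            cols[f"time[{t:g}]"] = d
            if "group[treatment]" in cols:
                cols[f"group[treatment]:time[{t:g}]"] = group_ind * d
        if spec.baseline_as_covariate:
            base_t = _transform(resp["baseline"].to_numpy(float),
                                spec.response_transform)
            cols["baseline"] = base_t
            self._baseline_grand_mean = float(np.mean(
                _transform(baseline.to_numpy(float),
                           spec.response_transform)))
        else:
            self._baseline_grand_mean = None

        X = np.column_stack(list(cols.values()))
        self.exog_names = list(cols)
        self.endog, self.exog = y, X
        self.ref_time = ref_time
        self.times = times
        self.frame = resp
        animals = resp["animal_id"].to_numpy()
        _, starts = np.unique(animals, return_index=True)
        starts = np.sort(starts)
        bounds = list(starts) + [len(animals)]
        self._blocks = [(bounds[i], bounds[i + 1])
                        for i in range(len(starts))]
        self.n_animals = len(self._blocks)
        self.groups_of_animals = {
            a: g for a, g in zip(resp["animal_id"], resp["group"])
        }
        # columns constant within every animal (between-animal effects)
        self._between_cols = np.array([
            all(len(set(np.round(X[s:e, j], 12))) == 1
                for s, e in self._blocks)
            for j in range(X.shape[1])
        ])

    # -- REML machinery -------------------------------------------------

    def _gls(self, rho: float):
        """GLS quantities at a fixed correlation parameter."""
        X, y = self.exog, self.endog
        n, p = X.shape
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet_v = 0.0
        cinv_cache: dict[int, tuple[np.ndarray, float]] = {}
        for s, e in self._blocks:
            m = e - s
            if m not in cinv_cache:
                C = _correlation_matrix(m, rho, self.spec.correlation)
                sign, logdet = np.linalg.slogdet(C)
                if sign <= 0:
                    raise EstimationError("correlation matrix not PD")
                cinv_cache[m] = (np.linalg.inv(C), logdet)
            Cinv, logdet = cinv_cache[m]
            Xb, yb = X[s:e], y[s:e]
            xtvx += Xb.T @ Cinv @ Xb
            xtvy += Xb.T @ Cinv @ yb
            ytvy += yb @ Cinv @ yb
            logdet_v += logdet
        try:
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                f"{self.gene}: singular design matrix"
            ) from exc
        rss = float(ytvy - xtvy @ beta)
        return beta, xtvx, rss, logdet_v

    def _reml(self, rho: float) -> float:
        """Restricted log-likelihood with sigma^2 profiled out."""
        n, p = self.exog.shape
        beta, xtvx, rss, logdet_v = self._gls(rho)
        if rss <= 0:
            rss = 1e-300
        sigma2 = rss / (n - p)
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise EstimationError(f"{self.gene}: X'V^-1X not PD")
        return -0.5 * ((n - p) * np.log(sigma2) + logdet_v + logdet_xtvx
                       + (n - p))

    def fit(self) -> "GeneFitResults":
        n, p = self.exog.shape
        if n <= p:
            raise EstimationError(
                f"{self.gene}: {n} observations for {p} parameters"
            )
        if np.linalg.matrix_rank(self.exog) < p:
            raise EstimationError(f"{self.gene}: singular design matrix")
        max_block = max(e - s for s, e in self._blocks)
        if self.spec.correlation == "independence" or max_block == 1:
            rho = 0.0
        else:
            res = optimize.minimize_scalar(
                lambda r: -self._reml(r),
                bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                options={"xatol": 1e-10},
            )
            if not res.success:
                raise EstimationError(
                    f"{self.gene}: REML search failed: {res.message}"
                )
            rho = float(res.x)
        beta, xtvx, rss, _ = self._gls(rho)
        sigma2 = rss / (n - p)
        if sigma2 <= 0 or not np.isfinite(sigma2):
            raise EstimationError(
                f"{self.gene}: degenerate residual variance"
            )
        cov_beta = sigma2 * np.linalg.inv(xtvx)
        loglik = self._reml(rho)
        return GeneFitResults(
            model=self, beta=beta, cov_beta=cov_beta, rho=rho,
            sigma2=float(sigma2), reml_loglik=float(loglik),
        )

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix, gene: str,
                    design: StudyDesign,
                    spec: ModelSpec = ModelSpec()) -> "GeneExpressionModel":
        return cls(matrix.values.loc[gene], design, spec, gene=gene)

    # -- degrees of freedom --------------------------------------------

    def _df_partition(self) -> tuple[float, float]:
        n, p = self.exog.shape
        q_between = int(self._between_cols.sum())
        df_between = self.n_animals - q_between
        df_within = (n - p) - df_between
        if df_between <= 0 or df_within <= 0:
            # fall back to the pooled residual df for tiny designs
            return max(n - p, 1), max(n - p, 1)
        return df_between, df_within

    def contrast_df(self, L: np.ndarray) -> float:
        df_between, df_within = self._df_partition()
        within = np.abs(L[~self._between_cols]).sum() > 1e-12
        return df_within if within else df_between


@dataclass
class GeneFitResults:
    """REML fit of :class:`GeneExpressionModel` for one gene.

    Carries fixed-effect estimates and their covariance, the estimated
    AR1 correlation and residual variance, least-squares means and the
    contrast machinery.
    """

    model: GeneExpressionModel
    beta: np.ndarray
    cov_beta: np.ndarray
    rho: float
    sigma2: float
    reml_loglik: float
    _lsmeans: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def gene(self) -> str:
        return self.model.gene

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.model.exog_names)

    @property
    def resid(self) -> np.ndarray:
        """Marginal residuals y - X beta."""
        return self.model.endog - self.model.exog @ self.beta

    @property
    def resid_standardized(self) -> np.ndarray:
        return self.resid / np.sqrt(self.sigma2)

    # -- least-squares means -------------------------------------------

    def _lsm_vector(self, group: str, time: float) -> np.ndarray:
        """Contrast vector producing the LSM of cell (group, time).

        Averages over the baseline covariate at its grand mean.
        """
        m = self.model
        if time not in m.times:
            raise ValueError(f"time {time} not modeled (times: {m.times})")
        L = np.zeros(len(m.exog_names))
        for j, name in enumerate(m.exog_names):
            if name == "Intercept":
                L[j] = 1.0
            elif name == "group[treatment]":
                L[j] = 1.0 if group == "treatment" else 0.0
            elif name == f"time[{time:g}]":
                L[j] = 1.0
            elif name == f"group[treatment]:time[{time:g}]":
                L[j] = 1.0 if group == "treatment" else 0.0
            elif name == "baseline":
                L[j] = m._baseline_grand_mean
        return L

    def lsmeans(self) -> pd.DataFrame:
        """LSM +- SE for every modeled (group, time) cell."""
        if self._lsmeans is not None:
            return self._lsmeans
        m = self.model
        groups = [g for g in GROUPS
                  if g in set(m.frame["group"])]
        rows = []
        for g in groups:
            for t in m.times:
                L = self._lsm_vector(g, t)
                est = float(L @ self.beta)
                se = float(np.sqrt(L @ self.cov_beta @ L))
                rows.append({"gene": self.gene, "group": g, "time_h": t,
                             "estimate": est, "se": se})
        self._lsmeans = pd.DataFrame(rows)
        return self._lsmeans

    # -- contrasts ------------------------------------------------------

    def t_test(self, L: np.ndarray, label: str) -> ContrastResult:
        est = float(L @ self.beta)
        var = float(L @ self.cov_beta @ L)
        if var <= 0:
            raise EstimationError(f"{self.gene}: non-positive contrast "
                                  "variance")
        se = float(np.sqrt(var))
        df = self.model.contrast_df(L)
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return ContrastResult(label=label, estimate=est, se=se, df=df,
                              t=t, p_value=float(p),
                              alpha=self.model.spec.alpha)

    def contrast_between_groups(self, time: float) -> ContrastResult:
        """Test LSM(control, t) - LSM(treatment, t) = 0."""
        L = (self._lsm_vector("control", time)
             - self._lsm_vector("treatment", time))
        return self.t_test(L, f"control-vs-treatment@{time:g}h")

    def contrast_within_group(self, group: str, time: float,
                              reference_time: float) -> ContrastResult:
        """Test LSM(g, t) - LSM(g, t_ref) = 0 within one group."""
        L = (self._lsm_vector(group, time)
             - self._lsm_vector(group, reference_time))
        return self.t_test(
            L, f"{group}:{time:g}h-vs-{reference_time:g}h"
        )

    # -- diagnostics and presentation ----------------------------------

    def residual_normality(self) -> dict:
        """Shapiro-Wilk and Anderson-Darling on standardized residuals.

        Advisory only; never gates the fit.
        """
        r = self.resid_standardized
        if r.size < 8:
            raise InsufficientDataError(
                "normality checks need >= 8 residuals"
            )
        if np.ptp(r) == 0:
            raise InsufficientDataError(
                "residuals are constant; normality tests undefined"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = stats.shapiro(r)
            ad = stats.anderson(r, dist="norm")
        return {"shapiro_w": float(w), "shapiro_p": float(p),
                "anderson_darling_a2": float(ad.statistic)}

    def summary(self) -> str:
        lines = [
            f"Gene expression model: {self.gene}",
            f"  observations: {len(self.model.endog)}   "
            f"animals: {self.model.n_animals}",
            f"  correlation: {self.model.spec.correlation} "
            f"(rho = {self.rho:.4f})   sigma2 = {self.sigma2:.4g}",
            f"  REML log-likelihood: {self.reml_loglik:.4f}",
            "",
            f"  {'term':<32}{'coef':>12}{'se':>12}",
        ]
        for name, b, se in zip(self.model.exog_names, self.beta,
                               self.beta_se):
            lines.append(f"  {name:<32}{b:>12.4f}{se:>12.4f}")
        lines.append("")
        lines.append(f"  {'group':<12}{'time_h':>8}{'lsmean':>12}{'se':>12}")
        for _, row in self.lsmeans().iterrows():
            lines.append(
                f"  {row['group']:<12}{row['time_h']:>8g}"
                f"{row['estimate']:>12.4f}{row['se']:>12.4f}"
            )
        return "\n".join(lines)

    def plot_lsmeans(self, ax=None):
        """Grouped bar chart of LSM +- SE, one bar per (group, time) cell."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        lsm = self.lsmeans()
        groups = list(dict.fromkeys(lsm["group"]))
        times = sorted(lsm["time_h"].unique())
        width = 0.8 / len(groups)
        for k, g in enumerate(groups):
            sub = lsm[lsm["group"] == g].set_index("time_h").loc[times]
            x = np.arange(len(times)) + k * width
            ax.bar(x, sub["estimate"], width=width, yerr=sub["se"],
                   capsize=3, label=g)
        ax.set_xticks(np.arange(len(times)) + width * (len(groups) - 1) / 2)
        ax.set_xticklabels([f"{t:g} h" for t in times])
        ax.set_ylabel("normalized counts (LSM)")
        ax.set_title(self.gene)
        ax.legend()
        return ax


# -- functional surface ------------------------------------------------


def fit_gene(values: pd.Series, design: StudyDesign,
             spec: ModelSpec = ModelSpec(), gene: str = "") -> GeneFitResults:
    """Fit the repeated-measures model for one gene's values."""
    return GeneExpressionModel(values, design, spec, gene=gene).fit()


def lsmeans(fit: GeneFitResults) -> pd.DataFrame:
    return fit.lsmeans()


def contrast_between_groups(fit: GeneFitResults,
                            time: float) -> ContrastResult:
    return fit.contrast_between_groups(time)


def baseline_spec(spec: ModelSpec) -> ModelSpec:
    """The companion three-timepoint no-covariate variant of ``spec``."""
    times = tuple(sorted({spec.baseline_time, *spec.times_modeled}))
    return replace(spec, times_modeled=times, baseline_as_covariate=False)


def contrast_vs_baseline(values: pd.Series, design: StudyDesign,
                         spec: ModelSpec, group: str,
                         time: float, gene: str = "") -> ContrastResult:
    """Within-group contrast of time t against baseline.

    Fitted via the three-timepoint variant (all times as repeated
    measures, no covariate, AR1 by measurement order).
    """
    bspec = baseline_spec(spec)
    fit = GeneExpressionModel(values, design, bspec, gene=gene).fit()
    return fit.contrast_within_group(group, time, spec.baseline_time)


@dataclass
class PanelFitResults:
    """Fits, LSMs, and the contrast table for a whole gene panel."""

    fits: dict[str, GeneFitResults]
    baseline_fits: dict[str, GeneFitResults]
    contrasts: pd.DataFrame
    lsmeans: pd.DataFrame
    failed: dict[str, str]
    spec: ModelSpec

    def summary(self) -> str:
        n_sig = int(self.contrasts["significant"].sum())
        lines = [
            f"Panel fit: {len(self.fits)} genes "
            f"({len(self.failed)} degenerate/failed)",
            f"  contrasts: {len(self.contrasts)} "
            f"({n_sig} significant at alpha = {self.spec.alpha})",
        ]
        for gene, reason in self.failed.items():
            lines.append(f"  skipped {gene}: {reason}")
        return "\n".join(lines)

    def contrasts_csv(self) -> str:
        return self.contrasts.to_csv(index=False)

    def lsmeans_csv(self) -> str:
        return self.lsmeans.to_csv(index=False)


def fit_all_genes(matrix: ExpressionMatrix, design: StudyDesign,
                  spec: ModelSpec = ModelSpec(),
                  adjust: Optional[str] = None) -> PanelFitResults:
    """Fit every endogenous gene; collect LSMs and both contrast families.

    ``adjust='bh'`` appends a Benjamini-Hochberg adjusted p column
    (off by default: the motivating analysis reports unadjusted p).
    """
    if matrix.stage != "fully_normalized":
        raise EstimationError("fit_all_genes requires a fully normalized "
                              "matrix")
    genes = matrix.endogenous_genes
    fits: dict[str, GeneFitResults] = {}
    baseline_fits: dict[str, GeneFitResults] = {}
    failed: dict[str, str] = {}
    records = []
    lsm_rows = []
    bspec = baseline_spec(spec)
    groups = sorted(set(design.rows["group"]),
                    key=lambda g: GROUPS.index(g))
    for gene in genes:
        values = matrix.values.loc[gene]
        if np.ptp(values.to_numpy(float)) == 0:
            failed[gene] = "constant expression (degenerate)"
            continue
        try:
            fit = GeneExpressionModel(values, design, spec,
                                      gene=gene).fit()
            bfit = GeneExpressionModel(values, design, bspec,
                                       gene=gene).fit()
        except EstimationError as exc:
            failed[gene] = str(exc)
            continue
        fits[gene] = fit
        baseline_fits[gene] = bfit
        lsm_rows.append(bfit.lsmeans())
        for t in sorted(spec.times_modeled):
            if len(groups) == 2:
                c = fit.contrast_between_groups(t)
                records.append({"gene": gene, **c.as_dict()})
            for g in groups:
                c = bfit.contrast_within_group(g, t, spec.baseline_time)
                records.append({"gene": gene, **c.as_dict()})
    contrasts = pd.DataFrame(
        records, columns=["gene", "contrast_label", "estimate", "se",
                          "df", "t", "p", "significant"],
    )
    if adjust == "bh" and len(contrasts):
        contrasts["p_bh"] = _benjamini_hochberg(contrasts["p"].to_numpy())
    lsm = (pd.concat(lsm_rows, ignore_index=True) if lsm_rows
           else pd.DataFrame(columns=["gene", "group", "time_h",
                                      "estimate", "se"]))
    return PanelFitResults(fits=fits, baseline_fits=baseline_fits,
                           contrasts=contrasts, lsmeans=lsm,
                           failed=failed, spec=spec)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def residual_normality(fit: GeneFitResults) -> dict:
    return fit.residual_normality()
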