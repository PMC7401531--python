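"""Synthetic RCC run-set generation with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two groups of animals sampled at three times, per-animal latent
log2-scale trajectories with AR1 correlation, per-lane technical scale
factors, negative-binomial endogenous counts, and Poisson spike-in
positive-control ladders and negative-control background.  Defaults mirror
the motivating study design: 8 animals per group, times 0/4/24 h
(48 lanes), the packaged 15-gene panel, 555 requested fields of view, and
the 6-probe 4-fold positive ladder.

Each lane (and each animal's latent trajectory) has its own RNG stream
derived from (seed, identifier), so identical seeds regenerate byte-
identical RCC files and lane subsets are independently reproducible.
"""

from __future__ import annotations

import copy
import json
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .codeset import CodeSet, default_panel
from .errors import ConfigError
from .io import LaneAttributes, LaneCounts
from .runset import RunSet, StudyDesign, assemble_runset

QC_FAILURE_MODES = ("fov", "binding_density", "linearity", "lod")

#: Plausible baseline expression (normalized-count scale) for the packaged
#: panel: reference genes high and stable, IL8 markedly high pre-stimulus,
#: CRH low, remaining targets moderate.
DEFAULT_BASELINE_MEAN = {
    "IFNG": 150.0, "IL1B": 800.0, "IL6": 120.0, "IL8": 3000.0,
    "TNFA": 400.0, "IL10": 200.0, "AGTR2": 90.0, "CRH": 40.0,
    "NGF": 60.0, "NOS1": 80.0, "PGHS2": 600.0, "TAC1": 70.0,
    "GAPDH": 9000.0, "GUSB": 1500.0, "YWHAZ": 4000.0,
}


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions emulated."""

    n_per_group: int = 8
    times_h: tuple[float, ...] = (0.0, 4.0, 24.0)
    codeset: Optional[CodeSet] = None
    baseline_mean: Optional[dict[str, float]] = None
    dispersion: float = 20.0  # negative-binomial size; inf -> Poisson
    log2_effects: dict[tuple[str, str, float], float] = field(
        default_factory=dict
    )  # (gene, group, time_h) -> log2 fold change vs baseline
    rho_within_animal: float = 0.5
    animal_sd: float = 0.5  # log2-scale SD of the latent trajectory
    lane_scale_sd: float = 0.15  # SD of log lane scale factors
    background_mean: float = 5.0  # negative-control Poisson mean
    pos_scale: float = 150.0  # spike-in counts per fM
    fov_requested: int = 555
    qc_failures: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if list(self.times_h) != sorted(self.times_h):
            raise ConfigError("times_h must be sorted ascending")
        if not -1 < self.rho_within_animal < 1:
            raise ConfigError("rho_within_animal must be in (-1, 1)")
        for name, v in (("dispersion", self.dispersion),
                        ("pos_scale", self.pos_scale)):
            if v <= 0:
                raise ConfigError(f"{name} must be positive")
        for name, v in (("animal_sd", self.animal_sd),
                        ("lane_scale_sd", self.lane_scale_sd),
                        ("background_mean", self.background_mean)):
            if v < 0:
                raise ConfigError(f"{name} must be non-negative")
        for _, mode in self.qc_failures:
            if mode not in QC_FAILURE_MODES:
                raise ConfigError(f"unknown QC failure mode {mode!r}")

    def resolved_codeset(self) -> CodeSet:
        return self.codeset if self.codeset is not None else default_panel()

    def resolved_baseline(self, codeset: CodeSet) -> dict[str, float]:
        base = dict(DEFAULT_BASELINE_MEAN)
        if self.baseline_mean:
            base.update(self.baseline_mean)
        return {p.name: base.get(p.name, 500.0)
                for p in codeset.gene_probes}


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    seed: int
    log2_effects: dict[tuple[str, str, float], float]
    lane_scales: dict[str, float]
    latent: dict[str, dict[str, list[float]]]  # animal -> gene -> per-time

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "log2_effects": [
                {"gene": g, "group": grp, "time_h": t, "log2fc": v}
                for (g, grp, t), v in sorted(self.log2_effects.items())
            ],
            "lane_scales": self.lane_scales,
            "latent": self.latent,
        }, indent=1, sort_keys=True)


def _stream(seed: int, *tokens) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, tokens)."""
    key = zlib.crc32("/".join(str(t) for t in tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _ar1_chol(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    C = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(C)


def _nb_draw(rng: np.random.Generator, mean: float,
             dispersion: float) -> int:
    if mean <= 0:
        return 0
    if math.isinf(dispersion):
        return int(rng.poisson(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def default_design(config: SimConfig) -> StudyDesign:
    rows = []
    for group, prefix in (("control", "C"), ("treatment", "T")):
        for i in range(1, config.n_per_group + 1):
            animal = f"{prefix}{i:02d}"
            for t in config.times_h:
                rows.append({
                    "sample_id": f"{animal}_t{t:g}", "animal_id": animal,
                    "group": group, "time_h": t,
                })
    return StudyDesign(pd.DataFrame(rows))


def simulate_runset(config: SimConfig) -> tuple[RunSet, GroundTruth]:
    """Draw a full run set and its ground truth, deterministically per seed."""
    config.validate()
    codeset = config.resolved_codeset()
    baseline = config.resolved_baseline(codeset)
    design = default_design(config)
    times = list(config.times_h)
    gene_probes = [p.name for p in codeset.gene_probes]
    chol = _ar1_chol(len(times), config.rho_within_animal)

    latent: dict[str, dict[str, list[float]]] = {}
    for animal in design.animals:
        rng = _stream(config.seed, "animal", animal)
        z = config.animal_sd * (chol @ rng.standard_normal(
            (len(times), len(gene_probes))))
        latent[animal] = {
            g: [float(v) for v in z[:, j]]
            for j, g in enumerate(gene_probes)
        }

    lanes = []
    lane_scales: dict[str, float] = {}
    for _, row in design.rows.iterrows():
        sid, animal = row["sample_id"], row["animal_id"]
        group, t = row["group"], float(row["time_h"])
        rng = _stream(config.seed, "lane", sid)
        scale = float(np.exp(config.lane_scale_sd * rng.standard_normal()))
        lane_scales[sid] = scale
        t_idx = times.index(t)
        counts: dict[str, int] = {}
        for probe in codeset:
            if probe.probe_class in ("endogenous", "reference"):
                eff = config.log2_effects.get((probe.name, group, t), 0.0)
                z = latent[animal][probe.name][t_idx]
                mean = baseline[probe.name] * 2.0 ** (eff + z) * scale
                counts[probe.name] = _nb_draw(rng, mean, config.dispersion)
            elif probe.probe_class == "positive":
                mean = config.pos_scale * probe.concentration_fM * scale
                counts[probe.name] = int(rng.poisson(mean))
            else:
                counts[probe.name] = int(
                    rng.poisson(config.background_mean * scale))
        total = sum(counts.values())
        attrs = LaneAttributes(
            lane_id=sid, fov_requested=config.fov_requested,
            fov_counted=config.fov_requested,
            binding_density=total / (config.fov_requested * 100.0),
            cartridge_id="SIM",
        )
        lanes.append(LaneCounts(sample_id=sid, attributes=attrs,
                                counts=counts))

    runset = assemble_runset(lanes, codeset, design)
    for selector, mode in config.qc_failures:
        runset = inject_qc_failure(runset, selector, mode)
    truth = GroundTruth(
        seed=config.seed, log2_effects=dict(config.log2_effects),
        lane_scales=lane_scales, latent=latent,
    )
    return runset, truth


def inject_qc_failure(runset: RunSet, lane_selector: str,
                      mode: str) -> RunSet:
    """Minimally perturb one lane so exactly the chosen QC check fails.

    * ``fov``: fov_counted set to floor(0.74 * fov_requested).
    * ``binding_density``: recorded density pushed just above 2.25.
    * ``linearity``: top and bottom ladder counts swapped.
    * ``lod``: negative-control counts raised to straddle the POS_E count.
    """
    if mode not in QC_FAILURE_MODES:
        raise ConfigError(f"unknown QC failure mode {mode!r}")
    try:
        runset.lane_for(lane_selector)
    except KeyError:
        raise ConfigError(
            f"no lane matches selector {lane_selector!r}"
        ) from None
    new_lanes = []
    for lane in runset.lanes:
        if lane.sample_id != lane_selector:
            new_lanes.append(lane)
            continue
        lane = copy.deepcopy(lane)
        if mode == "fov":
            lane.attributes.fov_counted = int(
                0.74 * lane.attributes.fov_requested)
        elif mode == "binding_density":
            lane.attributes.binding_density = 2.26
        elif mode == "linearity":
            positives = sorted(runset.codeset.positives,
                               key=lambda p: p.concentration_fM)
            lo, hi = positives[0].name, positives[-1].name
            lane.counts[lo], lane.counts[hi] = (lane.counts[hi],
                                                lane.counts[lo])
        else:  # lod
            pos_e = lane.counts["POS_E"]
            for i, probe in enumerate(runset.codeset.negatives):
                lane.counts[probe.name] = pos_e + i
        new_lanes.append(lane)
    return RunSet(codeset=runset.codeset, lanes=new_lanes,
                  design=runset.design)


def simulate_gaussian_linear(n_per_group: int = 8,
                             times: tuple[float, ...] = (0.0, 4.0, 24.0),
                             mu: float = 100.0,
                             effects: Optional[dict] = None,
                             rho: float = 0.0,
                             sigma: float = 10.0,
                             baseline_slope: float = 0.5,
                             baseline_sd: float = 10.0,
                             seed: int = 0,
                             gene: str = "GENE"
                             ) -> tuple[pd.Series, StudyDesign]:
    """Single-gene data exactly matching the covariate model's assumptions.

    Each animal gets a baseline value x0 ~ N(mu, baseline_sd^2), recorded
    at the first time in ``times``.  Post-baseline responses are
    y(animal, t) = mu + effect(group, t) + baseline_slope * (x0 - mu) + e,
    with e drawn per animal from a multivariate normal with SD ``sigma``
    and AR1(rho) correlation in measurement order over the post-baseline
    times.  ``effects`` maps (group, time_h) -> additive shift on the
    response scale.  Used for clean parameter-recovery tests.
    """
    effects = effects or {}
    config = SimConfig(n_per_group=n_per_group, times_h=tuple(times))
    design = default_design(config)
    post = list(times)[1:]
    chol = _ar1_chol(len(post), rho)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6C696E]))
    values = {}
    for animal in design.animals:
        group = design.rows.loc[
            design.rows["animal_id"] == animal, "group"].iloc[0]
        x0 = mu + baseline_sd * rng.standard_normal()
        values[f"{animal}_t{times[0]:g}"] = x0
        e = sigma * (chol @ rng.standard_normal(len(post)))
        for k, t in enumerate(post):
            values[f"{animal}_t{t:g}"] = (
                mu + effects.get((group, t), 0.0)
                + baseline_slope * (x0 - mu) + e[k]
            )
    series = pd.Series(values, name=gene)
    return series.loc[design.sample_ids], design


def scenario_library() -> dict[str, SimConfig]:
    """Named generator configurations used across tests and the CLI."""
    up = {}  # planted upregulation pattern, log2 fold changes
    for gene, grp, t, fc in [
        ("IL8", "control", 4.0, 1.5), ("IL8", "control", 24.0, 1.0),
        ("IL8", "treatment", 4.0, 0.7), ("IL8", "treatment", 24.0, 0.8),
        ("IL1B", "control", 4.0, 1.0), ("IL1B", "control", 24.0, 1.0),
        ("IL1B", "treatment", 4.0, 1.5),
        ("IFNG", "treatment", 4.0, 0.5), ("IFNG", "treatment", 24.0, 0.8),
        ("NOS1", "control", 24.0, 1.0), ("PGHS2", "control", 24.0, 1.2),
        ("AGTR2", "control", 4.0, 1.0), ("AGTR2", "control", 24.0, 1.0),
        ("AGTR2", "treatment", 4.0, 1.0), ("AGTR2", "treatment", 24.0, 1.0),
        ("IL10", "treatment", 4.0, 0.8), ("IL6", "control", 24.0, 0.8),
        ("NGF", "control", 4.0, 0.8), ("TAC1", "control", 24.0, 1.0),
        ("TNFA", "control", 24.0, 1.0), ("TNFA", "treatment", 24.0, 1.0),
        ("CRH", "control", 4.0, 0.5),
    ]:
        up[(gene, grp, t)] = fc

    paper_like = SimConfig(log2_effects=up, seed=2020)
    return {
        "null": SimConfig(seed=101),
        "paper_like": paper_like,
        "rho_grid": SimConfig(rho_within_animal=0.6, seed=606),
        "qc_one_failure": replace(
            paper_like,
            qc_failures=[(f"T{paper_like.n_per_group:02d}_t24", "fov")],
            seed=2021,
        ),
    }
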