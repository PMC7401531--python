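"""End-to-end pipeline orchestration: QC -> normalize -> per-gene fits.

A single :class:`PipelineConfig` (optionally loaded from YAML) drives the
whole run; outputs are deterministic for identical inputs and config, with
floats printed at 9 significant digits for byte-stable regression checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .codeset import default_panel, load_codeset
from .errors import ConfigError, RCCPipeError
from .io import read_rcc
from .model import ModelSpec, fit_all_genes
from .normalize import NormalizeOptions, normalize_runset
from .power import PowerSpec
from .qc import QCThresholds, run_qc
from .runset import RunSet, StudyDesign, assemble_runset

FLOAT_FORMAT = "%.9g"


@dataclass
class PipelineConfig:
    rcc_dir: str = ""
    codeset_path: str = ""  # empty -> packaged panel
    design_path: str = ""
    out_dir: str = "out"
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    normalize: NormalizeOptions = field(default_factory=NormalizeOptions)
    model: ModelSpec = field(default_factory=ModelSpec)
    power: PowerSpec = field(default_factory=PowerSpec)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            kwargs = {}
            for key in ("rcc_dir", "codeset_path", "design_path",
                        "out_dir", "seed"):
                if key in raw:
                    kwargs[key] = raw[key]
            for key, typ in (("thresholds", QCThresholds),
                             ("normalize", NormalizeOptions),
                             ("model", ModelSpec),
                             ("power", PowerSpec)):
                if key in raw:
                    sub = dict(raw[key])
                    for tup in ("times_modeled",):
                        if tup in sub:
                            sub[tup] = tuple(sub[tup])
                    kwargs[key] = typ(**sub)
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid pipeline config: {exc}") from exc

    def to_yaml(self) -> str:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return yaml.safe_dump({
            "rcc_dir": self.rcc_dir, "codeset_path": self.codeset_path,
            "design_path": self.design_path, "out_dir": self.out_dir,
            "seed": self.seed,
            "thresholds": plain(self.thresholds),
            "normalize": plain(self.normalize),
            "model": plain(self.model),
            "power": plain(self.power),
        }, sort_keys=True)

    def validate_paths(self) -> None:
        for label, p in (("rcc_dir", self.rcc_dir),
                         ("design_path", self.design_path)):
            if not p or not Path(p).exists():
                raise ConfigError(f"{label} not resolvable: {p!r}")
        if self.codeset_path and not Path(self.codeset_path).exists():
            raise ConfigError(
                f"codeset_path not resolvable: {self.codeset_path!r}"
            )


def load_runset(config: PipelineConfig) -> RunSet:
    config.validate_paths()
    codeset = (load_codeset(Path(config.codeset_path).read_text())
               if config.codeset_path else default_panel())
    design = StudyDesign.from_csv(config.design_path)
    lanes = [read_rcc(p.read_text())
             for p in sorted(Path(config.rcc_dir).glob("*.rcc"))
             ] or [read_rcc(p.read_text())
                   for p in sorted(Path(config.rcc_dir).glob("*.RCC"))]
    if not lanes:
        raise ConfigError(f"no .rcc files under {config.rcc_dir}")
    return assemble_runset(lanes, codeset, design)


def _write(path: Path, text: str, log: list[str]) -> None:
    path.write_text(text)
    log.append(f"wrote {path.name} ({len(text)} bytes)")


def run_pipeline(config: PipelineConfig,
                 runset: RunSet | None = None) -> Path:
    """Run QC, normalization and the per-gene fits; write all artifacts.

    Returns the output directory.  Raises subclasses of
    :class:`RCCPipeError` on hard errors.
    """
    log: list[str] = []
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if runset is None:
        runset = load_runset(config)
    log.append(f"loaded {len(runset.lanes)} lanes, "
               f"{len(runset.codeset)} probes")

    report = run_qc(runset, config.thresholds)
    log.extend(report.log_lines())
    _write(out / "qc_report.csv",
           report.table.to_csv(index_label="sample_id",
                               float_format=FLOAT_FORMAT), log)

    matrix = normalize_runset(runset, config.thresholds, config.normalize)
    log.append(
        f"normalized {matrix.values.shape[0]} genes x "
        f"{matrix.values.shape[1]} lanes "
        f"(drop_qc_failures={config.normalize.drop_qc_failures})"
    )
    _write(out / "factors.csv",
           matrix.factors.table.to_csv(index_label="sample_id",
                                       float_format=FLOAT_FORMAT), log)
    _write(out / "normalized.tsv",
           matrix.values.to_csv(sep="\t", index_label="gene",
                                float_format=FLOAT_FORMAT), log)

    design = runset.design
    if config.normalize.drop_qc_failures:
        design = StudyDesign(design.rows[
            design.rows["sample_id"].isin(matrix.values.columns)])
    panel = fit_all_genes(matrix, design, config.model)
    log.append(panel.summary())
    _write(out / "lsmeans.csv",
           panel.lsmeans.to_csv(index=False, float_format=FLOAT_FORMAT),
           log)
    _write(out / "contrasts.csv",
           panel.contrasts.to_csv(index=False, float_format=FLOAT_FORMAT),
           log)
    (out / "run_log").write_text("\n".join(log) + "\n")
    return out
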