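"""Run configuration: YAML loading and validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .libraries import ANCHOR_DEFAULT
from .simulate import SimConfig


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    Exactly one read source is used: a ``simulate`` block, or a mapping of
    time point -> existing FASTQ path under ``fastq``.  Analysis flags
    mirror the CLI options of the individual stages.
    """

    seed: int = 0
    outdir: str = "run"
    anchor: str = ANCHOR_DEFAULT
    timepoints: tuple[int, ...] = (0, 150, 270)
    simulate: SimConfig | None = None
    fastq: dict[int, str] | None = None
    plaques: str | None = None
    normalize_depth: bool = False
    denominator: str = "cleaned"
    diversity_mode: str = "unique"
    ef_bins: tuple[float, ...] | None = None
    log_level: str = "INFO"


_SIM_KEYS = {
    "timepoints",
    "depth",
    "error_rate",
    "n_clones",
    "rate_means",
    "rate_sds",
    "wt_fraction_0",
    "r_wt",
    "exact_mode",
    "amber_rate",
    "amber_suppression",
    "anchor",
    "flank5",
    "flank3",
}


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise ConfigurationError(f"cannot parse {path}{where}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", 0))
    cfg.outdir = str(raw.get("outdir", cfg.outdir))
    cfg.anchor = str(raw.get("anchor", cfg.anchor))
    cfg.timepoints = tuple(int(t) for t in raw.get("timepoints", cfg.timepoints))
    if "simulate" in raw and raw["simulate"] is not None:
        block = dict(raw["simulate"])
        unknown = set(block) - _SIM_KEYS
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown simulate keys: {', '.join(sorted(unknown))}"
            )
        block.setdefault("timepoints", cfg.timepoints)
        block["timepoints"] = tuple(int(t) for t in block["timepoints"])
        block.setdefault("anchor", cfg.anchor)
        cfg.simulate = SimConfig(seed=cfg.seed, **block)
    if "fastq" in raw and raw["fastq"] is not None:
        cfg.fastq = {int(t): str(p) for t, p in raw["fastq"].items()}
    cfg.plaques = raw.get("plaques")
    analysis = raw.get("analysis", {}) or {}
    cfg.normalize_depth = bool(analysis.get("normalize_depth", False))
    cfg.denominator = str(analysis.get("denominator", "cleaned"))
    cfg.diversity_mode = str(analysis.get("diversity_mode", "unique"))
    if analysis.get("ef_bins") is not None:
        cfg.ef_bins = tuple(float(b) for b in analysis["ef_bins"])
    cfg.log_level = str(raw.get("log_level", "INFO"))
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Return all invariant violations; an empty list means the config is valid."""
    problems: list[str] = []
    if not isinstance(cfg.seed, int):
        problems.append("seed: must be an integer")
    if not cfg.timepoints:
        problems.append("timepoints: must be non-empty")
    elif any(b <= a for a, b in zip(cfg.timepoints, cfg.timepoints[1:])):
        problems.append("timepoints: must be strictly increasing")
    if len(cfg.anchor) < 10:
        problems.append("anchor: must be at least 10 nt")
    if cfg.simulate is None and cfg.fastq is None:
        problems.append("inputs: need either a simulate block or fastq paths")
    if cfg.simulate is not None:
        problems.extend(f"simulate.{v}" for v in cfg.simulate.violations())
    if cfg.fastq is not None:
        for t in cfg.timepoints:
            if t not in cfg.fastq:
                problems.append(f"fastq: no file for time point {t}")
        for t, p in cfg.fastq.items():
            if not Path(p).exists():
                problems.append(f"fastq: missing file {p} (t={t})")
    if cfg.plaques is not None and not Path(cfg.plaques).exists():
        problems.append(f"plaques: missing file {cfg.plaques}")
    if cfg.denominator not in ("cleaned", "all"):
        problems.append("analysis.denominator: must be 'cleaned' or 'all'")
    if cfg.diversity_mode not in ("unique", "singleton"):
        problems.append("analysis.diversity_mode: must be 'unique' or 'singleton'")
    if cfg.ef_bins is not None:
        if len(cfg.ef_bins) < 2 or any(
            b <= a for a, b in zip(cfg.ef_bins, cfg.ef_bins[1:])
        ) or cfg.ef_bins[0] <= 0:
            problems.append("analysis.ef_bins: must be >= 2 positive increasing edges")
    return problems
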