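"""End-to-end orchestration: simulate/load -> classify -> metrics -> enrichment.

Every run writes a fixed set of TSV tables plus a machine-readable
``manifest.json`` (seed, config hash, package and dependency versions, file
list) so that any output can be reproduced from the manifest alone.  All
randomness flows from the single master seed in the run configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, validate_config
from .enrichment import (
    ef_distribution,
    ef_library_shares,
    enrichment_factors,
    relative_frequencies,
)
from .errors import PipelineError
from .libraries import LIBRARY_ORDER
from .metrics import (
    diversity_summary,
    library_fold_change,
    titer_fold_change,
    wt_percentage,
    wt_share_of_removed,
)
from .reads import TimepointCounts, process_fastq, summary_frame
from .simulate import simulate_run

logger = logging.getLogger("phagepool")

DEFAULT_EF_BINS = (0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("[%s] starting", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {
            **{k: v for k, v in vars(cfg).items() if k != "simulate"},
            "simulate": asdict(cfg.simulate) if cfg.simulate else None,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


@_stage("simulate")
def _obtain_fastqs(cfg: RunConfig, outdir: Path) -> dict[int, Path]:
    if cfg.fastq is not None:
        return {t: Path(p) for t, p in cfg.fastq.items()}
    paths = simulate_run(cfg.simulate, outdir / "sim")
    return {t: paths[f"t{t}"] for t in cfg.timepoints}


@_stage("classify")
def _classify(cfg: RunConfig, fastqs: dict[int, Path], outdir: Path) -> dict[int, TimepointCounts]:
    counts: dict[int, TimepointCounts] = {}
    for t in cfg.timepoints:
        counts[t] = process_fastq(fastqs[t], cfg.anchor, t)
        counts[t].write_tsv(outdir / f"counts_t{t}.tsv")
        logger.info(
            "[classify] t=%d: %d reads, %d cleaned, %d removed (%d WT)",
            t,
            counts[t].total_reads,
            counts[t].cleaned_count,
            counts[t].removed_count,
            counts[t].wt_count,
        )
    summary_frame(counts.values()).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return counts


@_stage("metrics")
def _metrics(cfg: RunConfig, counts: dict[int, TimepointCounts], outdir: Path) -> dict:
    t0 = cfg.timepoints[0]
    wt_rows = []
    div_rows = []
    for t in cfg.timepoints:
        share = wt_share_of_removed(counts[t]) if counts[t].removed_count else None
        wt_rows.append(
            {
                "timepoint": t,
                "wt_pct_of_total": 100.0 * wt_percentage(counts[t]),
                "wt_pct_of_removed": 100.0 * share if share is not None else float("nan"),
            }
        )
        div = diversity_summary(counts[t], mode=cfg.diversity_mode)
        row = {
            "timepoint": t,
            "distinct_pct": div.distinct_pct,
            "repeated_pct": div.repeated_pct,
        }
        for lib in LIBRARY_ORDER:
            row[f"distinct_pct_{lib.lower()}"] = div.per_library_distinct_pct[lib]
        div_rows.append(row)
    pd.DataFrame(wt_rows).to_csv(outdir / "wt_summary.tsv", sep="\t", index=False)
    pd.DataFrame(div_rows).to_csv(outdir / "diversity.tsv", sep="\t", index=False)

    fc_rows = []
    for t in cfg.timepoints[1:]:
        fc = library_fold_change(counts[t0], counts[t], cfg.normalize_depth)
        for lib in LIBRARY_ORDER:
            fc_rows.append({"interval": f"{t0}-{t}", "library": lib, "fold_change": fc[lib]})
    fc_frame = pd.DataFrame(fc_rows)
    fc_frame.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)

    if cfg.plaques:
        titers = titer_fold_change(pd.read_csv(cfg.plaques, sep="\t"))
        titers.to_csv(outdir / "titers.tsv", sep="\t", index=False)
    return {"wt": wt_rows, "diversity": div_rows, "fold_changes": fc_rows}


@_stage("enrich")
def _enrich(cfg: RunConfig, counts: dict[int, TimepointCounts], outdir: Path) -> dict:
    freq = {
        t: relative_frequencies(counts[t], denominator=cfg.denominator)
        for t in cfg.timepoints
    }
    bins = cfg.ef_bins or DEFAULT_EF_BINS
    shares_rows = []
    hist_frames = []
    for a, b in zip(cfg.timepoints, cfg.timepoints[1:]):
        ef = enrichment_factors(freq[a], freq[b])
        ef.table.to_csv(outdir / f"ef_{a}_{b}.tsv", sep="\t", index=False)
        shares = ef_library_shares(ef, rounded=True) if not ef.table.empty else None
        for lib in LIBRARY_ORDER:
            shares_rows.append(
                {
                    "interval": f"{a}-{b}",
                    "library": lib,
                    "share_pct": shares[lib] if shares else float("nan"),
                }
            )
        if not ef.table.empty:
            hist = ef_distribution(ef, bins)
            hist.insert(0, "interval", f"{a}-{b}")
            hist_frames.append(hist)
    pd.DataFrame(shares_rows).to_csv(outdir / "ef_shares.tsv", sep="\t", index=False)
    if hist_frames:
        pd.concat(hist_frames, ignore_index=True).to_csv(
            outdir / "ef_hist.tsv", sep="\t", index=False
        )
    return {"ef_shares": shares_rows}


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    problems = validate_config(cfg)
    if problems:
        raise PipelineError("[config] " + "; ".join(problems))
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(message)s",
    )
    fastqs = _obtain_fastqs(cfg, outdir)
    counts = _classify(cfg, fastqs, outdir)
    results = _metrics(cfg, counts, outdir)
    results.update(_enrich(cfg, counts, outdir))
    manifest = {
        "package": "phagepool",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_sha256": _config_hash(cfg),
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("[done] %d tables written to %s", len(manifest["outputs"]), outdir)
    return manifest
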