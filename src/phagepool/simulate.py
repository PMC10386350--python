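"""Synthetic competitive-propagation amplicon simulator with known ground truth.

The generator emulates the statistical structure of a pooled-library
propagation assay: equal phage input per library (10^9 pfu each), an
insertless wild-type (WT) compartment, per-clone exponential growth
``N_i(t) = N_i(0) * exp(r_i * t)`` over the assay time points (0, 150 and
270 min), multinomial read sampling at a configured depth per time point,
and iid per-base substitution error.  Reads are standard single-end
amplicons: a constant 5' flank ending in the anchor motif, the NNK-encoded
insert (absent for WT reads), and a constant 3' flank encoding the mature
pIII N-terminus.  The flank sequences are synthetic stand-ins for the
unpublished vector context; the anchor contract is what downstream
classification relies on.

Amber (TAG) codons can be injected into randomized positions at a
configurable rate.  Under an amber-suppressing host the displayed residue
is Q, but in-silico translation of the sequenced DNA still yields ``*``,
so such reads are discarded by the classifier — mirroring how stop-bearing
reads behave in a real analysis.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SimulationError
from .libraries import (
    AA20,
    AMBER_CODON,
    ANCHOR_DEFAULT,
    CYS_NT,
    FLANK3_DEFAULT,
    FLANK5_DEFAULT,
    LEADING_NT,
    LIBRARY_ORDER,
    LINKER_NT,
    NNK_BY_AA,
    LibrarySpec,
    get_library,
)
from .reads import translate

#: phage input per library in the competitive assay (pfu)
LIBRARY_INPUT_PFU = 1.0e9

_EXP_LIMIT = 700.0  # beyond this, exp() overflows a float64


# --- domain types -----------------------------------------------------------

@dataclass(frozen=True)
class Clone:
    clone_id: str
    library: str
    peptide: str  # randomized residues as displayed (Q at suppressed amber sites)
    insert_nt: str
    r: float  # growth rate, per minute
    n0: float = 1.0  # initial copy number
    has_amber: bool = False


@dataclass
class ClonePool:
    """Ground-truth clone set plus the WT compartment."""

    clones: list[Clone]
    wt_fraction_0: float = 0.0
    r_wt: float = 0.0
    amber_suppression: bool = False

    def __post_init__(self) -> None:
        self.validate()

    @property
    def total_n0(self) -> float:
        return sum(c.n0 for c in self.clones)

    @property
    def wt_n0(self) -> float:
        """WT initial copies such that WT is ``wt_fraction_0`` of the whole pool."""
        w = self.wt_fraction_0
        return w / (1.0 - w) * self.total_n0

    def validate(self) -> None:
        if not 0.0 <= self.wt_fraction_0 < 1.0:
            raise ConfigurationError(
                f"wt_fraction_0 must be in [0, 1), got {self.wt_fraction_0}"
            )
        if not math.isfinite(self.r_wt):
            raise ConfigurationError("r_wt must be finite")
        for clone in self.clones:
            spec = get_library(clone.library)
            if len(clone.peptide) != spec.peptide_length:
                raise ConfigurationError(
                    f"{clone.clone_id}: peptide length {len(clone.peptide)} != "
                    f"{spec.peptide_length}"
                )
            if "*" in clone.peptide and not clone.has_amber:
                raise ConfigurationError(
                    f"{clone.clone_id}: stop in randomized residues"
                )
            if clone.n0 < 0:
                raise ConfigurationError(f"{clone.clone_id}: negative N0")
            if not math.isfinite(clone.r):
                raise ConfigurationError(f"{clone.clone_id}: non-finite growth rate")
            window = spec.displayed_window(clone.peptide)
            if _host_translate(clone.insert_nt, self.amber_suppression) != window:
                raise ConfigurationError(
                    f"{clone.clone_id}: insert does not translate to its window"
                )


def _host_translate(nt: str, amber_suppression: bool) -> str:
    aa = translate(nt)
    if amber_suppression:
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        aa = "".join(
            "Q" if codon == AMBER_CODON else res for codon, res in zip(codons, aa)
        )
    return aa


@dataclass
class SimConfig:
    """All knobs of one simulated propagation run.

    Defaults are the emulated assay conditions: time points 0/150/270 min,
    10^5 reads per time point, 0.1% per-base error, 1000 clones per library,
    12.5% initial WT, and library-level growth-rate means ordered
    PhD7 > PhD12 > PhDC7C around a ~28 min doubling time with 20% relative
    spread between clones.
    """

    seed: int
    timepoints: tuple[int, ...] = (0, 150, 270)
    depth: int | dict[int, int] = 100_000
    error_rate: float = 0.001
    n_clones: int | dict[str, int] = 1000
    rate_means: dict[str, float] = field(
        default_factory=lambda: {"PhD7": 0.026, "PhD12": 0.024, "PhDC7C": 0.022}
    )
    rate_sds: dict[str, float] | None = None  # default: 0.2 * mean
    wt_fraction_0: float = 0.125
    r_wt: float = 0.024
    exact_mode: bool = False
    amber_rate: float = 0.0
    amber_suppression: bool = False
    anchor: str = ANCHOR_DEFAULT
    flank5: str = FLANK5_DEFAULT
    flank3: str = FLANK3_DEFAULT

    def depth_at(self, timepoint: int) -> int:
        if isinstance(self.depth, dict):
            return int(self.depth[timepoint])
        return int(self.depth)

    def n_clones_for(self, library: str) -> int:
        if isinstance(self.n_clones, dict):
            return int(self.n_clones[library])
        return int(self.n_clones)

    def sd_for(self, library: str) -> float:
        if self.rate_sds is not None:
            return float(self.rate_sds[library])
        return 0.2 * float(self.rate_means[library])

    def violations(self) -> list[str]:
        out = []
        if not isinstance(self.seed, int):
            out.append("seed: must be an integer")
        for t in self.timepoints:
            try:
                if self.depth_at(t) <= 0:
                    out.append(f"depth: must be a positive integer at t={t}")
            except KeyError:
                out.append(f"depth: no depth configured for t={t}")
        if not 0.0 <= self.error_rate <= 0.1:
            out.append("error_rate: must be in [0, 0.1]")
        if not self.timepoints or self.timepoints[0] != 0:
            out.append("timepoints: must start at 0")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            out.append("timepoints: must be strictly increasing")
        for lib in LIBRARY_ORDER:
            try:
                if self.n_clones_for(lib) < 1:
                    out.append(f"n_clones: must be >= 1 for {lib}")
                if lib not in self.rate_means:
                    out.append(f"rate_means: missing {lib}")
                elif self.sd_for(lib) < 0:
                    out.append(f"rate_sds: must be >= 0 for {lib}")
            except KeyError:
                out.append(f"n_clones: missing {lib}")
        if not 0.0 <= self.wt_fraction_0 < 1.0:
            out.append("wt_fraction_0: must be in [0, 1)")
        if not 0.0 <= self.amber_rate <= 1.0:
            out.append("amber_rate: must be in [0, 1]")
        if len(self.anchor) < 10:
            out.append("anchor: must be at least 10 nt")
        if not self.flank5.endswith(self.anchor):
            out.append("flank5: must end with the anchor motif")
        if len(self.flank3) < 51:
            out.append("flank3: must be at least 51 nt (17 codons)")
        return out

    def validate(self) -> None:
        problems = self.violations()
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass
class SimulatedTimepoint:
    """Reads emitted at one time point, aligned index-wise with ground truth."""

    timepoint: int
    read_ids: list[str]
    sequences: list[str]
    clone_indices: np.ndarray  # index into pool.clones; len(pool.clones) = WT


# --- seeding ----------------------------------------------------------------

def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent random substreams derived from one master seed."""
    names = ("clones", "rates", "codons", "amber", "sampling", "errors")
    root = np.random.SeedSequence(seed)
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


# --- clone construction -----------------------------------------------------

def back_translate_nnk(peptide: str, seed: int | np.random.Generator) -> str:
    """Back-translate a peptide using one uniformly chosen NNK codon per residue.

    The amber codon TAG is never chosen (it encodes a stop); every canonical
    residue has at least one NNK codon, tryptophan and methionine exactly one.
    """
    rng = np.random.default_rng(seed)
    codons = []
    for residue in peptide:
        if residue not in AA20:
            raise ConfigurationError(
                f"cannot NNK-encode non-canonical residue {residue!r}"
            )
        options = NNK_BY_AA[residue]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _insert_nt(spec: LibrarySpec, peptide_nt: str) -> str:
    if spec.cyclic:
        return LEADING_NT + CYS_NT + peptide_nt + CYS_NT + LINKER_NT
    return LEADING_NT + peptide_nt + LINKER_NT


def sample_library_clones(
    spec: LibrarySpec | str,
    n: int,
    rate_mean: float,
    rate_sd: float,
    seed: int | np.random.Generator,
    n0: float = 1.0,
) -> list[Clone]:
    """Draw ``n`` clones: uniform NNK-encodable peptides, Normal growth rates."""
    if isinstance(spec, str):
        spec = get_library(spec)
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if rate_sd < 0:
        raise ConfigurationError(f"rate_sd must be >= 0, got {rate_sd}")
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(AA20), size=(n, spec.peptide_length))
    rates = rng.normal(rate_mean, rate_sd, size=n)
    clones = []
    for i in range(n):
        peptide = "".join(letters[i])
        clones.append(
            Clone(
                clone_id=f"{spec.name}_{i:05d}",
                library=spec.name,
                peptide=peptide,
                insert_nt=_insert_nt(spec, back_translate_nnk(peptide, rng)),
                r=float(rates[i]),
                n0=n0,
            )
        )
    return clones


def _inject_amber(
    clone: Clone,
    spec: LibrarySpec,
    rate: float,
    suppression: bool,
    rng: np.random.Generator,
) -> Clone:
    hits = np.nonzero(rng.random(spec.peptide_length) < rate)[0]
    if hits.size == 0:
        return clone
    offset = 2 if spec.cyclic else 1  # codons before the randomized stretch
    codons = [clone.insert_nt[i : i + 3] for i in range(0, len(clone.insert_nt), 3)]
    peptide = list(clone.peptide)
    for pos in hits:
        codons[offset + pos] = AMBER_CODON
        peptide[pos] = "Q" if suppression else "*"
    return replace(
        clone,
        peptide="".join(peptide),
        insert_nt="".join(codons),
        has_amber=True,
    )


def build_pool(config: SimConfig) -> ClonePool:
    """Sample the full three-library pool described by ``config``.

    Each library receives the same total input (10^9 copies split evenly
    over its clones).  Inserts are redrawn if they would create a second
    anchor occurrence in the read, keeping window location unambiguous.
    """
    config.validate()
    rngs = _substreams(config.seed)
    clones: list[Clone] = []
    for lib in LIBRARY_ORDER:
        spec = get_library(lib)
        n = config.n_clones_for(lib)
        drawn = sample_library_clones(
            spec,
            n,
            config.rate_means[lib],
            config.sd_for(lib),
            rngs["clones"],
            n0=LIBRARY_INPUT_PFU / n,
        )
        for clone in drawn:
            if config.amber_rate > 0:
                clone = _inject_amber(
                    clone, spec, config.amber_rate, config.amber_suppression,
                    rngs["amber"],
                )
            for _attempt in range(100):
                template = config.flank5 + clone.insert_nt + config.flank3
                if template.count(config.anchor) == 1:
                    break
                peptide = "".join(
                    rngs["codons"].choice(list(AA20), size=spec.peptide_length)
                )
                clone = replace(
                    clone,
                    peptide=peptide,
                    insert_nt=_insert_nt(
                        spec, back_translate_nnk(peptide, rngs["codons"])
                    ),
                )
            else:
                raise SimulationError(
                    f"{clone.clone_id}: could not avoid duplicate anchor"
                )
            clones.append(clone)
    return ClonePool(
        clones=clones,
        wt_fraction_0=config.wt_fraction_0,
        r_wt=config.r_wt,
        amber_suppression=config.amber_suppression,
    )


# --- dynamics and sampling --------------------------------------------------

def simulate_trajectories(
    pool: ClonePool, timepoints: Sequence[int]
) -> np.ndarray:
    """Copy numbers ``N_i(t) = N_i(0) exp(r_i t)``; last row is the WT compartment."""
    rates = np.array([c.r for c in pool.clones] + [pool.r_wt])
    n0 = np.array([c.n0 for c in pool.clones] + [pool.wt_n0])
    t = np.asarray(timepoints, dtype=float)
    exponents = np.outer(rates, t)
    # empty compartments stay empty no matter the rate
    too_big = np.nonzero((exponents.max(axis=1) > _EXP_LIMIT) & (n0 > 0))[0]
    if too_big.size:
        idx = int(too_big[0])
        cid = pool.clones[idx].clone_id if idx < len(pool.clones) else "WT"
        raise SimulationError(f"{cid}: r*t = {exponents[idx].max():.1f} overflows")
    with np.errstate(over="ignore"):
        traj = np.where(
            n0[:, None] > 0, n0[:, None] * np.exp(np.minimum(exponents, _EXP_LIMIT)), 0.0
        )
    if not np.all(np.isfinite(traj)):
        raise SimulationError("non-finite copy number in trajectories")
    return traj


def largest_remainder(p: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` with proportions closest to ``p``."""
    ideal = p * total
    base = np.floor(ideal).astype(np.int64)
    shortfall = total - int(base.sum())
    if shortfall:
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:shortfall]] += 1
    return base


_BASES = b"ACGT"
_ALTERNATIVES = {b: bytes(x for x in _BASES if x != b) for b in _BASES}


def emit_reads(
    pool: ClonePool, trajectories: np.ndarray, config: SimConfig
) -> dict[int, SimulatedTimepoint]:
    """Sample reads at every configured time point.

    Stochastic mode draws read counts multinomially with probabilities
    proportional to ``N_i(t)`` and applies iid per-base substitutions at the
    configured error rate.  In ``exact_mode`` counts are the largest-remainder
    rounding of ``depth * p_i`` and the error rate is forced to zero.
    """
    config.validate()
    rngs = _substreams(config.seed)
    rng_s, rng_e = rngs["sampling"], rngs["errors"]
    templates = [config.flank5 + c.insert_nt + config.flank3 for c in pool.clones]
    templates.append(config.flank5 + config.flank3)  # WT: no insert
    lengths = np.array([len(s) for s in templates])
    eps = 0.0 if config.exact_mode else config.error_rate
    out: dict[int, SimulatedTimepoint] = {}
    for ti, t in enumerate(config.timepoints):
        depth = config.depth_at(t)
        if depth <= 0:
            raise ConfigurationError(f"depth must be positive at t={t}")
        pop = trajectories[:, ti]
        total = pop.sum()
        if total <= 0:
            raise SimulationError(f"empty pool at t={t}")
        p = pop / total
        if config.exact_mode:
            counts = largest_remainder(p, depth)
        else:
            counts = rng_s.multinomial(depth, p)
        seqs: list[str] = []
        for i, c in enumerate(counts):
            if c:
                seqs.extend([templates[i]] * int(c))
        clone_idx = np.repeat(np.arange(len(templates)), counts)
        if eps > 0:
            read_len = lengths[clone_idx]
            n_err = rng_e.binomial(read_len, eps)
            for j in np.nonzero(n_err)[0]:
                raw = bytearray(seqs[j], "ascii")
                for pos in rng_e.integers(0, len(raw), size=n_err[j]):
                    raw[pos] = _ALTERNATIVES[raw[pos]][rng_e.integers(3)]
                seqs[j] = raw.decode("ascii")
        read_ids = [f"t{t}_r{j:06d}" for j in range(len(seqs))]
        out[t] = SimulatedTimepoint(
            timepoint=t, read_ids=read_ids, sequences=seqs, clone_indices=clone_idx
        )
    return out


# --- output -----------------------------------------------------------------

QUALITY_CHAR = "?"  # constant Phred+33 Q30


def write_fastq(sim: SimulatedTimepoint, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for read_id, seq in zip(sim.read_ids, sim.sequences):
            fh.write(f"@{read_id}\n{seq}\n+\n{QUALITY_CHAR * len(seq)}\n")


def truth_frame(
    sims: dict[int, SimulatedTimepoint], pool: ClonePool
) -> pd.DataFrame:
    """Ground-truth table: ``read_id, clone_id, library, peptide, is_wt``."""
    n_clones = len(pool.clones)
    frames = []
    for t in sorted(sims):
        sim = sims[t]
        idx = sim.clone_indices
        is_wt = idx == n_clones
        frames.append(
            pd.DataFrame(
                {
                    "read_id": sim.read_ids,
                    "clone_id": [
                        "WT" if w else pool.clones[i].clone_id
                        for i, w in zip(idx, is_wt)
                    ],
                    "library": [
                        "" if w else pool.clones[i].library
                        for i, w in zip(idx, is_wt)
                    ],
                    "peptide": [
                        "" if w else pool.clones[i].peptide
                        for i, w in zip(idx, is_wt)
                    ],
                    "is_wt": is_wt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_run(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Full simulation to disk: ``t<min>.fastq`` per time point + ``truth.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pool = build_pool(config)
    traj = simulate_trajectories(pool, config.timepoints)
    sims = emit_reads(pool, traj, config)
    paths: dict[str, Path] = {}
    for t, sim in sims.items():
        path = outdir / f"t{t}.fastq"
        write_fastq(sim, path)
        paths[f"t{t}"] = path
    truth_path = outdir / "truth.tsv"
    truth_frame(sims, pool).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    config_path = outdir / "sim_config.yaml"
    config_path.write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )
    paths["config"] = config_path
    return paths
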