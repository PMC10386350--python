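"""Relative frequencies, enrichment factors, EF>1 shares and histograms."""

import math
from collections import Counter

import numpy as np
import pytest

from phagepool.enrichment import (
    ef_distribution,
    ef_library_shares,
    enrichment_factors,
    relative_frequencies,
)
from phagepool.errors import ConfigurationError, InputError
from phagepool.reads import TimepointCounts, process_records
from phagepool.simulate import (
    SimConfig,
    build_pool,
    emit_reads,
    simulate_trajectories,
)


def _counts(timepoint=0, phd7=None, phd12=None, phdc7c=None, removed=0, wt=0):
    return TimepointCounts(
        timepoint=timepoint,
        per_library={
            "PhD7": Counter(phd7 or {}),
            "PhD12": Counter(phd12 or {}),
            "PhDC7C": Counter(phdc7c or {}),
        },
        removed_count=removed,
        wt_count=wt,
    )


# --- relative frequencies ---------------------------------------------------

def test_relative_frequency_examples():
    single = relative_frequencies(_counts(phd7={"AAAAAAA": 10}))
    assert single.table.freq.tolist() == [1.0]
    two = relative_frequencies(_counts(phd7={"A": 25, "B": 75}))
    assert dict(zip(two.table.peptide, two.table.freq))["A"] == 0.25
    assert two.table.freq.sum() == pytest.approx(1.0, abs=1e-12)


def test_relative_frequency_denominator_modes():
    counts = _counts(phd7={"A": 50}, removed=50, wt=50)
    assert relative_frequencies(counts, "cleaned").table.freq.iloc[0] == 1.0
    assert relative_frequencies(counts, "all").table.freq.iloc[0] == 0.5
    with pytest.raises(ConfigurationError):
        relative_frequencies(counts, "bogus")
    with pytest.raises(InputError):
        relative_frequencies(_counts(removed=5))


def test_exact_mode_frequencies_match_ground_truth_proportions():
    cfg = SimConfig(seed=13, n_clones=20, depth=10_000, exact_mode=True)
    pool = build_pool(cfg)
    traj = simulate_trajectories(pool, cfg.timepoints)
    sims = emit_reads(pool, traj, cfg)
    tallies = process_records(
        zip(sims[0].read_ids, sims[0].sequences), cfg.anchor, 0
    )
    ft = relative_frequencies(tallies)
    by_pep = dict(zip(ft.table.peptide, ft.table.freq))
    cleaned = tallies.cleaned_count
    idx, counts = np.unique(sims[0].clone_indices, return_counts=True)
    for i, c in zip(idx, counts):
        if i == len(pool.clones):
            continue
        assert by_pep[pool.clones[i].peptide] == pytest.approx(c / cleaned)


# --- enrichment factors -----------------------------------------------------

def test_ef_identity_and_arithmetic():
    c0 = _counts(0, phd7={"A": 25, "B": 75})
    ef = enrichment_factors(
        relative_frequencies(c0), relative_frequencies(_counts(150, phd7={"A": 25, "B": 75}))
    )
    assert (ef.table.ef == 1.0).all()
    ef2 = enrichment_factors(
        relative_frequencies(_counts(0, phd7={"A": 1, "B": 99})),
        relative_frequencies(_counts(150, phd7={"A": 4, "B": 96})),
    )
    assert dict(zip(ef2.table.peptide, ef2.table.ef))["A"] == pytest.approx(4.0)


def test_ef_requires_time_order_and_warns_on_empty_overlap():
    a = relative_frequencies(_counts(0, phd7={"A": 1}))
    b = relative_frequencies(_counts(150, phd7={"B": 1}))
    with pytest.raises(InputError):
        enrichment_factors(b, a)
    with pytest.warns(UserWarning, match="overlap"):
        ef = enrichment_factors(a, b)
    assert ef.table.empty


def test_ef_overlap_is_count_intersection():
    a = relative_frequencies(_counts(0, phd7={"A": 5, "B": 5}, phd12={"C": 5}))
    b = relative_frequencies(_counts(150, phd7={"A": 5}, phd12={"C": 5, "D": 5}))
    ef = enrichment_factors(a, b)
    assert set(ef.table.peptide) == {"A", "C"}


def test_ef_against_closed_form_two_clone_race():
    """EF_i tracks exp((r_i - r_pool) * dt) with the pool log-growth rate."""
    cfg = SimConfig(
        seed=31,
        n_clones={"PhD7": 1, "PhD12": 1, "PhDC7C": 1},
        depth=200_000,
        exact_mode=True,
        wt_fraction_0=0.0,
        rate_means={"PhD7": 0.028, "PhD12": 0.020, "PhDC7C": 0.024},
        rate_sds={"PhD7": 0.0, "PhD12": 0.0, "PhDC7C": 0.0},
    )
    pool = build_pool(cfg)
    traj = simulate_trajectories(pool, cfg.timepoints)
    sims = emit_reads(pool, traj, cfg)
    tallies = {
        t: process_records(zip(s.read_ids, s.sequences), cfg.anchor, t)
        for t, s in sims.items()
    }
    ef = enrichment_factors(
        relative_frequencies(tallies[0]), relative_frequencies(tallies[270])
    )
    by_lib = dict(zip(ef.table.library, ef.table.ef))
    r_pool = math.log(traj[:, 2].sum() / traj[:, 0].sum()) / 270
    assert by_lib["PhD7"] == pytest.approx(math.exp((0.028 - r_pool) * 270), rel=1e-3)
    assert by_lib["PhD12"] == pytest.approx(math.exp((0.020 - r_pool) * 270), rel=1e-3)
    assert by_lib["PhD7"] > 1 > by_lib["PhD12"]


def test_ef_brute_force_oracle_on_random_tables(rng):
    """EFTable equals a direct dict-arithmetic recomputation from raw counts."""
    peptides = [f"P{i:04d}" for i in range(1000)]
    c0 = {p: int(rng.integers(0, 20)) for p in peptides}
    c1 = {p: int(rng.integers(0, 20)) for p in peptides}
    tc0 = _counts(0, phd7={p: c for p, c in c0.items() if c > 0})
    tc1 = _counts(150, phd7={p: c for p, c in c1.items() if c > 0})
    ef = enrichment_factors(relative_frequencies(tc0), relative_frequencies(tc1))
    got = dict(zip(ef.table.peptide, ef.table.ef))
    n0, n1 = sum(tc0.per_library["PhD7"].values()), sum(tc1.per_library["PhD7"].values())
    expected = {
        p: (c1[p] / n1) / (c0[p] / n0)
        for p in peptides
        if c0[p] > 0 and c1[p] > 0
    }
    assert got.keys() == expected.keys()
    for p in expected:
        assert got[p] == pytest.approx(expected[p], rel=1e-12)


# --- EF > 1 shares ----------------------------------------------------------

def _ef_table_from(counts0, counts1):
    return enrichment_factors(
        relative_frequencies(counts0), relative_frequencies(counts1)
    )


def test_ef_shares_match_retained_row_fractions():
    # 9 / 69 / 22 enriched rows -> 9% / 69% / 22%
    phd7 = {f"A{i}": 1 for i in range(9)}
    phd12 = {f"B{i}": 1 for i in range(69)}
    phdc7c = {f"C{i}": 1 for i in range(22)}
    c0 = _counts(0, phd7=phd7, phd12=phd12, phdc7c=phdc7c)
    # at t1 every peptide doubles except depth doubles too -> add filler to
    # keep all EFs > 1: halve the denominator instead by dropping filler
    filler = {"ZZZ": 100}
    c0 = _counts(0, phd7={**phd7, **filler}, phd12=phd12, phdc7c=phdc7c)
    c1 = _counts(150, phd7=phd7, phd12=phd12, phdc7c=phdc7c)
    shares = ef_library_shares(_ef_table_from(c0, c1))
    assert shares == {"PhD7": 9.0, "PhD12": 69.0, "PhDC7C": 22.0}


def test_ef_shares_exclude_ef_of_exactly_one():
    c0 = _counts(0, phd7={"A": 10, "B": 10})
    c1 = _counts(150, phd7={"A": 10, "B": 10})
    with pytest.warns(UserWarning, match="EF > 1"):
        assert ef_library_shares(_ef_table_from(c0, c1)) is None


def test_ef_shares_single_library_is_total():
    c0 = _counts(0, phd7={"A": 1, "Z": 9})
    c1 = _counts(150, phd7={"A": 5, "Z": 5})
    shares = ef_library_shares(_ef_table_from(c0, c1))
    assert shares == {"PhD7": 100.0, "PhD12": 0.0, "PhDC7C": 0.0}


# --- EF distribution --------------------------------------------------------

def test_ef_distribution_bins_and_conservation():
    c0 = _counts(0, phd7={"A": 10, "B": 10}, phd12={"C": 20})
    c1 = _counts(150, phd7={"A": 20, "B": 5}, phd12={"C": 15})
    ef = _ef_table_from(c0, c1)
    hist = ef_distribution(ef, bins=[0.25, 0.5, 1.0, 2.0, 4.0])
    per_lib_totals = hist.groupby("library")["count"].sum()
    assert per_lib_totals["PhD7"] == 2 and per_lib_totals["PhD12"] == 1
    # single known value: A has EF (20/40)/(10/40) = 2 -> [2, 4] bin
    row = hist[(hist.library == "PhD7") & (hist.bin_left == 2.0)]
    assert row["count"].iloc[0] >= 1


def test_ef_distribution_rejects_bad_bins():
    c0 = _counts(0, phd7={"A": 1, "B": 1})
    c1 = _counts(150, phd7={"A": 1, "B": 1})
    ef = _ef_table_from(c0, c1)
    with pytest.raises(ConfigurationError):
        ef_distribution(ef, bins=[-1.0, 1.0, 2.0])
    with pytest.raises(ConfigurationError):
        ef_distribution(ef, bins=[2.0, 1.0])


def test_ef_two_point_consistency_on_sampled_run(small_run):
    cfg = small_run["config"]
    tallies = {
        t: process_records(zip(s.read_ids, s.sequences), cfg.anchor, t)
        for t, s in small_run["sims"].items()
    }
    f = {t: relative_frequencies(tallies[t]) for t in (0, 150, 270)}
    ef_01 = enrichment_factors(f[0], f[150])
    ef_12 = enrichment_factors(f[150], f[270])
    ef_02 = enrichment_factors(f[0], f[270])
    prod = (
        ef_01.table.set_index(["library", "peptide"]).ef
        * ef_12.table.set_index(["library", "peptide"]).ef
    ).dropna()
    direct = ef_02.table.set_index(["library", "peptide"]).ef
    joint = prod.index.intersection(direct.index)
    assert len(joint) > 0
    assert np.allclose(prod.loc[joint], direct.loc[joint], atol=1e-9, rtol=0)
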