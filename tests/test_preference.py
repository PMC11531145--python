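"""Host-preference statistics: d', constrained permutations, 2DP, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rootfungi import CommunityTable, SampleMetadata
from rootfungi.community import CommunityDataError, to_binary
from rootfungi.preference import (
    bh_fdr,
    build_bipartite,
    dprime,
    dprime_bounds,
    kl_specialization,
    shuffle_within_position,
    standardized_preference,
    two_dim_preference,
)


def _exhaustive_bounds(total, caps):
    """Brute-force d_min/d_max over all integer allocations with cell caps."""
    caps = list(caps)
    q = np.array(caps) / sum(caps)
    best_lo, best_hi = np.inf, -np.inf
    def rec(j, rem, cells):
        nonlocal best_lo, best_hi
        if j == len(caps) - 1:
            if rem > caps[j]:
                return
            d = kl_specialization(np.array(cells + [rem]), q)
            best_lo, best_hi = min(best_lo, d), max(best_hi, d)
            return
        for v in range(min(rem, caps[j]) + 1):
            rec(j + 1, rem - v, cells + [v])
    rec(0, total, [])
    return best_lo, best_hi


class TestDPrime:
    def test_proportional_row_scores_zero(self):
        mat = np.array([[6, 3, 1], [12, 6, 2]])  # rows proportional to marginals
        d = dprime(mat)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_specialists_score_one(self):
        d = dprime(np.array([[10, 0], [0, 10]]))
        assert np.allclose(d, 1.0)
        lo, hi = _exhaustive_bounds(10, [10, 10])
        got_lo, got_hi = dprime_bounds(10, np.array([10, 10]))
        assert got_hi == pytest.approx(hi)
        assert got_lo == pytest.approx(lo)

    def test_mixed_row_matches_exhaustive_oracle(self):
        mat = np.array([[6, 2], [2, 6]])
        q = mat.sum(axis=0) / mat.sum()
        d = dprime(mat)
        lo, hi = _exhaustive_bounds(8, mat.sum(axis=0))
        expect = (kl_specialization(mat[0], q) - lo) / (hi - lo)
        assert d[0] == pytest.approx(expect)

    def test_single_plant_column_flagged_nan(self):
        assert np.isnan(dprime(np.array([[5], [3]]))).all()

    def test_scale_invariance_by_positive_integer(self):
        # the KL part is exactly invariant; the integer-redistribution bounds
        # relax slightly with finer granularity, so d' is invariant up to a
        # small discretisation term that vanishes as the matrix grows
        mat = np.array([[5, 2, 1], [1, 4, 2], [2, 2, 4]])
        assert np.allclose(dprime(mat), dprime(3 * mat), atol=0.02)
        assert np.allclose(dprime(10 * mat), dprime(30 * mat), atol=0.002)

    def test_matrix_path_agrees_with_scalar_bounds(self):
        rng = np.random.default_rng(7)
        mat = rng.integers(0, 6, size=(5, 3))
        mat[:, 0] += 1
        ct = mat.sum(axis=0)
        q = ct / ct.sum()
        got = dprime(mat)
        for i, row in enumerate(mat):
            lo, hi = dprime_bounds(int(row.sum()), ct)
            expect = (kl_specialization(row, q) - lo) / (hi - lo)
            assert got[i] == pytest.approx(expect, abs=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_match_exhaustive_search_small_totals(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 4)
        caps = rng.integers(1, 7, size=k)
        total = int(rng.integers(1, min(12, caps.sum()) + 1))
        lo, hi = dprime_bounds(total, caps)
        elo, ehi = _exhaustive_bounds(total, caps)
        assert lo == pytest.approx(elo, abs=1e-10)
        assert hi == pytest.approx(ehi, abs=1e-10)


class TestBipartite:
    def _data(self):
        rng = np.random.default_rng(0)
        rows = []
        samples = []
        for q in range(6):
            for i in range(4):
                host = ["Pinus", "Betula"][i % 2]
                sid = f"r{q}_{i}"
                rows.append((sid, "root", f"p{q}", q * 5.0, 0.0, host))
                samples.append(sid)
        meta = SampleMetadata(pd.DataFrame(
            rows, columns=["sample_id", "kind", "position_id", "x", "y", "host_plant"]))
        counts = rng.integers(0, 2, size=(len(samples), 5))
        counts[:, 0] = 1  # ubiquitous OTU
        table = CommunityTable(pd.DataFrame(
            counts, index=samples, columns=[f"o{j}" for j in range(5)]))
        return table, meta

    def test_occurrence_filter_boundary(self):
        table, meta = self._data()
        bip = build_bipartite(table, meta, min_otu_occurrence=24, min_host_samples=1)
        assert bip.otu_ids == ["o0"]  # only the ubiquitous OTU occurs in all 24

    def test_cell_counts_cross_tabulate(self):
        table, meta = self._data()
        bip = build_bipartite(table, meta, min_otu_occurrence=1, min_host_samples=1)
        df = bip.as_frame()
        assert df.loc["o0", "Pinus"] == 12 and df.loc["o0", "Betula"] == 12
        assert bip.m == bip.n.sum()

    def test_empty_result_errors(self):
        table, meta = self._data()
        with pytest.raises(CommunityDataError):
            build_bipartite(table, meta, min_otu_occurrence=1000)


class TestShuffle:
    def test_multiset_per_position_preserved(self):
        rng = np.random.default_rng(1)
        roots = pd.DataFrame({
            "sample_id": [f"r{i}" for i in range(9)],
            "position_id": ["p0"] * 3 + ["p1"] * 3 + ["p2"] * 3,
            "host_plant": ["A", "A", "B", "B", "C", "C", "A", "B", "C"],
        })
        for _ in range(10):
            perm = shuffle_within_position(roots, rng)
            for pos, grp in roots.groupby("position_id"):
                orig = sorted(grp["host_plant"])
                new = sorted(perm.loc[grp["sample_id"]])
                assert orig == new

    def test_single_sample_position_fixed(self):
        rng = np.random.default_rng(2)
        roots = pd.DataFrame({
            "sample_id": ["r0", "r1", "r2"],
            "position_id": ["p0", "p1", "p1"],
            "host_plant": ["A", "B", "C"],
        })
        perm = shuffle_within_position(roots, rng)
        assert perm.loc["r0"] == "A"

    def test_two_position_toy_matches_exhaustive_distribution(self):
        # 2 positions x 2 samples with hosts (A,B) each: four equally likely
        # joint arrangements of which two are distinct per position
        rng = np.random.default_rng(3)
        roots = pd.DataFrame({
            "sample_id": ["a1", "a2", "b1", "b2"],
            "position_id": ["p0", "p0", "p1", "p1"],
            "host_plant": ["A", "B", "A", "B"],
        })
        seen = {}
        n = 4000
        for _ in range(n):
            perm = shuffle_within_position(roots, rng)
            key = tuple(perm[s] for s in ["a1", "a2", "b1", "b2"])
            seen[key] = seen.get(key, 0) + 1
        assert len(seen) == 4  # exhaustive: 2 options per position
        for count in seen.values():
            assert count / n == pytest.approx(0.25, abs=0.03)


def _null_toy(seed=0, n_pos=8, per_pos=4, n_otus=6):
    rng = np.random.default_rng(seed)
    rows, samples = [], []
    hosts = ["Pinus", "Betula"]
    for q in range(n_pos):
        for i in range(per_pos):
            sid = f"r{q}_{i}"
            rows.append((sid, "root", f"p{q}", q * 5.0, 0.0, hosts[rng.integers(2)]))
            samples.append(sid)
    meta = SampleMetadata(pd.DataFrame(
        rows, columns=["sample_id", "kind", "position_id", "x", "y", "host_plant"]))
    counts = (rng.uniform(size=(len(samples), n_otus)) < 0.5).astype(int)
    table = CommunityTable(pd.DataFrame(
        counts, index=samples, columns=[f"o{j}" for j in range(n_otus)]))
    return table, meta


class TestStandardizedPreference:
    def test_monoculture_positions_degenerate(self):
        rng = np.random.default_rng(4)
        rows, samples = [], []
        for q in range(6):
            host = "Pinus" if q < 3 else "Betula"
            for i in range(3):
                sid = f"r{q}_{i}"
                rows.append((sid, "root", f"p{q}", q * 5.0, 0.0, host))
                samples.append(sid)
        meta = SampleMetadata(pd.DataFrame(
            rows, columns=["sample_id", "kind", "position_id", "x", "y", "host_plant"]))
        counts = (rng.uniform(size=(18, 4)) < 0.6).astype(int)
        table = CommunityTable(pd.DataFrame(
            counts, index=samples, columns=list("wxyz")))
        res = standardized_preference(table, meta, n_perm=50, seed=0,
                                      min_otu_occurrence=1, min_host_samples=1)
        assert res.otus["degenerate"].all()
        assert (res.otus["z"] == 0).all()

    def test_null_toy_z_centred(self):
        zs = []
        for seed in range(30):
            table, meta = _null_toy(seed)
            res = standardized_preference(table, meta, n_perm=200, seed=seed,
                                          min_otu_occurrence=3, min_host_samples=1)
            zs.append(res.otus.loc[~res.otus["degenerate"], "z"].to_numpy())
        z = np.concatenate(zs)
        assert abs(z.mean()) < 0.15
        assert 0.8 < z.std() < 1.2

    def test_plant_scores_share_permutation_stream(self):
        table, meta = _null_toy(5)
        res = standardized_preference(table, meta, n_perm=100, seed=9,
                                      min_otu_occurrence=3, min_host_samples=1)
        tdp = two_dim_preference(table, meta, n_perm=100, seed=9,
                                 min_otu_occurrence=3, min_host_samples=1)
        assert list(tdp.score.index) == list(res.otus.index)
        assert list(tdp.score.columns) == list(res.plants.index)


class TestTwoDimPreference:
    def test_score_zero_when_observed_equals_null_mean(self):
        table, meta = _null_toy(6)
        tdp = two_dim_preference(table, meta, n_perm=300, seed=1,
                                 min_otu_occurrence=3, min_host_samples=1)
        # an OTU present in every sample cannot move under permutation
        counts = table.counts.copy()
        counts[:, 0] = 1
        table2 = CommunityTable(pd.DataFrame(counts, index=table.sample_ids,
                                             columns=table.otu_ids))
        tdp2 = two_dim_preference(table2, meta, n_perm=300, seed=1,
                                  min_otu_occurrence=3, min_host_samples=1)
        assert np.isnan(tdp2.score.loc["o0"]).all()  # sd 0 -> flagged

    def test_toy_matches_exhaustive_enumeration(self):
        # one position with 2 samples (hosts A, B): exactly two arrangements
        meta = SampleMetadata(pd.DataFrame(
            [("r0", "root", "p0", 0.0, 0.0, "A"), ("r1", "root", "p0", 0.0, 0.0, "B")],
            columns=["sample_id", "kind", "position_id", "x", "y", "host_plant"]))
        table = CommunityTable(pd.DataFrame(
            [[1, 1], [0, 1]], index=["r0", "r1"], columns=["u", "v"]))
        tdp = two_dim_preference(table, meta, n_perm=2000, seed=2,
                                 min_otu_occurrence=1, min_host_samples=1)
        # OTU u occurs only in r0: N(u, A) is 1 or 0 with equal probability
        # -> mean 0.5, sd 0.5, observed 1 -> score 1
        assert tdp.score.loc["u", "A"] == pytest.approx(1.0, abs=0.1)
        assert np.isnan(tdp.score.loc["v", "A"])  # v in both samples: sd 0


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_example_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr(np.ones(5)), 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
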