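"""Windowed FST/π sweep scan, candidate selection and gene annotation."""

import numpy as np
import pandas as pd
import pytest

from popscan.genio import GeneModel, MISSING, PopulationPanel
from popscan.simdata import SimConfig, SweepSpec, simulate_populations
from popscan.sweepscan import (
    CandidateSets,
    Window,
    genes_in_windows,
    log2_pi_ratio,
    make_windows,
    merge_and_annotate,
    merge_windows,
    rod,
    scan,
    select_candidates,
    wc_fst,
    wc_site_components,
    z_transform,
)

from conftest import make_gm, two_pop_panel


def wc_oracle(geno_a, geno_b):
    """Textbook Weir & Cockerham (1984) two-population per-site components,
    written as plain scalar arithmetic from genotype lists."""
    a_list = [g for g in geno_a if g != MISSING]
    b_list = [g for g in geno_b if g != MISSING]
    n1, n2 = len(a_list), len(b_list)
    if n1 < 2 or n2 < 2:
        return float("nan"), float("nan")
    p1 = sum(a_list) / (2 * n1)
    p2 = sum(b_list) / (2 * n2)
    h1 = sum(1 for g in a_list if g == 1) / n1
    h2 = sum(1 for g in b_list if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar in (0.0, 1.0):
        return float("nan"), float("nan")
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


class TestMakeWindows:
    def test_truncated_final_windows(self):
        w = make_windows({"1": 100_000})
        assert len(w) == 10
        assert w[0].start == 0 and w[0].end == 40_000
        assert w[-1].start == 90_000 and w[-1].end == 100_000

    def test_length_equal_to_window(self):
        assert len(make_windows({"1": 40_000})) == 4

    def test_every_position_covered_and_interior_four_deep(self):
        L = 200_000
        windows = make_windows({"1": L})
        depth = np.zeros(L, dtype=int)
        for w in windows:
            depth[w.start : w.end] += 1
        assert depth.min() >= 1
        assert (depth[30_000 : L - 30_000] == 4).all()


class TestWCFst:
    def test_fixed_difference_is_exactly_one(self):
        d = np.vstack([np.zeros((10, 3)), np.full((10, 3), 2)]).astype(np.int8)
        gm = make_gm(d)
        assert wc_fst(gm, two_pop_panel(gm), "popA", "popB") == 1.0

    def test_identical_populations_near_zero(self, rng):
        block = rng.choice([0, 1, 2], size=(10, 50), p=[0.25, 0.5, 0.25])
        d = np.vstack([block, block]).astype(np.int8)
        gm = make_gm(d)
        est = wc_fst(gm, two_pop_panel(gm), "popA", "popB")
        assert est <= 0 and abs(est) < 0.2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracle(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = int(r.integers(2, 11)), int(r.integers(2, 11))
        m = int(r.integers(5, 51))
        d = np.vstack(
            [
                r.choice([0, 1, 2, MISSING], size=(n1, m), p=[0.35, 0.2, 0.35, 0.1]),
                r.choice([0, 1, 2, MISSING], size=(n2, m), p=[0.2, 0.3, 0.4, 0.1]),
            ]
        ).astype(np.int8)
        gm = make_gm(d)
        panel = PopulationPanel(
            {s: ("popA" if i < n1 else "popB") for i, s in enumerate(gm.sample_ids)}
        )
        a, total = wc_site_components(gm, panel, "popA", "popB")
        num = den = 0.0
        for j in range(m):
            ao, to = wc_oracle(d[:n1, j], d[n1:, j])
            if np.isnan(ao):
                assert np.isnan(a[j])
                continue
            assert a[j] == pytest.approx(ao, abs=1e-12)
            assert total[j] == pytest.approx(to, abs=1e-12)
            num += ao
            den += to
        if den:
            assert wc_fst(gm, panel, "popA", "popB") == pytest.approx(
                num / den, abs=1e-12
            )

    def test_window_restriction(self, rng):
        d = rng.choice([0, 1, 2], size=(12, 20)).astype(np.int8)
        gm = make_gm(d)  # positions 1000..20000
        panel = two_pop_panel(gm)
        full = wc_fst(gm, panel, "popA", "popB")
        left = wc_fst(gm, panel, "popA", "popB", Window("1", 0, 10_000))
        right = wc_fst(gm, panel, "popA", "popB", Window("1", 10_000, 20_000))
        assert np.isfinite(left) and np.isfinite(right)
        assert left != right or full == left


class TestRatioStatistics:
    def test_rod_values(self):
        assert rod(0.001, 0.004) == pytest.approx(0.75)
        assert rod(0.002, 0.002) == 0.0
        assert rod(0.0, 0.004) == 1.0
        assert np.isnan(rod(0.001, 0.0))

    def test_log2_ratio_values(self):
        assert log2_pi_ratio(0.004, 0.001) == pytest.approx(2.0)
        assert log2_pi_ratio(0.003, 0.003) == 0.0
        assert np.isnan(log2_pi_ratio(0.0, 0.001))
        assert log2_pi_ratio(0.004, 0.0) == np.inf  # fully swept window

    def test_log2_equals_neg_log2_one_minus_rod(self, rng):
        pi_t = rng.uniform(1e-5, 1e-3, size=50)
        pi_c = rng.uniform(1e-5, 1e-3, size=50)
        lhs = log2_pi_ratio(pi_c, pi_t)
        rhs = -np.log2(1.0 - rod(pi_t, pi_c))
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestZTransform:
    def test_three_point_example(self):
        np.testing.assert_allclose(z_transform([0.1, 0.2, 0.3]), [-1, 0, 1],
                                   atol=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            z_transform([0.5, 0.5, 0.5])

    def test_standardization_and_nan_propagation(self, rng):
        x = rng.normal(size=100)
        x[[3, 7]] = np.nan
        z = z_transform(x)
        fin = np.isfinite(z)
        assert np.isnan(z[3]) and np.isnan(z[7])
        assert np.mean(z[fin]) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z[fin], ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestSelectCandidates:
    @staticmethod
    def _df(fst, div):
        n = len(fst)
        return pd.DataFrame(
            {"CHROM": "1", "BIN_START": np.arange(n) * 10_000,
             "BIN_END": np.arange(n) * 10_000 + 40_000,
             "Z_FST": fst, "ROD": div}
        )

    def test_five_percent_of_hundred(self, rng):
        fst = rng.permutation(100).astype(float)
        div = rng.permutation(100).astype(float)
        cand = select_candidates(self._df(fst, div))
        assert cand.fst_windows.size == 5
        assert cand.div_windows.size == 5
        assert cand.joint_windows.size <= 5

    def test_identical_ranking_full_intersection(self):
        v = np.arange(100, dtype=float)
        cand = select_candidates(self._df(v, v))
        assert cand.joint_windows.size == 5

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError, match="too few"):
            select_candidates(self._df(np.arange(5.0), np.arange(5.0)))

    def test_nan_windows_excluded_from_quantile(self):
        fst = np.arange(40, dtype=float)
        fst[:10] = np.nan
        cand = select_candidates(self._df(fst, fst), q=0.1)
        assert cand.fst_windows.size == 3  # 10% of 30 finite values
        assert not np.isin(cand.fst_windows, np.arange(10)).any()


class TestMergeAnnotate:
    def test_overlapping_windows_merge(self):
        df = TestSelectCandidates._df(np.arange(10.0), np.arange(10.0))
        regions = merge_windows(df, np.array([0, 1]))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 50_000)

    def test_gene_window_intersection_one_bp(self):
        df = TestSelectCandidates._df(np.arange(10.0), np.arange(10.0))
        genes = [GeneModel("g1", "1", 45_001, 60_000),  # 5 kb into [0,50k)
                 GeneModel("g2", "1", 50_001, 60_000)]  # starts past it
        hit = genes_in_windows(df, np.array([0, 1]), genes)
        assert hit == {"g1"}

    def test_gene_sets_match_brute_force(self, rng):
        from popscan.simdata import simulate_genes

        df = TestSelectCandidates._df(
            rng.normal(size=60), rng.normal(size=60))
        genes = simulate_genes({"1": 700_000}, 30, seed=9)
        idx_f = rng.choice(60, size=8, replace=False)
        idx_d = rng.choice(60, size=8, replace=False)
        cand = CandidateSets(np.sort(idx_f), np.sort(idx_d),
                             np.sort(np.intersect1d(idx_f, idx_d)), 0.0, 0.0)
        regions, gene_sets = merge_and_annotate(df, cand, genes)

        def brute(idx):
            out = set()
            for g in genes:
                for i in idx:
                    s, e = df.BIN_START[i], df.BIN_END[i]
                    if g.start - 1 < e and g.end > s:
                        out.add(g.gene_id)
            return out

        assert gene_sets["fst"] == brute(idx_f)
        assert gene_sets["diversity"] == brute(idx_d)
        assert gene_sets["joint"] == brute(idx_f) & brute(idx_d)
        for r in regions:
            assert r.end > r.start
        for a, b in zip(regions[:-1], regions[1:]):
            assert a.end < b.start or a.chrom != b.chrom


@pytest.fixture(scope="module")
def sweep_scan():
    # 5-Mb chromosome: ~500 windows, so the top-5% budget (~25) can hold the
    # ~23 windows touching a 200-kb sweep
    cfg = SimConfig(
        n_sites=10_000, samples_per_pop=20, chrom_lengths={"1": 5_000_000},
        divergence_f=0.1, seed=11,
        sweeps=[SweepSpec("pop1", "1", 2_000_000, 2_200_000, 1.0)],
    )
    gm, panel, truth = simulate_populations(cfg)
    return scan(gm, panel, "pop1", "pop2"), truth


class TestScanIntegration:

    def test_rod_and_log2_rankings_identical(self, sweep_scan):
        df, _ = sweep_scan
        a = select_candidates(df, div_stat="ROD")
        b = select_candidates(df, div_stat="LOG2_RATIO")
        np.testing.assert_array_equal(a.div_windows, b.div_windows)

    def test_fst_bounded_and_z_standardized(self, sweep_scan):
        df, _ = sweep_scan
        fst = df["WEIGHTED_FST"].dropna()
        assert (fst <= 1.0).all() and (fst > -0.2).all()
        z = df["Z_FST"].dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_sweep_windows_enriched_in_both_tails(self, sweep_scan):
        df, truth = sweep_scan
        sw = truth["sweeps"][0]
        overlap = (df.BIN_END > sw["start"]) & (df.BIN_START < sw["end"])
        cand = select_candidates(df)
        in_joint = np.isin(np.flatnonzero(overlap), cand.joint_windows)
        assert in_joint.mean() >= 0.5

    def test_chromosome_processing_order_invariance(self):
        cfg = SimConfig(n_sites=2000, samples_per_pop=10,
                        chrom_lengths={"1": 400_000, "2": 400_000},
                        missing_rate=0.0, seed=4)
        gm, panel, _ = simulate_populations(cfg)
        df = scan(gm, panel, "pop1", "pop2")
        # reverse chromosome order and rescan
        idx = np.concatenate([np.flatnonzero(gm.chrom == "2"),
                              np.flatnonzero(gm.chrom == "1")])
        gm2 = make_gm(gm.dosage[:, idx], pos=gm.pos[idx], chrom=gm.chrom[idx],
                      sample_ids=gm.sample_ids)
        panel2 = PopulationPanel(dict(panel.mapping))
        df2 = scan(gm2, panel2, "pop1", "pop2",
                   chrom_lengths={"2": 400_000, "1": 400_000})
        m1 = df.set_index(["CHROM", "BIN_START"]).sort_index()
        m2 = df2.set_index(["CHROM", "BIN_START"]).sort_index()
        pd.testing.assert_frame_equal(m1[["WEIGHTED_FST", "ROD"]],
                                      m2[["WEIGHTED_FST", "ROD"]])
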