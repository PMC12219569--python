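import numpy as np
import pandas as pd
import pytest

from regshift.io import GeneModel, GenomicInterval, SignalTrack
from regshift.regpot import (
    RPParams,
    compute_rp,
    delta_rp,
    insilico_delete,
    isd_delta_rp,
    match_background_genes,
    rank_regulators,
    targeted_isd,
)


def make_track(values, chrom="chr1"):
    return SignalTrack({chrom: np.asarray(values, dtype=float)})


def brute_force_rp(track, gene, delta, window):
    """Independent per-base oracle: every base is its own bin centered at
    base + 0.5."""
    total = 0.0
    arr = track.data[gene.chrom]
    for i, v in enumerate(arr):
        d = abs(i + 0.5 - gene.tss)
        if d <= window:
            total += v * 2.0 ** (-d / delta)
    return total


class TestRPParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            RPParams(decay_half_distance=0)
        with pytest.raises(ValueError):
            RPParams(decay_half_distance=1000, window=500, bin_size=100)
        with pytest.raises(ValueError):
            RPParams(window=100_000, bin_size=3_000)


class TestComputeRP:
    params = RPParams(decay_half_distance=100, window=1000, bin_size=10)

    def test_unit_mass_at_tss(self):
        # one unit in the bin whose center coincides with the TSS (d=0)
        track = make_track(np.zeros(2000))
        track.data["chr1"][505] = 1.0          # bin [500,510) centered at 505
        gene = GeneModel("g", "chr1", 505, 600, "+")
        rp = compute_rp(track, [gene], self.params)
        assert rp["g"] == pytest.approx(1.0)

    def test_half_decay_at_delta(self):
        track = make_track(np.zeros(2000))
        track.data["chr1"][605] = 1.0          # bin center 605, 100 bp away
        gene = GeneModel("g", "chr1", 505, 700, "+")
        rp = compute_rp(track, [gene], self.params)
        assert rp["g"] == pytest.approx(0.5)

    def test_additivity(self):
        track = make_track(np.zeros(2000))
        track.data["chr1"][505] = 1.0
        track.data["chr1"][605] = 1.0
        gene = GeneModel("g", "chr1", 505, 700, "+")
        assert compute_rp(track, [gene], self.params)["g"] == pytest.approx(1.5)

    def test_beyond_window_contributes_nothing(self):
        track = make_track(np.zeros(4000))
        track.data["chr1"][3005] = 50.0        # 2.5 kb from TSS, W = 1 kb
        gene = GeneModel("g", "chr1", 505, 600, "+")
        assert compute_rp(track, [gene], self.params)["g"] == 0.0

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(5)
        track = make_track(rng.poisson(2.0, 20).astype(float))
        params = RPParams(decay_half_distance=4, window=12, bin_size=1)
        genes = [GeneModel(f"g{i}", "chr1", i + 1, 20, "+") for i in range(10)]
        rp = compute_rp(track, genes, params)
        for g in genes:
            expected = brute_force_rp(track, g, 4, 12)
            assert rp[g.gene_id] == pytest.approx(expected, rel=1e-9)

    def test_linearity_in_signal(self, default_dataset):
        from regshift.pipeline import consensus_track
        track = consensus_track(default_dataset)
        genes = default_dataset.genes[:20]
        rp1 = compute_rp(track, genes)
        scaled = SignalTrack({c: 3.5 * a for c, a in track.data.items()})
        rp2 = compute_rp(scaled, genes)
        pd.testing.assert_series_equal(rp2, 3.5 * rp1)

    def test_tss_off_chromosome_rejected(self):
        track = make_track(np.zeros(100))
        gene = GeneModel("g", "chr1", 50, 500, "-")   # TSS at 499
        with pytest.raises(ValueError, match="off chromosome"):
            compute_rp(track, [gene], RPParams(10, 100, 10))


class TestInsilicoDelete:
    def test_empty_site_set_is_identity(self):
        track = make_track([1, 2, 3, 4])
        out = insilico_delete(track, [])
        np.testing.assert_array_equal(out.data["chr1"], track.data["chr1"])

    def test_full_coverage_zeroes_track(self):
        track = make_track([1, 2, 3, 4])
        out = insilico_delete(track, [GenomicInterval("chr1", 0, 4)])
        assert out.library_size == 0.0

    def test_masking_reduces_rp_by_masked_share(self):
        # site holds 30% of the gene's weighted signal at distance 0
        params = RPParams(decay_half_distance=100, window=1000, bin_size=10)
        track = make_track(np.zeros(2000))
        track.data["chr1"][500:510] = 0.7      # 7 units in the TSS bin
        track.data["chr1"][510:513] = 1.0      # 3 units in the next bin
        gene = GeneModel("g", "chr1", 505, 600, "+")
        before = compute_rp(track, [gene], params)
        masked = insilico_delete(track, [GenomicInterval("chr1", 510, 513)])
        after = compute_rp(masked, [gene], params)
        d = delta_rp(before, after)["g"]
        w0, w1 = 1.0, 2.0 ** (-10 / 100)       # bin centers at d=0 and d=10
        assert d == pytest.approx(3 * w1 / (7 * w0 + 3 * w1), rel=1e-9)


class TestDeltaRP:
    def test_fractional_reduction_arithmetic(self):
        d = delta_rp(pd.Series({"g": 10.0}), pd.Series({"g": 8.9}))
        assert d["g"] == pytest.approx(0.11)

    def test_identity_and_total_deletion(self):
        before = pd.Series({"a": 5.0, "b": 0.0})
        assert delta_rp(before, before).tolist() == [0.0, 0.0]
        total = delta_rp(before, pd.Series({"a": 0.0, "b": 0.0}))
        assert total["a"] == 1.0 and total["b"] == 0.0

    def test_increase_after_masking_rejected(self):
        with pytest.raises(ValueError, match="increased"):
            delta_rp(pd.Series({"g": 1.0}), pd.Series({"g": 2.0}))

    def test_monotone_in_site_set_inclusion(self, default_dataset):
        from regshift.pipeline import consensus_track
        ds = default_dataset
        track = consensus_track(ds)
        genes = ds.genes
        sites = ds.annotation.sites[ds.config.planted_regulator]
        small = isd_delta_rp(track, sites[:50], genes)
        large = isd_delta_rp(track, sites, genes)
        assert (large >= small - 1e-12).all()


class TestRankRegulators:
    def test_flat_tf_ranks_bottom_with_p_one(self):
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        active = pd.Series(rng.random(40), index=genes)
        flat = pd.Series(0.0, index=genes)
        ranking = rank_regulators(
            {"A": active, "Z": flat}, de_genes=set(genes[:10]),
            all_genes=genes, n_background=20, seed=0)
        assert ranking.iloc[-1]["tf"] == "Z"
        assert ranking.iloc[-1]["p"] == 1.0

    def test_empty_de_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_regulators({}, set(), ["g1"], n_background=1)

    def test_background_budget_enforced(self):
        d = {"A": pd.Series({"g1": 0.1, "g2": 0.2})}
        with pytest.raises(ValueError, match="n_background"):
            rank_regulators(d, {"g1"}, ["g1", "g2"], n_background=5)

    def test_null_pvalues_roughly_uniform(self, default_dataset):
        # random DE sets: rank-sum p over repeated draws is uniform
        from scipy import stats

        from regshift.pipeline import consensus_track
        ds = default_dataset
        track = consensus_track(ds)
        delta = {tf: isd_delta_rp(track, s, ds.genes)
                 for tf, s in list(ds.annotation.sites.items())[1:3]}
        gene_ids = [g.gene_id for g in ds.genes]
        rng = np.random.default_rng(123)
        pvals = []
        for i in range(100):
            de = set(rng.choice(gene_ids, size=20, replace=False))
            r = rank_regulators(delta, de, gene_ids, n_background=100,
                                seed=int(rng.integers(2**31)))
            pvals.extend(r["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMatchBackgroundGenes:
    def test_single_stratum_composition(self):
        genes = [f"g{i:02d}" for i in range(30)]
        expr = pd.Series(np.arange(30, dtype=float), index=genes)
        de = {"g10", "g11"}                     # both mid-expression
        sets = match_background_genes(de, genes, expr, n_sets=5, set_size=2,
                                      n_bins=3, seed=1)
        # stratum 1 covers ranks 10..19
        stratum = set(genes[10:20]) - de
        for s in sets:
            assert len(s) == 2 and set(s) <= stratum

    def test_contract_sizes(self, default_dataset):
        ds = default_dataset
        expr = pd.Series({g.gene_id: g.expression for g in ds.genes})
        gene_ids = list(expr.index)
        de = set(ds.annotation.target_genes)
        sets = match_background_genes(de, gene_ids, expr, n_sets=50,
                                      set_size=len(de), seed=3)
        assert len(sets) == 50
        assert all(len(s) == len(de) and not (set(s) & de) for s in sets)

    def test_set_size_must_match(self):
        with pytest.raises(ValueError, match="set_size"):
            match_background_genes({"a"}, ["a", "b"], pd.Series({"a": 1.0, "b": 2.0}),
                                   n_sets=1, set_size=2)

    def test_oversubscribed_stratum_named(self):
        genes = ["a", "b", "c", "d"]
        expr = pd.Series([1.0, 2.0, 3.0, 4.0], index=genes)
        with pytest.raises(ValueError, match="stratum"):
            match_background_genes({"c", "d"}, genes, expr, n_sets=1,
                                   set_size=2, n_bins=2)

    def test_matched_sets_track_de_expression(self, default_dataset):
        # expression is log-normal, so matching is assessed on the log scale
        # (the arithmetic mean of a quantile-matched set is dominated by
        # top-decile tail draws and is not a stable matching summary)
        ds = default_dataset
        expr = pd.Series({g.gene_id: g.expression for g in ds.genes})
        log_expr = np.log2(expr)
        de = set(ds.annotation.target_genes)
        means = []
        for seed in range(20):
            sets = match_background_genes(de, list(expr.index), expr,
                                          n_sets=50, set_size=len(de),
                                          seed=seed)
            means.append(np.mean([log_expr[list(s)].mean() for s in sets]))
        de_mean = log_expr[list(de)].mean()
        assert abs(np.mean(means) - de_mean) / abs(de_mean) < 0.05


class TestTargetedISD:
    def test_empty_altered_sites(self, default_dataset):
        ds = default_dataset
        from regshift.pipeline import consensus_track, de_gene_set
        expr = pd.Series({g.gene_id: g.expression for g in ds.genes})
        res = targeted_isd(consensus_track(ds), [], ds.genes,
                           de_gene_set(ds.de_treated), expr, n_null=50)
        assert res.observed == 0 and res.p == 1.0

    def test_threshold_is_strict(self):
        # engineered gene losing exactly 10% of RP: not counted as disrupted
        params = RPParams(decay_half_distance=100, window=1000, bin_size=10)
        track = make_track(np.zeros(4000))
        genes = []
        for i in range(10):
            tss = 205 + i * 300                 # bin centers at 205, 505, ...
            track.data["chr1"][tss] = 9.0
            track.data["chr1"][tss + 1] = 1.0
            genes.append(GeneModel(f"g{i}", "chr1", tss, tss + 50, "+"))
        expr = pd.Series(1.0, index=[g.gene_id for g in genes])
        site = [GenomicInterval("chr1", 206, 207)]   # exactly 1 of g0's 10 units
        res = targeted_isd(track, site, genes, {"g0"}, expr, n_null=20,
                           params=params, pad=0, n_bins=2, seed=0)
        assert res.observed == 0
        res2 = targeted_isd(track, [GenomicInterval("chr1", 205, 207)],
                            genes, {"g0"}, expr, n_null=20, params=params,
                            pad=0, n_bins=2, seed=0)
        assert res2.observed == 1

    def test_add_one_estimator_bounds(self, default_dataset):
        ds = default_dataset
        from regshift.pipeline import consensus_track, de_gene_set
        expr = pd.Series({g.gene_id: g.expression for g in ds.genes})
        res = targeted_isd(consensus_track(ds), ds.annotation.altered_sites,
                           ds.genes, de_gene_set(ds.de_treated), expr,
                           n_null=99, seed=2)
        assert res.p >= 1 / 100
        assert len(res.null_counts) == 99
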