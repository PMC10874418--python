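"""Gene Set Z-scores, Fisher overrepresentation, cell-type correlation."""

import numpy as np
import pandas as pd
import pytest
from math import comb

from chronosom.annotate import (
    GeneSetCollection,
    annotate_spots,
    correlate_celltypes,
    fisher_overrepresentation,
    geneset_zscore,
)
from chronosom.spots import Spot


def hypergeom_tail_oracle(a: int, N: int, K: int, n: int) -> float:
    """Brute-force upper tail P(X >= a) by summing exact binomial products."""
    total = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(a, min(K, n) + 1)
        if n - x <= N - K
    ) / total


class TestGenesetZscore:
    def test_full_universe_set_gives_zero(self, small_cohort):
        cfg, X, meta, truth = small_cohort
        z = geneset_zscore(X, list(X.index))
        assert np.allclose(z.to_numpy(), 0.0)

    def test_hand_evaluated_formula(self):
        """Centered values {1,1,-1,-1}, set = first two genes:
        Z = (1 - 0) / ((2/sqrt(3)) / sqrt(2)) = sqrt(6)/2 ~ 1.2247."""
        X = pd.DataFrame(
            {"s1": [1.0, 1.0, -1.0, -1.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        z = geneset_zscore(X, ["g1", "g2"])
        assert z["s1"] == pytest.approx(np.sqrt(6) / 2, abs=1e-4)

    def test_scale_invariance(self, small_cohort):
        cfg, X, meta, truth = small_cohort
        genes = truth.modules["M1"]
        z1 = geneset_zscore(X, genes)
        z2 = geneset_zscore(X * 3.7, genes)
        assert np.allclose(z1.to_numpy(), z2.to_numpy())

    def test_empty_intersection_rejected(self, small_cohort):
        cfg, X, meta, truth = small_cohort
        with pytest.raises(ValueError, match="no genes"):
            geneset_zscore(X, ["nope1", "nope2"])

    def test_module_zscore_tracks_planted_trajectory(self, small_cohort):
        """The planted module's set Z-score is more extreme where the planted
        trajectory is extreme than in mid-range samples."""
        cfg, X, meta, truth = small_cohort
        from chronosom.preprocess import center_genes

        Xc = center_genes(X)
        mod = "M1"  # early logistic decline: extreme young vs old
        z = geneset_zscore(Xc, truth.modules[mod])
        traj = truth.trajectories[mod](meta["age"].to_numpy())
        extreme = np.abs(traj - traj.mean()) > np.quantile(np.abs(traj - traj.mean()), 0.7)
        assert np.abs(z[extreme]).mean() > np.abs(z[~extreme]).mean()


class TestFisherOverrepresentation:
    def test_spot_equals_universe_forces_p_one(self):
        uni = [f"g{i}" for i in range(30)]
        rec = fisher_overrepresentation(uni, uni[:7], uni)
        assert rec.p == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one_for_enrichment_tail(self):
        uni = [f"g{i}" for i in range(40)]
        rec = fisher_overrepresentation(uni[:10], uni[30:], uni)
        assert rec.in_spot_in_set == 0
        assert rec.p == pytest.approx(1.0)

    def test_matches_bruteforce_hypergeometric_tail(self):
        """Sampled 2x2 tables with margins <= 50 agree with the enumeration
        oracle within 1e-10 (exhaustive sweep lives in the acceptance run)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 51))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            a_max = min(K, n)
            a = int(rng.integers(0, a_max + 1))
            if n - a > N - K:
                continue
            uni = [f"g{i}" for i in range(N)]
            spot = uni[:n]
            geneset = uni[:a] + uni[n : n + (K - a)]
            rec = fisher_overrepresentation(spot, geneset, uni)
            assert rec.in_spot_in_set == a
            assert rec.p == pytest.approx(hypergeom_tail_oracle(a, N, K, n), abs=1e-10)

    def test_example_table_overlap5(self):
        """Universe 100, set 10, spot 10, overlap 5: p equals the brute-force
        tail sum."""
        uni = [f"g{i}" for i in range(100)]
        spot = uni[:10]
        geneset = uni[:5] + uni[10:15]
        rec = fisher_overrepresentation(spot, geneset, uni)
        assert rec.p == pytest.approx(hypergeom_tail_oracle(5, 100, 10, 10), abs=1e-12)

    def test_p_monotone_decreasing_in_overlap(self):
        N, K, n = 40, 12, 10
        ps = [hypergeom_tail_oracle(a, N, K, n) for a in range(0, min(K, n) + 1)]
        uni = [f"g{i}" for i in range(N)]
        got = []
        for a in range(0, min(K, n) + 1):
            spot = uni[:n]
            geneset = uni[:a] + uni[n : n + (K - a)]
            got.append(fisher_overrepresentation(spot, geneset, uni).p)
        assert np.allclose(got, ps, atol=1e-12)
        assert all(got[i + 1] <= got[i] for i in range(len(got) - 1))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_overrepresentation(["g1"], ["g1"], [])


class TestAnnotateSpots:
    def test_planted_set_is_top_hit_per_spot(self, small_cohort):
        """End to end: each recovered spot's own module set attains the
        minimum p across all sets."""
        from chronosom.preprocess import center_genes
        from chronosom.som_portrait import train_som
        from chronosom.spots import segment_spots, summary_maps
        from chronosom.synthetic_data import generate_genesets

        cfg, X, meta, truth = small_cohort
        Xc = center_genes(X)
        model = train_som(Xc, k=8, epochs=20)
        maps = summary_maps(model, meta["diagnosis"])
        spots = segment_spots(
            maps.variance, quantile=0.8, min_size=3, model=model,
            similarity_threshold=0.9,
        )
        coll = generate_genesets(truth, extra_random_sets=4, seed=1)
        table = annotate_spots(spots, coll, universe=list(X.index))
        # map each spot to its best-matching planted module
        for spot in spots:
            gs = set(spot.genes)
            mod, jac = max(
                (
                    (m, len(gs & set(g)) / len(gs | set(g)))
                    for m, g in truth.modules.items()
                ),
                key=lambda t: t[1],
            )
            if jac < 0.6:
                continue
            sub = table[table["spot"] == spot.label].sort_values("p")
            assert sub.iloc[0]["set"] == f"SET_{mod}"
        # BH adjustment is valid
        assert (table["p_adjusted"] >= table["p"] - 1e-12).all()
        assert (table["p_adjusted"] <= 1.0).all()


class TestCorrelateCelltypes:
    def test_identical_signature_linked(self):
        samples = [f"s{i}" for i in range(10)]
        expr = pd.DataFrame([np.arange(10.0)], index=["A"], columns=samples)
        sig = pd.DataFrame([np.arange(10.0)], index=["neuron"], columns=samples)
        r, edges = correlate_celltypes(expr, sig, r_threshold=0.5)
        assert r.loc["A", "neuron"] == pytest.approx(1.0)
        assert len(edges) == 1

    def test_threshold_is_strict(self):
        """r exactly at the threshold is NOT linked."""
        samples = [f"s{i}" for i in range(3)]
        expr = pd.DataFrame([[1.0, 0.0, -1.0]], index=["A"], columns=samples)
        sig = pd.DataFrame([[1.0, 0.0, -1.0]], index=["x"], columns=samples)
        r, edges = correlate_celltypes(expr, sig, r_threshold=1.0)
        assert r.loc["A", "x"] == pytest.approx(1.0)
        assert len(edges) == 0

    def test_independent_signature_rarely_linked(self):
        """Null Monte-Carlo: with n=200 samples an independent random
        signature stays below |r| = 0.5 in >=99% of seeds."""
        samples = [f"s{i}" for i in range(200)]
        base = np.sin(np.linspace(0, 6, 200))
        expr = pd.DataFrame([base], index=["A"], columns=samples)
        dropped = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            sig = pd.DataFrame([rng.normal(size=200)], index=["x"], columns=samples)
            r, edges = correlate_celltypes(expr, sig, r_threshold=0.5)
            dropped += abs(r.loc["A", "x"]) < 0.5
        assert dropped >= 0.99 * n_rep

    def test_constant_rows_skipped_with_warning(self):
        samples = [f"s{i}" for i in range(5)]
        expr = pd.DataFrame(
            [[1.0] * 5, [1, 2, 3, 4, 5]], index=["flat", "ok"], columns=samples
        )
        sig = pd.DataFrame([[1, 2, 3, 4, 5.0]], index=["x"], columns=samples)
        with pytest.warns(UserWarning, match="constant"):
            r, edges = correlate_celltypes(expr, sig)
        assert np.isnan(r.loc["flat", "x"])
        assert r.loc["ok", "x"] == pytest.approx(1.0)


def test_geneset_collection_validation():
    with pytest.raises(ValueError, match="empty"):
        GeneSetCollection({"bad": []})
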