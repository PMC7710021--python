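"""Sparse logistic regression, stability selection and motif clustering."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from nfkbrepo.consensus import GenomicInterval
from nfkbrepo.mealr import (
    cluster_motifs,
    fit_sparse_lr,
    map_motifs_to_genes,
    motif_similarity,
    sample_background,
    select_across_datasets,
    stability_select,
    StabilitySelection,
)
from nfkbrepo.motifs import FeatureTable, PositionWeightMatrix, to_log_odds


def penalised_loglik(beta0, beta, X, y, lam):
    z = beta0 + X @ beta
    ll = np.sum(y * z - np.log1p(np.exp(z)))
    return ll - lam * np.sum(np.abs(beta))


def oracle_fit(X, y, lam, grid_half_width=6.0, steps=61):
    """Dense grid over (beta0, beta) followed by a Nelder-Mead polish.

    Independent of the package's optimiser; handles the |.| kink by
    polishing from the best grid point with a derivative-free method.
    """
    m = X.shape[1]
    axes = [np.linspace(-grid_half_width, grid_half_width, steps)] * (m + 1)
    best, best_val = None, -np.inf
    for point in itertools.product(*axes):
        val = penalised_loglik(point[0], np.array(point[1:]), X, y, lam)
        if val > best_val:
            best, best_val = np.array(point), val
    res = minimize(
        lambda p: -penalised_loglik(p[0], p[1:], X, y, lam),
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000},
    )
    return res.x[0], res.x[1:]


def _table(X, y):
    X = np.asarray(X, float)
    return FeatureTable(
        seq_ids=[f"s{i}" for i in range(len(y))],
        labels=np.asarray(y),
        X=X,
        matrix_ids=[f"m{j}" for j in range(X.shape[1])],
    )


class TestFitSparseLR:
    def test_all_zero_features_give_symmetric_model(self):
        ft = _table(np.zeros((6, 2)), [1, 1, 1, 0, 0, 0])
        model = fit_sparse_lr(ft, lam=0.5, standardise=False)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(model.coef, 0.0, atol=1e-8)
        np.testing.assert_allclose(model.predict_proba(ft.X), 0.5, atol=1e-6)

    def test_perfect_separator_matches_grid_oracle(self):
        X = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        ft = _table(X, y)
        model = fit_sparse_lr(ft, lam=0.5, standardise=False)
        b0, b = oracle_fit(X, y, 0.5)
        assert model.coef[0] > 0
        assert model.coef[0] == pytest.approx(b[0], abs=1e-4)
        assert model.intercept == pytest.approx(b0, abs=1e-4)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 2.0])
    def test_two_feature_tables_match_grid_oracle(self, lam):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 2))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        ft = _table(X, y)
        model = fit_sparse_lr(ft, lam=lam, standardise=False)
        b0, b = oracle_fit(X, y, lam, grid_half_width=4.0, steps=33)
        np.testing.assert_allclose(model.coef, b, atol=1e-3)
        assert model.intercept == pytest.approx(b0, abs=1e-3)

    def test_huge_penalty_empties_the_selection(self):
        rng = np.random.default_rng(0)
        ft = _table(rng.normal(size=(10, 3)), [1] * 5 + [0] * 5)
        model = fit_sparse_lr(ft, lam=1e6)
        assert model.selected == frozenset()

    def test_monotone_sparsity_along_lambda_path(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=0.5, size=40) > 0).astype(int)
        ft = _table(X, y)
        sizes = [len(fit_sparse_lr(ft, lam).selected) for lam in (0.01, 0.1, 1.0, 10.0, 100.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_standardised_coefficients_backtransform(self):
        rng = np.random.default_rng(5)
        X = rng.normal(loc=3.0, scale=2.0, size=(30, 2))
        y = (X[:, 0] > 3).astype(int)
        ft = _table(X, y)
        model = fit_sparse_lr(ft, lam=1.0, standardise=True)
        # raw-scale parameters must reproduce the standardised-scale probabilities
        mu, sd = X.mean(axis=0), X.std(axis=0)
        z_std = model.coef_fitted @ ((X - mu) / sd).T
        z_raw = model.intercept + X @ model.coef
        np.testing.assert_allclose(z_raw - z_raw.mean(), z_std - z_std.mean(), atol=1e-8)

    def test_negative_lambda_rejected(self):
        ft = _table(np.zeros((4, 1)), [1, 1, 0, 0])
        with pytest.raises(ValueError):
            fit_sparse_lr(ft, lam=-1.0)


class TestSampleBackground:
    def _pool(self, n=100):
        return [GenomicInterval("chr1", i * 1000, i * 1000 + 200, "", f"p{i}") for i in range(n)]

    def test_forced_selection_excludes_overlappers(self):
        pool = self._pool(100)
        peaks = [GenomicInterval("chr1", i * 1000 + 100, i * 1000 + 300) for i in range(10)]
        sample = sample_background(pool, peaks, n=90, seed=0)
        assert len(sample) == 90
        assert {p.name for p in sample} == {f"p{i}" for i in range(10, 100)}

    def test_same_seed_reproduces_sample(self):
        pool = self._pool(50)
        a = sample_background(pool, None, n=20, seed=42)
        b = sample_background(pool, None, n=20, seed=42)
        assert [p.name for p in a] == [p.name for p in b]

    def test_shortfall_is_reported(self):
        pool = self._pool(100)
        peaks = [GenomicInterval("chr1", i * 1000 + 100, i * 1000 + 300) for i in range(10)]
        with pytest.raises(ValueError, match="short by 1"):
            sample_background(pool, peaks, n=91, seed=0)


class TestStabilitySelection:
    def test_retained_is_intersection(self):
        sel = StabilitySelection(
            per_run_selected=[frozenset("abc"), frozenset("ab"), frozenset("abd"),
                              frozenset("ab"), frozenset("ab")],
            per_run_lambda=[1.0] * 5,
        )
        assert sel.retained == frozenset("ab")

    def test_motif_selected_in_four_of_five_runs_is_dropped(self):
        runs = [frozenset({"m", "x"})] * 4 + [frozenset({"x"})]
        sel = StabilitySelection(per_run_selected=runs, per_run_lambda=[1.0] * 5)
        assert "m" not in sel.retained and "x" in sel.retained

    def test_planted_motif_recovered(self):
        from nfkbrepo.simulate import FixtureSpec, make_peak_dataset

        ds = make_peak_dataset(FixtureSpec(seed=7))
        loms = [to_log_odds(p) for p in ds.pwms]
        sel = stability_select(
            ds.positives, ds.pool, loms, lam=None, runs=5, seed=7,
            peaks=ds.peaks, pool_intervals=ds.pool_intervals,
        )
        assert ds.truth["planted_motif"] in sel.retained
        for run in sel.per_run_selected:
            assert sel.retained <= run

    def test_single_run_is_identity(self):
        from nfkbrepo.simulate import FixtureSpec, make_peak_dataset

        ds = make_peak_dataset(FixtureSpec(seed=2, n_positive=60, n_background_pool=120, n_decoys=3))
        loms = [to_log_odds(p) for p in ds.pwms]
        sel = stability_select(ds.positives, ds.pool, loms, lam=1.0, runs=1, seed=0)
        assert sel.retained == sel.per_run_selected[0]


class TestCrossDatasetSupport:
    def test_support_threshold(self):
        sets = [{"m9", "m10", "m8"}] * 8 + [{"m9", "m10"}] + [{"m10"}]
        table = select_across_datasets(sets, min_support=9)
        included = set(table.loc[table["included"], "motif_id"])
        assert included == {"m9", "m10"}
        assert table.set_index("motif_id").loc["m8", "support"] == 8

    def test_min_support_one_is_union(self):
        sets = [{"a"}, {"b"}, {"c"}]
        table = select_across_datasets(sets, min_support=1)
        assert set(table.loc[table["included"], "motif_id"]) == {"a", "b", "c"}

    def test_empty_input_empty_output(self):
        assert select_across_datasets([], min_support=9).empty


def brute_force_similarity(a, b, min_overlap=4):
    """Exhaustive offset/orientation enumeration with per-column Pearson."""
    def col_r(x, y):
        if x.std() < 1e-12 and y.std() < 1e-12:
            return 1.0
        if x.std() < 1e-12 or y.std() < 1e-12:
            return 0.0
        return np.corrcoef(x, y)[0, 1]

    best = None
    rc = b.probs[::-1][:, [3, 2, 1, 0]]
    for pb in (b.probs, rc):
        for shift in range(-len(pb) + 1, len(a.probs)):
            lo, hi = max(0, shift), min(len(a.probs), shift + len(pb))
            if hi - lo < min_overlap:
                continue
            rs = [col_r(a.probs[i], pb[i - shift]) for i in range(lo, hi)]
            val = float(np.mean(rs))
            best = val if best is None else max(best, val)
    return 0.0 if best is None else (best + 1) / 2


class TestMotifSimilarity:
    def test_identity_and_symmetry(self, random_pwm_factory):
        a, b = random_pwm_factory(1, 8), random_pwm_factory(2, 6)
        assert motif_similarity(a, a) == pytest.approx(1.0)
        assert motif_similarity(a, b) == pytest.approx(motif_similarity(b, a), abs=1e-12)

    def test_reverse_complement_scores_one(self, random_pwm_factory):
        a = random_pwm_factory(3, 7)
        assert motif_similarity(a, a.reverse_complement()) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, random_pwm_factory):
        for sa, sb in [(1, 2), (3, 4), (5, 6)]:
            a, b = random_pwm_factory(sa, 7), random_pwm_factory(sb, 5)
            assert motif_similarity(a, b) == pytest.approx(
                brute_force_similarity(a, b), abs=1e-9
            )

    def test_short_overlap_scores_zero(self):
        a = PositionWeightMatrix("a", np.tile([0.7, 0.1, 0.1, 0.1], (3, 1)))
        b = PositionWeightMatrix("b", np.tile([0.1, 0.7, 0.1, 0.1], (3, 1)))
        assert motif_similarity(a, b, min_overlap=4) == 0.0


class TestClusterMotifs:
    def test_identical_pair_plus_outsider(self, random_pwm_factory):
        a = random_pwm_factory(1, 8)
        twin = PositionWeightMatrix("M_twin", a.probs.copy())
        rng = np.random.default_rng(9)
        other = PositionWeightMatrix("M_other", rng.dirichlet(np.ones(4), size=8))
        clusters = cluster_motifs([a, twin, other], threshold=0.95)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_threshold_one_on_distinct_motifs_gives_singletons(self, random_pwm_factory):
        motifs = [random_pwm_factory(s, 6) for s in range(4)]
        clusters = cluster_motifs(motifs, threshold=1.0)
        assert all(len(c.members) == 1 for c in clusters)

    def test_equals_brute_force_connected_components(self, random_pwm_factory):
        import networkx as nx

        motifs = [random_pwm_factory(s, 6) for s in range(6)]
        threshold = 0.8
        clusters = cluster_motifs(motifs, threshold=threshold)
        g = nx.Graph()
        g.add_nodes_from(m.id for m in motifs)
        for i in range(6):
            for j in range(i + 1, 6):
                if motif_similarity(motifs[i], motifs[j]) >= threshold:
                    g.add_edge(motifs[i].id, motifs[j].id)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        assert {c.members for c in clusters} == expected

    def test_invalid_threshold(self, random_pwm_factory):
        with pytest.raises(ValueError):
            cluster_motifs([random_pwm_factory(0)], threshold=0.0)


class TestMotifGeneMapping:
    def test_shared_tf_deduplicates(self):
        mapping = {"m1": ["RELA"], "m2": ["RELA"], "m3": ["JUN"]}
        genes, missing = map_motifs_to_genes(["m1", "m2", "m3"], mapping)
        assert set(genes) == {"RELA", "JUN"}
        assert genes["RELA"] == ["m1", "m2"]
        assert missing == []

    def test_empty_and_missing(self):
        genes, missing = map_motifs_to_genes([], {})
        assert genes == {} and missing == []
        genes, missing = map_motifs_to_genes(["mX"], {"m1": ["A"]})
        assert genes == {} and missing == ["mX"]

    def test_tsv_mapping(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("matrix_id\tgene\nm1\tRELA\nm1\tNFKB1\nm2\tJUN\n")
        genes, missing = map_motifs_to_genes(["m1", "m2"], path)
        assert set(genes) == {"RELA", "NFKB1", "JUN"}
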