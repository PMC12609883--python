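"""Derivation pipeline: standardization, k-means, LDA, cut-off search."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from orbitmorph.classifier import classify_full_frame
from orbitmorph.derivation import (
    cv_lda,
    derive_rule_cutoffs,
    fit_lda,
    kmeans,
    name_clusters,
    optimize_depth_cutoffs,
    predict_lda,
    standardize,
)
from orbitmorph.synthetic_data import generate_cohort

RAW_COLS = ["depth_mm", "height_mm", "width_mm"]


class TestStandardize:
    def test_closed_form_column(self):
        Z, scaler = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(Z.ravel(), [-1.0, 0.0, 1.0])
        assert scaler.means[0] == 2.0 and scaler.sds[0] == 1.0

    def test_round_trip(self, rng):
        X = rng.normal(size=(50, 3)) * [2, 5, 0.1] + [10, -3, 0]
        Z, scaler = standardize(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-9)
        assert np.allclose(scaler.inverse(Z), X, atol=1e-9)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant column"):
            standardize(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))

    def test_constants_match_mixture_moments(
        self, big_frame, default_params, quadrature_oracle
    ):
        """Cohort-level mean/sd vs analytic mixture moments by quadrature."""
        X = big_frame[RAW_COLS].to_numpy(float)
        _, scaler = standardize(X)
        w = np.array([p.prevalence for p in default_params])
        for j, dim in enumerate(("depth", "height", "width")):
            ms, vs = zip(
                *(
                    quadrature_oracle(
                        p.dimension(dim).mean,
                        p.dimension(dim).sd,
                        p.dimension(dim).minimum,
                        p.dimension(dim).maximum,
                    )
                    for p in default_params
                )
            )
            mean = float(w @ np.array(ms))
            var = float(w @ (np.array(vs) + np.array(ms) ** 2) - mean**2)
            assert scaler.means[j] == pytest.approx(mean, abs=0.05)
            assert scaler.sds[j] == pytest.approx(np.sqrt(var), abs=0.05)


class TestKMeans:
    def test_three_distant_points(self):
        X = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        model = kmeans(X, k=3, seed=0, restarts=3)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(model.labels.tolist())) == 3

    @pytest.mark.parametrize("seed", [0, 1, 7, 42])
    def test_two_tight_blobs_recovered_for_any_seed(self, seed):
        rng = np.random.default_rng(99)
        a = rng.normal(loc=(-10, -10), scale=0.01, size=(40, 2))
        b = rng.normal(loc=(10, 10), scale=0.01, size=(40, 2))
        X = np.vstack([a, b])
        model = kmeans(X, k=2, seed=seed, restarts=1)
        labels = model.labels
        assert len(set(labels[:40].tolist())) == 1
        assert len(set(labels[40:].tolist())) == 1
        assert labels[0] != labels[40]

    def test_duplication_invariance(self, rng):
        # three well-separated blobs so both runs reach the global optimum
        X = np.vstack(
            [rng.normal(c, 0.3, size=(20, 3)) for c in ((0, 0, 0), (6, 0, 0), (0, 6, 0))]
        )
        m1 = kmeans(X, k=3, seed=5, restarts=5)
        m2 = kmeans(np.vstack([X, X]), k=3, seed=5, restarts=5)
        c1 = np.array(sorted(m1.centers.tolist()))
        c2 = np.array(sorted(m2.centers.tolist()))
        assert np.allclose(c1, c2, atol=1e-6)

    def test_determinism(self, rng):
        X = rng.normal(size=(120, 3))
        m1 = kmeans(X, k=3, seed=11, restarts=10)
        m2 = kmeans(X, k=3, seed=11, restarts=10)
        assert np.array_equal(m1.labels, m2.labels)
        assert np.allclose(m1.centers, m2.centers)

    def test_matches_library_objective(self, rng):
        """Independent cross-check: inertia on par with scikit-learn's."""
        from sklearn.cluster import KMeans as SkKMeans

        X = rng.normal(size=(300, 3)) + rng.choice([-4, 0, 4], size=(300, 1))
        ours = kmeans(X, k=3, seed=0, restarts=10)
        sk = SkKMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia <= sk.inertia_ * 1.001

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least"):
            kmeans(np.zeros((2, 2)), k=3)


class TestNameClusters:
    def test_published_type_means_map_correctly(self):
        # centroids at the published per-type (D, H, W) means
        centers = {
            0: [43.52, 32.79, 36.76],  # deepest -> B
            1: [40.1, 35.97, 37.11],  # tallest -> A
            2: [38.56, 32.48, 34.22],  # remainder -> C
        }
        from orbitmorph.derivation import ClusterModel

        X = np.array([centers[i] for i in [0, 1, 2] for _ in range(5)])
        labels = np.repeat([0, 1, 2], 5)
        model = ClusterModel(centers=np.zeros((3, 3)), labels=labels, inertia=0.0)
        mapping = name_clusters(model, X)
        assert mapping == {1: "A", 0: "B", 2: "C"}

    def test_label_permutation_invariance(self, rng):
        from orbitmorph.derivation import ClusterModel

        X = np.vstack(
            [
                rng.normal((40, 36, 37), 0.5, size=(20, 3)),
                rng.normal((43.5, 32.8, 36.8), 0.5, size=(20, 3)),
                rng.normal((38.6, 32.5, 34.2), 0.5, size=(20, 3)),
            ]
        )
        base_labels = np.repeat([0, 1, 2], 20)
        m0 = ClusterModel(centers=np.zeros((3, 3)), labels=base_labels, inertia=0.0)
        base_map = name_clusters(m0, X)
        perm = {0: 2, 1: 0, 2: 1}
        m1 = ClusterModel(
            centers=np.zeros((3, 3)),
            labels=np.array([perm[c] for c in base_labels]),
            inertia=0.0,
        )
        permuted_map = name_clusters(m1, X)
        for old, new in perm.items():
            assert permuted_map[new] == base_map[old]

    def test_degenerate_tie_warns(self):
        from orbitmorph.derivation import ClusterModel

        X = np.ones((9, 3))
        model = ClusterModel(
            centers=np.zeros((3, 3)), labels=np.repeat([0, 1, 2], 3), inertia=0.0
        )
        with pytest.warns(UserWarning, match="tied"):
            mapping = name_clusters(model, X)
        assert mapping == {0: "A", 1: "B", 2: "C"}  # index tie-break


class TestLda:
    def test_separated_classes_perfect_cv(self, rng):
        X = np.vstack(
            [rng.normal((-5, 0, 0), 0.1, (30, 3)), rng.normal((5, 0, 0), 0.1, (30, 3))]
        )
        y = np.repeat(["a", "b"], 30)
        mean, sd = cv_lda(X, y, folds=5, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_one_dimensional_boundary_is_midpoint(self, rng):
        """Equal-prior two-class 1-D problem: Bayes boundary at the midpoint."""
        x = np.concatenate([rng.normal(0.0, 1.0, 500), rng.normal(4.0, 1.0, 500)])
        y = np.repeat([0, 1], 500)
        model = fit_lda(x[:, None], y, priors=np.array([0.5, 0.5]))
        m0, m1 = model.means.ravel()
        # the two discriminant scores cross where the label flips
        grid = np.linspace(m0, m1, 200001)
        pred = predict_lda(model, grid[:, None]).astype(int)
        boundary = grid[np.argmax(pred == 1)]
        assert boundary == pytest.approx((m0 + m1) / 2, abs=1e-4)

    def test_agrees_with_gaussian_posterior_oracle(self, rng):
        """Score argmax equals the brute-force pooled-Gaussian posterior."""
        X = np.vstack(
            [
                rng.multivariate_normal((0, 0, 0), np.eye(3), 80),
                rng.multivariate_normal((2, 1, 0), np.eye(3), 50),
                rng.multivariate_normal((-1, 2, 1), np.eye(3), 70),
            ]
        )
        y = np.repeat(["A", "B", "C"], [80, 50, 70])
        model = fit_lda(X, y)
        pts = rng.normal(0.5, 2.0, size=(1500, 3))
        pred = predict_lda(model, pts)
        dens = np.column_stack(
            [
                np.log(model.priors[i])
                + multivariate_normal(model.means[i], model.pooled_cov).logpdf(pts)
                for i in range(3)
            ]
        )
        oracle = np.asarray(model.classes, dtype=object)[dens.argmax(axis=1)]
        assert (pred == oracle).all()

    def test_agrees_with_library_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack(
            [
                rng.multivariate_normal((0, 0, 0), np.eye(3), 100),
                rng.multivariate_normal((3, 0, 1), np.eye(3), 100),
                rng.multivariate_normal((0, 3, -1), np.eye(3), 100),
            ]
        )
        y = np.repeat(["A", "B", "C"], 100)
        ours = predict_lda(fit_lda(X, y), X)
        theirs = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert (ours == theirs).mean() > 0.995

    def test_singular_covariance_reports_condition(self, rng):
        x = rng.normal(size=(40, 1))
        X = np.hstack([x, x])  # perfectly collinear
        y = np.repeat([0, 1], 20)
        with pytest.raises(ValueError, match="condition number"):
            fit_lda(X, y)

    def test_class_size_and_prior_validation(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="too small"):
            fit_lda(X, np.array([0, 0, 1, 1, 2]))
        with pytest.raises(ValueError, match="priors"):
            fit_lda(rng.normal(size=(8, 2)), np.repeat([0, 1], 4), priors=np.array([0.9, 0.3]))

    def test_cv_is_seeded(self, rng):
        X = rng.normal(size=(90, 3)) + np.repeat([[0], [2], [4]], 30, axis=0)
        y = np.repeat(["A", "B", "C"], 30)
        assert cv_lda(X, y, seed=3) == cv_lda(X, y, seed=3)


class TestRuleCutoffs:
    def test_perfectly_separated_toy(self, rng):
        nh = 30
        H = np.concatenate(
            [rng.normal(40, 0.1, nh), rng.normal(30, 0.1, nh), rng.normal(30, 0.1, nh)]
        )
        D = np.concatenate(
            [rng.normal(40, 0.1, nh), rng.normal(45, 0.1, nh), rng.normal(35, 0.1, nh)]
        )
        W = np.full(3 * nh, 35.0)
        labels = np.repeat(["A", "B", "C"], nh)
        cuts = derive_rule_cutoffs(np.column_stack([D, H, W]), labels)
        assert 30.5 < cuts.h_cut < 39.5
        assert 35.5 < cuts.d_cut < 44.5
        assert cuts.tree_accuracy == 1.0

    def test_self_consistency_with_published_rule(self):
        frame = generate_cohort(n=400, seed=21).data
        labeled = classify_full_frame(frame)
        X = frame[RAW_COLS].to_numpy(float)
        cuts = derive_rule_cutoffs(X, labeled["pred_type"].to_numpy(object))
        assert cuts.tree_accuracy == 1.0

    def test_three_single_points_midpoints(self):
        X = np.array([[40.0, 38.0, 35.0], [46.0, 30.0, 35.0], [36.0, 28.0, 35.0]])
        labels = np.array(["A", "B", "C"])
        cuts = derive_rule_cutoffs(X, labels)
        assert cuts.h_cut == pytest.approx((30.0 + 38.0) / 2)
        assert cuts.d_cut == pytest.approx((36.0 + 46.0) / 2)

    def test_missing_class_rejected(self):
        X = np.random.default_rng(0).normal(35, 2, size=(20, 3))
        with pytest.raises(ValueError, match="must be present"):
            derive_rule_cutoffs(X, np.repeat(["A", "B"], 10))


def _brute_force_depth_pairs(D, labels):
    """O(m^2) exhaustive oracle for the depth cut-off search."""
    u = np.unique(D)
    cands = (u[:-1] + u[1:]) / 2
    best = (-1, None, None)
    for i, t1 in enumerate(cands):
        for t2 in cands[i + 1 :]:
            pred = np.where(D <= t1, "C", np.where(D <= t2, "A", "B"))
            acc = (pred == labels).mean()
            if acc > best[0]:
                best = (acc, t1, t2)
    return best


class TestDepthCutoffs:
    def test_three_disjoint_bands(self, rng):
        D = np.concatenate(
            [rng.uniform(30, 34, 25), rng.uniform(36, 40, 25), rng.uniform(42, 46, 25)]
        )
        labels = np.repeat(["C", "A", "B"], 25)
        res = optimize_depth_cutoffs(D, labels, bootstrap_B=50, seed=0)
        assert 34 < res.d1 < 36 and 40 < res.d2 < 42
        assert res.depth_accuracy == 1.0
        lo1, hi1 = res.d1_ci
        lo2, hi2 = res.d2_ci
        assert lo1 <= res.d1 <= hi1 and lo2 <= res.d2 <= hi2

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            D = rng.normal(40, 3, size=60).round(1)
            labels = rng.choice(list("ABC"), size=60)
            if len(np.unique(D)) < 3 or set(labels) != {"A", "B", "C"}:
                continue
            res = optimize_depth_cutoffs(D, labels, bootstrap_B=1, seed=trial)
            acc, t1, t2 = _brute_force_depth_pairs(D, labels)
            assert res.depth_accuracy == pytest.approx(acc)
            assert res.d1 == pytest.approx(t1) and res.d2 == pytest.approx(t2)

    def test_identical_depths_rejected(self):
        with pytest.raises(ValueError, match="distinct depth"):
            optimize_depth_cutoffs(
                np.full(30, 40.0), np.repeat(["A", "B", "C"], 10), bootstrap_B=1
            )

    def test_bootstrap_seeded(self, rng):
        D = rng.normal(40, 3, size=120)
        labels = np.repeat(["C", "A", "B"], 40)[np.argsort(np.argsort(D))]
        a = optimize_depth_cutoffs(D, labels, bootstrap_B=100, seed=9)
        b = optimize_depth_cutoffs(D, labels, bootstrap_B=100, seed=9)
        assert a.d1_ci == b.d1_ci and a.d2_ci == b.d2_ci


class TestPipelineDeterminism:
    def test_fixed_seed_reproduces_models(self):
        frame = generate_cohort(n=300, seed=8).data
        X = frame[RAW_COLS].to_numpy(float)
        results = []
        for _ in range(2):
            Z, _ = standardize(X)
            model = kmeans(Z, k=3, seed=8, restarts=5)
            mapping = name_clusters(model, X)
            labels = np.array([mapping[int(c)] for c in model.labels])
            cv = cv_lda(Z, labels, seed=8)
            cuts = optimize_depth_cutoffs(X[:, 0], labels, bootstrap_B=20, seed=8)
            results.append((model.centers.tolist(), labels.tolist(), cv, cuts))
        assert results[0] == results[1]
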