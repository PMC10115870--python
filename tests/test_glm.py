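import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dysmap.errors import DegenerateDesignError, InvalidArgumentError
from dysmap.glm import (
    NonSphericity,
    _enumerate_labelings,
    build_design,
    critical_t_uncorrected,
    estimate_nonsphericity,
    extract_clusters,
    fit_glm,
    fwe_threshold_maxT,
    t_contrast,
)
from dysmap.records import StimulationRecord
from dysmap.volumes import Volume, make_grid

from conftest import make_records


def records_from_labels(labels_per_subject):
    """Subjects with given binary label sequences, at arbitrary coordinates."""
    records = []
    for s, labels in enumerate(labels_per_subject):
        for i, lab in enumerate(labels):
            records.append(
                StimulationRecord(
                    f"s{s:02d}", (float(i), float(s), 0.0), {"b": int(lab)}
                )
            )
    return records


def gls_oracle(X, V, y, c):
    """Brute-force generalised least squares with explicit V inversion."""
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.pinv(XtVX) @ X.T @ Vi @ y
    df = len(y) - np.linalg.matrix_rank(X)
    resid = y - X @ beta
    rss = resid @ Vi @ resid
    s2 = rss / df
    t = (c @ beta) / np.sqrt(s2 * c @ np.linalg.pinv(XtVX) @ c)
    return beta, s2, t


class TestBuildDesign:
    def test_paper_scale_rank_and_df(self):
        # 477 rows over 37 subjects: 33 subjects with 13 rows, 4 with 12
        records = []
        count = 0
        for s in range(37):
            n = 13 if s < 33 else 12
            for i in range(n):
                records.append(
                    StimulationRecord(
                        f"s{s:02d}",
                        (float(i), float(s), 0.0),
                        {"b": int((count := count + 1) % 3 == 0)},
                    )
                )
        assert len(records) == 477
        design = build_design(records, "b")
        assert design.rank == 38
        assert design.df == 439

    def test_small_case(self):
        design = build_design(records_from_labels([(1, 0), (1, 0)]), "b")
        assert design.rank == 3
        assert design.df == 1

    def test_one_indicator_per_row(self, toy_records):
        design = build_design(toy_records, "b")
        subject_part = design.X[:, : design.behaviour_col]
        assert np.allclose(subject_part.sum(axis=1), 1.0)

    def test_constant_behaviour_rejected(self):
        with pytest.raises(DegenerateDesignError):
            build_design(records_from_labels([(1, 1), (1, 1)]), "b")


class TestNonSphericity:
    def test_null_recovery(self, rng):
        records = make_records(20, 10, rng)
        design = build_design(records, "b")
        Y = rng.normal(size=(50, 200))
        ns = estimate_nonsphericity(Y, design)
        assert abs(ns.rho) < 0.05

    def test_compound_symmetry_recovery(self):
        # 40 subjects x 10 rows, true rho 0.5, averaged over 20 replicates
        rhos = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            records = make_records(40, 10, rng)
            design = build_design(records, "b")
            n = design.n_rows
            ns_true = NonSphericity(rho=0.5, blocks=design.subject_blocks, n_rows=n)
            L = np.linalg.cholesky(ns_true.covariance())
            Y = rng.normal(size=(30, n)) @ L.T
            rhos.append(estimate_nonsphericity(Y, design).rho)
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.1)

    def test_rho_zero_gls_equals_ols(self, rng):
        records = make_records(5, 4, rng)
        design = build_design(records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=design.n_rows)
        assert np.allclose(ns.whitener(), np.eye(design.n_rows))
        Y = rng.normal(size=(7, design.n_rows))
        fit = fit_glm(Y, design, ns)
        beta_ols = Y @ np.linalg.pinv(design.X).T
        assert np.allclose(fit.beta, beta_ols, atol=1e-10)

    def test_singleton_blocks_rho_zero(self, caplog):
        # all-singleton blocks leave no within-subject pairs; stub the design
        # since the full model would be saturated
        from types import SimpleNamespace

        g = np.array([1.0, 0.0, 1.0, 0.0])
        design = SimpleNamespace(
            X=np.column_stack([np.eye(4), g]),
            behaviour_col=4,
            subject_blocks={f"s{i}": np.array([i]) for i in range(4)},
            n_rows=4,
        )
        Y = np.random.default_rng(0).normal(size=(5, 4))
        with caplog.at_level("INFO"):
            ns = estimate_nonsphericity(Y, design)
        assert ns.rho == 0.0
        assert any("singleton" in m for m in caplog.messages)

    def test_whitener_whitens(self, rng):
        blocks = {"a": np.arange(0, 4), "b": np.arange(4, 9), "c": np.arange(9, 11)}
        ns = NonSphericity(rho=0.6, blocks=blocks, n_rows=11)
        V, W = ns.covariance(), ns.whitener()
        assert np.allclose(W @ V @ W.T, np.eye(11), atol=1e-10)
        # simulation check: whitened CS noise has identity covariance
        L = np.linalg.cholesky(V)
        E = rng.normal(size=(200_000, 11)) @ L.T @ W.T
        assert np.allclose(np.cov(E.T), np.eye(11), atol=0.05)


class TestFitAndContrast:
    def test_hand_computed_ols(self):
        # frozen oracle: brute-force normal equations on a 6-row design
        records = records_from_labels([(1, 0, 0), (1, 1, 0)])
        design = build_design(records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=6)
        Y = np.array([[2.0, 1.0, 0.0, 5.0, 4.0, 1.0]])
        fit = fit_glm(Y, design, ns)
        assert np.allclose(fit.beta[0], [1 / 6, 5 / 3, 2.5], atol=1e-10)
        assert fit.df == 3
        t = t_contrast(fit, design.behaviour_contrast())
        assert t[0] == pytest.approx(3.273268353539886, abs=1e-10)

    def test_scale_invariance(self, rng, toy_records):
        design = build_design(toy_records, "b")
        ns = estimate_nonsphericity(rng.normal(size=(8, design.n_rows)), design)
        Y = rng.normal(size=(8, design.n_rows))
        t1 = t_contrast(fit_glm(Y, design, ns), design.behaviour_contrast())
        t2 = t_contrast(fit_glm(3.7 * Y, design, ns), design.behaviour_contrast())
        assert np.allclose(t1, t2, atol=1e-10)

    def test_exact_fit_flagged(self, toy_records):
        design = build_design(toy_records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=design.n_rows)
        b = np.arange(design.n_cols, dtype=float)
        Y = (design.X @ b)[None, :]
        fit = fit_glm(Y, design, ns)
        assert fit.n_zero_variance == 1
        t = t_contrast(fit, design.behaviour_contrast())
        assert t[0] == 0.0

    def test_sign_flip_negates_t(self, rng, toy_records):
        design = build_design(toy_records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=design.n_rows)
        Y = rng.normal(size=(6, design.n_rows))
        fit = fit_glm(Y, design, ns)
        c = design.behaviour_contrast()
        assert np.allclose(
            t_contrast(fit, c), -t_contrast(fit, -c), atol=1e-12
        )

    def test_zero_contrast_rejected(self, toy_records, rng):
        design = build_design(toy_records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=design.n_rows)
        fit = fit_glm(rng.normal(size=(3, design.n_rows)), design, ns)
        with pytest.raises(InvalidArgumentError):
            t_contrast(fit, np.zeros(design.n_cols))

    def test_null_t_distribution_matches_student(self, rng):
        records = make_records(12, 8, rng)
        design = build_design(records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=design.n_rows)
        Y = rng.normal(size=(4000, design.n_rows))
        t = t_contrast(fit_glm(Y, design, ns), design.behaviour_contrast())
        _, p = stats.kstest(t, stats.t(df=design.df).cdf)
        assert p > 0.01

    def test_gls_oracle_equivalence(self, rng):
        # <= 8 row instances, several rho values, vs brute-force GLS
        for rho in (0.0, 0.3, 0.6, -0.2):
            records = records_from_labels([(1, 0, 0), (0, 1, 0), (1, 0)])
            design = build_design(records, "b")
            ns = NonSphericity(rho=rho, blocks=design.subject_blocks,
                               n_rows=design.n_rows)
            Y = rng.normal(size=(3, design.n_rows))
            fit = fit_glm(Y, design, ns)
            t = t_contrast(fit, design.behaviour_contrast())
            V = ns.covariance()
            for v in range(Y.shape[0]):
                beta_o, s2_o, t_o = gls_oracle(
                    design.X, V, Y[v], design.behaviour_contrast()
                )
                assert np.allclose(fit.beta[v], beta_o, atol=1e-8)
                assert fit.sigma2[v] == pytest.approx(s2_o, abs=1e-8)
                assert t[v] == pytest.approx(t_o, abs=1e-8)

    def test_df_invariant_under_whitening(self, rng):
        for _ in range(50):
            n_sub = int(rng.integers(2, 6))
            per = int(rng.integers(2, 5))
            records = make_records(n_sub, per, rng)
            design = build_design(records, "b")
            rho = float(rng.uniform(-0.2, 0.8))
            ns = NonSphericity(rho=rho, blocks=design.subject_blocks,
                               n_rows=design.n_rows)
            fit = fit_glm(rng.normal(size=(2, design.n_rows)), design, ns)
            assert fit.df == design.n_rows - design.rank


class TestCriticalT:
    def test_paper_displayed_threshold(self):
        assert round(critical_t_uncorrected(0.001, 439), 2) == 3.11

    def test_median_is_zero(self):
        for df in (3, 30, 300):
            assert critical_t_uncorrected(0.5, df) == pytest.approx(0.0, abs=1e-12)

    def test_tabulated_value(self):
        assert critical_t_uncorrected(0.05, 10) == pytest.approx(1.812, abs=5e-4)

    def test_monotone_in_p_and_df(self):
        ps = [0.001, 0.01, 0.05, 0.2]
        vals = [critical_t_uncorrected(p, 20) for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        dfs = [2, 5, 20, 200, 200_000]
        vals = [critical_t_uncorrected(0.01, d) for d in dfs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        z = stats.norm.isf(0.01)
        assert vals[-1] == pytest.approx(z, abs=1e-3)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            critical_t_uncorrected(0.0, 10)
        with pytest.raises(InvalidArgumentError):
            critical_t_uncorrected(0.5, 0)


def _mask_and_Y(rng, n_rows, shape=(4, 4, 4)):
    grid = make_grid(shape, 2.0)
    mask = Volume(grid, np.ones(shape))
    Y = rng.normal(size=(np.prod(shape), n_rows))
    return grid, mask, Y


class TestMaxT:
    def test_exhaustive_matches_independent_enumeration(self, rng):
        # 2 subjects x 3 rows: all 9 within-subject labelings, oracle via GLS
        records = records_from_labels([(1, 0, 0), (0, 1, 1)])
        design = build_design(records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=6)
        grid, mask, Y = _mask_and_Y(rng, 6)
        res = fwe_threshold_maxT(Y, design, ns, mask, alpha=0.2, n_perm=100, seed=0)
        assert res.method == "perm_maxT_exact"

        # independent oracle: refit the full GLM for every labeling
        max_ts = []
        for la in itertools.combinations(range(3), 1):
            for lb in itertools.combinations(range(3), 2):
                g = np.zeros(6)
                for i in la:
                    g[i] = 1
                for j in lb:
                    g[3 + j] = 1
                X = design.X.copy()
                X[:, design.behaviour_col] = g
                ts = []
                for v in range(Y.shape[0]):
                    _, _, t = gls_oracle(
                        X, np.eye(6), Y[v], design.behaviour_contrast()
                    )
                    ts.append(t)
                max_ts.append(max(ts))
        max_ts = np.sort(max_ts)
        k = math.ceil((1 - 0.2) * len(max_ts))
        assert res.critical_t == pytest.approx(max_ts[k - 1], abs=1e-8)
        assert len(res.max_t_distribution) == 9

    def test_alpha_one_gives_min(self, rng):
        records = records_from_labels([(1, 0, 0, 1), (0, 1, 1, 0)])
        design = build_design(records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=8)
        grid, mask, Y = _mask_and_Y(rng, 8)
        res = fwe_threshold_maxT(Y, design, ns, mask, alpha=1.0, n_perm=50, seed=0)
        assert res.critical_t == pytest.approx(res.max_t_distribution.min())

    def test_too_few_permutations_warns(self, rng):
        records = records_from_labels([(1, 0), (0, 1)])
        design = build_design(records, "b")
        ns = NonSphericity(rho=0.0, blocks=design.subject_blocks, n_rows=4)
        grid, mask, Y = _mask_and_Y(rng, 4)
        with pytest.warns(UserWarning, match="distinct"):
            fwe_threshold_maxT(Y, design, ns, mask, alpha=0.05, n_perm=500, seed=0)

    def test_observed_t_matches_full_fit(self, rng, toy_records):
        # the fast residualised statistic must equal the full-model contrast t
        design = build_design(toy_records, "b")
        Y = rng.normal(size=(30, design.n_rows))
        ns = estimate_nonsphericity(Y, design)
        fit = fit_glm(Y, design, ns)
        t_full = t_contrast(fit, design.behaviour_contrast())
        grid = make_grid((30, 1, 1), 2.0)
        mask = Volume(grid, np.ones((30, 1, 1)))
        res = fwe_threshold_maxT(Y, design, ns, mask, alpha=0.5, n_perm=100, seed=0)
        # sig_map marks exactly the voxels with the full-model t >= critical_t,
        # i.e. the fast residualised statistic agrees with t_contrast
        sig = t_full >= res.critical_t
        assert np.array_equal(res.sig_map.values.ravel() > 0, sig)

    def test_enumeration_covers_all_labelings(self):
        g = np.array([1.0, 0.0, 0.0, 1.0, 1.0, 0.0])
        blocks = {"a": np.arange(3), "b": np.arange(3, 6)}
        labelings = {tuple(gp) for gp in _enumerate_labelings(g, blocks)}
        assert len(labelings) == 3 * 3
        assert tuple(g) in labelings


class TestClusters:
    def make_maps(self, sig, t):
        grid = make_grid(sig.shape, 2.0)
        return Volume(grid, sig.astype(float)), Volume(grid, t)

    def test_two_blobs(self):
        sig = np.zeros((10, 10, 10))
        sig[1:3, 1:3, 1:3] = 1
        sig[7:9, 7:9, 7:9] = 1
        t = np.random.default_rng(0).uniform(1, 2, sig.shape) * sig
        table = extract_clusters(*self.make_maps(sig, t))
        assert len(table) == 2
        assert table["extent_voxels"].sum() == sig.sum()
        assert table["peak_t"].is_monotonic_decreasing

    def test_single_voxel(self):
        sig = np.zeros((6, 6, 6))
        sig[3, 3, 3] = 1
        t = sig * 4.2
        table = extract_clusters(*self.make_maps(sig, t))
        assert len(table) == 1
        assert table.loc[0, "extent_voxels"] == 1
        assert table.loc[0, "peak_t"] == pytest.approx(4.2)
        assert (table.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]] == 6.0).all()

    def test_diagonal_touch_is_one_cluster(self):
        # 26-connectivity joins voxels sharing only a corner
        sig = np.zeros((6, 6, 6))
        sig[2, 2, 2] = 1
        sig[3, 3, 3] = 1
        t = sig.copy()
        table = extract_clusters(*self.make_maps(sig, t))
        assert len(table) == 1

    def test_empty_map(self):
        sig = np.zeros((5, 5, 5))
        table = extract_clusters(*self.make_maps(sig, sig))
        assert len(table) == 0
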