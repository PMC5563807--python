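import numpy as np
import pandas as pd
import pytest

from mortprof.ca import (
    add_supplementary,
    axis_summary,
    classify_context,
    context_mean_profiles,
    correspondence_analysis,
    default_orientation,
    orient_axes,
    project_supplementary,
    stack_deviates,
)


def oracle_eig_ca(N):
    """Independent brute-force CA: eigendecomposition of S^T S.

    Returns (inertias desc, column principal coordinates), built directly
    from the textbook definitions without calling the package.
    """
    N = np.asarray(N, dtype=float)
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    lam, V = np.linalg.eigh(S.T @ S)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0, None)
    V = V[:, order]
    a = min(N.shape[0] - 1, N.shape[1] - 1)
    lam, V = lam[:a], V[:, :a]
    G = V * np.sqrt(lam) / np.sqrt(c)[:, None]
    return lam, G


def random_table(rng, max_rows=8, max_cols=7):
    i = rng.integers(2, max_rows + 1)
    k = rng.integers(2, max_cols + 1)
    return rng.gamma(1.0, 1.0, size=(i, k))


class TestCorrespondenceAnalysis:
    def test_identical_rows_zero_inertia(self):
        table = np.tile([0.2, 0.3, 0.5], (6, 1)) * 4.0
        res = correspondence_analysis(table)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-20)
        assert res.n_axes == 0

    def test_2x2_closed_form(self, rng):
        for _ in range(20):
            N = rng.gamma(1.0, 1.0, size=(2, 2))
            P = N / N.sum()
            r, c = P.sum(axis=1), P.sum(axis=0)
            lam1 = (P[0, 0] * P[1, 1] - P[0, 1] * P[1, 0]) ** 2 / (
                r[0] * r[1] * c[0] * c[1]
            )
            res = correspondence_analysis(N)
            assert res.n_axes == 1
            assert res.principal_inertias[0] == pytest.approx(lam1, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(25):
            N = random_table(rng)
            lam, G = oracle_eig_ca(N)
            res = correspondence_analysis(N)
            assert np.allclose(res.principal_inertias, lam[: res.n_axes], atol=1e-10)
            assert np.allclose(
                np.abs(res.col_coords), np.abs(G[:, : res.n_axes]), atol=1e-10
            )

    def test_total_inertia_equals_mean_square_contingency(self, rng):
        for _ in range(10):
            N = random_table(rng)
            P = N / N.sum()
            E = np.outer(P.sum(axis=1), P.sum(axis=0))
            phi2 = ((P - E) ** 2 / E).sum()
            res = correspondence_analysis(N)
            assert res.total_inertia == pytest.approx(phi2, abs=1e-12)

    def test_contributions_sum_to_1000_per_axis(self, rng):
        res = correspondence_analysis(random_table(rng))
        assert np.allclose(res.col_contrib.sum(axis=0), 1000.0, atol=1e-9)

    def test_masses_sum_to_one(self, rng):
        res = correspondence_analysis(random_table(rng))
        assert res.col_mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.row_mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_inertias_nonincreasing(self, rng):
        res = correspondence_analysis(random_table(rng))
        assert np.all(np.diff(res.principal_inertias) <= 1e-15)

    def test_zero_mass_column_dropped_with_warning(self, rng):
        N = random_table(rng)
        N[:, 1] = 0.0
        with pytest.warns(UserWarning, match="zero-mass columns"):
            res = correspondence_analysis(N, [f"c{k}" for k in range(N.shape[1])])
        assert res.dropped_cols == ("c1",)
        assert len(res.col_labels) == N.shape[1] - 1

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(np.array([[1.0, -0.1], [0.5, 0.5]]))

    def test_zero_table_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(np.zeros((3, 3)))


class TestSupplementary:
    def test_centroid_maps_to_origin(self, rng):
        N = random_table(rng)
        res = correspondence_analysis(N)
        coords = project_supplementary(res, res.col_mass)
        assert np.allclose(coords, 0.0, atol=1e-10)

    def test_vertex_gives_standard_coordinates(self, rng):
        N = random_table(rng, max_rows=6, max_cols=5)
        res = correspondence_analysis(N)
        k = 1
        e = np.zeros(len(res.col_labels))
        e[k] = 1.0
        coords = project_supplementary(res, e)
        assert np.allclose(coords, res.col_standard_coords()[k], atol=1e-10)

    def test_projection_leaves_result_unchanged(self, rng):
        N = random_table(rng)
        res_plain = correspondence_analysis(N)
        res_supp = correspondence_analysis(N)
        K = N.shape[1]
        profiles = {f"s{j}": rng.dirichlet(np.ones(K)) for j in range(4)}
        add_supplementary(res_supp, profiles)
        assert np.allclose(
            res_supp.principal_inertias, res_plain.principal_inertias, atol=0
        )
        assert np.array_equal(res_supp.col_coords, res_plain.col_coords)
        assert np.array_equal(res_supp.row_coords, res_plain.row_coords)

    def test_mismatched_class_count_errors(self, rng):
        res = correspondence_analysis(random_table(rng, max_cols=5))
        with pytest.raises(ValueError, match="classes"):
            project_supplementary(res, np.ones(11) / 11)


class TestStackDeviates:
    def _table(self, scheme, n_ctx=5):
        rng = np.random.default_rng(0)
        data = rng.integers(1, 20, size=(n_ctx, scheme.n_classes)).astype(float)
        t = pd.DataFrame(data, columns=list(scheme.labels),
                         index=pd.Index([f"c{i}" for i in range(n_ctx)],
                                        name="context_id"))
        t["N"] = data.sum(axis=1)
        return t

    def test_block_shape_and_order(self, scheme):
        t = self._table(scheme)
        ca_in = stack_deviates(t, scheme.labels, nsim=100, master_seed=7)
        assert ca_in.active.shape == (500, 7)
        assert list(pd.unique(ca_in.row_context)) == [f"c{i}" for i in range(5)]

    def test_deterministic(self, scheme):
        t = self._table(scheme)
        a = stack_deviates(t, scheme.labels, nsim=50, master_seed=3)
        b = stack_deviates(t, scheme.labels, nsim=50, master_seed=3)
        assert np.array_equal(a.active, b.active)

    def test_adding_context_preserves_existing_blocks(self, scheme):
        t5 = self._table(scheme, 5)
        t6 = self._table(scheme, 6)
        a = stack_deviates(t5, scheme.labels, nsim=40, master_seed=3)
        b = stack_deviates(t6, scheme.labels, nsim=40, master_seed=3)
        assert np.array_equal(a.active, b.active[:200])

    def test_single_context_single_draw_degenerates(self, scheme):
        t = self._table(scheme, 1)
        ca_in = stack_deviates(t, scheme.labels, nsim=1, master_seed=0)
        assert ca_in.active.shape == (1, 7)
        res = correspondence_analysis(ca_in.active, scheme.labels)
        assert res.n_axes == 0
        assert res.total_inertia == pytest.approx(0.0, abs=1e-20)

    def test_empty_table_errors(self, scheme):
        empty = pd.DataFrame(columns=list(scheme.labels))
        with pytest.raises(ValueError):
            stack_deviates(empty, scheme.labels)

    def test_stability_across_seeds(self, scheme):
        """Total inertia is a stable functional of the deviate cloud."""
        t = self._table(scheme, 8)
        inertias = [
            correspondence_analysis(
                stack_deviates(t, scheme.labels, nsim=2000, master_seed=s).active,
                scheme.labels,
            ).total_inertia
            for s in range(10)
        ]
        cv = np.std(inertias) / np.mean(inertias)
        assert cv < 0.01


class TestReporting:
    def test_axis_summary_layout(self, scheme):
        rng = np.random.default_rng(1)
        res = correspondence_analysis(rng.gamma(1, 1, size=(10, 7)), scheme.labels)
        summ = axis_summary(res, n_axes=3)
        assert list(summ["age_class"]) == list(scheme.labels)
        assert abs(summ["mass_permille"].sum() - 1000) <= 3  # rounding slack
        for a in (1, 2, 3):
            assert abs(summ[f"F{a}_ctr_permille"].sum() - 1000) <= 3

    def test_axis_summary_needs_three_axes(self):
        res = correspondence_analysis(np.random.default_rng(0).gamma(1, 1, (2, 2)))
        with pytest.raises(ValueError):
            axis_summary(res, n_axes=3)

    def test_orientation_convention(self, scheme):
        rng = np.random.default_rng(2)
        res = correspondence_analysis(rng.gamma(1, 1, size=(12, 7)), scheme.labels)
        orient_axes(res, default_orientation(scheme))
        assert res.col_coords[scheme.index(">8y"), 0] >= 0
        assert res.col_coords[scheme.index("3-6y"), 1] >= 0

    def test_orientation_preserves_oracle_match(self, scheme):
        rng = np.random.default_rng(3)
        N = rng.gamma(1, 1, size=(12, 7))
        lam, G = oracle_eig_ca(N)
        res = orient_axes(
            correspondence_analysis(N, scheme.labels), default_orientation(scheme)
        )
        assert np.allclose(np.abs(res.col_coords), np.abs(G[:, : res.n_axes]), atol=1e-10)


class TestClassifyContext:
    def test_exact_match_distance_zero(self):
        refs = {"A": np.array([1.0, 2.0]), "B": np.array([-1.0, 0.0])}
        out = classify_context({"x": np.array([1.0, 2.0])}, refs)
        assert out.loc[0, "nearest"] == "A"
        assert out.loc[0, "distance"] == 0.0

    def test_tie_goes_to_first_listed_with_warning(self, caplog):
        refs = {"A": np.array([1.0, 0.0]), "B": np.array([-1.0, 0.0])}
        with caplog.at_level("WARNING"):
            out = classify_context({"x": np.array([0.0, 0.0])}, refs)
        assert out.loc[0, "nearest"] == "A"
        assert "equidistant" in caplog.text

    def test_no_references_errors(self):
        with pytest.raises(ValueError):
            classify_context({"x": np.zeros(2)}, {})


def test_context_mean_profiles(scheme):
    rng = np.random.default_rng(4)
    t = pd.DataFrame(
        rng.integers(1, 9, size=(3, 7)).astype(float),
        columns=list(scheme.labels),
        index=pd.Index(["a", "b", "c"], name="context_id"),
    )
    ca_in = stack_deviates(t, scheme.labels, nsim=300, master_seed=0)
    means = context_mean_profiles(ca_in)
    assert set(means) == {"a", "b", "c"}
    for v in means.values():
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
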