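import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.spatial.distance import pdist, squareform

from magpipe.community_ordination import (
    bray_curtis,
    nmds,
    rda,
    variable_loadings,
)


def counts_df(values, prefix="s"):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"v{j}" for j in range(arr.shape[1])],
    )


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(counts_df([[1, 2, 3], [1, 2, 3]]))
        assert d["s0", "s1"] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(counts_df([[5, 0, 0], [0, 3, 2]]))
        assert d["s0", "s1"] == 1.0

    def test_formula_example(self):
        d = bray_curtis(counts_df([[1, 2, 3], [2, 1, 3]]))
        assert d["s0", "s1"] == pytest.approx(1 / 6, abs=1e-15)

    def test_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            x = rng.integers(0, 20, size=(6, 9)).astype(float)
            x[x.sum(axis=1) == 0, 0] = 1.0
            ours = bray_curtis(counts_df(x)).data
            for i in range(6):
                for j in range(6):
                    ref = 0.0 if i == j else scipy_braycurtis(x[i], x[j])
                    assert ours[i, j] == pytest.approx(ref, abs=1e-12)

    def test_all_zero_row_named_in_error(self):
        with pytest.raises(ValueError, match="s1"):
            bray_curtis(counts_df([[1, 2], [0, 0]]))


class TestNmds:
    def euclid_dm(self, pts):
        pts = np.asarray(pts, dtype=float)
        ids = [f"s{i}" for i in range(len(pts))]
        return skbio.DistanceMatrix(squareform(pdist(pts)), ids=ids)

    def test_exactly_embeddable_reaches_zero_stress(self):
        rng = np.random.default_rng(0)
        dm = self.euclid_dm(rng.normal(size=(9, 2)))
        res = nmds(dm, k_axes=2, seed=1)
        assert res.stress < 1e-6

    def test_three_points_always_embed(self):
        dm = skbio.DistanceMatrix(
            np.array([[0, 1, 1], [1, 0, 10], [1, 10, 0]], dtype=float),
            ids=["a", "b", "c"],
        )
        res = nmds(dm, seed=3)
        assert res.stress < 1e-6

    def test_stress_history_non_increasing(self):
        rng = np.random.default_rng(5)
        x = rng.integers(1, 30, size=(8, 6)).astype(float)
        dm = bray_curtis(counts_df(x))
        res = nmds(dm, seed=7)
        hist = res.stress_history
        assert all(a >= b - 1e-14 for a, b in zip(hist, hist[1:]))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        dm = self.euclid_dm(rng.normal(size=(7, 3)))
        r1 = nmds(dm, seed=11)
        r2 = nmds(dm, seed=11)
        assert np.array_equal(r1.coordinates.values, r2.coordinates.values)
        assert r1.stress == r2.stress

    def test_too_few_samples(self):
        dm = skbio.DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nmds(dm)


class TestRda:
    def test_noiseless_linear_response_fraction_one(self):
        rng = np.random.default_rng(1)
        x = counts_df(rng.normal(size=(12, 3)), prefix="s")
        y = pd.DataFrame(
            x.values @ rng.normal(size=(3, 5)), index=x.index,
            columns=[f"y{j}" for j in range(5)],
        )
        res = rda(y, x)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_response_fraction_zero(self):
        n = 8
        x = counts_df(np.repeat([[1.0], [-1.0]], n // 2, axis=0))
        rng = np.random.default_rng(2)
        y_raw = rng.normal(size=(n, 3))
        yc = y_raw - y_raw.mean(axis=0)
        xc = x.values - x.values.mean(axis=0)
        # project response out of the constraint space
        y_orth = yc - xc @ np.linalg.lstsq(xc, yc, rcond=None)[0]
        y = pd.DataFrame(y_orth, index=x.index, columns=["a", "b", "c"])
        res = rda(y, x)
        assert res.constrained_fraction == pytest.approx(0.0, abs=1e-10)

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            y = counts_df(rng.normal(size=(10, 5)))
            x = pd.DataFrame(
                rng.normal(size=(10, 2)), index=y.index, columns=["c1", "c2"]
            )
            res = rda(y, x)
            yc = y.values - y.values.mean(axis=0)
            xc = x.values - x.values.mean(axis=0)
            fitted = xc @ np.linalg.pinv(xc) @ yc
            frac = (fitted**2).sum() / (yc**2).sum()
            eigs = np.sort(
                np.linalg.eigvalsh(fitted.T @ fitted / (len(y) - 1))
            )[::-1][: len(res.eigenvalues)]
            assert res.constrained_fraction == pytest.approx(frac, abs=1e-10)
            np.testing.assert_allclose(res.eigenvalues, eigs, atol=1e-10)

    def test_variance_conservation(self):
        rng = np.random.default_rng(4)
        y = counts_df(rng.normal(size=(15, 6)))
        x = pd.DataFrame(rng.normal(size=(15, 3)), index=y.index,
                         columns=list("abc"))
        res = rda(y, x)
        yc = y.values - y.values.mean(axis=0)
        xc = x.values - x.values.mean(axis=0)
        fitted = xc @ np.linalg.lstsq(xc, yc, rcond=None)[0]
        resid = yc - fitted
        total = (yc**2).sum()
        assert (fitted**2).sum() + (resid**2).sum() == pytest.approx(total, abs=1e-8 * total)

    def test_categorical_constraints_dummy_coded(self):
        y = counts_df([[1, 0], [2, 1], [10, 5], [11, 6]])
        groups = pd.DataFrame(
            {"site": ["up", "up", "down", "down"]}, index=y.index
        )
        res = rda(y, groups)
        assert 0.9 < res.constrained_fraction <= 1.0 + 1e-12

    def test_rank_deficient_constraints_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(6)
        y = counts_df(rng.normal(size=(8, 3)))
        base = rng.normal(size=(8, 1))
        x = pd.DataFrame(
            np.hstack([base, 2 * base]), index=y.index, columns=["a", "b"]
        )
        with caplog.at_level("WARNING", logger="magpipe"):
            res = rda(y, x)
        assert "redundant" in caplog.text
        assert 0.0 <= res.constrained_fraction <= 1.0

    def test_mismatched_rows_rejected(self):
        y = counts_df([[1, 2], [3, 4]])
        x = pd.DataFrame([[1.0]], index=["other"], columns=["c"])
        with pytest.raises(ValueError):
            rda(y, x)


def test_variable_loadings_are_correlations():
    rng = np.random.default_rng(8)
    x = counts_df(rng.integers(1, 30, size=(10, 4)).astype(float))
    res = nmds(bray_curtis(x), seed=2)
    loadings = variable_loadings(x, res)
    assert loadings.shape == (4, 2)
    assert (loadings.abs().values <= 1.0 + 1e-12).all()
    v = x["v0"].to_numpy()
    a = res.coordinates["NMDS1"].to_numpy()
    assert loadings.loc["v0", "NMDS1"] == pytest.approx(np.corrcoef(v, a)[0, 1])
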