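import numpy as np
import pandas as pd
import pytest
from oracles import nipals_first_component

from mirsig.splsda import (
    BlockDataset,
    SplsdaModel,
    balanced_error_rate,
    cross_block_similarity,
    fit_block_splsda,
    loo_tune,
    max_median_group,
    predict_group,
    preprocess_blocks,
    soft_select,
    stability_scores,
)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def make_dataset(X, y, block="miR", X2=None, block2="clinical"):
    index = pd.Index([f"s{i}" for i in range(len(y))], name="sample_id")
    blocks = {block: pd.DataFrame(X, index=index,
                                  columns=[f"f{j}" for j in range(X.shape[1])])}
    if X2 is not None:
        blocks[block2] = pd.DataFrame(X2, index=index,
                                      columns=[f"c{j}" for j in range(X2.shape[1])])
    return BlockDataset(blocks, pd.Series(y, index=index, name="dose"))


def random_groups(rng, n, levels=(0, 20, 40, 80)):
    y = np.array(list(levels) * (n // len(levels) + 1))[:n]
    rng.shuffle(y)
    return y


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_constant_column_dropped(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        X[:, 2] = 5.0
        ds = make_dataset(X, random_groups(rng, 12))
        pre = preprocess_blocks(ds)
        assert pre.features["miR"] == ["f0", "f1", "f3"]
        assert pre.dropped["miR"] == ["f2"]

    def test_standardized_input_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        pre = preprocess_blocks(make_dataset(X, random_groups(rng, 20)))
        assert np.allclose(pre.X["miR"], X, atol=1e-12)

    def test_indicator_columns_centered(self):
        rng = np.random.default_rng(2)
        pre = preprocess_blocks(make_dataset(rng.normal(size=(16, 3)),
                                             random_groups(rng, 16)))
        assert np.allclose(pre.Y.sum(axis=0), 0.0, atol=1e-12)
        assert pre.Y.shape[1] == 4

    def test_missing_value_named(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        X[4, 1] = np.nan
        with pytest.raises(ValueError, match="s4.*f1"):
            preprocess_blocks(make_dataset(X, random_groups(rng, 8)))


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    u=arrays(np.float64, st.integers(2, 30),
             elements=st.floats(-100, 100, allow_nan=False)),
    keep=st.integers(1, 30),
)
def test_soft_select_properties(u, keep):
    """Support never exceeds keep, kept signs are preserved, and discarded
    entries had magnitudes no larger than every kept one."""
    out = soft_select(u, keep)
    nz = np.flatnonzero(out)
    assert len(nz) <= min(keep, len(u))
    assert all(np.sign(out[i]) == np.sign(u[i]) for i in nz)
    if keep < len(u):
        kept_min = np.abs(u[nz]).min() if len(nz) else np.inf
        dropped = np.setdiff1d(np.arange(len(u)), nz)
        thresh = np.sort(np.abs(u))[::-1][keep]
        assert np.abs(u[dropped]).max() <= kept_min + 1e-12 if len(dropped) else True
        assert np.allclose(np.abs(out[nz]), np.abs(u[nz]) - thresh)


def test_soft_select_support_and_shrinkage():
    u = np.array([3.0, -5.0, 1.0, 4.0, -2.0])
    out = soft_select(u, 2)
    assert np.count_nonzero(out) == 2
    # kept entries are the two largest magnitudes, shrunk by the 3rd largest (3.0)
    assert out[1] == -2.0 and out[3] == 1.0
    assert np.array_equal(soft_select(u, 5), u)


@pytest.mark.parametrize("seed", range(20))
def test_dense_single_block_matches_nipals(seed):
    """With one block and no sparsity, component 1 is classical PLS-DA:
    scores match an independent NIPALS oracle to cosine >= 0.999."""
    rng = np.random.default_rng(seed)
    n, p = int(rng.integers(16, 40)), int(rng.integers(5, 25))
    X = rng.normal(size=(n, p))
    y = random_groups(rng, n, levels=(0, 20, 40, 80)[: int(rng.integers(2, 5))])
    ds = make_dataset(X, y)
    pre = preprocess_blocks(ds)
    model = fit_block_splsda(ds, ncomp=1, keepX=None)
    t_oracle = nipals_first_component(pre.X["miR"], pre.Y)
    t_model = model.scores["miR"][:, 0]
    cos = abs(t_model @ t_oracle) / (np.linalg.norm(t_model) * np.linalg.norm(t_oracle))
    assert cos >= 0.999


def test_keepx_one_gives_single_nonzero_loading():
    rng = np.random.default_rng(5)
    ds = make_dataset(rng.normal(size=(20, 10)), random_groups(rng, 20))
    model = fit_block_splsda(ds, ncomp=2, keepX={"miR": 1})
    for h in range(2):
        assert np.count_nonzero(model.loadings["miR"][:, h]) == 1


@pytest.mark.parametrize("keepx", [3, 7, 10])
def test_support_size_equals_keepx(keepx):
    rng = np.random.default_rng(6)
    ds = make_dataset(rng.normal(size=(24, 15)), random_groups(rng, 24))
    model = fit_block_splsda(ds, ncomp=2, keepX={"miR": keepx})
    for h in range(2):
        assert np.count_nonzero(model.loadings["miR"][:, h]) == keepx


def separable_two_class(rng, n=20, p=10, gap=6.0):
    y = np.repeat([0, 80], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += np.where(y == 80, gap, 0.0)
    X[:, 1] -= np.where(y == 80, gap, 0.0)
    return X, y


def test_separable_classes_auc_one():
    from mirsig.evaluate import one_vs_rest_roc

    rng = np.random.default_rng(7)
    X, y = separable_two_class(rng)
    ds = make_dataset(X, y)
    model = fit_block_splsda(ds, ncomp=1, keepX={"miR": 2})
    _, scores = predict_group(model, ds.blocks)
    rocs = one_vs_rest_roc(scores, ds.outcome)
    assert all(r.auc == 1.0 for r in rocs)


def test_predict_training_samples_perfectly():
    rng = np.random.default_rng(8)
    X, y = separable_two_class(rng)
    ds = make_dataset(X, y)
    model = fit_block_splsda(ds, ncomp=1, keepX={"miR": 2})
    pred, _ = predict_group(model, ds.blocks)
    assert (pred.to_numpy() == y).all()


def test_midpoint_tie_breaks_to_first_group_and_flags():
    model = SplsdaModel(
        block_names=["miR"], loadings={"miR": np.array([[1.0]])},
        scores={"miR": np.zeros((4, 1))}, defl={"miR": np.zeros((1, 1))},
        y_loadings=np.zeros((2, 1)), y_scores=np.zeros((4, 1)),
        features={"miR": ["f0"]}, means={"miR": np.zeros(1)},
        sds={"miR": np.ones(1)}, groups=[0, 80],
        centroids=np.array([[-1.0], [1.0]]), ncomp=1,
        keepX={"miR": [1]}, converged=[True],
    )
    new = {"miR": pd.DataFrame({"f0": [0.0]}, index=["mid"])}
    pred, scores = predict_group(model, new)
    assert pred.loc["mid"] == 0
    assert pred.attrs["ties"] == ["mid"]
    assert scores.loc["mid", 0] == scores.loc["mid", 80]


def test_feature_order_permutation_invariant():
    rng = np.random.default_rng(9)
    X, y = separable_two_class(rng)
    ds = make_dataset(X, y)
    model = fit_block_splsda(ds, ncomp=1, keepX={"miR": 3})
    pred1, s1 = predict_group(model, ds.blocks)
    permuted = {"miR": ds.blocks["miR"].iloc[:, ::-1]}
    pred2, s2 = predict_group(model, permuted)
    pd.testing.assert_series_equal(pred1, pred2)
    assert np.allclose(s1.to_numpy(), s2.to_numpy())


def test_successive_scores_orthogonal(default_dataset):
    model = fit_block_splsda(default_dataset, ncomp=3, keepX={"miR": 10})
    for b in model.block_names:
        T = model.scores[b]
        for h in range(3):
            for k in range(h):
                cos = abs(T[:, h] @ T[:, k]) / (
                    np.linalg.norm(T[:, h]) * np.linalg.norm(T[:, k]) + 1e-30)
                assert cos < 1e-6


def test_scale_equivariance():
    """Multiplying a raw column by a positive constant changes nothing after
    standardization."""
    rng = np.random.default_rng(10)
    X, y = separable_two_class(rng)
    ds1 = make_dataset(X, y)
    X2 = X.copy()
    X2[:, 0] *= 37.5
    ds2 = make_dataset(X2, y)
    m1 = fit_block_splsda(ds1, ncomp=2, keepX={"miR": 4})
    m2 = fit_block_splsda(ds2, ncomp=2, keepX={"miR": 4})
    assert np.allclose(m1.scores["miR"], m2.scores["miR"], atol=1e-8)
    assert np.allclose(m1.loadings["miR"], m2.loadings["miR"], atol=1e-8)


def test_deterministic_given_data(default_dataset):
    m1 = fit_block_splsda(default_dataset, ncomp=2, keepX={"miR": 7})
    m2 = fit_block_splsda(default_dataset, ncomp=2, keepX={"miR": 7})
    assert np.array_equal(m1.loadings["miR"], m2.loadings["miR"])
    assert np.array_equal(m1.scores["clinical"], m2.scores["clinical"])


# ---------------------------------------------------------------------------
# LOO tuning and stability
# ---------------------------------------------------------------------------

def test_loo_tune_separable_reaches_zero_ber():
    rng = np.random.default_rng(11)
    X, y = separable_two_class(rng, n=16)
    ds = make_dataset(X, y)
    ncomp, keepX, trace = loo_tune(ds, ncomp_grid=(1,), keepx_grid=(2, 4))
    assert trace["ber"].min() == 0.0
    assert len(trace) == 2
    assert (trace["n_folds"] == 16).all()


def test_loo_tune_tie_prefers_smaller_model():
    rng = np.random.default_rng(12)
    X, y = separable_two_class(rng, n=16)
    ds = make_dataset(X, y)
    ncomp, keepX, trace = loo_tune(ds, ncomp_grid=(1, 2), keepx_grid=(2, 4))
    assert ncomp == 1
    assert keepX["miR"] == [2]


def test_singleton_class_fold_skipped():
    """If exclusions leave a class with one sample, its LOO fold is skipped
    (per-class error undefined) with a warning rather than crashing."""
    rng = np.random.default_rng(13)
    X = rng.normal(size=(10, 4))
    y = np.array([0, 0, 0, 0, 20, 20, 20, 20, 80, 80])
    ds = make_dataset(X, y)
    mask = np.ones(10, bool)
    mask[9] = False            # drop one 80 Gy animal -> singleton class view
    degenerate = ds.subset(mask)
    with pytest.warns(UserWarning, match="single sample"):
        from mirsig.splsda import loo_predictions

        preds, _ = loo_predictions(degenerate, 1, {"miR": 2})
    assert len(preds) == 8


def test_stability_extremes_and_planted_feature():
    """A feature carrying all the class signal is selected in every LOO fold
    (stability 1); pure-noise features that never enter stay at 0."""
    rng = np.random.default_rng(14)
    n = 24
    y = random_groups(rng, n)
    X = rng.normal(size=(n, 12)) * 0.2
    X[:, 5] = np.log2(1 + y) + rng.normal(0, 0.05, n)   # dominant planted feature
    ds = make_dataset(X, y)
    stab = stability_scores(ds, ncomp=1, keepX={"miR": 3})
    s = stab.set_index("feature")["stability"]
    assert s["f5"] == 1.0
    assert (s >= 0.0).all() and (s <= 1.0).all()
    assert (s == 0.0).sum() >= 5


# ---------------------------------------------------------------------------
# signature annotations
# ---------------------------------------------------------------------------

class TestMaxMedianGroup:
    def _expr(self, col):
        y = pd.Series(np.repeat([0, 20, 40, 80], 5))
        return pd.DataFrame({"m": col}), y

    def test_monotone_up_gives_highest_dose(self):
        expr, y = self._expr(np.repeat([0.0, 1.0, 2.0, 3.0], 5))
        out = max_median_group(expr, y)
        assert out.loc["m", "max_median_group"] == 80

    def test_monotone_down_gives_control(self):
        expr, y = self._expr(np.repeat([3.0, 2.0, 1.0, 0.0], 5))
        out = max_median_group(expr, y)
        assert out.loc["m", "max_median_group"] == 0

    def test_flat_ties_to_higher_dose_with_flag(self):
        expr, y = self._expr(np.zeros(20))
        out = max_median_group(expr, y)
        assert out.loc["m", "max_median_group"] == 80
        assert bool(out.loc["m", "tie"])


class TestCrossBlockSimilarity:
    def _toy_model(self, ncomp, Xa, Xb, Ta, Tb):
        return SplsdaModel(
            block_names=["miR", "clinical"],
            loadings={"miR": np.zeros((Xa.shape[1], ncomp)),
                      "clinical": np.zeros((Xb.shape[1], ncomp))},
            scores={"miR": Ta, "clinical": Tb},
            defl={"miR": np.zeros((Xa.shape[1], ncomp)),
                  "clinical": np.zeros((Xb.shape[1], ncomp))},
            y_loadings=np.zeros((2, ncomp)), y_scores=np.zeros((len(Xa), ncomp)),
            features={"miR": [f"f{j}" for j in range(Xa.shape[1])],
                      "clinical": [f"c{j}" for j in range(Xb.shape[1])]},
            means={}, sds={}, groups=[0, 80],
            centroids=np.zeros((2, ncomp)), ncomp=ncomp,
            keepX={}, converged=[True] * ncomp,
            X0={"miR": Xa, "clinical": Xb},
        )

    def test_score_copies_have_similarity_one(self):
        rng = np.random.default_rng(15)
        ta, tb = rng.normal(size=(12, 1)), rng.normal(size=(12, 1))
        model = self._toy_model(1, ta, tb, ta, tb)
        pairs, full = cross_block_similarity(model, cutoff=0.5)
        assert full.loc["f0", "c0"] == pytest.approx(1.0)
        assert len(pairs) == 1

    def test_cutoff_above_one_empties_list(self):
        rng = np.random.default_rng(16)
        ta, tb = rng.normal(size=(12, 1)), rng.normal(size=(12, 1))
        model = self._toy_model(1, ta, tb, ta, tb)
        pairs, _ = cross_block_similarity(model, cutoff=1.01)
        assert pairs.empty

    def test_two_component_values_match_direct_formula(self):
        rng = np.random.default_rng(17)
        n = 15
        Xa, Xb = rng.normal(size=(n, 4)), rng.normal(size=(n, 3))
        Ta, Tb = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
        model = self._toy_model(2, Xa, Xb, Ta, Tb)
        _, full = cross_block_similarity(model, cutoff=0.0)
        for i in range(4):
            for j in range(3):
                expected = sum(
                    np.corrcoef(Xa[:, i], Ta[:, h])[0, 1]
                    * np.corrcoef(Xb[:, j], Tb[:, h])[0, 1]
                    for h in range(2)
                )
                assert full.iloc[i, j] == pytest.approx(expected, abs=1e-12)


def test_dense_fit_cross_checked_against_mixomics(tmp_path):
    """Independent cross-check: dense single-block component-1 scores agree
    with the reference R implementation (mixOmics::plsda) to cosine ~1."""
    import subprocess

    rng = np.random.default_rng(42)
    n, p = 24, 8
    X = rng.normal(size=(n, p))
    y = np.array([0, 20, 40, 80] * (n // 4))
    rng.shuffle(y)
    X[:, 0] += 0.8 * np.log2(1 + y)
    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    np.savetxt(tmp_path / "y.csv", y, fmt="%d")
    script = f"""
    suppressMessages(library(mixOmics))
    X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
    y <- factor(scan("{tmp_path}/y.csv", quiet=TRUE))
    fit <- plsda(X, y, ncomp=1)
    write.csv(fit$variates$X, "{tmp_path}/t.csv", row.names=FALSE)
    """
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                          timeout=300)
    assert proc.returncode == 0, proc.stderr
    t_ref = pd.read_csv(tmp_path / "t.csv").to_numpy().ravel()
    ds = make_dataset(X, y)
    model = fit_block_splsda(ds, ncomp=1, keepX=None)
    t = model.scores["miR"][:, 0]
    cos = abs(t @ t_ref) / (np.linalg.norm(t) * np.linalg.norm(t_ref))
    assert cos >= 0.999


def test_balanced_error_rate_definition():
    y = np.array([0, 0, 0, 80, 80])
    pred = np.array([0, 0, 80, 80, 0])
    # class 0: 1/3 wrong; class 80: 1/2 wrong
    assert balanced_error_rate(y, pred) == pytest.approx((1 / 3 + 1 / 2) / 2)
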