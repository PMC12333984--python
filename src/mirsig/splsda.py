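"""Multiblock sparse PLS discriminant analysis with LOO tuning and stability.

The model couples named data blocks (here a miRNA expression block and a
clinical block) through a design matrix of inter-block connection weights,
while discriminating a categorical outcome (dose group) encoded as a centered
indicator matrix.  Each component is a sparse, unit-norm linear combination
of a block's features; sparsity is imposed by keeping the keepX
largest-magnitude entries of each update and soft-shrinking them by the next
largest magnitude (a rank-constrained Lasso step).  Model size (number of
components, keepX per component) is tuned by leave-one-out cross-validation
on the balanced error rate, and feature stability is the fraction of LOO
folds in which a feature is selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .normalize import NormalizedExpression

logger = logging.getLogger(__name__)

_TOL = 1e-6
_MAX_ITER = 100


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class BlockDataset:
    """Aligned named blocks + categorical outcome for one cohort/timepoint."""

    blocks: dict[str, pd.DataFrame]
    outcome: pd.Series
    design: pd.DataFrame = None     # feature-block x feature-block weights in [0,1]
    outcome_weight: float = 1.0

    def __post_init__(self) -> None:
        names = list(self.blocks)
        index = self.blocks[names[0]].index
        for b in names[1:]:
            if not self.blocks[b].index.equals(index):
                raise ValueError(f"block {b!r} sample order differs from {names[0]!r}")
        if not self.outcome.index.equals(index):
            raise ValueError("outcome sample order differs from blocks")
        counts = self.outcome.value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError("outcome needs >= 2 levels with >= 2 samples each")
        if self.design is None:
            self.design = default_design(names)

    @property
    def n_samples(self) -> int:
        return len(self.outcome)

    def subset(self, mask: np.ndarray) -> "BlockDataset":
        ds = object.__new__(BlockDataset)
        ds.blocks = {b: df.iloc[mask] for b, df in self.blocks.items()}
        ds.outcome = self.outcome.iloc[mask]
        ds.design = self.design
        ds.outcome_weight = self.outcome_weight
        return ds


def default_design(names: list[str], off_diag: float = 0.1) -> pd.DataFrame:
    """Full design: weak miR<->clinical coupling, zero diagonal."""
    d = pd.DataFrame(off_diag, index=names, columns=names)
    np.fill_diagonal(d.values, 0.0)
    return d


def build_block_dataset(
    expr: NormalizedExpression,
    clinical: pd.DataFrame | None = None,
    design_weight: float = 0.1,
    outcome_weight: float = 1.0,
) -> BlockDataset:
    """Assemble the miR (+ clinical) blocks, aligned and imputed.

    Missing (−)ΔCt is imputed at the assay's observed minimum (Ct truncation
    means the target was below the detection limit, i.e. at its lowest
    expression); missing clinical fields take the within-cohort median.
    ``dose_gy`` is the outcome, never a clinical feature.
    """
    mir = expr.values.copy()
    n_missing = int(mir.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d missing (−)ΔCt values at per-assay minima", n_missing)
        mir = mir.fillna(mir.min())
    blocks = {"miR": mir}
    if clinical is not None:
        clin = clinical.reindex(mir.index).drop(columns=["dose_gy"], errors="ignore")
        clin = clin.select_dtypes(include=[np.number]).astype(float)
        n_missing = int(clin.isna().sum().sum())
        if n_missing:
            logger.info("imputing %d missing clinical values at column medians", n_missing)
            clin = clin.fillna(clin.median())
        clin = clin.dropna(axis=1, how="all")
        blocks["clinical"] = clin
    outcome = expr.dose_groups.loc[mir.index]
    design = default_design(list(blocks), design_weight)
    return BlockDataset(blocks, outcome, design, outcome_weight)


@dataclass
class Preprocessed:
    """Standardized blocks + centered outcome indicator, with training stats."""

    X: dict[str, np.ndarray]
    features: dict[str, list[str]]
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    dropped: dict[str, list[str]]
    Y: np.ndarray
    groups: list
    y_labels: np.ndarray
    sample_ids: list
    design: pd.DataFrame
    outcome_weight: float


def preprocess_blocks(dataset: BlockDataset) -> Preprocessed:
    """Center/scale every column to unit variance; drop zero-variance columns;
    expand the outcome into a centered indicator matrix (one column/group)."""
    X, feats, means, sds, dropped = {}, {}, {}, {}, {}
    for name, df in dataset.blocks.items():
        arr = df.to_numpy(float)
        nan_pos = np.argwhere(np.isnan(arr))
        if len(nan_pos):
            i, j = nan_pos[0]
            raise ValueError(
                f"missing value in block {name!r}: sample {df.index[i]!r}, "
                f"feature {df.columns[j]!r}")
        mu = arr.mean(axis=0)
        sigma = arr.std(axis=0, ddof=1)
        keep = sigma > 0
        if not keep.all():
            dropped[name] = list(df.columns[~keep])
            logger.info("block %r: dropped zero-variance columns %s", name, dropped[name])
        else:
            dropped[name] = []
        X[name] = (arr[:, keep] - mu[keep]) / sigma[keep]
        feats[name] = list(df.columns[keep])
        means[name], sds[name] = mu[keep], sigma[keep]
    groups = sorted(dataset.outcome.unique())
    indicator = np.stack([(dataset.outcome == g).to_numpy(float) for g in groups], axis=1)
    Y = indicator - indicator.mean(axis=0)
    return Preprocessed(
        X=X, features=feats, means=means, sds=sds, dropped=dropped,
        Y=Y, groups=groups, y_labels=dataset.outcome.to_numpy(),
        sample_ids=list(dataset.outcome.index),
        design=dataset.design, outcome_weight=dataset.outcome_weight,
    )


@dataclass
class SplsdaModel:
    """Fitted multiblock sPLS-DA: loadings, scores, projection machinery."""

    block_names: list[str]
    loadings: dict[str, np.ndarray]        # p_b x ncomp, unit L2 columns
    scores: dict[str, np.ndarray]          # n x ncomp
    defl: dict[str, np.ndarray]            # p_b x ncomp regression vectors for deflation
    y_loadings: np.ndarray                 # G x ncomp
    y_scores: np.ndarray                   # n x ncomp
    features: dict[str, list[str]]
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    groups: list
    centroids: np.ndarray                  # G x ncomp, on block-averaged scores
    ncomp: int
    keepX: dict[str, list[int]]
    converged: list[bool]
    X0: dict[str, np.ndarray] = None       # standardized training blocks (pre-deflation)
    tuning_trace: pd.DataFrame = None
    stability: pd.DataFrame = None         # columns: component, feature, stability
    signature: pd.DataFrame = None         # columns: component, miRNA, stability, loading

    def loadings_frame(self, block: str) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings[block], index=self.features[block],
            columns=[f"comp{h+1}" for h in range(self.ncomp)],
        )

    def support(self, block: str, comp: int) -> list[str]:
        a = self.loadings[block][:, comp]
        return [f for f, v in zip(self.features[block], a) if v != 0.0]


# ---------------------------------------------------------------------------
# core fit
# ---------------------------------------------------------------------------

def soft_select(u: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest-|u| entries, shrunk by the (keep+1)-th largest
    magnitude, signs preserved; everything else zero."""
    p = len(u)
    if keep >= p:
        return u.copy()
    order = np.lexsort((np.arange(p), -np.abs(u)))   # stable: magnitude desc, index asc
    thresh = np.abs(u[order[keep]])
    out = np.zeros_like(u)
    idx = order[:keep]
    out[idx] = np.sign(u[idx]) * (np.abs(u[idx]) - thresh)
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def _init_loading(Xb: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Dominant left singular vector of X_b^T Y, sign-fixed for determinism."""
    M = Xb.T @ Y
    u = np.linalg.svd(M, full_matrices=False)[0][:, 0]
    peak = np.argmax(np.abs(u))
    return u * np.sign(u[peak]) if u[peak] != 0 else u


def _normalize_keepx(keepX, block_names, feats, ncomp) -> dict[str, list[int]]:
    out = {}
    for b in block_names:
        p = len(feats[b])
        if keepX is None:
            kx = p
        elif isinstance(keepX, dict):
            kx = keepX.get(b, p)
        else:
            kx = keepX
        if isinstance(kx, (int, np.integer)):
            kx = [int(kx)] * ncomp
        kx = [min(int(s), p) for s in kx]
        if len(kx) < ncomp:
            kx = kx + [kx[-1]] * (ncomp - len(kx))
        if any(s < 1 for s in kx):
            raise ValueError(f"keepX for block {b!r} must be >= 1")
        out[b] = kx[:ncomp]
    return out


def fit_block_splsda(
    data: BlockDataset | Preprocessed,
    ncomp: int = 2,
    keepX=None,
    deflate_outcome: bool = True,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> SplsdaModel:
    """Fit the multiblock sPLS-DA.

    Per component: block loadings start at the dominant left singular vector
    of X_b^T Y, then cycle — each block regresses on the design-weighted sum
    of the other blocks' scores plus the outcome score, is rank-thresholded to
    keepX features and re-normalized — until the largest loading change falls
    below ``tol``.  Blocks are then deflated on their own scores (the outcome
    block too, by default).
    """
    pre = preprocess_blocks(data) if isinstance(data, BlockDataset) else data
    names = list(pre.X)
    keepx = _normalize_keepx(keepX, names, pre.features, ncomp)
    Xw = {b: pre.X[b].copy() for b in names}
    Yw = pre.Y.copy()
    n = Yw.shape[0]
    w_y = pre.outcome_weight
    D = pre.design

    loadings = {b: np.zeros((Xw[b].shape[1], ncomp)) for b in names}
    scores = {b: np.zeros((n, ncomp)) for b in names}
    defl = {b: np.zeros((Xw[b].shape[1], ncomp)) for b in names}
    y_loadings = np.zeros((Yw.shape[1], ncomp))
    y_scores = np.zeros((n, ncomp))
    converged: list[bool] = []

    for h in range(ncomp):
        a = {b: _unit(soft_select(_init_loading(Xw[b], Yw), keepx[b][h])) for b in names}
        t = {b: Xw[b] @ a[b] for b in names}
        ok = False
        for _ in range(max_iter):
            a_y = _unit(Yw.T @ sum(t[b] for b in names))
            t_y = Yw @ a_y
            change = 0.0
            for b in names:
                drive = w_y * t_y
                for k in names:
                    if k != b:
                        drive = drive + D.loc[b, k] * t[k]
                new = _unit(soft_select(Xw[b].T @ drive, keepx[b][h]))
                change = max(change, float(np.max(np.abs(new - a[b]))))
                a[b] = new
                t[b] = Xw[b] @ new
            if change < tol:
                ok = True
                break
        if not ok:
            warnings.warn(f"component {h+1} did not converge in {max_iter} iterations",
                          stacklevel=2)
        converged.append(ok)
        a_y = _unit(Yw.T @ sum(t[b] for b in names))
        t_y = Yw @ a_y
        for b in names:
            tb = t[b]
            denom = float(tb @ tb)
            c = (Xw[b].T @ tb) / denom if denom > 0 else np.zeros(Xw[b].shape[1])
            Xw[b] -= np.outer(tb, c)
            loadings[b][:, h], scores[b][:, h], defl[b][:, h] = a[b], tb, c
        y_loadings[:, h], y_scores[:, h] = a_y, t_y
        if deflate_outcome:
            denom = float(t_y @ t_y)
            if denom > 0:
                Yw -= np.outer(t_y, (Yw.T @ t_y) / denom)

    avg = sum(scores[b] for b in names) / len(names)
    centroids = np.stack([avg[pre.y_labels == g].mean(axis=0) for g in pre.groups])
    return SplsdaModel(
        block_names=names, loadings=loadings, scores=scores, defl=defl,
        y_loadings=y_loadings, y_scores=y_scores,
        features=pre.features, means=pre.means, sds=pre.sds,
        groups=pre.groups, centroids=centroids, ncomp=ncomp, keepX=keepx,
        converged=converged, X0={b: pre.X[b] for b in names},
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _project_block(model: SplsdaModel, block: str, Xnew: np.ndarray) -> np.ndarray:
    """Sequential projection through the training deflation."""
    T = np.zeros((Xnew.shape[0], model.ncomp))
    x = Xnew.copy()
    for h in range(model.ncomp):
        th = x @ model.loadings[block][:, h]
        T[:, h] = th
        x = x - np.outer(th, model.defl[block][:, h])
    return T


def transform(model: SplsdaModel, new_blocks: dict[str, pd.DataFrame]) -> dict[str, np.ndarray]:
    """Standardize new samples with training statistics and project per block."""
    out = {}
    for b in model.block_names:
        if b not in new_blocks:
            raise KeyError(f"block {b!r} missing from new data")
        df = new_blocks[b]
        missing = set(model.features[b]) - set(df.columns)
        if missing:
            raise ValueError(f"block {b!r} lacks training features: {sorted(missing)}")
        arr = df[model.features[b]].to_numpy(float)
        Z = (arr - model.means[b]) / model.sds[b]
        out[b] = _project_block(model, b, Z)
    return out


def predict_group(
    model: SplsdaModel, new_blocks: dict[str, pd.DataFrame]
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each sample the group with the nearest training centroid on the
    block-averaged component scores; return continuous per-group scores
    (negative Euclidean distances) for ROC use.  Exact ties break to the
    lexicographically first group and are flagged in the series' attrs."""
    T = transform(model, new_blocks)
    avg = sum(T[b] for b in model.block_names) / len(model.block_names)
    d = np.linalg.norm(avg[:, None, :] - model.centroids[None, :, :], axis=2)
    index = new_blocks[model.block_names[0]].index
    scores = pd.DataFrame(-d, index=index, columns=model.groups)
    best = d.argmin(axis=1)
    ties = (d == d[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    labels = pd.Series([model.groups[i] for i in best], index=index, name="predicted")
    labels.attrs["ties"] = list(index[ties])
    return labels, scores


def balanced_error_rate(y_true: np.ndarray, y_pred: np.ndarray, groups=None) -> float:
    """Mean per-class misclassification rate."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    groups = sorted(set(y_true)) if groups is None else groups
    errs = [np.mean(y_pred[y_true == g] != g) for g in groups if (y_true == g).any()]
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# leave-one-out machinery: tuning, stability, held-out scores
# ---------------------------------------------------------------------------

def loo_predictions(
    dataset: BlockDataset,
    ncomp: int,
    keepX,
    deflate_outcome: bool = True,
    collect_supports: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """One LOO pass: per-fold refit, held-out prediction and (optionally) the
    selected support of each fold's fit.  Folds whose held-out class has no
    other member are skipped with a warning."""
    n = dataset.n_samples
    labels = dataset.outcome
    rows, supports = [], []
    counts = labels.value_counts()
    for i in range(n):
        if counts[labels.iloc[i]] < 2:
            warnings.warn(
                f"skipping LOO fold for sample {labels.index[i]!r}: its class has a "
                "single sample, per-class error is undefined", stacklevel=2)
            continue
        mask = np.ones(n, bool)
        mask[i] = False
        train = dataset.subset(mask)
        model = fit_block_splsda(train, ncomp=ncomp, keepX=keepX,
                                 deflate_outcome=deflate_outcome)
        held = {b: df.iloc[[i]] for b, df in dataset.blocks.items()}
        pred, score = predict_group(model, held)
        row = {"sample_id": labels.index[i], "true": labels.iloc[i],
               "predicted": pred.iloc[0]}
        row.update({f"score_{g}": score.iloc[0][g] for g in model.groups})
        rows.append(row)
        if collect_supports:
            supports.append({
                (b, h): frozenset(model.support(b, h))
                for b in model.block_names for h in range(ncomp)
            })
    return pd.DataFrame(rows), supports


def loo_tune(
    dataset: BlockDataset,
    ncomp_grid=(1, 2, 3),
    keepx_grid=(3, 5, 7, 10, 15, 20, 30),
    sparse_block: str = "miR",
    deflate_outcome: bool = True,
) -> tuple[int, dict, pd.DataFrame]:
    """Choose (ncomp, keepX) minimizing the LOO balanced error rate.

    The keepX grid applies to ``sparse_block``; other blocks keep all
    features.  Ties break toward fewer components, then smaller total keepX,
    then grid order.
    """
    if not len(ncomp_grid) or not len(keepx_grid):
        raise ValueError("grids must be non-empty")
    trace_rows = []
    best = None
    for order, (ncomp, kx) in enumerate(product(ncomp_grid, keepx_grid)):
        keepX = {sparse_block: [int(kx)] * ncomp}
        preds, _ = loo_predictions(dataset, ncomp, keepX,
                                   deflate_outcome=deflate_outcome)
        ber = balanced_error_rate(preds["true"], preds["predicted"])
        trace_rows.append({"ncomp": ncomp, "keepX": kx, "ber": ber,
                           "n_folds": len(preds)})
        key = (ber, ncomp, ncomp * kx, order)
        if best is None or key < best[0]:
            best = (key, ncomp, keepX)
    trace = pd.DataFrame(trace_rows)
    _, ncomp, keepX = best
    logger.info("LOO tuning chose ncomp=%d keepX=%s (BER %.3f)",
                ncomp, keepX, best[0][0])
    return ncomp, keepX, trace


def stability_scores(
    dataset: BlockDataset,
    ncomp: int,
    keepX,
    sparse_block: str = "miR",
    deflate_outcome: bool = True,
) -> pd.DataFrame:
    """Fraction of LOO folds in which each feature enters each component's support."""
    _, supports = loo_predictions(dataset, ncomp, keepX,
                                  deflate_outcome=deflate_outcome,
                                  collect_supports=True)
    n_folds = len(supports)
    rows = []
    feats = dataset.blocks[sparse_block].columns
    for h in range(ncomp):
        count = {f: 0 for f in feats}
        for s in supports:
            for f in s[(sparse_block, h)]:
                count[f] += 1
        for f in feats:
            rows.append({"component": h + 1, "feature": f,
                         "stability": count[f] / n_folds if n_folds else np.nan})
    return pd.DataFrame(rows)


def fit_tuned(
    dataset: BlockDataset,
    ncomp_grid=(1, 2, 3),
    keepx_grid=(3, 5, 7, 10, 15, 20, 30),
    sparse_block: str = "miR",
    deflate_outcome: bool = True,
) -> SplsdaModel:
    """Tune by LOO, fit on the full data, attach stability and the signature."""
    ncomp, keepX, trace = loo_tune(dataset, ncomp_grid, keepx_grid,
                                   sparse_block, deflate_outcome)
    model = fit_block_splsda(dataset, ncomp=ncomp, keepX=keepX,
                             deflate_outcome=deflate_outcome)
    model.tuning_trace = trace
    model.stability = stability_scores(dataset, ncomp, keepX,
                                       sparse_block, deflate_outcome)
    stab = model.stability.set_index(["component", "feature"])["stability"]
    rows = []
    for h in range(ncomp):
        a = model.loadings[sparse_block][:, h]
        for f, v in zip(model.features[sparse_block], a):
            if v != 0.0:
                rows.append({"component": h + 1, "miRNA": f,
                             "stability": float(stab.get((h + 1, f), np.nan)),
                             "loading": float(v)})
    model.signature = pd.DataFrame(rows, columns=["component", "miRNA", "stability", "loading"])
    return model


# ---------------------------------------------------------------------------
# signature annotations
# ---------------------------------------------------------------------------

def max_median_group(
    expression: pd.DataFrame, groups: pd.Series, features: list[str] | None = None
) -> pd.DataFrame:
    """Per feature, the dose group with the maximal median expression.

    Ties resolve to the higher dose and are flagged.
    """
    feats = list(features) if features is not None else list(expression.columns)
    levels = sorted(groups.unique())
    med = expression[feats].groupby(groups.values).median().reindex(levels)
    rows = []
    for f in feats:
        col = med[f]
        top = col.max()
        winners = [g for g in levels if np.isclose(col[g], top)]
        rows.append({"feature": f, "max_median_group": winners[-1],
                     "tie": len(winners) > 1})
    return pd.DataFrame(rows).set_index("feature")


def cross_block_similarity(
    model: SplsdaModel,
    block_a: str = "miR",
    block_b: str = "clinical",
    cutoff: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Component-mediated similarity between variables of two blocks.

    similarity(x, y) = sum_h corr(x, t_a,h) * corr(y, t_b,h), the standard
    correlation-circle construction.  Returns (pairs with |s| >= cutoff,
    full matrix).  Zero-variance variables are skipped with a log entry.
    """
    if model.X0 is None:
        raise ValueError("model lacks stored training blocks")

    def comp_corr(block: str) -> pd.DataFrame:
        X = model.X0[block]
        cors = np.zeros((X.shape[1], model.ncomp))
        keep = []
        for j, f in enumerate(model.features[block]):
            if np.std(X[:, j]) == 0:
                logger.info("similarity: skipping zero-variance variable %r", f)
                continue
            keep.append(f)
            for h in range(model.ncomp):
                th = model.scores[block][:, h]
                sd = np.std(th)
                cors[j, h] = 0.0 if sd == 0 else float(np.corrcoef(X[:, j], th)[0, 1])
        return pd.DataFrame(cors[[model.features[block].index(f) for f in keep]],
                            index=keep, columns=range(model.ncomp))

    ca, cb = comp_corr(block_a), comp_corr(block_b)
    full = pd.DataFrame(ca.to_numpy() @ cb.to_numpy().T, index=ca.index, columns=cb.index)
    pairs = (
        full.stack(future_stack=True)
        .rename("similarity")
        .reset_index()
        .rename(columns={"level_0": "var_a", "level_1": "var_b"})
    )
    pairs = pairs[pairs["similarity"].abs() >= cutoff].reset_index(drop=True)
    return pairs, full
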