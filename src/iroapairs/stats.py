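"""Univariate and multivariate statistics on the ratio matrix.

Three views of the same metabolites x samples ratio matrix:

* per-metabolite unpaired two-sample t-tests on log2 ratios (pooled-variance
  Student by default, Welch as an option), with optional Benjamini-Hochberg
  q-values;
* PCA of the samples with a deterministic sign convention and variance
  fractions for a scree plot;
* a random-forest classifier of treatment vs control with the three
  classical forest readouts: out-of-bag (OOB) error, per-metabolite mean
  decrease accuracy (MDA, per-tree OOB permutation importance), and the
  tree-proximity matrix embedded in two dimensions by classical
  multidimensional scaling.

The ensemble itself is scikit-learn's; OOB bookkeeping, MDA, proximity and
the MDS embedding are computed here so that their definitions (and hence
their determinism under a fixed seed) are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .quantification import RatioMatrix

__all__ = [
    "TTestResult",
    "PCAResult",
    "RFResult",
    "unpaired_t_test",
    "bh_qvalues",
    "pca",
    "random_forest_mda",
    "top_importance",
]


# ---------------------------------------------------------------------------
# univariate


@dataclass
class TTestResult:
    """Per-row t statistics: frame with columns t, df, p (index = row_id)."""

    frame: pd.DataFrame
    log_transformed: bool
    welch: bool


def unpaired_t_test(
    matrix: RatioMatrix,
    log_transform: bool = True,
    welch: bool = False,
) -> TTestResult:
    """Unpaired two-sample t-test of treatment vs control, per metabolite.

    Pooled-variance Student's t by default (``welch=True`` for unequal
    variances); ratios are log2-transformed first unless ``log_transform``
    is disabled.  Degenerate rows with zero variance in both groups get
    p = 1 when the means are equal and p = 0 otherwise, with t = +-inf by
    sign of the mean difference.
    """
    t_cols = matrix.group_columns("treatment")
    c_cols = matrix.group_columns("control")
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    x = matrix.ratios[t_cols].to_numpy(dtype=float)
    y = matrix.ratios[c_cols].to_numpy(dtype=float)
    if log_transform:
        x, y = np.log2(x), np.log2(y)
    n1, n2 = x.shape[1], y.shape[1]
    import warnings

    with warnings.catch_warnings():
        # constant rows trip scipy's precision-loss warning; they are handled
        # explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        if welch:
            res = sps.ttest_ind(x, y, axis=1, equal_var=False)
            df = res.df
        else:
            res = sps.ttest_ind(x, y, axis=1, equal_var=True)
            df = np.full(x.shape[0], n1 + n2 - 2, dtype=float)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance: scipy yields nan; resolve by mean equality
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        diff = x.mean(axis=1) - y.mean(axis=1)
        equal = diff == 0
        t[degenerate & equal] = 0.0
        p[degenerate & equal] = 1.0
        shifted = degenerate & ~equal
        t[shifted] = np.sign(diff[shifted]) * np.inf
        p[shifted] = 0.0
    frame = pd.DataFrame({"t": t, "df": df, "p": p}, index=matrix.ratios.index)
    return TTestResult(frame=frame, log_transformed=log_transform, welch=welch)


def bh_qvalues(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up q-values."""
    q = sps.false_discovery_control(p.to_numpy(), method="bh")
    return pd.Series(q, index=p.index, name="q")


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components
    variance_fraction: np.ndarray
    scaling: str


def pca(matrix: RatioMatrix, scaling: str = "autoscale", n_components: int | None = None) -> PCAResult:
    """PCA of samples over log2 ratios.

    ``scaling="center"`` mean-centers each metabolite; ``"autoscale"``
    additionally divides by its standard deviation (constant metabolites are
    dropped first).  Components are the right singular vectors of the scaled
    samples x metabolites matrix; each loading vector's sign is fixed so its
    largest-magnitude entry is positive.
    """
    if scaling not in ("center", "autoscale"):
        raise ValueError(f"unknown scaling {scaling!r}")
    data = np.log2(matrix.ratios.to_numpy(dtype=float)).T  # samples x metabolites
    samples = list(matrix.ratios.columns)
    rows = np.asarray(matrix.ratios.index)
    if data.shape[0] < 3:
        raise ValueError("need >= 3 samples for PCA")
    data = data - data.mean(axis=0)
    if scaling == "autoscale":
        sd = data.std(axis=0, ddof=1)
        keep = sd > 0
        data, rows = data[:, keep] / sd[keep], rows[keep]
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = rank if n_components is None else min(n_components, rank)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|.| loading entry positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    var = s**2
    var_frac = var / (data.var(axis=0, ddof=0).sum() * data.shape[0])
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=samples, columns=comp),
        loadings=pd.DataFrame(vt.T, index=rows, columns=comp),
        variance_fraction=var_frac,
        scaling=scaling,
    )


# ---------------------------------------------------------------------------
# random forest


@dataclass
class RFResult:
    oob_error: float
    oob_votes: pd.DataFrame  # samples x classes, vote fractions
    proximity: pd.DataFrame  # samples x samples
    mds_coords: pd.DataFrame  # samples x 2
    mda: pd.Series  # per-metabolite mean decrease accuracy
    n_trees: int
    seed: int


def _classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson double-centering MDS of a distance matrix."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    w, v = np.clip(w[order], 0, None), v[:, order]
    coords = v * np.sqrt(w)
    # deterministic orientation
    for c in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, c])))
        if coords[i, c] < 0:
            coords[:, c] *= -1
    return coords


def random_forest_mda(
    matrix: RatioMatrix,
    n_trees: int = 500,
    seed: int = 0,
) -> RFResult:
    """Random-forest classification of treatment vs control.

    A forest of ``n_trees`` gini trees (bootstrap per tree, sqrt(m) features
    per split) is grown on log2 ratios.  From its out-of-bag bookkeeping:

    * ``oob_error`` — error of the majority OOB vote per sample;
    * ``mda`` — for each metabolite, the mean over trees of (OOB accuracy
      minus OOB accuracy after permuting that metabolite's values among the
      tree's OOB samples), the permutation operationalization of mean
      decrease accuracy;
    * ``proximity`` — fraction of trees placing two samples in the same
      terminal node, embedded in 2-D by classical MDS on 1 - proximity.
    """
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    x = np.log2(matrix.ratios.to_numpy(dtype=float)).T  # samples x metabolites
    y = np.array([matrix.groups[s] for s in matrix.ratios.columns])
    samples = list(matrix.ratios.columns)
    row_ids = list(matrix.ratios.index)
    n, m = x.shape
    if min(np.sum(y == c) for c in np.unique(y)) < 3:
        raise ValueError("need >= 3 samples per group")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        criterion="gini",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    ).fit(x, y)
    classes = list(forest.classes_)
    y_enc = np.array([classes.index(v) for v in y])  # trees predict class indices

    # OOB votes and error
    votes = np.zeros((n, len(classes)))
    mda_sum = np.zeros(m)
    rng = np.random.default_rng(seed)
    for tree, bag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), bag)
        if oob.size == 0:
            continue
        pred = tree.predict(x[oob]).astype(int)
        for i, cls_idx in zip(oob, pred):
            votes[i, cls_idx] += 1
        acc = float(np.mean(pred == y_enc[oob]))
        for jf in range(m):
            xp = x[oob].copy()
            xp[:, jf] = xp[rng.permutation(oob.size), jf]
            acc_p = float(np.mean(tree.predict(xp).astype(int) == y_enc[oob]))
            mda_sum[jf] += acc - acc_p
    voted = votes.sum(axis=1) > 0
    oob_pred = np.argmax(votes, axis=1)
    oob_error = float(np.mean(oob_pred[voted] != y_enc[voted]))

    # proximity over all trees
    leaves = forest.apply(x)  # samples x trees
    prox = (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)
    np.fill_diagonal(prox, 1.0)
    coords = _classical_mds(1.0 - prox, k=2)

    vote_frac = votes / np.maximum(votes.sum(axis=1, keepdims=True), 1)
    return RFResult(
        oob_error=oob_error,
        oob_votes=pd.DataFrame(vote_frac, index=samples, columns=classes),
        proximity=pd.DataFrame(prox, index=samples, columns=samples),
        mds_coords=pd.DataFrame(coords, index=samples, columns=["MDS1", "MDS2"]),
        mda=pd.Series(mda_sum / n_trees, index=row_ids, name="mda"),
        n_trees=n_trees,
        seed=seed,
    )


def top_importance(rf: RFResult, k: int, log2fc: pd.Series | None = None) -> pd.DataFrame:
    """The k metabolites with highest MDA, ties broken by row_id.

    When per-row log2 fold changes are supplied, each metabolite is
    annotated with its direction of change (increase/decrease under
    treatment), mirroring the colored variable-importance plot convention.
    """
    if k > len(rf.mda):
        raise ValueError("k exceeds number of metabolites")
    order = rf.mda.to_frame().assign(row_id=rf.mda.index)
    order = order.sort_values(["mda", "row_id"], ascending=[False, True]).head(k)
    out = order[["mda"]].copy()
    if log2fc is not None:
        out["direction"] = np.where(log2fc.reindex(out.index) >= 0, "increase", "decrease")
    return out
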