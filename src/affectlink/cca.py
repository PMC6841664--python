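"""Cross-modal canonical correlation analysis and behaviour correlation.

Given two standardized cue matrices X (n x p) and Y (n x q), CCA finds
weight pairs (a_k, b_k) maximizing corr(X a_k, Y b_k) subject to the
variate pairs of different components being uncorrelated.  We solve the
(optionally ridge-regularized) problem through the whitened
cross-covariance SVD:

    K = (Cxx + r I)^{-1/2} Cxy (Cyy + r I)^{-1/2} = U S V^T,

with canonical correlations S and weights (Cxx + r I)^{-1/2} U etc.
Structure correlations ("loadings") — the correlation of each original
feature with a canonical variate — are reported alongside the weights,
because feature attribution in this package is loading-based.

The behaviour analysis projects trials onto the first canonical variate
of each side and computes Pearson correlations with valence/arousal,
a class-mean linear model against the 12-way emotion tags, and
paired-sample t-tests between per-subject band coefficients.

Statistical caveat: the analysis windows overlap heavily (15 s windows,
1 s hop), so rows are strongly dependent and nominal p-values are
optimistic; ``block_permutation_pvalue`` permutes at the clip level as
the honest alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CCAResult",
    "standardize",
    "cca_fit",
    "top_loadings",
    "loading_weight_share",
    "project_and_correlate",
    "regress_emotions",
    "paired_band_ttest",
    "fit_per_subject",
    "aggregate_loadings",
    "block_permutation_pvalue",
]

log = logging.getLogger(__name__)


@dataclass
class CCAResult:
    weights_x: np.ndarray            # (p, k)
    weights_y: np.ndarray            # (q, k)
    canonical_correlations: np.ndarray  # (k,) decreasing, in [0, 1]
    loadings_x: np.ndarray           # (p, k) structure correlations
    loadings_y: np.ndarray           # (q, k)
    x_names: list[str]
    y_names: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray

    def variates(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Canonical variate scores for (possibly new) data rows."""
        return ((np.asarray(x) - self.x_mean) @ self.weights_x,
                (np.asarray(y) - self.y_mean) @ self.weights_y)


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

def standardize(m: np.ndarray, names: list[str] | None = None,
                ) -> tuple[np.ndarray, list[str]]:
    """Column-wise z-scoring; constant columns are dropped with a warning.

    Returns the standardized matrix and the names of the surviving
    columns (positional names are generated when none are given).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if names is None:
        names = [f"col{i}" for i in range(m.shape[1])]
    sd = m.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        log.warning("dropping constant columns: %s", dropped)
    z = (m[:, keep] - m[:, keep].mean(axis=0)) / sd[keep]
    return z, [n for n, k in zip(names, keep) if k]


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _inv_sqrt(c: np.ndarray, ridge: float) -> np.ndarray:
    c = c + ridge * np.eye(c.shape[0])
    evals, vecs = np.linalg.eigh(c)
    tol = 1e-10 * max(float(evals.max()), 1.0)
    if evals.min() < tol:
        raise np.linalg.LinAlgError(
            "covariance is rank-deficient; pass a positive ridge")
    return vecs @ np.diag(1.0 / np.sqrt(evals)) @ vecs.T


def cca_fit(x: np.ndarray, y: np.ndarray, n_components: int | None = None,
            ridge: float = 1e-3, x_names: list[str] | None = None,
            y_names: list[str] | None = None) -> CCAResult:
    """Fit (regularized) CCA between two row-aligned cue matrices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal row counts")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    n, p = x.shape
    q = y.shape[1]
    k = min(p, q) if n_components is None else n_components
    if k > min(p, q):
        raise ValueError("n_components exceeds min(p, q)")
    x_names = x_names or [f"x{i}" for i in range(p)]
    y_names = y_names or [f"y{i}" for i in range(q)]

    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    yc = y - y_mean
    cxx = xc.T @ xc / (n - 1)
    cyy = yc.T @ yc / (n - 1)
    cxy = xc.T @ yc / (n - 1)

    wxx = _inv_sqrt(cxx, ridge)
    wyy = _inv_sqrt(cyy, ridge)
    u, s, vt = np.linalg.svd(wxx @ cxy @ wyy)
    wx = (wxx @ u)[:, :k]
    wy = (wyy @ vt.T)[:, :k]
    corrs = np.clip(s[:k], 0.0, 1.0)

    def _loadings(mat: np.ndarray, scores: np.ndarray) -> np.ndarray:
        ms = mat.std(axis=0)
        ss = scores.std(axis=0)
        cov = mat.T @ (scores - scores.mean(axis=0)) / n
        denom = np.outer(np.maximum(ms, 1e-300), np.maximum(ss, 1e-300))
        return cov / denom

    ux = xc @ wx
    uy = yc @ wy
    return CCAResult(weights_x=wx, weights_y=wy, canonical_correlations=corrs,
                     loadings_x=_loadings(xc, ux), loadings_y=_loadings(yc, uy),
                     x_names=list(x_names), y_names=list(y_names),
                     x_mean=x_mean, y_mean=y_mean)


def fit_per_subject(x: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                    **kwargs) -> dict[int, CCAResult]:
    """Fit one CCA per subject (the default grouping)."""
    subjects = np.asarray(subjects)
    return {int(s): cca_fit(x[subjects == s], y[subjects == s], **kwargs)
            for s in np.unique(subjects)}


def aggregate_loadings(results: dict[int, CCAResult], side: str = "x",
                       component: int = 0) -> np.ndarray:
    """Across-subject mean absolute loading on one component."""
    mats = [np.abs(getattr(r, f"loadings_{side}")[:, component])
            for r in results.values()]
    return np.mean(mats, axis=0)


# --------------------------------------------------------------------------
# inspection
# --------------------------------------------------------------------------

def top_loadings(res: CCAResult, side: str = "x", k: int = 3,
                 component: int = 0) -> list[tuple[str, float]]:
    """Features ranked by |loading| on one component; frozen-order ties."""
    names = res.x_names if side == "x" else res.y_names
    load = (res.loadings_x if side == "x" else res.loadings_y)[:, component]
    if k > len(names):
        raise ValueError("k exceeds the feature count")
    order = np.argsort(-np.abs(load), kind="stable")  # stable => column-order ties
    return [(names[i], float(load[i])) for i in order[:k]]


def loading_weight_share(res: CCAResult, side: str = "x", k: int = 5,
                         component: int = 0) -> float:
    """Share of total |loading| carried by the top-k features, in [0, 1]."""
    load = np.abs((res.loadings_x if side == "x" else res.loadings_y)[:, component])
    total = load.sum()
    if total == 0:
        return 0.0
    return float(np.sort(load)[::-1][:k].sum() / total)


# --------------------------------------------------------------------------
# behaviour correlation
# --------------------------------------------------------------------------

def project_and_correlate(res: CCAResult, x: np.ndarray, y: np.ndarray,
                          valence: np.ndarray, arousal: np.ndarray) -> dict:
    """Pearson r between first-component variates and valence/arousal.

    For each side also reports the original cue maximizing
    |corr(cue, variate)| * |corr(variate, label)| — the cue through
    which the canonical component best explains that label.
    """
    ux, uy = res.variates(x, y)
    out: dict = {}
    for side, scores, names, loadings in (
            ("x", ux[:, 0], res.x_names, res.loadings_x[:, 0]),
            ("y", uy[:, 0], res.y_names, res.loadings_y[:, 0])):
        if scores.std() == 0:
            raise ValueError("zero-variance canonical variate")
        side_out = {}
        for label_name, lab in (("valence", valence), ("arousal", arousal)):
            r, p = stats.pearsonr(scores, np.asarray(lab, dtype=float))
            best = int(np.argmax(np.abs(loadings) * abs(r)))
            side_out[label_name] = {"r": float(r), "p": float(p),
                                    "best_cue": names[best]}
        out[side] = side_out
    return out


def regress_emotions(scores: np.ndarray, emotions: np.ndarray,
                     min_per_class: int = 2) -> dict:
    """Class-mean linear model of the variate on emotion tags.

    One-hot regression with intercept = grand mean; each class
    coefficient is the class-mean deviation from it, weighted by class
    frequency the coefficients sum to zero.  Classes with fewer than
    ``min_per_class`` trials are excluded (logged).  Returns the
    largest-|coefficient| class and the full coefficient table.
    """
    scores = np.asarray(scores, dtype=float)
    emotions = np.asarray(emotions)
    classes, counts = np.unique(emotions, return_counts=True)
    kept = classes[counts >= min_per_class]
    if len(kept) < 2:
        raise ValueError("need at least two emotion classes with enough trials")
    dropped = set(classes) - set(kept)
    if dropped:
        log.warning("excluding sparse emotion classes: %s", sorted(dropped))
    sel = np.isin(emotions, kept)
    scores, emotions = scores[sel], emotions[sel]
    grand = scores.mean()
    coefs = {str(c): float(scores[emotions == c].mean() - grand) for c in kept}
    best = max(coefs, key=lambda c: abs(coefs[c]))
    return {"intercept": float(grand), "coefficients": coefs,
            "max_class": best, "max_coefficient": coefs[best]}


def paired_band_ttest(coefs: np.ndarray, band_a: int, band_b: int,
                      ) -> tuple[float, float]:
    """Paired-sample t-test between two band columns of a subject x band table.

    Zero-variance differences use the documented sentinel: t = 0, p = 1
    when the mean difference is also zero, otherwise t = +/-inf, p = 0.
    """
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape[0] < 3:
        raise ValueError("need >= 3 subjects for a paired test")
    d = coefs[:, band_a] - coefs[:, band_b]
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(coefs[:, band_a], coefs[:, band_b])
    return float(t), float(p)


def block_permutation_pvalue(scores: np.ndarray, labels: np.ndarray,
                             blocks: np.ndarray, n_perm: int = 999,
                             seed: int = 0) -> float:
    """Clip-level permutation p-value for corr(variate, label).

    Labels are shuffled jointly within entire blocks (all windows of a
    clip keep their label together), respecting the sliding-window
    dependence that nominal p-values ignore.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    blocks = np.asarray(blocks)
    uniq = np.unique(blocks)
    block_label = {b: labels[blocks == b][0] for b in uniq}
    obs = abs(stats.pearsonr(scores, labels)[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation([block_label[b] for b in uniq])
        lab = np.empty_like(labels)
        for b, v in zip(uniq, perm):
            lab[blocks == b] = v
        if lab.std() == 0:
            continue
        if abs(stats.pearsonr(scores, lab)[0]) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
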