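"""Axis-model encoding in the feature principal subspace.

Each cell's preferred axis is the direction in the 50-component feature space
whose 1-D linear projection captures the largest fraction of its response
variance. That direction is the normalized ordinary-least-squares coefficient
vector of the per-image mean response on the principal-component scores; it
is estimated with 10-fold cross-validation over images, the ten fold axes are
sign-aligned and averaged into the overall preferred axis, and every image's
projection is computed exactly once from a fold whose fit excluded it.

Split-half reliability bounds what any model can explain: responses are split
into two repeat halves, per-image half-means are correlated across images,
and the Spearman-Brown formula 2*rho/(1+rho) converts the half correlation
into the explainable variance fraction (clamped to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "SplitHalfReliability",
    "PreferredAxis",
    "TuningCurve1D",
    "LayerEncodingProfile",
    "explainable_variance",
    "fit_preferred_axis",
    "principal_orthogonal_axis",
    "tuning_curve",
    "layer_encoding_profile",
    "rescale_projections",
]


@dataclass
class SplitHalfReliability:
    unit_id: int
    rho: float
    explainable: float  # 2*rho/(1+rho), clamped to [0, 1]
    raw_explainable: float  # before clamping, for audit
    clamped: bool


@dataclass
class PreferredAxis:
    unit_id: int
    fold_axes: np.ndarray  # (n_folds, n_pcs), unit rows
    axis: np.ndarray  # unit vector
    cv_projections: np.ndarray  # held-out projection per image
    ev_cv: float  # cross-validated fraction of response variance explained


@dataclass
class TuningCurve1D:
    unit_id: int
    axis_kind: str  # "preferred" | "principal_orthogonal"
    bin_edges: np.ndarray
    bin_means: np.ndarray  # NaN for empty bins
    bin_counts: np.ndarray


@dataclass
class LayerEncodingProfile:
    area: str
    layer_names: list[str]
    summed_ev: np.ndarray  # per layer, sum of cross-validated EV over cells
    summed_explainable: float
    best_layer: np.ndarray  # per cell, index into layer_names

    @property
    def normalized(self) -> np.ndarray:
        return self.summed_ev / self.summed_explainable


def explainable_variance(
    tensor: np.ndarray, unit_ids: np.ndarray | None = None, split_rule: str = "odd_even",
    seed: int = 0,
) -> list[SplitHalfReliability]:
    """Split-half explainable variance for every unit of a response tensor.

    ``tensor`` is (units, images, repeats) with >= 2 repeats. The default
    deterministic split assigns odd and even repeat indices to the two
    halves; ``split_rule='random'`` shuffles repeats first (seeded).
    Constant half-means leave rho undefined (NaN).
    """
    tensor = np.asarray(tensor, dtype=float)
    n_units, n_images, n_repeats = tensor.shape
    if n_repeats < 2:
        raise ValueError("need >= 2 repeats per image")
    idx = np.arange(n_repeats)
    if split_rule == "random":
        idx = np.random.default_rng(seed).permutation(idx)
    elif split_rule != "odd_even":
        raise ValueError(f"unknown split_rule {split_rule!r}")
    half_a = tensor[:, :, idx[0::2]].mean(axis=2)
    half_b = tensor[:, :, idx[1::2]].mean(axis=2)
    if unit_ids is None:
        unit_ids = np.arange(n_units)
    out = []
    for i in range(n_units):
        a, b = half_a[i], half_b[i]
        if a.std() == 0 or b.std() == 0:
            out.append(SplitHalfReliability(int(unit_ids[i]), float("nan"), float("nan"),
                                            float("nan"), False))
            continue
        rho = float(np.corrcoef(a, b)[0, 1])
        raw = 2.0 * rho / (1.0 + rho) if rho > -1.0 else float("-inf")
        clamped = raw < 0.0 or raw > 1.0
        out.append(
            SplitHalfReliability(
                int(unit_ids[i]), rho, float(np.clip(raw, 0.0, 1.0)), float(raw), clamped
            )
        )
    return out


def _ols_axis(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normalized OLS coefficient vector of y on centred x (with intercept)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    gram = xc.T @ xc
    try:
        beta = np.linalg.solve(gram, xc.T @ yc)
    except np.linalg.LinAlgError:
        # rank-deficient design: small ridge fallback
        beta = np.linalg.solve(gram + 1e-6 * np.trace(gram) * np.eye(gram.shape[0]), xc.T @ yc)
    norm = np.linalg.norm(beta)
    return beta / norm if norm > 0 else beta


def fit_preferred_axis(
    responses: np.ndarray,
    pc_scores: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    unit_id: int = -1,
) -> PreferredAxis:
    """Cross-validated preferred-axis estimate for one cell.

    ``responses`` are per-image mean responses; ``pc_scores`` is the
    (n_images, n_pcs) score matrix (kept in eigenvalue scale, not whitened).
    Folds are a seeded shuffle-split over images. Fold axes are sign-aligned
    to the first fold (ties toward a positive first coordinate) before
    averaging and renormalising. ``ev_cv`` is the squared Pearson correlation
    between held-out projections and responses.
    """
    y = np.asarray(responses, dtype=float)
    x = np.asarray(pc_scores, dtype=float)
    n_images = x.shape[0]
    if n_images < 100:
        raise ValueError("need >= 100 images to fit a preferred axis")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_axes = []
    cv_proj = np.empty(n_images)
    for train, test in kf.split(x):
        axis = _ols_axis(x[train], y[train])
        fold_axes.append(axis)
        cv_proj[test] = x[test] @ axis
    fold_axes = np.asarray(fold_axes)
    ref = fold_axes[0]
    if np.all(ref == 0):
        ref = np.eye(fold_axes.shape[1])[0]
    signs = np.array([np.sign(a @ ref) or np.sign(a[0]) or 1.0 for a in fold_axes])
    mean_axis = (fold_axes * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(mean_axis)
    axis = mean_axis / norm if norm > 0 else mean_axis
    if y.std() == 0 or cv_proj.std() == 0:
        ev = 0.0
    else:
        ev = float(np.corrcoef(cv_proj, y)[0, 1] ** 2)
    return PreferredAxis(
        unit_id=unit_id, fold_axes=fold_axes, axis=axis, cv_projections=cv_proj, ev_cv=ev
    )


def principal_orthogonal_axis(axis: np.ndarray) -> np.ndarray:
    """First-PC direction projected onto the hyperplane orthogonal to ``axis``.

    If the preferred axis is (numerically) parallel to the first principal
    component, the construction falls back to the second component.
    """
    a = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-6):
        raise ValueError("axis must be a unit vector")
    for k in range(2):
        e = np.zeros_like(a)
        e[k] = 1.0
        o = e - (e @ a) * a
        norm = np.linalg.norm(o)
        if norm > 1e-8:
            return o / norm
    raise ValueError("axis is parallel to both of the first two principal components")


def rescale_projections(projections: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map the 1st/99th projection percentiles onto [-1, +1].

    Uses nearest-rank percentiles so that the inner range contains 98% of
    the stimuli up to the discreteness of the sample. Returns the rescaled
    projections and the (low, high) anchors.
    """
    p = np.asarray(projections, dtype=float)
    # nearest-rank anchors chosen so the closed interval [lo, hi] holds 98%
    # of the sample as exactly as the discreteness allows
    lo = np.quantile(p, 0.01, method="higher")
    hi = np.quantile(p, 0.99, method="lower")
    if hi == lo:
        return np.zeros_like(p), float(lo), float(hi)
    return 2.0 * (p - lo) / (hi - lo) - 1.0, float(lo), float(hi)


def tuning_curve(
    responses: np.ndarray,
    projections: np.ndarray,
    axis_kind: str = "preferred",
    n_bins: int = 16,
    unit_id: int = -1,
) -> TuningCurve1D:
    """Binned mean response along a rescaled axis projection.

    Equal-width bins over [-1, 1] after percentile rescaling; images falling
    outside the anchors land in the edge bins' exterior and are kept in the
    outermost bins. Empty bins are NaN, not zero.
    """
    y = np.asarray(responses, dtype=float)
    scaled, _, _ = rescale_projections(projections)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scaled, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = y[sel].mean()
    return TuningCurve1D(
        unit_id=unit_id, axis_kind=axis_kind, bin_edges=edges, bin_means=means, bin_counts=counts
    )


def layer_encoding_profile(
    per_image_responses: np.ndarray,
    feature_banks: dict[str, "object"],
    explainable: np.ndarray,
    area: str = "",
    n_folds: int = 10,
    seed: int = 0,
) -> LayerEncodingProfile:
    """Compare how well each extractor layer's principal subspace encodes an area.

    ``per_image_responses`` is (n_cells, n_images); ``feature_banks`` maps
    layer name to a bank with ``pc_scores`` over the same image set;
    ``explainable`` is the per-cell explainable variance. Per cell and layer
    the cross-validated EV comes from :func:`fit_preferred_axis`; the area
    profile is the cell-summed EV per layer normalized by the cell-summed
    explainable variance, and ``best_layer`` is each cell's argmax layer.
    """
    resp = np.asarray(per_image_responses, dtype=float)
    layer_names = list(feature_banks)
    n_cells = resp.shape[0]
    ev = np.zeros((n_cells, len(layer_names)))
    for j, name in enumerate(layer_names):
        scores = feature_banks[name].pc_scores
        for i in range(n_cells):
            ev[i, j] = fit_preferred_axis(resp[i], scores, n_folds=n_folds, seed=seed).ev_cv
    return LayerEncodingProfile(
        area=area,
        layer_names=layer_names,
        summed_ev=ev.sum(axis=0),
        summed_explainable=float(np.nansum(np.asarray(explainable, dtype=float))),
        best_layer=np.argmax(ev, axis=1),
    )
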