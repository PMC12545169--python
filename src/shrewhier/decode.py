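"""Population decoding of feature principal components and image reconstruction.

Decoding regresses individual feature principal components on the responses
of repeatedly subsampled 100-cell populations, scoring the cross-validated
fraction of each component's variance explained. Reconstruction maps a
decoded 50-component vector back to the full feature space through the
(orthonormal-basis) pseudoinverse, then retrieves the nearest image from an
auxiliary bank that was never shown. Accuracy is summarised by the
normalized decoding distance

    |v_recon - v_original| / |v_best - v_original|,

where v_best is the feature vector of the auxiliary image closest to the
original: a value of 1 means the retrieval is as good as the auxiliary bank
allows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "PCDecodingResult",
    "ReconstructionRecord",
    "decode_pcs",
    "reconstruct_feature_vector",
    "nearest_auxiliary",
    "normalized_decoding_distance",
    "decode_feature_vectors",
    "area_reconstruction_summary",
]


@dataclass
class PCDecodingResult:
    area: str
    pc_index: int
    fraction_explained: float  # mean over resamples of held-out R^2
    resample_sd: float
    n_cells_sampled: int
    n_resamples: int


@dataclass
class ReconstructionRecord:
    image_id: int
    v_original: np.ndarray
    v_recon: np.ndarray
    v_best: np.ndarray
    chosen_auxiliary_id: int  # nearest auxiliary to v_recon (the reconstruction shown)
    best_auxiliary_id: int  # nearest auxiliary to v_original (the denominator)

    @property
    def normalized_distance(self) -> float:
        return normalized_decoding_distance(self)


def _cv_r2_columns(x: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Held-out R^2 of OLS predictions for each column of y, clipped at 1 above."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train, test in kf.split(x):
        model = LinearRegression().fit(x[train], y[train])
        pred[test] = model.predict(x[test])
    ss_res = ((y - pred) ** 2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return np.where(ss_tot > 0, r2, np.nan)


def decode_pcs(
    responses: np.ndarray,
    pc_scores: np.ndarray,
    n_cells: int = 100,
    n_resamples: int = 20,
    n_folds: int = 10,
    seed: int = 0,
    area: str = "",
) -> list[PCDecodingResult]:
    """Fraction of each principal component's variance decodable from an area.

    ``responses`` is (n_images, n_total_cells) per-image mean responses;
    per resample, ``n_cells`` cells are drawn without replacement and every
    PC is regressed on the sampled response matrix with ``n_folds``-fold
    cross-validation. Negative held-out R^2 is reported raw; values cannot
    exceed 1 by construction.
    """
    resp = np.asarray(responses, dtype=float)
    scores = np.asarray(pc_scores, dtype=float)
    n_images, n_total = resp.shape
    if n_cells > n_total:
        raise ValueError(
            f"n_cells={n_cells} exceeds the {n_total} cells available; "
            f"use n_cells <= {n_total}"
        )
    if n_images < 2 * n_cells:
        warnings.warn(
            f"only {n_images} images for {n_cells} regressors; "
            "cross-validated estimates will be noisy"
        )
    rng = np.random.default_rng(seed)
    n_pcs = scores.shape[1]
    r2 = np.empty((n_resamples, n_pcs))
    for s in range(n_resamples):
        cells = rng.choice(n_total, size=n_cells, replace=False)
        r2[s] = _cv_r2_columns(resp[:, cells], scores, n_folds, seed=int(rng.integers(2**31)))
    return [
        PCDecodingResult(
            area=area,
            pc_index=j,
            fraction_explained=float(np.nanmean(r2[:, j])),
            resample_sd=float(np.nanstd(r2[:, j])),
            n_cells_sampled=n_cells,
            n_resamples=n_resamples,
        )
        for j in range(n_pcs)
    ]


def reconstruct_feature_vector(
    decoded_scores: np.ndarray, pc_basis: np.ndarray, pc_mean: np.ndarray
) -> np.ndarray:
    """Map decoded principal-component scores back to full feature space.

    For an orthonormal projection the Moore-Penrose pseudoinverse is the
    transpose, so the reconstruction is ``pc_mean + pc_basis @ scores``.
    """
    y = np.asarray(decoded_scores, dtype=float)
    basis = np.asarray(pc_basis, dtype=float)
    if y.shape[-1] != basis.shape[1]:
        raise ValueError(f"decoded vector has {y.shape[-1]} components, basis expects {basis.shape[1]}")
    return np.asarray(pc_mean, dtype=float) + y @ basis.T


def nearest_auxiliary(v: np.ndarray, aux_features: np.ndarray, aux_ids: np.ndarray) -> int:
    """Auxiliary image id with the smallest Euclidean distance to ``v``.

    Exhaustive scan; ties broken toward the lowest image id.
    """
    v = np.asarray(v, dtype=float)
    aux = np.asarray(aux_features, dtype=float)
    d2 = ((aux - v) ** 2).sum(axis=1)
    order = np.argsort(np.asarray(aux_ids))
    best = order[np.argmin(d2[order])]  # scan in id order so ties pick the lowest id
    return int(np.asarray(aux_ids)[best])


def normalized_decoding_distance(record: ReconstructionRecord) -> float:
    """Reconstruction error relative to the best achievable retrieval."""
    denom = np.linalg.norm(record.v_best - record.v_original)
    if denom == 0:
        raise ValueError(
            "v_best coincides with v_original: the auxiliary bank must be "
            "disjoint from the presented images"
        )
    return float(np.linalg.norm(record.v_recon - record.v_original) / denom)


def decode_feature_vectors(
    responses: np.ndarray,
    pc_scores: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated decoded PC scores for every image (n_images, n_pcs).

    Each image's scores are predicted by OLS models trained on folds that
    exclude it; this is the decoding stage feeding reconstruction.
    """
    resp = np.asarray(responses, dtype=float)
    scores = np.asarray(pc_scores, dtype=float)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(scores)
    for train, test in kf.split(resp):
        model = LinearRegression().fit(resp[train], scores[train])
        pred[test] = model.predict(resp[test])
    return pred


def area_reconstruction_summary(
    responses: np.ndarray,
    image_ids: np.ndarray,
    feature_bank,
    aux_features: np.ndarray,
    aux_ids: np.ndarray,
    n_cells: int = 100,
    n_folds: int = 10,
    seed: int = 0,
    area: str = "",
) -> tuple[float, float, list[ReconstructionRecord]]:
    """Mean normalized decoding distance for one area.

    Subsamples ``n_cells`` cells (matched across areas), decodes every
    image's 50 feature components with cross-validation, reconstructs full
    feature vectors and scores each against the best possible auxiliary
    retrieval. Returns (mean, SD, records).
    """
    resp = np.asarray(responses, dtype=float)
    n_images, n_total = resp.shape
    if n_images < 50:
        raise ValueError("need >= 50 images for a reconstruction summary")
    rng = np.random.default_rng(seed)
    if n_cells < n_total:
        cells = rng.choice(n_total, size=n_cells, replace=False)
        resp = resp[:, cells]
    decoded = decode_feature_vectors(resp, feature_bank.pc_scores, n_folds=n_folds,
                                     seed=int(rng.integers(2**31)))
    records = []
    aux = np.asarray(aux_features, dtype=float)
    aux_ids = np.asarray(aux_ids)
    for i in range(n_images):
        v_orig = feature_bank.features[i]
        v_recon = reconstruct_feature_vector(decoded[i], feature_bank.pc_basis, feature_bank.pc_mean)
        best_id = nearest_auxiliary(v_orig, aux, aux_ids)
        chosen_id = nearest_auxiliary(v_recon, aux, aux_ids)
        v_best = aux[np.flatnonzero(aux_ids == best_id)[0]]
        records.append(
            ReconstructionRecord(
                image_id=int(image_ids[i]),
                v_original=v_orig,
                v_recon=v_recon,
                v_best=v_best,
                chosen_auxiliary_id=chosen_id,
                best_auxiliary_id=best_id,
            )
        )
    dists = np.array([r.normalized_distance for r in records])
    return float(dists.mean()), float(dists.std()), records
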