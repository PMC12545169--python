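"""Face selectivity, identity decoding, view invariance and low-level controls.

Face selectivity is scored per cell with a Welch t statistic between its
per-image mean responses to faces and to all other images, together with the
face-selectivity index FSI = (mu_face - mu_nonface) / (mu_face + mu_nonface).
Cells with t > 5 are "face cells"; t >= 15 marks highly selective cells.

Identity decoding uses Gaussian naive Bayes: per class (image), each neuron's
response is modelled as an independent Gaussian (variance floored at 1e-6);
classifiers are trained on all but one repeat and tested on the held-out
repeat, resampling both the neuron subset and the train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SelectivityScore",
    "IdentityDecodingCurve",
    "face_selectivity",
    "gnb_predict",
    "gnb_identity_decoding",
    "invariance_index",
]

FACE_CELL_T = 5.0
HIGHLY_SELECTIVE_T = 15.0
GNB_VARIANCE_FLOOR = 1e-6


@dataclass
class SelectivityScore:
    unit_id: int
    t_score: float
    fsi: float
    face_cell: bool  # t > 5
    highly_selective: bool  # t >= 15


@dataclass
class IdentityDecodingCurve:
    area: str
    stimulus_subset: str  # "faces" | "objects"
    n_cells_grid: np.ndarray
    accuracy: np.ndarray  # mean over resamples, per n_cells
    accuracy_sd: np.ndarray
    n_classes: int

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


def face_selectivity(
    image_means: np.ndarray, is_face: np.ndarray, unit_id: int = -1
) -> SelectivityScore:
    """Welch t score and FSI from per-image mean responses of one cell."""
    r = np.asarray(image_means, dtype=float)
    is_face = np.asarray(is_face, dtype=bool)
    if is_face.sum() < 5 or (~is_face).sum() < 5:
        raise ValueError("need >= 5 face and >= 5 non-face images")
    face, rest = r[is_face], r[~is_face]
    t, _ = stats.ttest_ind(face, rest, equal_var=False)
    mu_f, mu_o = face.mean(), rest.mean()
    fsi = float("nan") if mu_f + mu_o == 0 else (mu_f - mu_o) / (mu_f + mu_o)
    return SelectivityScore(
        unit_id=unit_id,
        t_score=float(t),
        fsi=float(fsi),
        face_cell=bool(t > FACE_CELL_T),
        highly_selective=bool(t >= HIGHLY_SELECTIVE_T),
    )


def gnb_predict(
    train: np.ndarray, test: np.ndarray, variance_floor: float = GNB_VARIANCE_FLOOR
) -> np.ndarray:
    """Gaussian-naive-Bayes class predictions.

    ``train`` is (n_classes, n_repeats_train, n_cells); ``test`` is
    (n_trials, n_cells). Classes have flat priors. Returns the predicted
    class index per test trial.
    """
    mu = train.mean(axis=1)  # (n_classes, n_cells)
    var = np.maximum(train.var(axis=1), variance_floor)
    # log-likelihood of each test trial under each class
    diff = test[:, None, :] - mu[None, :, :]
    ll = -0.5 * ((diff**2) / var[None] + np.log(2 * np.pi * var)[None]).sum(axis=2)
    return np.argmax(ll, axis=1)


def gnb_identity_decoding(
    tensor: np.ndarray,
    n_cells_grid: np.ndarray | list[int],
    n_neuron_resamples: int = 500,
    n_split_resamples: int = 200,
    n_images: int = 201,
    seed: int = 0,
    area: str = "",
    stimulus_subset: str = "objects",
    cell_pool: np.ndarray | None = None,
) -> IdentityDecodingCurve:
    """Identity-decoding accuracy as a function of population size.

    ``tensor`` is (units, images, repeats) evoked counts. Per resample a
    random image subset of size ``n_images`` defines the classes, a random
    neuron subset is drawn (from ``cell_pool`` if given, e.g. face cells
    only), one repeat is held out for testing, and accuracy is the fraction
    of held-out trials assigned to the correct image. The curve reports the
    mean over all neuron x split resamples; chance is 1/n_images.
    """
    tensor = np.asarray(tensor, dtype=float)
    n_units, n_total_images, n_repeats = tensor.shape
    n_images = min(n_images, n_total_images)
    rng = np.random.default_rng(seed)
    pool = np.arange(n_units) if cell_pool is None else np.asarray(cell_pool)
    n_cells_grid = np.asarray(n_cells_grid, dtype=int)
    acc = np.empty((len(n_cells_grid), n_neuron_resamples, n_split_resamples))
    for g, n_cells in enumerate(n_cells_grid):
        n_cells = min(n_cells, len(pool))
        for a in range(n_neuron_resamples):
            cells = rng.choice(pool, size=n_cells, replace=False)
            imgs = rng.choice(n_total_images, size=n_images, replace=False)
            sub = tensor[np.ix_(cells, imgs)]  # (cells, images, repeats)
            for b in range(n_split_resamples):
                held = rng.integers(n_repeats)
                train = np.delete(sub, held, axis=2).transpose(1, 2, 0)
                test = sub[:, :, held].T  # (images, cells)
                pred = gnb_predict(train, test)
                acc[g, a, b] = np.mean(pred == np.arange(n_images))
    return IdentityDecodingCurve(
        area=area,
        stimulus_subset=stimulus_subset,
        n_cells_grid=n_cells_grid,
        accuracy=acc.mean(axis=(1, 2)),
        accuracy_sd=acc.std(axis=(1, 2)),
        n_classes=int(n_images),
    )


def invariance_index(tensor: np.ndarray, frontal_index: int = 0) -> float:
    """Mean correlation between frontal and non-frontal population responses.

    ``tensor`` is (identities, views, units); for each identity the Pearson
    correlation between the frontal-view population vector and each
    non-frontal view is averaged over views, then over identities.
    Identities with a constant population vector are skipped.
    """
    tensor = np.asarray(tensor, dtype=float)
    n_ids, n_views, _ = tensor.shape
    if n_views < 2:
        raise ValueError("need a frontal view plus at least one non-frontal view")
    per_identity = []
    for i in range(n_ids):
        frontal = tensor[i, frontal_index]
        if frontal.std() == 0:
            continue
        cors = []
        for v in range(n_views):
            if v == frontal_index:
                continue
            other = tensor[i, v]
            if other.std() == 0:
                continue
            cors.append(np.corrcoef(frontal, other)[0, 1])
        if cors:
            per_identity.append(np.mean(cors))
    if not per_identity:
        raise ValueError("no identity had a non-constant population vector")
    return float(np.mean(per_identity))
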