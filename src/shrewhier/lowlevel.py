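"""Low-level image indices and the control analyses built on them.

Thirteen scalar indices summarise each image's low-level content (versioned
set v1): mean luminance, RMS contrast, Michelson contrast, foreground area,
perimeter, compactness, aspect ratio, centroid x, centroid y, spectral
centroid, spectral bandwidth, orientation anisotropy and edge density. The
controls quantify how much response variance such indices explain, both
globally and restricted to each cell's fitted receptive field, and evaluate
identity coding within spectral-content groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import filters, measure

from .receptive_fields import RFFit
from .tuning import VarianceDecomposition

__all__ = [
    "INDEX_NAMES",
    "INDEX_SET_VERSION",
    "lowlevel_indices",
    "index_variance_explained",
    "rf_windowed_luminance_contrast",
    "spectral_groups",
    "identity_variance_by_spectral_group",
]

INDEX_SET_VERSION = "v1"
INDEX_NAMES = (
    "mean_luminance",
    "rms_contrast",
    "michelson_contrast",
    "foreground_area",
    "perimeter",
    "compactness",
    "aspect_ratio",
    "centroid_x",
    "centroid_y",
    "spectral_centroid",
    "spectral_bandwidth",
    "orientation_anisotropy",
    "edge_density",
)


def _foreground_mask(img: np.ndarray) -> np.ndarray:
    # threshold against the grey background; Otsu fails on near-constant images
    if img.max() - img.min() < 1e-3:
        return np.zeros_like(img, dtype=bool)
    thr = filters.threshold_otsu(img)
    mask = img > thr
    if mask.mean() > 0.5:
        mask = ~mask
    return mask


def _spectral_stats(img: np.ndarray) -> tuple[float, float]:
    f = np.fft.fftshift(np.abs(np.fft.fft2(img - img.mean())))
    n = img.shape[0]
    fy, fx = np.meshgrid(np.fft.fftshift(np.fft.fftfreq(n)), np.fft.fftshift(np.fft.fftfreq(n)), indexing="ij")
    r = np.hypot(fx, fy)
    w = f / f.sum() if f.sum() > 0 else np.full_like(f, 1.0 / f.size)
    centroid = float((w * r).sum())
    bandwidth = float(np.sqrt((w * (r - centroid) ** 2).sum()))
    return centroid, bandwidth


def _orientation_anisotropy(img: np.ndarray) -> float:
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    if mag.sum() == 0:
        return 0.0
    ang = np.arctan2(gy, gx)
    # orientation (pi-periodic) resultant length, gradient-magnitude weighted
    c = (mag * np.cos(2 * ang)).sum()
    s = (mag * np.sin(2 * ang)).sum()
    return float(np.hypot(c, s) / mag.sum())


def lowlevel_indices(pixels: np.ndarray, image_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Compute the 13 low-level indices for every image of a (n, H, W) stack."""
    pixels = np.asarray(pixels, dtype=float)
    n, h, w = pixels.shape
    if image_ids is None:
        image_ids = np.arange(n)
    rows = []
    for img, img_id in zip(pixels, image_ids):
        mask = _foreground_mask(img)
        area = float(mask.mean())
        if mask.any():
            perim = float(measure.perimeter(mask)) / (h * w) ** 0.5
            ys, xs = np.nonzero(mask)
            cx, cy = float(xs.mean() / w), float(ys.mean() / h)
            hgt = np.ptp(ys) + 1
            wid = np.ptp(xs) + 1
            aspect = float(wid / hgt)
            compact = float(4 * np.pi * mask.sum() / max(measure.perimeter(mask), 1.0) ** 2)
        else:
            perim, cx, cy, aspect, compact = 0.0, 0.5, 0.5, 1.0, 0.0
        centroid, bandwidth = _spectral_stats(img)
        edges = filters.sobel(img)
        edge_density = float((edges > 0.1).mean())
        mx, mn = img.max(), img.min()
        rows.append(
            dict(
                image_id=int(img_id),
                mean_luminance=float(img.mean()),
                rms_contrast=float(img.std()),
                michelson_contrast=float((mx - mn) / (mx + mn)) if mx + mn > 0 else 0.0,
                foreground_area=area,
                perimeter=perim,
                compactness=compact,
                aspect_ratio=aspect,
                centroid_x=cx,
                centroid_y=cy,
                spectral_centroid=centroid,
                spectral_bandwidth=bandwidth,
                orientation_anisotropy=_orientation_anisotropy(img),
                edge_density=edge_density,
            )
        )
    df = pd.DataFrame(rows).set_index("image_id")
    df.attrs["index_set_version"] = INDEX_SET_VERSION
    return df


def index_variance_explained(
    image_means: np.ndarray, index_values: np.ndarray
) -> float:
    """Percent of a cell's per-image response variance explained by one index
    (simple linear regression, training fit)."""
    y = np.asarray(image_means, dtype=float)
    x = np.asarray(index_values, dtype=float)
    if y.std() == 0 or x.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(100.0 * r**2)


def rf_windowed_luminance_contrast(
    pixels: np.ndarray,
    rf_fit: RFFit,
    monitor_extent_deg: tuple[float, float] = (108.0, 76.0),
    image_extent_deg: float = 20.0,
    image_center: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Luminance and contrast inside a cell's receptive field, per image.

    Each image is assumed centred on the receptive field (stimuli were placed
    at the mapped centre) and to subtend ``image_extent_deg``; pixels are
    weighted by the fitted circular Gaussian evaluated on that patch.
    Returns a frame with ``rf_luminance`` and ``rf_contrast`` per image.
    """
    pixels = np.asarray(pixels, dtype=float)
    n, h, w = pixels.shape
    # degrees per pixel within the stimulus patch; RF sits at the patch centre
    xs = (np.arange(w) - (w - 1) / 2) * image_extent_deg / w
    ys = (np.arange(h) - (h - 1) / 2) * image_extent_deg / h
    xx, yy = np.meshgrid(xs, ys)
    wgt = np.exp(-(xx**2 + yy**2) / (2 * rf_fit.sigma**2))
    wgt = wgt / wgt.sum()
    lum = (pixels * wgt).sum(axis=(1, 2))
    var = ((pixels - lum[:, None, None]) ** 2 * wgt).sum(axis=(1, 2))
    return pd.DataFrame(dict(rf_luminance=lum, rf_contrast=np.sqrt(var)))


def spectral_groups(indices: pd.DataFrame, n_groups: int = 7) -> np.ndarray:
    """Partition images into spectral-centroid quantile groups of near-equal size.

    Returns a group label (0..n_groups-1) per image; group sizes differ by at
    most one.
    """
    centroid = indices["spectral_centroid"].to_numpy()
    order = np.argsort(centroid, kind="stable")
    labels = np.empty(len(centroid), dtype=int)
    splits = np.array_split(order, n_groups)
    for g, idx in enumerate(splits):
        labels[idx] = g
    return labels


def identity_variance_by_spectral_group(
    tensor: np.ndarray, group_labels: np.ndarray
) -> pd.DataFrame:
    """Area-scope identity variance within each spectral group.

    ``tensor`` is (units, images, repeats). Within each group, trial
    responses are decomposed by image identity and summed across cells.
    """
    tensor = np.asarray(tensor, dtype=float)
    n_units, n_images, n_repeats = tensor.shape
    rows = []
    for g in np.unique(group_labels):
        sel = np.flatnonzero(group_labels == g)
        v_tot = v_res = 0.0
        for u in range(n_units):
            r = tensor[u, sel, :].ravel()
            lab = np.repeat(sel, n_repeats)
            v_tot += r.var()
            means = tensor[u, sel, :].mean(axis=1)
            v_res += ((tensor[u, sel, :] - means[:, None]) ** 2).mean()
        pct = float("nan") if v_tot == 0 else 100.0 * (v_tot - v_res) / v_tot
        rows.append(dict(group=int(g), n_images=len(sel), pct_identity=pct))
    return pd.DataFrame(rows)
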