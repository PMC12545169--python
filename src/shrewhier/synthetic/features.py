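"""Pluggable image feature extraction with a principal-subspace summary.

The default extractor is a deterministic Gabor energy stack with a seeded
random readout — no trained network and no weights to download. "Layers"
differ by the spatial pooling window, which grows monotonically with depth,
mimicking the receptive-field growth of a deep network's stages. An external
DNN can be plugged in through the same interface when available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import ImageBank

__all__ = ["FeatureBank", "extract_features", "gabor_filter_bank", "available_extractors"]

DEFAULT_N_PCS = 50
DEFAULT_OUT_DIM = 4096


@dataclass
class FeatureBank:
    """Per-layer feature matrix with its 50-component principal subspace.

    ``pc_basis`` columns are orthonormal loadings; ``pc_scores`` are the
    centred features projected onto them:
    ``pc_scores = (features - pc_mean) @ pc_basis``.
    """

    layer_name: str
    image_ids: np.ndarray
    features: np.ndarray  # (n_images, D)
    pc_basis: np.ndarray  # (D, n_pcs)
    pc_mean: np.ndarray  # (D,)
    pc_scores: np.ndarray  # (n_images, n_pcs)

    @classmethod
    def from_features(
        cls, features: np.ndarray, image_ids: np.ndarray, layer_name: str, n_pcs: int = DEFAULT_N_PCS
    ) -> "FeatureBank":
        """Build the principal-subspace summary with an SVD (deterministic)."""
        x = np.asarray(features, dtype=float)
        n, d = x.shape
        if n_pcs > min(n - 1, d):
            raise ValueError(f"n_pcs={n_pcs} too large for a {n} x {d} feature matrix")
        mean = x.mean(axis=0)
        xc = x - mean
        # economy SVD; fix signs so the result is reproducible across runs
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        signs = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
        vt = vt * signs[:, None]
        basis = vt[:n_pcs].T
        scores = xc @ basis
        return cls(
            layer_name=layer_name,
            image_ids=np.asarray(image_ids, dtype=int),
            features=x,
            pc_basis=basis,
            pc_mean=mean,
            pc_scores=scores,
        )

    @property
    def n_pcs(self) -> int:
        return self.pc_basis.shape[1]


def gabor_filter_bank(
    size: int, n_orientations: int = 4, frequencies: tuple[float, ...] = (0.12, 0.25)
) -> np.ndarray:
    """Fourier-domain complex Gabor transfer functions, (n_filters, size, size)."""
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    filters = []
    for f0 in frequencies:
        for k in range(n_orientations):
            theta = k * np.pi / n_orientations
            # Gaussian in the frequency domain centred on (f0, theta);
            # one-sided, so the spatial filter is complex (quadrature pair)
            cx, cy = f0 * np.cos(theta), f0 * np.sin(theta)
            sigma = 0.4 * f0
            g = np.exp(-((fx - cx) ** 2 + (fy - cy) ** 2) / (2 * sigma**2))
            filters.append(g)
    return np.asarray(filters)


def _gabor_energy(pixels: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Per-image complex Gabor magnitude maps, (n_images, n_filters, H, W)."""
    f_img = np.fft.fft2(pixels)  # (n, H, W)
    out = np.empty((pixels.shape[0], filters.shape[0]) + pixels.shape[1:])
    for j, filt in enumerate(filters):
        out[:, j] = np.abs(np.fft.ifft2(f_img * filt[None]))
    return out


def _avg_pool(maps: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool the trailing two axes by an integer factor."""
    n, c, h, w = maps.shape
    f = min(factor, h)
    hh, ww = h // f, w // f
    m = maps[:, :, : hh * f, : ww * f].reshape(n, c, hh, f, ww, f)
    return m.mean(axis=(3, 5))


def _builtin_layer_features(
    energy: np.ndarray, pool_factor: int, out_dim: int, rng: np.random.Generator
) -> np.ndarray:
    pooled = _avg_pool(energy, pool_factor)
    n = pooled.shape[0]
    # rectification happens at the Gabor stage (energy magnitude); the
    # readout is purely linear, and there is no per-bank normalisation so
    # features are a pure function of the image and auxiliary banks live in
    # the same space
    flat = pooled.reshape(n, -1)
    d_in = flat.shape[1]
    w = rng.standard_normal((d_in, out_dim)) / np.sqrt(d_in)
    return flat @ w


def available_extractors() -> tuple[str, ...]:
    return ("builtin-gabor-random",)


def extract_features(
    bank: ImageBank,
    extractor: str = "builtin-gabor-random",
    layers: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_pcs: int = DEFAULT_N_PCS,
    out_dim: int = DEFAULT_OUT_DIM,
    seed: int = 0,
) -> dict[str, FeatureBank]:
    """Extract per-layer feature banks from an image bank.

    With the builtin extractor, layer ``k`` pools Gabor energy maps over a
    ``2**k`` pixel window before a seeded random linear readout with
    rectification, so deeper layers integrate over larger regions of the
    image. Each layer gets an independent readout (seeded from ``seed`` and
    the layer index) and its own PCA summary.

    Raises
    ------
    ValueError
        If ``extractor`` is not a known plug-in; the message lists the
        available extractor labels.
    """
    if extractor not in available_extractors():
        raise ValueError(
            f"unknown extractor {extractor!r}; available: {', '.join(available_extractors())}"
        )
    size = bank.image_shape[0]
    filters = gabor_filter_bank(size)
    energy = _gabor_energy(bank.pixels, filters)
    banks: dict[str, FeatureBank] = {}
    for layer in layers:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(layer,)))
        feats = _builtin_layer_features(energy, 2**layer, out_dim, rng)
        name = f"layer{layer}"
        banks[name] = FeatureBank.from_features(feats, bank.image_ids, name, n_pcs=n_pcs)
    return banks
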