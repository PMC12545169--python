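"""Procedural grayscale image banks: textures with spectrally matched noise,
and an object bank with a distinct face recipe.

The texture generator is not a photorealistic texture-synthesis method; it
builds family-structured band-pass images whose higher-order statistics are
destroyed by Fourier phase scrambling, which is exactly the texture-vs-noise
contrast the analyses quantify. Faces are generated from a stereotyped
part-based recipe (oval outline, eyes, mouth) so that they form a cluster in
any reasonable feature space without ever injecting category labels into the
features themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageBank", "make_texture_bank", "make_object_bank", "phase_scramble"]


@dataclass
class ImageBank:
    """A bank of grayscale images with category metadata.

    Attributes
    ----------
    image_ids
        Unique integer ids, one per image.
    pixels
        Array (n_images, H, W), values in [0, 1].
    category
        Per-image label in {"face", "object", "texture", "noise"}.
    family
        Texture-family label (1-based) or -1 where not applicable.
    partner_id
        For texture/noise pairs, the id of the spectrally matched partner;
        -1 otherwise.
    n_repeats
        Presentations per image scheduled for this bank.
    """

    image_ids: np.ndarray
    pixels: np.ndarray
    category: np.ndarray
    family: np.ndarray = field(default=None)  # type: ignore[assignment]
    partner_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_repeats: int = 1

    def __post_init__(self) -> None:
        self.image_ids = np.asarray(self.image_ids, dtype=int)
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.category = np.asarray(self.category, dtype=object)
        n = len(self.image_ids)
        if len(np.unique(self.image_ids)) != n:
            raise ValueError("image ids must be unique")
        if self.pixels.shape[0] != n or self.pixels.ndim != 3:
            raise ValueError("pixels must be (n_images, H, W)")
        if self.family is None:
            self.family = np.full(n, -1, dtype=int)
        if self.partner_id is None:
            self.partner_id = np.full(n, -1, dtype=int)

    def __len__(self) -> int:
        return len(self.image_ids)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def index_of(self, image_id: int) -> int:
        idx = np.flatnonzero(self.image_ids == image_id)
        if idx.size == 0:
            raise KeyError(f"image id {image_id} not in bank")
        return int(idx[0])


def _check_shape(image_shape: tuple[int, int]) -> tuple[int, int]:
    h, w = image_shape
    if h != w:
        raise ValueError(f"image_shape must be square, got {image_shape}")
    if h < 16:
        raise ValueError(f"image_shape too small ({h} px); need >= 16")
    return h, w


def phase_scramble(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomize Fourier phases of an image, preserving the amplitude spectrum.

    The random phase field is taken from the FFT of white noise, so it is
    Hermitian-symmetric and the output is real. The DC component (mean
    luminance) is untouched.
    """
    f = np.fft.fft2(img)
    noise = rng.standard_normal(img.shape)
    phase = np.angle(np.fft.fft2(noise))
    scrambled = np.abs(f) * np.exp(1j * phase)
    scrambled[0, 0] = f[0, 0]  # keep mean luminance
    return np.real(np.fft.ifft2(scrambled))


def _oriented_bandpass_mask(n: int, theta: float, f0: float, bw_f: float, bw_t: float) -> np.ndarray:
    """Fourier-domain oriented band-pass mask (log-frequency x orientation)."""
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    r = np.hypot(fx, fy)
    ang = np.arctan2(fy, fx)
    with np.errstate(divide="ignore"):
        radial = np.exp(-((np.log(np.maximum(r, 1e-6) / f0)) ** 2) / (2 * bw_f**2))
    d = np.angle(np.exp(1j * 2 * (ang - theta))) / 2.0  # orientation diff, pi-periodic
    angular = np.exp(-(d**2) / (2 * bw_t**2))
    mask = radial * angular
    mask[0, 0] = 0.0
    return mask


def _filtered_noise(n: int, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal((n, n))
    out = np.real(np.fft.ifft2(np.fft.fft2(w) * mask))
    s = out.std()
    return out / s if s > 0 else out


def make_texture_bank(
    n_families: int = 15,
    samples_per_family: int = 5,
    image_shape: tuple[int, int] = (64, 64),
    n_repeats: int = 5,
    seed: int | np.random.Generator = 0,
) -> ImageBank:
    """Family-structured textures plus spectrally matched noise controls.

    Each family has a recipe (two oriented band-pass channels plus a shared
    template, with a rectified cross-scale component that creates phase
    alignment); samples within a family mix the template with independent
    filtered noise, so within-family images correlate more strongly than
    across families. Every texture image gets a phase-scrambled partner with
    an identical Fourier amplitude spectrum, labelled ``noise``.

    The default 15 families x 5 samples plus matched controls give a
    150-image stimulus set.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    n, _ = _check_shape(image_shape)
    rng = np.random.default_rng(seed)

    textures = []
    families = []
    for fam in range(1, n_families + 1):
        theta = rng.uniform(0, np.pi)
        f0 = rng.uniform(0.06, 0.20)
        mask1 = _oriented_bandpass_mask(n, theta, f0, 0.45, 0.35)
        mask2 = _oriented_bandpass_mask(n, theta + rng.uniform(-0.4, 0.4), 2 * f0, 0.45, 0.5)
        template = _filtered_noise(n, mask1, rng)
        for _ in range(samples_per_family):
            indep = _filtered_noise(n, mask1, rng)
            fine = _filtered_noise(n, mask2, rng)
            img = 0.8 * template + 0.45 * indep
            # cross-scale phase alignment: fine structure gated by the
            # coarse envelope -> higher-order statistics that phase
            # scrambling destroys
            img = img + 0.5 * fine * np.maximum(template, 0)
            img = img / img.std()
            textures.append(0.5 + 0.08 * img)
            families.append(fam)

    textures = np.clip(np.asarray(textures), 0.0, 1.0)
    n_tex = len(textures)
    noises = np.stack([phase_scramble(t, rng) for t in textures])
    noises = np.clip(noises, 0.0, 1.0)

    pixels = np.concatenate([textures, noises])
    ids = np.arange(2 * n_tex)
    category = np.array(["texture"] * n_tex + ["noise"] * n_tex, dtype=object)
    family = np.asarray(families + families, dtype=int)
    partner = np.concatenate([ids[n_tex:], ids[:n_tex]])
    return ImageBank(
        image_ids=ids,
        pixels=pixels,
        category=category,
        family=family,
        partner_id=partner,
        n_repeats=n_repeats,
    )


def _coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)
    return np.meshgrid(c, c, indexing="xy")


def _blob_mask(n: int, rng: np.random.Generator) -> np.ndarray:
    """Silhouette from a thresholded mixture of anisotropic Gaussian bumps."""
    xx, yy = _coords(n)
    field_ = np.zeros((n, n))
    for _ in range(rng.integers(2, 6)):
        cx, cy = rng.uniform(-0.45, 0.45, size=2)
        sx, sy = rng.uniform(0.08, 0.35, size=2)
        ang = rng.uniform(0, np.pi)
        xr = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
        yr = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
        field_ += np.exp(-(xr**2 / (2 * sx**2) + yr**2 / (2 * sy**2)))
    return field_ > np.quantile(field_, rng.uniform(0.72, 0.9))


def _face_image(n: int, rng: np.random.Generator) -> np.ndarray:
    """Stereotyped face: oval head, symmetric eyes, nose hint and mouth."""
    xx, yy = _coords(n)
    img = np.full((n, n), 0.5)
    ry = rng.uniform(0.62, 0.78)
    rx = ry / rng.uniform(1.25, 1.45)
    tone = rng.uniform(0.62, 0.85)
    head = (xx / rx) ** 2 + (yy / ry) ** 2 <= 1.0
    img[head] = tone
    eye_dx = rx * rng.uniform(0.38, 0.5)
    eye_y = -ry * rng.uniform(0.25, 0.38)
    eye_r = rng.uniform(0.05, 0.08)
    for sx in (-1, 1):
        eye = (xx - sx * eye_dx) ** 2 + (yy - eye_y) ** 2 <= eye_r**2
        img[eye] = rng.uniform(0.05, 0.2)
    nose = (np.abs(xx) <= 0.035) & (yy > eye_y + 0.08) & (yy < 0.12)
    img[nose & head] = tone - 0.12
    mouth_y = ry * rng.uniform(0.35, 0.5)
    mouth = (np.abs(yy - mouth_y) <= 0.045) & (np.abs(xx) <= rx * rng.uniform(0.35, 0.5))
    img[mouth & head] = rng.uniform(0.1, 0.3)
    return img


def _object_image(n: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((n, n), 0.5)
    mask = _blob_mask(n, rng)
    tone = rng.uniform(0.08, 0.95)
    img[mask] = tone
    # interior shading so objects are not flat silhouettes
    xx, yy = _coords(n)
    shade = 0.12 * (rng.uniform(-1, 1) * xx + rng.uniform(-1, 1) * yy)
    img[mask] = np.clip(img[mask] + shade[mask], 0.02, 0.98)
    return img


def make_object_bank(
    n_objects: int = 1392,
    n_faces: int = 201,
    image_shape: tuple[int, int] = (64, 64),
    n_repeats: int = 10,
    seed: int | np.random.Generator = 0,
) -> ImageBank:
    """Object-and-face bank; defaults mirror a 1,392 + 201 = 1,593 image set.

    Objects are shaded random silhouettes on a grey field; faces come from a
    distinct part-based recipe, so they cluster in feature space by
    construction of appearance, not by label.
    """
    if n_objects < 0 or n_faces < 0:
        raise ValueError("counts must be non-negative")
    n, _ = _check_shape(image_shape)
    rng = np.random.default_rng(seed)
    pixels = np.empty((n_objects + n_faces, n, n))
    for i in range(n_objects):
        pixels[i] = _object_image(n, rng)
    for j in range(n_faces):
        pixels[n_objects + j] = _face_image(n, rng)
    category = np.array(["object"] * n_objects + ["face"] * n_faces, dtype=object)
    return ImageBank(
        image_ids=np.arange(n_objects + n_faces),
        pixels=np.clip(pixels, 0.0, 1.0),
        category=category,
        n_repeats=n_repeats,
    )
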