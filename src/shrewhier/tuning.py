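"""Grating tuning, categorical variance decomposition and texture modulation.

Orientation tuning is fit with a modified Von Mises curve treating 0-180 deg
as the full period; spatial-frequency tuning with a Gaussian in log
frequency. A cell's fit is "included" when the fitted peak amplitude reaches
at least half of its average grating-evoked rate.

Variance explained by a categorical variable follows a one-way fixed-effects
decomposition: 100 * (V_total - V_residual) / V_total with population
(divide-by-n) variances, where V_residual is the variance around the level
means. At area scope, total and residual variances are summed across cells
before normalising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "OrientationFit",
    "SpatialFreqFit",
    "VarianceDecomposition",
    "TextureDivergence",
    "fit_orientation",
    "fit_spatial_frequency",
    "variance_explained_categorical",
    "area_variance_explained",
    "texture_divergence",
    "texture_family_variance_timecourse",
    "circular_orientation_error",
]


@dataclass
class OrientationFit:
    unit_id: int
    theta_pref: float  # deg, [0, 180)
    kappa: float
    amplitude: float
    baseline: float
    included: bool


@dataclass
class SpatialFreqFit:
    unit_id: int
    f_pref: float  # cycles/deg
    log_sigma: float
    amplitude: float
    baseline: float
    included: bool
    unbounded: bool = False  # preferred frequency clamped to the tested range


@dataclass
class VarianceDecomposition:
    scope: str  # "cell" | "area"
    variable: str
    v_total: float
    v_residual: float

    @property
    def pct_explained(self) -> float:
        if self.v_total <= 0:
            return float("nan")
        return 100.0 * (self.v_total - self.v_residual) / self.v_total


@dataclass
class TextureDivergence:
    area: str
    time_s: np.ndarray
    texture_mean: np.ndarray
    noise_mean: np.ndarray
    texture_sem: np.ndarray
    noise_sem: np.ndarray
    p_values: np.ndarray
    divergence_latency: float | None


def circular_orientation_error(theta_a: float, theta_b: float) -> float:
    """Absolute orientation difference on the 180-degree circle (<= 90)."""
    d = (theta_a - theta_b) % 180.0
    return float(min(d, 180.0 - d))


def _inclusion(amplitude: float, responses: np.ndarray) -> bool:
    return bool(amplitude >= 0.5 * np.mean(responses))


def fit_orientation(
    orientations_deg: np.ndarray, responses: np.ndarray, unit_id: int = -1
) -> OrientationFit:
    """Fit R(theta) = B + A * exp(kappa * (cos(2*(theta - theta_pref)) - 1)).

    ``orientations_deg`` and ``responses`` are matched per-trial (or
    per-condition mean) arrays; trials are pooled across spatial frequency
    and phase. Degenerate all-equal responses give A = 0, included = False.
    """
    theta = np.deg2rad(np.asarray(orientations_deg, dtype=float))
    r = np.asarray(responses, dtype=float)
    if len(np.unique(orientations_deg)) < 4:
        raise ValueError("need >= 4 distinct orientations")
    if np.ptp(r) == 0:
        return OrientationFit(unit_id, float(orientations_deg[0]) % 180.0, 0.0, 0.0, float(r[0]), False)

    def model(p):
        b, a, kappa, t0 = p
        return b + a * np.exp(kappa * (np.cos(2 * (theta - t0)) - 1.0))

    # initialise at the best-responding orientation
    uo = np.unique(orientations_deg)
    means = np.array([r[orientations_deg == o].mean() for o in uo])
    t0_init = np.deg2rad(uo[np.argmax(means)])
    p0 = [max(means.min(), 0.0), max(means.max() - means.min(), 1e-3), 1.5, t0_init]
    res = least_squares(
        lambda p: model(p) - r,
        p0,
        bounds=([0, 0, 0.05, -np.pi], [np.inf, np.inf, 50.0, 2 * np.pi]),
        max_nfev=2000,
    )
    b, a, kappa, t0 = res.x
    theta_pref = float(np.rad2deg(t0) % 180.0)
    return OrientationFit(unit_id, theta_pref, float(kappa), float(a), float(b), _inclusion(a, r))


def fit_spatial_frequency(
    sf_cpd: np.ndarray, responses: np.ndarray, unit_id: int = -1
) -> SpatialFreqFit:
    """Fit R(f) = B + A * exp(-(ln f - ln f_pref)^2 / (2 sigma_f^2)).

    A monotone response over the tested range drives the fitted centre to a
    bound; the fit is then clamped to the range edge and flagged
    ``unbounded``.
    """
    f = np.asarray(sf_cpd, dtype=float)
    r = np.asarray(responses, dtype=float)
    uf = np.unique(f)
    if len(uf) < 3:
        raise ValueError("need >= 3 distinct spatial frequencies")
    if np.ptp(r) == 0:
        return SpatialFreqFit(unit_id, float(uf[0]), 1.0, 0.0, float(r[0]), False)
    logf = np.log(f)

    def model(p):
        b, a, lf0, sig = p
        return b + a * np.exp(-((logf - lf0) ** 2) / (2 * sig**2))

    means = np.array([r[f == v].mean() for v in uf])
    lf0_init = np.log(uf[np.argmax(means)])
    lo_bound, hi_bound = np.log(uf[0]) - 1.5, np.log(uf[-1]) + 1.5
    p0 = [max(means.min(), 0.0), max(means.max() - means.min(), 1e-3), lf0_init, 0.7]
    res = least_squares(
        lambda p: model(p) - r,
        p0,
        bounds=([0, 0, lo_bound, 0.05], [np.inf, np.inf, hi_bound, 5.0]),
        max_nfev=2000,
    )
    b, a, lf0, sig = res.x
    unbounded = bool(lf0 <= np.log(uf[0]) - 1.49 or lf0 >= np.log(uf[-1]) + 1.49)
    f_pref = float(np.clip(np.exp(lf0), uf[0], uf[-1])) if unbounded else float(np.exp(lf0))
    return SpatialFreqFit(
        unit_id, f_pref, float(sig), float(a), float(b), _inclusion(a, r), unbounded
    )


def variance_explained_categorical(
    responses: np.ndarray, labels: np.ndarray, variable: str = "", scope: str = "cell"
) -> VarianceDecomposition:
    """One-way categorical variance decomposition for a single cell.

    Uses population (divide-by-n) variances for both terms so the percentage
    is a scale-free ratio. Every level must have at least two trials.
    """
    r = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    levels, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every level needs >= 2 trials")
    v_total = r.var()
    level_means = np.bincount(inv, weights=r) / counts
    v_residual = ((r - level_means[inv]) ** 2).mean()
    return VarianceDecomposition(scope=scope, variable=variable, v_total=v_total, v_residual=v_residual)


def area_variance_explained(
    per_cell: list[VarianceDecomposition], variable: str = ""
) -> VarianceDecomposition:
    """Area-scope aggregation: sum totals and residuals across cells first."""
    v_tot = float(sum(d.v_total for d in per_cell))
    v_res = float(sum(d.v_residual for d in per_cell))
    return VarianceDecomposition(scope="area", variable=variable, v_total=v_tot, v_residual=v_res)


def texture_divergence(
    texture_rates: np.ndarray,
    noise_rates: np.ndarray,
    time_s: np.ndarray,
    alpha: float = 0.01,
    n_consecutive: int = 1,
    area: str = "",
) -> TextureDivergence:
    """Texture-vs-noise divergence latency of an area's population response.

    ``texture_rates`` and ``noise_rates`` are (n_cells, n_bins) trial-averaged
    rates. Per time bin, a paired two-tailed t-test across cells compares the
    two classes; the divergence latency is the first bin (optionally the
    first of ``n_consecutive`` significant bins) with p < alpha. No
    multiple-comparisons correction is applied, matching the per-bin rule.
    """
    tex = np.asarray(texture_rates, dtype=float)
    noi = np.asarray(noise_rates, dtype=float)
    if tex.shape != noi.shape:
        raise ValueError("texture and noise rate matrices must have equal shape")
    n_cells = tex.shape[0]
    if n_cells < 10:
        raise ValueError("need >= 10 cells for the divergence test")
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_rel(tex, noi, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    sig = p < alpha
    latency = None
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= n_consecutive:
            latency = float(time_s[i - n_consecutive + 1])
            break
    sem = lambda x: x.std(axis=0, ddof=1) / np.sqrt(n_cells)
    return TextureDivergence(
        area=area,
        time_s=np.asarray(time_s, dtype=float),
        texture_mean=tex.mean(axis=0),
        noise_mean=noi.mean(axis=0),
        texture_sem=sem(tex),
        noise_sem=sem(noi),
        p_values=p,
        divergence_latency=latency,
    )


def texture_family_variance_timecourse(
    rates: np.ndarray, family_labels: np.ndarray, time_s: np.ndarray
) -> np.ndarray:
    """Per-time-bin area-scope variance explained by texture family.

    ``rates`` is (n_cells, n_trials, n_bins): single-trial responses of every
    cell per time bin. Returns the percentage time series (NaN where the
    decomposition is undefined, e.g. a single family).
    """
    rates = np.asarray(rates, dtype=float)
    family_labels = np.asarray(family_labels)
    n_cells, n_trials, n_bins = rates.shape
    if len(np.unique(family_labels)) < 2:
        return np.full(n_bins, np.nan)
    out = np.empty(n_bins)
    for b in range(n_bins):
        per_cell = [
            variance_explained_categorical(rates[c, :, b], family_labels, "texture_family")
            for c in range(n_cells)
        ]
        out[b] = area_variance_explained(per_cell, "texture_family").pct_explained
    return out
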