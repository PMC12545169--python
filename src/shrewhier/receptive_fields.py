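"""Receptive-field mapping from locally sparse noise.

ON and OFF fields are mapped independently from responses to white and black
dot frames. Because every frame shows one dot per scheduling-grid cell, each
frame's spikes credit all of that frame's dot locations; the reverse-
correlation average cancels the off-field credits since distant dot positions
are decorrelated by design. The per-location mean-count surface is then fit
with a circular 2D Gaussian on a constant baseline, and the field is scored
with a Poisson-null quality statistic Q: the number of standard deviations by
which the observed spike count within 10 degrees of the fitted centre exceeds
the baseline expectation. Only Q > 5 counts as a receptive field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import DEFAULT_MONITOR, Monitor
from .responses import count_in_windows
from .synthetic.schedules import SparseNoiseFrame

__all__ = [
    "RFHistogram",
    "RFFit",
    "build_rf_histogram",
    "fit_rf",
    "rf_quality",
    "rf_size",
    "map_receptive_field",
]

QUALITY_THRESHOLD = 5.0
QUALITY_RADIUS_DEG = 10.0


@dataclass
class RFHistogram:
    """Spike-count histogram over dot locations, one polarity."""

    unit_id: int
    polarity: str  # "ON" | "OFF"
    positions: np.ndarray  # (n_locations, 2) azimuth/elevation deg
    counts: np.ndarray  # spikes credited to each location
    presentations: np.ndarray  # times each location was shown

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts / np.maximum(self.presentations, 1)


@dataclass
class RFFit:
    unit_id: int
    polarity: str
    center: tuple[float, float]
    sigma: float
    amplitude: float
    baseline: float
    quality: float
    has_rf: bool
    converged: bool = True


def build_rf_histogram(
    spike_times: np.ndarray,
    frames: list[SparseNoiseFrame],
    polarity: str,
    response_window: tuple[float, float] = (0.0, 0.1),
    unit_id: int = -1,
) -> RFHistogram:
    """Accumulate the 2D spike-count histogram for one polarity.

    ``polarity`` is "ON" (white frames) or "OFF" (black frames). Locations
    never presented are absent from the histogram rather than zero-filled.
    """
    want = {"ON": "white", "OFF": "black"}[polarity]
    sel = [f for f in frames if f.polarity == want]
    if not sel:
        raise ValueError(f"no {want} frames in the schedule")
    onsets = np.array([f.onset_s for f in sel])
    spikes = count_in_windows(
        np.asarray(spike_times), onsets + response_window[0], onsets + response_window[1]
    )
    acc: dict[tuple[float, float], list[float]] = {}
    for f, c in zip(sel, spikes):
        for pos in f.dot_positions:
            key = (round(pos[0], 6), round(pos[1], 6))
            if key not in acc:
                acc[key] = [0.0, 0.0]
            acc[key][0] += c
            acc[key][1] += 1
    keys = sorted(acc)
    positions = np.array(keys)
    counts = np.array([acc[k][0] for k in keys])
    pres = np.array([acc[k][1] for k in keys])
    return RFHistogram(
        unit_id=unit_id, polarity=polarity, positions=positions, counts=counts, presentations=pres
    )


def _gaussian_surface(p: np.ndarray, xy: np.ndarray) -> np.ndarray:
    b, a, x0, y0, sigma = p
    d2 = (xy[:, 0] - x0) ** 2 + (xy[:, 1] - y0) ** 2
    return b + a * np.exp(-d2 / (2.0 * sigma**2))


def fit_rf(
    hist: RFHistogram,
    monitor: Monitor = DEFAULT_MONITOR,
    n_starts: int = 3,
    sigma_bounds: tuple[float, float] = (1.0, 40.0),
) -> RFFit:
    """Least-squares circular-Gaussian fit to the per-location mean counts.

    The Gaussian is forced to be circular (one sigma) to prevent
    overfitting. Initialisation is multi-start from the ``n_starts`` largest
    histogram peaks; the centre is bounded to the monitor plus a 10-degree
    margin. The returned fit carries the quality statistic from
    :func:`rf_quality` and ``has_rf`` set accordingly.
    """
    mask = hist.presentations > 0
    if mask.sum() < 20:
        raise ValueError("need >= 20 sampled locations to fit a receptive field")
    xy = hist.positions[mask]
    z = hist.mean_counts[mask]

    lo = [0.0, 0.0, -monitor.half_azimuth_deg - 10, -monitor.half_elevation_deg - 10, sigma_bounds[0]]
    hi = [
        max(z.max(), 1e-6),
        max(2 * (z.max() - z.min()), 1e-6),
        monitor.half_azimuth_deg + 10,
        monitor.half_elevation_deg + 10,
        sigma_bounds[1],
    ]
    peaks = np.argsort(z)[::-1][:n_starts]
    best = None
    converged = False
    for pk in peaks:
        p0 = np.array(
            [
                np.median(z),
                max(z[pk] - np.median(z), 1e-3),
                xy[pk, 0],
                xy[pk, 1],
                5.0,
            ]
        )
        p0 = np.clip(p0, lo, hi)
        try:
            res = least_squares(
                lambda p: _gaussian_surface(p, xy) - z, p0, bounds=(lo, hi), max_nfev=2000
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
            converged = True
    if best is None:
        fit = RFFit(
            unit_id=hist.unit_id,
            polarity=hist.polarity,
            center=(np.nan, np.nan),
            sigma=np.nan,
            amplitude=np.nan,
            baseline=float(np.median(z)),
            quality=np.nan,
            has_rf=False,
            converged=False,
        )
        return fit
    b, a, x0, y0, sigma = best.x
    fit = RFFit(
        unit_id=hist.unit_id,
        polarity=hist.polarity,
        center=(float(x0), float(y0)),
        sigma=float(sigma),
        amplitude=float(a),
        baseline=float(b),
        quality=np.nan,
        has_rf=False,
        converged=converged,
    )
    q = rf_quality(hist, fit)
    fit.quality = q
    fit.has_rf = bool(np.isfinite(q) and q > QUALITY_THRESHOLD)
    return fit


def rf_quality(hist: RFHistogram, fit: RFFit, radius_deg: float = QUALITY_RADIUS_DEG) -> float:
    """Poisson-null quality: (observed - expected) / sqrt(expected).

    Expected spikes within ``radius_deg`` of the fitted centre come from the
    fitted baseline times the presentation count there. Returns NaN when the
    expectation is zero (quality undefined, no receptive field).
    """
    d = np.hypot(hist.positions[:, 0] - fit.center[0], hist.positions[:, 1] - fit.center[1])
    near = (d <= radius_deg) & (hist.presentations > 0)
    expected = fit.baseline * hist.presentations[near].sum()
    if expected <= 0:
        return float("nan")
    observed = hist.counts[near].sum()
    return float((observed - expected) / np.sqrt(expected))


def rf_size(fit: RFFit, convention: str = "fwhm") -> float:
    """Receptive-field size in degrees under a declared convention.

    ``fwhm`` (default): full-width-at-half-maximum diameter,
    2*sqrt(2*ln 2)*sigma; ``2sigma``: diameter of 2 sigma.
    """
    if not fit.has_rf:
        raise ValueError("rf_size requires a fit with has_rf=True")
    if convention == "fwhm":
        return float(2.0 * np.sqrt(2.0 * np.log(2.0)) * fit.sigma)
    if convention == "2sigma":
        return float(2.0 * fit.sigma)
    raise ValueError(f"unknown size convention {convention!r}")


def map_receptive_field(
    spike_times: np.ndarray,
    frames: list[SparseNoiseFrame],
    response_window: tuple[float, float] = (0.0, 0.1),
    unit_id: int = -1,
    monitor: Monitor = DEFAULT_MONITOR,
) -> dict[str, RFFit]:
    """Build histograms and fit ON and OFF receptive fields for one unit."""
    out = {}
    for polarity in ("ON", "OFF"):
        hist = build_rf_histogram(spike_times, frames, polarity, response_window, unit_id)
        out[polarity] = fit_rf(hist, monitor=monitor)
    return out
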