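"""Responsiveness testing, recording-stability filtering and latency estimation.

A unit is deemed responsive to a stimulus class when its mean evoked count in
the 100-ms response window exceeds the expectation of a Poisson model fitted
to the 50-ms pre-stimulus baseline by at least five standard deviations (of
the mean of N Poisson windows, i.e. sqrt(lambda/N)). A unit is "visually
responsive" overall if it passes for any class.

The stability filter handles slow drift across the repeat blocks of the
object set: the per-block waveform amplitude is proxied by the mean spike
amplitude, a threshold is set at 0.6 x the third-largest block amplitude, and
blocks whose suprathreshold spike count falls more than two standard
deviations below the across-block mean are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .responses import BASELINE_WINDOW, RESPONSE_WINDOW, count_in_windows, spikes_by_unit

__all__ = [
    "ResponsivenessResult",
    "BlockStabilityResult",
    "LatencyEstimate",
    "test_responsive",
    "responsiveness_table",
    "filter_stable_blocks",
    "half_peak_latency",
]


@dataclass
class ResponsivenessResult:
    unit_id: int
    stim_class: str
    z_score: float
    responsive: bool
    threshold_sd: float = 5.0
    lambda_baseline: float = 0.0  # expected count per response window
    n_trials: int = 0


@dataclass
class BlockStabilityResult:
    unit_id: int
    block_amplitudes: np.ndarray
    amplitude_threshold: float
    suprathreshold_counts: np.ndarray
    kept_blocks: np.ndarray  # boolean


@dataclass
class LatencyEstimate:
    unit_id: int
    psth_rate: np.ndarray  # Hz per bin
    bin_edges: np.ndarray
    baseline_rate: float
    peak_rate: float
    peak_time: float
    passes_peak_test: bool
    half_peak_latency: float | None


def test_responsive(
    spike_times: np.ndarray,
    events: pd.DataFrame,
    stim_class: str = "",
    threshold_sd: float = 5.0,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    unit_id: int = -1,
    include_baseline_variance: bool = True,
) -> ResponsivenessResult:
    """Poisson-null responsiveness test for one unit and one stimulus class.

    The baseline mean count is rescaled to the duration of the response
    window to give the null expectation ``lambda``; the z score is the mean
    evoked count minus ``lambda`` over its null standard deviation. Because
    ``lambda`` is itself estimated from the same N baseline windows, the
    proper null SD is ``sqrt(lambda * (1 + s) / N)`` with ``s`` the
    response/baseline duration ratio; with the naive
    ``include_baseline_variance=False`` convention (``sqrt(lambda / N)``)
    the null z is over-dispersed by sqrt(1 + s). A zero baseline is floored
    at half a spike over all baseline windows so the statistic stays finite.
    """
    if len(events) < 10:
        raise ValueError(f"need >= 10 events to test responsiveness, got {len(events)}")
    onsets = events["onset_s"].to_numpy()
    n = len(onsets)
    resp = count_in_windows(spike_times, onsets + response_window[0], onsets + response_window[1])
    base = count_in_windows(spike_times, onsets + baseline_window[0], onsets + baseline_window[1])
    scale = (response_window[1] - response_window[0]) / (baseline_window[1] - baseline_window[0])
    lam = base.mean() * scale
    lam = max(lam, 0.5 / n)
    var = lam * (1.0 + scale) / n if include_baseline_variance else lam / n
    z = (resp.mean() - lam) / np.sqrt(var)
    return ResponsivenessResult(
        unit_id=unit_id,
        stim_class=stim_class,
        z_score=float(z),
        responsive=bool(z >= threshold_sd),
        threshold_sd=threshold_sd,
        lambda_baseline=float(lam),
        n_trials=n,
    )


def responsiveness_table(
    spikes: pd.DataFrame,
    events_by_class: dict[str, pd.DataFrame],
    threshold_sd: float = 5.0,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> pd.DataFrame:
    """Per-unit x class responsiveness, plus the any-class summary flag."""
    per_unit = spikes_by_unit(spikes)
    area = spikes.groupby("unit_id")["area"].first()
    rows = []
    for unit, times in per_unit.items():
        any_resp = False
        for cls, ev in events_by_class.items():
            r = test_responsive(
                times, ev, cls, threshold_sd, response_window, baseline_window, unit_id=unit
            )
            any_resp = any_resp or r.responsive
            rows.append(
                dict(
                    unit_id=unit,
                    area=area.loc[unit],
                    stim_class=cls,
                    z_score=r.z_score,
                    responsive=r.responsive,
                )
            )
        for row in rows[-len(events_by_class) :]:
            row["visually_responsive"] = any_resp
    return pd.DataFrame(rows)


def filter_stable_blocks(
    spike_amplitudes: np.ndarray,
    spike_blocks: np.ndarray,
    n_blocks: int,
    unit_id: int = -1,
) -> BlockStabilityResult:
    """Flag unstable repeat blocks of one unit from spike amplitudes.

    With fewer than three blocks the third-largest amplitude does not exist;
    the filter is skipped with a warning and all blocks are kept.
    """
    spike_amplitudes = np.asarray(spike_amplitudes, dtype=float)
    spike_blocks = np.asarray(spike_blocks, dtype=int)
    amps = np.array(
        [
            spike_amplitudes[spike_blocks == b].mean() if (spike_blocks == b).any() else 0.0
            for b in range(n_blocks)
        ]
    )
    if n_blocks < 3:
        warnings.warn("fewer than 3 blocks: stability filter skipped, all blocks kept")
        return BlockStabilityResult(
            unit_id=unit_id,
            block_amplitudes=amps,
            amplitude_threshold=0.0,
            suprathreshold_counts=np.array(
                [(spike_blocks == b).sum() for b in range(n_blocks)], dtype=float
            ),
            kept_blocks=np.ones(n_blocks, dtype=bool),
        )
    threshold = 0.6 * np.sort(amps)[-3]
    counts = np.array(
        [
            ((spike_blocks == b) & (spike_amplitudes >= threshold)).sum()
            for b in range(n_blocks)
        ],
        dtype=float,
    )
    kept = counts >= counts.mean() - 2.0 * counts.std()
    return BlockStabilityResult(
        unit_id=unit_id,
        block_amplitudes=amps,
        amplitude_threshold=float(threshold),
        suprathreshold_counts=counts,
        kept_blocks=kept,
    )


def half_peak_latency(
    spike_times: np.ndarray,
    events: pd.DataFrame,
    bin_s: float = 0.005,
    percentile: float = 99.75,
    t_range: tuple[float, float] = (-0.05, 0.2),
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    unit_id: int = -1,
) -> LatencyEstimate:
    """Half-peak response latency from the trial-summed PSTH.

    The unit passes the peak test if the peak bin's summed count exceeds the
    ``percentile`` point of the Poisson distribution implied by baseline
    firing (baseline count per bin x number of trials). The latency is the
    left edge of the first bin at or above the midpoint between baseline and
    peak rate.
    """
    onsets = events["onset_s"].to_numpy()
    n_trials = len(onsets)
    edges = np.arange(t_range[0], t_range[1] + bin_s / 2, bin_s)
    rel = (np.asarray(spike_times)[None, :] - onsets[:, None]).ravel()
    counts, _ = np.histogram(rel, bins=edges)
    rate = counts / (n_trials * bin_s)

    base_count = count_in_windows(
        spike_times, onsets + baseline_window[0], onsets + baseline_window[1]
    ).sum()
    base_dur = baseline_window[1] - baseline_window[0]
    r_b = base_count / (n_trials * base_dur)
    lam_bin = r_b * bin_s * n_trials  # expected summed count per bin under the null

    post = edges[:-1] >= 0
    peak_idx = np.flatnonzero(post)[np.argmax(counts[post])]
    peak_count = counts[peak_idx]
    r_p = rate[peak_idx]
    crit = stats.poisson.ppf(percentile / 100.0, lam_bin)
    passes = bool(peak_count > crit)

    latency = None
    if passes:
        half = (r_b + r_p) / 2.0
        for i in np.flatnonzero(post):
            if rate[i] >= half:
                latency = float(edges[i])
                break
    return LatencyEstimate(
        unit_id=unit_id,
        psth_rate=rate,
        bin_edges=edges,
        baseline_rate=float(r_b),
        peak_rate=float(r_p),
        peak_time=float(edges[peak_idx]),
        passes_peak_test=passes,
        half_peak_latency=latency,
    )
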