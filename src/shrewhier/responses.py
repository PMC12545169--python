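"""Spike-count extraction: event windows, response tensors and PSTHs.

The response tensor (units x images x repeats of evoked spike counts in the
response window) is the hub that all downstream analyses consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "spikes_by_unit",
    "count_in_windows",
    "response_matrix",
    "response_tensor",
    "psth_counts",
    "time_resolved_rates",
]

RESPONSE_WINDOW = (0.0, 0.1)  # s, relative to stimulus onset
BASELINE_WINDOW = (-0.05, 0.0)


def spikes_by_unit(spikes: pd.DataFrame) -> dict[int, np.ndarray]:
    """Split a tidy spike table into per-unit sorted time arrays."""
    out = {}
    for unit, grp in spikes.groupby("unit_id"):
        out[int(unit)] = np.sort(grp["time_s"].to_numpy())
    return out


def count_in_windows(times: np.ndarray, starts: np.ndarray, stops: np.ndarray) -> np.ndarray:
    """Spike counts of one unit in many [start, stop) windows."""
    times = np.asarray(times)
    return np.searchsorted(times, stops) - np.searchsorted(times, starts)


def response_matrix(
    spikes: pd.DataFrame,
    events: pd.DataFrame,
    window: tuple[float, float] = RESPONSE_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts per unit x event in a window relative to each onset.

    Returns ``(counts, unit_ids)`` with counts shaped (n_units, n_events) in
    the event-table row order.
    """
    onsets = events["onset_s"].to_numpy()
    starts, stops = onsets + window[0], onsets + window[1]
    per_unit = spikes_by_unit(spikes)
    unit_ids = np.array(sorted(per_unit))
    counts = np.empty((len(unit_ids), len(events)))
    for i, u in enumerate(unit_ids):
        counts[i] = count_in_windows(per_unit[u], starts, stops)
    return counts, unit_ids


def response_tensor(
    spikes: pd.DataFrame,
    events: pd.DataFrame,
    window: tuple[float, float] = RESPONSE_WINDOW,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evoked-count tensor (units x images x repeats).

    Events must carry ``stim_id`` and ``repeat`` columns; every stimulus must
    appear with the same set of repeat indices. Returns
    ``(tensor, unit_ids, image_ids)`` with image ids sorted ascending and
    repeats ordered by repeat index.
    """
    counts, unit_ids = response_matrix(spikes, events, window)
    stim = events["stim_id"].to_numpy()
    rep = events["repeat"].to_numpy()
    image_ids = np.unique(stim)
    repeats = np.unique(rep)
    tensor = np.full((len(unit_ids), len(image_ids), len(repeats)), np.nan)
    img_pos = {int(s): i for i, s in enumerate(image_ids)}
    rep_pos = {int(r): i for i, r in enumerate(repeats)}
    for col, (s, r) in enumerate(zip(stim, rep)):
        tensor[:, img_pos[int(s)], rep_pos[int(r)]] = counts[:, col]
    if np.isnan(tensor).any():
        raise ValueError("incomplete design: some (stim, repeat) cells have no event")
    return tensor, unit_ids, image_ids


def psth_counts(
    times: np.ndarray,
    onsets: np.ndarray,
    t_range: tuple[float, float] = (-0.05, 0.2),
    bin_s: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-summed PSTH of one unit.

    Returns ``(counts_per_bin, bin_edges)``; edges are relative to onset.
    """
    edges = np.arange(t_range[0], t_range[1] + bin_s / 2, bin_s)
    rel = (np.asarray(times)[None, :] - np.asarray(onsets)[:, None]).ravel()
    counts, _ = np.histogram(rel, bins=edges)
    return counts.astype(float), edges


def time_resolved_rates(
    spikes: pd.DataFrame,
    events: pd.DataFrame,
    t_range: tuple[float, float] = (0.0, 0.167),
    bin_s: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-unit trial-averaged firing rate per time bin (units x bins), in Hz."""
    onsets = events["onset_s"].to_numpy()
    per_unit = spikes_by_unit(spikes)
    unit_ids = np.array(sorted(per_unit))
    edges = np.arange(t_range[0], t_range[1] + bin_s / 2, bin_s)
    rates = np.empty((len(unit_ids), len(edges) - 1))
    for i, u in enumerate(unit_ids):
        counts, _ = psth_counts(per_unit[u], onsets, t_range, bin_s)
        rates[i] = counts / (len(onsets) * bin_s)
    return rates, unit_ids, edges
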