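"""Forward model: from ground-truth neurons and schedules to spike tables.

Spiking is inhomogeneous Poisson. Each stimulus presentation contributes an
evoked rate (receptive-field, grating-tuning, texture and axis-model terms)
that switches on after the unit's response latency and lasts for the stimulus
duration; a homogeneous baseline process runs throughout the session. Any
negative instantaneous rate is clipped at zero and counted in the returned
log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureBank
from .images import ImageBank
from .neurons import GroundTruthNeuron
from .schedules import SparseNoiseFrame

__all__ = ["Session", "simulate_session", "simulate_response_tensor", "zscored_projection"]


@dataclass
class Session:
    """Everything the simulator needs: schedules plus the image/feature banks.

    Any stimulus class may be absent (None). ``object_features`` must cover
    every image id referenced by ``object_events``.
    """

    sparse_noise: list[SparseNoiseFrame] | None = None
    grating_events: pd.DataFrame | None = None
    texture_events: pd.DataFrame | None = None
    object_events: pd.DataFrame | None = None
    texture_bank: ImageBank | None = None
    object_bank: ImageBank | None = None
    object_features: FeatureBank | None = None

    def __post_init__(self) -> None:
        for events, bank in (
            (self.texture_events, self.texture_bank),
            (self.object_events, self.object_bank),
        ):
            if events is not None and bank is not None:
                missing = set(events["stim_id"]) - set(bank.image_ids.tolist())
                if missing:
                    raise ValueError(f"events reference image ids not in bank: {sorted(missing)[:5]}")

    @property
    def end_time(self) -> float:
        t = 0.0
        if self.sparse_noise:
            t = max(t, self.sparse_noise[-1].onset_s + self.sparse_noise[-1].duration_s)
        for ev in (self.grating_events, self.texture_events, self.object_events):
            if ev is not None and len(ev):
                t = max(t, float((ev["onset_s"] + ev["duration_s"]).max()))
        return t + 0.5


def zscored_projection(pc_scores: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Project images onto an axis and z-score across the bank."""
    proj = np.asarray(pc_scores, dtype=float) @ np.asarray(axis, dtype=float)
    sd = proj.std()
    return (proj - proj.mean()) / sd if sd > 0 else proj * 0.0


def _poisson_interval_spikes(
    rng: np.random.Generator, rates: np.ndarray, starts: np.ndarray, durations: np.ndarray
) -> np.ndarray:
    """Draw Poisson spikes for many constant-rate intervals at once."""
    lam = np.maximum(rates, 0.0) * np.maximum(durations, 0.0)
    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    s = np.repeat(starts, counts)
    d = np.repeat(durations, counts)
    return s + d * rng.random(total)


def _neuron_sparse_noise_rates(neuron: GroundTruthNeuron, frames: list[SparseNoiseFrame]) -> np.ndarray:
    if neuron.rf_polarity == "none" or neuron.rf_gain == 0:
        return np.zeros(len(frames))
    want = {"ON": "white", "OFF": "black"}.get(neuron.rf_polarity)
    cx, cy = neuron.rf_center
    two_s2 = 2.0 * neuron.rf_sigma**2
    rates = np.zeros(len(frames))
    for i, f in enumerate(frames):
        if want is not None and f.polarity != want:
            continue
        dots = np.asarray(f.dot_positions)
        d2 = (dots[:, 0] - cx) ** 2 + (dots[:, 1] - cy) ** 2
        rates[i] = neuron.rf_gain * np.exp(-d2 / two_s2).sum()
    return rates


def _neuron_grating_rates(neuron: GroundTruthNeuron, events: pd.DataFrame) -> np.ndarray:
    theta = np.deg2rad(events["orientation"].to_numpy())
    theta0 = np.deg2rad(neuron.pref_orientation)
    vm = np.exp(neuron.vm_kappa * (np.cos(2 * (theta - theta0)) - 1.0))
    logf = np.log(events["spatial_frequency"].to_numpy())
    sf = np.exp(-((logf - np.log(neuron.pref_sf)) ** 2) / (2 * neuron.sf_logsigma**2))
    return neuron.grating_gain * vm * sf


def simulate_session(
    neurons: list[GroundTruthNeuron],
    session: Session,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a full recording session.

    Returns
    -------
    spikes
        Tidy spike table: ``unit_id, area, time_s, amplitude``, sorted by
        unit then time.
    events
        Concatenated event table over all scheduled stimulus classes.
    log
        Bookkeeping: ``rate_clips`` counts events where a negative rate was
        clipped to zero.
    """
    rng = np.random.default_rng(seed)
    log = {"rate_clips": 0}

    event_frames = [
        ev
        for ev in (session.grating_events, session.texture_events, session.object_events)
        if ev is not None
    ]
    all_events = pd.concat(event_frames, ignore_index=True) if event_frames else pd.DataFrame()

    # object-block boundaries for amplitude drift
    block_starts = block_ids = None
    if session.object_events is not None and "block" in session.object_events:
        ob = session.object_events
        grp = ob.groupby("block")["onset_s"].min().sort_index()
        block_starts = grp.to_numpy()
        block_ids = grp.index.to_numpy()

    # per-image axis drive, shared projection cache
    obj_proj: dict[int, np.ndarray] = {}
    if session.object_events is not None:
        fb = session.object_features
        if fb is None:
            raise ValueError("object events scheduled but no object_features provided")
        id_to_row = {int(i): k for k, i in enumerate(fb.image_ids)}
        obj_rows = np.array([id_to_row[int(i)] for i in session.object_events["stim_id"]])

    tex_is_texture = None
    if session.texture_events is not None:
        bank = session.texture_bank
        cat = {int(i): c for i, c in zip(bank.image_ids, bank.category)}
        tex_is_texture = np.array(
            [cat[int(i)] == "texture" for i in session.texture_events["stim_id"]]
        )

    t_end = session.end_time
    rows_unit, rows_time, rows_amp, rows_area = [], [], [], []
    for neuron in neurons:
        times = [rng.random(rng.poisson(neuron.baseline_rate * t_end)) * t_end]

        if session.sparse_noise:
            rates = _neuron_sparse_noise_rates(neuron, session.sparse_noise)
            onsets = np.array([f.onset_s for f in session.sparse_noise]) + neuron.latency
            durs = np.array([f.duration_s for f in session.sparse_noise])
            times.append(_poisson_interval_spikes(rng, rates, onsets, durs))

        if session.grating_events is not None:
            ev = session.grating_events
            rates = _neuron_grating_rates(neuron, ev)
            onsets = ev["onset_s"].to_numpy() + neuron.latency
            durs = ev["duration_s"].to_numpy()
            times.append(_poisson_interval_spikes(rng, rates, onsets, durs))

        if session.texture_events is not None:
            ev = session.texture_events
            onsets = ev["onset_s"].to_numpy()
            durs = ev["duration_s"].to_numpy()
            base = np.full(len(ev), neuron.texture_base_gain)
            times.append(_poisson_interval_spikes(rng, base, onsets + neuron.latency, durs))
            if neuron.texture_gain != 0:
                extra = np.where(tex_is_texture, neuron.texture_gain, 0.0)
                tex_lat = neuron.texture_latency
                ok = durs - (tex_lat - 0.0) > 0
                times.append(
                    _poisson_interval_spikes(
                        rng,
                        extra[ok],
                        onsets[ok] + tex_lat,
                        (onsets[ok] + durs[ok] + neuron.latency) - (onsets[ok] + tex_lat),
                    )
                )

        if session.object_events is not None:
            ev = session.object_events
            key = id(neuron)
            z_all = zscored_projection(session.object_features.pc_scores, neuron.axis_true)
            drive = neuron.object_base_gain + neuron.axis_gain * neuron.ramp(z_all)
            rates = drive[obj_rows]
            neg = rates < 0
            if neg.any():
                log["rate_clips"] += int(neg.sum())
                rates = np.maximum(rates, 0.0)
            onsets = ev["onset_s"].to_numpy() + neuron.latency
            durs = ev["duration_s"].to_numpy()
            times.append(_poisson_interval_spikes(rng, rates, onsets, durs))

        t = np.sort(np.concatenate(times))
        amp = np.full(t.size, neuron.base_amplitude)
        if block_starts is not None and neuron.block_amplitude_profile is not None:
            prof = neuron.block_amplitude_profile
            idx = np.searchsorted(block_starts, t, side="right") - 1
            in_blocks = idx >= 0
            mult = np.ones(t.size)
            mult[in_blocks] = prof[np.minimum(idx[in_blocks], len(prof) - 1)]
            amp = amp * mult
        amp = amp * np.exp(rng.normal(0, 0.05, t.size))  # per-spike jitter

        rows_unit.append(np.full(t.size, neuron.unit_id))
        rows_area.append(np.full(t.size, neuron.area, dtype=object))
        rows_time.append(t)
        rows_amp.append(amp)

    spikes = pd.DataFrame(
        dict(
            unit_id=np.concatenate(rows_unit).astype(int),
            area=np.concatenate(rows_area),
            time_s=np.concatenate(rows_time),
            amplitude=np.concatenate(rows_amp),
        )
    ).sort_values(["unit_id", "time_s"], ignore_index=True)
    return spikes, all_events, log


def simulate_response_tensor(
    neurons: list[GroundTruthNeuron],
    pc_scores: np.ndarray,
    n_repeats: int = 10,
    window_s: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Directly sample an evoked-count tensor (units x images x repeats).

    Shortcut for analyses that start from the response tensor: per-trial
    counts are Poisson with mean
    ``(baseline + object_base + axis_gain * ramp(z)) * window_s``. This skips
    spike times, latencies and receptive fields, but shares the axis-model
    rate equation with :func:`simulate_session`.
    """
    rng = np.random.default_rng(seed)
    n_units = len(neurons)
    n_images = pc_scores.shape[0]
    lam = np.empty((n_units, n_images))
    for i, neuron in enumerate(neurons):
        z = zscored_projection(pc_scores, neuron.axis_true)
        rate = neuron.baseline_rate + neuron.object_base_gain + neuron.axis_gain * neuron.ramp(z)
        lam[i] = np.maximum(rate, 0.0) * window_s
    return rng.poisson(lam[..., None], size=(n_units, n_images, n_repeats)).astype(float)
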