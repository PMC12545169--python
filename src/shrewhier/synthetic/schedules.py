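"""Stimulus schedules: sparse-noise frames, grating conditions and image blocks.

Schedules are deterministic given a seed. Event streams are returned both as
typed records (for the simulator) and as tidy :class:`pandas.DataFrame` tables
(the on-disk interchange format; see :mod:`shrewhier.io`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geometry import DEFAULT_MONITOR, STIM_DURATION_S, STIM_PERIOD_S, Monitor

__all__ = [
    "SparseNoiseFrame",
    "GratingCondition",
    "make_sparse_noise_schedule",
    "make_grating_schedule",
    "make_image_schedule",
    "grating_events_frame",
    "sparse_noise_events_frame",
]


@dataclass(frozen=True)
class SparseNoiseFrame:
    """One frame of the locally sparse dot stimulus.

    Every frame shows one dot per scheduling-grid cell, all of a single
    polarity (all white or all black on a grey field), so that ON and OFF
    receptive fields can be reconstructed without interference.
    """

    frame_index: int
    polarity: str  # "white" | "black"
    dot_positions: tuple[tuple[float, float], ...]  # (azimuth, elevation) deg
    dot_size_deg: float
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.polarity not in ("white", "black"):
            raise ValueError(f"polarity must be 'white' or 'black', got {self.polarity!r}")
        if self.dot_size_deg <= 0:
            raise ValueError("dot_size_deg must be positive")


@dataclass(frozen=True)
class GratingCondition:
    """A static sinusoidal grating condition (full-field)."""

    condition_id: int
    orientation_deg: float  # in [0, 180)
    spatial_frequency_cpd: float
    phase_deg: float


def make_sparse_noise_schedule(
    grid_shape: tuple[int, int] = (4, 3),
    dot_size_deg: float = 5.0,
    frame_duration_s: float = 0.1,
    n_frames: int = 2000,
    lattice_shape: tuple[int, int] = (32, 18),
    monitor: Monitor = DEFAULT_MONITOR,
    t0: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[SparseNoiseFrame]:
    """Generate a locally sparse noise schedule.

    The monitor is divided into a coarse scheduling grid (default 4 x 3); in
    each frame one dot is placed pseudo-randomly inside every grid cell, so
    distant parts of the visual field are stimulated in a decorrelated way.
    Candidate dot centres live on a finer lattice (default 32 x 18 across the
    monitor) so that spike-count histograms accumulate over a fixed set of
    locations. Frame polarities form a balanced, shuffled white/black
    sequence.

    Parameters
    ----------
    grid_shape
        Scheduling grid as (columns, rows).
    dot_size_deg
        Side of the square dots, degrees. Must fit inside one grid cell.
    n_frames
        Total frame count; must be even so polarities balance exactly.
    lattice_shape
        Candidate-position lattice as (n_azimuth, n_elevation); must be an
        integer multiple of ``grid_shape`` along both axes.
    """
    rng = np.random.default_rng(seed)
    n_cols, n_rows = grid_shape
    if n_cols < 1 or n_rows < 1:
        raise ValueError("grid_shape entries must be positive")
    if n_frames % 2:
        raise ValueError("n_frames must be even for a balanced polarity sequence")
    cell_w = monitor.width_deg / n_cols
    cell_h = monitor.height_deg / n_rows
    if dot_size_deg > min(cell_w, cell_h):
        raise ValueError(
            f"dot_size_deg={dot_size_deg} does not fit in a "
            f"{cell_w:.1f} x {cell_h:.1f} deg grid cell"
        )
    n_az, n_el = lattice_shape
    if n_az % n_cols or n_el % n_rows:
        raise ValueError("lattice_shape must be a multiple of grid_shape on both axes")
    az_centres, el_centres = monitor.lattice(lattice_shape)
    per_cell_az = n_az // n_cols
    per_cell_el = n_el // n_rows

    # Balanced polarity sequence, shuffled.
    polarity = np.array(["white", "black"]).repeat(n_frames // 2)
    rng.shuffle(polarity)

    frames: list[SparseNoiseFrame] = []
    for k in range(n_frames):
        dots = []
        for ci in range(n_cols):
            for ri in range(n_rows):
                ia = ci * per_cell_az + rng.integers(per_cell_az)
                ie = ri * per_cell_el + rng.integers(per_cell_el)
                dots.append((float(az_centres[ia]), float(el_centres[ie])))
        frames.append(
            SparseNoiseFrame(
                frame_index=k,
                polarity=str(polarity[k]),
                dot_positions=tuple(dots),
                dot_size_deg=dot_size_deg,
                onset_s=t0 + k * frame_duration_s,
                duration_s=frame_duration_s,
            )
        )
    return frames


def make_grating_schedule(
    n_orientations: int = 6,
    sf_values: np.ndarray | None = None,
    n_phases: int = 4,
    n_repeats: int = 5,
    duration_s: float = STIM_DURATION_S,
    period_s: float = STIM_PERIOD_S,
    t0: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[GratingCondition], pd.DataFrame]:
    """Full-factorial static-grating schedule.

    Defaults give six evenly spread orientations, five spatial frequencies
    between 0.1 and 1.6 cycles/deg and four phases — 120 conditions — each
    repeated ``n_repeats`` times in a globally shuffled order.

    Returns
    -------
    conditions, events
        The unique conditions and a tidy event table with one row per
        presentation (columns ``stim_id, stim_class, onset_s, duration_s,
        orientation, spatial_frequency, phase, repeat``).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    if sf_values is None:
        sf_values = np.geomspace(0.1, 1.6, 5)
    sf_values = np.asarray(sf_values, dtype=float)
    if np.any(sf_values <= 0):
        raise ValueError("spatial frequencies must be positive")
    oris = np.arange(n_orientations) * (180.0 / n_orientations)
    phases = np.arange(n_phases) * (360.0 / max(n_phases, 1))

    conditions = []
    cid = 0
    for ori in oris:
        for sf in sf_values:
            for ph in phases:
                conditions.append(
                    GratingCondition(
                        condition_id=cid,
                        orientation_deg=float(ori),
                        spatial_frequency_cpd=float(sf),
                        phase_deg=float(ph),
                    )
                )
                cid += 1

    order = np.repeat(np.arange(len(conditions)), n_repeats)
    rng.shuffle(order)
    rows = []
    for k, idx in enumerate(order):
        c = conditions[idx]
        rows.append(
            dict(
                stim_id=c.condition_id,
                stim_class="gratings",
                onset_s=t0 + k * period_s,
                duration_s=duration_s,
                orientation=c.orientation_deg,
                spatial_frequency=c.spatial_frequency_cpd,
                phase=c.phase_deg,
            )
        )
    events = pd.DataFrame(rows)
    events["repeat"] = events.groupby("stim_id").cumcount()
    return conditions, events


def make_image_schedule(
    image_ids: np.ndarray,
    n_repeats: int,
    stim_class: str,
    duration_s: float = STIM_DURATION_S,
    period_s: float = STIM_PERIOD_S,
    t0: float = 0.0,
    block_gap_s: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Blocked image schedule: each repeat is one shuffled pass over the bank.

    Object images are shown in ten such blocks, textures and their noise
    controls in five. The ``block`` column records the repeat block, which the
    recording-stability filter uses as its unit of inclusion.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    image_ids = np.asarray(image_ids)
    rows = []
    t = t0
    for b in range(n_repeats):
        order = rng.permutation(image_ids)
        for img in order:
            rows.append(
                dict(
                    stim_id=int(img),
                    stim_class=stim_class,
                    onset_s=t,
                    duration_s=duration_s,
                    block=b,
                )
            )
            t += period_s
        t += block_gap_s
    events = pd.DataFrame(rows)
    events["repeat"] = events["block"]
    return events


def sparse_noise_events_frame(frames: list[SparseNoiseFrame]) -> pd.DataFrame:
    """Serialize sparse-noise frames to the tidy event-table format."""
    rows = []
    for f in frames:
        rows.append(
            dict(
                stim_id=f.frame_index,
                stim_class="sparse_noise",
                onset_s=f.onset_s,
                duration_s=f.duration_s,
                params_json=json.dumps(
                    dict(
                        polarity=f.polarity,
                        dot_positions=list(map(list, f.dot_positions)),
                        dot_size_deg=f.dot_size_deg,
                    )
                ),
            )
        )
    return pd.DataFrame(rows)


def grating_events_frame(events: pd.DataFrame) -> pd.DataFrame:
    """Pack grating parameter columns into ``params_json`` for CSV export."""
    out = events[["stim_id", "stim_class", "onset_s", "duration_s"]].copy()
    out["params_json"] = [
        json.dumps(dict(orientation=o, spatial_frequency=s, phase=p))
        for o, s, p in zip(events["orientation"], events["spatial_frequency"], events["phase"])
    ]
    return out
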