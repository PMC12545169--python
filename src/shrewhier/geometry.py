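"""Monitor geometry shared by stimulus generation and receptive-field mapping.

All positions are in degrees of visual angle. The screen centre is (0, 0),
azimuth is positive rightward and elevation positive upward. The default
extent matches a monitor subtending +/-54 deg horizontally and +/-38 deg
vertically at the viewing distance used for head-fixed recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Half-extent of the stimulation monitor, degrees (azimuth, elevation).
MONITOR_HALF_EXTENT_DEG = (54.0, 38.0)

#: Image presentation rhythm: 167 ms of stimulus interleaved with 167 ms grey.
STIM_DURATION_S = 0.167
STIM_PERIOD_S = 1.0 / 3.0


@dataclass(frozen=True)
class Monitor:
    """Rectangular stimulation area in degrees of visual angle."""

    half_azimuth_deg: float = MONITOR_HALF_EXTENT_DEG[0]
    half_elevation_deg: float = MONITOR_HALF_EXTENT_DEG[1]

    @property
    def width_deg(self) -> float:
        return 2.0 * self.half_azimuth_deg

    @property
    def height_deg(self) -> float:
        return 2.0 * self.half_elevation_deg

    def contains(self, az: np.ndarray, el: np.ndarray, margin: float = 0.0) -> np.ndarray:
        az = np.asarray(az)
        el = np.asarray(el)
        return (
            (np.abs(az) <= self.half_azimuth_deg + margin)
            & (np.abs(el) <= self.half_elevation_deg + margin)
        )

    def lattice(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Centres of a ``(n_az, n_el)`` lattice tiling the monitor.

        Returns two 1-D arrays of azimuth and elevation centres.
        """
        n_az, n_el = shape
        az = -self.half_azimuth_deg + (np.arange(n_az) + 0.5) * self.width_deg / n_az
        el = -self.half_elevation_deg + (np.arange(n_el) + 0.5) * self.height_deg / n_el
        return az, el


DEFAULT_MONITOR = Monitor()
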