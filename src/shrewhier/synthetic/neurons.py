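"""Ground-truth model neurons for the forward simulator.

Every fitted quantity in the analysis pipeline has a hidden counterpart here:
receptive-field centre and width, preferred orientation and spatial
frequency, response latency, texture modulation (with its own onset), a
preferred axis in the 50-dimensional feature space, and a per-block waveform
amplitude profile for the recording-stability filter. Recovery tests compare
fits against these parameters; the analysis code never sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import DEFAULT_MONITOR, Monitor

__all__ = ["GroundTruthNeuron", "make_population", "AREA_DEFAULTS"]


@dataclass
class GroundTruthNeuron:
    """Hidden parameters of one simulated unit.

    Rates are in Hz, times in seconds, positions and widths in degrees of
    visual angle. ``axis_true`` is a unit vector in the feature principal
    subspace; ``axis_gain`` scales the (optionally rectified) ramp response
    to the z-scored projection of an image onto that axis.
    """

    unit_id: int
    area: str
    baseline_rate: float = 3.0
    latency: float = 0.05
    rf_center: tuple[float, float] = (0.0, 0.0)
    rf_sigma: float = 5.0
    rf_polarity: str = "both"  # ON | OFF | both | none
    rf_gain: float = 20.0
    pref_orientation: float = 0.0  # deg, [0, 180)
    vm_kappa: float = 2.0
    pref_sf: float = 0.4  # cycles/deg
    sf_logsigma: float = 0.7
    grating_gain: float = 15.0
    axis_true: np.ndarray | None = None
    axis_gain: float = 10.0
    axis_nonlinearity: str = "rectified"  # rectified | linear
    object_base_gain: float = 4.0
    texture_base_gain: float = 8.0
    texture_gain: float = 0.0
    texture_latency: float | None = None  # defaults to `latency`
    base_amplitude: float = 100.0
    block_amplitude_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.rf_sigma <= 0:
            raise ValueError("rf_sigma must be positive")
        if self.rf_polarity not in ("ON", "OFF", "both", "none"):
            raise ValueError(f"bad rf_polarity {self.rf_polarity!r}")
        if self.axis_nonlinearity not in ("rectified", "linear"):
            raise ValueError(f"bad axis_nonlinearity {self.axis_nonlinearity!r}")
        if self.axis_true is not None:
            a = np.asarray(self.axis_true, dtype=float)
            norm = np.linalg.norm(a)
            if norm == 0:
                raise ValueError("axis_true must be non-zero")
            self.axis_true = a / norm
        if self.texture_latency is None:
            self.texture_latency = self.latency
        if self.block_amplitude_profile is not None:
            self.block_amplitude_profile = np.asarray(self.block_amplitude_profile, dtype=float)

    def ramp(self, z: np.ndarray) -> np.ndarray:
        """Axis-model nonlinearity applied to z-scored projections."""
        z = np.asarray(z, dtype=float)
        return np.maximum(z, 0.0) if self.axis_nonlinearity == "rectified" else z


# Plausible per-area medians for a posterior-to-anterior ladder: receptive
# fields widen and latencies lengthen moving anteriorly; TP has weak spatial
# structure (few mappable RFs).
AREA_DEFAULTS: dict[str, dict] = {
    "V1": dict(rf_sigma=4.0, latency=0.040, rf_frac=0.9),
    "V2": dict(rf_sigma=7.0, latency=0.055, rf_frac=0.85),
    "Pulv": dict(rf_sigma=10.0, latency=0.060, rf_frac=0.6),
    "TP": dict(rf_sigma=12.0, latency=0.070, rf_frac=0.1),
    "TI-ITi": dict(rf_sigma=13.0, latency=0.080, rf_frac=0.5),
    "ITr": dict(rf_sigma=16.0, latency=0.090, rf_frac=0.5),
}


def make_population(
    n_units: int,
    area: str = "V1",
    n_pcs: int = 50,
    seed: int | np.random.Generator = 0,
    monitor: Monitor = DEFAULT_MONITOR,
    rf_center_spread: float = 10.0,
    rf_center_mean: tuple[float, float] = (0.0, 0.0),
    rf_sigma: float | None = None,
    latency: float | None = None,
    baseline_range: tuple[float, float] = (1.0, 8.0),
    axis_gain: float = 10.0,
    texture_gain: float = 0.0,
    texture_latency: float | None = None,
    n_blocks: int = 10,
    amplitude_drift_sd: float = 0.05,
    unit_id_start: int = 0,
) -> list[GroundTruthNeuron]:
    """Sample a population of ground-truth neurons for one area.

    Per-area receptive-field width and latency default to the
    :data:`AREA_DEFAULTS` ladder; both jitter across units (lognormal for
    sigma, +/-10 ms uniform for latency). Receptive-field centres cluster
    around ``rf_center_mean`` with spread ``rf_center_spread``, mimicking the
    retinotopic clustering of a single penetration. Preferred axes are drawn
    uniformly on the unit sphere of the ``n_pcs``-dimensional feature space
    with a bias toward the first components (where most stimulus variance
    lives). Block amplitude profiles drift multiplicatively around 1.
    """
    rng = np.random.default_rng(seed)
    defaults = AREA_DEFAULTS.get(area, AREA_DEFAULTS["V1"])
    sigma0 = rf_sigma if rf_sigma is not None else defaults["rf_sigma"]
    lat0 = latency if latency is not None else defaults["latency"]
    rf_frac = defaults.get("rf_frac", 0.8)

    neurons = []
    for k in range(n_units):
        raw_axis = rng.standard_normal(n_pcs)
        raw_axis[: min(5, n_pcs)] *= 3.0  # bias toward leading components
        has_rf = rng.random() < rf_frac
        polarity = rng.choice(["ON", "OFF", "both"]) if has_rf else "none"
        neurons.append(
            GroundTruthNeuron(
                unit_id=unit_id_start + k,
                area=area,
                baseline_rate=float(rng.uniform(*baseline_range)),
                latency=float(np.clip(lat0 + rng.uniform(-0.01, 0.01), 0.01, None)),
                rf_center=(
                    float(rf_center_mean[0] + rng.normal(0, rf_center_spread)),
                    float(rf_center_mean[1] + rng.normal(0, rf_center_spread)),
                ),
                rf_sigma=float(sigma0 * rng.lognormal(0, 0.2)),
                rf_polarity=str(polarity),
                rf_gain=float(rng.uniform(15, 40)),
                pref_orientation=float(rng.uniform(0, 180)),
                vm_kappa=float(rng.uniform(1.0, 3.0)),
                pref_sf=float(np.exp(rng.uniform(np.log(0.15), np.log(1.2)))),
                sf_logsigma=float(rng.uniform(0.5, 1.0)),
                grating_gain=float(rng.uniform(10, 30)),
                axis_true=raw_axis,
                axis_gain=float(axis_gain),
                texture_base_gain=float(rng.uniform(5, 12)),
                texture_gain=float(texture_gain),
                texture_latency=texture_latency,
                base_amplitude=float(rng.uniform(60, 150)),
                block_amplitude_profile=np.clip(
                    1.0 + rng.normal(0, amplitude_drift_sd, n_blocks).cumsum() * 0.3, 0.2, None
                ),
            )
        )
    return neurons
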