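"""Synthetic HIFU heating/cooling experiments.

Real acquisitions pair an ellipsoidal focal hot spot with four thermocouple
traces and three ultrasound-derived modality images (B-mode, elastography,
Doppler).  This module emulates those experiments end to end:

* an exponential-approach / exponential-decay temperature field with a
  Gaussian-ellipsoid spatial footprint (a deliberately simple bioheat
  stand-in — the hot spot grows sigmoidally while the transducer is on and
  relaxes exponentially after it stops);
* virtual thermocouples read by bilinear interpolation at millimetre
  positions;
* three modality renderers, each a smooth strictly monotone map of local
  temperature plus i.i.d. Gaussian pixel noise, with a slope change above
  the coagulative-necrosis threshold (~52 degC) and an optional focal
  displacement drift on the B-mode-like channel that mimics tissue being
  pushed away from the focus as necrosis develops;
* patch extraction around probe positions and a seeded train/validation
  split.

All stochastic operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "HeatingScenario",
    "FieldSequence",
    "ModalityImageSequence",
    "MultimodalPatchSet",
    "heating_envelope",
    "simulate_temperature_history",
    "modality_map",
    "invert_modality_map",
    "render_modalities",
    "extract_patch_dataset",
    "split_dataset",
    "in_vivo_scenario",
    "phantom_scenario",
    "in_vitro_scenario",
]

MODALITY_NAMES = ("UBI", "UEI", "UDI")


def _default_probes(focal_center, spacing_mm=3.0, n=4):
    """Probes along the lateral axis, first at the focal center, 3 mm apart."""
    a, l = focal_center
    return tuple((a, l + i * spacing_mm) for i in range(n))


@dataclass(frozen=True)
class HeatingScenario:
    """Configuration of one synthetic heating/cooling experiment.

    Positions are (axial_mm, lateral_mm); image row = axial (depth),
    column = lateral.  ``focal_dims`` are Gaussian sigmas matching the
    ellipsoid semi-axes of a nominal 3 x 3 x 5 mm focal zone reduced to the
    axial-lateral imaging plane (axial sigma 2.5 mm, lateral 1.5 mm).
    ``duty_cycle`` / ``center_freq_hz`` / ``intensity_kw_cm2`` are acquisition
    metadata recorded but never used by the heat model.
    """

    focal_center: tuple[float, float] = (16.0, 10.0)
    focal_dims: tuple[float, float] = (2.5, 1.5)
    peak_delta_T: float = 15.0
    baseline_T: float = 37.0
    tau_heat: float = 200.0
    tau_cool: float = 300.0
    heat_on_interval: tuple[float, float] = (0.0, 900.0)
    probe_positions: tuple[tuple[float, float], ...] | None = None
    denaturation_T: float = 52.0
    duty_cycle: float = 0.65
    center_freq_hz: float = 1.0e6
    intensity_kw_cm2: float = 5.0
    dt: float = 0.2
    grid_spacing: float = 0.5
    image_dims: tuple[int, int] = (64, 64)
    displacement: bool = False
    displacement_max_mm: float = 1.0
    displacement_tau: float = 120.0
    noise_sigma: tuple[float, ...] = (0.02, 0.02, 0.02)
    name: str = "custom"

    def __post_init__(self):
        if self.probe_positions is None:
            object.__setattr__(
                self, "probe_positions", _default_probes(self.focal_center)
            )
        else:
            object.__setattr__(
                self,
                "probe_positions",
                tuple(tuple(float(x) for x in p) for p in self.probe_positions),
            )
        self.validate()

    def validate(self) -> None:
        scalars = [
            self.peak_delta_T, self.baseline_T, self.tau_heat, self.tau_cool,
            self.denaturation_T, self.dt, self.grid_spacing,
            *self.focal_center, *self.focal_dims, *self.heat_on_interval,
        ]
        if not np.all(np.isfinite(scalars)):
            raise ValueError("scenario parameters must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if min(self.focal_dims) <= 0:
            raise ValueError("focal_dims must be > 0")
        if self.tau_heat <= 0 or self.tau_cool <= 0:
            raise ValueError("tau_heat and tau_cool must be > 0")
        if self.heat_on_interval[1] < self.heat_on_interval[0]:
            raise ValueError("heat_on_interval must be ordered (start, stop)")
        h, w = self.image_dims
        max_ax = (h - 1) * self.grid_spacing
        max_lat = (w - 1) * self.grid_spacing
        for i, (a, l) in enumerate(self.probe_positions):
            if not (0.0 <= a <= max_ax and 0.0 <= l <= max_lat):
                raise ValueError(
                    f"probe {i} at ({a}, {l}) mm lies outside the "
                    f"{max_ax} x {max_lat} mm image grid"
                )

    def probe_pixels(self) -> np.ndarray:
        """Probe positions in fractional pixel coordinates, shape (P, 2)."""
        return np.asarray(self.probe_positions, dtype=float) / self.grid_spacing

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HeatingScenario":
        d = dict(d)
        for key in ("focal_center", "focal_dims", "heat_on_interval", "image_dims",
                    "noise_sigma"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("probe_positions") is not None:
            d["probe_positions"] = tuple(tuple(p) for p in d["probe_positions"])
        return cls(**d)


@dataclass
class FieldSequence:
    """Ground-truth temperature frames plus virtual thermocouple readings."""

    frames: np.ndarray          # (T, H, W) degC
    times: np.ndarray           # (T,) s
    probe_readings: np.ndarray  # (T, P) degC
    scenario: HeatingScenario

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ModalityImageSequence:
    """Rendered modality images aligned frame-by-frame with a FieldSequence."""

    images: np.ndarray                 # (M, T, H, W)
    modality_names: tuple[str, ...]
    noise_params: tuple[float, ...]
    seed: int

    @property
    def n_modalities(self) -> int:
        return self.images.shape[0]


@dataclass
class MultimodalPatchSet:
    """Aligned multimodal patches X* (M, S, H, W) with temperature labels Y (S,)."""

    patches: np.ndarray       # (M, S, H, W)
    labels: np.ndarray        # (S,) degC
    frame_index: np.ndarray   # (S,)
    probe_index: np.ndarray   # (S,)
    modality_names: tuple[str, ...] = MODALITY_NAMES

    @property
    def n_samples(self) -> int:
        return self.patches.shape[1]

    def take(self, indices) -> "MultimodalPatchSet":
        idx = np.asarray(indices)
        return MultimodalPatchSet(
            patches=self.patches[:, idx],
            labels=self.labels[idx],
            frame_index=self.frame_index[idx],
            probe_index=self.probe_index[idx],
            modality_names=self.modality_names,
        )

    def target_modality(self, name: str = "UBI") -> np.ndarray:
        """Patches of a single (target) modality, shape (S, H, W)."""
        m = self.modality_names.index(name)
        return self.patches[m]


def heating_envelope(scenario: HeatingScenario, t) -> np.ndarray:
    """Normalized source envelope e(t) in [0, 1).

    Exponential approach toward 1 with tau_heat while the transducer is on,
    exponential decay with tau_cool after it stops.
    """
    t = np.asarray(t, dtype=float)
    t0, t1 = scenario.heat_on_interval
    e_stop = 1.0 - np.exp(-(t1 - t0) / scenario.tau_heat)
    heating = 1.0 - np.exp(-np.clip(t - t0, 0.0, None) / scenario.tau_heat)
    cooling = e_stop * np.exp(-np.clip(t - t1, 0.0, None) / scenario.tau_cool)
    env = np.where(t < t0, 0.0, np.where(t <= t1, heating, cooling))
    return env


def gaussian_footprint(scenario: HeatingScenario) -> np.ndarray:
    """Spatial weight G(x) on the pixel grid; G = 1 at the focal center."""
    h, w = scenario.image_dims
    ax = np.arange(h) * scenario.grid_spacing
    lat = np.arange(w) * scenario.grid_spacing
    da = (ax - scenario.focal_center[0]) / scenario.focal_dims[0]
    dl = (lat - scenario.focal_center[1]) / scenario.focal_dims[1]
    return np.exp(-0.5 * (da[:, None] ** 2 + dl[None, :] ** 2))


def bilinear_at(image: np.ndarray, points_px: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a 2D image at fractional (row, col) pixels."""
    pts = np.asarray(points_px, dtype=float)
    return ndimage.map_coordinates(image, pts.T, order=1, mode="nearest")


def simulate_temperature_history(scenario: HeatingScenario, duration: float) -> FieldSequence:
    """Simulate T = floor(duration/dt)+1 temperature frames.

    The field is ``baseline + peak_delta_T * e(t) * G(x)`` with the
    envelope of :func:`heating_envelope` and the Gaussian-ellipsoid
    footprint ``G``.  Probe readings are bilinear samples of the frames at
    the scenario's probe positions (exact, since interpolation is linear in
    the field).
    """
    scenario.validate()
    if duration < scenario.dt:
        raise ValueError("duration must be at least one sampling interval")
    t0, t1 = scenario.heat_on_interval
    if t0 < 0 or t1 > duration:
        raise ValueError("heat_on_interval must lie within [0, duration]")

    n = int(np.floor(duration / scenario.dt)) + 1
    times = np.arange(n) * scenario.dt
    env = heating_envelope(scenario, times)
    G = gaussian_footprint(scenario)
    frames = scenario.baseline_T + scenario.peak_delta_T * env[:, None, None] * G[None]
    g_probe = bilinear_at(G, scenario.probe_pixels())
    probe_readings = scenario.baseline_T + scenario.peak_delta_T * np.outer(env, g_probe)
    return FieldSequence(frames=frames, times=times,
                         probe_readings=probe_readings, scenario=scenario)


# --- modality rendering ----------------------------------------------------
#
# Each modality applies a strictly monotone map phi_m to an "effective
# temperature" v(T): v = T below the denaturation threshold, slope doubled
# above it (continuous).  The maps are stand-ins -- no quantitative
# temperature-to-intensity relation is published for these modalities -- but
# they preserve the property the learning method relies on: local image
# statistics vary monotonically with temperature.

_PHI3_SCALE = 0.08


def _regime(T, denaturation_T):
    T = np.asarray(T, dtype=float)
    return np.where(T <= denaturation_T, T, denaturation_T + 2.0 * (T - denaturation_T))


def _regime_inv(v, denaturation_T):
    v = np.asarray(v, dtype=float)
    return np.where(v <= denaturation_T, v, denaturation_T + 0.5 * (v - denaturation_T))


def modality_map(T, modality: int, denaturation_T: float = 52.0) -> np.ndarray:
    """Noise-free intensity phi_m(T) for modality index 0 (UBI-like, affine),
    1 (UEI-like, saturating) or 2 (UDI-like, accelerating exponential)."""
    v = _regime(T, denaturation_T)
    if modality == 0:
        return 0.10 + 0.018 * (v - 20.0)
    if modality == 1:
        return 0.5 + 0.45 * np.tanh((v - 45.0) / 12.0)
    if modality == 2:
        return _PHI3_SCALE * np.exp((v - 20.0) / 20.0)
    raise ValueError(f"unknown modality index {modality}")


def invert_modality_map(intensity, modality: int, denaturation_T: float = 52.0) -> np.ndarray:
    """Analytic inverse of :func:`modality_map` (valid for noise-free input)."""
    I = np.asarray(intensity, dtype=float)
    if modality == 0:
        v = 20.0 + (I - 0.10) / 0.018
    elif modality == 1:
        v = 45.0 + 12.0 * np.arctanh(np.clip((I - 0.5) / 0.45, -1 + 1e-15, 1 - 1e-15))
    elif modality == 2:
        v = 20.0 + 20.0 * np.log(I / _PHI3_SCALE)
    else:
        raise ValueError(f"unknown modality index {modality}")
    return _regime_inv(v, denaturation_T)


def displacement_drift(field: FieldSequence) -> np.ndarray:
    """Axial drift (mm) of the B-mode hot-spot appearance per frame.

    Accumulates while the field maximum exceeds the denaturation threshold,
    saturating at ``displacement_max_mm`` -- a stand-in for tissue being
    displaced by coagulative necrosis, which moves the bright vaporization
    region away from the positioning point.
    """
    sc = field.scenario
    hot = field.frames.max(axis=(1, 2)) >= sc.denaturation_T
    time_above = np.cumsum(hot) * sc.dt
    return sc.displacement_max_mm * (1.0 - np.exp(-time_above / sc.displacement_tau))


def render_modalities(
    field: FieldSequence,
    scenario: HeatingScenario | None = None,
    noise_params=None,
    seed: int | None = None,
) -> ModalityImageSequence:
    """Render the three modality image sequences from a temperature history.

    ``seed`` is mandatory: rendering is the only stochastic step in the
    simulator and must be reproducible bit-for-bit.
    """
    if seed is None:
        raise ValueError("render_modalities requires an explicit integer seed")
    sc = scenario if scenario is not None else field.scenario
    sigmas = tuple(float(s) for s in (noise_params if noise_params is not None
                                      else sc.noise_sigma))
    if len(sigmas) != len(MODALITY_NAMES):
        raise ValueError(f"need {len(MODALITY_NAMES)} noise sigmas, got {len(sigmas)}")
    if min(sigmas) < 0:
        raise ValueError("noise sigmas must be >= 0")

    rng = np.random.default_rng(seed)
    n_frames = field.frames.shape[0]
    images = np.empty((len(MODALITY_NAMES),) + field.frames.shape, dtype=float)

    drift_px = None
    if sc.displacement:
        drift_px = displacement_drift(field) / sc.grid_spacing

    for m in range(len(MODALITY_NAMES)):
        source = field.frames
        if m == 0 and drift_px is not None:
            source = np.empty_like(field.frames)
            for t in range(n_frames):
                if drift_px[t] > 0:
                    # shift the apparent pattern toward shallower depth
                    source[t] = ndimage.shift(
                        field.frames[t], (drift_px[t], 0.0), order=1, mode="nearest"
                    )
                else:
                    source[t] = field.frames[t]
        images[m] = modality_map(source, m, sc.denaturation_T)
        if sigmas[m] > 0:
            images[m] += rng.normal(0.0, sigmas[m], size=images[m].shape)
    return ModalityImageSequence(images=images, modality_names=MODALITY_NAMES,
                                 noise_params=sigmas, seed=int(seed))


def extract_patch_dataset(
    images: ModalityImageSequence,
    field: FieldSequence,
    probe_positions=None,
    patch_size: int = 16,
) -> MultimodalPatchSet:
    """Cut aligned patches of every modality around each probe in each frame.

    Sample ``(t, p)`` (ordered frame-major) is the ``patch_size`` square
    whose top-left corner is ``round(probe_px) - patch_size//2`` (0-based,
    half-open ranges, row = axial), labelled with the probe reading of that
    frame.
    """
    sc = field.scenario
    if probe_positions is None:
        probe_positions = sc.probe_positions
    probes_px = np.asarray(probe_positions, dtype=float) / sc.grid_spacing
    centers = np.rint(probes_px).astype(int)
    half = patch_size // 2
    M, T, H, W = images.images.shape
    P = len(centers)

    for p, (r, c) in enumerate(centers):
        r0, c0 = r - half, c - half
        if r0 < 0 or c0 < 0 or r0 + patch_size > H or c0 + patch_size > W:
            raise ValueError(
                f"probe {p} at pixel ({r}, {c}) is too close to the image "
                f"border for a {patch_size} x {patch_size} patch"
            )

    patches = np.empty((M, T, P, patch_size, patch_size), dtype=float)
    for p, (r, c) in enumerate(centers):
        r0, c0 = r - half, c - half
        patches[:, :, p] = images.images[:, :, r0:r0 + patch_size, c0:c0 + patch_size]
    patches = patches.reshape(M, T * P, patch_size, patch_size)

    labels = field.probe_readings[:, :P].reshape(T * P)
    frame_index = np.repeat(np.arange(T), P)
    probe_index = np.tile(np.arange(P), T)
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels contain non-finite values")
    return MultimodalPatchSet(patches=patches, labels=labels,
                              frame_index=frame_index, probe_index=probe_index,
                              modality_names=images.modality_names)


def split_dataset(ds: MultimodalPatchSet, ratio: float = 0.7, seed: int | None = None):
    """Seeded 7:3-style split; floor(S*ratio) samples train, remainder validate."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    S = ds.n_samples
    if S < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(S)
    n_train = int(np.floor(S * ratio))
    train_idx = np.sort(perm[:n_train])
    val_idx = np.sort(perm[n_train:])
    return ds.take(train_idx), ds.take(val_idx)


# --- study-condition presets ------------------------------------------------

def in_vivo_scenario() -> HeatingScenario:
    """Closed-loop heat (0-900 s) and cool (to 2500 s) run at 37 degC baseline.

    The focal peak approaches the ~52 degC denaturation onset; four probes
    sit 3 mm apart along the lateral axis starting at the focal center.
    """
    return HeatingScenario(
        name="in_vivo",
        baseline_T=37.0,
        peak_delta_T=15.0,
        tau_heat=200.0,
        tau_cool=300.0,
        heat_on_interval=(0.0, 900.0),
        noise_sigma=(0.02, 0.02, 0.02),
        displacement=False,
    )


def phantom_scenario() -> HeatingScenario:
    """Heating-only tissue-mimicking phantom run: 25 degC baseline, low noise,
    peak below the denaturation threshold, no displacement artifact."""
    return HeatingScenario(
        name="phantom",
        baseline_T=25.0,
        peak_delta_T=18.0,
        tau_heat=150.0,
        tau_cool=200.0,
        heat_on_interval=(0.0, 600.0),
        noise_sigma=(0.005, 0.005, 0.005),
        displacement=False,
    )


def in_vitro_scenario() -> HeatingScenario:
    """Ex vivo muscle-like run heated through the denaturation regime with the
    focal displacement artifact switched on."""
    return HeatingScenario(
        name="in_vitro",
        baseline_T=25.0,
        peak_delta_T=32.0,
        tau_heat=180.0,
        tau_cool=250.0,
        heat_on_interval=(0.0, 700.0),
        noise_sigma=(0.015, 0.015, 0.015),
        displacement=True,
        displacement_max_mm=1.0,
        displacement_tau=120.0,
    )


def with_sampling(scenario: HeatingScenario, dt: float) -> HeatingScenario:
    """Scenario copy resampled at a coarser interval (e.g. 10x the native
    200 ms acquisition period for desk-scale runs)."""
    return replace(scenario, dt=dt)
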