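"""Synthetic two-group cohorts of trial-wise cortical source activity.

The generator stands in for a clinical event-related EEG study in which the
quantity of interest is the current density on a registered spherical
cortical surface: every subject contributes a few hundred single trials,
each a vertices x time array.  Both groups share the same evoked response —
temporal Gaussian components at fixed latencies inside fixed cortical
regions riding on spatially correlated background noise — but in the
patient group the amplitude of one component (the region of interest within
a given latency window) is attenuated by a multiplicative factor ``delta``.
That attenuation is the planted ground truth the downstream classifier and
saliency analysis are expected to recover.

Clinical/cognitive scores correlated with the per-subject effective effect
amplitude can be attached to the cohort table, so that the correlation
stage of the analysis has a known population target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .geometry import (
    angular_distance,
    fibonacci_sphere,
    latlon,
    random_rotation,
    unit_vector,
)

__all__ = [
    "SurfaceGeometry",
    "LeadField",
    "SourceTrialSet",
    "EvokedComponent",
    "EffectSpec",
    "make_sphere_surface",
    "make_lead_field",
    "region_nearest",
    "simulate_subject",
    "simulate_cohort",
    "iter_subject_trials",
    "simulate_clinical_scores",
    "preprocess_trial",
]


@dataclass(frozen=True)
class SurfaceGeometry:
    """Vertices on a registered unit sphere with a region parcellation."""

    vertex_coords: np.ndarray  # (n_vertices, 3), unit norm
    region_labels: np.ndarray  # (n_vertices,) int region ids

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_regions(self) -> int:
        return int(self.region_labels.max()) + 1

    def region_mask(self, region_id: int) -> np.ndarray:
        mask = self.region_labels == region_id
        if not mask.any():
            raise ValueError(f"unknown region id {region_id}")
        return mask


@dataclass(frozen=True)
class LeadField:
    """Gain matrix mapping source amplitudes to sensor measurements."""

    gain: np.ndarray  # (n_channels, n_vertices)
    channel_coords: np.ndarray  # (n_channels, 3) sensor sites on the sphere

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]


@dataclass
class SourceTrialSet:
    """Per-subject trials x vertices x time current density (a.u.)."""

    data: np.ndarray
    t_start_ms: float
    t_end_ms: float
    fs_hz: float
    subject_id: str
    group: str  # "control" | "patient"

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[-1]
        return self.t_start_ms + np.arange(n) * 1000.0 / self.fs_hz

    def __post_init__(self) -> None:
        n_expected = round((self.t_end_ms - self.t_start_ms) / 1000.0 * self.fs_hz)
        if self.data.shape[-1] != n_expected:
            raise ValueError(
                f"time axis length {self.data.shape[-1]} does not match epoch "
                f"[{self.t_start_ms}, {self.t_end_ms}) ms at {self.fs_hz} Hz "
                f"(expected {n_expected})"
            )


@dataclass(frozen=True)
class EvokedComponent:
    """One temporal Gaussian bump confined to a cortical region."""

    region_id: int
    latency_ms: float
    width_ms: float  # Gaussian SD of the temporal envelope
    amplitude: float


@dataclass(frozen=True)
class EffectSpec:
    """Cohort-level simulation parameters, including the planted effect.

    ``delta`` multiplies the amplitude of the component whose region is
    ``roi_region_id`` (the one overlapping ``window_ms``) in the patient
    group only; ``delta = 1`` plants no effect.  ``noise_sd`` is the
    per-vertex SD of the spatially correlated background, in the same
    arbitrary units as the component amplitudes; ``subject_sd`` scales the
    between-subject variability of the overall evoked amplitude.
    """

    roi_region_id: int = 0
    window_ms: tuple[float, float] = (300.0, 350.0)
    delta: float = 0.5
    components: tuple[EvokedComponent, ...] = ()
    noise_sd: float = 0.5
    subject_sd: float = 0.2
    noise_length_scale_rad: float = 0.3
    n_noise_modes: int = 192
    t_start_ms: float = -1200.0
    t_end_ms: float = 800.0
    fs_hz: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        lo, hi = self.window_ms
        if not (self.t_start_ms <= lo < hi <= self.t_end_ms):
            raise ValueError("effect window must lie inside the epoch")


def default_components(surface: SurfaceGeometry) -> tuple[EvokedComponent, ...]:
    """Two evoked components mimicking an early visual and a late parietal
    response: an occipital bump at 200 ms and a right-parietal bump at
    325 ms (latencies in the N1 / P300 range)."""
    occ = region_nearest(surface, lat_rad=-0.2, lon_rad=3.0)
    par = region_nearest(surface, lat_rad=0.7, lon_rad=2.6)
    if par == occ:  # coarse parcellations can merge the two sites
        centers = _region_centers(surface)
        order = np.argsort(
            angular_distance(centers, unit_vector(0.7, 2.6)).ravel()
        )
        par = int(order[1]) if len(order) > 1 else occ
    return (
        EvokedComponent(region_id=occ, latency_ms=200.0, width_ms=25.0, amplitude=1.0),
        EvokedComponent(region_id=par, latency_ms=325.0, width_ms=20.0, amplitude=1.0),
    )


def default_effect_spec(surface: SurfaceGeometry, **overrides) -> EffectSpec:
    """EffectSpec with the default component layout for *surface*; the
    planted effect sits on the parietal 325 ms component (window
    300-350 ms)."""
    comps = default_components(surface)
    spec = EffectSpec(roi_region_id=comps[1].region_id, components=comps)
    return replace(spec, **overrides) if overrides else spec


def make_sphere_surface(
    n_vertices: int, n_regions: int, seed: int = 0
) -> SurfaceGeometry:
    """Near-uniform spherical vertex set with a Voronoi parcellation.

    Vertices form a Fibonacci lattice; region seed points are a second,
    randomly rotated Fibonacci lattice, and each vertex takes the label of
    its nearest seed (spherical Voronoi cells).  Deterministic given *seed*.
    """
    if n_vertices < 1 or n_regions < 1 or n_regions > n_vertices:
        raise ValueError(
            f"need n_vertices >= n_regions >= 1, got {n_vertices}, {n_regions}"
        )
    coords = fibonacci_sphere(n_vertices)
    rng = np.random.default_rng(seed)
    seeds = fibonacci_sphere(n_regions) @ random_rotation(rng).T
    labels = np.argmax(coords @ seeds.T, axis=1)
    # relabel so ids are contiguous even if a cell is empty
    uniq, labels = np.unique(labels, return_inverse=True)
    return SurfaceGeometry(vertex_coords=coords, region_labels=labels)


def _region_centers(surface: SurfaceGeometry) -> np.ndarray:
    centers = np.empty((surface.n_regions, 3))
    for r in range(surface.n_regions):
        c = surface.vertex_coords[surface.region_labels == r].mean(axis=0)
        centers[r] = c / np.linalg.norm(c)
    return centers


def region_nearest(surface: SurfaceGeometry, lat_rad: float, lon_rad: float) -> int:
    """Id of the region whose centroid is closest to a given direction."""
    target = unit_vector(lat_rad, lon_rad)
    return int(np.argmax(_region_centers(surface) @ target))


def make_lead_field(
    surface: SurfaceGeometry,
    n_channels: int,
    seed: int = 0,
    sensor_spread_rad: float = 0.6,
) -> LeadField:
    """Smooth synthetic gain matrix: each sensor's sensitivity decays as a
    Gaussian of the angular distance between the vertex and the sensor
    site.  Sensor sites are a randomly rotated Fibonacci lattice."""
    if n_channels < 2:
        raise ValueError(f"need at least 2 channels, got {n_channels}")
    rng = np.random.default_rng(seed)
    sites = fibonacci_sphere(n_channels) @ random_rotation(rng).T
    dist = angular_distance(sites, surface.vertex_coords)
    gain = np.exp(-0.5 * (dist / sensor_spread_rad) ** 2)
    return LeadField(gain=gain, channel_coords=sites)


# ---------------------------------------------------------------------------
# cohort simulation


def _noise_basis(surface: SurfaceGeometry, spec: EffectSpec) -> np.ndarray:
    """(n_vertices, n_modes) mixing matrix for spatially correlated noise.

    Latent white-noise modes live at quasi-uniform directions; vertices mix
    them with Gaussian weights of angular distance (length scale
    ``noise_length_scale_rad``), rows scaled to unit variance so the
    per-vertex noise SD is exactly ``noise_sd``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6E6F]))
    modes = fibonacci_sphere(spec.n_noise_modes) @ random_rotation(rng).T
    dist = angular_distance(surface.vertex_coords, modes)
    b = np.exp(-0.5 * (dist / spec.noise_length_scale_rad) ** 2)
    norms = np.sqrt((b**2).sum(axis=1, keepdims=True))
    return (b / norms).astype(np.float32)


def _component_templates(
    surface: SurfaceGeometry, spec: EffectSpec, times_ms: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    """Per component: (vertex indicator, temporal envelope, is_roi)."""
    out = []
    for comp in spec.components:
        space = surface.region_mask(comp.region_id).astype(np.float32)
        env = comp.amplitude * np.exp(
            -0.5 * ((times_ms - comp.latency_ms) / comp.width_ms) ** 2
        )
        out.append((space, env.astype(np.float32), comp.region_id == spec.roi_region_id))
    return out


def _subject_rng(spec: EffectSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 1 + subject_index]))


def simulate_subject(
    surface: SurfaceGeometry,
    spec: EffectSpec,
    subject_index: int,
    group: str,
    n_trials: int,
    _basis: np.ndarray | None = None,
) -> tuple[SourceTrialSet, float]:
    """Simulate one subject; returns the trial set and the effective planted
    amplitude a_s (subject evoked scale, times delta for patients)."""
    if group not in ("control", "patient"):
        raise ValueError(f"group must be 'control' or 'patient', got {group!r}")
    rng = _subject_rng(spec, subject_index)
    basis = _noise_basis(surface, spec) if _basis is None else _basis
    n_t = round((spec.t_end_ms - spec.t_start_ms) / 1000.0 * spec.fs_hz)
    times = spec.t_start_ms + np.arange(n_t) * 1000.0 / spec.fs_hz

    subject_scale = float(max(rng.normal(1.0, spec.subject_sd), 0.05))
    a_s = subject_scale * (spec.delta if group == "patient" else 1.0)

    evoked = np.zeros((surface.n_vertices, n_t), dtype=np.float32)
    for space, env, is_roi in _component_templates(surface, spec, times):
        amp = a_s if is_roi else subject_scale
        evoked += amp * space[:, None] * env[None, :]

    # one latent draw and one mixing GEMM for all trials of the subject
    latent = rng.standard_normal((basis.shape[1], n_trials * n_t)).astype(np.float32)
    noise = (spec.noise_sd * (basis @ latent)).reshape(
        surface.n_vertices, n_trials, n_t
    )
    data = np.ascontiguousarray(noise.transpose(1, 0, 2))
    data += evoked[None]

    trials = SourceTrialSet(
        data=data,
        t_start_ms=spec.t_start_ms,
        t_end_ms=spec.t_end_ms,
        fs_hz=spec.fs_hz,
        subject_id=f"{'ctl' if group == 'control' else 'pat'}{subject_index:03d}",
        group=group,
    )
    return trials, a_s


def simulate_cohort(
    surface: SurfaceGeometry,
    spec: EffectSpec,
    n_per_group: int,
    n_trials: int,
) -> tuple[pd.DataFrame, list[SourceTrialSet]]:
    """Simulate a full two-group cohort, materializing every subject.

    Returns the cohort table (subject_id, group, a_s, n_trials, seed) and a
    list of per-subject trial sets.  For cohorts too large to hold in
    memory use :func:`iter_subject_trials` instead, which regenerates the
    identical subjects lazily.
    """
    table = cohort_table(spec, n_per_group, n_trials)
    basis = _noise_basis(surface, spec)
    sets = []
    for idx, row in table.iterrows():
        trials, a_s = simulate_subject(
            surface, spec, int(row["subject_index"]), row["group"], n_trials, basis
        )
        assert abs(a_s - row["a_s"]) < 1e-12
        sets.append(trials)
    return table, sets


def cohort_table(spec: EffectSpec, n_per_group: int, n_trials: int) -> pd.DataFrame:
    """Cohort metadata with the ground-truth planted amplitude a_s.

    a_s is reproduced from the same per-subject random streams the trial
    simulation uses, so the table is consistent with the trial data without
    simulating any trial.
    """
    if n_per_group < 1 or n_trials < 1:
        raise ValueError("n_per_group and n_trials must be >= 1")
    rows = []
    for idx in range(2 * n_per_group):
        group = "control" if idx < n_per_group else "patient"
        rng = _subject_rng(spec, idx)
        subject_scale = float(max(rng.normal(1.0, spec.subject_sd), 0.05))
        a_s = subject_scale * (spec.delta if group == "patient" else 1.0)
        rows.append(
            {
                "subject_id": f"{'ctl' if group == 'control' else 'pat'}{idx:03d}",
                "subject_index": idx,
                "group": group,
                "a_s": a_s,
                "n_trials": n_trials,
                "seed": spec.seed,
            }
        )
    return pd.DataFrame(rows)


def iter_subject_trials(
    surface: SurfaceGeometry,
    spec: EffectSpec,
    cohort: pd.DataFrame,
):
    """Yield (row, SourceTrialSet) per cohort subject without holding the
    whole cohort in memory.  Deterministic: re-iterating regenerates
    bit-identical data."""
    basis = _noise_basis(surface, spec)
    for _, row in cohort.iterrows():
        trials, _ = simulate_subject(
            surface,
            spec,
            int(row["subject_index"]),
            row["group"],
            int(row["n_trials"]),
            basis,
        )
        yield row, trials


def simulate_clinical_scores(
    cohort: pd.DataFrame,
    rho_target: float,
    score_name: str = "score",
    score_mean: float = 0.0,
    score_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach a clinical score column correlated with the planted amplitude.

    The score is a linear transform of the standardized a_s plus Gaussian
    noise with weights (rho, sqrt(1-rho^2)), so the population correlation
    with a_s is exactly ``rho_target`` and the sample correlation converges
    to it as the cohort grows.  ``rho_target = +/-1`` yields a noiseless
    deterministic score.
    """
    if abs(rho_target) > 1.0:
        raise ValueError(f"|rho_target| must be <= 1, got {rho_target}")
    if score_sd <= 0:
        raise ValueError("score_sd must be positive")
    a = cohort["a_s"].to_numpy(dtype=float)
    z = (a - a.mean()) / a.std(ddof=0) if a.std(ddof=0) > 0 else np.zeros_like(a)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(a))
    latent = rho_target * z + np.sqrt(1.0 - rho_target**2) * noise
    out = cohort.copy()
    out[score_name] = score_mean + score_sd * latent
    return out


def preprocess_trial(
    trial: np.ndarray,
    fs_hz: float,
    t_start_ms: float,
    lowpass_hz: float = 30.0,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    filter_order: int = 4,
) -> np.ndarray:
    """Zero-phase lowpass plus pre-stimulus baseline correction.

    Applies a forward-backward Butterworth lowpass (cutoff ``lowpass_hz``)
    along the time axis of a vertices x time array, then subtracts each
    vertex's mean over the baseline window so the post-baseline mean is
    exactly zero.  The epoch must cover the baseline window.
    """
    trial = np.asarray(trial)
    n_t = trial.shape[-1]
    times = t_start_ms + np.arange(n_t) * 1000.0 / fs_hz
    b0, b1 = baseline_ms
    in_baseline = (times >= b0) & (times < b1)
    if not in_baseline.any():
        raise ValueError(
            f"epoch starting at {t_start_ms} ms does not cover the baseline "
            f"window [{b0}, {b1}) ms"
        )
    sos = signal.butter(filter_order, lowpass_hz, btype="low", fs=fs_hz, output="sos")
    # filter flattened and chunked in the input precision: the whole-array
    # call churns far more memory than the arithmetic needs
    flat = np.ascontiguousarray(trial).reshape(-1, n_t)
    out = np.empty_like(flat)
    step = 8192
    for i in range(0, flat.shape[0], step):
        out[i : i + step] = signal.sosfiltfilt(sos, flat[i : i + step], axis=-1)
    out = out.reshape(trial.shape)
    out = out - out[..., in_baseline].mean(axis=-1, keepdims=True).astype(out.dtype)
    return out
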