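"""Synthetic lung phantoms for desk-scale elasticity-heterogeneity analysis.

A phantom emulates the study inputs: an end-exhalation attenuation volume
(HU) with five disjoint lobe labels, a ground-truth per-voxel Young's
modulus map with controllable inter- and intralobar heterogeneity, a
bellows-like breathing amplitude/flow signal sampled at 100 Hz, and a set
of displacement vector fields (DVFs) standing in for scans deformably
registered to a reference geometry.

Elasticity within each lobe is drawn from a two-component log-normal
mixture: a "healthy" component and a soft "diseased" component whose mass
sits inside the 1-3 kPa COPD biomarker band. The mixture weight is
calibrated analytically so the expected fraction of voxels in the band
equals the lobe's diseased-fraction target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

# Lobe labelling convention (0 = background):
#   1 = left upper, 2 = left lower, 3 = right upper, 4 = right middle,
#   5 = right lower.
LOBE_LABELS = (1, 2, 3, 4, 5)

#: HU threshold separating parenchyma (strictly below) from vessels/tumor.
PARENCHYMA_HU_THRESHOLD = -700.0

#: COPD biomarker band in kPa: low elasticity indicates diseased tissue.
BIOMARKER_BAND = (1.0, 3.0)

# Diseased mixture component: log-normal with ~95% of its mass inside the
# biomarker band (median 1.9 kPa, log-sd 0.22).
_DISEASED_MEDIAN_KPA = 1.9
_DISEASED_SIGMA = 0.22

# Parenchymal HU model: normal around -860 HU, clipped strictly below the
# vessel threshold so phantom parenchyma is parenchyma by construction.
_PARENCHYMA_HU_MEAN = -860.0
_PARENCHYMA_HU_SD = 35.0
_VESSEL_HU = -100.0
_TUMOR_HU = 30.0
_BACKGROUND_HU = 0.0


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LobeElasticityParams:
    """Per-lobe elasticity distribution parameters.

    healthy_median_kpa : median of the healthy log-normal component (kPa)
    healthy_sigma      : log-sd of the healthy component (sets intralobar CV)
    diseased_fraction  : target fraction of voxels in the biomarker band
    """

    healthy_median_kpa: float
    healthy_sigma: float
    diseased_fraction: float

    def __post_init__(self) -> None:
        if self.healthy_median_kpa <= 0 or self.healthy_sigma <= 0:
            raise ValueError("elasticity parameters must be strictly positive")
        if not 0.0 <= self.diseased_fraction <= 1.0:
            raise ValueError("diseased_fraction must lie in [0, 1]")

    def band_probability_healthy(self) -> float:
        """P(healthy component in the biomarker band)."""
        lo, hi = BIOMARKER_BAND
        d = stats.lognorm(s=self.healthy_sigma, scale=self.healthy_median_kpa)
        return float(d.cdf(hi) - d.cdf(lo))

    def mixture_weight(self) -> float:
        """Diseased-component weight hitting the band-fraction target."""
        lo, hi = BIOMARKER_BAND
        dd = stats.lognorm(s=_DISEASED_SIGMA, scale=_DISEASED_MEDIAN_KPA)
        p_d = float(dd.cdf(hi) - dd.cdf(lo))
        p_h = self.band_probability_healthy()
        if p_d <= p_h:  # pragma: no cover - components are well separated
            raise ValueError("diseased component does not dominate the band")
        return float(np.clip((self.diseased_fraction - p_h) / (p_d - p_h), 0.0, 1.0))

    def expected_mean_kpa(self) -> float:
        """Analytic mean of the mixture (kPa)."""
        w = self.mixture_weight()
        mean_h = self.healthy_median_kpa * math.exp(self.healthy_sigma**2 / 2)
        mean_d = _DISEASED_MEDIAN_KPA * math.exp(_DISEASED_SIGMA**2 / 2)
        return w * mean_d + (1.0 - w) * mean_h


@dataclass(frozen=True)
class TumorSpec:
    """Spherical tumor(s): host lobe label(s) and radius in mm."""

    lobes: tuple[int, ...]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        for lb in self.lobes:
            if lb not in LOBE_LABELS:
                raise ValueError(
                    f"tumor lobe label {lb} invalid; must be one of {LOBE_LABELS}"
                )
        if self.radius_mm <= 0:
            raise ValueError("tumor radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    severity_preset: str = "none"
    lobar_elasticity_params: tuple[LobeElasticityParams, ...] = ()
    vessel_fraction: float = 0.02
    tumor_spec: TumorSpec | None = None
    #: peak superior-inferior motion, mm per amplitude unit (inferior lobes)
    motion_amplitude_mm: float = 8.0
    #: peak hysteresis motion, mm per (amplitude unit / s) of flow
    motion_hysteresis_mm: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lobar_elasticity_params) != len(LOBE_LABELS):
            raise ValueError("exactly 5 lobar elasticity parameter sets required")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if not 0.0 <= self.vessel_fraction < 1.0:
            raise ValueError("vessel_fraction must lie in [0, 1)")


# --------------------------------------------------------------------------
# Severity presets
# --------------------------------------------------------------------------

# Per-preset lobar parameters (lobe order 1..5). Lower lobes (labels 2, 5)
# are stiffer, mirroring their larger inspiratory deformation. The
# moderate_severe preset concentrates disease in the left upper lobe with
# markedly higher dispersion, the classic upper-lobe-predominant emphysema
# pattern.
_PRESETS: dict[str, tuple[LobeElasticityParams, ...]] = {
    "homogeneous": tuple(
        LobeElasticityParams(5.5, 0.40, 0.10) for _ in LOBE_LABELS
    ),
    "none": (
        LobeElasticityParams(5.2, 0.38, 0.07),
        LobeElasticityParams(6.0, 0.38, 0.06),
        LobeElasticityParams(5.2, 0.38, 0.08),
        LobeElasticityParams(5.5, 0.38, 0.07),
        LobeElasticityParams(6.0, 0.38, 0.09),
    ),
    "mild": (
        LobeElasticityParams(5.0, 0.40, 0.14),
        LobeElasticityParams(5.8, 0.40, 0.10),
        LobeElasticityParams(5.0, 0.40, 0.12),
        LobeElasticityParams(5.3, 0.40, 0.11),
        LobeElasticityParams(5.8, 0.40, 0.16),
    ),
    "moderate_severe": (
        LobeElasticityParams(4.6, 0.55, 0.45),
        LobeElasticityParams(5.5, 0.42, 0.15),
        LobeElasticityParams(4.8, 0.42, 0.13),
        LobeElasticityParams(5.1, 0.42, 0.14),
        LobeElasticityParams(5.5, 0.42, 0.16),
    ),
}

SEVERITY_PRESETS = tuple(_PRESETS)


def severity_preset(name: str, **overrides) -> PhantomSpec:
    """Return a fully populated :class:`PhantomSpec` for a named preset.

    Presets parameterize COPD severity groups: ``none``, ``mild``,
    ``moderate_severe`` (one markedly diseased, high-dispersion lobe) and
    ``homogeneous`` (identical lobar distributions; the null case).
    Keyword overrides are forwarded to the spec (e.g. ``seed=7``).
    """
    try:
        params = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown severity preset {name!r}; valid presets: "
            f"{', '.join(sorted(_PRESETS))}"
        ) from None
    return PhantomSpec(
        severity_preset=name, lobar_elasticity_params=params, **overrides
    )


# --------------------------------------------------------------------------
# Anatomy
# --------------------------------------------------------------------------

def _lobe_label_volume(shape: tuple[int, int, int]) -> np.ndarray:
    """Two half-ellipsoid 'lungs' split by oblique planes into 2 + 3 lobes.

    Axes: x = left-right, y = anterior-posterior, z = inferior(0)->superior.
    """
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    xn = (x + 0.5) / nx
    yn = (y + 0.5) / ny
    zn = (z + 0.5) / nz

    def ellipsoid(cx, sx):
        return (
            ((xn - cx) / sx) ** 2
            + ((yn - 0.5) / 0.38) ** 2
            + ((zn - 0.5) / 0.45) ** 2
        ) <= 1.0

    left = ellipsoid(0.28, 0.17)
    right = ellipsoid(0.72, 0.19)

    labels = np.zeros(shape, dtype=np.int16)
    # Left: oblique fissure rising from posterior-inferior to anterior.
    left_lower = zn < (0.32 + 0.35 * yn)
    labels[left & ~left_lower] = 1
    labels[left & left_lower] = 2
    # Right: oblique fissure, then a roughly horizontal fissure bounding the
    # anterior middle lobe.
    right_lower = zn < (0.28 + 0.35 * yn)
    right_rest = right & ~right_lower
    middle = right_rest & (zn < 0.66) & (yn < 0.56)
    labels[right_rest & ~middle] = 3
    labels[right_rest & middle] = 4
    labels[right & right_lower] = 5
    return labels


@dataclass
class Phantom:
    """One synthetic subject: anatomy, ground truth, and motion truth."""

    spec: PhantomSpec
    hu_exhale: np.ndarray          # 3D float, HU
    lobe_labels: np.ndarray        # 3D int16, 0 background / 1..5 lobes
    elasticity_truth: np.ndarray   # 3D float, kPa (0 outside lung)
    tumor_labels: np.ndarray       # 3D bool
    alpha: np.ndarray              # (..., 3) mm per amplitude unit
    beta: np.ndarray               # (..., 3) mm per flow unit

    @property
    def lung_mask(self) -> np.ndarray:
        return self.lobe_labels > 0


def _place_vessels(
    rng: np.random.Generator, lung: np.ndarray, target_fraction: float
) -> np.ndarray:
    """Mark thin random tube-like tracks through the lung as vessels."""
    vessels = np.zeros_like(lung, dtype=bool)
    if target_fraction <= 0:
        return vessels
    n_lung = int(lung.sum())
    target = int(round(target_fraction * n_lung))
    lung_idx = np.argwhere(lung)
    shape = np.asarray(lung.shape)
    guard = 0
    while vessels.sum() < target and guard < 10_000:
        guard += 1
        start = lung_idx[rng.integers(len(lung_idx))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.integers(5, max(6, int(shape.max() // 2)))
        t = np.arange(-length, length + 1)[:, None]
        pts = np.round(start[None, :] + t * direction[None, :]).astype(int)
        ok = np.all((pts >= 0) & (pts < shape[None, :]), axis=1)
        pts = pts[ok]
        inside = lung[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[inside]
        vessels[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return vessels & lung


def _place_tumors(
    spec: PhantomSpec, lobe_labels: np.ndarray
) -> np.ndarray:
    """Spherical tumor at the centroid of each requested host lobe."""
    tumors = np.zeros(lobe_labels.shape, dtype=bool)
    if spec.tumor_spec is None:
        return tumors
    spacing = np.asarray(spec.spacing)
    coords = np.stack(
        np.meshgrid(*[np.arange(n) for n in lobe_labels.shape], indexing="ij"),
        axis=-1,
    ) * spacing
    for lb in spec.tumor_spec.lobes:
        in_lobe = lobe_labels == lb
        if not in_lobe.any():
            raise ValueError(f"tumor host lobe {lb} is empty in this geometry")
        center = coords[in_lobe].mean(axis=0)
        r = np.linalg.norm(coords - center, axis=-1)
        tumors |= (r <= spec.tumor_spec.radius_mm) & in_lobe
    return tumors


def _sample_lobe_elasticity(
    rng: np.random.Generator, params: LobeElasticityParams, n: int
) -> np.ndarray:
    w = params.mixture_weight()
    diseased = rng.random(n) < w
    values = np.empty(n)
    n_d = int(diseased.sum())
    values[diseased] = rng.lognormal(
        math.log(_DISEASED_MEDIAN_KPA), _DISEASED_SIGMA, n_d
    )
    values[~diseased] = rng.lognormal(
        math.log(params.healthy_median_kpa), params.healthy_sigma, n - n_d
    )
    return values


def _motion_truth(
    spec: PhantomSpec, lung: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth (alpha, beta) fields, largest in the inferior lobes.

    The dominant motion is superior-inferior (diaphragm-driven) and decays
    smoothly from lung base to apex; a small anterior-posterior component
    emulates chest-wall motion. Hysteresis (beta) follows the same spatial
    pattern at a much smaller scale. Fields are zero outside the lung.
    """
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    zn = (z + 0.5) / nz
    yn = (y + 0.5) / ny
    base_weight = (1.0 - zn) ** 2  # quadratic decay apex-ward
    alpha = np.zeros(spec.grid_shape + (3,))
    alpha[..., 2] = -spec.motion_amplitude_mm * base_weight
    alpha[..., 1] = 0.15 * spec.motion_amplitude_mm * base_weight * (yn - 0.5)
    beta = np.zeros(spec.grid_shape + (3,))
    beta[..., 2] = -spec.motion_hysteresis_mm * base_weight
    beta[..., 1] = 0.3 * spec.motion_hysteresis_mm * base_weight * (0.5 - yn)
    alpha[~lung] = 0.0
    beta[~lung] = 0.0
    return alpha, beta


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one synthetic subject; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    labels = _lobe_label_volume(spec.grid_shape)
    lung = labels > 0

    elasticity = np.zeros(spec.grid_shape)
    for lb, params in zip(LOBE_LABELS, spec.lobar_elasticity_params):
        in_lobe = labels == lb
        elasticity[in_lobe] = _sample_lobe_elasticity(
            rng, params, int(in_lobe.sum())
        )

    hu = np.full(spec.grid_shape, _BACKGROUND_HU)
    parench_hu = rng.normal(_PARENCHYMA_HU_MEAN, _PARENCHYMA_HU_SD, int(lung.sum()))
    hu[lung] = np.minimum(parench_hu, PARENCHYMA_HU_THRESHOLD - 5.0)

    vessels = _place_vessels(rng, lung, spec.vessel_fraction)
    hu[vessels] = _VESSEL_HU
    tumors = _place_tumors(spec, labels)
    hu[tumors] = _TUMOR_HU
    # Vessels/tumor are stiff structures; their truth values sit far above
    # the parenchymal range (they are excluded by the -700 HU mask anyway).
    elasticity[vessels] = 50.0
    elasticity[tumors] = 80.0

    alpha, beta = _motion_truth(spec, lung)
    return Phantom(
        spec=spec,
        hu_exhale=hu,
        lobe_labels=labels,
        elasticity_truth=elasticity,
        tumor_labels=tumors,
        alpha=alpha,
        beta=beta,
    )


# --------------------------------------------------------------------------
# Breathing signal
# --------------------------------------------------------------------------

@dataclass
class BreathingSignal:
    """Bellows-like amplitude/flow signal, uniformly sampled.

    Amplitude units are arbitrary (the bellows voltage is uncalibrated);
    only relative amplitudes matter to the motion model. Flow is the time
    derivative of the amplitude.
    """

    time: np.ndarray       # s
    amplitude: np.ndarray  # a.u.
    flow: np.ndarray       # a.u./s

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


def generate_breathing_signal(
    duration: float,
    period: float = 4.0,
    drift: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 100.0,
    period_variability: float = 0.05,
    depth_variability: float = 0.08,
) -> BreathingSignal:
    """Quasi-periodic breathing amplitude with cycle-to-cycle variability.

    Each breathing cycle is a raised-cosine bump whose period and depth are
    perturbed around their nominal values (fractional standard deviations
    ``period_variability`` and ``depth_variability``); a linear baseline
    ``drift`` (amplitude units per second) emulates bellows drift. With both
    variabilities at zero the signal is the exact raised cosine
    ``0.5*(1 - cos(2*pi*t/period))``. Flow is the central-difference
    derivative of the amplitude.
    """
    if duration <= 0 or period <= 0:
        raise ValueError("duration and period must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, duration, dt)

    # Draw per-cycle periods/depths until the cycles cover the duration.
    n_cycles = int(np.ceil(duration / period)) + 4
    periods = period * (1.0 + period_variability * rng.standard_normal(n_cycles))
    periods = np.maximum(periods, 0.3 * period)
    depths = np.maximum(1.0 + depth_variability * rng.standard_normal(n_cycles), 0.2)
    edges = np.concatenate([[0.0], np.cumsum(periods)])

    cycle = np.searchsorted(edges, t, side="right") - 1
    phase = (t - edges[cycle]) / periods[cycle]
    amplitude = depths[cycle] * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    amplitude = amplitude + drift * t
    flow = np.gradient(amplitude, dt, edge_order=2)
    return BreathingSignal(time=t, amplitude=amplitude, flow=flow)


# --------------------------------------------------------------------------
# Scan sets (registered-scan stand-in)
# --------------------------------------------------------------------------

@dataclass
class ScanSet:
    """DVFs with paired (amplitude, flow) values on one reference grid.

    Entry ``reference_index`` defines the reference geometry; its DVF is
    identically zero and all other DVFs are displacements relative to it
    (the output a deformable registration of the other scans would give).
    """

    dvfs: np.ndarray        # (N, nx, ny, nz, 3), mm
    v: np.ndarray           # (N,) amplitude
    f: np.ndarray           # (N,) flow
    spacing: tuple[float, float, float]
    reference_index: int = 0

    @property
    def n_scans(self) -> int:
        return len(self.v)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.dvfs.shape[1:4]


def generate_scan_set(
    phantom: Phantom,
    signal: BreathingSignal,
    n_scans: int = 25,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScanSet:
    """Sample breathing states and emit ground-truth (optionally noised) DVFs.

    Each scan samples one (v, f) state of the signal; its DVF relative to
    the reference state (the first sample) is
    ``alpha*(v - v_ref) + beta*(f - f_ref)`` plus i.i.d. Gaussian noise of
    standard deviation ``noise_sd`` mm per component, emulating residual
    registration error. At least 3 scans are required: the motion model has
    three unknown vector coefficients per voxel.
    """
    if n_scans < 3:
        raise ValueError(
            "n_scans must be >= 3: the motion model fits 3 unknown vector "
            "coefficients (reference position, amplitude, flow) per voxel"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(signal.time), size=n_scans, replace=False)
    v = signal.amplitude[idx]
    f = signal.flow[idx]
    shape = phantom.spec.grid_shape
    dvfs = np.zeros((n_scans,) + shape + (3,))
    for i in range(1, n_scans):
        dvfs[i] = phantom.alpha * (v[i] - v[0]) + phantom.beta * (f[i] - f[0])
        if noise_sd > 0:
            dvfs[i] += rng.normal(0.0, noise_sd, shape + (3,))
    return ScanSet(
        dvfs=dvfs, v=v, f=f, spacing=phantom.spec.spacing, reference_index=0
    )
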