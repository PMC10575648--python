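"""5D breathing-motion model: per-voxel tissue position as a linear
function of breathing amplitude and flow.

The model states that tissue position X equals a reference position X0
plus alpha*v (inspiratory motion proportional to breathing amplitude v)
plus beta*f (hysteresis motion proportional to breathing rate f). Fitting
is plain per-voxel ordinary least squares of the registered displacements
on the design (1, v, f); end-exhalation and end-inhalation geometries are
synthesized at chosen amplitude percentiles with zero flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import BreathingSignal, ScanSet


@dataclass
class MotionModelParams:
    """Per-voxel motion coefficients on the reference grid.

    ``x0_disp`` is the displacement of the zero-amplitude, zero-flow tissue
    position relative to the reference geometry (the fitted intercept);
    ``alpha`` is mm per amplitude unit, ``beta`` mm per flow unit, and
    ``fit_residual`` the per-voxel RMS residual (mm) over all scans and
    displacement components.
    """

    x0_disp: np.ndarray       # (..., 3) mm
    alpha: np.ndarray         # (..., 3) mm per amplitude unit
    beta: np.ndarray          # (..., 3) mm per flow unit
    fit_residual: np.ndarray  # (...,) mm, >= 0
    spacing: tuple[float, float, float]

    def reference_positions(self) -> np.ndarray:
        """World-coordinate tissue positions at zero amplitude and flow."""
        shape = self.fit_residual.shape
        coords = np.stack(
            np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
        ) * np.asarray(self.spacing)
        return coords + self.x0_disp


def fit_motion_model(scans: ScanSet) -> MotionModelParams:
    """Fit the motion model per voxel by ordinary least squares.

    Regresses each displacement component on the design (1, v, f) across
    scans. Requires the design to have full column rank: at least three
    scans with non-collinear (1, v, f) rows, i.e. the amplitudes and flows
    must not be jointly degenerate.
    """
    v, f = scans.v, scans.f
    design = np.column_stack([np.ones_like(v), v, f])
    singvals = np.linalg.svd(design, compute_uv=False)
    if len(v) < 3 or singvals[-1] < 1e-10 * singvals[0]:
        raise ValueError(
            "rank-deficient motion design: the (1, v, f) rows are collinear "
            "(e.g. all amplitudes equal and all flows equal); at least 3 "
            "scans spanning distinct breathing states are required"
        )
    n = scans.n_scans
    shape = scans.grid_shape
    d = scans.dvfs.reshape(n, -1)
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)
    resid = d - design @ coef
    rms = np.sqrt(
        np.mean(resid.reshape(n, *shape, 3) ** 2, axis=(0, -1))
    )
    full = shape + (3,)
    return MotionModelParams(
        x0_disp=coef[0].reshape(full),
        alpha=coef[1].reshape(full),
        beta=coef[2].reshape(full),
        fit_residual=rms,
        spacing=scans.spacing,
    )


def percentile_amplitude(signal: BreathingSignal, p: float) -> float:
    """Amplitude percentile (linear interpolation between order statistics)."""
    if not 0 <= p <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    if len(signal.amplitude) == 0:
        raise ValueError("empty breathing signal")
    return float(np.percentile(signal.amplitude, p))


@dataclass
class PhasePair:
    """End-exhalation / end-inhalation displacement fields (zero flow).

    DVFs are relative to the reference geometry; ``exhale_to_inhale_dvf``
    is their voxel-wise difference, which by model linearity equals
    ``alpha * (v_inhale - v_exhale)``.
    """

    exhale_dvf: np.ndarray
    inhale_dvf: np.ndarray
    v_exhale: float
    v_inhale: float

    @property
    def exhale_to_inhale_dvf(self) -> np.ndarray:
        return self.inhale_dvf - self.exhale_dvf


def synthesize_phase_pair(
    params: MotionModelParams,
    signal: BreathingSignal,
    p_exhale: float = 5.0,
    p_inhale: float = 85.0,
) -> PhasePair:
    """Evaluate the model at two amplitude percentiles with zero flow.

    End-exhalation and end-inhalation are taken at the ``p_exhale``-th and
    ``p_inhale``-th percentile amplitudes (defaults 5 and 85); the flow
    term contributes exactly nothing since f = 0 at both phases.
    """
    if not (0 <= p_exhale <= 100 and 0 <= p_inhale <= 100):
        raise ValueError("percentiles must lie in [0, 100]")
    if p_exhale > p_inhale:
        raise ValueError("p_exhale must not exceed p_inhale")
    v_ex = percentile_amplitude(signal, p_exhale)
    v_in = percentile_amplitude(signal, p_inhale)
    return PhasePair(
        exhale_dvf=params.x0_disp + params.alpha * v_ex,
        inhale_dvf=params.x0_disp + params.alpha * v_in,
        v_exhale=v_ex,
        v_inhale=v_in,
    )


def warp_volume(
    volume: np.ndarray,
    dvf: np.ndarray,
    spacing: tuple[float, float, float],
    fill_value: float = 0.0,
) -> np.ndarray:
    """Pull-back trilinear resampling: ``out(x) = volume(x + dvf(x))``.

    ``dvf`` is in mm on the same grid as ``volume``; out-of-bounds samples
    take ``fill_value``.
    """
    if dvf.shape[:-1] != volume.shape or dvf.shape[-1] != 3:
        raise ValueError(
            f"grid mismatch: volume {volume.shape} vs dvf {dvf.shape}"
        )
    idx = np.meshgrid(*[np.arange(n) for n in volume.shape], indexing="ij")
    coords = [
        idx[ax] + dvf[..., ax] / spacing[ax] for ax in range(3)
    ]
    return ndimage.map_coordinates(
        volume.astype(float),
        coords,
        order=1,
        mode="constant",
        cval=fill_value,
    )
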