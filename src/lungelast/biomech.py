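"""Quasi-static biomechanical model of lung parenchyma and the inverse
Young's-modulus estimator.

The parenchyma is discretised as a lattice of finite elements: one node
per parenchymal voxel, elastic springs on the 6 face-neighbor links and
shear springs (fixed modulus, 4 kPa by default) on the 12 edge-diagonal
links, which resist angular distortion of the lattice. Internal forces on
a node are the sum of elastic, shear, and dashpot damping contributions
over its links:

* elastic:  ``f = YM_ab * (dL/L) * u_hat``  along the current link
  direction, with the link stiffness ``YM_ab`` the mean of the two nodes'
  Young's moduli (kPa);
* shear:    the same spring law on the diagonal links with the fixed
  shear modulus ``S_ab``;
* damping:  ``f = mu_ab * (v_b - v_a)`` (relative-velocity dashpot).

Forces are per unit link cross-section, so stiffnesses carry kPa and
strains are dimensionless. The static equilibrium under prescribed
boundary displacements is found by dynamic relaxation: damped explicit
pseudo-time stepping with fictitious nodal masses scaled to the incident
link stiffness and kinetic damping (velocities reset at kinetic-energy
peaks), which needs no damping-coefficient tuning.

The inverse estimator iterates: solve the forward model, compare local
link strains of the model displacement field against the target DVF, and
update each node's Young's modulus multiplicatively by the strain ratio
raised to an under-relaxation power, clamped to a physiological range.
A region that deforms more than the target is too soft and is stiffened,
and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Fixed shear modulus on diagonal links, kPa.
DEFAULT_SHEAR_MODULUS_KPA = 4.0

#: Young's modulus clamp, kPa; brackets the 1-3 kPa biomarker band with
#: generous headroom on both sides.
YM_MIN_KPA = 0.1
YM_MAX_KPA = 100.0

_FACE_OFFSETS = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
_DIAGONAL_OFFSETS = (
    (1, 1, 0), (1, -1, 0),
    (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
)


class ForwardSolveError(RuntimeError):
    """Dynamic relaxation failed to reach the force tolerance."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class EstimationDivergenceError(RuntimeError):
    """The inverse loop's DVF error grew over consecutive iterations."""


# --------------------------------------------------------------------------
# Element grid
# --------------------------------------------------------------------------

@dataclass
class ElementGrid:
    """Finite-element node lattice over a parenchyma mask.

    Nodes are ordered in C order over the mask voxels. Each link appears
    once, with ``link_a < link_b``; ``link_is_shear`` separates diagonal
    (shear) links from face (elastic) links. ``boundary_mask`` marks nodes
    with prescribed displacements ``boundary_disp``.
    """

    node_ijk: np.ndarray          # (n, 3) voxel indices
    positions: np.ndarray         # (n, 3) rest positions, mm
    link_a: np.ndarray            # (m,) node indices
    link_b: np.ndarray            # (m,)
    rest_length: np.ndarray       # (m,) mm, > 0
    link_is_shear: np.ndarray     # (m,) bool
    boundary_mask: np.ndarray     # (n,) bool
    boundary_disp: np.ndarray     # (n, 3) mm, zero on interior nodes
    spacing: tuple[float, float, float]
    grid_shape: tuple[int, int, int]
    shear_modulus: float = DEFAULT_SHEAR_MODULUS_KPA
    damping: float = 1.0          # dashpot factor mu_ab, uniform per link

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_links(self) -> int:
        return len(self.link_a)

    def node_values_from_volume(self, volume: np.ndarray) -> np.ndarray:
        """Sample a voxel map (3D or 3D+vector) at the node voxels."""
        i, j, k = self.node_ijk.T
        return volume[i, j, k]

    def volume_from_node_values(
        self, values: np.ndarray, fill: float = 0.0
    ) -> np.ndarray:
        """Scatter per-node values back onto the voxel grid."""
        shape = self.grid_shape + values.shape[1:]
        out = np.full(shape, fill, dtype=float)
        i, j, k = self.node_ijk.T
        out[i, j, k] = values
        return out


def build_element_grid(
    parenchyma_mask: np.ndarray,
    spacing: tuple[float, float, float],
    dvf: np.ndarray | None = None,
    boundary_mask: np.ndarray | None = None,
    shear_modulus: float = DEFAULT_SHEAR_MODULUS_KPA,
) -> ElementGrid:
    """Build the node lattice for a parenchyma mask.

    One node per masked voxel; elastic links to the 6 face neighbors and
    shear links to the 12 edge-diagonal neighbors (each counted once). By
    default boundary nodes are the mask-surface nodes (fewer than 6 face
    neighbors inside the mask); pass ``boundary_mask`` (3D boolean) to
    override. Prescribed boundary displacements are sampled from ``dvf``
    (mm) where given, else zero.
    """
    mask = np.asarray(parenchyma_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty parenchyma mask")
    spacing = tuple(float(s) for s in spacing)
    node_ijk = np.argwhere(mask)
    n = len(node_ijk)
    index = np.full(mask.shape, -1, dtype=np.int64)
    index[mask] = np.arange(n)

    a_list, b_list, len_list, shear_list = [], [], [], []
    face_degree = np.zeros(n, dtype=np.int64)
    for offsets, is_shear in ((_FACE_OFFSETS, False), (_DIAGONAL_OFFSETS, True)):
        for off in offsets:
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            for ax, o in enumerate(off):
                if o > 0:
                    src[ax] = slice(0, mask.shape[ax] - o)
                    dst[ax] = slice(o, mask.shape[ax])
                elif o < 0:
                    src[ax] = slice(-o, mask.shape[ax])
                    dst[ax] = slice(0, mask.shape[ax] + o)
            both = mask[tuple(src)] & mask[tuple(dst)]
            a = index[tuple(src)][both]
            b = index[tuple(dst)][both]
            if len(a) == 0:
                continue
            a_list.append(a)
            b_list.append(b)
            length = float(
                np.sqrt(sum((o * s) ** 2 for o, s in zip(off, spacing)))
            )
            len_list.append(np.full(len(a), length))
            shear_list.append(np.full(len(a), is_shear))
            if not is_shear:
                face_degree += np.bincount(a, minlength=n)
                face_degree += np.bincount(b, minlength=n)

    if a_list:
        link_a = np.concatenate(a_list)
        link_b = np.concatenate(b_list)
        rest_length = np.concatenate(len_list)
        link_is_shear = np.concatenate(shear_list)
    else:  # single isolated voxel
        link_a = np.empty(0, dtype=np.int64)
        link_b = np.empty(0, dtype=np.int64)
        rest_length = np.empty(0)
        link_is_shear = np.empty(0, dtype=bool)

    if boundary_mask is None:
        node_boundary = face_degree < 6
    else:
        node_boundary = np.asarray(boundary_mask, dtype=bool)[mask]
    if dvf is not None:
        i, j, k = node_ijk.T
        disp = np.asarray(dvf, dtype=float)[i, j, k]
    else:
        disp = np.zeros((n, 3))
    boundary_disp = np.where(node_boundary[:, None], disp, 0.0)

    return ElementGrid(
        node_ijk=node_ijk,
        positions=node_ijk * np.asarray(spacing),
        link_a=link_a,
        link_b=link_b,
        rest_length=rest_length,
        link_is_shear=link_is_shear,
        boundary_mask=node_boundary,
        boundary_disp=boundary_disp,
        spacing=spacing,
        grid_shape=mask.shape,
        shear_modulus=shear_modulus,
    )


# --------------------------------------------------------------------------
# Elasticity maps
# --------------------------------------------------------------------------

@dataclass
class ElasticityMap:
    """Per-node Young's modulus in kPa."""

    ym: np.ndarray  # (n,) kPa
    provenance: str = "initialized"  # initialized | estimated | truth
    ym_min: float = YM_MIN_KPA
    ym_max: float = YM_MAX_KPA

    def __post_init__(self) -> None:
        self.ym = np.clip(np.asarray(self.ym, dtype=float), self.ym_min, self.ym_max)

    def to_volume(self, grid: ElementGrid, fill: float = 0.0) -> np.ndarray:
        return grid.volume_from_node_values(self.ym, fill=fill)


def init_elasticity_from_hu(
    hu: np.ndarray,
    mask: np.ndarray,
    ym_min: float = YM_MIN_KPA,
    ym_max: float = YM_MAX_KPA,
    ym_at_threshold: float = 5.0,
) -> ElasticityMap:
    """Initial Young's modulus from end-exhalation attenuation.

    Denser tissue starts stiffer: an affine map takes -1000 HU (air) to
    ``ym_min`` and -700 HU (the parenchyma ceiling) to ``ym_at_threshold``
    kPa, clamped to [ym_min, ym_max]; the map is monotone non-decreasing
    in HU.
    """
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(hu, dtype=float)[mask]
    ym = ym_min + (values + 1000.0) / 300.0 * (ym_at_threshold - ym_min)
    return ElasticityMap(
        ym=np.clip(ym, ym_min, ym_max),
        provenance="initialized",
        ym_min=ym_min,
        ym_max=ym_max,
    )


# --------------------------------------------------------------------------
# Forces
# --------------------------------------------------------------------------

def _link_stiffness(grid: ElementGrid, ym: ElasticityMap) -> np.ndarray:
    """Per-link stiffness (kPa): nodal-YM mean on elastic links, the fixed
    shear modulus on diagonal links."""
    k = 0.5 * (ym.ym[grid.link_a] + ym.ym[grid.link_b])
    return np.where(grid.link_is_shear, grid.shear_modulus, k)


def _spring_forces(
    grid: ElementGrid, k_link: np.ndarray, displacements: np.ndarray
) -> np.ndarray:
    """Elastic + shear forces at every node for a displacement field."""
    n = grid.n_nodes
    forces = np.zeros((n, 3))
    if grid.n_links == 0:
        return forces
    cur = grid.positions + displacements
    d = cur[grid.link_b] - cur[grid.link_a]
    ell = np.linalg.norm(d, axis=1)
    # f = k * strain along the current unit link direction; pulls node a
    # toward b when the link is stretched.
    scale = k_link * (ell - grid.rest_length) / (grid.rest_length * ell)
    fvec = scale[:, None] * d
    for c in range(3):
        forces[:, c] = np.bincount(
            grid.link_a, weights=fvec[:, c], minlength=n
        ) - np.bincount(grid.link_b, weights=fvec[:, c], minlength=n)
    return forces


def compute_forces(
    grid: ElementGrid,
    ym: ElasticityMap,
    displacements: np.ndarray,
    velocities: np.ndarray | None = None,
) -> np.ndarray:
    """Total internal force on every node: elastic + shear + dashpot.

    Pure function of the state; the dashpot term ``mu_ab * (v_b - v_a)``
    contributes only when velocities are given. Internal forces sum to the
    zero vector (Newton's third law) by construction.
    """
    forces = _spring_forces(grid, _link_stiffness(grid, ym), displacements)
    if velocities is not None and grid.n_links > 0:
        rel = velocities[grid.link_b] - velocities[grid.link_a]
        n = grid.n_nodes
        for c in range(3):
            w = grid.damping * rel[:, c]
            forces[:, c] += np.bincount(
                grid.link_a, weights=w, minlength=n
            ) - np.bincount(grid.link_b, weights=w, minlength=n)
    return forces


# --------------------------------------------------------------------------
# Forward solve (dynamic relaxation)
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _forces_kernel(pos, u, link_a, link_b, rest, k_link, out):  # pragma: no cover
    out[:] = 0.0
    for l in range(link_a.shape[0]):
        ia, ib = link_a[l], link_b[l]
        dx = pos[ib, 0] + u[ib, 0] - pos[ia, 0] - u[ia, 0]
        dy = pos[ib, 1] + u[ib, 1] - pos[ia, 1] - u[ia, 1]
        dz = pos[ib, 2] + u[ib, 2] - pos[ia, 2] - u[ia, 2]
        ell = np.sqrt(dx * dx + dy * dy + dz * dz)
        s = k_link[l] * (ell - rest[l]) / (rest[l] * ell)
        fx, fy, fz = s * dx, s * dy, s * dz
        out[ia, 0] += fx
        out[ia, 1] += fy
        out[ia, 2] += fz
        out[ib, 0] -= fx
        out[ib, 1] -= fy
        out[ib, 2] -= fz


@njit(cache=True, fastmath=True)
def _dr_kernel(pos, link_a, link_b, rest, k_link, interior_idx, mass, u,
               tol, max_iter, check_every):  # pragma: no cover
    """Kinetic-damping dynamic relaxation; mutates ``u`` in place.

    Returns (iterations, residual, converged, initial_residual).
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    _forces_kernel(pos, u, link_a, link_b, rest, k_link, forces)
    res0 = 0.0
    for idx in interior_idx:
        f = np.sqrt(
            forces[idx, 0] ** 2 + forces[idx, 1] ** 2 + forces[idx, 2] ** 2
        )
        if f > res0:
            res0 = f
    if tol < 0.0:
        tol = 1e-4 * res0
    if res0 <= tol:
        return 0, res0, True, res0
    ke_prev = 0.0
    residual = res0
    for it in range(1, max_iter + 1):
        ke = 0.0
        for idx in interior_idx:
            m = mass[idx]
            vel[idx, 0] += forces[idx, 0] / m
            vel[idx, 1] += forces[idx, 1] / m
            vel[idx, 2] += forces[idx, 2] / m
            u[idx, 0] += vel[idx, 0]
            u[idx, 1] += vel[idx, 1]
            u[idx, 2] += vel[idx, 2]
            ke += m * (vel[idx, 0] ** 2 + vel[idx, 1] ** 2 + vel[idx, 2] ** 2)
        if ke < ke_prev:
            # kinetic-energy peak passed: backtrack to the peak position
            # and restart from rest (kinetic damping)
            for idx in interior_idx:
                m = mass[idx]
                u[idx, 0] -= 1.5 * vel[idx, 0] - 0.5 * forces[idx, 0] / m
                u[idx, 1] -= 1.5 * vel[idx, 1] - 0.5 * forces[idx, 1] / m
                u[idx, 2] -= 1.5 * vel[idx, 2] - 0.5 * forces[idx, 2] / m
            vel[:] = 0.0
            ke = 0.0
        ke_prev = ke
        _forces_kernel(pos, u, link_a, link_b, rest, k_link, forces)
        if it % check_every == 0 or it == max_iter:
            residual = 0.0
            for idx in interior_idx:
                f = np.sqrt(
                    forces[idx, 0] ** 2
                    + forces[idx, 1] ** 2
                    + forces[idx, 2] ** 2
                )
                if f > residual:
                    residual = f
            if residual <= tol:
                return it, residual, True, res0
    return max_iter, residual, False, res0

@dataclass
class SolveState:
    """Equilibrium (or last) state of a forward solve."""

    displacements: np.ndarray     # (n, 3) mm
    velocities: np.ndarray        # (n, 3)
    residual_force_norm: float    # max interior node force magnitude
    iterations: int
    converged: bool = True


def forward_solve(
    grid: ElementGrid,
    ym: ElasticityMap,
    tol: float | None = None,
    max_iter: int = 40_000,
    warm_start: np.ndarray | None = None,
    check_every: int = 10,
) -> SolveState:
    """Static equilibrium under the prescribed boundary displacements.

    Dynamic relaxation: explicit pseudo-time stepping with unit time step,
    fictitious nodal masses proportional to incident link stiffness (which
    makes the step unconditionally stable), and kinetic damping. ``tol``
    is the maximum interior residual-force magnitude; the default is 1e-4
    of the initial force scale set by the boundary displacement. Raises
    :class:`ForwardSolveError` on non-convergence.
    """
    n = grid.n_nodes
    interior = ~grid.boundary_mask
    k_link = _link_stiffness(grid, ym)

    u = np.array(grid.boundary_disp, dtype=float)
    if warm_start is not None:
        u[interior] = warm_start[interior]
    if not interior.any():
        res = 0.0
        return SolveState(u, np.zeros((n, 3)), res, 0, True)

    # Fictitious mass: twice the incident stiffness-per-length sum bounds
    # the largest eigenfrequency at 1, so dt = 1 is stable.
    k_per_len = k_link / grid.rest_length
    mass = np.zeros(n)
    mass += np.bincount(grid.link_a, weights=k_per_len, minlength=n)
    mass += np.bincount(grid.link_b, weights=k_per_len, minlength=n)
    mass = 2.0 * np.maximum(mass, 1e-12)

    it, residual, converged, _res0 = _dr_kernel(
        np.ascontiguousarray(grid.positions, dtype=np.float64),
        grid.link_a.astype(np.int64),
        grid.link_b.astype(np.int64),
        grid.rest_length.astype(np.float64),
        k_link.astype(np.float64),
        np.flatnonzero(interior).astype(np.int64),
        mass,
        u,
        -1.0 if tol is None else float(tol),
        int(max_iter),
        int(check_every),
    )
    if not converged:
        raise ForwardSolveError(
            f"dynamic relaxation did not reach tolerance within "
            f"{max_iter} iterations (last residual {residual:.3g})",
            residual=residual,
            iterations=max_iter,
        )
    return SolveState(u, np.zeros((n, 3)), residual, it, True)


# --------------------------------------------------------------------------
# Inverse elasticity estimation
# --------------------------------------------------------------------------

def _node_strain(grid: ElementGrid, displacements: np.ndarray) -> np.ndarray:
    """Mean absolute link strain over each node's elastic (face) links."""
    n = grid.n_nodes
    el = ~grid.link_is_shear
    a, b, L = grid.link_a[el], grid.link_b[el], grid.rest_length[el]
    cur = grid.positions + displacements
    ell = np.linalg.norm(cur[b] - cur[a], axis=1)
    s = np.abs(ell - L) / L
    num = np.bincount(a, weights=s, minlength=n) + np.bincount(
        b, weights=s, minlength=n
    )
    deg = np.bincount(a, minlength=n) + np.bincount(b, minlength=n)
    return num / np.maximum(deg, 1)


def _fill_from_neighbors(
    grid: ElementGrid, values: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Replace invalid entries with the median over valid link neighbors."""
    out = values.copy()
    if valid.all():
        return out
    out[~valid] = 1.0
    a, b = grid.link_a, grid.link_b
    valid = valid.copy()
    # breadth-first passes so factors propagate into deep invalid regions
    while not valid.all():
        m1 = ~valid[a] & valid[b]
        m2 = ~valid[b] & valid[a]
        idx = np.concatenate([a[m1], b[m2]])
        vals = np.concatenate([out[b[m1]], out[a[m2]]])
        if len(idx) == 0:
            break  # disconnected invalid nodes keep the neutral factor 1
        order = np.argsort(idx, kind="stable")
        idx, vals = idx[order], vals[order]
        starts = np.flatnonzero(np.r_[True, np.diff(idx) > 0])
        for s, e in zip(starts, np.r_[starts[1:], len(idx)]):
            out[idx[s]] = float(np.median(vals[s:e]))
        valid[idx] = True
    return out


def _smooth_node_field(
    grid: ElementGrid, values: np.ndarray, sigma: float
) -> np.ndarray:
    """Mask-aware Gaussian smoothing of a per-node field (normalized
    convolution, so values outside the parenchyma never bleed in)."""
    vol = grid.volume_from_node_values(values, fill=0.0)
    w = grid.volume_from_node_values(np.ones(grid.n_nodes), fill=0.0)
    num = ndimage.gaussian_filter(vol, sigma)
    den = ndimage.gaussian_filter(w, sigma)
    i, j, k = grid.node_ijk.T
    return num[i, j, k] / np.maximum(den[i, j, k], 1e-12)


@dataclass
class EstimationResult:
    """Inverse-estimation output: the map plus its convergence trace."""

    elasticity: ElasticityMap
    error_trace: list[float] = field(default_factory=list)  # mean |model-target| mm
    outer_iterations: int = 0
    converged: bool = False
    #: stopped because the DVF error plateaued (discrepancy-style stop:
    #: iterating past the data's noise floor only chases noise)
    stalled: bool = False


def estimate_elasticity(
    grid: ElementGrid,
    target_dvf: np.ndarray,
    init: ElasticityMap,
    outer_tol: float = 0.1,
    max_outer: int = 30,
    gamma: float = 0.5,
    forward_tol: float | None = None,
    forward_max_iter: int = 40_000,
    smooth_sigma_voxels: float = 0.0,
    strain_smooth_sigma_voxels: float = 1.0,
    ym_smooth_sigma_voxels: float = 1.0,
    ym_smooth_decay: float = 0.7,
    update_margin_voxels: float = 0.0,
    min_improvement: float = 0.005,
) -> EstimationResult:
    """Iteratively estimate per-node Young's modulus matching a target DVF.

    Each outer iteration solves the forward model under the boundary
    displacements prescribed from the target, compares node-local link
    strains of the model field against those of the target field, and
    updates ``YM <- YM * (model_strain / target_strain)**gamma`` (clamped
    per step and to the physiological range). Nodes with negligible target
    strain or displacement (< 1e-6 mm) are excluded from the ratio and
    inherit the median update factor of their link neighbors. Convergence
    is declared when the mean displacement error over interior nodes falls
    below ``outer_tol`` (mm); an error growing over 5 consecutive outer
    iterations raises :class:`EstimationDivergenceError`. The loop also
    stops (``stalled=True``) when the relative error improvement drops
    below ``min_improvement``: for noisy targets the error bottoms out at
    the noise floor, and iterating past it degrades the modulus map.

    ``smooth_sigma_voxels`` applies a Gaussian pre-filter to the target
    DVF. Raw link strains amplify displacement noise by 1/spacing, so for
    registration-noise-scale errors (~0.5 mm on 2 mm links) a sigma of
    about 2 voxels is recommended; leave at 0 for noiseless targets.

    ``strain_smooth_sigma_voxels`` smooths the model and target strain
    fields (mask-aware) before the ratio is taken, so updates respond to
    regional strain mismatch rather than voxel-scale wiggles: a single
    voxel's modulus has almost no displacement signature, and forcing the
    model to chase voxel-scale strain detail amplifies noise without
    bound.

    ``ym_smooth_sigma_voxels`` smooths log-YM after each update
    (mask-aware Gaussian). Voxel-scale modulus speckle is nearly invisible
    to the displacement field — the inverse problem is ill-posed at that
    scale — so without this regularization speckle from the initialization
    or from strain noise persists indefinitely. The sigma decays by
    ``ym_smooth_decay`` each outer iteration (coarse-to-fine): strong
    early smoothing removes speckle while later iterations sharpen
    genuine regional contrast without eroding it.
    """
    target_dvf = np.asarray(target_dvf, dtype=float)
    if smooth_sigma_voxels > 0:
        target_dvf = np.stack(
            [
                ndimage.gaussian_filter(target_dvf[..., c], smooth_sigma_voxels)
                for c in range(3)
            ],
            axis=-1,
        )
    target_u = grid.node_values_from_volume(target_dvf)
    # boundary conditions must come from the target field
    grid.boundary_disp = np.where(
        grid.boundary_mask[:, None], target_u, 0.0
    )
    interior = ~grid.boundary_mask
    target_strain = _node_strain(grid, target_u)
    tiny = (target_strain < 1e-9) | (
        np.linalg.norm(target_u, axis=1) < 1e-6
    )
    if update_margin_voxels > 0:
        # strains within a filter length of the prescribed boundary are
        # dominated by boundary noise and filter edge effects; those nodes
        # inherit their update factors from deeper neighbors instead
        bvol = grid.volume_from_node_values(
            grid.boundary_mask.astype(float), fill=0.0
        )
        dist = ndimage.distance_transform_edt(bvol == 0.0)
        i, j, k = grid.node_ijk.T
        tiny |= dist[i, j, k] <= update_margin_voxels
    if strain_smooth_sigma_voxels > 0:
        target_strain = _smooth_node_field(
            grid, target_strain, strain_smooth_sigma_voxels
        )

    ym = ElasticityMap(
        init.ym.copy(), "estimated", init.ym_min, init.ym_max
    )
    trace: list[float] = []
    warm = None
    growing = 0
    for outer in range(1, max_outer + 1):
        state = forward_solve(
            grid, ym, tol=forward_tol, max_iter=forward_max_iter,
            warm_start=warm,
        )
        warm = state.displacements
        err = float(
            np.mean(
                np.linalg.norm(
                    state.displacements[interior] - target_u[interior], axis=1
                )
            )
        ) if interior.any() else 0.0
        trace.append(err)
        logger.info("inverse outer %d: mean DVF error %.4f mm", outer, err)
        if err <= outer_tol:
            return EstimationResult(ym, trace, outer, True)
        if (
            len(trace) >= 2
            and err > (1.0 - min_improvement) * trace[-2]
        ):
            return EstimationResult(ym, trace, outer, False, stalled=True)
        if len(trace) >= 2 and err > trace[-2]:
            growing += 1
            if growing >= 5:
                raise EstimationDivergenceError(
                    f"mean DVF error grew for 5 consecutive iterations "
                    f"(last {err:.4f} mm)"
                )
        else:
            growing = 0

        model_strain = _node_strain(grid, state.displacements)
        if strain_smooth_sigma_voxels > 0:
            model_strain = _smooth_node_field(
                grid, model_strain, strain_smooth_sigma_voxels
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = model_strain / target_strain
        factor = np.where(tiny, 1.0, ratio) ** gamma
        factor = _fill_from_neighbors(grid, factor, ~tiny)
        factor = np.clip(factor, 0.25, 4.0)
        new_ym = np.clip(ym.ym * factor, ym.ym_min, ym.ym_max)
        sigma_k = ym_smooth_sigma_voxels * ym_smooth_decay ** (outer - 1)
        if sigma_k > 0.05:
            new_ym = np.exp(_smooth_node_field(grid, np.log(new_ym), sigma_k))
        ym = ElasticityMap(new_ym, "estimated", ym.ym_min, ym.ym_max)
    return EstimationResult(ym, trace, max_outer, False)
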