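"""Quasi-static extracellular potential solve on a voxelised layered slab.

The potential obeys the conduction equation div(sigma grad phi) = 0 with
current injected through disc electrode footprints on the skin surface
(uniform Neumann current density over each active disc), an insulating
boundary elsewhere on the top and sides, and a grounded (phi = 0) bottom
face standing in for a distant return electrode.

Discretisation is cell-centred finite volume on a tensor-product grid
whose vertical coordinates are aligned to the four layer interfaces, so
every cell lies in exactly one tissue layer.  Face conductances use the
harmonic mean of the adjacent cell conductivities, which preserves
current continuity across layer interfaces; the resulting system is
symmetric positive definite.

Coordinates are right-handed with z increasing into the skin and the
surface at z = 0.  Lengths are mm at the API surface and metres inside
the assembly; potentials are volts and fields V/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .config_space import ArrayLayout, ElectrodeConfig, electrode_centers
from .tissue import FingertipModel, effective_conductivity

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class GridResolution:
    """Voxel-grid resolution controls.

    ``lateral_step_mm`` sets the uniform x/y cell size; ``cells_per_layer``
    the vertical cell count inside each of the four layers (every layer
    must span at least two cells so the interface-aligned conductivity
    profile is resolved).
    """

    lateral_step_mm: float = 1.0
    cells_per_layer: tuple[int, int, int, int] = (2, 2, 8, 8)
    margin_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.lateral_step_mm <= 0:
            raise ValueError("lateral step must be positive")
        if any(n < 2 for n in self.cells_per_layer):
            raise ValueError("every layer needs at least 2 vertical cells")


@dataclass
class VoxelGrid:
    """Tensor-product voxel grid with per-cell conductivity.

    Arrays are indexed ``[iz, iy, ix]`` with iz = 0 the surface row of
    cells.  Edge coordinates are in mm.
    """

    x_edges_mm: np.ndarray
    y_edges_mm: np.ndarray
    z_edges_mm: np.ndarray
    sigma: np.ndarray  # (nz, ny, nx), S/m
    layer_index: np.ndarray  # (nz, ny, nx), int

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("cell conductivities must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sigma.shape

    @property
    def x_centers_mm(self) -> np.ndarray:
        return 0.5 * (self.x_edges_mm[:-1] + self.x_edges_mm[1:])

    @property
    def y_centers_mm(self) -> np.ndarray:
        return 0.5 * (self.y_edges_mm[:-1] + self.y_edges_mm[1:])

    @property
    def z_centers_mm(self) -> np.ndarray:
        return 0.5 * (self.z_edges_mm[:-1] + self.z_edges_mm[1:])

    @property
    def cell_volumes_m3(self) -> np.ndarray:
        dx = np.diff(self.x_edges_mm) * MM
        dy = np.diff(self.y_edges_mm) * MM
        dz = np.diff(self.z_edges_mm) * MM
        return dz[:, None, None] * dy[None, :, None] * dx[None, None, :]

    @classmethod
    def from_layers(
        cls,
        x_edges_mm: Sequence[float],
        y_edges_mm: Sequence[float],
        layers: Sequence[tuple[float, float, int]],
    ) -> "VoxelGrid":
        """Build a grid from ``(thickness_mm, sigma_S_per_m, n_cells)`` rows.

        A generic constructor used both by :func:`build_grid` and by
        closed-form test harnesses (homogeneous or two-layer slabs).
        """
        x = np.asarray(x_edges_mm, dtype=float)
        y = np.asarray(y_edges_mm, dtype=float)
        z_parts = [np.array([0.0])]
        sig_cols: list[np.ndarray] = []
        idx_cols: list[np.ndarray] = []
        z0 = 0.0
        for li, (thick, sigma, n) in enumerate(layers):
            if n < 2:
                raise ValueError("every layer needs at least 2 vertical cells")
            edges = np.linspace(z0, z0 + thick, n + 1)
            z_parts.append(edges[1:])
            sig_cols.append(np.full(n, sigma))
            idx_cols.append(np.full(n, li, dtype=int))
            z0 += thick
        z = np.concatenate(z_parts)
        nz = len(z) - 1
        ny = len(y) - 1
        nx = len(x) - 1
        sigma_map = np.broadcast_to(
            np.concatenate(sig_cols)[:, None, None], (nz, ny, nx)
        ).copy()
        layer_map = np.broadcast_to(
            np.concatenate(idx_cols)[:, None, None], (nz, ny, nx)
        ).copy()
        return cls(x, y, z, sigma_map, layer_map)


def build_grid(
    model: FingertipModel,
    config: ElectrodeConfig,
    resolution: GridResolution = GridResolution(),
) -> VoxelGrid:
    """Voxelise a fingertip model, checking the array fits laterally."""
    ext_x, ext_y = model.lateral_extent_mm
    width = 2 * config.diameter_mm + config.spacing_mm
    height = 3 * config.diameter_mm + 2 * config.spacing_mm
    if width + 2 * resolution.margin_mm > ext_x or height + 2 * resolution.margin_mm > ext_y:
        raise ValueError(
            f"array bounding rectangle {width:.1f} x {height:.1f} mm plus "
            f"{resolution.margin_mm} mm margin does not fit lateral extent {model.lateral_extent_mm}"
        )
    step = resolution.lateral_step_mm
    nx = max(int(round(ext_x / step)), 2)
    ny = max(int(round(ext_y / step)), 2)
    x_edges = np.linspace(-ext_x / 2, ext_x / 2, nx + 1)
    y_edges = np.linspace(-ext_y / 2, ext_y / 2, ny + 1)
    rows = [
        (
            layer.thickness_mm,
            effective_conductivity(layer.cole_cole, model.effective_frequency_hz),
            n,
        )
        for layer, n in zip(model.layers, resolution.cells_per_layer)
    ]
    return VoxelGrid.from_layers(x_edges, y_edges, rows)


@dataclass(frozen=True)
class FieldFeatures:
    """Scalar summaries of the field-magnitude distribution over a region."""

    e_max: float  # V/m
    e_avg: float  # V/m, volume-weighted mean
    e_int: float  # V*m^2, sum of |E| * cell volume
    region: str = "below_stratum_corneum"


@dataclass
class PotentialField:
    """Solved nodal (cell-centre) potential, referenced to the grounded face."""

    phi: np.ndarray  # (nz, ny, nx), volts
    grid: VoxelGrid
    injected_current_ma: float
    residual: float


def _face_conductances(grid: VoxelGrid):
    """Harmonic-mean face conductances (S) in x, y, z plus the bottom
    Dirichlet half-cell conductances."""
    sig = grid.sigma
    dx = np.diff(grid.x_edges_mm) * MM
    dy = np.diff(grid.y_edges_mm) * MM
    dz = np.diff(grid.z_edges_mm) * MM

    def harm(a, b):
        return 2.0 * a * b / (a + b)

    # x faces: between ix and ix+1
    ax = dy[None, :, None] * dz[:, None, None]
    gx = harm(sig[:, :, :-1], sig[:, :, 1:]) * ax / (0.5 * (dx[:-1] + dx[1:]))[None, None, :]
    ay = dx[None, None, :] * dz[:, None, None]
    gy = harm(sig[:, :-1, :], sig[:, 1:, :]) * ay / (0.5 * (dy[:-1] + dy[1:]))[None, :, None]
    az = dx[None, :] * dy[:, None]  # (ny, nx)
    gz = harm(sig[:-1, :, :], sig[1:, :, :]) * az[None, :, :] / (
        0.5 * (dz[:-1] + dz[1:])
    )[:, None, None]
    g_bottom = sig[-1, :, :] * az / (dz[-1] / 2.0)
    return gx, gy, gz, g_bottom


def _assemble(grid: VoxelGrid) -> sp.csr_matrix:
    nz, ny, nx = grid.shape
    n = nz * ny * nx
    gx, gy, gz, g_bottom = _face_conductances(grid)

    def flat(iz, iy, ix):
        return (iz * ny + iy) * nx + ix

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n)

    iz, iy, ix = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx - 1), indexing="ij")
    a = flat(iz, iy, ix).ravel()
    b = flat(iz, iy, ix + 1).ravel()
    g = gx.ravel()
    rows += [a, b]
    cols += [b, a]
    vals += [-g, -g]
    np.add.at(diag, a, g)
    np.add.at(diag, b, g)

    iz, iy, ix = np.meshgrid(np.arange(nz), np.arange(ny - 1), np.arange(nx), indexing="ij")
    a = flat(iz, iy, ix).ravel()
    b = flat(iz, iy + 1, ix).ravel()
    g = gy.ravel()
    rows += [a, b]
    cols += [b, a]
    vals += [-g, -g]
    np.add.at(diag, a, g)
    np.add.at(diag, b, g)

    iz, iy, ix = np.meshgrid(np.arange(nz - 1), np.arange(ny), np.arange(nx), indexing="ij")
    a = flat(iz, iy, ix).ravel()
    b = flat(iz + 1, iy, ix).ravel()
    g = gz.ravel()
    rows += [a, b]
    cols += [b, a]
    vals += [-g, -g]
    np.add.at(diag, a, g)
    np.add.at(diag, b, g)

    # grounded bottom face via half-cell conductance to phi = 0
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    a = flat(np.full_like(iy, nz - 1), iy, ix).ravel()
    np.add.at(diag, a, g_bottom.ravel())

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return A.tocsr()


def top_source_from_discs(
    grid: VoxelGrid, layout: ArrayLayout, active: Iterable[int], current_ma: float
) -> np.ndarray:
    """Per-top-cell injected current (A), uniform density over the active discs."""
    active = sorted(set(active))
    if not active:
        raise ValueError("at least one active electrode is required")
    if any(i < 0 or i >= len(layout.centers) for i in active):
        raise ValueError(f"active electrode indices must be in 0..{len(layout.centers) - 1}")
    xc = grid.x_centers_mm
    yc = grid.y_centers_mm
    X, Y = np.meshgrid(xc, yc, indexing="xy")  # (ny, nx)
    covered = np.zeros_like(X, dtype=bool)
    r = layout.radius_mm
    for i in active:
        cx, cy = layout.centers[i]
        covered |= (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
    if not covered.any():
        raise ValueError("no surface cell lies under an active disc; refine the grid")
    dx = np.diff(grid.x_edges_mm) * MM
    dy = np.diff(grid.y_edges_mm) * MM
    areas = dy[:, None] * dx[None, :]
    total = float(areas[covered].sum())
    b_top = np.zeros_like(areas)
    b_top[covered] = (current_ma * 1e-3) * areas[covered] / total
    return b_top


def solve_potential(
    grid: VoxelGrid,
    *,
    layout: ArrayLayout | None = None,
    active: Iterable[int] | None = None,
    top_current_a: np.ndarray | None = None,
    current_ma: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    method: str = "cg",
) -> PotentialField:
    """Solve div(sigma grad phi) = 0 with disc-source Neumann top boundary.

    Either ``layout``+``active`` (disc footprints carrying ``current_ma``
    total) or an explicit per-top-cell current array ``top_current_a``
    must be given.  ``method`` is "cg" (Jacobi-preconditioned conjugate
    gradients at relative tolerance ``tol``, default; the system is
    symmetric positive definite and deterministic) or "direct" (sparse
    LU in symmetric mode).  The discrete residual is checked in both
    cases.
    """
    if not 0.0 <= abs(current_ma) <= 10.0:
        raise ValueError("drive amplitude must lie within the 0-10 mA device range")
    nz, ny, nx = grid.shape
    if top_current_a is None:
        if layout is None or active is None:
            raise ValueError("provide layout+active or an explicit top_current_a array")
        top_current_a = top_source_from_discs(grid, layout, active, current_ma)
    else:
        top_current_a = np.asarray(top_current_a, dtype=float)
        if top_current_a.shape != (ny, nx):
            raise ValueError("top_current_a must have shape (ny, nx)")
        current_ma = float(top_current_a.sum() / 1e-3)

    b = np.zeros(nz * ny * nx)
    b[: ny * nx] = top_current_a.ravel()

    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        return PotentialField(np.zeros((nz, ny, nx)), grid, 0.0, 0.0)

    A = _assemble(grid)
    if method == "direct":
        lu = spla.splu(
            A.tocsc(),
            permc_spec="MMD_AT_PLUS_A",
            options=dict(SymmetricMode=True),
            diag_pivot_thresh=0.0,
        )
        phi = lu.solve(b)
    elif method == "cg":
        M = spla.LinearOperator(A.shape, matvec=lambda v: v / A.diagonal())
        phi, info = spla.cg(A, b, rtol=tol, maxiter=max_iter, M=M)
        if info != 0:
            res = float(np.linalg.norm(A @ phi - b) / bnorm)
            raise RuntimeError(
                f"CG failed to converge within {max_iter} iterations (residual {res:.3e})"
            )
    else:
        raise ValueError(f"unknown solver method {method!r}")
    residual = float(np.linalg.norm(A @ phi - b) / bnorm)
    if residual > 10 * tol:
        raise RuntimeError(f"solver residual {residual:.3e} exceeds 10*tol")
    return PotentialField(phi.reshape(nz, ny, nx), grid, current_ma, residual)


def plane_current_a(p: PotentialField, k: int) -> float:
    """Net current (A) crossing the horizontal cell-interface plane ``k``
    (between cell rows k and k+1); k = nz-1 is the grounded bottom face.

    Used to verify discrete current conservation: every plane should
    carry the full injected current.
    """
    grid = p.grid
    nz = grid.shape[0]
    _, _, gz, g_bottom = _face_conductances(grid)
    if k == nz - 1:
        return float((g_bottom * p.phi[-1]).sum())
    if not 0 <= k < nz - 1:
        raise ValueError("plane index out of range")
    return float((gz[k] * (p.phi[k] - p.phi[k + 1])).sum())


def electric_field(p: PotentialField) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre field E = -grad(phi) via central differences.

    Returns ``(e_vec, e_mag)`` where ``e_vec`` has shape (3, nz, ny, nx)
    ordered (Ex, Ey, Ez) in V/m.
    """
    zc = p.grid.z_centers_mm * MM
    yc = p.grid.y_centers_mm * MM
    xc = p.grid.x_centers_mm * MM
    dz, dy, dx = np.gradient(p.phi, zc, yc, xc)
    e_vec = np.stack([-dx, -dy, -dz])
    e_mag = np.sqrt((e_vec**2).sum(axis=0))
    return e_vec, e_mag


REGIONS = ("all", "below_stratum_corneum", "dermis")


def extract_field_features(
    e_mag: np.ndarray, grid: VoxelGrid, region: str = "below_stratum_corneum"
) -> FieldFeatures:
    """Emax / Eavg / Eint of the field magnitude over a tissue region.

    The default region excludes the stratum corneum so that contact-edge
    cells do not dominate Emax; perception arises in the innervated
    deeper layers.
    """
    if region == "all":
        mask = np.ones(grid.shape, dtype=bool)
    elif region == "below_stratum_corneum":
        mask = grid.layer_index >= 1
    elif region == "dermis":
        mask = grid.layer_index == 2
    else:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if not mask.any():
        raise ValueError(f"region {region!r} contains no cells")
    vols = grid.cell_volumes_m3[mask]
    mags = e_mag[mask]
    e_int = float((mags * vols).sum())
    e_avg = float(e_int / vols.sum())
    return FieldFeatures(e_max=float(mags.max()), e_avg=e_avg, e_int=e_int, region=region)


def sample_potential_along_path(p: PotentialField, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of phi (V) at ``points_mm`` given as (n, 3)
    rows of (x, y, z) in mm.

    Because phi is referenced to the grounded face, these values equal
    the line integral of -E from each point to the reference, so they
    serve directly as per-node extracellular potentials.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    interp = RegularGridInterpolator(
        (p.grid.z_centers_mm, p.grid.y_centers_mm, p.grid.x_centers_mm),
        p.phi,
        bounds_error=True,
    )
    try:
        return interp(pts[:, [2, 1, 0]])
    except ValueError as exc:
        raise ValueError(f"sample point outside the interpolable grid interior: {exc}") from exc


def save_field_h5(path: str, p: PotentialField, e_mag: np.ndarray | None = None) -> None:
    """Persist a field snapshot (coordinates, sigma, phi, optionally |E|)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("x_edges_mm", data=p.grid.x_edges_mm)
        f.create_dataset("y_edges_mm", data=p.grid.y_edges_mm)
        f.create_dataset("z_edges_mm", data=p.grid.z_edges_mm)
        f.create_dataset("sigma_s_per_m", data=p.grid.sigma)
        f.create_dataset("phi_v", data=p.phi)
        if e_mag is not None:
            f.create_dataset("e_mag_v_per_m", data=e_mag)
        f.attrs["injected_current_ma"] = p.injected_current_ma
        f.attrs["residual"] = p.residual
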