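"""Sorter geometry and the 2-D Stokes flow in one column unit cell.

The device is a row of identical vertical columns bridged by a feed
conduit below and a collection conduit above, both pumped left-to-right at
the same mean velocity.  With the device Reynolds number well below one
(rho U L / mu ~ 0.3), inertia is negligible and the planar (x-z) flow in a
periodic unit cell -- one column plus half a wall pitch of each conduit on
either side -- satisfies the Stokes equations.  They are solved here in
stream-function/vorticity form,

    lap(psi) = -omega,      lap(omega) = 0,

by red-black SOR with Thom's wall-vorticity closure.  Fully developed
plane-Poiseuille profiles are imposed at the four conduit ports, and zero
net flux through the column is imposed through the wall stream-function
constants (both column walls carry the same psi), matching the observed
absence of conduit-to-conduit crossflow in the physical device.

The third dimension (3 mm depth) is treated as invariant; the planar model
replaces a full 3-D CFD solve, so its diagnostics are order-of-magnitude
statements about the real device, not calibrated predictions.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, SolverError
from .units import to_si


@dataclass(frozen=True)
class SorterGeometry:
    """Dimensions of the sorter and its operating velocity (SI units).

    Defaults reproduce the reference device: ten 18 x 3 x 3 mm columns,
    1 x 3 mm conduits, 41 mm internal length, 0.5 mm/s mean conduit
    velocity.  ``column_pitch`` is derived as device_length / n_columns.
    """

    n_columns: int = 10
    column_height: float = 18e-3
    column_width: float = 3e-3
    column_depth: float = 3e-3
    feed_height: float = 1e-3
    collection_height: float = 1e-3
    conduit_depth: float = 3e-3
    device_length: float = 41e-3
    mean_conduit_velocity: float = 0.5e-3

    def __post_init__(self):
        if self.n_columns < 1:
            raise InvalidInputError("need at least one column")
        positive = (
            "column_width column_depth feed_height collection_height "
            "conduit_depth device_length"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.mean_conduit_velocity < 0:
            raise InvalidInputError("mean_conduit_velocity must be >= 0")
        if self.column_height < 0:
            raise InvalidInputError("column_height must be >= 0")
        if self.column_pitch < self.column_width:
            raise InvalidInputError(
                "column pitch (device_length / n_columns) smaller than column width"
            )

    @property
    def column_pitch(self) -> float:
        return self.device_length / self.n_columns

    @property
    def total_height(self) -> float:
        return self.feed_height + self.column_height + self.collection_height

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_GEOMETRY_KEYS = {
    "n_columns": None,
    "column_height": "length",
    "column_width": "length",
    "column_depth": "length",
    "feed_height": "length",
    "collection_height": "length",
    "conduit_depth": "length",
    "device_length": "length",
    "mean_conduit_velocity": "velocity",
}


def build_geometry(config: dict | None = None) -> SorterGeometry:
    """Build a geometry from a (possibly unit-suffixed) config mapping.

    An empty config yields the reference device.  Degenerate dimensions
    (e.g. a zero column height) are rejected here; the bare dataclass still
    accepts ``column_height=0`` as the straight-conduit validation limit.
    """
    config = dict(config or {})
    kwargs = {}
    for key, value in config.items():
        if key not in _GEOMETRY_KEYS:
            raise InvalidInputError(f"unknown geometry key {key!r}")
        if key == "n_columns":
            kwargs[key] = int(value)
        else:
            kwargs[key] = to_si(value, _GEOMETRY_KEYS[key])
    geom = SorterGeometry(**kwargs)
    if geom.column_height <= 0:
        raise InvalidInputError("column_height must be > 0 for a sorting device")
    return geom


@dataclass
class FlowField2D:
    """Discrete stream-function/velocity field on the x-z unit cell.

    Arrays are indexed ``[iz, ix]`` with z up.  ``mask`` is True on fluid
    nodes (walls included); velocity is identically zero on solid and wall
    nodes.  ``velocity_at`` interpolates bilinearly and wraps x by the
    column pitch, so the same unit-cell field serves the whole device.
    """

    x: np.ndarray
    z: np.ndarray
    psi: np.ndarray
    u_x: np.ndarray
    u_z: np.ndarray
    mask: np.ndarray
    grid_spacing: float
    residual: float
    geometry: SorterGeometry
    residual_history: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u_x, self.u_z)

    @property
    def max_speed(self) -> float:
        return float(self.speed.max(initial=0.0))

    def velocity_at(self, xq, zq) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear velocity sample at arbitrary points (x wrapped by pitch)."""
        p = self.geometry.column_pitch
        xq = np.mod(np.asarray(xq, dtype=float), p)
        zq = np.asarray(zq, dtype=float)
        h = self.grid_spacing
        fx = np.clip(xq / h, 0.0, self.x.size - 1.001)
        fz = np.clip(zq / h, 0.0, self.z.size - 1.001)
        i0 = fx.astype(int)
        k0 = fz.astype(int)
        tx = fx - i0
        tz = fz - k0
        ux = (
            self.u_x[k0, i0] * (1 - tx) * (1 - tz)
            + self.u_x[k0, i0 + 1] * tx * (1 - tz)
            + self.u_x[k0 + 1, i0] * (1 - tx) * tz
            + self.u_x[k0 + 1, i0 + 1] * tx * tz
        )
        uz = (
            self.u_z[k0, i0] * (1 - tx) * (1 - tz)
            + self.u_z[k0, i0 + 1] * tx * (1 - tz)
            + self.u_z[k0 + 1, i0] * (1 - tx) * tz
            + self.u_z[k0 + 1, i0 + 1] * tx * tz
        )
        return ux, uz

    def to_frame(self):
        import pandas as pd

        zz, xx = np.meshgrid(self.z, self.x, indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "z": zz.ravel(),
                "u_x": self.u_x.ravel(),
                "u_z": self.u_z.ravel(),
                "psi": self.psi.ravel(),
                "fluid": self.mask.ravel().astype(int),
            }
        )


def _poiseuille_profile(s: np.ndarray, mean: float) -> np.ndarray:
    """Plane-Poiseuille velocity with unit-mean normalisation (peak 1.5x)."""
    return 6.0 * mean * s * (1.0 - s)


def _cell_layout(geom: SorterGeometry, h: float):
    """Snap the unit cell onto the grid; returns index bounds."""
    nxc = int(round(geom.column_pitch / h))
    kf = int(round(geom.feed_height / h))
    kc = int(round(geom.column_height / h))
    kt = int(round(geom.collection_height / h))
    nw = int(round(geom.column_width / h))
    if kf < 4 or kt < 4:
        raise InvalidInputError("grid too coarse for the conduit heights")
    if kc > 0 and (nw < 4 or nxc - nw < 2):
        raise InvalidInputError("grid too coarse for the column width")
    i0 = (nxc - nw) // 2  # column wall snapped to the nearest node
    return nxc, kf, kc, kt, nw, i0


def solve_unit_cell_flow(
    geometry: SorterGeometry,
    grid_spacing: float = 1e-4,
    tolerance: float = 1e-8,
    max_iterations: int = 200_000,
    sor_factor: float = 1.7,
    wall_relax: float = 0.5,
    check_every: int = 200,
) -> FlowField2D:
    """Solve the steady Stokes flow in one column unit cell.

    Boundary conditions: plane Poiseuille (mean ``geometry.mean_conduit_velocity``)
    at all four conduit ports, no-slip on every wall, zero net flux through
    the column imposed via equal wall stream-function constants.  With
    ``column_height == 0`` the domain degenerates to the feed conduit alone
    (the straight-channel validation limit).

    Raises :class:`SolverError` (carrying the residual history) on
    non-convergence within ``max_iterations``.
    """
    geom = geometry
    h = float(grid_spacing)
    if geom.column_height > 0 and h > geom.column_width / 10 + 1e-15:
        raise InvalidInputError("grid_spacing must be <= column_width / 10")

    nxc, kf, kc, kt, nw, i0 = _cell_layout(geom, h)
    u_mean = geom.mean_conduit_velocity
    q_b = u_mean * geom.feed_height  # 2-D flux per unit depth
    straight = kc == 0
    if straight:
        nz = kf + 1
        q_t = 0.0
    else:
        nz = kf + kc + kt + 1
        q_t = u_mean * geom.collection_height
    nx = nxc + 1

    fluid = np.zeros((nz, nx), dtype=bool)
    fluid[: kf + 1, :] = True
    if not straight:
        fluid[kf + kc :, :] = True
        fluid[kf : kf + kc + 1, i0 : i0 + nw + 1] = True

    solid_pad = np.ones((nz + 2, nx + 2), dtype=bool)
    solid_pad[1:-1, 1:-1] = ~fluid
    # any of the 8 neighbours solid (or off-grid vertically)
    near_solid = np.zeros((nz, nx), dtype=bool)
    for dz in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dz == 0 and dx == 0:
                continue
            near_solid |= solid_pad[1 + dz : nz + 1 + dz, 1 + dx : nx + 1 + dx]

    ix_grid = np.broadcast_to(np.arange(nx), (nz, nx))
    port = fluid & ((ix_grid == 0) | (ix_grid == nx - 1))
    wall = fluid & near_solid & ~port
    interior = fluid & ~wall & ~port

    z = np.arange(nz) * h
    x = np.arange(nx) * h

    # --- Dirichlet stream function -------------------------------------
    psi = np.zeros((nz, nx))
    smooth = lambda s: 3.0 * s**2 - 2.0 * s**3  # integral of Poiseuille
    # ports
    omega = np.zeros((nz, nx))
    for col in (0, nx - 1):
        rows = np.nonzero(fluid[:, col])[0]
        bot = rows[rows <= kf]
        s = z[bot] / geom.feed_height
        psi[bot, col] = q_b * smooth(s)
        omega[bot, col] = -6.0 * u_mean * (1.0 - 2.0 * s) / geom.feed_height
        if not straight:
            top = rows[rows >= kf + kc]
            s = (z[top] - (geom.feed_height + geom.column_height)) / geom.collection_height
            psi[top, col] = q_b + q_t * smooth(s)
            omega[top, col] = -6.0 * u_mean * (1.0 - 2.0 * s) / geom.collection_height
    # walls: floor 0, ceiling q_b + q_t, everything between q_b
    wz, wx = np.nonzero(wall)
    wall_psi = np.full(wz.size, q_b)
    wall_psi[wz == 0] = 0.0
    wall_psi[wz == nz - 1] = q_b + q_t
    psi[wz, wx] = wall_psi

    if u_mean == 0.0:
        u_x = np.zeros_like(psi)
        u_z = np.zeros_like(psi)
        return FlowField2D(x, z, psi, u_x, u_z, fluid, h, 0.0, geom, [], {"iterations": 0})

    # --- index bookkeeping for vectorised red-black SOR -----------------
    iz, ix = np.nonzero(interior)
    parity = (iz + ix) & 1
    groups = [(iz[parity == c], ix[parity == c]) for c in (0, 1)]

    # wall-vorticity closure: one- and two-cell neighbours along each normal.
    # Jensen's (7 psi_w - 8 psi_1 + psi_2) / (2 h^2) is second order (exact
    # for the cubic Poiseuille stream function); fall back to Thom's
    # 2 (psi_w - psi_1) / h^2 when the two-cell node is not fluid.
    int_pad = np.zeros((nz + 2, nx + 2), dtype=bool)
    int_pad[1:-1, 1:-1] = interior
    flu_pad = np.zeros((nz + 4, nx + 4), dtype=bool)
    flu_pad[2:-2, 2:-2] = fluid
    nbr_dirs = ((1, 0), (-1, 0), (0, 1), (0, -1))
    nbr_ok = []
    nbr2_ok = []
    for dz, dx in nbr_dirs:
        ok1 = int_pad[1 + wz + dz, 1 + wx + dx]
        ok2 = ok1 & flu_pad[2 + wz + 2 * dz, 2 + wx + 2 * dx]
        nbr_ok.append(ok1)
        nbr2_ok.append(ok2)
    nbr_ok = np.array(nbr_ok)  # (4, n_wall)
    nbr2_ok = np.array(nbr2_ok)
    nbr_cnt = nbr_ok.sum(axis=0)
    has_nbr = nbr_cnt > 0

    h2 = h * h
    omega_scale = 6.0 * u_mean / min(geom.feed_height, geom.collection_height)
    residual_history: list[float] = []

    def _sweep(arr, src, w):
        # SOR on lap(arr) = -src (src=omega for psi, 0 for omega itself)
        for giz, gix in groups:
            new = 0.25 * (
                arr[giz, gix + 1]
                + arr[giz, gix - 1]
                + arr[giz + 1, gix]
                + arr[giz - 1, gix]
                + (h2 * src[giz, gix] if src is not None else 0.0)
            )
            arr[giz, gix] += w * (new - arr[giz, gix])

    converged = False
    iterations = 0
    for it in range(1, max_iterations + 1):
        iterations = it
        _sweep(psi, omega, sor_factor)
        # wall vorticity, averaged over available normal directions
        num = np.zeros(wz.size)
        for d, (dz, dx) in enumerate(nbr_dirs):
            ok1 = nbr_ok[d]
            ok2 = nbr2_ok[d]
            thom_only = ok1 & ~ok2
            if np.any(ok2):
                num[ok2] += (
                    7.0 * psi[wz[ok2], wx[ok2]]
                    - 8.0 * psi[wz[ok2] + dz, wx[ok2] + dx]
                    + psi[wz[ok2] + 2 * dz, wx[ok2] + 2 * dx]
                ) / 4.0
            if np.any(thom_only):
                num[thom_only] += (
                    psi[wz[thom_only], wx[thom_only]]
                    - psi[wz[thom_only] + dz, wx[thom_only] + dx]
                )
        new_wall = np.zeros(wz.size)
        new_wall[has_nbr] = 2.0 * num[has_nbr] / (nbr_cnt[has_nbr] * h2)
        omega[wz, wx] += wall_relax * (new_wall - omega[wz, wx])
        _sweep(omega, None, 1.0)

        if it % check_every == 0:
            res_psi = np.abs(
                psi[iz, ix + 1] + psi[iz, ix - 1] + psi[iz + 1, ix] + psi[iz - 1, ix]
                - 4.0 * psi[iz, ix] + h2 * omega[iz, ix]
            ).max() / (h2 * omega_scale)
            res_om = np.abs(
                omega[iz, ix + 1] + omega[iz, ix - 1] + omega[iz + 1, ix]
                + omega[iz - 1, ix] - 4.0 * omega[iz, ix]
            ).max() / (4.0 * omega_scale)
            res = max(res_psi, res_om)
            residual_history.append(res)
            if res <= tolerance:
                converged = True
                break
    if not converged:
        raise SolverError(
            f"stream-function/vorticity iteration did not reach {tolerance:g} "
            f"within {max_iterations} iterations (last residual "
            f"{residual_history[-1] if residual_history else math.nan:g})",
            residual_history,
        )

    # differentiate on a copy whose solid web carries the wall constant,
    # otherwise one-sided stencils at ports/walls read garbage across it
    psi_fill = psi.copy()
    psi_fill[~fluid] = q_b
    u_x = np.gradient(psi_fill, h, axis=0)
    u_z = -np.gradient(psi_fill, h, axis=1)
    moving = interior | port
    u_x[~moving] = 0.0
    u_z[~moving] = 0.0
    # ports carry the imposed fully developed profile exactly
    for col in (0, nx - 1):
        rows = np.nonzero(fluid[:, col])[0]
        bot = rows[rows <= kf]
        u_x[bot, col] = _poiseuille_profile(z[bot] / geom.feed_height, u_mean)
        u_z[bot, col] = 0.0
        if not straight:
            top = rows[rows >= kf + kc]
            s = (z[top] - (geom.feed_height + geom.column_height)) / geom.collection_height
            u_x[top, col] = _poiseuille_profile(s, u_mean)
            u_z[top, col] = 0.0

    return FlowField2D(
        x,
        z,
        psi,
        u_x,
        u_z,
        fluid,
        h,
        residual_history[-1],
        geom,
        residual_history,
        {"iterations": iterations, "tolerance": tolerance, "sor_factor": sor_factor},
    )


def analytic_fallback_field(geometry: SorterGeometry, grid_spacing: float = 1e-4) -> FlowField2D:
    """Cheap divergence-consistent stand-in for the solved field.

    Plane Poiseuille in both conduits (everywhere along x, ignoring the
    junction perturbation), zero velocity inside the columns.  Useful for
    fast agent simulations and as a degenerate reference in tests; it has
    no junction vortices by construction.
    """
    geom = geometry
    h = float(grid_spacing)
    nxc, kf, kc, kt, nw, i0 = _cell_layout(geom, h)
    straight = kc == 0
    nz = (kf + 1) if straight else (kf + kc + kt + 1)
    nx = nxc + 1
    u_mean = geom.mean_conduit_velocity
    q_b = u_mean * geom.feed_height
    q_t = 0.0 if straight else u_mean * geom.collection_height

    z = np.arange(nz) * h
    x = np.arange(nx) * h
    fluid = np.zeros((nz, nx), dtype=bool)
    fluid[: kf + 1, :] = True
    psi = np.zeros((nz, nx))
    u_x = np.zeros((nz, nx))
    smooth = lambda s: 3.0 * s**2 - 2.0 * s**3
    s = np.clip(z[: kf + 1] / geom.feed_height, 0.0, 1.0)
    psi[: kf + 1, :] = (q_b * smooth(s))[:, None]
    u_x[: kf + 1, :] = _poiseuille_profile(s, u_mean)[:, None]
    if not straight:
        fluid[kf + kc :, :] = True
        fluid[kf : kf + kc + 1, i0 : i0 + nw + 1] = True
        psi[kf : kf + kc, i0 : i0 + nw + 1] = q_b
        st = np.clip(
            (z[kf + kc :] - (geom.feed_height + geom.column_height))
            / geom.collection_height,
            0.0,
            1.0,
        )
        psi[kf + kc :, :] = (q_b + q_t * smooth(st))[:, None]
        u_x[kf + kc :, :] = _poiseuille_profile(st, u_mean)[:, None]
    # no-slip rows
    u_x[0, :] = 0.0
    u_x[min(kf, nz - 1), :] = np.where(fluid[min(kf, nz - 1), :], u_x[min(kf, nz - 1), :], 0.0)
    u_z = np.zeros_like(u_x)
    return FlowField2D(
        x, z, psi, u_x, u_z, fluid, h, 0.0, geom, [], {"kind": "analytic"}
    )


def _column_interior(field: FlowField2D):
    """Index bounds of column nodes at least one cell from the side walls."""
    geom = field.geometry
    h = field.grid_spacing
    nxc, kf, kc, kt, nw, i0 = _cell_layout(geom, h)
    if kc == 0:
        return None
    return kf, kf + kc, i0 + 1, i0 + nw  # z rows [kf, kf+kc], x cols (i0, i0+nw)


def vortex_diagnostics(
    field: FlowField2D,
    geometry: SorterGeometry | None = None,
    threshold: float = 0.01,
    mouth: str = "bottom",
) -> tuple[float, float]:
    """Peak circulation speed in the column and vortex penetration depth.

    ``max_column_speed`` is the maximum speed over column nodes more than
    one grid cell from the side walls.  ``penetration_depth`` is the
    distance from the chosen column mouth at which the horizontal-slice
    maximum speed first falls below ``threshold`` (default 1%) of its
    mouth value (linearly interpolated between rows); a column too short
    for the decay returns its full height.
    """
    geom = geometry or field.geometry
    bounds = _column_interior(field)
    if bounds is None:
        raise InvalidInputError("field has no column (straight-conduit domain)")
    k_lo, k_hi, i_lo, i_hi = bounds
    speed = field.speed
    block = speed[k_lo : k_hi + 1, i_lo:i_hi]
    if block.size == 0 or not np.any(block > 0):
        return 0.0, 0.0
    # interior excludes the mouth rows shared with the conduits
    max_speed = float(speed[k_lo + 1 : k_hi, i_lo:i_hi].max(initial=0.0))
    slice_max = block.max(axis=1)
    if mouth == "bottom":
        profile = slice_max
    elif mouth == "top":
        profile = slice_max[::-1]
    else:
        raise InvalidInputError("mouth must be 'bottom' or 'top'")
    ref = profile[0]
    if ref <= 0:
        return max_speed, 0.0
    h = field.grid_spacing
    below = np.nonzero(profile < threshold * ref)[0]
    if below.size == 0:
        return max_speed, geom.column_height
    k = below[0]
    # linear interpolation between rows k-1 and k
    f_hi, f_lo = profile[k - 1], profile[k]
    frac = (f_hi - threshold * ref) / (f_hi - f_lo) if f_hi > f_lo else 0.0
    return max_speed, float((k - 1 + frac) * h)


def transit_time(length: float, mean_velocity: float) -> float:
    """Advection time ``length / mean_velocity`` of a fluid parcel."""
    if not mean_velocity > 0:
        raise InvalidInputError("mean velocity must be > 0")
    if length < 0:
        raise InvalidInputError("length must be >= 0")
    return length / mean_velocity


@dataclass(frozen=True)
class FluxBalance:
    """Relative flux mismatches (dimensionless, vs. the conduit flux)."""

    feed_mismatch: float
    collection_mismatch: float
    column_net_flux: float

    @property
    def worst(self) -> float:
        return max(abs(self.feed_mismatch), abs(self.collection_mismatch), abs(self.column_net_flux))


def check_flux_balance(field: FlowField2D) -> FluxBalance:
    """Port-to-port flux conservation and net vertical flux in the column.

    Fluxes are trapezoid integrals of the computed velocity (not read off
    psi), so this is an independent consistency check of the solve.
    """
    geom = field.geometry
    h = field.grid_spacing
    nxc, kf, kc, kt, nw, i0 = _cell_layout(geom, h)
    q_ref = geom.mean_conduit_velocity * geom.feed_height
    if q_ref == 0:
        return FluxBalance(0.0, 0.0, 0.0)

    def port_flux(col, rows):
        return np.trapezoid(field.u_x[rows, col], dx=h)

    bot_rows = slice(0, kf + 1)
    q_in_b = port_flux(0, bot_rows)
    q_out_b = port_flux(field.x.size - 1, bot_rows)
    feed = (q_out_b - q_in_b) / q_ref
    if kc == 0:
        return FluxBalance(float(feed), 0.0, 0.0)
    top_rows = slice(kf + kc, field.z.size)
    q_in_t = port_flux(0, top_rows)
    q_out_t = port_flux(field.x.size - 1, top_rows)
    coll = (q_out_t - q_in_t) / q_ref
    k_mid = kf + kc // 2
    q_col = np.trapezoid(field.u_z[k_mid, i0 : i0 + nw + 1], dx=h)
    return FluxBalance(float(feed), float(coll), float(q_col / q_ref))


def plot_streamlines(field: FlowField2D, path=None, n_levels: int = 31):
    """Stream-function contour plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 8))
    psi = np.where(field.mask, field.psi, np.nan)
    ax.contour(field.x * 1e3, field.z * 1e3, psi, levels=n_levels, linewidths=0.7)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_aspect("equal")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
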