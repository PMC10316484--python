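"""Lagrangian propagule dispersal on gridded currents.

Particles are advected hourly with a fourth-order Runge-Kutta scheme on
bilinearly (space) and linearly (time) interpolated velocities, given an
isotropic random-walk kick per hour (displacement sqrt(2 K dt) per axis),
and tracked for a competency window (default 7 days).  Connectivity from
site i to site j is the average number of particles per release event
released at i whose track enters j's 500 m x 500 m detection cell.
Overwater (least-cost sea) distances come from Dijkstra shortest paths on
the sea-cell graph of the land-mask raster.

Velocity fields are xarray Datasets with variables u, v (time, y, x; m/s),
mask (y, x; True on land), planar meter coordinates and attribute ``dx``
(see `seascapegen.simulate.simulate_velocity_field`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .types import DirectedMatrix, DistanceMatrix, SiteTable, ValidationError

__all__ = [
    "ReleaseSchedule",
    "TrajectorySet",
    "ConnectivityMatrix",
    "advect",
    "run_releases",
    "connectivity_matrix",
    "overwater_distance",
]


@dataclass
class ReleaseSchedule:
    """Release timing: particles per release, interval, and window.

    ``release_hours`` are hours into the velocity field's time axis.  The
    field-season default (100 particles, 3-day intervals over a Sep-Jan
    spawning window repeated yearly) is produced by :meth:`seasonal`.
    """

    release_hours: np.ndarray
    particles_per_release: int = 100

    def __post_init__(self) -> None:
        self.release_hours = np.asarray(self.release_hours, dtype=float)
        if len(self.release_hours) == 0:
            raise ValidationError("release schedule is empty")
        if self.particles_per_release < 1:
            raise ValidationError("need at least 1 particle per release")

    @classmethod
    def seasonal(
        cls,
        years: int = 4,
        season_days: int = 153,  # Sep 1 - Jan 31
        interval_days: int = 3,
        particles_per_release: int = 100,
        year_hours: int = 8760,
    ) -> "ReleaseSchedule":
        hours = []
        for y in range(years):
            start = y * year_hours
            hours.extend(start + 24 * d for d in range(0, season_days, interval_days))
        return cls(np.array(hours, dtype=float), particles_per_release)

    @classmethod
    def uniform(cls, start_h: float, end_h: float, interval_h: float, particles_per_release: int = 100) -> "ReleaseSchedule":
        return cls(np.arange(start_h, end_h + 1e-9, interval_h), particles_per_release)


@dataclass
class TrajectorySet:
    """Hourly particle fixes: positions (n, n_hours+1, 2) in meters."""

    positions: np.ndarray
    release_time: float
    status: np.ndarray  # "active" | "beached" per particle


class ConnectivityMatrix(DirectedMatrix):
    """Directed site x site average particle counts per release."""

    def __init__(self, site_ids, values, n_releases: int, diagonal_policy: str = "keep"):
        super().__init__(site_ids=site_ids, values=values)
        self.n_releases = n_releases
        self.diagonal_policy = diagonal_policy


# ------------------------------------------------------------- advection

def _interp_velocity(field: xr.Dataset, pos: np.ndarray, t_h: float) -> np.ndarray:
    """Bilinear-in-space, linear-in-time velocity at positions (n, 2).

    Positions outside the domain get zero velocity (they are handled by
    the land policy).  Land cells carry zero velocity in the field itself,
    so velocities taper toward the coast.
    """
    x = field["x"].values
    y = field["y"].values
    t = field["time"].values
    dx = float(field.attrs["dx"])
    nt = len(t)

    ti = np.clip(np.searchsorted(t, t_h, side="right") - 1, 0, nt - 2)
    w_t = np.clip((t_h - t[ti]) / (t[ti + 1] - t[ti]), 0.0, 1.0)
    u0 = field["u"].values[ti]
    u1 = field["u"].values[ti + 1]
    v0 = field["v"].values[ti]
    v1 = field["v"].values[ti + 1]
    U = u0 * (1 - w_t) + u1 * w_t
    V = v0 * (1 - w_t) + v1 * w_t

    fx = (pos[:, 0] - x[0]) / dx
    fy = (pos[:, 1] - y[0]) / dx
    ix = np.floor(fx).astype(int)
    iy = np.floor(fy).astype(int)
    wx = fx - ix
    wy = fy - iy
    ny, nx = U.shape

    out = np.zeros_like(pos)
    valid = (ix >= -1) & (ix <= nx - 1) & (iy >= -1) & (iy <= ny - 1)

    def cell(val, jy, jx):
        ok = (jx >= 0) & (jx < nx) & (jy >= 0) & (jy < ny)
        res = np.zeros(len(jx))
        res[ok] = val[jy[ok], jx[ok]]
        return res

    for grid, col in ((U, 0), (V, 1)):
        v00 = cell(grid, iy, ix)
        v01 = cell(grid, iy, ix + 1)
        v10 = cell(grid, iy + 1, ix)
        v11 = cell(grid, iy + 1, ix + 1)
        interp = (
            v00 * (1 - wx) * (1 - wy)
            + v01 * wx * (1 - wy)
            + v10 * (1 - wx) * wy
            + v11 * wx * wy
        )
        out[:, col] = np.where(valid, interp, 0.0)
    return out


def _on_land(field: xr.Dataset, pos: np.ndarray) -> np.ndarray:
    """True where a position falls on a masked (land) cell or outside the
    domain footprint."""
    dx = float(field.attrs["dx"])
    x0 = field["x"].values[0] - dx / 2
    y0 = field["y"].values[0] - dx / 2
    mask = field["mask"].values
    ny, nx = mask.shape
    ix = np.floor((pos[:, 0] - x0) / dx).astype(int)
    iy = np.floor((pos[:, 1] - y0) / dx).astype(int)
    out = np.ones(len(pos), dtype=bool)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    out[inside] = mask[iy[inside], ix[inside]]
    return out


def advect(
    field: xr.Dataset,
    start_positions: np.ndarray,
    start_time: float = 0.0,
    duration_h: int = 168,
    substeps: int = 1,
    diffusivity: float = 1.0,
    land_policy: str = "freeze",
    seed: int = 0,
) -> TrajectorySet:
    """Track particles for ``duration_h`` hours from ``start_time``.

    Per outer hour: RK4 integration in ``substeps`` sub-intervals, then a
    diffusion kick sqrt(2 K dt) * N(0,1) per axis.  ``land_policy``:
    "freeze" keeps the previous position when a step would land on a
    masked cell (the particle may move later); "beach" removes it
    permanently.  Deterministic given the seed; with diffusivity 0 the
    trajectory is seed-independent.
    """
    if land_policy not in ("freeze", "beach"):
        raise ValueError("land_policy must be 'freeze' or 'beach'")
    pos = np.asarray(start_positions, dtype=float).copy()
    n = len(pos)
    if _on_land(field, pos).any():
        raise ValidationError("start positions must be on sea cells")
    t_max = float(field["time"].values[-1])
    if start_time + duration_h > t_max + 1e-9:
        raise ValidationError("advection window exceeds field time coverage")

    rng = np.random.default_rng(seed)
    fixes = np.empty((n, duration_h + 1, 2))
    fixes[:, 0] = pos
    beached = np.zeros(n, dtype=bool)
    dt = 3600.0 / substeps

    for h in range(duration_h):
        t0 = start_time + h
        for s in range(substeps):
            ts = t0 + s / substeps
            active = ~beached
            if not active.any():
                break
            p = pos[active]
            k1 = _interp_velocity(field, p, ts)
            k2 = _interp_velocity(field, p + 0.5 * dt * k1, ts + 0.5 * dt / 3600)
            k3 = _interp_velocity(field, p + 0.5 * dt * k2, ts + 0.5 * dt / 3600)
            k4 = _interp_velocity(field, p + dt * k3, ts + dt / 3600)
            prop = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            bad = _on_land(field, prop)
            prop[bad] = p[bad]  # freeze this sub-step
            if land_policy == "beach":
                idx = np.flatnonzero(active)
                beached[idx[bad]] = True
            pos[active] = prop
        if diffusivity > 0:
            active = ~beached
            kick = np.sqrt(2 * diffusivity * 3600.0) * rng.standard_normal((int(active.sum()), 2))
            prop = pos[active] + kick
            bad = _on_land(field, prop)
            prop[bad] = pos[active][bad]
            if land_policy == "beach":
                idx = np.flatnonzero(active)
                beached[idx[bad]] = True
            pos[active] = prop
        fixes[:, h + 1] = pos
    status = np.where(beached, "beached", "active")
    return TrajectorySet(positions=fixes, release_time=start_time, status=status)


# ------------------------------------------------------------- releases

def run_releases(
    field: xr.Dataset,
    sites: SiteTable,
    schedule: ReleaseSchedule,
    detection_cell_m: float = 500.0,
    duration_h: int = 168,
    substeps: int = 1,
    diffusivity: float = 1.0,
    land_policy: str = "freeze",
    count_policy: str = "once_per_release",
    seed: int = 0,
) -> np.ndarray:
    """Run the full release schedule; returns the per-release count tensor
    (n_releases, n_sites, n_sites) of particles from site i detected in
    site j.

    Particles start uniformly within each site's detection cell (a square
    of side ``detection_cell_m`` centered on the site).  A particle counts
    once per (release, target site) if any hourly fix falls inside the
    target cell ("once_per_release"); "per_fix" counts every hourly fix.
    """
    if sites.crs != "planar":
        raise ValidationError("dispersal runs on planar (meter) site coordinates")
    coords = sites.coords
    half = detection_cell_m / 2.0
    S = len(sites)
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(schedule.release_hours), S, S))

    # validate release cells
    for s in range(S):
        probe = coords[s][None, :]
        if _on_land(field, probe)[0]:
            raise ValidationError(f"site {sites.site_ids[s]} detection cell is on land")

    for r, t0 in enumerate(schedule.release_hours):
        starts = []
        origin = []
        for s in range(S):
            offs = rng.uniform(-half, half, size=(schedule.particles_per_release, 2))
            p = coords[s][None, :] + offs
            # nudge any draw that fell on land back to the site center
            bad = _on_land(field, p)
            p[bad] = coords[s]
            starts.append(p)
            origin.extend([s] * schedule.particles_per_release)
        starts = np.vstack(starts)
        origin = np.asarray(origin)
        traj = advect(
            field, starts, start_time=float(t0), duration_h=duration_h,
            substeps=substeps, diffusivity=diffusivity, land_policy=land_policy,
            seed=int(rng.integers(2**31 - 1)),
        )
        fixes = traj.positions  # (n, H+1, 2)
        for j in range(S):
            inside = (
                (np.abs(fixes[:, :, 0] - coords[j, 0]) <= half)
                & (np.abs(fixes[:, :, 1] - coords[j, 1]) <= half)
            )
            if count_policy == "once_per_release":
                hit = inside.any(axis=1).astype(float)
            elif count_policy == "per_fix":
                hit = inside.sum(axis=1).astype(float)
            else:
                raise ValueError("count_policy must be 'once_per_release' or 'per_fix'")
            for s in range(S):
                counts[r, s, j] += hit[origin == s].sum()
    return counts


def connectivity_matrix(
    counts: np.ndarray,
    site_ids: list[str],
    diagonal_policy: str = "keep",
) -> ConnectivityMatrix:
    """Average the per-release count tensor into the directed connectivity
    matrix (mean particles from i detected in j per release)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3 or counts.shape[0] < 1:
        raise ValidationError("count tensor must be (n_releases, S, S) with >=1 release")
    avg = counts.mean(axis=0)
    if diagonal_policy == "zero":
        np.fill_diagonal(avg, 0.0)
    elif diagonal_policy != "keep":
        raise ValueError("diagonal_policy must be 'keep' or 'zero'")
    return ConnectivityMatrix(
        site_ids=list(site_ids), values=avg,
        n_releases=counts.shape[0], diagonal_policy=diagonal_policy,
    )


# ----------------------------------------------------- overwater distance

_NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_NEIGHBORS_16 = _NEIGHBORS_8 + [
    (-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1),
]


def overwater_distance(
    land_mask: np.ndarray,
    sites: SiteTable,
    cell_size_m: float,
    neighbors: int = 16,
    snap_tolerance_cells: int = 2,
) -> DistanceMatrix:
    """Shortest sea path between sites without crossing land, in km.

    Dijkstra on the sea-cell lattice graph; edge weights are planar
    distances between cell centers (8- or 16-neighbor stencil; the
    16-neighbor stencil adds knight moves and keeps the discretization
    error of straight-line distance within ~2%).  Sites are snapped to
    the nearest sea cell within ``snap_tolerance_cells``.
    """
    mask = np.asarray(land_mask, dtype=bool)
    ny, nx = mask.shape
    if neighbors == 8:
        stencil = _NEIGHBORS_8
    elif neighbors == 16:
        stencil = _NEIGHBORS_16
    else:
        raise ValueError("neighbors must be 8 or 16")

    sea = ~mask
    node_id = -np.ones((ny, nx), dtype=int)
    node_id[sea] = np.arange(sea.sum())
    n_nodes = sea.sum()

    rows, cols, wts = [], [], []
    for dy, dxs in stencil:
        src_y, src_x = np.nonzero(sea)
        ty, tx = src_y + dy, src_x + dxs
        ok = (ty >= 0) & (ty < ny) & (tx >= 0) & (tx < nx)
        src_y, src_x, ty, tx = src_y[ok], src_x[ok], ty[ok], tx[ok]
        ok = sea[ty, tx]
        src_y, src_x, ty, tx = src_y[ok], src_x[ok], ty[ok], tx[ok]
        if abs(dy) == 2 or abs(dxs) == 2:
            # knight move: the two cells straddling the segment midpoint
            # must both be sea, so the path cannot jump a land sliver
            if abs(dy) == 2:
                mids = [(dy // 2, 0), (dy // 2, dxs)]
            else:
                mids = [(0, dxs // 2), (dy, dxs // 2)]
            ok2 = np.ones(len(src_y), dtype=bool)
            for my, mx in mids:
                ok2 &= sea[src_y + my, src_x + mx]
            src_y, src_x, ty, tx = src_y[ok2], src_x[ok2], ty[ok2], tx[ok2]
        w = np.hypot(dy, dxs) * cell_size_m
        rows.extend(node_id[src_y, src_x])
        cols.extend(node_id[ty, tx])
        wts.extend([w] * len(src_y))
    graph = coo_matrix((wts, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()

    # snap sites to sea cells
    coords = sites.coords
    site_nodes = []
    for s, sid in enumerate(sites.site_ids):
        ix = int(np.floor(coords[s, 0] / cell_size_m))
        iy = int(np.floor(coords[s, 1] / cell_size_m))
        found = None
        for radius in range(snap_tolerance_cells + 1):
            best = None
            for ddy in range(-radius, radius + 1):
                for ddx in range(-radius, radius + 1):
                    jy, jx = iy + ddy, ix + ddx
                    if 0 <= jy < ny and 0 <= jx < nx and sea[jy, jx]:
                        d = ddy**2 + ddx**2
                        if best is None or d < best[0]:
                            best = (d, jy, jx)
            if best is not None:
                found = best
                break
        if found is None:
            raise ValidationError(f"site {sid} has no sea cell within {snap_tolerance_cells} cells")
        site_nodes.append(node_id[found[1], found[2]])

    dist = dijkstra(graph, directed=False, indices=site_nodes)
    out = dist[:, site_nodes] / 1000.0
    if np.isinf(out).any():
        warnings.warn("some site pairs are disconnected by land; distance set to inf")
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(site_ids=sites.site_ids, values=out)
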