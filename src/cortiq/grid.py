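"""Curvilinear cortical coordinates from a Laplacian potential field.

The cortex is parameterised between two manually delineated boundaries:
the pial surface (potential 0) and the gray/white-matter interface
(potential 1).  Solving Laplace's equation between them yields a smooth
potential whose gradient streamlines connect the two boundaries without
crossing, playing the role of cortical columns.  Tracing a fixed number
of streamlines from evenly spaced pial seeds and sampling each at fixed
arc-length fractions gives every subject the same (line, depth) lattice,
i.e. anatomical correspondence without image registration.

Geometry is 2D (a single coronal slice).  World coordinates are in mm
with a voxel-center origin; images are indexed [row, col] with
x = origin_x + col * spacing, y = origin_y + row * spacing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon

__all__ = [
    "Frame",
    "BoundaryPair",
    "LaplaceField",
    "CorticalGrid",
    "GridSamples",
    "solve_laplace",
    "trace_gridlines",
    "sample_along",
]


@dataclass(frozen=True)
class Frame:
    """2D raster frame: world mm, voxel-center origin, 0-based indices."""

    origin: tuple[float, float]  # world (x, y) of pixel [0, 0]
    spacing: float  # mm, isotropic
    shape: tuple[int, int]  # (n_rows, n_cols)

    def world(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                self.origin[0] + np.asarray(cols) * self.spacing,
                self.origin[1] + np.asarray(rows) * self.spacing,
            ],
            axis=-1,
        )

    def index(self, xy: np.ndarray) -> np.ndarray:
        """World -> fractional (row, col)."""
        xy = np.asarray(xy)
        col = (xy[..., 0] - self.origin[0]) / self.spacing
        row = (xy[..., 1] - self.origin[1]) / self.spacing
        return np.stack([row, col], axis=-1)


@dataclass
class BoundaryPair:
    """Pial and white-matter polylines (world mm), plus the lateral caps.

    The polylines run in corresponding order (point 0 of each on the
    same lateral end); the caps are the straight segments joining
    corresponding endpoints, closing the cortical ribbon.
    """

    pial: np.ndarray  # (n, 2)
    wm: np.ndarray  # (m, 2)

    def __post_init__(self) -> None:
        self.pial = np.asarray(self.pial, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        for name, arr in (("pial", self.pial), ("wm", self.wm)):
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"{name} polyline must be (n>=2, 2)")
        pl, wl = LineString(self.pial), LineString(self.wm)
        if not pl.is_simple or not wl.is_simple:
            raise ValueError("boundary polylines must be non-self-intersecting")
        if pl.intersects(wl):
            raise ValueError("pial and white-matter boundaries cross")
        if not self.polygon().is_valid:
            raise ValueError("boundaries do not enclose a simple ribbon region")

    def polygon(self) -> Polygon:
        return Polygon(np.vstack([self.pial, self.wm[::-1]]))

    def caps(self) -> tuple[LineString, LineString]:
        return (
            LineString([self.pial[0], self.wm[0]]),
            LineString([self.pial[-1], self.wm[-1]]),
        )

    # CSV dialect: two files or one file with a boundary column
    def save(self, path) -> None:
        rows = [("pial", x, y) for x, y in self.pial]
        rows += [("wm", x, y) for x, y in self.wm]
        df = pd.DataFrame(rows, columns=["boundary", "x_mm", "y_mm"])
        with open(path, "w") as fh:
            fh.write("# cortiq boundaries; world mm, voxel-center origin\n")
            df.to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "BoundaryPair":
        df = pd.read_csv(path, comment="#")
        return cls(
            pial=df[df.boundary == "pial"][["x_mm", "y_mm"]].to_numpy(),
            wm=df[df.boundary == "wm"][["x_mm", "y_mm"]].to_numpy(),
        )


@dataclass
class LaplaceField:
    """Discrete Laplace solution on the cortical ribbon."""

    phi: np.ndarray  # (rows, cols); nan outside the ribbon
    frame: Frame
    region: np.ndarray  # bool mask of interior ribbon pixels
    residual: float
    n_iter: int
    phi_filled: np.ndarray = field(repr=False, default=None)  # for interpolation
    grad_x: np.ndarray = field(repr=False, default=None)
    grad_y: np.ndarray = field(repr=False, default=None)

    def gradient_interpolator(self):
        """Bilinear interpolator of normalised grad(phi), callable on world xy."""
        gx, gy = self.grad_x, self.grad_y
        frame = self.frame

        def interp(xy: np.ndarray) -> np.ndarray:
            rc = frame.index(xy)
            gxv = _bilinear(gx, rc)
            gyv = _bilinear(gy, rc)
            g = np.stack([gxv, gyv], axis=-1)
            norm = np.linalg.norm(g, axis=-1, keepdims=True)
            return g / np.maximum(norm, 1e-30)

        return interp

    def phi_interpolator(self):
        frame = self.frame

        def interp(xy: np.ndarray) -> np.ndarray:
            return _bilinear(self.phi_filled, frame.index(xy))

        return interp


def _bilinear(img: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at fractional (row, col) points (clamped)."""
    r = np.clip(rc[..., 0], 0, img.shape[0] - 1.001)
    c = np.clip(rc[..., 1], 0, img.shape[1] - 1.001)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    return (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r0 + 1, c0] * fr * (1 - fc)
        + img[r0, c0 + 1] * (1 - fr) * fc
        + img[r0 + 1, c0 + 1] * fr * fc
    )


def solve_laplace(
    boundaries: BoundaryPair,
    spacing: float,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    omega: float = 1.9,
) -> LaplaceField:
    """Solve Laplace's equation on the ribbon between the boundaries.

    Dirichlet conditions phi = 0 on the pial boundary and phi = 1 on the
    white-matter boundary; no-flux (Neumann) conditions on the lateral
    caps.  Solved by red-black successive over-relaxation on a regular
    grid of the given spacing, to a maximum 5-point residual of ``tol``.
    """
    poly = boundaries.polygon()
    if poly.area <= 0:
        raise ValueError("boundaries enclose an empty region")
    minx, miny, maxx, maxy = poly.bounds
    pad = 2 * spacing
    origin = (minx - pad, miny - pad)
    n_cols = int(np.ceil((maxx + pad - origin[0]) / spacing)) + 1
    n_rows = int(np.ceil((maxy + pad - origin[1]) / spacing)) + 1
    frame = Frame(origin, spacing, (n_rows, n_cols))

    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    xy = frame.world(rows, cols)
    region = shapely.contains_xy(poly, xy[..., 0], xy[..., 1])
    if not np.any(region):
        raise ValueError("no grid points fall inside the ribbon region")

    # classify exterior pixels bordering the region by nearest boundary
    border = ~region & (
        np.roll(region, 1, 0) | np.roll(region, -1, 0)
        | np.roll(region, 1, 1) | np.roll(region, -1, 1)
    )
    pial_line = LineString(boundaries.pial)
    wm_line = LineString(boundaries.wm)
    cap_a, cap_b = boundaries.caps()
    pts = shapely.points(xy[border][:, 0], xy[border][:, 1])
    dists = np.stack(
        [
            shapely.distance(pts, pial_line),
            shapely.distance(pts, wm_line),
            np.minimum(shapely.distance(pts, cap_a), shapely.distance(pts, cap_b)),
        ],
        axis=1,
    )
    nearest = np.argmin(dists, axis=1)  # 0 pial, 1 wm, 2 cap
    bc_type = np.zeros(region.shape, dtype=np.int8)  # 0: neumann/none
    bc_type[border] = np.where(nearest == 0, 1, np.where(nearest == 1, 2, 0))
    ghost_delta = np.zeros(region.shape)
    ghost_delta[border] = np.where(
        nearest == 0, dists[:, 0], np.where(nearest == 1, dists[:, 1], 0.0)
    )
    is_dir = bc_type > 0
    dir_base = np.where(bc_type == 2, 1.0, 0.0)

    # Shortley-Weller stencil: where a neighbour is a Dirichlet ghost the
    # stencil arm is shortened to the actual boundary crossing
    # (approximated by h minus the ghost's distance to the polyline),
    # giving sub-pixel boundary accuracy without any unstable ghost
    # feedback; Neumann (cap/outside) neighbours mirror the centre value.
    h = spacing
    shifts = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    arms = []
    nb_is_dir = []
    nb_is_reg = []
    nb_base = []
    bc_lines = {1: pial_line, 2: wm_line}
    for dr, dc in shifts:
        nd = np.roll(is_dir, (dr, dc), axis=(0, 1))
        nr = np.roll(region, (dr, dc), axis=(0, 1))
        delta = np.roll(ghost_delta, (dr, dc), axis=(0, 1))
        a = np.where(nd, np.clip(h - delta, 0.05 * h, h), h)
        # exact axis-aligned boundary crossings for the cells that border
        # a Dirichlet ghost (rolling by (dr, dc) fetches the neighbour at
        # (-dr, -dc) in index space)
        nb_bc = np.roll(bc_type, (dr, dc), axis=(0, 1))
        cells = region & nd
        cr, cc = np.nonzero(cells)
        if len(cr):
            p0 = frame.world(cr, cc)
            p1 = frame.world(cr - dr, cc - dc)
            for bt in (1, 2):
                sel = nb_bc[cr, cc] == bt
                if not np.any(sel):
                    continue
                segs = shapely.linestrings(
                    np.stack([p0[sel], p1[sel]], axis=1)
                )
                hits = shapely.intersection(segs, bc_lines[bt])
                for m, hit in zip(np.nonzero(sel)[0], hits):
                    coords = shapely.get_coordinates(hit)
                    if len(coords):
                        d = np.linalg.norm(coords - p0[m], axis=1).min()
                        a[cr[m], cc[m]] = np.clip(d, 0.05 * h, h)
        arms.append(a)
        nb_is_dir.append(nd)
        nb_is_reg.append(nr)
        nb_base.append(np.roll(dir_base, (dr, dc), axis=(0, 1)))
    # coefficients 2/(a_d (a_d + a_opp)) per direction (opposites paired)
    coeffs = []
    for k, (dr, dc) in enumerate(shifts):
        opp = k + 1 if k % 2 == 0 else k - 1
        coeffs.append(2.0 / (arms[k] * (arms[k] + arms[opp])))
    csum = sum(coeffs)

    phi = np.zeros(region.shape)
    phi[is_dir] = dir_base[is_dir]
    phi[region] = 0.5  # interior start value

    parity = (rows + cols) % 2

    def weighted_avg(p: np.ndarray) -> np.ndarray:
        num = np.zeros_like(p)
        for k, (dr, dc) in enumerate(shifts):
            v = np.roll(p, (dr, dc), axis=(0, 1))
            val = np.where(
                nb_is_dir[k], nb_base[k], np.where(nb_is_reg[k], v, p)
            )
            num += coeffs[k] * val
        return num / csum

    n_iter = 0
    residual = np.inf
    for n_iter in range(1, max_iter + 1):
        for color in (0, 1):
            avg = weighted_avg(phi)
            upd = region & (parity == color)
            phi[upd] += omega * (avg[upd] - phi[upd])
        residual = float(np.max(np.abs(weighted_avg(phi)[region] - phi[region])))
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"Laplace solver did not converge: residual {residual:.3g} after "
            f"{max_iter} iterations"
        )

    # filled field for interpolation/tracing: extrapolate ghost values so
    # the interpolated potential crosses 0/1 exactly at the boundaries,
    # then nearest-fill the remainder
    ghost_vals = np.full(region.shape, np.nan)
    nb_sum = np.zeros(region.shape)
    nb_cnt = np.zeros(region.shape)
    for dr, dc in shifts:
        v = np.roll(phi, (dr, dc), axis=(0, 1))
        reg = np.roll(region, (dr, dc), axis=(0, 1))
        nb_sum += np.where(reg, v, 0.0)
        nb_cnt += reg
    have = is_dir & (nb_cnt > 0)
    arm_c = np.clip(h - ghost_delta, 0.2 * h, h)
    gfac = np.clip(ghost_delta / arm_c, 0.0, 3.0)
    nb_mean = np.where(have, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    ghost_vals[have] = dir_base[have] + gfac[have] * (
        dir_base[have] - nb_mean[have]
    )
    phi_filled = np.where(region, phi, ghost_vals)
    from scipy.ndimage import distance_transform_edt

    if np.any(np.isnan(phi_filled)):
        idx = distance_transform_edt(
            np.isnan(phi_filled), return_distances=False, return_indices=True
        )
        phi_filled = phi_filled[tuple(idx)]

    # gradient field from trusted cells only (region + Dirichlet ghost
    # ring), masked one-sided differences where central ones would cross
    # untrusted values, then nearest-extended outward — this keeps the
    # streamline directions clean near the lateral caps and corners
    trusted = region | have
    tphi = np.where(trusted, phi_filled, np.nan)
    gy = _masked_gradient(tphi, h, axis=0)
    gx = _masked_gradient(tphi, h, axis=1)
    known = np.isfinite(gx) & np.isfinite(gy) & region
    if not np.all(known):
        idx = distance_transform_edt(
            ~known, return_distances=False, return_indices=True
        )
        gx = gx[tuple(idx)]
        gy = gy[tuple(idx)]

    phi_out = np.where(region, phi, np.nan)
    return LaplaceField(
        phi=phi_out,
        frame=frame,
        region=region,
        residual=residual,
        n_iter=n_iter,
        phi_filled=phi_filled,
        grad_x=gx,
        grad_y=gy,
    )


def _masked_gradient(arr: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Central differences falling back to one-sided where a neighbour
    is NaN; NaN where no finite neighbour exists along the axis."""
    fwd = np.roll(arr, -1, axis=axis)
    bwd = np.roll(arr, 1, axis=axis)
    # roll wraps around; invalidate the wrapped edge
    edge = [slice(None)] * arr.ndim
    edge[axis] = -1
    fwd[tuple(edge)] = np.nan
    edge[axis] = 0
    bwd[tuple(edge)] = np.nan
    central = (fwd - bwd) / (2 * h)
    onesided_f = (fwd - arr) / h
    onesided_b = (arr - bwd) / h
    out = central
    out = np.where(np.isnan(out), onesided_f, out)
    out = np.where(np.isnan(out), onesided_b, out)
    return out


@dataclass
class CorticalGrid:
    """Traced grid-lines through the Laplacian field.

    ``trajectories`` lists (n_i, 2) world-mm point chains running from
    the pial boundary to the white-matter boundary; ``seed_normals``
    holds the inward pial normal at each seed (unit vectors).
    """

    trajectories: list[np.ndarray]
    seeds: np.ndarray  # (n_lines, 2)
    seed_normals: np.ndarray  # (n_lines, 2)
    excluded: list[int]  # indices of lines dropped (lateral exit)
    frame: Frame

    @property
    def n_lines(self) -> int:
        return len(self.trajectories)

    def lengths(self) -> np.ndarray:
        return np.array(
            [np.sum(np.linalg.norm(np.diff(t, axis=0), axis=1)) for t in self.trajectories]
        )

    def sample_points(self, n_depth: int = 10) -> np.ndarray:
        """(n_lines, n_depth, 2) world coordinates at arc-length
        fractions (k + 0.5)/n_depth along each trajectory (bin
        midpoints, avoiding the partial-volume pial/WM borders)."""
        fracs = (np.arange(n_depth) + 0.5) / n_depth
        out = np.empty((self.n_lines, n_depth, 2))
        for i, traj in enumerate(self.trajectories):
            seg = np.linalg.norm(np.diff(traj, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            s = fracs * arc[-1]
            out[i, :, 0] = np.interp(s, arc, traj[:, 0])
            out[i, :, 1] = np.interp(s, arc, traj[:, 1])
        return out

    def sample_tangents(self, n_depth: int = 10) -> np.ndarray:
        """Unit tangents (depth direction, pial->WM) at the sample points."""
        pts = self.sample_points(n_depth)
        out = np.empty_like(pts)
        for i, traj in enumerate(self.trajectories):
            seg = np.diff(traj, axis=0)
            seglen = np.linalg.norm(seg, axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seglen)])
            mid = 0.5 * (arc[:-1] + arc[1:])
            s = ((np.arange(n_depth) + 0.5) / n_depth) * arc[-1]
            j = np.clip(np.searchsorted(mid, s), 0, len(seg) - 1)
            t = seg[j] / np.maximum(seglen[j][:, None], 1e-30)
            out[i] = t
        return out

    def to_json(self, path) -> None:
        payload = {
            "frame": {
                "origin": list(self.frame.origin),
                "spacing": self.frame.spacing,
                "shape": list(self.frame.shape),
            },
            "seeds": self.seeds.tolist(),
            "seed_normals": self.seed_normals.tolist(),
            "excluded": self.excluded,
            "trajectories": [t.tolist() for t in self.trajectories],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CorticalGrid":
        with open(path) as fh:
            payload = json.load(fh)
        fr = payload["frame"]
        return cls(
            trajectories=[np.asarray(t) for t in payload["trajectories"]],
            seeds=np.asarray(payload["seeds"]),
            seed_normals=np.asarray(payload["seed_normals"]),
            excluded=list(payload["excluded"]),
            frame=Frame(tuple(fr["origin"]), fr["spacing"], tuple(fr["shape"])),
        )


def _polyline_arc_positions(poly: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = fracs * arc[-1]
    return np.stack(
        [np.interp(s, arc, poly[:, 0]), np.interp(s, arc, poly[:, 1])], axis=-1
    )


def _polyline_tangent_at(poly: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    seg = np.diff(poly, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    mid = 0.5 * (arc[:-1] + arc[1:])
    s = fracs * arc[-1]
    j = np.clip(np.searchsorted(mid, s), 0, len(seg) - 1)
    return seg[j] / np.maximum(seglen[j][:, None], 1e-30)


def trace_gridlines(
    fieldsol: LaplaceField,
    boundaries: BoundaryPair,
    n_lines: int = 50,
    step_frac: float = 0.25,
    max_excluded_frac: float = 0.10,
) -> CorticalGrid:
    """Trace streamlines of the Laplacian gradient from pial to WM.

    Seeds sit at equal arc-length intervals (bin midpoints) along the
    pial polyline.  Each line follows the normalised gradient of phi
    with a 4th-order Runge-Kutta integrator at a fixed step of
    ``step_frac`` grid cells, until it crosses the white-matter
    polyline.  Lines exiting through a lateral cap are excluded with a
    warning; more than ``max_excluded_frac`` of lines excluded is an
    error.
    """
    fracs = (np.arange(n_lines) + 0.5) / n_lines
    seeds = _polyline_arc_positions(boundaries.pial, fracs)
    tangents = _polyline_tangent_at(boundaries.pial, fracs)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=-1)
    # orient normals inward (towards increasing phi)
    phi_int = fieldsol.phi_interpolator()
    h = fieldsol.frame.spacing
    probe = phi_int(seeds + 0.5 * h * normals) - phi_int(seeds - 0.5 * h * normals)
    normals[probe < 0] *= -1.0

    grad = fieldsol.gradient_interpolator()
    wm_line = LineString(boundaries.wm)
    step = step_frac * h
    max_steps = int(20.0 * (np.sqrt(boundaries.polygon().area) + 1.0) / step)

    # integrate all lines simultaneously; a line finishes once the
    # interpolated potential reaches phi_stop — the last fraction of a
    # voxel, where the discrete field is least accurate, is covered by a
    # straight ("ballistic") continuation to the exact WM crossing
    phi_stop = 0.97
    paths: list[list[np.ndarray]] = [[seeds[i].copy()] for i in range(n_lines)]
    p = seeds.copy()
    active = np.ones(n_lines, dtype=bool)
    done = np.zeros(n_lines, dtype=bool)
    stalled = np.zeros(n_lines, dtype=int)
    for _ in range(max_steps):
        if not np.any(active):
            break
        pa = p[active]
        k1 = grad(pa)
        k2 = grad(pa + 0.5 * step * k1)
        k3 = grad(pa + 0.5 * step * k2)
        k4 = grad(pa + step * k3)
        p_new = pa + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        phi_new = phi_int(p_new)
        phi_old = phi_int(pa)
        idx = np.flatnonzero(active)
        for j, i in enumerate(idx):
            paths[i].append(p_new[j].copy())
            if phi_new[j] >= phi_stop:
                done[i] = True
                active[i] = False
            elif phi_new[j] <= phi_old[j] - 1e-9:
                stalled[i] += 1  # moving against the potential: lost
                if stalled[i] > 10:
                    active[i] = False
        p[active] = p_new[[j for j, i in enumerate(idx) if active[i]]]

    from shapely.ops import substring

    trajectories: list[np.ndarray] = []
    excluded: list[int] = []
    for i in range(n_lines):
        if not done[i]:
            excluded.append(i)
            continue
        pts = np.asarray(paths[i])
        # extend straight along the final direction so the path reaches
        # (and slightly overshoots) the WM polyline, then truncate at
        # the first crossing
        direction = pts[-1] - pts[-2]
        direction /= max(np.linalg.norm(direction), 1e-12)
        reach = max(20.0 * step, 0.1 * np.linalg.norm(pts[-1] - pts[0]))
        pts_ext = np.vstack([pts, pts[-1] + reach * direction])
        path_ls = LineString(pts_ext)
        if path_ls.intersects(wm_line):
            hits = shapely.get_coordinates(path_ls.intersection(wm_line))
            s = min(
                path_ls.project(shapely.points(c[0], c[1])) for c in hits
            )
            if s <= 0:
                excluded.append(i)
                continue
            pts = shapely.get_coordinates(substring(path_ls, 0.0, s))
        else:
            # no crossing even after extension: snap if close, else drop
            endpoint = shapely.points(*pts[-1])
            gap = float(shapely.distance(endpoint, wm_line))
            if gap > 4.0 * step:
                excluded.append(i)
                continue
            snapped = wm_line.interpolate(wm_line.project(endpoint))
            pts = np.vstack([pts, [snapped.x, snapped.y]])
        trajectories.append(pts)
    if excluded:
        warnings.warn(
            f"{len(excluded)}/{n_lines} grid-lines excluded (lateral exit or "
            "no WM crossing)",
            stacklevel=2,
        )
    if len(excluded) > max_excluded_frac * n_lines:
        raise RuntimeError(
            f"{len(excluded)} of {n_lines} grid-lines failed to reach the "
            "white-matter boundary"
        )
    keep = [i for i in range(n_lines) if i not in excluded]
    return CorticalGrid(
        trajectories=trajectories,
        seeds=seeds[keep],
        seed_normals=normals[keep],
        excluded=excluded,
        frame=fieldsol.frame,
    )


@dataclass
class GridSamples:
    """Metric values sampled on the (line, depth) lattice."""

    values: np.ndarray  # (n_lines, n_depth) or (n_lines, n_depth, n_metrics)
    metric: str | list[str]
    subject: str = ""
    group: str = ""
    hemisphere: str = ""

    def to_frame(self) -> pd.DataFrame:
        vals = self.values
        if vals.ndim == 2:
            vals = vals[:, :, None]
            metrics = [self.metric]
        else:
            metrics = list(self.metric)
        rows = []
        for li in range(vals.shape[0]):
            for di in range(vals.shape[1]):
                for mi, m in enumerate(metrics):
                    rows.append(
                        (self.subject, self.group, self.hemisphere, li, di, m,
                         vals[li, di, mi])
                    )
        return pd.DataFrame(
            rows,
            columns=["subject", "group", "hemisphere", "line", "depth",
                     "metric", "value"],
        )


def sample_along(
    grid: CorticalGrid,
    image: np.ndarray,
    frame: Frame,
    n_depth: int = 10,
    validity_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a metric image at the grid's (line, depth) lattice.

    Bilinear interpolation that respects the validity mask: invalid
    neighbours are dropped from the weighted mean and a sample whose
    four neighbours are all invalid is returned as NaN (missing), never
    zero-filled.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(frame.shape):
        raise ValueError(
            f"image shape {image.shape} does not match frame {frame.shape}"
        )
    if validity_mask is None:
        validity_mask = np.isfinite(image)
    else:
        validity_mask = np.asarray(validity_mask, dtype=bool) & np.isfinite(image)
    pts = grid.sample_points(n_depth)
    rc = frame.index(pts)
    r = np.clip(rc[..., 0], 0, image.shape[0] - 1.001)
    c = np.clip(rc[..., 1], 0, image.shape[1] - 1.001)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    img = np.where(validity_mask, image, 0.0)
    out = np.zeros(pts.shape[:2])
    wsum = np.zeros(pts.shape[:2])
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (1, 0, fr * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 1, fr * fc),
    ):
        vmask = validity_mask[r0 + dr, c0 + dc]
        out += np.where(vmask, img[r0 + dr, c0 + dc] * w, 0.0)
        wsum += np.where(vmask, w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = out / wsum
    res[wsum <= 1e-12] = np.nan
    return res
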