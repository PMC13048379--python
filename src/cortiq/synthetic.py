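"""Synthetic ground-truth generators.

This module produces every input the pipeline consumes, with known
ground truth alongside:

* discrete diffusion-tensor distributions (DTDs) — ensembles of
  microscopic Gaussian compartments whose exact moments are computable
  by :func:`cortiq.qti.dtd_moments`;
* b-tensor encoded signals from the exact multi-Gaussian forward model
  S = S0 * sum_i f_i exp(-<B, D_i>);
* a curved cortical-ribbon phantom (annulus sector) with depth- and
  position-dependent microstructure, per-subject boundary jitter, a
  two-group design with a spatially localised planted effect, and
  Rician noise;
* histology-like texture images (oriented stripes, sparse blobs, vortex
  fields) with recorded ground-truth orientation and area fraction.

Units: diffusivities in um^2/ms, b-tensors in ms/um^2 inside the signal
model (scheme files are s/mm^2; 1 ms/um^2 = 1000 s/mm^2), geometry in
mm, image pixel sizes in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .btensor import BTensor, BTensorScheme, mat_to_voigt
from .grid import BoundaryPair, Frame
from .qti import dtd_moments, METRIC_NAMES

__all__ = [
    "DiffusionTensorDistribution",
    "DWIVolume",
    "CortexPhantom",
    "PhantomConfig",
    "EffectConfig",
    "Subject",
    "dtd_signal",
    "make_dtd",
    "watson_directions",
    "add_rician_noise",
    "make_cortex_phantom",
    "simulate_dwi",
    "build_cohort",
    "make_histology_image",
    "FREE_WATER_D",
]

#: free-water diffusivity bound at body temperature, um^2/ms
FREE_WATER_D = 3.0


@dataclass
class DiffusionTensorDistribution:
    """Discrete ensemble of microscopic diffusion tensors.

    ``tensors``: (n, 3, 3) symmetric PSD matrices in um^2/ms;
    ``weights``: nonnegative fractions summing to 1.
    """

    tensors: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.tensors = np.atleast_3d(np.asarray(self.tensors, dtype=float))
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise ValueError("tensors must have shape (n, 3, 3)")
        if self.tensors.shape[0] == 0:
            raise ValueError("DTD must contain at least one tensor")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.tensors.shape[0],) or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per tensor")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = w / total
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, 1, 2)):
            raise ValueError("tensors must be symmetric")
        ev = np.linalg.eigvalsh(self.tensors)
        if np.min(ev) < -1e-9:
            raise ValueError("tensors must be positive semidefinite")

    @property
    def n(self) -> int:
        return self.tensors.shape[0]

    def rotated(self, r: np.ndarray) -> "DiffusionTensorDistribution":
        rt = np.einsum("ab,nbc,dc->nad", r, self.tensors, r)
        return DiffusionTensorDistribution(rt, self.weights.copy())


def dtd_signal(
    dtd: DiffusionTensorDistribution,
    btensor,
    S0: float = 1.0,
) -> np.ndarray:
    """Exact multi-Gaussian forward signal S = S0 sum_i f_i exp(-<B, D_i>).

    ``btensor`` may be a :class:`BTensor`, a (3, 3) matrix or an
    (m, 3, 3) stack, in ms/um^2 (a trace above 100 trips a unit-mismatch
    error: s/mm^2 was probably passed unconverted).
    """
    if isinstance(btensor, BTensor):
        b = btensor.matrix[None]
    else:
        b = np.asarray(btensor, dtype=float)
        if b.shape == (3, 3):
            b = b[None]
    if b.ndim != 3 or b.shape[1:] != (3, 3):
        raise ValueError("btensor must be (3,3) or (m,3,3)")
    tr = np.einsum("mii->m", b)
    if np.any(tr > 100.0):
        raise ValueError(
            f"b-tensor trace {tr.max():.3g} looks like s/mm^2; the signal "
            "model expects ms/um^2 (divide by 1000)"
        )
    b6 = mat_to_voigt(b)  # (m, 6)
    d6 = mat_to_voigt(dtd.tensors)  # (n, 6)
    att = np.exp(-b6 @ d6.T)  # (m, n)
    s = S0 * att @ dtd.weights
    if isinstance(btensor, BTensor) or np.asarray(btensor).shape == (3, 3):
        return float(s[0])
    return s


def watson_directions(
    mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample unit vectors from a Watson distribution (axial symmetry).

    Density proportional to exp(kappa * (mu . x)^2); kappa = 0 is the
    uniform sphere, kappa -> inf collapses onto +/- mu.  Rejection
    sampling from the uniform sphere with envelope exp(kappa).
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if not np.isfinite(kappa):
        return np.tile(mu, (n, 1))
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        x = rng.standard_normal((m, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        t2 = (x @ mu) ** 2
        accept = rng.random(m) < np.exp(kappa * (t2 - 1.0))
        x = x[accept]
        take = min(len(x), n - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return out


def _axisym_tensor(direction: np.ndarray, ad: float, rd: float) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return rd * np.eye(3) + (ad - rd) * np.outer(d, d)


def make_dtd(
    family: str,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> DiffusionTensorDistribution:
    """Construct a DTD from one of three generative families.

    ``"watson_sticks"`` — identical prolate compartments whose symmetry
    axes are Watson-dispersed around ``mu`` with concentration
    ``kappa`` (inf = perfectly coherent, 0 = uniform).  Params:
    eigenvalues (ad, rd), mu, kappa, n.

    ``"iso_spheres"`` — isotropic compartments with a discrete size
    (diffusivity) distribution.  Params: diffusivities, weights.

    ``"cortex"`` — three-compartment mixture mimicking gray matter:
    a Watson-dispersed radial anisotropic population (axons/dendrites),
    an isotropic cellular pool, and a free-water pool at 3.0 um^2/ms.
    Params: f_aniso, f_free, ad, rd, d_cell, mu, kappa, n.

    All eigenvalues are required to lie in [0, 3.0] um^2/ms.
    """
    p = dict(params or {})
    rng = rng or np.random.default_rng()

    if family == "watson_sticks":
        ad = float(p.get("ad", 2.0))
        rd = float(p.get("rd", 0.2))
        kappa = float(p.get("kappa", np.inf))
        n = int(p.get("n", 200))
        mu = np.asarray(p.get("mu", (0.0, 0.0, 1.0)), dtype=float)
        _check_eigs(ad, rd)
        dirs = watson_directions(mu, kappa, n, rng)
        tensors = np.stack([_axisym_tensor(d, ad, rd) for d in dirs])
        return DiffusionTensorDistribution(tensors, np.full(n, 1.0 / n))

    if family == "iso_spheres":
        ds = np.atleast_1d(np.asarray(p.get("diffusivities", (1.0, 3.0)), float))
        w = np.atleast_1d(
            np.asarray(p.get("weights", np.full(len(ds), 1.0 / len(ds))), float)
        )
        _check_eigs(*ds)
        tensors = ds[:, None, None] * np.eye(3)[None]
        return DiffusionTensorDistribution(tensors, w)

    if family == "cortex":
        f_aniso = float(p.get("f_aniso", 0.4))
        f_free = float(p.get("f_free", 0.1))
        if f_aniso + f_free > 1.0 + 1e-9:
            raise ValueError("compartment fractions exceed 1")
        f_cell = max(1.0 - f_aniso - f_free, 0.0)
        ad = float(p.get("ad", 2.0))
        rd = float(p.get("rd", 0.25))
        d_cell = float(p.get("d_cell", 0.6))
        kappa = float(p.get("kappa", 12.0))
        n = int(p.get("n", 30))
        mu = np.asarray(p.get("mu", (1.0, 0.0, 0.0)), dtype=float)
        _check_eigs(ad, rd, d_cell)
        dirs = watson_directions(mu, kappa, n, rng)
        tensors = [_axisym_tensor(d, ad, rd) for d in dirs]
        weights = [f_aniso / n] * n
        tensors.append(d_cell * np.eye(3))
        weights.append(f_cell)
        tensors.append(FREE_WATER_D * np.eye(3))
        weights.append(f_free)
        return DiffusionTensorDistribution(np.stack(tensors), np.array(weights))

    raise ValueError(f"unknown DTD family {family!r}")


def _check_eigs(*vals: float) -> None:
    for v in vals:
        if v < 0 or v > FREE_WATER_D + 1e-9:
            raise ValueError(
                f"diffusivity {v} um^2/ms outside [0, {FREE_WATER_D}]"
            )


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude-MR (Rician) noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


# ----------------------------------------------------------------------
# cortical ribbon phantom


@dataclass
class PhantomConfig:
    """Geometry and microstructure of the annulus-sector cortex phantom.

    The ribbon is the sector of an annulus: pial surface at radius
    ``r_pial`` mm, gray/white interface at ``r_wm``, spanning
    ``theta_span`` degrees.  Depth d in [0, 1] runs pial -> WM, the
    tangential coordinate s in [0, 1] runs across the sector.  The
    anisotropic (radially oriented) compartment fraction peaks at
    mid-depth, free water near the pial surface — a cartoon of cortical
    lamination, not a quantitative atlas.
    """

    r_pial: float = 3.6
    r_wm: float = 2.0
    theta_span: float = 70.0  # degrees
    voxel_size: float = 0.2  # mm
    jitter_amplitude: float = 0.05  # mm, smooth per-subject boundary deformation
    jitter_modes: int = 3
    n_boundary_pts: int = 200
    # microstructure
    kappa: float = 12.0
    ad: float = 2.0
    rd: float = 0.25
    d_cell: float = 0.6
    n_sticks: int = 30
    f_aniso_base: float = 0.2
    f_aniso_peak: float = 0.4  # added at mid-depth (sin(pi d) profile)
    f_free_pial: float = 0.15  # decays over depth
    n_depth_bins: int = 48  # quantisation of depth for shared DTDs

    def f_aniso(self, d: np.ndarray) -> np.ndarray:
        return self.f_aniso_base + self.f_aniso_peak * np.sin(np.pi * d)

    def f_free(self, d: np.ndarray) -> np.ndarray:
        return 0.03 + self.f_free_pial * np.exp(-((d / 0.2) ** 2))


@dataclass
class EffectConfig:
    """A spatially localised group-B perturbation of the microstructure.

    Applied inside the (s, d) block ``s_range`` x ``d_range``: the
    anisotropic compartment fraction is multiplied by
    ``f_aniso_scale``, or, when ``uFA_delta`` is given, scaled so that
    the ground-truth uFA drops by that absolute amount (solved per depth
    bin by bisection on the exact DTD moments).
    """

    s_range: tuple[float, float] = (0.4, 0.6)
    d_range: tuple[float, float] = (0.3, 0.7)
    f_aniso_scale: float | None = None
    uFA_delta: float | None = None

    def is_null(self) -> bool:
        return self.f_aniso_scale is None and self.uFA_delta is None


@dataclass
class CortexPhantom:
    """Voxelised cortical ribbon with per-voxel ground-truth DTDs."""

    frame: Frame
    cortex_mask: np.ndarray  # (rows, cols) bool
    depth: np.ndarray  # normalised depth in [0, 1]; nan outside
    tangential: np.ndarray  # s in [0, 1]; nan outside
    boundaries: BoundaryPair
    lesion_mask: np.ndarray
    group: str
    truth: dict[str, np.ndarray]  # ground-truth metric maps
    dtd_bins: list[DiffusionTensorDistribution] = field(repr=False, default=None)
    bin_index: np.ndarray = field(repr=False, default=None)  # per-voxel bin
    orientation: np.ndarray = field(repr=False, default=None)  # radial angle


@dataclass
class DWIVolume:
    """Noisy b-tensor encoded signals on the phantom grid."""

    signal: np.ndarray  # (rows, cols, n_measurements), >= 0
    S0: np.ndarray  # (rows, cols)
    scheme: BTensorScheme
    sigma: float
    frame: Frame

    def __post_init__(self) -> None:
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError("measurement count does not match scheme length")
        if np.any(self.signal < 0):
            raise ValueError("signals must be nonnegative")


@dataclass
class Subject:
    subject_id: str
    group: str
    dwi: DWIVolume
    boundaries: BoundaryPair
    phantom: CortexPhantom


def _sector_boundaries(
    cfg: PhantomConfig, rng: np.random.Generator | None
) -> BoundaryPair:
    half = np.deg2rad(cfg.theta_span) / 2.0
    theta = np.linspace(-half, half, cfg.n_boundary_pts)
    rp = np.full_like(theta, cfg.r_pial)
    rw = np.full_like(theta, cfg.r_wm)
    if rng is not None and cfg.jitter_amplitude > 0:
        for r in (rp, rw):
            for k in range(1, cfg.jitter_modes + 1):
                amp = rng.normal(0.0, cfg.jitter_amplitude / cfg.jitter_modes)
                phase = rng.uniform(0, 2 * np.pi)
                r += amp * np.sin(k * (theta + half) / (2 * half) * 2 * np.pi + phase)
    pial = np.stack([rp * np.sin(theta), rp * np.cos(theta)], axis=-1)
    wm = np.stack([rw * np.sin(theta), rw * np.cos(theta)], axis=-1)
    return BoundaryPair(pial=pial, wm=wm)


def make_cortex_phantom(
    cfg: PhantomConfig | None = None,
    group: str = "control",
    effect: EffectConfig | None = None,
    rng: np.random.Generator | None = None,
    jitter: bool = True,
) -> CortexPhantom:
    """Build a voxelised ribbon phantom with ground-truth DTDs.

    DTDs are shared across voxels within a (depth bin, lesion flag)
    class up to in-plane rotation to the local radial direction; since
    all derived metrics are rotation invariant the truth maps depend
    only on the class, while signals use the rotated tensors.
    """
    cfg = cfg or PhantomConfig()
    rng = rng or np.random.default_rng()
    boundaries = _sector_boundaries(cfg, rng if jitter else None)

    half = np.deg2rad(cfg.theta_span) / 2.0
    pad = 2 * cfg.voxel_size
    xmax = cfg.r_pial * np.sin(half) + 3 * cfg.jitter_amplitude + pad
    ymin = cfg.r_wm * np.cos(half) - 3 * cfg.jitter_amplitude - pad
    ymax = cfg.r_pial + 3 * cfg.jitter_amplitude + pad
    origin = (-xmax, ymin)
    n_cols = int(np.ceil(2 * xmax / cfg.voxel_size)) + 1
    n_rows = int(np.ceil((ymax - ymin) / cfg.voxel_size)) + 1
    frame = Frame(origin, cfg.voxel_size, (n_rows, n_cols))

    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    xy = frame.world(rows, cols)
    theta = np.arctan2(xy[..., 0], xy[..., 1])
    r = np.hypot(xy[..., 0], xy[..., 1])

    # per-angle boundary radii (interpolate the possibly jittered polylines)
    btheta = np.arctan2(boundaries.pial[:, 0], boundaries.pial[:, 1])
    rp = np.interp(theta.ravel(), btheta, np.hypot(*boundaries.pial.T[::-1]))
    wtheta = np.arctan2(boundaries.wm[:, 0], boundaries.wm[:, 1])
    rw = np.interp(theta.ravel(), wtheta, np.hypot(*boundaries.wm.T[::-1]))
    rp = rp.reshape(theta.shape)
    rw = rw.reshape(theta.shape)

    inside = (np.abs(theta) <= half) & (r <= rp) & (r >= rw)
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = np.where(inside, (rp - r) / np.maximum(rp - rw, 1e-9), np.nan)
    s = np.where(inside, (theta + half) / (2 * half), np.nan)

    effect = effect or EffectConfig()
    lesion = np.zeros_like(inside)
    if group == "treated" and not effect.is_null():
        lesion = (
            inside
            & (s >= effect.s_range[0]) & (s <= effect.s_range[1])
            & (depth >= effect.d_range[0]) & (depth <= effect.d_range[1])
        )

    # canonical DTDs per depth bin (oriented along +x), lesion variants
    # too; the microstructure template is deterministic (a fixed seed)
    # so that all subjects share the same ground-truth tissue and differ
    # only through boundary jitter, lesion, and noise
    edges = np.linspace(0.0, 1.0, cfg.n_depth_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dtd_rng = np.random.default_rng(715517)
    dtds: list[DiffusionTensorDistribution] = []
    truth_scalars = []
    for healthy in (True, False):
        for d in centers:
            fa_frac = float(cfg.f_aniso(np.array(d)))
            if not healthy:
                fa_frac *= _lesion_scale(cfg, effect, float(d))
            dtd = make_dtd(
                "cortex",
                dict(
                    f_aniso=fa_frac,
                    f_free=float(cfg.f_free(np.array(d))),
                    ad=cfg.ad,
                    rd=cfg.rd,
                    d_cell=cfg.d_cell,
                    kappa=cfg.kappa,
                    n=cfg.n_sticks,
                    mu=(1.0, 0.0, 0.0),
                ),
                dtd_rng,
            )
            dtds.append(dtd)
            _, _, maps = dtd_moments(dtd)
            truth_scalars.append({k: float(getattr(maps, k)) for k in METRIC_NAMES})

    bin_idx = np.full(inside.shape, -1, dtype=int)
    db = np.clip(np.digitize(depth[inside], edges) - 1, 0, cfg.n_depth_bins - 1)
    bin_idx[inside] = db
    bin_idx[lesion] += cfg.n_depth_bins  # lesion variants in the second half

    truth = {
        k: np.full(inside.shape, np.nan) for k in METRIC_NAMES
    }
    flat_bins = bin_idx[inside]
    for k in METRIC_NAMES:
        vals = np.array([t[k] for t in truth_scalars])
        arr = truth[k]
        arr[inside] = vals[flat_bins]

    # local radial angle: direction of increasing depth (pial -> WM)
    orient = np.where(inside, np.arctan2(-xy[..., 1], -xy[..., 0]), np.nan)

    return CortexPhantom(
        frame=frame,
        cortex_mask=inside,
        depth=depth,
        tangential=s,
        boundaries=boundaries,
        lesion_mask=lesion,
        group=group,
        truth=truth,
        dtd_bins=dtds,
        bin_index=bin_idx,
        orientation=orient,
    )


def _lesion_scale(cfg: PhantomConfig, effect: EffectConfig, d: float) -> float:
    """Anisotropic-fraction multiplier realising the configured effect."""
    if effect.f_aniso_scale is not None:
        return float(effect.f_aniso_scale)
    if effect.uFA_delta is None:
        return 1.0
    # bisect on the exact moments for the scale giving the target uFA drop
    base_frac = float(cfg.f_aniso(np.array(d)))
    f_free = float(cfg.f_free(np.array(d)))

    def ufa_of(scale: float) -> float:
        dtd = make_dtd(
            "cortex",
            dict(
                f_aniso=base_frac * scale,
                f_free=f_free,
                ad=cfg.ad,
                rd=cfg.rd,
                d_cell=cfg.d_cell,
                kappa=np.inf,  # coherent proxy: uFA is kappa-invariant
                n=1,
            ),
        )
        return float(dtd_moments(dtd)[2].uFA)

    target = ufa_of(1.0) - effect.uFA_delta
    lo, hi = 0.0, 1.0
    if ufa_of(0.0) >= target:
        return 0.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if ufa_of(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _rotate_voigt_inplane(d6: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotate Voigt tensors (n_comp, 6) by per-voxel in-plane angles.

    Returns (n_vox, n_comp, 6).  Rotation about the z axis mapping the
    canonical +x orientation onto the local radial direction.
    """
    from .btensor import voigt_to_mat

    mats = voigt_to_mat(d6)  # (n_comp, 3, 3)
    c, s_ = np.cos(angle), np.sin(angle)
    zero = np.zeros_like(c)
    one = np.ones_like(c)
    rot = np.stack(
        [
            np.stack([c, -s_, zero], -1),
            np.stack([s_, c, zero], -1),
            np.stack([zero, zero, one], -1),
        ],
        -2,
    )  # (n_vox, 3, 3)
    out = np.einsum("vab,nbc,vdc->vnad", rot, mats, rot)
    return mat_to_voigt(out)


def simulate_dwi(
    phantom: CortexPhantom,
    scheme: BTensorScheme,
    S0: float = 1.0,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DWIVolume:
    """Forward-simulate the phantom through the acquisition scheme."""
    rng = rng or np.random.default_rng()
    b6 = scheme.voigt(units="ms/um^2")  # (m, 6)
    shape = phantom.cortex_mask.shape
    sig = np.zeros(shape + (len(scheme),))
    inside = phantom.cortex_mask
    angles = phantom.orientation[inside]
    bins = phantom.bin_index[inside]
    vox_signals = np.zeros((inside.sum(), len(scheme)))
    for bi in np.unique(bins):
        sel = bins == bi
        dtd = phantom.dtd_bins[bi]
        d6 = mat_to_voigt(dtd.tensors)
        d6rot = _rotate_voigt_inplane(d6, angles[sel])  # (v, n, 6)
        att = np.exp(-np.einsum("mk,vnk->vmn", b6, d6rot))
        vox_signals[sel] = S0 * np.einsum("vmn,n->vm", att, dtd.weights)
    sig[inside] = vox_signals
    noisy = add_rician_noise(sig, sigma, rng)
    s0map = np.where(inside, S0, 0.0)
    return DWIVolume(
        signal=noisy, S0=s0map, scheme=scheme, sigma=sigma, frame=phantom.frame
    )


def build_cohort(
    phantom_config: PhantomConfig,
    n_control: int,
    n_treated: int,
    effect_config: EffectConfig | None,
    scheme: BTensorScheme,
    sigma: float,
    rng: np.random.Generator,
) -> list[Subject]:
    """Simulate a two-group cohort with independent jitter and noise.

    Each subject gets independently jittered boundaries (a small smooth
    deformation of the annulus radii) and independent Rician noise; the
    treated group carries the planted effect.  Ground-truth metric maps
    travel with each subject's phantom for validation.
    """
    if n_control < 2 or n_treated < 2:
        raise ValueError("need at least 2 subjects per group for a t-test")
    subjects: list[Subject] = []
    for group, count in (("control", n_control), ("treated", n_treated)):
        for i in range(count):
            sub_rng = np.random.default_rng(rng.integers(2**31))
            phantom = make_cortex_phantom(
                phantom_config, group=group, effect=effect_config, rng=sub_rng
            )
            dwi = simulate_dwi(phantom, scheme, S0=1.0, sigma=sigma, rng=sub_rng)
            subjects.append(
                Subject(
                    subject_id=f"{group}_{i:02d}",
                    group=group,
                    dwi=dwi,
                    boundaries=phantom.boundaries,
                    phantom=phantom,
                )
            )
    return subjects


# ----------------------------------------------------------------------
# histology-like texture images


def make_histology_image(
    pattern: str,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Generate a texture image plus its ground truth.

    Patterns
    --------
    ``"stripes"`` — sinusoidal stripes mimicking coherent myelinated
    (MBP+) fibres.  Params: shape, pixel_size_um, period_um, angle_deg
    (structure orientation, 0 = along +x), orientation_jitter_deg,
    noise.  Truth: orientation_deg.
    ``"blobs"`` — sparse bright foreground mimicking GFAP+ astrocyte
    processes, with an exactly recorded foreground mask.  Params:
    shape, area_fraction, smooth_px, noise.  Truth: mask, area_fraction.
    ``"vortex"`` — concentric rings: locally coherent texture whose
    orientation field swirls around the centre.  Truth: orientation map.
    ``"noise"`` — white noise; ground-truth coherency 0.
    """
    p = dict(params or {})
    rng = rng or np.random.default_rng()
    shape = tuple(p.get("shape", (256, 256)))
    pixel = float(p.get("pixel_size_um", 1.0))

    if pattern == "stripes":
        period = float(p.get("period_um", 12.0)) / pixel
        angle = np.deg2rad(float(p.get("angle_deg", 0.0)))
        jitter = np.deg2rad(float(p.get("orientation_jitter_deg", 0.0)))
        noise = float(p.get("noise", 0.0))
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        if jitter > 0:
            dtheta = gaussian_filter(rng.standard_normal(shape), 8.0)
            dtheta *= jitter / max(dtheta.std(), 1e-12)
        else:
            dtheta = np.zeros(shape)
        a = angle + dtheta
        # structure direction a in Cartesian terms (y up); the phase
        # coordinate runs perpendicular to the structures
        phase = (-xx * np.sin(a) - yy * np.cos(a)) * 2 * np.pi / period
        img = 0.5 + 0.5 * np.sin(phase)
        img += noise * rng.standard_normal(shape)
        truth = {
            "orientation_deg": np.rad2deg(a),
            "pixel_size_um": pixel,
        }
        return img, truth

    if pattern == "blobs":
        target = float(p.get("area_fraction", 0.15))
        smooth = float(p.get("smooth_px", 4.0))
        noise = float(p.get("noise", 0.03))
        pot = gaussian_filter(rng.standard_normal(shape), smooth)
        thr = np.quantile(pot, 1.0 - target)
        mask = pot > thr
        img = 0.15 + 0.8 * mask.astype(float)
        img = gaussian_filter(img, 0.8)
        img += noise * rng.standard_normal(shape)
        truth = {
            "mask": mask,
            "area_fraction": float(mask.mean()),
            "pixel_size_um": pixel,
        }
        return img, truth

    if pattern == "vortex":
        period = float(p.get("period_um", 12.0)) / pixel
        cy, cx = p.get("center", (shape[0] / 2, shape[1] / 2))
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        r = np.hypot(xx - cx, yy - cy)
        img = 0.5 + 0.5 * np.sin(2 * np.pi * r / period)
        # tangential structure direction (Cartesian angles, y up)
        dxc = xx - cx
        dyc = -(yy - cy)
        ori = np.rad2deg(np.arctan2(dxc, -dyc))
        ori = ((ori + 90.0) % 180.0) - 90.0
        truth = {"orientation_deg": ori, "pixel_size_um": pixel}
        return img, truth

    if pattern == "noise":
        img = rng.standard_normal(shape)
        return img, {"coherency": 0.0, "pixel_size_um": pixel}

    raise ValueError(f"unknown texture pattern {pattern!r}")
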