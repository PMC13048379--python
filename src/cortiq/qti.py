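"""Q-space trajectory imaging (QTI) with positivity constraints.

The b-tensor encoded signal of a voxel containing an ensemble of
microscopic Gaussian diffusion environments (a diffusion tensor
distribution, DTD) admits the cumulant expansion

    ln S(B) = ln S0 - <B, <D>> + 1/2 <B (x) B, C>,

where <D> is the ensemble-mean diffusion tensor (6 unique elements) and
C = <D (x) D> - <D> (x) <D> is the fourth-order covariance of the DTD
(21 unique elements).  Fitting this model to a multi-shell, multi-shape
acquisition yields, per voxel, the four DTI metrics (MD, AD, RD, FA)
and four covariance metrics: microscopic fractional anisotropy (uFA),
microscopic orientation coherence (CC = FA^2/uFA^2), and the isotropic
and anisotropic kurtosis (K_bulk, K_shear).

The "+" of QTI+ refers to positivity constraints: the unconstrained
weighted-least-squares solution can leave the physical cone at realistic
noise levels (producing e.g. negative kurtosis); the constrained refit
projects onto the convex set { <D> PSD, C PSD }, which guarantees all
sign invariants of the derived metrics.

Everything internal runs in um^2/ms (diffusivities) and ms/um^2
(b-tensors); 1 ms/um^2 = 1000 s/mm^2.

Voigt convention: (xx, yy, zz, xy, xz, yz) with sqrt(2) scaling on the
off-diagonals, for both the 6-vector of a symmetric 3x3 tensor and the
21-vector of a symmetric 6x6 (Voigt-basis) fourth-order tensor, so all
inner products reduce to dot products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .btensor import BTensorScheme, mat_to_voigt, voigt_to_mat

__all__ = [
    "QTIFit",
    "MetricMaps",
    "design_matrix",
    "fit_qti",
    "qti_metrics",
    "dtd_moments",
    "validity_filter",
    "c66_to_c21",
    "c21_to_c66",
    "METRIC_NAMES",
]

METRIC_NAMES = ("FA", "MD", "AD", "RD", "uFA", "CC", "K_bulk", "K_shear")

_SQRT2 = np.sqrt(2.0)

# index pairs (i <= j) of the 6x6 Voigt matrix, diagonal first
_C21_DIAG = [(i, i) for i in range(6)]
_C21_OFF = [(i, j) for i in range(6) for j in range(i + 1, 6)]

#: isotropic fourth-order bases as 6x6 Voigt matrices
E_ISO = np.eye(6) / 3.0
_VI = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
E_BULK = np.outer(_VI, _VI) / 9.0
E_SHEAR = E_ISO - E_BULK


def c66_to_c21(c: np.ndarray) -> np.ndarray:
    """Symmetric 6x6 Voigt matrix (or stack) -> 21-vector.

    Order: the 6 diagonal entries, then the 15 upper off-diagonals
    (row-major) scaled by sqrt(2), preserving Frobenius inner products.
    """
    c = np.asarray(c)
    cols = [c[..., i, j] for i, j in _C21_DIAG]
    cols += [_SQRT2 * c[..., i, j] for i, j in _C21_OFF]
    return np.stack(cols, axis=-1)


def c21_to_c66(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`c66_to_c21`."""
    v = np.asarray(v)
    out = np.zeros(v.shape[:-1] + (6, 6))
    for k, (i, j) in enumerate(_C21_DIAG):
        out[..., i, j] = v[..., k]
    for k, (i, j) in enumerate(_C21_OFF):
        out[..., i, j] = v[..., 6 + k] / _SQRT2
        out[..., j, i] = v[..., 6 + k] / _SQRT2
    return out


def design_matrix(scheme: BTensorScheme) -> np.ndarray:
    """Cumulant-model design matrix, (n_measurements, 28).

    Row form [1, -b6, 1/2 * voigt21(b6 (x) b6)] with b-tensors in
    ms/um^2, so the coefficient vector is (ln S0, d6 in um^2/ms,
    c21 in um^4/ms^2).

    Raises on a rank-deficient scheme (e.g. a single-shape protocol,
    which cannot separate the isotropic from the anisotropic covariance
    components).
    """
    scheme.validate()
    b6 = scheme.voigt(units="ms/um^2")  # (n, 6)
    outer = b6[:, :, None] * b6[:, None, :]
    x = np.concatenate(
        [np.ones((len(b6), 1)), -b6, 0.5 * c66_to_c21(outer)], axis=1
    )
    rank = np.linalg.matrix_rank(x, tol=1e-10 * np.abs(x).max())
    if rank < 28:
        raise ValueError(
            f"scheme design matrix is rank-deficient (rank {rank} < 28): the "
            "acquisition cannot determine all 21 covariance components; "
            "linear-only schemes, for instance, cannot separate K_bulk from "
            "K_shear. Add more b-tensor shapes/directions."
        )
    return x


@dataclass
class QTIFit:
    """Per-voxel cumulant-model fit.

    Attributes are stacked over voxels: ``lnS0`` (n,), ``mean_d``
    (n, 3, 3) in um^2/ms, ``cov_c`` (n, 6, 6) Voigt in um^4/ms^2.
    ``valid`` flags voxels that were actually fit.
    """

    lnS0: np.ndarray
    mean_d: np.ndarray
    cov_c: np.ndarray
    valid: np.ndarray
    residual_norm: np.ndarray
    constrained: np.ndarray  # True where the PSD refit was engaged
    n_clipped: int = 0  # non-positive signals clipped before log

    @property
    def n_voxels(self) -> int:
        return self.lnS0.shape[0]

    def beta(self) -> np.ndarray:
        """(n, 28) coefficient stack [lnS0, d6, c21]."""
        return np.concatenate(
            [
                self.lnS0[:, None],
                mat_to_voigt(self.mean_d),
                c66_to_c21(self.cov_c),
            ],
            axis=1,
        )


def _beta_to_parts(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return beta[:, 0], voigt_to_mat(beta[:, 1:7]), c21_to_c66(beta[:, 7:28])


def _project_psd_sym(mats: np.ndarray) -> np.ndarray:
    """Project a stack of symmetric matrices onto the PSD cone."""
    w, v = np.linalg.eigh(mats)
    w = np.maximum(w, 0.0)
    return np.einsum("...ij,...j,...kj->...ik", v, w, v)


def _project_cone(beta: np.ndarray) -> np.ndarray:
    """Project (n, 28) coefficients onto { <D> PSD } x { C PSD }."""
    out = beta.copy()
    out[:, 1:7] = mat_to_voigt(_project_psd_sym(voigt_to_mat(beta[:, 1:7])))
    out[:, 7:28] = c66_to_c21(_project_psd_sym(c21_to_c66(beta[:, 7:28])))
    return out


def fit_qti(
    signals: np.ndarray,
    scheme: BTensorScheme,
    constraints: str | None = "psd",
    n_reweight: int = 2,
    psd_tol: float = 1e-8,
    max_iter: int = 500,
) -> QTIFit:
    """Fit the QTI cumulant model voxel-wise.

    Parameters
    ----------
    signals : (n_voxels, n_measurements) array
        Magnitude signals.  Non-positive values are clipped to a small
        epsilon before taking logarithms (count reported on the fit).
    scheme : BTensorScheme
        Must match the measurement axis of ``signals``.
    constraints : {"psd", None}
        "psd" enforces <D> >= 0 and C >= 0 via an accelerated
        projected-gradient refit of the weighted least-squares problem;
        None returns the plain (2x reweighted) WLS solution.

    The WLS weights are the squared model-predicted signals (the
    standard heteroscedasticity correction for log-linearised fits),
    iterated ``n_reweight`` times from an OLS start.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals contain non-finite values")
    if signals.shape[1] != len(scheme):
        raise ValueError(
            f"signal has {signals.shape[1]} measurements but scheme has "
            f"{len(scheme)}"
        )
    if constraints not in (None, "psd"):
        raise ValueError(f"unknown constraints {constraints!r}")

    x = design_matrix(scheme)
    n_vox = signals.shape[0]
    valid = np.any(signals > 0, axis=1)

    eps = 1e-10 * max(float(signals.max(initial=0.0)), 1.0)
    n_clipped = int(np.sum(signals[valid] <= 0))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} non-positive signal values clipped before log",
            stacklevel=2,
        )
    s = np.clip(signals[valid], eps, None)
    y = np.log(s)

    # OLS start, then predicted-signal-squared WLS
    beta = np.linalg.lstsq(x, y.T, rcond=None)[0].T  # (n_valid, 28)
    w = None
    for _ in range(n_reweight):
        pred = np.exp(np.clip(x @ beta.T, -700, 700)).T  # (n_valid, m)
        w = pred**2
        xw = x[None, :, :] * w[:, :, None]
        gram = np.einsum("nmi,mj->nij", xw, x)
        rhs = np.einsum("nmi,nm->ni", xw, y)
        beta = np.linalg.solve(gram, rhs[..., None])[..., 0]

    residual = np.linalg.norm(x @ beta.T - y.T, axis=0)
    constrained_flags = np.zeros(beta.shape[0], dtype=bool)

    if constraints == "psd" and w is not None:
        d_eigs = np.linalg.eigvalsh(voigt_to_mat(beta[:, 1:7]))[:, 0]
        c_eigs = np.linalg.eigvalsh(c21_to_c66(beta[:, 7:28]))[:, 0]
        d_scale = np.maximum(np.abs(beta[:, 1:7]).max(axis=1), 1e-12)
        c_scale = np.maximum(np.abs(beta[:, 7:28]).max(axis=1), 1e-12)
        bad = (d_eigs < -psd_tol * d_scale) | (c_eigs < -psd_tol * c_scale)
        if np.any(bad):
            beta[bad] = _constrained_refit(
                x, y[bad], w[bad], beta[bad], max_iter=max_iter
            )
            residual[bad] = np.linalg.norm(x @ beta[bad].T - y[bad].T, axis=0)
            constrained_flags[bad] = True

    lnS0 = np.full(n_vox, np.nan)
    mean_d = np.full((n_vox, 3, 3), np.nan)
    cov_c = np.full((n_vox, 6, 6), np.nan)
    res = np.full(n_vox, np.nan)
    cons = np.zeros(n_vox, dtype=bool)
    b0, bd, bc = _beta_to_parts(beta)
    lnS0[valid] = b0
    mean_d[valid] = bd
    cov_c[valid] = bc
    res[valid] = residual
    cons[valid] = constrained_flags
    return QTIFit(
        lnS0=lnS0,
        mean_d=mean_d,
        cov_c=cov_c,
        valid=valid,
        residual_norm=res,
        constrained=cons,
        n_clipped=n_clipped,
    )


def _constrained_refit(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    beta0: np.ndarray,
    max_iter: int = 500,
    rtol: float = 1e-10,
) -> np.ndarray:
    """FISTA on the WLS objective over the PSD x PSD product cone.

    The feasible set is convex and the objective is a convex quadratic,
    so accelerated projected gradient converges to the constrained
    optimum.  Each iterate is projected, so the returned solution is
    feasible up to eigendecomposition round-off.
    """
    xw = x[None, :, :] * w[:, :, None]
    gram = np.einsum("nmi,mj->nij", xw, x)  # (n, 28, 28)
    rhs = np.einsum("nmi,nm->ni", xw, y)
    lip = np.linalg.eigvalsh(gram)[:, -1]  # per-voxel Lipschitz constant
    step = (1.0 / np.maximum(lip, 1e-30))[:, None]

    beta = _project_cone(beta0)
    z = beta.copy()
    t = 1.0
    obj_prev = None
    for _ in range(max_iter):
        grad = np.einsum("nij,nj->ni", gram, z) - rhs
        beta_new = _project_cone(z - step * grad)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = beta_new + ((t - 1.0) / t_new) * (beta_new - beta)
        beta, t = beta_new, t_new
        obj = float(
            np.sum(
                np.einsum("ni,nij,nj->n", beta, gram, beta) / 2
                - np.einsum("ni,ni->n", beta, rhs)
            )
        )
        if obj_prev is not None and abs(obj_prev - obj) <= rtol * (1 + abs(obj)):
            break
        obj_prev = obj
    return _project_cone(beta)


@dataclass
class MetricMaps:
    """The eight per-voxel scalar maps plus the validity mask.

    DTI family: FA, MD, AD, RD (from the mean tensor <D>).
    Covariance family: uFA, CC, K_bulk, K_shear (from C), along with the
    intermediate variances V_MD (bulk) and V_shear.
    """

    FA: np.ndarray
    MD: np.ndarray
    AD: np.ndarray
    RD: np.ndarray
    uFA: np.ndarray
    CC: np.ndarray
    K_bulk: np.ndarray
    K_shear: np.ndarray
    V_MD: np.ndarray
    V_shear: np.ndarray
    mask: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _metrics_from_moments(mean_d: np.ndarray, cov_c: np.ndarray) -> MetricMaps:
    """Shared metric formulas for fitted and exact (oracle) moments.

    With E_bulk, E_shear, E_iso the isotropic fourth-order bases:
      FA^2   = 3/2 * (<D>(x)<D> : E_shear) / (<D>(x)<D> : E_iso)
      uFA^2  = 3/2 * (<D(x)D> : E_shear) / (<D(x)D> : E_iso)
      CC     = FA^2 / uFA^2
      V_MD   = C : E_bulk,  V_shear = C : E_shear
      K_bulk = 3 V_MD / MD^2,  K_shear = 6/5 V_shear / MD^2
    """
    mean_d = np.asarray(mean_d)
    cov_c = np.asarray(cov_c)
    single = mean_d.ndim == 2
    if single:
        mean_d = mean_d[None]
        cov_c = cov_c[None]

    finite = np.all(np.isfinite(mean_d), axis=(1, 2)) & np.all(
        np.isfinite(cov_c), axis=(1, 2)
    )
    d6 = mat_to_voigt(np.where(finite[:, None, None], mean_d, 0.0))
    c66 = np.where(finite[:, None, None], cov_c, 0.0)

    eig = np.sort(np.linalg.eigvalsh(voigt_to_mat(d6)), axis=1)[:, ::-1]
    md = np.einsum("ni->n", d6[:, :3]) / 3.0
    ad = eig[:, 0]
    rd = 0.5 * (eig[:, 1] + eig[:, 2])

    dd = d6[:, :, None] * d6[:, None, :]  # <D>(x)<D> in Voigt
    dtot = c66 + dd  # <D (x) D>

    def contract(m, e):
        return np.einsum("nij,ij->n", m, e)

    with np.errstate(invalid="ignore", divide="ignore"):
        fa2 = 1.5 * contract(dd, E_SHEAR) / contract(dd, E_ISO)
        ufa2 = 1.5 * contract(dtot, E_SHEAR) / contract(dtot, E_ISO)
        fa = np.sqrt(np.clip(fa2, 0.0, None))
        ufa = np.sqrt(np.clip(ufa2, 0.0, None))
        cc = np.where(ufa2 > 0, fa2 / ufa2, np.nan)
        v_md = contract(c66, E_BULK)
        v_sh = contract(c66, E_SHEAR)
        k_bulk = 3.0 * v_md / md**2
        k_shear = 1.2 * v_sh / md**2

    mask = finite & (md > 0)
    nanfill = ~mask

    def _mask(a):
        a = a.copy()
        a[nanfill] = np.nan
        return a

    maps = MetricMaps(
        FA=_mask(fa),
        MD=_mask(md),
        AD=_mask(ad),
        RD=_mask(rd),
        uFA=_mask(ufa),
        CC=_mask(cc),
        K_bulk=_mask(k_bulk),
        K_shear=_mask(k_shear),
        V_MD=_mask(v_md),
        V_shear=_mask(v_sh),
        mask=mask,
    )
    if single:
        for name in list(METRIC_NAMES) + ["V_MD", "V_shear", "mask"]:
            setattr(maps, name, getattr(maps, name)[0])
    return maps


def qti_metrics(fit: QTIFit) -> MetricMaps:
    """Derive the eight scalar metrics from a per-voxel fit."""
    maps = _metrics_from_moments(fit.mean_d, fit.cov_c)
    maps.mask = maps.mask & fit.valid
    return maps


def dtd_moments(dtd) -> tuple[np.ndarray, np.ndarray, MetricMaps]:
    """Exact moments and metrics of a discrete diffusion tensor
    distribution — the brute-force oracle against which fits are judged.

    <D> = sum_i f_i D_i ;  C = sum_i f_i d6_i d6_i^T - d6 d6^T (Voigt).
    Returns (mean_d 3x3, cov_c 6x6, MetricMaps of scalars).
    """
    tensors = np.asarray(dtd.tensors, dtype=float)
    weights = np.asarray(dtd.weights, dtype=float)
    mean_d = np.einsum("i,ijk->jk", weights, tensors)
    d6 = mat_to_voigt(tensors)  # (n, 6)
    second = np.einsum("i,ij,ik->jk", weights, d6, d6)
    m6 = mat_to_voigt(mean_d)
    cov_c = second - np.outer(m6, m6)
    return mean_d, cov_c, _metrics_from_moments(mean_d, cov_c)


def validity_filter(
    maps: MetricMaps, reference_fraction: float = 0.005
) -> tuple[MetricMaps, dict]:
    """Exclude voxels whose FA, uFA or CC fall outside [0, 1].

    Out-of-range values arise from fitting errors (noise pushing the
    covariance outside the physical cone); they are removed from the
    validity mask rather than clamped.  The report gives the excluded
    fraction, with a warning when it exceeds ``reference_fraction``
    (0.5%, the level observed in well-conditioned acquisitions).
    """
    mask = maps.mask.copy()
    in_range = np.ones_like(mask, dtype=bool)
    for name in ("FA", "uFA", "CC"):
        v = getattr(maps, name)
        with np.errstate(invalid="ignore"):
            bad = mask & np.isfinite(v) & ((v < 0.0) | (v > 1.0))
        in_range &= ~bad
    excluded = mask & ~in_range
    n_before = int(mask.sum())
    frac = float(excluded.sum()) / n_before if n_before else 0.0
    new_mask = mask & in_range
    out = MetricMaps(
        **{k: getattr(maps, k).copy() for k in METRIC_NAMES},
        V_MD=maps.V_MD.copy(),
        V_shear=maps.V_shear.copy(),
        mask=new_mask,
    )
    for name in list(METRIC_NAMES) + ["V_MD", "V_shear"]:
        arr = getattr(out, name)
        arr[excluded] = np.nan
    report = {
        "n_voxels": n_before,
        "n_excluded": int(excluded.sum()),
        "excluded_fraction": frac,
        "reference_fraction": reference_fraction,
        "exceeds_reference": frac > reference_fraction,
    }
    if report["exceeds_reference"]:
        warnings.warn(
            f"{frac:.2%} of voxels excluded by the validity filter "
            f"(reference bound {reference_fraction:.2%})",
            stacklevel=2,
        )
    return out, report
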