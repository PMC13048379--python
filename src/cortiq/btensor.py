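"""b-tensor algebra for multidimensional diffusion encoding.

In tensor-valued diffusion encoding the familiar diffusion-sensitising
vector is generalised to a second-order symmetric tensor

    B = integral q(t) q(t)^T dt,   q(t) = gamma * integral_0^t G(t') dt',

whose trace is the b-value and whose eigenvalue pattern defines the
encoding *shape*: linear (LTE, one nonzero eigenvalue, the classic
Stejskal-Tanner pulsed gradient), planar (PTE, two equal eigenvalues)
and spherical (STE, isotropic encoding).  This module provides

* numerical waveform -> b-tensor integration,
* analytic construction of the three canonical shapes,
* the axis-splitting trick that derives an LTE waveform (one gradient
  axis) and a PTE waveform (the remaining two axes) from a single STE
  waveform, preserving the gradient spectral content,
* deterministic electrostatic-repulsion direction sets, and
* multi-shell, multi-shape acquisition schemes with plain-text I/O.

Units: gradients in mT/m, time in ms, b-tensors in s/mm**2 unless noted.
Voigt convention (used by the scheme files and by :mod:`cortiq.qti`):
(xx, yy, zz, sqrt(2)*xy, sqrt(2)*xz, sqrt(2)*yz), so the Frobenius inner
product of two symmetric matrices equals the dot product of their Voigt
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "GAMMA_PROTON",
    "GradientWaveform",
    "BTensor",
    "BTensorScheme",
    "waveform_to_btensor",
    "split_ste_axes",
    "make_shape_btensor",
    "ste_waveform",
    "save_waveform",
    "load_waveform",
    "electrostatic_directions",
    "build_protocol_scheme",
    "mat_to_voigt",
    "voigt_to_mat",
]

#: Proton gyromagnetic ratio in rad / (ms * mT).
GAMMA_PROTON = 2.0 * np.pi * 42.577478518e3 * 1e-6 * 1e3  # = 267.522 rad/ms/mT

_SHAPES = ("linear", "planar", "spherical")

# normalised eigenvalue templates (descending) for shape classification
_SHAPE_EIGS = {
    "linear": np.array([1.0, 0.0, 0.0]),
    "planar": np.array([0.5, 0.5, 0.0]),
    "spherical": np.array([1.0, 1.0, 1.0]) / 3.0,
}

_OFF = np.sqrt(2.0)


def mat_to_voigt(m: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 matrix (or stack) -> 6-vector, sqrt(2)-scaled off-diagonals."""
    m = np.asarray(m)
    return np.stack(
        [
            m[..., 0, 0],
            m[..., 1, 1],
            m[..., 2, 2],
            _OFF * m[..., 0, 1],
            _OFF * m[..., 0, 2],
            _OFF * m[..., 1, 2],
        ],
        axis=-1,
    )


def voigt_to_mat(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`mat_to_voigt`."""
    v = np.asarray(v)
    xy = v[..., 3] / _OFF
    xz = v[..., 4] / _OFF
    yz = v[..., 5] / _OFF
    row0 = np.stack([v[..., 0], xy, xz], axis=-1)
    row1 = np.stack([xy, v[..., 1], yz], axis=-1)
    row2 = np.stack([xz, yz, v[..., 2]], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


@dataclass
class GradientWaveform:
    """Effective gradient waveform G(t).

    ``samples`` holds the *effective* gradient: the sign flip imposed by
    the refocusing pulse is already applied to the post-180 lobes, so
    q(t) is simply gamma times the running integral of ``samples``.
    ``pause`` may record the index range of the refocusing gap for
    bookkeeping; it does not affect any computation.
    """

    samples: np.ndarray  # (n, 3), mT/m
    dt: float  # ms
    pause: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("waveform samples must have shape (n, 3)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite amplitudes")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        return (self.samples.shape[0] - 1) * self.dt

    def q(self, gamma: float = GAMMA_PROTON) -> np.ndarray:
        """Dephasing vector q(t) in 1/m, same length as ``samples``."""
        return gamma * cumulative_trapezoid(
            self.samples, dx=self.dt, axis=0, initial=0.0
        )

    def with_axes(self, keep: tuple[int, ...]) -> "GradientWaveform":
        g = np.zeros_like(self.samples)
        g[:, list(keep)] = self.samples[:, list(keep)]
        return GradientWaveform(g, self.dt, self.pause)


def waveform_to_btensor(
    w: GradientWaveform,
    gamma: float = GAMMA_PROTON,
    rephase_rtol: float = 1e-3,
) -> "BTensor":
    """Integrate a gradient waveform into its b-tensor.

    B = integral q q^T dt, returned in s/mm**2.  Raises if the waveform
    does not rephase (residual q at the end of the waveform exceeds
    ``rephase_rtol`` times the peak |q|).
    """
    q = w.q(gamma)  # 1/m
    qmax = float(np.max(np.linalg.norm(q, axis=1), initial=0.0))
    qend = float(np.linalg.norm(q[-1]))
    if qmax > 0 and qend > rephase_rtol * qmax:
        raise ValueError(
            f"waveform does not rephase: residual |q| = {qend:.4g} 1/m "
            f"({qend / qmax:.2%} of peak)"
        )
    outer = q[:, :, None] * q[:, None, :]  # (n, 3, 3)
    b = np.trapezoid(outer, dx=w.dt, axis=0) * 1e-9  # ms/m**2 -> s/mm**2
    b = 0.5 * (b + b.T)
    return BTensor(b)


@dataclass
class BTensor:
    """A 3x3 symmetric positive-semidefinite encoding tensor in s/mm**2."""

    matrix: np.ndarray
    shape: str | None = None  # declared label; validated against eigenvalues
    psd_tol: float = 1e-6

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("b-tensor matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-10 * max(1.0, abs(m).max())):
            raise ValueError("b-tensor matrix must be symmetric")
        self.matrix = 0.5 * (m + m.T)
        ev = np.linalg.eigvalsh(self.matrix)
        if ev[0] < -self.psd_tol * max(self.b, 1.0):
            raise ValueError(
                f"b-tensor has negative eigenvalue {ev[0]:.4g} s/mm^2 "
                f"beyond tolerance"
            )
        if self.shape is None:
            self.shape = self.classify()
        elif self.shape not in _SHAPES:
            raise ValueError(f"unknown shape label {self.shape!r}")
        else:
            got = self.classify()
            if self.b > 0 and got != self.shape:
                raise ValueError(
                    f"declared shape {self.shape!r} inconsistent with "
                    f"eigenvalues (classified as {got!r})"
                )

    @property
    def b(self) -> float:
        """b-value: trace of the encoding tensor (s/mm**2)."""
        return float(np.trace(self.matrix))

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues in descending order."""
        return np.linalg.eigvalsh(self.matrix)[::-1]

    @property
    def orientation(self) -> np.ndarray:
        """Principal eigenvector (unit length)."""
        w, v = np.linalg.eigh(self.matrix)
        return v[:, -1]

    def classify(self, tol: float = 0.05) -> str:
        """Shape label from normalised eigenvalues (tolerance ``tol * b``)."""
        if self.b <= 0:
            return "spherical"  # zero tensor: isotropic by convention
        lam = self.eigenvalues / self.b
        for name, ref in _SHAPE_EIGS.items():
            if np.max(np.abs(lam - ref)) < tol:
                return name
        return "general"

    def voigt(self) -> np.ndarray:
        return mat_to_voigt(self.matrix)


def make_shape_btensor(
    shape: str, b: float, orientation: np.ndarray | None = None
) -> BTensor:
    """Analytic b-tensor of a canonical shape.

    linear    -> b * n n^T
    planar    -> (b/2) (I - n n^T)
    spherical -> (b/3) I          (orientation ignored)
    """
    if shape not in _SHAPES:
        raise ValueError(f"unknown shape label {shape!r}; expected one of {_SHAPES}")
    if b < 0:
        raise ValueError("b must be non-negative")
    if shape == "spherical":
        return BTensor(b / 3.0 * np.eye(3), shape="spherical")
    if orientation is None:
        raise ValueError(f"{shape} encoding requires an orientation vector")
    n = np.asarray(orientation, dtype=float)
    if n.shape != (3,) or not np.isclose(np.linalg.norm(n), 1.0, atol=1e-6):
        raise ValueError("orientation must be a 3-component unit vector")
    proj = np.outer(n, n)
    if shape == "linear":
        return BTensor(b * proj, shape="linear")
    return BTensor(b / 2.0 * (np.eye(3) - proj), shape="planar")


def split_ste_axes(
    w_ste: GradientWaveform,
) -> tuple[GradientWaveform, GradientWaveform]:
    """Derive LTE and PTE waveforms from an STE waveform.

    The z axis alone gives linear encoding; the x and y axes together
    give planar encoding.  Both inherit the parent's spectral content.
    Raises if any axis of the STE waveform is identically zero.
    """
    g = w_ste.samples
    scale = np.max(np.abs(g), initial=0.0)
    for ax, name in enumerate("xyz"):
        if np.max(np.abs(g[:, ax]), initial=0.0) <= 1e-12 * max(scale, 1.0):
            raise ValueError(
                f"degenerate STE waveform: {name} axis is identically zero"
            )
    return w_ste.with_axes((2,)), w_ste.with_axes((0, 1))


def ste_waveform(
    b: float = 2000.0,
    duration: float = 12.0,
    dt: float = 0.005,
    n_turns: int = 6,
    ramp_frac: float = 0.2,
) -> GradientWaveform:
    """Analytic spherical-tensor-encoding waveform.

    The dephasing vector q(t) sweeps a cone at the magic angle
    (arccos(1/sqrt(3))) with a raised-cosine amplitude envelope, the
    classic q-vector trajectory for isotropic encoding.  A final exact
    isotropising linear map is applied to q so that B equals (b/3) I to
    machine precision, which also nulls the xz/yz cross-moments; the
    axis-split identity B_lte + B_pte = B_ste then holds exactly.

    Parameters are in ms (duration, dt) and s/mm**2 (b).
    """
    if b < 0:
        raise ValueError("b must be non-negative")
    n = int(round(duration / dt)) + 1
    tau = np.linspace(0.0, 1.0, n)
    # raised-cosine ramps
    env = np.ones(n)
    r = max(ramp_frac, 1e-6)
    up = tau < r
    down = tau > 1.0 - r
    env[up] = 0.5 * (1.0 - np.cos(np.pi * tau[up] / r))
    env[down] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - tau[down]) / r))
    psi = 2.0 * np.pi * n_turns * tau
    ct = 1.0 / np.sqrt(3.0)  # cos(magic angle)
    st = np.sqrt(2.0 / 3.0)
    q = np.stack(
        [env * st * np.cos(psi), env * st * np.sin(psi), env * ct], axis=1
    )
    if b == 0:
        return GradientWaveform(np.zeros((n, 3)), dt)
    # isotropise: q' = A q with A = sqrt(b/3) * B^{-1/2}
    bmat = np.trapezoid(q[:, :, None] * q[:, None, :], dx=dt, axis=0)
    w_, v_ = np.linalg.eigh(bmat)
    a = (v_ * (1.0 / np.sqrt(w_))) @ v_.T
    q = q @ a.T
    # scale so that trace(B) = b (accounting for unit conversion)
    # with A as above trace = 3 in integration units; target b in s/mm^2
    q *= np.sqrt(b / 3.0 / 1e-9)  # q now in 1/m after gamma-free construction
    g = np.gradient(q, dt, axis=0) / GAMMA_PROTON  # mT/m
    # re-zero the tiny residual q(end) caused by differentiation error:
    # force exact rephasing by removing the mean gradient
    g -= np.trapezoid(g, dx=dt, axis=0) / duration
    return GradientWaveform(g, dt)


def electrostatic_directions(n: int, seed: int = 1234, n_iter: int = 2000) -> np.ndarray:
    """Deterministic antipodally-symmetric point set on the unit sphere.

    Gradient descent on the Coulomb energy of n charge pairs (each point
    interacts with all others and their antipodes), starting from a
    seeded random configuration.  Bit-reproducible for a given (n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            d = x[:, None, :] - sign * x[None, :, :]  # (n, n, 3)
            r2 = np.sum(d * d, axis=-1)
            np.fill_diagonal(r2, np.inf)
            r2 = np.maximum(r2, 1e-12)
            force += np.sum(d / r2[..., None] ** 1.5, axis=1)
        x = x + step * force / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


@dataclass
class BTensorScheme:
    """Ordered acquisition scheme: one b-tensor per measurement."""

    btensors: list[BTensor]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.btensors) == 0:
            raise ValueError("scheme is empty")

    def __len__(self) -> int:
        return len(self.btensors)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([t.b for t in self.btensors])

    @property
    def shapes(self) -> list[str]:
        return [t.shape for t in self.btensors]

    @property
    def matrices(self) -> np.ndarray:
        """(n, 3, 3) stack in s/mm**2."""
        return np.stack([t.matrix for t in self.btensors])

    def voigt(self, units: str = "s/mm^2") -> np.ndarray:
        """(n, 6) Voigt stack; units 's/mm^2' or 'ms/um^2'."""
        v = mat_to_voigt(self.matrices)
        if units == "ms/um^2":
            return v / 1000.0
        if units == "s/mm^2":
            return v
        raise ValueError(f"unknown units {units!r}")

    def shells(self, rtol: float = 0.05) -> np.ndarray:
        """Distinct nonzero b-values (clustered within ``rtol``), ascending."""
        bs = np.sort(self.bvals[self.bvals > 0])
        out: list[float] = []
        for b in bs:
            if not out or b > out[-1] * (1 + rtol):
                out.append(float(b))
        return np.array(out)

    def validate(self) -> None:
        """Check the minimum requirements for a QTI-fittable scheme."""
        if len(self) < 28:
            raise ValueError(
                f"scheme has {len(self)} measurements; QTI fitting needs >= 28"
            )
        nonzero_shapes = {t.shape for t in self.btensors if t.b > 0}
        if len(nonzero_shapes) < 2:
            raise ValueError(
                "scheme is rank-deficient: needs >= 2 b-tensor shapes "
                f"(got {sorted(nonzero_shapes)})"
            )
        if len(self.shells()) < 2:
            raise ValueError("scheme needs >= 2 b-value shells")
        if float(np.min(self.bvals)) > 0.15 * float(np.max(self.bvals)):
            raise ValueError("scheme needs a b=0 or minimal-b measurement")

    # --- plain-text I/O ---------------------------------------------------

    def save(self, path) -> None:
        header = (
            "# cortiq b-tensor scheme\n"
            "# columns: b(s/mm^2) shape xx yy zz sqrt2*xy sqrt2*xz sqrt2*yz\n"
            "# voigt convention: off-diagonals scaled by sqrt(2); units s/mm^2\n"
        )
        if self.provenance:
            header += f"# provenance: {self.provenance}\n"
        rows = []
        for t in self.btensors:
            v = t.voigt()
            rows.append(
                f"{t.b:.6g} {t.shape} " + " ".join(f"{x:.8g}" for x in v)
            )
        with open(path, "w") as fh:
            fh.write(header + "\n".join(rows) + "\n")

    @classmethod
    def load(cls, path) -> "BTensorScheme":
        """Read a scheme file.

        Accepts the native dialect (b, shape, 6 Voigt components) and a
        bare 3x3-per-line dialect (9 row-major matrix entries in s/mm^2;
        b and shape inferred).
        """
        tensors: list[BTensor] = []
        prov = ""
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "provenance:" in line:
                        prov = line.split("provenance:", 1)[1].strip()
                    continue
                parts = line.split()
                if len(parts) == 8:
                    v = np.array([float(x) for x in parts[2:]])
                    t = BTensor(voigt_to_mat(v), shape=parts[1])
                    if abs(t.b - float(parts[0])) > 0.01 * max(float(parts[0]), 1.0):
                        raise ValueError(
                            f"declared b={parts[0]} differs from trace {t.b:.4g} "
                            "by more than 1%"
                        )
                elif len(parts) == 9:
                    m = np.array([float(x) for x in parts]).reshape(3, 3)
                    t = BTensor(m)
                else:
                    raise ValueError(
                        f"unrecognised scheme row with {len(parts)} fields"
                    )
                tensors.append(t)
        return cls(tensors, provenance=prov)


_DEFAULT_SHELLS = (200.0, 700.0, 1400.0, 2000.0)


@dataclass
class ProtocolConfig:
    """Configuration of the multi-shell, multi-shape acquisition scheme.

    Defaults follow the study protocol: four b-value shells at
    200/700/1400/2000 s/mm^2 with 10 spherical encodings per shell.
    The per-shell linear and planar direction counts are configurable
    (the acquisition table does not pin them down); the default of 10
    per shell per shape keeps the scheme well-conditioned.
    """

    shells: tuple[float, ...] = _DEFAULT_SHELLS
    ste_per_shell: int = 10
    lte_per_shell: tuple[int, ...] | int = 10
    pte_per_shell: tuple[int, ...] | int = 10
    n_b0: int = 1
    direction_seed: int = 1234

    def counts(self, which: str) -> tuple[int, ...]:
        v = {"lte": self.lte_per_shell, "pte": self.pte_per_shell,
             "ste": self.ste_per_shell}[which]
        if np.isscalar(v):
            return tuple([int(v)] * len(self.shells))
        if len(v) != len(self.shells):
            raise ValueError(f"{which} direction counts must match shell count")
        return tuple(int(x) for x in v)


def build_protocol_scheme(config: ProtocolConfig | None = None) -> BTensorScheme:
    """Build the full acquisition scheme from a protocol configuration.

    Spherical encodings are nominally orientation-free but are tagged
    with rotated frames (matching an STE waveform rotated in 10
    directions per shell); linear and planar encodings use deterministic
    electrostatic-repulsion direction sets.
    """
    cfg = config or ProtocolConfig()
    tensors: list[BTensor] = []
    for _ in range(cfg.n_b0):
        tensors.append(BTensor(np.zeros((3, 3)), shape="spherical"))
    lte_counts = cfg.counts("lte")
    pte_counts = cfg.counts("pte")
    ste_counts = cfg.counts("ste")
    for i, b in enumerate(cfg.shells):
        for _ in range(ste_counts[i]):
            tensors.append(make_shape_btensor("spherical", b))
        if lte_counts[i] > 0:
            for n in electrostatic_directions(lte_counts[i], seed=cfg.direction_seed):
                tensors.append(make_shape_btensor("linear", b, n))
        if pte_counts[i] > 0:
            for n in electrostatic_directions(
                pte_counts[i], seed=cfg.direction_seed + 1
            ):
                tensors.append(make_shape_btensor("planar", b, n))
    scheme = BTensorScheme(
        tensors,
        provenance=(
            f"protocol shells={tuple(cfg.shells)} ste={ste_counts} "
            f"lte={lte_counts} pte={pte_counts} seed={cfg.direction_seed}"
        ),
    )
    scheme.validate()
    return scheme


def save_waveform(w: GradientWaveform, path) -> None:
    """Write a waveform as plain text: columns t(ms), Gx, Gy, Gz (mT/m)."""
    t = np.arange(w.samples.shape[0]) * w.dt
    header = (
        "# cortiq gradient waveform\n"
        "# columns: t(ms) Gx(mT/m) Gy(mT/m) Gz(mT/m); effective gradient\n"
        "# (post-refocusing polarity already applied)\n"
    )
    rows = [
        f"{ti:.6g} " + " ".join(f"{g:.8g}" for g in gi)
        for ti, gi in zip(t, w.samples)
    ]
    with open(path, "w") as fh:
        fh.write(header + "\n".join(rows) + "\n")


def load_waveform(path) -> GradientWaveform:
    """Read a plain-text waveform file (t, Gx, Gy, Gz columns).

    The time column must be uniformly spaced; dt is inferred from it.
    """
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 4:
        raise ValueError("waveform file needs 4 columns: t, Gx, Gy, Gz")
    t = data[:, 0]
    dts = np.diff(t)
    if len(dts) == 0:
        raise ValueError("waveform file needs at least 2 samples")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > 1e-6 * max(dt, 1e-12):
        raise ValueError("waveform time column is not uniformly spaced")
    return GradientWaveform(data[:, 1:4], dt)
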