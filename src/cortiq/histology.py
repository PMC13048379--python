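"""Structure-tensor texture analysis of histology-like images.

The local organisation of immunofluorescence textures (e.g. myelinated
MBP+ fibres) is summarised by the structure tensor

    J = G_sigma * (grad I grad I^T),

the Gaussian-windowed outer product of image gradients.  Its
eigen-structure gives, per pixel,

* energy     = lambda1 + lambda2           (texture strength),
* coherency  = (lambda1 - lambda2) / (lambda1 + lambda2) in [0, 1],
* orientation = dominant *structure* direction in degrees (-90, 90],
  0 deg = image x-axis (columns), positive counter-clockwise in
  Cartesian terms (y axis pointing up, i.e. against the row index).

Also provided: radiality (alignment of texture with the cortical
normal), Otsu-threshold area fractions for sparse markers (GFAP+
astrocytes), depth profiles, and group comparisons of region summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

from .stats import vertex_tests

__all__ = [
    "TextureMaps",
    "DepthProfile",
    "structure_tensor",
    "radiality",
    "area_fraction",
    "depth_profiles",
    "texture_group_compare",
]


@dataclass
class TextureMaps:
    """Structure-tensor maps of one image."""

    orientation: np.ndarray  # degrees in (-90, 90]; nan where energy ~ 0
    coherency: np.ndarray  # [0, 1]
    energy: np.ndarray  # >= 0
    sigma_um: float
    pixel_size_um: float


def structure_tensor(
    image: np.ndarray,
    sigma_um: float = 15.0,
    pixel_size_um: float = 1.0,
    inner_sigma_px: float = 1.0,
    energy_eps: float | None = None,
) -> TextureMaps:
    """Structure-tensor orientation/coherency/energy maps.

    Gradients are Gaussian derivatives at ``inner_sigma_px`` pixels;
    the tensor is windowed with a Gaussian of ``sigma_um`` (converted
    through the pixel size; default 15 um).  Constant images get
    energy 0 and, by convention, coherency 0; orientation is undefined
    (NaN) wherever energy is negligible.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("structure tensor analysis expects a 2D image")
    if sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    if sigma_um <= pixel_size_um:
        raise ValueError("sigma_um must exceed the pixel size")
    sigma_px = sigma_um / pixel_size_um
    # x = columns (axis 1), y = rows (axis 0); the row-axis/Cartesian
    # flip cancels inside atan2(2 Jxy, Jyy - Jxx), so the returned
    # orientation is already the Cartesian (y-up) structure angle
    ix = gaussian_filter(image, inner_sigma_px, order=(0, 1))
    iy = gaussian_filter(image, inner_sigma_px, order=(1, 0))
    jxx = gaussian_filter(ix * ix, sigma_px)
    jyy = gaussian_filter(iy * iy, sigma_px)
    jxy = gaussian_filter(ix * iy, sigma_px)

    energy = jxx + jyy  # = lambda1 + lambda2
    diff = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)  # = lambda1 - lambda2
    if energy_eps is None:
        energy_eps = 1e-12 * max(float(energy.max(initial=0.0)), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(energy > energy_eps, diff / energy, 0.0)
    orientation = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jyy - jxx))
    orientation = ((orientation + 90.0) % 180.0) - 90.0
    orientation[orientation <= -90.0] = 90.0
    orientation = np.where(energy > energy_eps, orientation, np.nan)
    return TextureMaps(
        orientation=orientation,
        coherency=np.clip(coherency, 0.0, 1.0),
        energy=energy,
        sigma_um=sigma_um,
        pixel_size_um=pixel_size_um,
    )


def radiality(maps: TextureMaps, normal_angle_deg: np.ndarray) -> np.ndarray:
    """|cos| of the angle between texture orientation and the pial normal.

    1 = perfectly radial texture (fibres running pial -> WM),
    0 = tangential.  ``normal_angle_deg`` is the pial-normal direction
    in the same convention as the orientation map (broadcastable).
    """
    normal = np.asarray(normal_angle_deg, dtype=float)
    try:
        delta = maps.orientation - normal
    except ValueError as err:
        raise ValueError(
            "normal field shape does not match the orientation map"
        ) from err
    return np.abs(np.cos(np.deg2rad(delta)))


def area_fraction(
    image: np.ndarray,
    threshold_method: str = "otsu",
    roi: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Foreground mask and percent area by automatic thresholding.

    Otsu's between-class-variance-maximising threshold; foreground is
    the brighter class.  Returns (mask, percent area within the ROI).
    Raises on a constant image (threshold undefined).
    """
    image = np.asarray(image, dtype=float)
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    vals = image if roi is None else image[np.asarray(roi, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    if np.ptp(vals) == 0:
        raise ValueError("constant image: threshold undefined")
    thr = threshold_otsu(vals)
    mask = image > thr
    if roi is None:
        pct = 100.0 * float(mask.mean())
    else:
        roi = np.asarray(roi, dtype=bool)
        pct = 100.0 * float(mask[roi].mean())
    return mask, pct


@dataclass
class DepthProfile:
    """Mean +/- SD of a measure in uniform cortical-depth bins."""

    bin_centers: np.ndarray  # depth fractions in [0, 1]
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    measure: str = ""
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.bin_centers,
                "mean": self.mean,
                "sd": self.sd,
                "n": self.n,
                "measure": self.measure,
                "group": self.group,
            }
        )


def depth_profiles(
    measure: np.ndarray,
    depth: np.ndarray,
    n_bins: int = 10,
    roi: np.ndarray | None = None,
    measure_name: str = "",
    group: str = "",
) -> DepthProfile:
    """Bin a measure map by normalised cortical depth.

    ``depth`` is a per-pixel depth-fraction map (e.g. a Laplacian
    potential between the delineated boundaries, or a straight-line
    depth within a rectangular column ROI), NaN outside the cortex.
    Empty bins yield NaN means (missing), never zero.
    """
    measure = np.asarray(measure, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if measure.shape != depth.shape:
        raise ValueError("measure and depth maps differ in shape")
    sel = np.isfinite(measure) & np.isfinite(depth)
    if roi is not None:
        sel &= np.asarray(roi, dtype=bool)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    d = np.clip(depth[sel], 0.0, 1.0)
    v = measure[sel]
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    for k in range(n_bins):
        vk = v[idx == k]
        n[k] = len(vk)
        if len(vk):
            mean[k] = vk.mean()
            sd[k] = vk.std(ddof=1) if len(vk) > 1 else 0.0
    return DepthProfile(centers, mean, sd, n, measure_name, group)


def column_depth_map(
    shape: tuple[int, int], axis: int = 0, roi: np.ndarray | None = None
) -> np.ndarray:
    """Straight-line depth fractions for a rectangular cortical column.

    ``axis`` is the depth axis (0 = rows increasing with depth).
    """
    n = shape[axis]
    frac = (np.arange(n) + 0.5) / n
    depth = frac[:, None] if axis == 0 else frac[None, :]
    depth = np.broadcast_to(depth, shape).copy()
    if roi is not None:
        depth[~np.asarray(roi, dtype=bool)] = np.nan
    return depth


def texture_group_compare(
    region_means: dict[str, np.ndarray] | pd.DataFrame,
    groups: tuple[str, str] = ("control", "treated"),
) -> pd.DataFrame:
    """Student's t comparisons of per-subject region summaries.

    ``region_means`` maps measure name -> (values_group_a,
    values_group_b) arrays of per-subject means, or a long DataFrame
    with columns (measure, group, value).  Returns one row per measure
    with t, two-sided p, and Cohen's d.
    """
    if isinstance(region_means, pd.DataFrame):
        packed = {}
        for m, sub in region_means.groupby("measure"):
            packed[m] = (
                sub[sub.group == groups[0]].value.to_numpy(),
                sub[sub.group == groups[1]].value.to_numpy(),
            )
        region_means = packed
    rows = []
    for measure, (a, b) in region_means.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"measure {measure!r}: need >= 2 subjects per group"
            )
        t, p, d = vertex_tests(a[:, None], b[:, None])
        rows.append((measure, len(a), len(b), t[0], p[0], d[0]))
    return pd.DataFrame(
        rows, columns=["measure", "n_a", "n_b", "t", "p", "d"]
    )
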