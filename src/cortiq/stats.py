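"""Vertex-wise two-group inference on the cortical grid.

Point-wise two-sample Student's t-tests (pooled variance) with Cohen's d
effect sizes, followed by family-wise-error control through
cluster-extent permutation testing: supra-threshold vertices
(p_uncorr below the cluster-forming threshold) are grouped into
connected clusters, and each observed cluster's extent is referred to
the permutation distribution of the *maximum* cluster extent obtained
by randomly relabelling subjects between groups.

Defaults follow the study design: cluster-forming threshold
p_uncorr < 0.01, 5000 permutations, significance at p_clus < 0.05,
4-connectivity on the (line, depth) lattice with clusters formed
separately for positive and negative effect signs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "ClusterStatsResult",
    "vertex_tests",
    "form_clusters",
    "permutation_pclus",
    "render_effect_map",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


def vertex_tests(
    samples_a: np.ndarray, samples_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t, two-sided p, and Cohen's d per vertex.

    ``samples_a``/``samples_b``: (n_subjects, ...) stacks; NaN entries
    are treated as missing and removed vertex-wise.  Vertices with
    fewer than 2 subjects in either group are returned as NaN; vertices
    with zero pooled variance get t = 0, p = 1, d = 0.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    na = np.sum(np.isfinite(a), axis=0)
    nb = np.sum(np.isfinite(b), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ma = np.nanmean(a, axis=0)
        mb = np.nanmean(b, axis=0)
        va = np.nanvar(a, axis=0, ddof=1)
        vb = np.nanvar(b, axis=0, ddof=1)
    ok = (na >= 2) & (nb >= 2)
    df = na + nb - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((na - 1) * va + (nb - 1) * vb) / np.maximum(df, 1)
        sp = np.sqrt(sp2)
        se = sp * np.sqrt(1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1))
        t = (ma - mb) / se
        d = (ma - mb) / sp
    zero_var = ok & (sp2 <= 0)
    t = np.where(zero_var, 0.0, t)
    d = np.where(zero_var, 0.0, d)
    p = np.full(t.shape, np.nan)
    val = ok & np.isfinite(t)
    p[val] = 2.0 * sps.t.sf(np.abs(t[val]), df[val])
    p = np.where(zero_var, 1.0, p)
    t = np.where(ok, t, np.nan)
    d = np.where(ok, d, np.nan)
    return t, p, d


def form_clusters(
    p_uncorr: np.ndarray,
    effect_sign: np.ndarray,
    alpha_form: float = 0.01,
    connectivity: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Group supra-threshold vertices into signed connected clusters.

    Vertices with p < ``alpha_form`` are clustered by 4- (default) or
    8-connectivity on the (line, depth) lattice, separately for
    positive and negative effect signs.  Returns (labels, extents):
    ``labels`` is 0 for sub-threshold vertices and 1..K otherwise;
    ``extents[k-1]`` is the vertex count of cluster k.
    """
    if connectivity == 4:
        struct = _STRUCT4
    elif connectivity == 8:
        struct = _STRUCT8
    else:
        raise ValueError("connectivity must be 4 or 8")
    with np.errstate(invalid="ignore"):
        supra = np.isfinite(p_uncorr) & (p_uncorr < alpha_form)
    labels = np.zeros(p_uncorr.shape, dtype=int)
    extents: list[int] = []
    offset = 0
    for sign in (1, -1):
        mask = supra & (np.sign(effect_sign) == sign)
        lab, n = ndimage.label(mask, structure=struct)
        if n:
            labels[lab > 0] = lab[lab > 0] + offset
            counts = np.bincount(lab[lab > 0])[1:]
            extents.extend(int(c) for c in counts)
            offset += n
    return labels, np.asarray(extents, dtype=int)


@dataclass
class ClusterStatsResult:
    """Full output of the cluster-extent permutation test."""

    t: np.ndarray
    p_uncorr: np.ndarray
    d: np.ndarray
    cluster_labels: np.ndarray
    cluster_extents: np.ndarray  # (n_clusters,)
    p_clus: np.ndarray  # (n_clusters,)
    null_max_extents: np.ndarray  # (n_perm,)
    alpha_form: float
    n_perm: int
    seed: int | None
    exhaustive: bool
    vertex_mask: np.ndarray  # vertices retained for testing

    def significant_clusters(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean map of vertices in clusters with p_clus < alpha."""
        out = np.zeros(self.cluster_labels.shape, dtype=bool)
        for k, p in enumerate(self.p_clus, start=1):
            if p < alpha:
                out |= self.cluster_labels == k
        return out

    def p_clus_map(self) -> np.ndarray:
        out = np.full(self.cluster_labels.shape, np.nan)
        for k, p in enumerate(self.p_clus, start=1):
            out[self.cluster_labels == k] = p
        return out

    def to_frame(self) -> pd.DataFrame:
        nl, nd = self.t.shape
        pc = self.p_clus_map()
        rows = []
        for li in range(nl):
            for di in range(nd):
                rows.append(
                    (li, di, self.t[li, di], self.p_uncorr[li, di],
                     self.d[li, di], int(self.cluster_labels[li, di]),
                     pc[li, di])
                )
        return pd.DataFrame(
            rows, columns=["line", "depth", "t", "p_uncorr", "d",
                           "cluster", "p_clus"]
        )

    def summary(self) -> dict:
        return {
            "n_clusters": int(len(self.cluster_extents)),
            "cluster_extents": self.cluster_extents.tolist(),
            "p_clus": [float(p) for p in self.p_clus],
            "n_significant": int(np.sum(self.p_clus < 0.05)),
            "alpha_form": self.alpha_form,
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
        }


def _tmaps_for_labelsets(
    data: np.ndarray, a_masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled-variance t-maps for many group relabelings.

    ``data``: (n_subjects, n_vertices) with NaN already excluded
    (vertices must be complete); ``a_masks``: (n_perm, n_subjects)
    boolean group-A memberships of fixed size.  Returns (t, p) of shape
    (n_perm, n_vertices).
    """
    n = data.shape[0]
    na = a_masks[0].sum()
    nb = n - na
    a = a_masks.astype(float)
    tot = data.sum(axis=0)
    tot2 = (data**2).sum(axis=0)
    sa = a @ data  # (n_perm, n_vertices)
    sa2 = a @ data**2
    sb = tot[None, :] - sa
    sb2 = tot2[None, :] - sa2
    ma = sa / na
    mb = sb / nb
    va = (sa2 - na * ma**2) / (na - 1)
    vb = (sb2 - nb * mb**2) / (nb - 1)
    df = n - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.where(sp2 <= 0, 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


def permutation_pclus(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    alpha_form: float = 0.01,
    n_perm: int = 5000,
    seed: int | None = 0,
    connectivity: int = 4,
) -> ClusterStatsResult:
    """Cluster-extent permutation test on the (line, depth) lattice.

    Group labels are shuffled without replacement (preserving group
    sizes); for each permutation the maximum cluster extent across both
    signs is recorded.  An observed cluster of extent e gets

        p_clus = (1 + #{permutation max extent >= e}) / (1 + n_perm)

    (the +1 makes the p-value valid, never zero).  When ``n_perm``
    meets or exceeds the number of distinct relabelings, all of them
    are enumerated instead (with the identity included and the plain
    count ratio used), after a warning.

    Vertices missing for any subject (or with < 2 subjects per group)
    are excluded from testing in the observed data and all permutations.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group sample grids differ in shape")
    na, nb = a.shape[0], b.shape[0]
    if na + nb < 4 or na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per group and >= 4 total")
    grid_shape = a.shape[1:]

    t_obs, p_obs, d_obs = vertex_tests(a, b)
    data = np.concatenate([a, b], axis=0).reshape(na + nb, -1)
    # a vertex is testable only if finite for every subject, so that the
    # >=2-per-group requirement survives every relabeling
    vertex_mask_flat = np.all(np.isfinite(data), axis=0)
    vertex_mask = vertex_mask_flat.reshape(grid_shape)
    p_masked = np.where(vertex_mask, p_obs, np.nan)
    labels, extents = form_clusters(p_masked, t_obs, alpha_form, connectivity)

    n_total = math.comb(na + nb, na)
    exhaustive = n_perm >= n_total
    rng = np.random.default_rng(seed)
    if exhaustive:
        warnings.warn(
            f"n_perm={n_perm} >= C({na + nb},{na})={n_total} distinct "
            "relabelings; enumerating exhaustively",
            stacklevel=2,
        )
        a_masks = np.zeros((n_total, na + nb), dtype=bool)
        for i, idx in enumerate(combinations(range(na + nb), na)):
            a_masks[i, list(idx)] = True
        n_used = n_total
    else:
        a_masks = np.zeros((n_perm, na + nb), dtype=bool)
        for i in range(n_perm):
            a_masks[i, rng.permutation(na + nb)[:na]] = True
        n_used = n_perm

    dsub = data[:, vertex_mask_flat]
    null_max = np.zeros(n_used, dtype=int)
    if dsub.shape[1] > 0:
        chunk = max(1, int(2e7 // max(dsub.shape[1], 1)))
        p_full = np.full(grid_shape, np.nan)
        for start in range(0, n_used, chunk):
            tm, pm = _tmaps_for_labelsets(dsub, a_masks[start : start + chunk])
            for j in range(tm.shape[0]):
                p_full[:] = np.nan
                p_full[vertex_mask] = pm[j]
                t_full = np.zeros(grid_shape)
                t_full[vertex_mask] = tm[j]
                _, ext = form_clusters(p_full, t_full, alpha_form, connectivity)
                null_max[start + j] = int(ext.max()) if len(ext) else 0

    if exhaustive:
        p_clus = np.array(
            [np.mean(null_max >= e) for e in extents], dtype=float
        )
    else:
        p_clus = np.array(
            [(1.0 + np.sum(null_max >= e)) / (1.0 + n_used) for e in extents],
            dtype=float,
        )
    return ClusterStatsResult(
        t=t_obs,
        p_uncorr=p_obs,
        d=d_obs,
        cluster_labels=labels,
        cluster_extents=extents,
        p_clus=p_clus,
        null_max_extents=null_max,
        alpha_form=alpha_form,
        n_perm=n_used,
        seed=seed,
        exhaustive=exhaustive,
        vertex_mask=vertex_mask,
    )


def render_effect_map(
    result: ClusterStatsResult,
    path=None,
    title: str = "",
    d_lim: float | None = None,
):
    """Render the vertex-wise effect-size map with inference overlays.

    One marker per (line, depth) vertex: colour and size encode Cohen's
    d, gray rings mark vertices below the cluster-forming threshold
    (p_uncorr < alpha_form), and vertices inside significant clusters
    (p_clus < 0.05) are outlined in black.  Returns the matplotlib
    figure; saves it when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nl, nd = result.d.shape
    lines, depths = np.meshgrid(np.arange(nl), np.arange(nd), indexing="ij")
    d = np.nan_to_num(result.d)
    if d_lim is None:
        d_lim = max(float(np.abs(d).max()), 1e-6)
    size = 10.0 + 60.0 * np.abs(d) / d_lim

    fig, ax = plt.subplots(figsize=(10, 3))
    with np.errstate(invalid="ignore"):
        supra = np.isfinite(result.p_uncorr) & (
            result.p_uncorr < result.alpha_form
        )
    ax.scatter(
        lines[supra], depths[supra], s=size[supra] + 70,
        facecolors="none", edgecolors="0.6", linewidths=1.2, zorder=1,
    )
    sig = result.significant_clusters(0.05)
    ax.scatter(
        lines[sig], depths[sig], s=size[sig] + 110,
        facecolors="none", edgecolors="black", linewidths=1.5, zorder=2,
    )
    sc = ax.scatter(
        lines.ravel(), depths.ravel(), c=d.ravel(), s=size.ravel(),
        cmap="RdBu_r", vmin=-d_lim, vmax=d_lim, zorder=3,
    )
    fig.colorbar(sc, ax=ax, label="Cohen's d")
    ax.set_xlabel("grid-line (medial - lateral)")
    ax.set_ylabel("depth (pial - WM)")
    ax.invert_yaxis()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
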