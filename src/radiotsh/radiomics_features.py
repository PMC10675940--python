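"""The 572-feature radiomic vector: first-order, shape and texture families.

Per region (tumor, peritumoral stroma) and phase map (S0, S_I, S_L) the
engine computes 18 first-order statistics and 75 texture features from
five matrix families -- GLCM (24), GLRLM (16), GLSZM (16), GLDM (14) and
NGTDM (5) -- for 93 features per region-phase.  Fourteen morphological
features are computed once from the tumor mask.  6 x 93 + 14 = 572.

Conventions (fixed so feature vectors are comparable across studies):
equal-width discretization into 32 gray levels per ROI; co-occurrence and
run-length matrices are built for the 13 unique 3D directions at distance
1, symmetrized (GLCM) and averaged over directions; percentiles use
linear interpolation; GLDM dependence size is 1 + the number of 26-
neighbors within ``alpha`` gray levels (the center voxel counts as
self-dependent, keeping emphasis denominators finite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial.distance import pdist
from skimage import measure

# one of each +/- pair of the 26 3D neighbor offsets
ANGLES_13 = [
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
]

FIRST_ORDER_FEATURES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)

SHAPE_FEATURES = (
    "mesh_volume",
    "voxel_volume",
    "surface_area",
    "surface_volume_ratio",
    "sphericity",
    "maximum_3d_diameter",
    "maximum_2d_diameter_slice",
    "maximum_2d_diameter_column",
    "maximum_2d_diameter_row",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
)

GLCM_FEATURES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_squares",
    "mcc",
)

GLRLM_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_variance",
    "run_entropy",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

GLSZM_FEATURES = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "size_zone_non_uniformity",
    "size_zone_non_uniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)

GLDM_FEATURES = (
    "small_dependence_emphasis",
    "large_dependence_emphasis",
    "gray_level_non_uniformity",
    "dependence_non_uniformity",
    "dependence_non_uniformity_normalized",
    "gray_level_variance",
    "dependence_variance",
    "dependence_entropy",
    "low_gray_level_emphasis",
    "high_gray_level_emphasis",
    "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

TEXTURE_FAMILIES = {
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

PHASES = ("S0", "SI", "SL")
REGIONS = ("tumor", "stroma")

_EPS = np.spacing(1.0)


@dataclass
class DiscretizedROI:
    """Masked volume mapped to integer gray levels 1..n_levels (0 = outside)."""

    levels: np.ndarray  # int array, full grid, 0 outside the mask
    mask: np.ndarray
    n_levels: int
    spacing: tuple[float, float, float]
    degenerate: bool = False  # constant intensity ROI


def discretize(
    volume: np.ndarray, mask: np.ndarray, n_bins: int = 32, spacing=(1.0, 1.0, 1.0)
) -> DiscretizedROI:
    """Equal-width binning of in-mask intensities into ``n_bins`` gray levels."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if n_bins < 2:
        raise ValueError("need at least 2 gray levels")
    x = np.asarray(volume, dtype=float)[mask]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn(
            "constant-intensity ROI: texture features take their degenerate limits",
            stacklevel=2,
        )
        levels[mask] = 1
        return DiscretizedROI(levels, mask, 1, tuple(spacing), degenerate=True)
    binned = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    binned[binned > n_bins] = n_bins  # the maximum lands in the top bin
    levels[mask] = binned
    return DiscretizedROI(levels, mask, n_bins, tuple(spacing))


# ---------------------------------------------------------------------------
# first order


def first_order(
    volume: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0), n_bins: int = 32
) -> dict[str, float]:
    """The 18 first-order intensity statistics of an ROI.

    Entropy and uniformity are computed on the ``n_bins``-level equal-width
    histogram; percentiles use linear interpolation.
    """
    mask = mask.astype(bool)
    x = np.asarray(volume, dtype=float)[mask]
    if x.size == 0:
        raise ValueError("empty ROI mask")
    voxel_volume = float(np.prod(spacing))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mean = float(x.mean())
    inner = x[(x >= p10) & (x <= p90)]
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins)
        p = hist / hist.sum()
        p = p[p > 0]
    else:
        p = np.array([1.0])
    return {
        "energy": float((x**2).sum()),
        "total_energy": float(voxel_volume * (x**2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "minimum": float(x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": float(x.max()),
        "mean": mean,
        "median": float(p50),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": float(
            np.abs(inner - inner.mean()).mean() if inner.size else 0.0
        ),
        "root_mean_squared": float(np.sqrt((x**2).mean())),
        "skewness": float(stats.skew(x)) if x.std() > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(x, fisher=False)) if x.std() > 0 else 0.0,
        "variance": float(x.var()),
        "uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# shape


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            from scipy.spatial import ConvexHull

            points = points[ConvexHull(points, qhull_options="QJ").vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    return float(pdist(points).max())


def shape_3d(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """The 14 morphological features of a binary tumor mask.

    Volume and surface area come from a marching-cubes mesh of the mask;
    axis lengths are 4*sqrt of the eigenvalues of the physical-coordinate
    covariance matrix (the principal axes of the best-fit ellipsoid).
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty tumor mask")
    spacing = tuple(float(s) for s in spacing)
    # mesh a lightly smoothed mask: marching cubes on the raw binary mask
    # overestimates the surface of smooth objects by ~8% (staircase bias)
    padded = np.pad(mask.astype(float), 2)
    smooth = ndimage.gaussian_filter(padded, sigma=1.0)
    if smooth.max() <= 0.5:  # thin structure erased by smoothing
        smooth = padded
    verts, faces, _, _ = measure.marching_cubes(smooth, level=0.5, spacing=spacing)
    verts -= 2.0 * np.asarray(spacing)  # undo the pad offset
    surface_area = float(measure.mesh_surface_area(verts, faces))
    # signed tetrahedron volumes against the origin
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    mesh_volume = float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)

    n_vox = int(mask.sum())
    voxel_volume = n_vox * float(np.prod(spacing))
    coords = np.column_stack(np.nonzero(mask)).astype(float) * np.asarray(spacing)
    eig = np.zeros(3)
    if n_vox > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    axes = 4.0 * np.sqrt(eig)

    sphericity = (np.pi ** (1 / 3)) * (6.0 * mesh_volume) ** (2 / 3) / surface_area

    # maximum diameters in 3D and per orthogonal plane, from surface voxels
    eroded = ndimage.binary_erosion(mask)
    surf = mask & ~eroded
    spts = np.column_stack(np.nonzero(surf)).astype(float) * np.asarray(spacing)
    max3d = _max_pairwise(spts)

    def plane_max(axis: int) -> float:
        keep = [i for i in range(3) if i != axis]
        best = 0.0
        vox = np.column_stack(np.nonzero(surf))
        for idx in np.unique(vox[:, axis]):
            pts = vox[vox[:, axis] == idx][:, keep].astype(float)
            pts *= np.asarray([spacing[i] for i in keep])
            best = max(best, _max_pairwise(pts))
        return best

    return {
        "mesh_volume": mesh_volume,
        "voxel_volume": voxel_volume,
        "surface_area": surface_area,
        "surface_volume_ratio": surface_area / mesh_volume if mesh_volume else 0.0,
        "sphericity": float(sphericity),
        "maximum_3d_diameter": max3d,
        "maximum_2d_diameter_slice": plane_max(2),  # in-plane (x, y)
        "maximum_2d_diameter_column": plane_max(1),  # (x, z)
        "maximum_2d_diameter_row": plane_max(0),  # (y, z)
        "major_axis_length": float(axes[0]),
        "minor_axis_length": float(axes[1]),
        "least_axis_length": float(axes[2]),
        "elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0,
        "flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0,
    }


# ---------------------------------------------------------------------------
# texture matrices


def _shifted_pairs(levels: np.ndarray, offset):
    """In-mask (level, neighbor level) pairs for one offset; 0 marks outside."""
    sl_a, sl_b = [], []
    for o in offset:
        if o >= 0:
            sl_a.append(slice(0, levels.shape[len(sl_a)] - o))
            sl_b.append(slice(o, levels.shape[len(sl_b)]))
        else:
            sl_a.append(slice(-o, levels.shape[len(sl_a)]))
            sl_b.append(slice(0, levels.shape[len(sl_b)] + o))
    a = levels[tuple(sl_a)].ravel()
    b = levels[tuple(sl_b)].ravel()
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


def glcm_matrix(droi: DiscretizedROI, distance: int = 1) -> np.ndarray:
    """Direction-averaged symmetric co-occurrence probability matrix."""
    ng = droi.n_levels
    acc = np.zeros((ng, ng))
    n_dir = 0
    for base in ANGLES_13:
        offset = tuple(distance * o for o in base)
        a, b = _shifted_pairs(droi.levels, offset)
        if a.size == 0:
            continue
        counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
        counts = counts + counts.T  # symmetric GLCM
        acc += counts / counts.sum()
        n_dir += 1
    if n_dir == 0:
        acc[0, 0] = 1.0
        return acc
    return acc / n_dir


def glcm_features(droi: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """The 24 gray-level co-occurrence features."""
    p = glcm_matrix(droi, distance)
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log2(outer[nz])).sum())
    nz2 = outer > 0
    hxy2 = float(-(outer[nz2] * np.log2(outer[nz2])).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    if sig_x * sig_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 1.0

    # maximal correlation coefficient via the Q matrix
    mcc = 1.0
    if ng > 1 and (px > 0).sum() > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p[:, None, :] * p[None, :, :]) / (
                px[:, None, None] * py[None, None, :]
            )
        q = np.nan_to_num(q, nan=0.0, posinf=0.0).sum(axis=2)
        eig = np.sort(np.abs(np.linalg.eigvals(q)))
        if eig.size >= 2:
            mcc = float(np.sqrt(max(eig[-2], 0.0)))

    da = float((k_diff * p_diff).sum())
    off = ii != jj
    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "joint_average": mu_x,
        "cluster_prominence": float((((ii + jj) - mu_x - mu_y) ** 4 * p).sum()),
        "cluster_shade": float((((ii + jj) - mu_x - mu_y) ** 3 * p).sum()),
        "cluster_tendency": float((((ii + jj) - mu_x - mu_y) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_variance": float((p[off] / (ii - jj)[off] ** 2).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": ent(p_sum),
        "sum_squares": float(((ii - mu_x) ** 2 * p).sum()),
        "mcc": mcc,
    }


def glrlm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Run-length count matrix P(level, run length), averaged over 13 directions."""
    levels = droi.levels
    ng = droi.n_levels
    max_run = max(levels.shape)
    acc = np.zeros((ng, max_run))
    for offset in ANGLES_13:
        # run starts: in-mask voxels whose predecessor along -offset differs
        prev = np.zeros_like(levels)
        core, shifted = _shifted_slices(levels.shape, offset)
        prev[shifted] = levels[core]
        starts = (levels > 0) & (prev != levels)
        pos = np.column_stack(np.nonzero(starts))
        lev = levels[starts]
        run_len = np.ones(len(pos), dtype=np.int64)
        cur = pos.copy()
        active = np.ones(len(pos), dtype=bool)
        off = np.asarray(offset)
        while active.any():
            cur[active] += off
            inb = active.copy()
            inb[active] = np.all(
                (cur[active] >= 0) & (cur[active] < levels.shape), axis=1
            )
            same = inb.copy()
            if inb.any():
                vals = levels[tuple(cur[inb].T)]
                same[inb] = vals == lev[inb]
            run_len[same] += 1
            active = same
        mat = np.zeros((ng, max_run))
        np.add.at(mat, (lev - 1, np.minimum(run_len, max_run) - 1), 1.0)
        acc += mat
    return acc / len(ANGLES_13)


def _shifted_slices(shape, offset):
    """Slices (core, shifted) so that shifted[i] = core[i] + offset elementwise."""
    core, dest = [], []
    for dim, o in zip(shape, offset):
        if o >= 0:
            core.append(slice(0, dim - o))
            dest.append(slice(o, dim))
        else:
            core.append(slice(-o, dim))
            dest.append(slice(0, dim + o))
    return tuple(core), tuple(dest)


def _run_zone_features(mat: np.ndarray, n_vox: int, kind: str) -> dict[str, float]:
    """Shared formula set of the run-length (kind='run') and size-zone
    (kind='area'/'zone') families."""
    ng, nr = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    r = np.arange(1, nr + 1, dtype=float)[None, :]
    total = mat.sum()
    if total == 0:
        raise ValueError("empty run/zone matrix")
    pg = mat.sum(axis=1)
    pr = mat.sum(axis=0)
    p = mat / total
    mu_i = (i * p).sum()
    mu_r = (r * p).sum()
    pn = p[p > 0]
    size = "area" if kind == "area" else "run"  # small_area vs short_run naming
    short = "small" if kind == "area" else "short"
    long_ = "large" if kind == "area" else "long"
    rn = {"run": "run_length", "area": "size_zone"}[kind]
    rv = {"run": "run", "area": "zone"}[kind]
    feats = {
        f"{short}_{size}_emphasis": (mat / r**2).sum() / total,
        f"{long_}_{size}_emphasis": (mat * r**2).sum() / total,
        "gray_level_non_uniformity": (pg**2).sum() / total,
        "gray_level_non_uniformity_normalized": (pg**2).sum() / total**2,
        f"{rn}_non_uniformity": (pr**2).sum() / total,
        f"{rn}_non_uniformity_normalized": (pr**2).sum() / total**2,
        f"{rv}_percentage": total / n_vox,
        "gray_level_variance": ((i - mu_i) ** 2 * p).sum(),
        f"{rv}_variance": ((r - mu_r) ** 2 * p).sum(),
        f"{rv}_entropy": float(-(pn * np.log2(pn)).sum()),
        f"low_gray_level_{rv}_emphasis": (mat / i**2).sum() / total,
        f"high_gray_level_{rv}_emphasis": (mat * i**2).sum() / total,
        f"{short}_{size}_low_gray_level_emphasis": (mat / (i**2 * r**2)).sum() / total,
        f"{short}_{size}_high_gray_level_emphasis": (mat * i**2 / r**2).sum() / total,
        f"{long_}_{size}_low_gray_level_emphasis": (mat * r**2 / i**2).sum() / total,
        f"{long_}_{size}_high_gray_level_emphasis": (mat * i**2 * r**2).sum() / total,
    }
    return {k: float(v) for k, v in feats.items()}


def glrlm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 16 gray-level run-length features."""
    mat = glrlm_matrix(droi)
    n_vox = int(droi.mask.sum())
    raw = _run_zone_features(mat, n_vox, "run")
    return {name: raw[name] for name in GLRLM_FEATURES}


def glszm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Size-zone count matrix P(level, zone size), zones 26-connected."""
    levels = droi.levels
    ng = droi.n_levels
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = int(droi.mask.sum())
    counts: dict[tuple[int, int], int] = {}
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(levels == g, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[(g, int(s))] = counts.get((g, int(s)), 0) + 1
    mat = np.zeros((ng, max_size))
    for (g, s), c in counts.items():
        mat[g - 1, s - 1] = c
    return mat


def glszm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 16 gray-level size-zone features (small/large area emphasis etc.)."""
    mat = glszm_matrix(droi)
    n_vox = int(droi.mask.sum())
    raw = _run_zone_features(mat, n_vox, "area")
    return {name: raw[name] for name in GLSZM_FEATURES}


def gldm_matrix(droi: DiscretizedROI, alpha: int = 0, distance: int = 1) -> np.ndarray:
    """Dependence count matrix P(level, dependence size).

    Dependence size = 1 + number of 26-neighbors (at ``distance``) whose
    gray level differs from the center by at most ``alpha``.
    """
    levels = droi.levels
    ng = droi.n_levels
    dep = np.zeros(levels.shape, dtype=np.int64)
    for base in ANGLES_13:
        for sign in (1, -1):
            offset = tuple(sign * distance * o for o in base)
            core, dest = _shifted_slices(levels.shape, offset)
            neighbor = np.zeros_like(levels)
            neighbor[core] = levels[dest]
            ok = (levels > 0) & (neighbor > 0) & (np.abs(levels - neighbor) <= alpha)
            dep[ok] += 1
    dep_size = dep + 1  # the center voxel is self-dependent
    nd = 27
    mat = np.zeros((ng, nd))
    m = droi.mask
    np.add.at(mat, (levels[m] - 1, dep_size[m] - 1), 1.0)
    return mat


def gldm_features(droi: DiscretizedROI, alpha: int = 0, distance: int = 1) -> dict[str, float]:
    """The 14 gray-level dependence features."""
    mat = gldm_matrix(droi, alpha, distance)
    ng, nd = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nd + 1, dtype=float)[None, :]
    total = mat.sum()
    pg = mat.sum(axis=1)
    pd_ = mat.sum(axis=0)
    p = mat / total
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    pn = p[p > 0]
    return {
        "small_dependence_emphasis": float((mat / j**2).sum() / total),
        "large_dependence_emphasis": float((mat * j**2).sum() / total),
        "gray_level_non_uniformity": float((pg**2).sum() / total),
        "dependence_non_uniformity": float((pd_**2).sum() / total),
        "dependence_non_uniformity_normalized": float((pd_**2).sum() / total**2),
        "gray_level_variance": float(((i - mu_i) ** 2 * p).sum()),
        "dependence_variance": float(((j - mu_j) ** 2 * p).sum()),
        "dependence_entropy": float(-(pn * np.log2(pn)).sum()),
        "low_gray_level_emphasis": float((mat / i**2).sum() / total),
        "high_gray_level_emphasis": float((mat * i**2).sum() / total),
        "small_dependence_low_gray_level_emphasis": float(
            (mat / (i**2 * j**2)).sum() / total
        ),
        "small_dependence_high_gray_level_emphasis": float(
            (mat * i**2 / j**2).sum() / total
        ),
        "large_dependence_low_gray_level_emphasis": float(
            (mat * j**2 / i**2).sum() / total
        ),
        "large_dependence_high_gray_level_emphasis": float(
            (mat * i**2 * j**2).sum() / total
        ),
    }


def ngtdm_table(droi: DiscretizedROI):
    """Per-level (n_i, p_i, s_i) of the neighborhood gray-tone difference matrix."""
    levels = droi.levels
    ng = droi.n_levels
    nsum = np.zeros(levels.shape)
    ncnt = np.zeros(levels.shape)
    for base in ANGLES_13:
        for sign in (1, -1):
            offset = tuple(sign * o for o in base)
            core, dest = _shifted_slices(levels.shape, offset)
            neighbor = np.zeros_like(levels)
            neighbor[core] = levels[dest]
            ok = (levels > 0) & (neighbor > 0)
            nsum[ok] += neighbor[ok]
            ncnt[ok] += 1
    valid = droi.mask & (ncnt > 0)
    lev = droi.levels[valid]
    diff = np.abs(lev - nsum[valid] / ncnt[valid])
    n_i = np.bincount(lev - 1, minlength=ng).astype(float)
    s_i = np.zeros(ng)
    np.add.at(s_i, lev - 1, diff)
    nv = n_i.sum()
    p_i = n_i / nv if nv else n_i
    return n_i, p_i, s_i, int(nv)


def ngtdm_features(droi: DiscretizedROI) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    n_i, p_i, s_i, nv = ngtdm_table(droi)
    ng = len(n_i)
    i = np.arange(1, ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    denom = float((p_i * s_i).sum())
    coarseness = 1.0 / denom if denom > 0 else 1e6

    contrast = 0.0
    if ngp > 1 and nv > 0:
        diff2 = (i[:, None] - i[None, :]) ** 2
        pp = p_i[:, None] * p_i[None, :]
        contrast = float((pp * diff2).sum() * s_i.sum() / nv / (ngp * (ngp - 1)))

    busyness = 0.0
    if ngp > 1:
        ipi = i * p_i
        denom_b = np.abs(ipi[present][:, None] - ipi[present][None, :]).sum()
        if denom_b > 0:
            busyness = float((p_i * s_i).sum() / denom_b)

    complexity = 0.0
    strength = 0.0
    if nv > 0:
        ia, ib = np.meshgrid(i, i, indexing="ij")
        pa, pb = np.meshgrid(p_i, p_i, indexing="ij")
        sa, sb = np.meshgrid(s_i, s_i, indexing="ij")
        both = (pa > 0) & (pb > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = np.abs(ia - ib) * (pa * sa + pb * sb) / (pa + pb)
        complexity = float(comp[both].sum() / nv)
        s_total = float(s_i.sum())
        if s_total > 0:
            strength = float(((pa + pb) * (ia - ib) ** 2)[both].sum() / s_total)

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# orchestration


def feature_names() -> list[str]:
    """The full, stable 572-name schema (version 1)."""
    names = [f"tumor_shape_{f}" for f in SHAPE_FEATURES]
    for region in REGIONS:
        for phase in PHASES:
            names += [f"{region}_{phase}_firstorder_{f}" for f in FIRST_ORDER_FEATURES]
            for family, feats in TEXTURE_FAMILIES.items():
                names += [f"{region}_{phase}_{family}_{f}" for f in feats]
    return names


def region_phase_features(
    volume: np.ndarray, mask: np.ndarray, spacing, n_bins: int = 32
) -> dict[str, float]:
    """The 93 intensity/texture features of one (region, phase) ROI."""
    out = {f"firstorder_{k}": v for k, v in first_order(volume, mask, spacing, n_bins).items()}
    droi = discretize(volume, mask, n_bins, spacing)
    for family, fn in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("gldm", gldm_features),
        ("ngtdm", ngtdm_features),
    ):
        for k, v in fn(droi).items():
            out[f"{family}_{k}"] = v
    return out


def extract_all(
    phases,
    tumor_mask: np.ndarray,
    stroma_mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    n_bins: int = 32,
):
    """The complete 572-feature vector for one patient.

    (18 first-order + 75 texture) features per region {tumor, stroma} and
    phase {S0, S_I, S_L} = 558, plus 14 shape features of the tumor mask.
    Returns a pandas Series ordered per :func:`feature_names`.
    """
    import pandas as pd

    phase_maps = phases.as_dict() if hasattr(phases, "as_dict") else dict(phases)
    values: dict[str, float] = {}
    for k, v in shape_3d(tumor_mask, spacing).items():
        values[f"tumor_shape_{k}"] = v
    for region, mask in (("tumor", tumor_mask), ("stroma", stroma_mask)):
        for phase in PHASES:
            feats = region_phase_features(phase_maps[phase], mask, spacing, n_bins)
            for k, v in feats.items():
                values[f"{region}_{phase}_{k}"] = v
    out = pd.Series(values).reindex(feature_names())
    if out.isna().any():
        missing = list(out.index[out.isna()])
        raise RuntimeError(f"feature schema mismatch: {missing[:5]}")
    if not np.isfinite(out.to_numpy()).all():
        bad = list(out.index[~np.isfinite(out.to_numpy())])
        raise ValueError(f"non-finite features: {bad[:5]}")
    return out
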