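"""DCE-MRI preprocessing: resampling, normalization, phase maps, tumor
segmentation and the peritumoral stroma band.

A dynamic contrast-enhanced series is one precontrast volume S0 plus
three to six postcontrast volumes on a shared grid.  The derived phase
maps are S0 itself, S_I (intermediate postcontrast minus S0) and S_L
(last postcontrast minus S0).  Tumors are segmented with a spatially
regularized fuzzy c-means initialized at a seed point; the stroma is a
ring of fixed in-plane width (default 25 voxels = 20 mm at 0.8 mm)
dilated outward from the tumor boundary within the breast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

DEFAULT_SPACING = (0.8, 0.8, 2.0)  # mm; in-plane x, y then slice thickness


@dataclass
class VolumeSeries:
    """Precontrast volume plus k postcontrast volumes on one grid."""

    s0: np.ndarray
    postcontrast: list[np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        k = len(self.postcontrast)
        if not 3 <= k <= 6:
            raise ValueError(f"need 3-6 postcontrast volumes, got {k}")
        for vol in self.postcontrast:
            if vol.shape != self.s0.shape:
                raise ValueError("all volumes must share the precontrast grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_postcontrast(self) -> int:
        return len(self.postcontrast)


@dataclass
class PhaseSet:
    """The three phase maps features are computed on."""

    s0: np.ndarray
    s_i: np.ndarray
    s_l: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"S0": self.s0, "SI": self.s_i, "SL": self.s_l}


def check_masks(tumor: np.ndarray, stroma: np.ndarray, breast: np.ndarray) -> None:
    """Assert the region-containment invariants: tumor and stroma are disjoint
    subsets of the breast."""
    if np.any(tumor & stroma):
        raise ValueError("tumor and stroma masks overlap")
    if np.any(tumor & ~breast):
        raise ValueError("tumor mask extends outside the breast")
    if np.any(stroma & ~breast):
        raise ValueError("stroma mask extends outside the breast")


def _zoom_factors(spacing, target_spacing):
    return tuple(s / t for s, t in zip(spacing, target_spacing))


def resample_volume(
    volume: np.ndarray,
    spacing,
    target_spacing=DEFAULT_SPACING,
    *,
    is_mask: bool = False,
) -> np.ndarray:
    """Resample one volume to ``target_spacing`` (trilinear; nearest for masks)."""
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be positive")
    factors = _zoom_factors(spacing, target_spacing)
    if np.allclose(factors, 1.0):
        return volume.copy()
    order = 0 if is_mask else 1
    out = ndimage.zoom(
        np.asarray(volume, dtype=float), factors, order=order, mode="nearest", grid_mode=True
    )
    return out.astype(bool) if is_mask else out


def resample_series(
    series: VolumeSeries,
    masks: dict[str, np.ndarray] | None = None,
    target_spacing=DEFAULT_SPACING,
) -> tuple[VolumeSeries, dict[str, np.ndarray]]:
    """Resample a whole series (and any masks) onto the target grid."""
    s0 = resample_volume(series.s0, series.spacing, target_spacing)
    posts = [resample_volume(v, series.spacing, target_spacing) for v in series.postcontrast]
    out_masks = {}
    for name, mask in (masks or {}).items():
        out_masks[name] = resample_volume(
            mask.astype(np.uint8), series.spacing, target_spacing, is_mask=True
        )
    return VolumeSeries(s0, posts, tuple(target_spacing)), out_masks


def normalize(volume: np.ndarray, parenchyma_mask: np.ndarray) -> np.ndarray:
    """Divide intensities by the mean over the parenchymal region."""
    if not parenchyma_mask.any():
        raise ValueError("empty parenchyma mask")
    mean = float(volume[parenchyma_mask.astype(bool)].mean())
    if mean <= 0:
        raise ValueError(f"parenchyma mean must be positive, got {mean}")
    return volume / mean


def parenchyma_mask(
    breast_mask: np.ndarray, tumor_mask: np.ndarray, stroma_mask: np.ndarray | None = None
) -> np.ndarray:
    """Default parenchyma: breast minus tumor (minus the stroma band if given)."""
    par = breast_mask.astype(bool) & ~tumor_mask.astype(bool)
    if stroma_mask is not None:
        par &= ~stroma_mask.astype(bool)
    return par


def intermediate_index(k: int) -> int:
    """1-based index of the intermediate postcontrast volume among k."""
    return int(np.ceil(k / 2))


def derive_phases(series: VolumeSeries) -> PhaseSet:
    """S0, S_I = intermediate - S0, S_L = last - S0."""
    k = series.n_postcontrast
    mid = intermediate_index(k)
    s_i = series.postcontrast[mid - 1] - series.s0
    s_l = series.postcontrast[k - 1] - series.s0
    return PhaseSet(series.s0.copy(), s_i, s_l)


# ---------------------------------------------------------------------------
# spatial fuzzy c-means segmentation


@dataclass
class SFCMResult:
    mask: np.ndarray
    membership: np.ndarray  # membership of the tumor class, full grid
    centers: np.ndarray
    n_iter: int
    converged: bool
    objective: list[float] = field(default_factory=list)


def _neighborhood_mean(memberships: np.ndarray, mask_idx, shape) -> np.ndarray:
    """Average each class membership over the 3x3 in-plane neighborhood."""
    c = memberships.shape[0]
    out = np.empty_like(memberships)
    grid = np.zeros(shape)
    for j in range(c):
        grid[:] = 0.0
        grid[mask_idx] = memberships[j]
        sm = ndimage.uniform_filter(grid, size=(3, 3, 1), mode="constant")
        out[j] = sm[mask_idx]
    return out


def segment_tumor_sfcm(
    volume: np.ndarray,
    seed_point,
    breast_mask: np.ndarray,
    *,
    n_classes: int = 2,
    fuzzifier: float = 2.0,
    spatial_weight: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> SFCMResult:
    """Segment the tumor with spatially regularized fuzzy c-means.

    Voxels inside the breast mask are clustered on intensity into
    ``n_classes`` classes.  After every standard FCM membership update the
    memberships are multiplied by their 3x3 in-plane neighborhood average
    raised to ``spatial_weight`` and renormalized, which suppresses
    isolated noise voxels.  The tumor class is the class the seed voxel
    belongs to; the returned mask is the connected component of the
    thresholded (>0.5) tumor membership that contains the seed.
    """
    breast_mask = breast_mask.astype(bool)
    seed_point = tuple(int(i) for i in seed_point)
    if not breast_mask[seed_point]:
        raise ValueError(f"seed point {seed_point} lies outside the breast mask")
    mask_idx = np.nonzero(breast_mask)
    x = np.asarray(volume, dtype=float)[mask_idx]
    n = x.size
    rankpos = np.linspace(0.1, 0.9, n_classes)
    centers = np.quantile(x, rankpos)
    # nudge the class nearest to the seed intensity onto it for a warm start
    seed_val = float(volume[seed_point])
    centers[np.argmin(np.abs(centers - seed_val))] = seed_val
    centers = np.sort(centers)

    m = fuzzifier
    u = None
    objective: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = (x[None, :] - centers[:, None]) ** 2 + 1e-12
        u = d2 ** (-1.0 / (m - 1.0))
        u /= u.sum(axis=0, keepdims=True)
        if spatial_weight > 0:
            h = _neighborhood_mean(u, mask_idx, volume.shape)
            u = u * h**spatial_weight
            u /= u.sum(axis=0, keepdims=True) + 1e-30
        um = u**m
        new_centers = (um @ x) / um.sum(axis=1)
        objective.append(float((um * d2).sum()))
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"spatial FCM did not converge in {max_iter} iterations; "
            "returning the final iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    # tumor class = the class with the highest membership at the seed voxel
    lin = np.ravel_multi_index(mask_idx, volume.shape)
    seed_lin = np.ravel_multi_index(seed_point, volume.shape)
    seed_flat_idx = int(np.searchsorted(lin, seed_lin))
    tumor_class = int(np.argmax(u[:, seed_flat_idx]))
    membership = np.zeros(volume.shape)
    membership[mask_idx] = u[tumor_class]

    thresholded = membership > 0.5
    labels, _ = ndimage.label(thresholded)
    seed_label = labels[seed_point]
    if seed_label == 0:
        warnings.warn(
            "seed voxel fell below the 0.5 membership threshold; "
            "using the largest tumor-class component",
            RuntimeWarning,
            stacklevel=2,
        )
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        seed_label = int(sizes.argmax()) if sizes.any() else 0
    tumor = labels == seed_label if seed_label else np.zeros_like(thresholded)
    return SFCMResult(tumor, membership, centers, n_iter, converged, objective)


def stroma_band(
    tumor_mask: np.ndarray, breast_mask: np.ndarray, width_px: int = 25
) -> np.ndarray:
    """Peritumoral stroma ring: per-slice dilation of the tumor by a disk of
    radius ``width_px`` in-plane voxels, minus the tumor, within the breast.

    At the default 0.8 mm in-plane resolution the default 25 px equal a
    20 mm band.
    """
    tumor_mask = tumor_mask.astype(bool)
    breast_mask = breast_mask.astype(bool)
    if not tumor_mask.any():
        raise ValueError("empty tumor mask")
    if width_px < 1:
        raise ValueError("band width must be at least 1 voxel")
    selem = disk(width_px)
    dilated = np.zeros_like(tumor_mask)
    for z in range(tumor_mask.shape[2]):
        sl = tumor_mask[:, :, z]
        if sl.any():
            dilated[:, :, z] = ndimage.binary_dilation(sl, structure=selem)
    band = dilated & ~tumor_mask & breast_mask
    return band
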