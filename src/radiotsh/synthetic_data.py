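"""Ground-truth simulators for every pipeline input.

Three generators cover the three data layers:

* marker-structured bulk expression cohorts with planted per-region cell
  abundances and a shared latent factor that controls how correlated the
  ten cell populations are within a survival group;
* multi-phase DCE-MRI tumor phantoms with known breast/tumor masks,
  per-tissue enhancement curves and a multiplicative Gaussian-random-field
  texture;
* exponential survival tables whose hazard depends on the planted
  good/poor group.

Every generator is deterministic given its seed and returns the planted
truth alongside the simulated data.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from radiotsh.image_prep import VolumeSeries

#: The ten cell populations scored from bulk expression: eight immune
#: lineages plus two stromal populations.
CELL_TYPES = (
    "T cells",
    "CD8 T cells",
    "Cytotoxic lymphocytes",
    "NK cells",
    "B lineage",
    "Monocytic lineage",
    "Myeloid dendritic cells",
    "Neutrophils",
    "Endothelial cells",
    "Fibroblasts",
)

REGIONS = ("tumor", "stroma")
GROUPS = ("good", "poor")


def generate_markers(n_per_type: int = 10, seed: int = 0) -> dict[str, list[str]]:
    """Create ten pairwise-disjoint synthetic marker gene sets.

    Gene identifiers look like gene symbols (random uppercase stems with a
    numeric suffix) and are unique across cell types.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(string.ascii_uppercase))
    seen: set[str] = set()
    markers: dict[str, list[str]] = {}
    for ct in CELL_TYPES:
        genes = []
        while len(genes) < n_per_type:
            stem = "".join(rng.choice(letters, size=4))
            name = f"{stem}{rng.integers(1, 20)}"
            if name not in seen:
                seen.add(name)
                genes.append(name)
        markers[ct] = genes
    return markers


def default_planted_abundance() -> dict[tuple[str, str, str], float]:
    """Planted mean log2 abundance per (cell type, region, group).

    Emulates the qualitative pattern seen in paired tumor/stroma cohorts:
    in the good-survival group every population is more abundant in the
    tumor than in the stroma (relative difference +0.5), while in the
    poor-survival group the tumor is depleted relative to the stroma
    (relative difference -0.4).
    """
    base = np.linspace(3.0, 6.0, len(CELL_TYPES))
    planted = {}
    for b, ct in zip(base, CELL_TYPES):
        planted[(ct, "tumor", "good")] = 1.5 * b
        planted[(ct, "stroma", "good")] = b
        planted[(ct, "tumor", "poor")] = 0.6 * b
        planted[(ct, "stroma", "poor")] = b
    return planted


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a simulated paired tumor/stroma cohort."""

    n_patients: int = 200
    n_genes: int = 1000
    planted_abundance: dict[tuple[str, str, str], float] = field(
        default_factory=default_planted_abundance
    )
    noise_sd: float = 0.3  # per-gene log2 noise
    latent_sd_good: float = 0.5  # patient latent factor: inter-cell-type correlation
    latent_sd_poor: float = 0.05
    good_fraction: float = 0.5
    background_mean: float = 3.0  # log2 mean of non-marker genes
    background_sd: float = 1.0
    hazard_ratio: float = 3.0  # poor-vs-good hazard multiplier
    baseline_hazard: float = 0.15  # events / year in the good group
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Simulated cohort plus its planted truth."""

    tumor_expr: pd.DataFrame  # genes x samples, linear scale
    stroma_expr: pd.DataFrame
    truth: dict[str, pd.DataFrame]  # region -> samples x cell types (log2 scale)
    groups: pd.Series  # sample -> good|poor
    markers: dict[str, list[str]]
    config: SyntheticCohortConfig


def generate_expression_cohort(
    config: SyntheticCohortConfig, markers: dict[str, list[str]]
) -> SyntheticCohort:
    """Simulate paired tumor/stroma bulk expression with planted abundances.

    Marker genes of cell type ``c`` in region ``r`` are drawn so that the
    per-patient mean log2 expression equals the planted abundance for the
    patient's group, shifted by a patient-level latent factor (shared by
    all cell types, inducing inter-type correlation) plus independent
    N(0, noise_sd) gene-level noise.  Non-marker genes are group-independent
    log-normal background.  The linear-scale matrices satisfy
    ``log2(x + 1) = planted log2 value``, so noise-free cohorts round-trip
    exactly through abundance estimation.
    """
    all_markers = [g for genes in markers.values() for g in genes]
    if len(set(all_markers)) != len(all_markers):
        raise ValueError("marker sets must be pairwise disjoint")
    if set(markers) != set(CELL_TYPES):
        raise ValueError("markers must cover exactly the ten cell types")
    if config.n_genes < len(all_markers):
        raise ValueError(
            f"n_genes={config.n_genes} is smaller than the {len(all_markers)} markers"
        )

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    samples = [f"P{i + 1:04d}" for i in range(n)]
    n_good = int(round(config.good_fraction * n))
    group_arr = np.array(["good"] * n_good + ["poor"] * (n - n_good))
    rng.shuffle(group_arr)
    groups = pd.Series(group_arr, index=samples, name="group")

    latent_sd = np.where(group_arr == "good", config.latent_sd_good, config.latent_sd_poor)
    latent = rng.normal(0.0, 1.0, size=n) * latent_sd

    n_bg = config.n_genes - len(all_markers)
    bg_genes = [f"BG{i + 1:05d}" for i in range(n_bg)]
    gene_index = all_markers + bg_genes

    truth: dict[str, pd.DataFrame] = {}
    exprs: dict[str, pd.DataFrame] = {}
    for region in REGIONS:
        log2 = np.empty((len(gene_index), n))
        truth_region = np.empty((n, len(CELL_TYPES)))
        row = 0
        for ci, ct in enumerate(CELL_TYPES):
            planted = np.array(
                [config.planted_abundance[(ct, region, g)] for g in group_arr]
            )
            per_patient = planted + latent
            truth_region[:, ci] = per_patient
            k = len(markers[ct])
            noise = rng.normal(0.0, config.noise_sd, size=(k, n)) if config.noise_sd else 0.0
            log2[row : row + k] = per_patient[None, :] + noise
            row += k
        if n_bg:
            log2[row:] = rng.normal(
                config.background_mean, config.background_sd, size=(n_bg, n)
            )
        linear = np.maximum(np.exp2(log2) - 1.0, 0.0)
        exprs[region] = pd.DataFrame(linear, index=gene_index, columns=samples)
        truth[region] = pd.DataFrame(truth_region, index=samples, columns=list(CELL_TYPES))

    return SyntheticCohort(
        tumor_expr=exprs["tumor"],
        stroma_expr=exprs["stroma"],
        truth=truth,
        groups=groups,
        markers=markers,
        config=config,
    )


# ---------------------------------------------------------------------------
# imaging phantoms


def default_enhancement(n_postcontrast: int) -> dict[str, np.ndarray]:
    """Per-tissue enhancement multipliers for S0 plus each postcontrast volume.

    The tumor enhances strongly (peaking at 2x precontrast around the
    intermediate phase, then a mild washout); parenchyma enhances slowly and
    weakly, emulating typical breast DCE kinetics.
    """
    t = np.arange(n_postcontrast + 1, dtype=float)  # 0 = precontrast
    tumor = 1.0 + 1.0 * (1 - np.exp(-1.8 * t)) * np.exp(-0.05 * t)
    parenchyma = 1.0 + 0.25 * t / max(n_postcontrast, 1)
    tumor[0] = parenchyma[0] = 1.0
    return {"tumor": tumor, "parenchyma": parenchyma}


@dataclass
class PhantomConfig:
    """Geometry, kinetics and texture of a simulated DCE-MRI exam."""

    shape: tuple[int, int, int] = (96, 96, 16)
    spacing: tuple[float, float, float] = (0.8, 0.8, 2.0)  # mm
    tumor_center_mm: tuple[float, float, float] | None = None  # defaults to grid center
    tumor_radii_mm: tuple[float, float, float] = (8.0, 8.0, 6.0)
    breast_margin_vox: int = 2  # shrink of the breast ellipsoid from the grid edge
    n_postcontrast: int = 3
    enhancement: dict[str, np.ndarray] | None = None  # tissue -> multipliers, len k+1
    texture_sigma_mm: float = 2.0
    texture_amplitude: float = 0.05  # parenchyma texture (fraction of base intensity)
    tumor_texture_amplitude: float | None = None  # defaults to texture_amplitude
    noise_sd: float = 0.04  # time-constant voxel noise, fraction of base intensity
    base_intensity: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.n_postcontrast <= 6:
            raise ValueError("n_postcontrast must be within [3, 6]")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class Phantom:
    series: VolumeSeries
    breast_mask: np.ndarray
    tumor_mask: np.ndarray
    seed_point: tuple[int, int, int]
    config: PhantomConfig


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    coords = np.meshgrid(
        *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum(((c - c0) / r) ** 2 for c, c0, r in zip(coords, center_mm, radii_mm))
    return d2 <= 1.0


def _texture_field(shape, spacing, sigma_mm, rng) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    white = rng.normal(size=shape)
    sigma_vox = [sigma_mm / sp for sp in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Simulate a DCE-MRI exam of an ellipsoidal tumor in an ellipsoidal breast.

    Voxel intensity of tissue ``T`` at timepoint ``t`` is
    ``base * (1 + amplitude_T * texture_T) * curve_T[t]`` plus a
    time-constant noise term scaled by the same curve, so a flat
    enhancement curve yields identical volumes at every timepoint.
    """
    rng = np.random.default_rng(config.seed)
    shape, spacing = config.shape, config.spacing
    extent_mm = [s * sp for s, sp in zip(shape, spacing)]
    breast_radii = [
        (s / 2 - config.breast_margin_vox) * sp for s, sp in zip(shape, spacing)
    ]
    grid_center = [e / 2 for e in extent_mm]
    breast = _ellipsoid_mask(shape, spacing, grid_center, breast_radii)

    center_mm = (
        tuple(config.tumor_center_mm) if config.tumor_center_mm is not None else grid_center
    )
    tumor = _ellipsoid_mask(shape, spacing, center_mm, config.tumor_radii_mm)
    if np.any(tumor & ~breast):
        raise ValueError("tumor does not fit inside the breast mask")

    curves = (
        config.enhancement
        if config.enhancement is not None
        else default_enhancement(config.n_postcontrast)
    )
    for name, curve in curves.items():
        if len(curve) != config.n_postcontrast + 1:
            raise ValueError(f"enhancement curve {name!r} must have k+1 points")

    amp_tum = (
        config.tumor_texture_amplitude
        if config.tumor_texture_amplitude is not None
        else config.texture_amplitude
    )
    tex_par = _texture_field(shape, spacing, config.texture_sigma_mm, rng)
    tex_tum = _texture_field(shape, spacing, config.texture_sigma_mm, rng)
    noise = rng.normal(0.0, config.noise_sd, size=shape)

    base = config.base_intensity
    par_signal = base * (1.0 + config.texture_amplitude * tex_par) + base * noise
    tum_signal = base * (1.0 + amp_tum * tex_tum) + base * noise

    volumes = []
    for t in range(config.n_postcontrast + 1):
        vol = np.zeros(shape)
        par = breast & ~tumor
        vol[par] = par_signal[par] * float(np.asarray(curves["parenchyma"])[t])
        vol[tumor] = tum_signal[tumor] * float(np.asarray(curves["tumor"])[t])
        volumes.append(vol)

    seed_point = tuple(
        int(round(c / sp)) for c, sp in zip(center_mm, spacing)
    )
    series = VolumeSeries(volumes[0], volumes[1:], tuple(spacing))
    return Phantom(series, breast, tumor, seed_point, config)


# ---------------------------------------------------------------------------
# survival tables


def generate_survival(groups: pd.Series, config: SyntheticCohortConfig) -> pd.DataFrame:
    """Exponential survival times whose hazard depends on the planted group.

    The good group has rate ``baseline_hazard`` (events/year); the poor
    group's rate is multiplied by ``hazard_ratio``.  Censoring times are
    independent exponentials whose rate is scaled so that the expected
    censored fraction equals ``censor_rate`` (conditionally on group, so
    censoring is non-informative given the covariate).  Clinical
    covariates (age, ER/PR/HER2, tumor size) are simulated independently
    of survival and exist so that adjusted Cox models are exercised with a
    realistic design matrix.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(groups)
    is_poor = (groups == "poor").to_numpy()
    rate = config.baseline_hazard * np.where(is_poor, config.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        censor_rate = rate * config.censor_rate / (1.0 - config.censor_rate)
        censor_time = rng.exponential(1.0 / censor_rate)
    else:
        censor_time = np.full(n, np.inf)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(np.minimum(event_time, censor_time), 1e-6)

    receptors = ["positive", "negative", "missing"]
    df = pd.DataFrame(
        {
            "patient_id": groups.index,
            "time": time,
            "event": event,
            "group": groups.to_numpy(),
            "age": np.round(rng.normal(57.0, 12.0, size=n), 1),
            "er": rng.choice(receptors, size=n, p=[0.7, 0.25, 0.05]),
            "pr": rng.choice(receptors, size=n, p=[0.6, 0.35, 0.05]),
            "her2": rng.choice(receptors, size=n, p=[0.2, 0.6, 0.2]),
            "tumor_size_mm": np.round(rng.gamma(4.0, 6.0, size=n) + 5.0, 1),
        }
    ).set_index("patient_id")
    return df
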