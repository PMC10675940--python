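import numpy as np
import pytest

from radiotsh import cell_abundance, image_prep
from radiotsh import synthetic_data as sd


@pytest.fixture(scope="session")
def markers():
    return sd.generate_markers(n_per_type=10, seed=7)


@pytest.fixture(scope="session")
def clean_cohort(markers):
    """Noise-free cohort: exact round trips and sign checks."""
    cfg = sd.SyntheticCohortConfig(
        n_patients=60,
        n_genes=300,
        noise_sd=0.0,
        latent_sd_good=0.0,
        latent_sd_poor=0.0,
        seed=21,
    )
    return sd.generate_expression_cohort(cfg, markers)


@pytest.fixture(scope="session")
def cohort(markers):
    """Default study conditions: n=200, log2 noise 0.3, correlated good group."""
    cfg = sd.SyntheticCohortConfig(n_patients=200, n_genes=500, seed=11)
    return sd.generate_expression_cohort(cfg, markers)


@pytest.fixture(scope="session")
def cohort_abundance(cohort):
    """Estimated tumor/stroma abundance tables for the default cohort."""
    return {
        "tumor": cell_abundance.estimate_abundance(
            cell_abundance.filter_genes(cohort.tumor_expr), cohort.markers
        ),
        "stroma": cell_abundance.estimate_abundance(
            cell_abundance.filter_genes(cohort.stroma_expr), cohort.markers
        ),
    }


@pytest.fixture(scope="session")
def phantom():
    return sd.generate_phantom(sd.PhantomConfig(seed=5))


@pytest.fixture(scope="session")
def phantom_rois(phantom):
    """Phases plus ground-truth tumor mask and derived stroma band."""
    phases = image_prep.derive_phases(phantom.series)
    band = image_prep.stroma_band(phantom.tumor_mask, phantom.breast_mask)
    return phases, phantom.tumor_mask, band


def random_levels(rng, shape=(4, 4, 2), ng=4, mask_frac=0.85):
    """Random discretized ROI: levels 1..ng inside a random mask, 0 outside."""
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < mask_frac
    if not mask.any():
        mask.flat[0] = True
    levels[~mask] = 0
    return levels
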