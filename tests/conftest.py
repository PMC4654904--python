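import numpy as np
import pytest

from cholestage import (
    SyntheticSpec,
    anova_screen,
    cluster_factors,
    generate,
    normalize_factors,
    significant_ids,
    similarity_matrix,
)

# small design mirroring the study shape at reduced size: 16 signal factors
# over the six archetypes plus 5 flat nulls
SMALL_MEMBERS = (3, 2, 2, 4, 3, 2)


@pytest.fixture(scope="session")
def small_noiseless():
    return generate(
        SyntheticSpec(
            members_per_archetype=SMALL_MEMBERS,
            n_null_factors=5,
            noise_sd=0.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_noisy():
    return generate(
        SyntheticSpec(
            members_per_archetype=SMALL_MEMBERS,
            n_null_factors=5,
            noise_sd=0.05,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def study_noiseless():
    """Full study-shaped dataset: 153 factors, 90 carrying signal."""
    return generate(SyntheticSpec(noise_sd=0.0, seed=0))


def run_clustering(data, truth, n_clusters=6):
    """Screen, normalize, similarity, cluster — shared analysis front end."""
    screened = anova_screen(data)
    keep = significant_ids(screened)
    norm = normalize_factors(data.subset(keep))
    sim = similarity_matrix(norm)
    clusters = cluster_factors(sim, n_clusters, norm)
    return screened, norm, sim, clusters


@pytest.fixture(scope="session")
def study_clustered(study_noiseless):
    data, truth = study_noiseless
    return run_clustering(data, truth)
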