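from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mplexcov.atlas import RoiAtlas, synthetic_atlas
from mplexcov.cohort import CohortTable


@pytest.fixture
def atlas4() -> RoiAtlas:
    return RoiAtlas(
        name="tiny4",
        regions=("lh-entorhinal", "lh-fusiform", "rh-entorhinal", "rh-fusiform"),
    )


def build_cohort(
    atlas: RoiAtlas,
    n_subjects: int,
    seed: int = 0,
    groups: tuple[str, ...] = ("A",),
    modalities: tuple[str, ...] = ("CTH", "FDG"),
) -> CohortTable:
    """Small random-but-reproducible cohort for plumbing tests."""
    rng = np.random.default_rng(seed)
    ids = [f"s{seed}-{i:03d}" for i in range(n_subjects)]
    covariates = pd.DataFrame(
        {
            "group": [groups[i % len(groups)] for i in range(n_subjects)],
            "age": rng.uniform(50, 80, n_subjects),
            "sex": rng.integers(0, 2, n_subjects).astype(float),
            "education": rng.uniform(8, 22, n_subjects),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    roi = {
        m: pd.DataFrame(
            rng.normal(2.5, 0.3, (n_subjects, atlas.n_regions)),
            index=covariates.index,
            columns=list(atlas.regions),
        )
        for m in modalities
    }
    return CohortTable(
        atlas=atlas, modalities=modalities, covariates=covariates, roi=roi
    )


@pytest.fixture
def cohort6(atlas4) -> CohortTable:
    return build_cohort(atlas4, 6, seed=1)


@pytest.fixture
def atlas8() -> RoiAtlas:
    return synthetic_atlas(8, name="tiny8")
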