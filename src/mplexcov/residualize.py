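"""Covariate residualization of regional values.

Before any network is built, each region's values are regressed on age,
sex and education,

    Y_i = b0 + b1*age + b2*sex + b3*education + e_i,

one ordinary-least-squares fit per region, and the residuals e_i replace
the raw values. This removes linear demographic confounds so the
between-subject correlation structure that defines the group networks is
not driven by shared age/sex/education gradients.

The fit uses a QR decomposition of the design matrix (numerically stable,
no regularization). When two groups are later compared, the regression is
fitted once on the pooled pair — not per group — so that subjects remain
exchangeable under the permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import COVARIATE_NAMES, CohortTable


@dataclass(frozen=True)
class ResidualModel:
    """Per-region OLS fit: intercept, covariate slopes, and residuals."""

    roi_id: str
    beta0: float
    beta1: float  # age
    beta2: float  # sex
    beta3: float  # education
    residuals: np.ndarray


def design_matrix(cohort: CohortTable) -> np.ndarray:
    """Intercept + age + sex + education design, one row per subject."""
    cov = cohort.covariates
    X = np.column_stack(
        [np.ones(len(cov))] + [cov[c].to_numpy(dtype=float) for c in COVARIATE_NAMES]
    )
    return X


def _check_full_rank(X: np.ndarray) -> None:
    """Raise naming the collinear covariate if the design is rank-deficient."""
    names = ("intercept",) + COVARIATE_NAMES
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            raise ValueError(
                f"rank-deficient design: covariate {names[j]!r} is collinear "
                "with the preceding columns (e.g. constant across subjects)"
            )
        rank = new_rank


def residualize(
    cohort: CohortTable, modality: str
) -> tuple[pd.DataFrame, dict[str, ResidualModel]]:
    """Regress age, sex and education out of every region of one modality.

    Returns
    -------
    residuals
        DataFrame (subjects x regions) of OLS residuals, same index and
        columns as the input ROI table.
    models
        Map region -> ResidualModel with the fitted coefficients.

    Raises
    ------
    ValueError
        If fewer than 5 subjects (4 parameters need n > 4) or the design
        matrix is rank-deficient.
    """
    if modality not in cohort.roi:
        raise KeyError(f"no modality {modality!r} in cohort")
    Y = cohort.roi[modality]
    n = len(Y)
    if n < 5:
        raise ValueError(
            f"residualization needs >= 5 subjects (got {n}): the model has 4 parameters"
        )
    X = design_matrix(cohort)
    _check_full_rank(X)
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y.to_numpy(dtype=float))
    resid = Y.to_numpy(dtype=float) - X @ beta
    frame = pd.DataFrame(resid, index=Y.index, columns=Y.columns)
    models = {
        region: ResidualModel(
            roi_id=region,
            beta0=float(beta[0, j]),
            beta1=float(beta[1, j]),
            beta2=float(beta[2, j]),
            beta3=float(beta[3, j]),
            residuals=resid[:, j].copy(),
        )
        for j, region in enumerate(Y.columns)
    }
    return frame, models


def coefficients_frame(models: dict[str, ResidualModel]) -> pd.DataFrame:
    """Per-region coefficient table (for audit dumps)."""
    rows = [
        {
            "region": m.roi_id,
            "beta0": m.beta0,
            "beta_age": m.beta1,
            "beta_sex": m.beta2,
            "beta_education": m.beta3,
        }
        for m in models.values()
    ]
    return pd.DataFrame(rows).set_index("region")
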