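"""Permutation inference on group differences of multiplex measures.

Group-level covariance networks have no subject-level values, so group
differences are tested nonparametrically: subjects of the two groups are
pooled, repeatedly reassigned at random to two pseudo-groups of the
original sizes, and the full per-group pipeline (correlation -> binarize
-> supra-adjacency -> measure) is recomputed for every reassignment. The
two-tailed p-value uses the add-one estimator

    p = (#{|D_null| >= |D_obs|} + 1) / (n_perm + 1),

so p is never exactly 0 — a finite number of permutations cannot support
that claim. The 2.5% / 97.5% quantiles of the null are reported alongside.

Covariate residualization is fitted ONCE on the pooled pair before
permuting, not refit per pseudo-group: under the null the subjects are
exchangeable, and a per-group fit would absorb part of any group
difference. For the nodal MPC, Benjamini-Hochberg FDR is applied across
the regions of one (comparison, measure, threshold) triple; global
measures are single tests per threshold and carry no FDR family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable
from .measures import degrees_to_participation
from .networks import binarize_weights
from .residualize import residualize

MEASURES = ("global_mpc", "nodal_mpc", "global_overlapping_degree")


@dataclass(frozen=True)
class ComparisonResult:
    """Observed difference, permutation null summary, and p-values.

    ``diff`` is first-listed group minus second (A - B); ``node`` is a
    region name for nodal measures, "global" otherwise. ``p_fdr`` equals
    ``p_two_tailed`` for global measures (family of one).
    """

    measure: str
    threshold: float
    node: str
    diff: float
    null_lo: float
    null_hi: float
    p_two_tailed: float
    p_fdr: float
    n_permutations: int
    seed: int
    significant: bool = False


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    Adjusted values are monotone-enforced; a test is rejected iff its
    adjusted p-value is <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _pipeline_stat(
    residuals_by_modality: dict[str, np.ndarray],
    idx: np.ndarray,
    d: float,
    mode: str,
    measure: str,
) -> np.ndarray | float:
    """Run correlation -> binarize -> measure for one subject index set.

    Degrees are taken within layers, so the supra-assembly (whose coupling
    never enters a degree) is bypassed here for speed; equivalence with the
    explicit build_supra path is covered by tests.
    """
    degrees = []
    for arr in residuals_by_modality.values():
        sub = arr[idx]
        corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        adj = binarize_weights(corr, d, mode)
        degrees.append(adj.sum(axis=1))
    k = np.column_stack(degrees)
    if measure == "global_overlapping_degree":
        return float(k.sum(axis=1).mean())
    p = degrees_to_participation(k)
    if measure == "nodal_mpc":
        return p
    if measure == "global_mpc":
        return float(p.mean())
    raise ValueError(f"unknown measure {measure!r}; one of {MEASURES}")


def permutation_test(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    measure: str,
    d: float,
    n_perm: int = 5000,
    seed: int = 0,
    threshold_mode: str = "density",
    fdr_q: float = 0.05,
) -> list[ComparisonResult]:
    """Permutation test of an A - B multiplex-measure difference.

    Returns one ComparisonResult for a global measure, or one per region
    for ``nodal_mpc`` (with BH-FDR across regions). Identical seeds give
    bit-identical results.

    Raises
    ------
    ValueError
        If either group has fewer than 3 subjects, fewer than 100
        permutations are requested, or the cohorts disagree on atlas or
        modalities.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; one of {MEASURES}")
    if n_perm < 100:
        raise ValueError(
            f"n_perm={n_perm} is too few to estimate a two-tailed p; use >= 100"
        )
    n_a, n_b = cohort_a.n_subjects, cohort_b.n_subjects
    if min(n_a, n_b) < 3:
        raise ValueError("each group needs >= 3 subjects for correlation")
    pooled = cohort_a.concat(cohort_b)
    residuals = {
        mod: residualize(pooled, mod)[0].to_numpy() for mod in pooled.modalities
    }
    idx_all = np.arange(n_a + n_b)
    idx_a, idx_b = idx_all[:n_a], idx_all[n_a:]

    def diff(ia: np.ndarray, ib: np.ndarray):
        sa = _pipeline_stat(residuals, ia, d, threshold_mode, measure)
        sb = _pipeline_stat(residuals, ib, d, threshold_mode, measure)
        return (
            sa - sb
            if isinstance(sa, np.ndarray)
            else float(sa) - float(sb)
        )

    obs = diff(idx_a, idx_b)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm,) + np.shape(obs))
    for t in range(n_perm):
        perm = rng.permutation(idx_all)
        # relabeling must preserve the pooled subject multiset
        assert np.array_equal(np.sort(perm), idx_all)
        null[t] = diff(perm[:n_a], perm[n_a:])

    abs_obs = np.abs(obs)
    exceed = (np.abs(null) >= abs_obs).sum(axis=0)
    p = (exceed + 1) / (n_perm + 1)
    lo = np.quantile(null, 0.025, axis=0)
    hi = np.quantile(null, 0.975, axis=0)

    if measure == "nodal_mpc":
        regions = cohort_a.atlas.regions
        p_adj, reject = fdr_bh(np.atleast_1d(p), q=fdr_q)
        return [
            ComparisonResult(
                measure=measure,
                threshold=d,
                node=regions[j],
                diff=float(obs[j]),
                null_lo=float(lo[j]),
                null_hi=float(hi[j]),
                p_two_tailed=float(p[j]),
                p_fdr=float(p_adj[j]),
                n_permutations=n_perm,
                seed=seed,
                significant=bool(reject[j]),
            )
            for j in range(len(regions))
        ]
    p_scalar = float(p)
    return [
        ComparisonResult(
            measure=measure,
            threshold=d,
            node="global",
            diff=float(obs),
            null_lo=float(lo),
            null_hi=float(hi),
            p_two_tailed=p_scalar,
            p_fdr=p_scalar,
            n_permutations=n_perm,
            seed=seed,
            significant=p_scalar <= fdr_q,
        )
    ]
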