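"""Demographic / clinical group statistics for cohort description tables.

One-way ANOVA for continuous variables (with a summary-statistics path so
published mean/sd/n rows can be re-tested without raw data), Pearson
chi-square for sex ratios, a tie-corrected Kruskal-Wallis test computed
directly from ordinal category counts (e.g. dementia-severity ratings),
and Bonferroni-corrected pairwise t tests as post hocs. Standard
deviations follow the sample (n-1) convention throughout. p-values come
from the usual asymptotic reference distributions (F, chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable


@dataclass(frozen=True)
class GroupSummary:
    """Published-table row for one group: n, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def anova_oneway(
    groups: Sequence[np.ndarray | Sequence[float] | GroupSummary],
) -> tuple[float, float]:
    """Classical one-way ANOVA F and p, from raw vectors or GroupSummary.

    The summary path reconstructs the between-group sum of squares from
    means and ns and the within-group sum from (n-1)*sd^2; given exact
    summaries it is algebraically identical to the raw-data F.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if all(isinstance(g, GroupSummary) for g in groups):
        ns = np.array([g.n for g in groups], dtype=float)
        means = np.array([g.mean for g in groups], dtype=float)
        sds = np.array([g.sd for g in groups], dtype=float)
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if any(len(a) < 2 for a in arrays):
            raise ValueError("each group needs n >= 2")
        ns = np.array([len(a) for a in arrays], dtype=float)
        means = np.array([a.mean() for a in arrays])
        sds = np.array([a.std(ddof=1) for a in arrays])
    k, N = len(ns), ns.sum()
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    if ssw == 0:
        raise ValueError("zero within-group variance in every group")
    F = (ssb / (k - 1)) / (ssw / (N - k))
    p = float(sps.f.sf(F, k - 1, N - k))
    return float(F), p


def chi_square_independence(
    table: np.ndarray | Sequence[Sequence[int]],
) -> tuple[float, float, int]:
    """Pearson chi-square of independence on a contingency table.

    No continuity correction (matches the convention for r x c tables).
    Returns (chi2, p, df).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("zero row/column margin")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p), int(df)


def kruskal_wallis_ordinal(
    counts: np.ndarray | Sequence[Sequence[int]],
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H from a group x category count table.

    Subjects within a category share that category's mid-rank; the raw

        H = 12 / (N(N+1)) * sum_g R_g^2 / n_g - 3(N+1)

    is divided by the tie correction 1 - sum(t^3 - t) / (N^3 - N), where t
    runs over the category totals. p from chi-square with k-1 df.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 groups of ordinal counts")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be non-negative integers")
    n_g = c.sum(axis=1)
    if (n_g < 1).any():
        raise ValueError("every group needs n >= 1")
    t = c.sum(axis=0)  # category totals over groups
    if (t > 0).sum() < 2:
        raise ValueError("all subjects fall in one category (no ranking possible)")
    N = t.sum()
    cum = np.concatenate([[0.0], np.cumsum(t)])
    midrank = cum[:-1] + (t + 1) / 2.0  # mid-rank of each category
    R = c @ midrank
    H = 12.0 / (N * (N + 1)) * (R**2 / n_g).sum() - 3.0 * (N + 1)
    correction = 1.0 - ((t**3 - t).sum()) / (N**3 - N)
    H /= correction
    k = c.shape[0]
    return float(H), float(sps.chi2.sf(H, k - 1))


def bonferroni_pairwise(
    groups: Sequence[np.ndarray | Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All pairwise two-sample t tests, rejected iff p <= alpha / n_pairs."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    pairs = list(combinations(range(len(arrays)), 2))
    rows = []
    for i, j in pairs:
        t, p = sps.ttest_ind(arrays[i], arrays[j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "t": float(t),
                "p": float(p),
                "reject": bool(p <= alpha / len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(
    cohort: CohortTable,
    variables: Sequence[str] = ("age", "education"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Demographics table: per-group mean/sd plus ANOVA and sex chi-square.

    One row per continuous variable with per-group ``mean``/``sd``
    columns, F and p; a final ``sex`` row tests the group x sex counts
    with Pearson chi-square.
    """
    labels = cohort.groups()
    by_group = {g: cohort.covariates[cohort.covariates["group"] == g] for g in labels}
    rows = []
    for var in variables:
        row: dict[str, object] = {"variable": var, "test": "anova"}
        vectors = []
        for g in labels:
            v = by_group[g][var].to_numpy(dtype=float)
            vectors.append(v)
            row[f"{g}_n"] = len(v)
            row[f"{g}_mean"] = float(v.mean())
            row[f"{g}_sd"] = float(v.std(ddof=1))
        F, p = anova_oneway(vectors)
        row["statistic"], row["p"] = F, p
        if p <= alpha and len(labels) > 2:
            posthoc = bonferroni_pairwise(vectors, alpha=alpha, labels=list(labels))
            sig = posthoc[posthoc["reject"]]
            row["post_hoc"] = "; ".join(
                f"{r.group_a}!={r.group_b}" for r in sig.itertuples()
            ) or "NS"
        else:
            row["post_hoc"] = "NS"
        rows.append(row)
    sex_counts = np.array(
        [
            [
                int((by_group[g]["sex"] == 1).sum()),
                int((by_group[g]["sex"] == 0).sum()),
            ]
            for g in labels
        ]
    )
    chi2, p, df = chi_square_independence(sex_counts)
    sex_row: dict[str, object] = {"variable": "sex", "test": "chi2"}
    for gi, g in enumerate(labels):
        sex_row[f"{g}_n"] = int(sex_counts[gi].sum())
        sex_row[f"{g}_mean"] = float(sex_counts[gi, 0])  # male count
        sex_row[f"{g}_sd"] = float(sex_counts[gi, 1])  # female count
    sex_row["statistic"], sex_row["p"], sex_row["post_hoc"] = chi2, p, "NS"
    rows.append(sex_row)
    return pd.DataFrame(rows)
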