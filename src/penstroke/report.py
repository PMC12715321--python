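"""Statistical reporting layer: group comparisons and correlations.

Wraps the standard two-sample and paired tests (Student t, Mann-Whitney U,
Wilcoxon signed-rank, chi-square) and Spearman rank correlation, and builds
the summary tables relating the micrographia metrics to the patient-level
classifier scores.  Tests are two-sided; the significance convention is
α = 0.05; no multiple-testing correction is applied by default (a
Benjamini-Hochberg helper is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

_TESTS = {
    ("unpaired", "parametric"): "unpaired_t",
    ("paired", "parametric"): "paired_t",
    ("unpaired", "rank"): "mann_whitney",
    ("paired", "rank"): "wilcoxon_signed_rank",
    ("unpaired", "categorical"): "chi_square",
}


@dataclass(frozen=True)
class GroupComparison:
    """One two-group test with its summary statistics."""

    variable: str
    groups: tuple[str, str]
    test: str
    statistic: float
    p_value: float
    summaries: tuple[tuple[float, float], tuple[float, float]]  # (mean, SD) per group

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between two variables."""

    variables: tuple[str, str]
    spearman_rho: float
    p_value: float


def compare_groups(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    design: str = "unpaired",
    family: str = "parametric",
    variable: str = "",
    groups: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-group comparison with the test picked by design and family.

    design ∈ {unpaired, paired}; family ∈ {parametric, rank, categorical}.
    Parametric unpaired is the classic equal-variance Student t.  For the
    categorical family, ``a`` and ``b`` are the per-group count vectors of a
    contingency table (groups × categories chi-square).
    """
    key = (design, family)
    if key not in _TESTS:
        raise ValueError(f"unsupported design/family combination {key}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if design == "paired" and len(a) != len(b):
        raise ValueError("paired design requires equal-length matched samples")
    if family != "categorical" and (len(a) < 2 or len(b) < 2):
        raise ValueError("need at least 2 observations per group")

    if key == ("unpaired", "parametric"):
        res = stats.ttest_ind(a, b, equal_var=True)
    elif key == ("paired", "parametric"):
        res = stats.ttest_rel(a, b)
    elif key == ("unpaired", "rank"):
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif key == ("paired", "rank"):
        res = stats.wilcoxon(a, b)
    else:  # chi-square on the groups × categories table
        table = np.vstack([a, b])
        res = stats.chi2_contingency(table, correction=False)

    return GroupComparison(
        variable=variable,
        groups=groups,
        test=_TESTS[key],
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summaries=(
            (float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0),
            (float(b.mean()), float(b.std(ddof=1)) if len(b) > 1 else 0.0),
        ),
    )


def correlate(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    variables: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs equal-length samples of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(variables, float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(variables, float(rho), float(p))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        adj[order[rank]] = running
    return adj


def build_report(
    metrics_summary: pd.DataFrame,
    scores: pd.DataFrame,
    manifest: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Group summary, pairwise comparisons, and LR-vs-metrics correlations.

    ``metrics_summary`` has per-subject consistent_area_mm2 / sequence_effect,
    ``scores`` the per-patient lr, ``manifest`` the subject → group mapping.
    Returns deterministic tables keyed 'summary', 'comparisons',
    'correlations'.
    """
    subjects = manifest[["subject_id", "group", "stage", "state"]].drop_duplicates()
    merged = metrics_summary.merge(subjects, on="subject_id", how="left", validate="many_to_one")
    if merged["group"].isna().any():
        orphans = sorted(merged.loc[merged["group"].isna(), "subject_id"].unique())
        raise KeyError(f"subjects missing from manifest: {orphans}")

    variables = ["consistent_area_mm2", "sequence_effect"]
    summary = (
        merged.groupby("group")[variables]
        .agg(["mean", "std", "count"])
        .sort_index()
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    summary = summary.reset_index()

    comparisons = []
    group_names = sorted(merged["group"].unique())
    for i, ga in enumerate(group_names):
        for gb in group_names[i + 1 :]:
            for var in variables:
                va = merged.loc[merged["group"] == ga, var].dropna()
                vb = merged.loc[merged["group"] == gb, var].dropna()
                if len(va) < 2 or len(vb) < 2:
                    continue
                res = compare_groups(va, vb, "unpaired", "parametric",
                                     variable=var, groups=(ga, gb))
                comparisons.append(
                    {"variable": var, "group_a": ga, "group_b": gb,
                     "test": res.test, "statistic": res.statistic,
                     "p_value": res.p_value,
                     "mean_a": res.summaries[0][0], "sd_a": res.summaries[0][1],
                     "mean_b": res.summaries[1][0], "sd_b": res.summaries[1][1]}
                )

    correlations = []
    if scores is not None and len(scores):
        scored = merged.merge(scores[["subject_id", "lr"]], on="subject_id", how="inner")
        for var in variables:
            sub = scored[[var, "lr"]].dropna()
            if len(sub) >= 3 and sub[var].nunique() > 1 and sub["lr"].nunique() > 1:
                res = correlate(sub["lr"], sub[var], variables=("lr", var))
                correlations.append(
                    {"x": "lr", "y": var, "spearman_rho": res.spearman_rho,
                     "p_value": res.p_value, "n": len(sub)}
                )

    return {
        "summary": summary,
        "comparisons": pd.DataFrame(comparisons),
        "correlations": pd.DataFrame(correlations),
    }
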