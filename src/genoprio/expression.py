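"""Differential-expression and co-expression validation of candidate genes.

Candidate risk genes found by genetic integration should, if real, show
dysregulated expression in affected tissue. This module runs one-way ANOVA
with Tukey HSD post-hoc tests across labelled sample groups (e.g. severe
asthma / mild-moderate asthma / control), classical pooled-variance Student
t-tests for two-group contrasts, and per-group Pearson co-expression
matrices whose differences across groups expose condition-specific
co-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class DegResult:
    gene_id: str
    group_means: dict[str, float]
    f_stat: float
    anova_p: float
    tukey: dict[tuple[str, str], float]
    ttest_p: float | None = None  # two-group runs only
    degenerate: bool = False      # zero within-group variance everywhere


@dataclass
class CoexpressionMatrix:
    correlations: pd.DataFrame  # gene x gene Pearson r within one group
    group: str
    n_samples: int


def _groups_of(matrix: ExpressionMatrix, gene_id: str):
    if gene_id not in matrix.values.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    labels = matrix.group_labels
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = []
    for lbl in labels:
        samples = matrix.group_samples(lbl)
        if len(samples) < 2:
            raise ValueError(f"group {lbl!r} has < 2 samples")
        arrays.append(matrix.values.loc[gene_id, samples].to_numpy(dtype=float))
    return labels, arrays


def anova_tukey(matrix: ExpressionMatrix, gene_id: str) -> DegResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise post-hoc p-values.

    Tukey HSD uses the studentized-range distribution with the pooled error
    degrees of freedom; unequal group sizes are handled by the Tukey-Kramer
    form. With exactly two groups the ANOVA p coincides with the pooled
    two-sided t-test p (F = t^2), which is also returned as ``ttest_p``.
    """
    labels, arrays = _groups_of(matrix, gene_id)
    means = {lbl: float(a.mean()) for lbl, a in zip(labels, arrays)}
    if all(a.var(ddof=1) == 0 for a in arrays):
        return DegResult(gene_id=gene_id, group_means=means, f_stat=np.nan,
                         anova_p=np.nan, tukey={}, degenerate=True)
    f_stat, anova_p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    tukey = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            tukey[(labels[i], labels[j])] = float(hsd.pvalue[i, j])
    ttest_p = None
    if len(labels) == 2:
        ttest_p = float(stats.ttest_ind(arrays[0], arrays[1],
                                        equal_var=True).pvalue)
    return DegResult(gene_id=gene_id, group_means=means, f_stat=float(f_stat),
                     anova_p=float(anova_p), tukey=tukey, ttest_p=ttest_p)


def two_group_ttest(matrix: ExpressionMatrix, gene_id: str, group_a: str,
                    group_b: str, welch: bool = False) -> float:
    """Two-sided Student t-test p between two groups.

    Pooled-variance (classical Student) by default; ``welch=True`` switches
    to the unequal-variance form.
    """
    for g in (group_a, group_b):
        if g not in matrix.group_labels:
            raise KeyError(f"unknown group label {g!r}")
    a = matrix.values.loc[gene_id, matrix.group_samples(group_a)].to_numpy(float)
    b = matrix.values.loc[gene_id, matrix.group_samples(group_b)].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 samples")
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def coexpression_matrix(matrix: ExpressionMatrix, genes: list[str],
                        group: str) -> CoexpressionMatrix:
    """Pearson co-expression of ``genes`` within one group's samples.

    Constant genes produce NaN rows/columns (flagged undefined) rather than
    an error; the diagonal stays 1 for non-constant genes.
    """
    samples = matrix.group_samples(group)
    if len(samples) < 3:
        raise ValueError(f"group {group!r} has {len(samples)} samples; need >= 3")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing}")
    sub = matrix.values.loc[genes, samples].astype(float)
    corr = sub.T.corr(method="pearson")
    return CoexpressionMatrix(correlations=corr, group=group,
                              n_samples=len(samples))


def anova_table(matrix: ExpressionMatrix, genes: list[str] | None = None
                ) -> pd.DataFrame:
    """Vectorized one-way ANOVA p-values for many genes at once.

    Convenience for calibration runs and CLI output; per-gene Tukey post-hoc
    values come from :func:`anova_tukey`.
    """
    if genes is None:
        genes = list(matrix.values.index)
    labels = matrix.group_labels
    arrays = [matrix.values.loc[genes, matrix.group_samples(lbl)]
              .to_numpy(dtype=float) for lbl in labels]
    f_stat, pvals = stats.f_oneway(*arrays, axis=1)
    return pd.DataFrame({"gene_id": genes, "f_stat": f_stat,
                         "anova_p": pvals})
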