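"""Pathway alteration scoring of expression data against normal tissue.

The load-bearing step is z-standardization of each tumour's expression to
the per-gene mean and standard deviation of a normal-tissue reference:
``z_gi = (x_gi - mu_g) / sigma_g``.  A sample's pathway alteration score
is then the unweighted mean of its z-scores over a gene set (here the
ERBB2/ERBB3 signalling set), so a score of -0.5 means the pathway's genes
sit on average half a normal-tissue standard deviation below normal.
Before standardization, batch/platform differences between the tumour
matrix and the reference cohort are removed by per-gene location-scale
alignment.  Group comparisons report both Welch's t and the exact
rank-sum test, and genes can be ranked by their mutated-vs-wild effect.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def align_batches(target: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Location-scale align the target batch to a reference cohort.

    Per shared gene, target values are rescaled so their mean and variance
    match the reference batch.  A gene with zero variance in the target is
    location-adjusted only; genes absent from the reference pass through
    unchanged (both with a warning).  Matrices are genes x samples.
    """
    shared = target.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("target and reference share no genes")
    absent = target.index.difference(reference.index)
    if len(absent):
        warnings.warn(
            f"{len(absent)} genes absent from reference pass through unadjusted",
            stacklevel=2,
        )
    out = target.copy().astype(float)
    t_mean = target.loc[shared].mean(axis=1)
    t_sd = target.loc[shared].std(axis=1, ddof=1)
    r_mean = reference.loc[shared].mean(axis=1)
    r_sd = reference.loc[shared].std(axis=1, ddof=1)
    flat = t_sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} genes have zero variance in target; "
            "location-only adjustment applied",
            stacklevel=2,
        )
    scale = pd.Series(np.where(flat, 1.0, r_sd / t_sd.where(~flat, 1.0)), index=shared)
    vals = out.loc[shared]
    out.loc[shared] = vals.sub(t_mean, axis=0).mul(scale, axis=0).add(r_mean, axis=0)
    return out


def standardize_to_normals(
    matrix: pd.DataFrame, normals: pd.DataFrame, ddof: int = 1
) -> pd.DataFrame:
    """z-standardize expression to the normal-tissue reference.

    z_gi = (x_gi - mu_g^normal) / sigma_g^normal per gene.  Genes absent
    from the normals, with fewer than 2 normal observations, or with zero
    normal variance are excluded (reported via a warning).
    """
    shared = matrix.index.intersection(normals.index)
    mu = normals.loc[shared].mean(axis=1)
    n_obs = normals.loc[shared].notna().sum(axis=1)
    sigma = normals.loc[shared].std(axis=1, ddof=ddof)
    usable = shared[(n_obs >= 2) & (sigma > 0)]
    excluded = matrix.index.difference(usable)
    if len(excluded):
        warnings.warn(
            f"{len(excluded)} genes excluded from standardization "
            f"(missing from normals or zero normal variance): "
            f"{excluded.tolist()[:5]}",
            stacklevel=2,
        )
    z = matrix.loc[usable].sub(mu.loc[usable], axis=0).div(sigma.loc[usable], axis=0)
    return z


def pathway_score(z: pd.DataFrame, geneset: list[str]) -> pd.DataFrame:
    """Per-sample pathway alteration score over a gene set.

    The score is the unweighted mean of z-scores across the gene-set genes
    present in the matrix; missing (NaN) values are dropped per sample and
    ``n_genes_used`` records how many genes entered each mean.
    """
    present = [g for g in geneset if g in z.index]
    if not present:
        raise ValueError("no gene-set gene present in the z matrix")
    sub = z.loc[present]
    return pd.DataFrame(
        {
            "score": sub.mean(axis=0, skipna=True),
            "n_genes_used": sub.notna().sum(axis=0),
        }
    )


def compare_groups(
    scores: pd.Series,
    labels: pd.Series,
    groups: tuple[str, str] | None = None,
    exact_max_n: int = 10,
) -> dict:
    """Two-group comparison of pathway scores.

    Reports two-sided Welch's t and the two-sided rank-sum
    (Mann-Whitney) test -- exact when the smaller group has at most
    ``exact_max_n`` samples -- plus the group means.  ``groups`` fixes the
    (a, b) orientation; differences are mean(a) - mean(b).
    """
    labels = labels.reindex(scores.index)
    if groups is None:
        uniq = sorted(labels.dropna().unique())
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, got {uniq}")
        groups = (uniq[0], uniq[1])
    a = scores[labels == groups[0]].dropna()
    b = scores[labels == groups[1]].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 samples")
    t = stats.ttest_ind(a, b, equal_var=False)
    method = "exact" if min(len(a), len(b)) <= exact_max_n else "asymptotic"
    mw = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "groups": groups,
        "n": (len(a), len(b)),
        "group_means": {groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        "mean_difference": float(a.mean() - b.mean()),
        "welch_t": float(t.statistic),
        "t_p": float(t.pvalue),
        "ranksum_stat": float(mw.statistic),
        "ranksum_p": float(mw.pvalue),
        "ranksum_method": method,
    }


def exact_ranksum_p(a, b) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Enumerates all C(n_a + n_b, n_a) ways to assign the pooled values to
    group a and counts arrangements whose Mann-Whitney U is at least as
    far from its null mean as the observed one.  Intended as an
    independent check of :func:`compare_groups` at small n (330
    arrangements for a 4-vs-7 split).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    mu = n_a * (n - n_a) / 2.0

    def u_stat(idx: tuple[int, ...]) -> float:
        rank_sum = ranks[list(idx)].sum()
        return rank_sum - n_a * (n_a + 1) / 2.0

    observed = abs(u_stat(tuple(range(n_a))) - mu)
    hits = 0
    total = 0
    for idx in itertools.combinations(range(n), n_a):
        total += 1
        if abs(u_stat(idx) - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


def rank_pathway_genes(
    z: pd.DataFrame,
    labels: pd.Series,
    geneset: list[str],
    groups: tuple[str, str] = ("mutated", "wild"),
) -> pd.DataFrame:
    """Order gene-set genes by their mutated-minus-wild mean z difference.

    Ascending order, so the most down-regulated gene in the mutated group
    comes first; ties break lexicographically by gene name.
    """
    present = [g for g in geneset if g in z.index]
    if not present:
        raise ValueError("no gene-set gene present in the z matrix")
    labels = labels.reindex(z.columns)
    a_cols = labels.index[labels == groups[0]]
    b_cols = labels.index[labels == groups[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("both groups need >= 2 samples")
    effect = z.loc[present, a_cols].mean(axis=1) - z.loc[present, b_cols].mean(axis=1)
    out = pd.DataFrame({"gene": effect.index, "effect": effect.to_numpy()})
    return out.sort_values(["effect", "gene"], kind="mergesort").reset_index(drop=True)


def copy_number_expression_assoc(copy_numbers: pd.Series, expression: pd.Series) -> dict:
    """Least-squares slope and Pearson correlation of expression on copy number."""
    cn = pd.Series(copy_numbers, dtype=float)
    ex = pd.Series(expression, dtype=float).reindex(cn.index)
    keep = cn.notna() & ex.notna()
    cn, ex = cn[keep], ex[keep]
    if len(cn) < 3:
        raise ValueError("need >= 3 paired observations")
    if cn.nunique() == 1:
        raise ValueError("copy numbers have zero variance")
    if ex.nunique() == 1:
        # flat response: slope 0, correlation undefined -> 0 by convention
        return {"slope": 0.0, "intercept": float(ex.iloc[0]), "correlation": 0.0, "n": len(cn)}
    fit = stats.linregress(cn, ex)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "correlation": float(fit.rvalue),
        "n": len(cn),
    }
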