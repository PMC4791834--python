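"""Co-expression statistics for complex members.

Pairwise Pearson correlations within and between complexes quantify the
co-regulation of complex members across proteome profiles; rank-sum
comparisons contrast member groups (e.g. stable vs variable members); and
complex-level profiles (mean over members) are clustered to find groups of
co-varying complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from stoichiovar._newick import linkage_to_newick
from stoichiovar.expression import ExpressionMatrix
from stoichiovar.resource import ComplexResource


@dataclass
class CorrelationSet:
    """Pairwise Pearson correlations, labelled by shared complex membership.

    ``pairs`` columns: protein_a, protein_b, same_complex, r.  Pairs with
    fewer than three commonly present samples are excluded.
    """

    pairs: pd.DataFrame

    def within(self) -> pd.Series:
        return self.pairs.loc[self.pairs["same_complex"], "r"]

    def between(self) -> pd.Series:
        return self.pairs.loc[~self.pairs["same_complex"], "r"]


def within_between_correlations(
    m: ExpressionMatrix,
    resource: ComplexResource,
    max_between_ratio: int = 10,
    seed: int = 0,
) -> CorrelationSet:
    """Pearson r for within-complex pairs and a sample of between-complex pairs.

    Between-complex pairs (proteins sharing no complex) are subsampled to at
    most ``max_between_ratio`` times the within-complex pair count; the
    subsample is seeded and reproducible.
    """
    proteins = [p for p in m.values.index if p in resource.proteins]
    idx = resource.index
    sub = m.values.loc[proteins]
    corr = sub.T.corr(method="pearson", min_periods=3)
    within_pairs = set()
    for c in resource:
        members = sorted(p for p in c.members if p in corr.index)
        within_pairs.update(combinations(members, 2))
    rows = []
    for a, b in sorted(within_pairs):
        r = corr.loc[a, b]
        if pd.notna(r):
            rows.append((a, b, True, float(r)))
    n_within = len(rows)
    rng = np.random.default_rng(seed)
    all_pairs = list(combinations(sorted(corr.index), 2))
    between_candidates = [
        (a, b) for a, b in all_pairs
        if not (set(idx.get(a, [])) & set(idx.get(b, [])))
    ]
    quota = min(len(between_candidates), max_between_ratio * max(n_within, 1))
    chosen = rng.choice(len(between_candidates), size=quota, replace=False) if quota else []
    for i in sorted(chosen):
        a, b = between_candidates[i]
        r = corr.loc[a, b]
        if pd.notna(r):
            rows.append((a, b, False, float(r)))
    pairs = pd.DataFrame(rows, columns=["protein_a", "protein_b", "same_complex", "r"])
    return CorrelationSet(pairs)


def member_co_expression(m: ExpressionMatrix, resource: ComplexResource) -> pd.Series:
    """Per protein, mean Pearson r with its co-complex members."""
    proteins = [p for p in m.values.index if p in resource.proteins]
    corr = m.values.loc[proteins].T.corr(method="pearson", min_periods=3)
    out = {}
    for c in resource:
        members = sorted(p for p in c.members if p in corr.index)
        if len(members) < 2:
            continue
        block = corr.loc[members, members]
        np.fill_diagonal(block.values, np.nan)
        mean_r = block.mean(axis=1, skipna=True)
        for p, r in mean_r.items():
            out.setdefault(p, []).append(r)
    return pd.Series({p: float(np.nanmean(v)) for p, v in out.items()}, name="mean_co_r")


def compare_member_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided rank-sum comparison of two value groups.

    Returns (W, p) where W is the rank-sum of the first group.  For
    n_a + n_b <= 12 the p-value is computed by exhaustive enumeration of rank
    assignments (valid under ties); larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: len(a)].sum())
    n = len(pooled)
    if n <= 12:
        # exact enumeration of rank assignments; two-sided p doubles the
        # smaller tail (valid under ties, matches the asymptotic convention)
        count_le = count_ge = total = 0
        for comb in combinations(range(n), len(a)):
            w = ranks[list(comb)].sum()
            total += 1
            if w <= w_obs + 1e-12:
                count_le += 1
            if w >= w_obs - 1e-12:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return w_obs, p
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return w_obs, float(p)


@dataclass
class ComplexClusteringResult:
    """Complex-profile correlation matrix and its average-linkage tree."""

    correlations: pd.DataFrame
    linkage: np.ndarray
    newick: str
    profiles: pd.DataFrame


def complex_profile_clustering(
    m: ExpressionMatrix, resource: ComplexResource
) -> ComplexClusteringResult:
    """Cluster complexes by the correlation of their mean member profiles.

    The profile of a complex is the unweighted per-sample mean over its
    quantified members (the input should be median-centered but *not*
    complex-wise normalized, since overall complex abundance is the signal
    here).  Complexes are clustered by average linkage on 1 - r.
    """
    profiles = {}
    for c in resource:
        members = [p for p in c.members if p in m.values.index]
        if members:
            profiles[c.complex_id] = m.values.loc[members].mean(axis=0, skipna=True)
    prof = pd.DataFrame(profiles).T  # complexes x samples
    if len(prof) < 2:
        raise ValueError("need at least two complexes with quantified members")
    corr = prof.T.corr(method="pearson", min_periods=3)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    newick = linkage_to_newick(Z, list(prof.index))
    return ComplexClusteringResult(corr, Z, newick, prof)
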