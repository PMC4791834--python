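"""Nearest-centroid classification of two-group proteome cohorts.

Compositional signatures (variable complex members) are evaluated as
classification features for distinguishing tissue groups (e.g. normal vs
cancer): feature sets of increasing size are sampled from the signature pool
and from all quantified proteins, each is scored by leave-one-out
nearest-centroid accuracy, and the two accuracy distributions are compared
per size with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist

from stoichiovar._newick import linkage_to_newick
from stoichiovar.coexpression import compare_member_groups
from stoichiovar.expression import quantile_normalize_frame


@dataclass
class CohortMatrix:
    """proteins x samples matrix with a two-group sample labelling."""

    values: pd.DataFrame
    groups: pd.Series  # sample id -> group label

    def __post_init__(self):
        if list(self.values.columns) != list(self.groups.index):
            raise ValueError("group labels must match matrix columns")
        levels = self.group_levels
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        for g in levels:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than two samples")

    @property
    def group_levels(self) -> list:
        return sorted(self.groups.unique())

    @property
    def feature_universe(self) -> list:
        return list(self.values.index)


def preprocess_cohort(
    raw: pd.DataFrame,
    groups: pd.Series,
    min_unique_peptides: int = 2,
    min_present_per_group: int = 4,
) -> CohortMatrix:
    """Filter, log2-transform and quantile-normalize a raw intensity table.

    ``raw`` columns: protein, unique_peptides, then per-sample intensities
    (0 or NaN = not quantified).  Proteins identified by fewer than
    ``min_unique_peptides`` unique peptides are dropped, then proteins
    quantified in fewer than ``min_present_per_group`` samples of any group;
    surviving intensities are log2-transformed and quantile-normalized.
    """
    if not {"protein", "unique_peptides"}.issubset(raw.columns):
        raise ValueError("raw table must have columns protein, unique_peptides")
    sample_cols = [c for c in raw.columns if c not in ("protein", "unique_peptides")]
    df = raw[raw["unique_peptides"] >= min_unique_peptides]
    values = df.set_index("protein")[sample_cols].astype(float)
    values = values.where(values > 0)
    present = values.notna()
    counts = present.T.groupby(groups).sum().T
    keep = (counts >= min_present_per_group).all(axis=1)
    values = np.log2(values.loc[keep])
    values = quantile_normalize_frame(values)
    return CohortMatrix(values, groups.loc[sample_cols])


def nearest_centroid_loo(cm: CohortMatrix, features) -> tuple[float, pd.Series]:
    """Leave-one-out nearest-centroid accuracy over the given features.

    For each held-out sample, per-group centroids are the feature means over
    the remaining samples; the sample is assigned to the group with the
    smaller Euclidean distance.  Ties leave the sample unclassified, counted
    as incorrect.  Missing feature values are treated as 0 deviations
    (ignored in both centroid and distance).
    """
    features = sorted(set(features))
    if not features:
        raise ValueError("feature set must be non-empty")
    missing = [f for f in features if f not in cm.values.index]
    if missing:
        raise ValueError(f"features not in the cohort universe: {missing}")
    X = cm.values.loc[features].to_numpy(dtype=float)  # features x samples
    g1, g2 = cm.group_levels
    labels = cm.groups.to_numpy()
    samples = list(cm.values.columns)
    present = ~np.isnan(X)
    Xf = np.where(present, X, 0.0)
    sums = {}
    cnts = {}
    for g in (g1, g2):
        mask = labels == g
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} needs >=2 samples for leave-one-out centroids")
        sums[g] = Xf[:, mask].sum(axis=1)
        cnts[g] = present[:, mask].sum(axis=1).astype(float)
    preds = {}
    for j, s in enumerate(samples):
        dists = {}
        for g in (g1, g2):
            if labels[j] == g:
                cnt = cnts[g] - present[:, j]
                total = sums[g] - Xf[:, j]
            else:
                cnt = cnts[g]
                total = sums[g]
            with np.errstate(invalid="ignore", divide="ignore"):
                centroid = np.where(cnt > 0, total / np.where(cnt > 0, cnt, 1), np.nan)
            diff = X[:, j] - centroid
            diff = diff[~np.isnan(diff)]
            dists[g] = float(np.sqrt((diff**2).sum()))
        if dists[g1] < dists[g2]:
            preds[s] = g1
        elif dists[g2] < dists[g1]:
            preds[s] = g2
        else:
            preds[s] = None  # tie: unclassified
    preds = pd.Series(preds)
    correct = sum(preds[s] == cm.groups[s] for s in preds.index)
    return correct / len(preds), preds


@dataclass
class SignatureEvalResult:
    """Accuracy distributions per feature-set size, signature vs random pool.

    ``summary`` columns: size, pool (signature/random), mean_accuracy,
    se_accuracy (sd / sqrt(n_samples)); ``accuracies`` holds each sampled
    feature set's accuracy; ``comparisons`` the per-size rank-sum p-values.
    """

    accuracies: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame
    sizes: list = field(default_factory=list)


def feature_sampling_eval(
    cm: CohortMatrix,
    signature_pool,
    sizes=tuple(range(4, 29, 4)),
    n_samples: int = 100,
    seed: int = 0,
    exclude_signature_from_random: bool = False,
) -> SignatureEvalResult:
    """Compare signature-derived features with random features over set sizes.

    For each size, ``n_samples`` feature sets are drawn without replacement
    from the signature pool and from the full quantified universe (optionally
    excluding signature members), each scored by leave-one-out
    nearest-centroid accuracy, and the two distributions compared with a
    two-sided rank-sum test.  Fully seeded and reproducible.
    """
    signature_pool = sorted(set(signature_pool) & set(cm.feature_universe))
    if not signature_pool:
        raise ValueError("signature pool is empty within the cohort universe")
    universe = sorted(cm.feature_universe)
    random_pool = (
        sorted(set(universe) - set(signature_pool))
        if exclude_signature_from_random
        else universe
    )
    rng = np.random.default_rng(seed)
    acc_rows = []
    cmp_rows = []
    for size in sizes:
        if size > len(signature_pool) or size > len(random_pool):
            raise ValueError(f"feature-set size {size} exceeds pool size")
        sig_acc, rnd_acc = [], []
        for i in range(n_samples):
            feats = rng.choice(signature_pool, size=size, replace=False)
            a, _ = nearest_centroid_loo(cm, feats)
            sig_acc.append(a)
            feats = rng.choice(random_pool, size=size, replace=False)
            a, _ = nearest_centroid_loo(cm, feats)
            rnd_acc.append(a)
        for pool, accs in (("signature", sig_acc), ("random", rnd_acc)):
            for a in accs:
                acc_rows.append({"size": size, "pool": pool, "accuracy": a})
        _, p = compare_member_groups(sig_acc, rnd_acc)
        cmp_rows.append(
            {
                "size": size,
                "signature_mean": float(np.mean(sig_acc)),
                "random_mean": float(np.mean(rnd_acc)),
                "p_two_sided": p,
            }
        )
    accuracies = pd.DataFrame(acc_rows)
    summary = (
        accuracies.groupby(["size", "pool"])["accuracy"]
        .agg(mean_accuracy="mean", sd="std")
        .reset_index()
    )
    summary["se_accuracy"] = summary["sd"] / np.sqrt(n_samples)
    summary = summary.drop(columns="sd")
    comparisons = pd.DataFrame(cmp_rows)
    return SignatureEvalResult(accuracies, summary, comparisons, sizes=list(sizes))


def hierarchical_dendrogram(cm: CohortMatrix, features) -> tuple[np.ndarray, str]:
    """Average-linkage Euclidean dendrogram over samples, as Newick.

    Mirrors the dendrogram view of cohort structure under a chosen feature
    set.  Leaf order is deterministic.
    """
    features = sorted(set(features))
    X = cm.values.loc[features].T.to_numpy(dtype=float)
    Z = average(pdist(X, metric="euclidean"))
    return Z, linkage_to_newick(Z, list(cm.values.columns))
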