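"""Proteome expression matrices with replicate structure.

Values are log2-scale abundances (iBAQ/LFQ style) or log2 ratios between
consecutive states; missing entries are NaN.  The sample design maps every
sample to a (condition, replicate) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """proteins x samples log2 abundance matrix plus sample design.

    Attributes
    ----------
    values : DataFrame indexed by protein id, columns are sample ids.
    design : DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``; (condition, replicate) pairs are unique and the index
        matches the value columns exactly (same order).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        v, d = self.values, self.design
        if v.index.has_duplicates:
            dupes = sorted(v.index[v.index.duplicated()].unique())
            raise ValueError(f"duplicate protein ids: {dupes}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in matrix")
        if list(v.columns) != list(d.index):
            missing = sorted(set(v.columns) ^ set(d.index))
            raise ValueError(f"design/sample mismatch: {missing}")
        pairs = list(zip(d["condition"], d["replicate"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (condition, replicate) pairs in design")
        arr = v.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("matrix contains non-finite (inf) values")

    @property
    def proteins(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def conditions(self) -> list:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.design["condition"]))

    def condition_of(self) -> pd.Series:
        """sample id -> condition."""
        return self.design["condition"]

    def subset_conditions(self, conditions) -> "ExpressionMatrix":
        keep = self.design.index[self.design["condition"].isin(set(conditions))]
        return ExpressionMatrix(self.values[list(keep)], self.design.loc[list(keep)])

    def subset_proteins(self, proteins) -> "ExpressionMatrix":
        keep = [p for p in self.values.index if p in set(proteins)]
        return ExpressionMatrix(self.values.loc[keep], self.design)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.design.copy())


def read_design(path) -> pd.DataFrame:
    """Read a sample design TSV (sample_id, condition, replicate)."""
    d = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(d.columns):
        raise ValueError(f"design file must have columns {sorted(required)}")
    d["replicate"] = d["replicate"].astype(int)
    if (d["replicate"] < 1).any():
        raise ValueError("replicate numbers must be positive")
    return d.set_index("sample_id")


def read_matrix(matrix_path, design_path, log_transform: bool = False) -> ExpressionMatrix:
    """Read a proteins x samples TSV and its design TSV.

    The matrix file has protein ids in the first column and sample ids in the
    header.  With ``log_transform``, non-positive values become missing and
    the rest are log2-transformed (for raw intensity exports).
    """
    v = pd.read_csv(matrix_path, sep="\t", index_col=0)
    d = read_design(design_path)
    if set(v.columns) != set(d.index):
        offending = sorted(set(v.columns) ^ set(d.index))
        raise ValueError(f"design/sample mismatch: {offending}")
    v = v[list(d.index)].astype(float)
    if log_transform:
        v = v.where(v > 0)
        v = np.log2(v)
    return ExpressionMatrix(v, d)


def write_matrix(m: ExpressionMatrix, matrix_path, design_path=None) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="protein_id")
    if design_path is not None:
        m.design.to_csv(design_path, sep="\t", index_label="sample_id")


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample's median of present values (column medians -> 0)."""
    med = m.values.median(axis=0, skipna=True)
    if med.isna().any():
        empty = sorted(med.index[med.isna()])
        raise ValueError(f"samples with no present values: {empty}")
    return ExpressionMatrix(m.values - med, m.design)


def filter_by_replication(m: ExpressionMatrix, min_reps_per_condition: int) -> ExpressionMatrix:
    """Keep proteins with >= ``min_reps_per_condition`` present values in every condition."""
    if min_reps_per_condition < 1:
        raise ValueError("min_reps_per_condition must be >= 1")
    present = m.values.notna()
    counts = present.T.groupby(m.design["condition"]).sum().T
    keep = (counts >= min_reps_per_condition).all(axis=1)
    return ExpressionMatrix(m.values.loc[keep], m.design)


def flag_outlier_replicates(m: ExpressionMatrix) -> list:
    """Flag replicates whose nearest neighbour is not from the same condition.

    Pairwise Pearson correlation is computed between samples over commonly
    present proteins; a sample is flagged when its most-correlated other
    sample belongs to a different condition, with ties resolved in favour of
    same-condition neighbours.  Conditions with a single replicate are never
    flagged.  Returns flagged sample ids; exclusion is left to the caller.
    """
    corr = m.values.corr(method="pearson", min_periods=3)
    cond = m.design["condition"]
    rep_counts = cond.value_counts()
    flags = []
    for s in m.samples:
        if rep_counts[cond[s]] < 2:
            continue
        others = [t for t in m.samples if t != s]
        r = corr.loc[s, others]
        if r.isna().all():
            continue
        best = r.max()
        # ties in favour of the same condition
        best_neighbours = [t for t in others if r[t] == best]
        if not any(cond[t] == cond[s] for t in best_neighbours):
            flags.append(s)
    return flags


def quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a DataFrame (missing-aware).

    Each column's present values are replaced by the mean quantile function of
    all columns evaluated at the value's proportional rank.  For a complete
    matrix this is exactly the mean of order statistics across columns; with
    missing values ranks are interpolated proportionally and the missingness
    pattern is preserved.  Ties within a column receive the mean of the values
    they would have been assigned.
    """
    arr = values.to_numpy(dtype=float)
    n_rows, n_cols = arr.shape
    counts = np.sum(~np.isnan(arr), axis=0)
    if (counts == 0).any():
        raise ValueError("column with no present values")
    m = int(counts.max())
    grid = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
    # mean quantile function across columns
    ref = np.zeros(m)
    for j in range(n_cols):
        col = np.sort(arr[~np.isnan(arr[:, j]), j])
        if len(col) == 1:
            ref += col[0]
        else:
            q = np.linspace(0.0, 1.0, len(col))
            ref += np.interp(grid, q, col)
    ref /= n_cols
    out = np.full_like(arr, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(arr[:, j])
        col = arr[mask, j]
        n = len(col)
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n)
        ranks[order] = np.arange(n)
        q = ranks / (n - 1) if n > 1 else np.full(n, 0.5)
        vals = np.interp(q, grid, ref)
        # average assigned values over ties
        s = pd.Series(vals).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[mask, j] = s
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so all share the same value distribution."""
    return ExpressionMatrix(quantile_normalize_frame(m.values), m.design)
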