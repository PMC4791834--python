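"""Moderated differential expression of complex members and variable calling.

Each condition is contrasted against the mean of the remaining conditions on
the complex-wise corrected matrix, per-protein variances are shrunk with the
standard hierarchical empirical-Bayes model (scaled inverse-chi-square prior
on the residual variance, hyperparameters by moment matching on log
variances), p-values are adjusted per condition by Benjamini-Hochberg, and a
member is called *variable* when its adjusted p falls below ``member_alpha``
in at least one condition.  A complex is *variable* when at least
``complex_threshold`` of its quantified members are variable.

A decoy benchmark re-runs the whole pipeline on size-preserving random
complex assignments, providing the null expectation of variable-member
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from stoichiovar.expression import ExpressionMatrix, median_center
from stoichiovar.normalization import CorrectedMatrix, normalize_complexwise
from stoichiovar.resource import ComplexResource, generate_decoys, restrict_to_quantified


@dataclass
class ContrastFit:
    """Per-(protein, condition) contrasts and per-protein residual variances.

    ``table`` columns: protein, condition, effect (log2 fold change of the
    condition versus the mean of the other conditions), se_unit (standard
    error per unit residual standard deviation).  ``s2`` and ``df`` hold each
    protein's pooled residual variance and degrees of freedom; proteins with
    zero residual df are flagged in ``zero_df``.
    """

    table: pd.DataFrame
    s2: pd.Series
    df: pd.Series
    zero_df: list = field(default_factory=list)


@dataclass
class EBayesFit:
    """Empirical-Bayes variance moderation fit.

    The residual variance of protein g with d_g degrees of freedom is shrunk
    toward the prior (d0, s0_sq):

        s_tilde_sq = (d0 * s0_sq + d_g * s2_g) / (d0 + d_g)

    d0 = inf collapses every variance to s0_sq (pooled-variance t); d0 = 0
    leaves variances untouched (ordinary t).
    """

    d0: float
    s0_sq: float
    s_tilde_sq: pd.Series = None
    df_total: pd.Series = None


@dataclass
class MemberCallTable:
    """Variable-member and variable-complex calls.

    ``members``: one row per (protein, condition) with log2fc, t_mod, p,
    p_adj and the per-condition variable flag.  ``protein_variable``: per
    protein, significant in at least one condition.  ``complexes``: per
    complex, quantified/variable member counts, fraction and verdict.
    """

    members: pd.DataFrame
    protein_variable: pd.Series
    complexes: pd.DataFrame
    ebayes: EBayesFit = None


def fit_condition_contrasts(cm: ExpressionMatrix) -> ContrastFit:
    """One-way fit per protein; contrast each condition vs the rest.

    The model per protein is a one-way layout on conditions over the
    protein's present values.  The contrast for condition c is the condition
    mean minus the unweighted mean of the other condition means, its standard
    error follows from the per-condition replicate counts and the pooled
    residual variance.  Proteins are contrasted only in conditions where they
    are present.
    """
    cond = cm.design["condition"]
    conditions = cm.conditions
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    X = cm.values
    present = X.notna()
    # per-condition means and replicate counts (proteins x conditions)
    means = X.T.groupby(cond).mean().T[conditions]
    counts = present.T.groupby(cond).sum().T[conditions]
    M = means.to_numpy(dtype=float)
    N = counts.to_numpy(dtype=float)
    k = (~np.isnan(M)).sum(axis=1).astype(float)  # conditions with data
    # residual sum of squares around condition means
    fitted = means[cond].to_numpy(dtype=float)  # broadcast back to samples
    resid = X.to_numpy(dtype=float) - fitted
    rss = np.nansum(resid**2, axis=1)
    n_obs = present.to_numpy().sum(axis=1)
    df = n_obs - k
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
        rowsum = np.nansum(M, axis=1)
        effect = M - (rowsum[:, None] - M) / (k[:, None] - 1.0)
        inv_n = np.where(N > 0, 1.0 / np.where(N > 0, N, 1), np.nan)
        inv_sum = np.nansum(inv_n, axis=1)
        se_unit = np.sqrt(inv_n + (inv_sum[:, None] - inv_n) / (k[:, None] - 1.0) ** 2)
    effect = np.where(np.isnan(M) | (k[:, None] < 2), np.nan, effect)
    rows = []
    prot_index = list(X.index)
    for j, c in enumerate(conditions):
        rows.append(
            pd.DataFrame(
                {
                    "protein": prot_index,
                    "condition": c,
                    "effect": effect[:, j],
                    "se_unit": se_unit[:, j],
                    "n_reps": N[:, j],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True).dropna(subset=["effect"])
    s2_series = pd.Series(s2, index=prot_index, name="s2")
    df_series = pd.Series(df.astype(float), index=prot_index, name="df")
    zero_df = [p for p, d in df_series.items() if d <= 0]
    return ContrastFit(table.reset_index(drop=True), s2_series, df_series, zero_df)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0_sq) from residual variances.

    Matches the mean and variance of log residual variances to the scaled-F
    sampling model via digamma/trigamma identities.  Identical variances (or
    too little spread beyond the chi-square sampling noise) give d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need at least two positive-df variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def ebayes_moderate(
    fit: ContrastFit,
    d0: float | None = None,
    s0_sq: float | None = None,
    min_proteins: int = 10,
) -> tuple[EBayesFit, pd.DataFrame]:
    """Moderated t-statistics and two-sided p-values for all contrasts.

    The prior (d0, s0_sq) is estimated from the positive-df residual
    variances unless supplied explicitly (d0=0 reproduces the ordinary t
    exactly).  With fewer than ``min_proteins`` usable variances the ordinary
    t is used (d0=0).  Zero-df proteins are excluded from the prior fit but
    still moderated: their posterior variance is s0_sq with d0 degrees of
    freedom.
    """
    usable = int(((fit.df > 0) & (fit.s2 > 0)).sum())
    if d0 is None:
        if usable >= min_proteins:
            d0, s0_sq = estimate_variance_prior(fit.s2.to_numpy(), fit.df.to_numpy())
        else:
            d0, s0_sq = 0.0, float("nan")
    elif s0_sq is None and d0 > 0:
        _, s0_sq = estimate_variance_prior(fit.s2.to_numpy(), fit.df.to_numpy())

    s2 = fit.s2.fillna(0.0)
    df = fit.df.clip(lower=0.0)
    if math.isinf(d0):
        s_tilde_sq = pd.Series(s0_sq, index=s2.index)
        df_total = pd.Series(math.inf, index=s2.index)
    elif d0 == 0:
        s_tilde_sq = fit.s2.copy()
        df_total = df.copy()
    else:
        s_tilde_sq = (d0 * s0_sq + df * s2) / (d0 + df)
        # zero-df proteins carry no variance information of their own
        s_tilde_sq[df <= 0] = s0_sq
        df_total = df + d0
    eb = EBayesFit(d0=d0, s0_sq=s0_sq if s0_sq is not None else float("nan"),
                   s_tilde_sq=s_tilde_sq, df_total=df_total)

    table = fit.table.copy()
    st = s_tilde_sq.reindex(table["protein"]).to_numpy()
    dft = df_total.reindex(table["protein"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = table["effect"].to_numpy() / (table["se_unit"].to_numpy() * np.sqrt(st))
    p = np.full_like(t_mod, np.nan)
    finite = np.isfinite(t_mod) & (dft > 0)
    inf_df = finite & np.isinf(dft)
    p[inf_df] = 2.0 * stats.norm.sf(np.abs(t_mod[inf_df]))
    reg = finite & ~np.isinf(dft)
    p[reg] = 2.0 * stats.t.sf(np.abs(t_mod[reg]), dft[reg])
    table["t_mod"] = t_mod
    table["p"] = p
    return eb, table


def bh_adjust(table: pd.DataFrame, p_col: str = "p", group_col: str = "condition") -> pd.DataFrame:
    """Benjamini-Hochberg step-up FDR adjustment within each condition."""
    out = table.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(group_col).groups.items():
        p = out.loc[idx, p_col]
        mask = p.notna()
        if mask.any():
            adj = multipletests(p[mask].to_numpy(), method="fdr_bh")[1]
            out.loc[p[mask].index, "p_adj"] = adj
    return out


def call_variable(
    table: pd.DataFrame,
    resource: ComplexResource,
    member_alpha: float = 0.05,
    complex_threshold: float = 0.20,
    ebayes: EBayesFit = None,
) -> MemberCallTable:
    """Variable-member and variable-complex verdicts from adjusted p-values.

    A member is variable when p_adj < ``member_alpha`` in at least one
    condition; a complex is variable when the fraction of variable members
    among its *quantified* members is at least ``complex_threshold``.
    """
    members = table.copy()
    members["variable_at_condition"] = members["p_adj"] < member_alpha
    members = members.rename(columns={"effect": "log2fc"})
    protein_variable = members.groupby("protein")["variable_at_condition"].any()
    tested = set(protein_variable.index)
    rows = []
    for c in resource:
        quantified = sorted(c.members & tested)
        if not quantified:
            continue
        n_var = int(protein_variable.loc[quantified].sum())
        frac = n_var / len(quantified)
        rows.append(
            {
                "complex_id": c.complex_id,
                "n_quantified": len(quantified),
                "n_variable": n_var,
                "fraction_variable": frac,
                "verdict": "variable" if frac >= complex_threshold else "stable",
            }
        )
    complexes = pd.DataFrame(
        rows, columns=["complex_id", "n_quantified", "n_variable", "fraction_variable", "verdict"]
    )
    return MemberCallTable(members, protein_variable, complexes, ebayes=ebayes)


def run_member_analysis(
    m: ExpressionMatrix,
    resource: ComplexResource,
    trim_fraction: float = 0.2,
    member_alpha: float = 0.05,
    complex_threshold: float = 0.20,
    min_members: int = 5,
    center: bool = True,
    d0: float | None = None,
) -> MemberCallTable:
    """Full complex-member pipeline: center, normalize, test, adjust, call."""
    mm = median_center(m) if center else m
    quantified = set(mm.values.index[mm.values.notna().any(axis=1)])
    res_q = restrict_to_quantified(resource, quantified, min_members=min_members)
    cm = normalize_complexwise(mm, res_q, trim_fraction=trim_fraction)
    fit = fit_condition_contrasts(cm)
    eb, table = ebayes_moderate(fit, d0=d0)
    table = bh_adjust(table)
    return call_variable(table, res_q, member_alpha, complex_threshold, ebayes=eb)


def decoy_benchmark(
    m: ExpressionMatrix,
    resource: ComplexResource,
    n_seeds: int = 20,
    condition_subsets: list | None = None,
    member_alpha: float = 0.05,
    complex_threshold: float = 0.20,
    min_members: int = 5,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Variable-member counts with real vs decoy complexes over condition subsets.

    ``condition_subsets`` is a list of nested, increasing condition lists
    (default: prefixes of length 2, 4, ... of all conditions).  For each
    subset the full pipeline runs once with the real resource and once per
    decoy seed; columns report the real count and the decoy mean +/- sd.
    """
    conditions = m.conditions
    if condition_subsets is None:
        sizes = list(range(2, len(conditions) + 1, 2))
        if sizes[-1] != len(conditions):
            sizes.append(len(conditions))
        condition_subsets = [conditions[:s] for s in sizes]
    for a, b in zip(condition_subsets, condition_subsets[1:]):
        if not set(a) <= set(b):
            raise ValueError("condition subsets must be nested and increasing")
    quantified = set(m.values.index[m.values.notna().any(axis=1)])
    res_q = restrict_to_quantified(resource, quantified, min_members=min_members)
    rows = []
    for subset in condition_subsets:
        sub = m.subset_conditions(subset)
        real = run_member_analysis(
            sub, res_q, member_alpha=member_alpha,
            complex_threshold=complex_threshold, min_members=min_members,
        )
        real_count = int(real.protein_variable.sum())
        decoy_counts = []
        for s in range(n_seeds):
            decoy = generate_decoys(res_q, seed=base_seed + s)
            d = run_member_analysis(
                sub, decoy, member_alpha=member_alpha,
                complex_threshold=complex_threshold, min_members=min_members,
            )
            decoy_counts.append(int(d.protein_variable.sum()))
        decoy_counts = np.array(decoy_counts, dtype=float)
        rows.append(
            {
                "n_conditions": len(subset),
                "real_variable_count": real_count,
                "decoy_variable_mean": decoy_counts.mean(),
                "decoy_variable_sd": decoy_counts.std(ddof=1) if n_seeds > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def fisher_overlap(set_a, set_b, universe) -> tuple[float, float, float]:
    """Fisher's exact test for the overlap of two sets within a universe.

    Returns (sample odds ratio, two-sided p, Jaccard index).  The two-sided p
    sums hypergeometric probabilities of tables at most as likely as the
    observed one.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    both = len(set_a & set_b)
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    neither = len(universe) - both - only_a - only_b
    table = [[both, only_a], [only_b, neither]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    union = len(set_a | set_b)
    jaccard = both / union if union else float("nan")
    return float(odds), float(p), float(jaccard)
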