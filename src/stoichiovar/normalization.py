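"""Complex-wise normalization of proteome profiles.

Members of a protein complex are globally co-expressed, so a change in
overall complex abundance makes every member look differentially expressed.
To expose compositional (stoichiometric) changes instead, each member's
relative abundance is corrected by subtracting the mean relative abundance of
the *other* members of its complex, per sample.  Proteins belonging to
several complexes receive the average corrected value over those complexes.

For a complex of n members with relative abundances r_1..r_n in a sample, the
corrected value of member p is

    c_p = r_p - mean_{q != p} r_q = (n * r_p - sum(r)) / (n - 1)

so, within a fully observed complex, corrected values sum to zero and any
shift applied to all members cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stoichiovar.expression import ExpressionMatrix
from stoichiovar.resource import ComplexResource


@dataclass
class CorrectedMatrix(ExpressionMatrix):
    """Complex-wise corrected relative abundances.

    Same layout as :class:`ExpressionMatrix`, restricted to proteins that are
    members of at least one complex of the resource used; ``resource`` records
    the membership the correction was computed with.
    """

    resource: ComplexResource = field(default=None)


def relative_abundance(m: ExpressionMatrix, trim_fraction: float = 0.2) -> ExpressionMatrix:
    """Per-protein relative abundance w.r.t. the trimmed mean of condition means.

    For each protein, per-condition means (over present replicates) are
    computed, ``floor(trim_fraction * C)`` of them are trimmed from each tail,
    and the mean of the rest is subtracted from all of the protein's values.
    With few conditions nothing is trimmed and the plain mean is used.
    Trimming on condition means (not individual replicates) keeps unbalanced
    replicate counts from biasing the reference.
    """
    if not (0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    cond = m.design["condition"]
    cmeans = m.values.T.groupby(cond).mean().T  # proteins x conditions
    arr = cmeans.to_numpy(dtype=float)
    ref = np.empty(arr.shape[0])
    for i in range(arr.shape[0]):
        row = arr[i][~np.isnan(arr[i])]
        if len(row) == 0:
            ref[i] = np.nan
            continue
        k = int(np.floor(trim_fraction * len(row)))
        row = np.sort(row)
        trimmed = row[k : len(row) - k] if k > 0 else row
        ref[i] = trimmed.mean()
    out = m.values.sub(pd.Series(ref, index=m.values.index), axis=0)
    return ExpressionMatrix(out, m.design)


def normalize_complexwise(
    m: ExpressionMatrix,
    resource: ComplexResource,
    trim_fraction: float = 0.2,
) -> CorrectedMatrix:
    """Subtract, per sample, the mean relative abundance of co-complex members.

    ``m`` should be median-centered and ``resource`` restricted to quantified
    proteins.  Members missing in a sample are excluded from that sample's
    "rest" mean; if fewer than two members of a complex are present in a
    sample, that complex contributes nothing there.  Multi-complex proteins
    receive the average corrected value over their complexes.
    """
    rel = relative_abundance(m, trim_fraction=trim_fraction)
    member_set = resource.proteins
    proteins = [p for p in rel.values.index if p in member_set]
    R = rel.values.loc[proteins]
    Rv = R.to_numpy(dtype=float)
    pos = {p: i for i, p in enumerate(proteins)}
    acc = np.zeros_like(Rv)
    cnt = np.zeros(Rv.shape, dtype=int)
    for c in resource:
        idx = np.array([pos[p] for p in sorted(c.members) if p in pos], dtype=int)
        if len(idx) < 2:
            continue
        sub = Rv[idx]  # members x samples
        present = ~np.isnan(sub)
        n = present.sum(axis=0)
        total = np.nansum(sub, axis=0)
        # c_p = r_p - (total - r_p) / (n_present - 1), defined when n_present >= 2
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = sub - (total - sub) / (n - 1.0)
        valid = present & (n >= 2)
        acc[idx] += np.where(valid, corrected, 0.0)
        cnt[idx] += valid
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)
    frame = pd.DataFrame(out, index=proteins, columns=R.columns)
    return CorrectedMatrix(frame, m.design.copy(), resource=resource)
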