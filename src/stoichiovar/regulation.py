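"""Transcriptional-regulation classification of variable complex members.

A variable member whose mRNA changes significantly, in the same direction and
in the same condition as the protein, is *transcriptionally regulated*
(class ``transcriptional_true``); a same-sign mRNA change above the
fold-change floor but without significance is a *trend*
(``transcriptional_trend``); anything else is ``not_transcriptional``.
Transcriptional cases can additionally be linked to an inversely expressed
miRNA targeting the same gene, suggesting a miRNA-based mechanism.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stoichiovar.differential import MemberCallTable

CLASS_TRUE = "transcriptional_true"
CLASS_TREND = "transcriptional_trend"
CLASS_NOT = "not_transcriptional"
CLASS_UNKNOWN = "unclassifiable"


def select_probesets(probe_table: pd.DataFrame) -> pd.DataFrame:
    """Keep, per gene, the probe set with the highest variance across samples.

    ``probe_table`` columns: probe, gene, then per-sample values.  Ties are
    broken lexicographically by probe id.  Genes represented by multiple
    probes would otherwise be over-weighted downstream.
    """
    if not {"probe", "gene"}.issubset(probe_table.columns):
        raise ValueError("probe table must have columns probe, gene")
    value_cols = [c for c in probe_table.columns if c not in ("probe", "gene")]
    if not value_cols:
        raise ValueError("probe table has no sample value columns")
    df = probe_table.copy()
    df["_var"] = df[value_cols].var(axis=1, ddof=1)
    df = df.sort_values(["gene", "_var", "probe"], ascending=[True, False, True])
    best = df.groupby("gene", sort=True).head(1).drop(columns="_var")
    return best.reset_index(drop=True)


def classify_regulation(
    protein_calls: MemberCallTable,
    mrna: pd.DataFrame,
    mapping: pd.DataFrame,
    fc_floor: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every variable (protein, condition) case by its mRNA behaviour.

    ``mrna`` columns: gene, condition, log2fc, p_adj (one row per gene and
    condition, adjusted p supplied by the caller).  ``mapping`` is a
    two-column (protein, gene) table.  Cases with no mapped gene or no mRNA
    record at that condition are reported as unclassifiable; a missing mRNA
    fold change is treated as missing data, never as a zero change.
    """
    gene_of = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    mrna_idx = mrna.set_index(["gene", "condition"])
    if mrna_idx.index.has_duplicates:
        raise ValueError("mRNA table must have one row per (gene, condition)")
    members = protein_calls.members
    variable = members[members["variable_at_condition"]]
    rows = []
    for _, rec in variable.iterrows():
        protein, cond, pfc = rec["protein"], rec["condition"], rec["log2fc"]
        gene = gene_of.get(protein)
        cls = CLASS_UNKNOWN
        mfc, mp = np.nan, np.nan
        if gene is not None and (gene, cond) in mrna_idx.index:
            row = mrna_idx.loc[(gene, cond)]
            mfc, mp = float(row["log2fc"]), float(row["p_adj"])
            if np.isnan(mfc):
                cls = CLASS_UNKNOWN
            elif abs(mfc) > fc_floor and np.sign(mfc) == np.sign(pfc):
                cls = CLASS_TRUE if mp < alpha else CLASS_TREND
            else:
                cls = CLASS_NOT
        rows.append(
            {
                "protein": protein,
                "gene": gene,
                "condition": cond,
                "protein_log2fc": pfc,
                "mrna_log2fc": mfc,
                "mrna_p_adj": mp,
                "class": cls,
                "mirna_linked": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein", "gene", "condition", "protein_log2fc",
            "mrna_log2fc", "mrna_p_adj", "class", "mirna_linked",
        ],
    )


def link_mirna(
    calls: pd.DataFrame,
    mirna_changes: pd.DataFrame,
    targets: pd.DataFrame,
    mirna_alpha: float = 0.01,
) -> pd.DataFrame:
    """Flag transcriptional cases with an anti-correlated significant miRNA.

    ``mirna_changes`` columns: mirna, condition, log2fc, p_adj; ``targets``
    columns: mirna, gene.  A case is linked when some miRNA targeting its
    gene is significant (p_adj < ``mirna_alpha``) at the same condition with
    a fold change of sign opposite to the mRNA change.  The flag is only set
    for transcriptional classes.
    """
    out = calls.copy()
    targets_of: dict[str, set] = {}
    for mi, g in zip(targets["mirna"].astype(str), targets["gene"].astype(str)):
        targets_of.setdefault(g, set()).add(mi)
    sig = mirna_changes[mirna_changes["p_adj"] < mirna_alpha]
    sig_idx: dict[tuple, float] = {
        (str(r["mirna"]), str(r["condition"])): float(r["log2fc"]) for _, r in sig.iterrows()
    }
    linked = []
    for _, rec in out.iterrows():
        flag = False
        if rec["class"] in (CLASS_TRUE, CLASS_TREND) and pd.notna(rec["mrna_log2fc"]):
            msign = np.sign(rec["mrna_log2fc"])
            for mi in sorted(targets_of.get(str(rec["gene"]), ())):
                fc = sig_idx.get((mi, str(rec["condition"])))
                if fc is not None and np.sign(fc) == -msign and msign != 0:
                    flag = True
                    break
        linked.append(flag)
    out["mirna_linked"] = linked
    return out
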