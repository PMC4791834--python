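"""Paralog co-regulation and switch detection.

Duplicated complex members (paralogs) often replace each other in complex
variants: when both members of a paralog pair are significantly regulated in
the same condition with fold changes of opposite sign, the pair is called a
*switch*.  Same-sign co-regulation is labelled co-directional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from stoichiovar.differential import MemberCallTable, fisher_overlap


@dataclass(frozen=True)
class ParalogPair:
    """An unordered paralog pair, stored canonically (lexicographic order)."""

    protein_a: str
    protein_b: str
    family_id: str = ""

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValueError("a paralog pair must contain two distinct proteins")
        if self.protein_b < self.protein_a:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)


def read_pairs(path) -> list:
    """Read a paralog-pair TSV (protein_a, protein_b[, family_id])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_a", "protein_b"}.issubset(df.columns):
        raise ValueError("pair table must have columns protein_a, protein_b")
    fam = df["family_id"] if "family_id" in df.columns else [""] * len(df)
    return [ParalogPair(a, b, f) for a, b, f in zip(df["protein_a"], df["protein_b"], fam)]


def find_coregulated_pairs(
    calls: MemberCallTable, pairs, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairs where both members are significant in the same condition.

    Returns one row per (pair, condition) with both members' log2 fold
    changes at that condition.  Pairs referencing proteins absent from the
    call table are skipped with a warning.
    """
    members = calls.members
    sig = members[members["p_adj"] < alpha].set_index(["protein", "condition"])
    tested = set(members["protein"])
    rows = []
    for pair in pairs:
        a, b = pair.protein_a, pair.protein_b
        if a not in tested or b not in tested:
            warnings.warn(f"paralog pair ({a}, {b}) not fully covered by calls; skipped")
            continue
        conds_a = {c for (p, c) in sig.index if p == a}
        conds_b = {c for (p, c) in sig.index if p == b}
        for cond in sorted(conds_a & conds_b):
            rows.append(
                {
                    "protein_a": a,
                    "protein_b": b,
                    "family_id": pair.family_id,
                    "condition": cond,
                    "fc_a": float(sig.loc[(a, cond), "log2fc"]),
                    "fc_b": float(sig.loc[(b, cond), "log2fc"]),
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "family_id", "condition", "fc_a", "fc_b"]
    )


def classify_switches(coregulated: pd.DataFrame) -> pd.DataFrame:
    """Label each co-regulated (pair, condition) record as switch or co-directional.

    A switch requires strictly opposite signs; a zero fold change cannot
    support a switch claim and yields co-directional.
    """
    out = coregulated.copy()
    sign_product = out["fc_a"].apply(_sign) * out["fc_b"].apply(_sign)
    out["direction"] = ["switch" if s == -1 else "co_directional" for s in sign_product]
    return out


def _sign(x: float) -> int:
    return 1 if x > 0 else (-1 if x < 0 else 0)


def rollup_pairs(switch_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-pair summary: a pair is a switch if any condition shows a switch."""
    if switch_calls.empty:
        return pd.DataFrame(columns=["protein_a", "protein_b", "family_id", "n_conditions", "direction"])
    grouped = switch_calls.groupby(["protein_a", "protein_b", "family_id"], sort=True)
    rows = []
    for (a, b, f), grp in grouped:
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "family_id": f,
                "n_conditions": len(grp),
                "direction": "switch" if (grp["direction"] == "switch").any() else "co_directional",
            }
        )
    return pd.DataFrame(rows)


def paralog_enrichment(variable_members, all_members, paralog_members):
    """Fisher's exact test for paralog enrichment among variable members.

    Tests the association between being a paralog and being variable within
    the universe of all quantified members.
    """
    paralog_members = set(paralog_members)
    if not paralog_members:
        raise ValueError("paralog member set is empty; the contingency table is undefined")
    return fisher_overlap(set(variable_members), paralog_members, set(all_members))
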