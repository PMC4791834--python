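"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates replicate-structured log2 proteome matrices with
co-regulated complex members: each protein value is

    baseline(protein) + complex_term(complex, sample) + effect + noise

where the complex term is shared by all members of a complex within a sample
(inducing within-complex correlation), the planted effect is an additive
log2 shift on selected *variable* members in their affected conditions, and
the noise is Gaussian.  Paralog pairs, matched mRNA/miRNA profiles with
transcriptional/trend/non-transcriptional regulation, and a two-group
cohort with planted signature features are generated on top of the same
truth object, so every downstream stage has a parameter-recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stoichiovar.expression import ExpressionMatrix
from stoichiovar.regulation import CLASS_NOT, CLASS_TREND, CLASS_TRUE
from stoichiovar.resource import ComplexDefinition, ComplexResource, _repair_duplicates
from stoichiovar.signature import CohortMatrix


@dataclass
class SyntheticTruth:
    """Planted ground truth; fully determines the expectation of every entry.

    ``member_effects``: one row per planted (protein, condition) effect with
    its log2 magnitude and, where applicable, paralog pair and regulation
    class annotations.  ``variable_proteins`` is the set of proteins with at
    least one planted effect.
    """

    resource: ComplexResource = None
    conditions: list = field(default_factory=list)
    member_effects: pd.DataFrame = None
    pair_table: pd.DataFrame = None
    regulation: pd.DataFrame = None
    mirna_linked_cases: set = field(default_factory=set)
    signature_proteins: set = field(default_factory=set)
    cohort_effect: float = 0.0
    params: dict = field(default_factory=dict)

    @property
    def variable_proteins(self) -> set:
        if self.member_effects is None or self.member_effects.empty:
            return set()
        return set(self.member_effects["protein"])

    def effects_frame(self) -> pd.DataFrame:
        if self.member_effects is None:
            return pd.DataFrame(columns=["protein", "condition", "effect"])
        return self.member_effects


def default_design(n_conditions: int = 16, n_replicates: int = 3) -> pd.DataFrame:
    """Design with conditions C01.. and replicates r1.., indexed by sample id."""
    rows = []
    for i in range(1, n_conditions + 1):
        for r in range(1, n_replicates + 1):
            rows.append((f"C{i:02d}_r{r}", f"C{i:02d}", r))
    d = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"])
    return d.set_index("sample_id")


def generate_resource(
    n_complexes: int = 100,
    size_range: tuple = (5, 30),
    n_proteins: int | None = None,
    multi_membership_rate: float = 0.1,
    seed: int = 0,
) -> tuple[ComplexResource, SyntheticTruth]:
    """Random complex resource with a stated fraction of shared members.

    Complex sizes are uniform in ``size_range`` (all >= 5 enforced by the
    default range).  A fraction ``multi_membership_rate`` of distinct
    proteins is assigned to two complexes; the rest belong to exactly one.
    ``n_proteins`` optionally fixes the number of distinct proteins (the
    remaining membership slots are filled by duplicating proteins into a
    second complex).
    """
    if size_range[0] < 2:
        raise ValueError("complex sizes must be >= 2")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_complexes)
    total = int(sizes.sum())
    if n_proteins is None:
        n_distinct = int(round(total / (1.0 + multi_membership_rate)))
    else:
        n_distinct = n_proteins
    n_multi = total - n_distinct
    if n_multi < 0 or n_multi > n_distinct:
        raise ValueError("incompatible n_proteins for the drawn complex sizes")
    width = len(str(n_distinct))
    proteins = [f"P{i:0{width}d}" for i in range(1, n_distinct + 1)]
    multi = list(rng.choice(proteins, size=n_multi, replace=False)) if n_multi else []
    pool = proteins + multi
    flat = [pool[i] for i in rng.permutation(len(pool))]
    bounds = np.cumsum([0] + list(sizes))
    cidx = np.empty(len(flat), dtype=int)
    for i in range(n_complexes):
        cidx[bounds[i] : bounds[i + 1]] = i
    flat, cidx = _repair_duplicates(flat, cidx, n_complexes, rng)
    defs = []
    for i in range(n_complexes):
        members = frozenset(flat[j] for j in range(len(flat)) if cidx[j] == i)
        cid = f"CPX{i + 1:03d}"
        defs.append(ComplexDefinition(cid, cid, "user", members))
    resource = ComplexResource(defs)
    truth = SyntheticTruth(
        resource=resource,
        conditions=list(default_design()["condition"].unique()),
        member_effects=pd.DataFrame(
            columns=["protein", "condition", "effect", "family_id", "is_switch"]
        ),
        params={
            "n_complexes": n_complexes,
            "size_range": tuple(size_range),
            "multi_membership_rate": multi_membership_rate,
            "seed": seed,
        },
    )
    return resource, truth


def generate_proteome(
    resource: ComplexResource,
    design: pd.DataFrame | None = None,
    variable_fraction: float = 0.22,
    effect_size_log2: float = 1.0,
    complex_abundance_sd: float = 1.0,
    noise_sd: float = 0.25,
    missing_rate: float = 0.0,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Replicate-structured log2 matrix with planted variable members.

    A fraction ``variable_fraction`` of complex member proteins receives an
    additive effect of magnitude ``effect_size_log2`` (random sign) in one
    randomly chosen condition; proteins already carrying effects in ``truth``
    (e.g. planted paralog switches) keep those and are not re-drawn.  The
    per-(complex, sample) abundance term is shared by co-members and induces
    their co-expression; effects are planted on individual members, so
    complex-wise normalization must recover them.
    """
    if design is None:
        design = default_design()
    rng = np.random.default_rng(seed)
    proteins = sorted(resource.proteins)
    conditions = list(dict.fromkeys(design["condition"]))
    samples = list(design.index)
    P, S = len(proteins), len(samples)
    if truth is None:
        truth = SyntheticTruth(resource=resource)
    truth.conditions = conditions
    effects = truth.effects_frame().copy()
    preplanted = set(effects["protein"]) if not effects.empty else set()
    n_var = int(round(variable_fraction * P))
    candidates = [p for p in proteins if p not in preplanted]
    n_new = max(0, n_var - len(preplanted))
    new_variable = (
        sorted(rng.choice(candidates, size=min(n_new, len(candidates)), replace=False))
        if n_new
        else []
    )
    new_rows = []
    for p in new_variable:
        cond = conditions[int(rng.integers(len(conditions)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        new_rows.append(
            {"protein": p, "condition": cond, "effect": sign * effect_size_log2,
             "family_id": "", "is_switch": False}
        )
    if new_rows:
        new_df = pd.DataFrame(new_rows)
        effects = new_df if effects.empty else pd.concat([effects, new_df], ignore_index=True)
    truth.member_effects = effects.reset_index(drop=True)

    baseline = rng.normal(0.0, 1.0, size=P)
    complex_terms = rng.normal(0.0, complex_abundance_sd, size=(len(resource), S))
    pos = {p: i for i, p in enumerate(proteins)}
    term_sum = np.zeros((P, S))
    term_cnt = np.zeros(P)
    for ci, c in enumerate(resource):
        for p in c.members:
            term_sum[pos[p]] += complex_terms[ci]
            term_cnt[pos[p]] += 1
    shared = term_sum / np.maximum(term_cnt, 1)[:, None]
    values = baseline[:, None] + shared + rng.normal(0.0, noise_sd, size=(P, S))
    cond_of_sample = design["condition"].to_numpy()
    for _, row in truth.member_effects.iterrows():
        if row["protein"] in pos and row["condition"] in conditions:
            cols = cond_of_sample == row["condition"]
            values[pos[row["protein"]], cols] += row["effect"]
    if missing_rate > 0:
        mask = rng.random(size=(P, S)) < missing_rate
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(values, index=proteins, columns=samples)
    m = ExpressionMatrix(frame, design.copy())
    truth.params.update(
        {
            "variable_fraction": variable_fraction,
            "effect_size_log2": effect_size_log2,
            "complex_abundance_sd": complex_abundance_sd,
            "noise_sd": noise_sd,
            "missing_rate": missing_rate,
            "proteome_seed": seed,
        }
    )
    return m, truth


def generate_paralog_switches(
    truth: SyntheticTruth,
    n_pairs: int = 20,
    switch_fraction: float = 0.7,
    effect_size_log2: float = 1.0,
    conditions: list | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant co-regulated paralog pairs inside complexes.

    Each pair lives in the same complex; a fraction ``switch_fraction`` of
    pairs receives opposite-sign effects at a shared random condition
    (switches), the rest same-sign effects (co-directional).  Call this
    *before* :func:`generate_proteome` so the matrix carries the effects.
    """
    rng = np.random.default_rng(seed)
    resource = truth.resource
    if resource is None:
        raise ValueError("truth must carry a resource")
    conditions = list(conditions) if conditions is not None else list(truth.conditions)
    if not conditions:
        raise ValueError("no conditions available for planting switches")
    eligible = [c for c in resource if c.size >= 4]
    if len(eligible) < n_pairs:
        raise ValueError("not enough complexes to host the requested pairs")
    chosen = rng.choice(len(eligible), size=n_pairs, replace=False)
    used: set = set(truth.effects_frame()["protein"]) if truth.member_effects is not None else set()
    rows_pairs, rows_eff = [], []
    n_switch = int(round(switch_fraction * n_pairs))
    for k, ci in enumerate(sorted(chosen)):
        members = sorted(set(eligible[ci].members) - used)
        if len(members) < 2:
            continue
        pick = rng.choice(len(members), size=2, replace=False)
        a, b = sorted(members[i] for i in pick)
        used.update((a, b))
        cond = conditions[int(rng.integers(len(conditions)))]
        is_switch = k < n_switch
        sign_a = 1.0 if rng.random() < 0.5 else -1.0
        sign_b = -sign_a if is_switch else sign_a
        fam = f"FAM{k + 1:03d}"
        rows_pairs.append(
            {"protein_a": a, "protein_b": b, "family_id": fam,
             "is_switch": is_switch, "condition": cond}
        )
        for p, s in ((a, sign_a), (b, sign_b)):
            rows_eff.append(
                {"protein": p, "condition": cond, "effect": s * effect_size_log2,
                 "family_id": fam, "is_switch": is_switch}
            )
    pair_table = pd.DataFrame(rows_pairs)
    eff = pd.DataFrame(rows_eff)
    prev = truth.effects_frame()
    truth.member_effects = eff if prev.empty else pd.concat([prev, eff], ignore_index=True)
    truth.pair_table = pair_table
    truth.conditions = conditions
    truth.params.update({"n_pairs": n_pairs, "switch_fraction": switch_fraction,
                         "switch_seed": seed})
    return pair_table, truth


def generate_transcriptome(
    truth: SyntheticTruth,
    transcriptional_fraction: float = 0.38,
    trend_fraction: float = 0.15,
    mirna_fraction: float = 0.45,
    fc_floor: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Matched mRNA and miRNA tables for the planted variable members.

    A fraction ``transcriptional_fraction`` of planted (protein, condition)
    cases gets a same-sign mRNA change clearing the fold-change floor; of
    those, ``trend_fraction`` are non-significant (trend) and the rest
    significant; ``mirna_fraction`` of the transcriptional cases receive an
    anti-correlated significant miRNA with a target-table entry.  All other
    genes get null mRNA profiles.  Returns (mrna, mirna, targets, mapping,
    truth); statistics are emitted as pre-adjusted p-values.
    """
    rng = np.random.default_rng(seed)
    effects = truth.effects_frame()
    if effects.empty:
        raise ValueError("truth has no planted effects; generate a proteome first")
    proteins = sorted(truth.resource.proteins) if truth.resource else sorted(set(effects["protein"]))
    conditions = list(truth.conditions)
    mapping = pd.DataFrame({"protein": proteins, "gene": [f"g_{p}" for p in proteins]})
    gene_of = dict(zip(mapping["protein"], mapping["gene"]))

    cases = effects[["protein", "condition", "effect"]].drop_duplicates(
        subset=["protein", "condition"]
    )
    n_cases = len(cases)
    n_tx = int(round(transcriptional_fraction * n_cases))
    order = rng.permutation(n_cases)
    tx_idx = set(order[:n_tx])
    n_trend = int(round(trend_fraction * n_tx))
    trend_idx = set(order[:n_trend])  # subset of transcriptional cases
    n_mirna = int(round(mirna_fraction * n_tx))
    # miRNA-linked cases are drawn from the transcriptional set
    mirna_idx = (
        set(rng.choice(sorted(tx_idx), size=min(n_mirna, n_tx), replace=False))
        if n_tx
        else set()
    )

    mrna_rows = {}
    reg_rows = []
    mirna_rows = []
    target_rows = []
    linked_cases = set()
    for pos_i, (_, rec) in enumerate(cases.reset_index(drop=True).iterrows()):
        p, cond, eff = rec["protein"], rec["condition"], rec["effect"]
        gene = gene_of[p]
        sign = 1.0 if eff > 0 else -1.0
        if pos_i in tx_idx:
            fc = sign * (fc_floor + 0.3 + abs(rng.normal(0.0, 0.3)))
            if pos_i in trend_idx:
                p_adj = float(rng.uniform(0.10, 0.60))
                cls = CLASS_TREND
            else:
                p_adj = float(rng.uniform(1e-6, 0.01))
                cls = CLASS_TRUE
            if pos_i in mirna_idx:
                mi = f"mir_{gene}"
                mirna_rows.append(
                    {"mirna": mi, "condition": cond,
                     "log2fc": -sign * (0.5 + abs(rng.normal(0.0, 0.3))),
                     "p_adj": float(rng.uniform(1e-6, 0.005))}
                )
                target_rows.append({"mirna": mi, "gene": gene})
                linked_cases.add((p, cond))
        else:
            fc = float(rng.uniform(-0.8 * fc_floor, 0.8 * fc_floor))
            p_adj = float(rng.uniform(0.2, 1.0))
            cls = CLASS_NOT
        mrna_rows[(gene, cond)] = {"gene": gene, "condition": cond, "log2fc": fc, "p_adj": p_adj}
        reg_rows.append({"protein": p, "condition": cond, "class": cls,
                         "mirna_linked": (p, cond) in linked_cases})
    # null profiles for every other gene x condition
    for p in proteins:
        gene = gene_of[p]
        for cond in conditions:
            if (gene, cond) not in mrna_rows:
                mrna_rows[(gene, cond)] = {
                    "gene": gene, "condition": cond,
                    "log2fc": float(rng.normal(0.0, 0.15)),
                    "p_adj": float(rng.uniform(0.2, 1.0)),
                }
    # decoy non-significant miRNAs
    for i in range(10):
        mirna_rows.append(
            {"mirna": f"mir_null_{i}", "condition": conditions[i % len(conditions)],
             "log2fc": float(rng.normal(0.0, 0.2)), "p_adj": float(rng.uniform(0.2, 1.0))}
        )
    mrna = pd.DataFrame(list(mrna_rows.values()))
    mirna = pd.DataFrame(mirna_rows)
    targets = pd.DataFrame(target_rows, columns=["mirna", "gene"])
    truth.regulation = pd.DataFrame(reg_rows)
    truth.mirna_linked_cases = linked_cases
    truth.params.update(
        {"transcriptional_fraction": transcriptional_fraction,
         "trend_fraction": trend_fraction, "mirna_fraction": mirna_fraction,
         "fc_floor": fc_floor, "transcriptome_seed": seed}
    )
    return mrna, mirna, targets, mapping, truth


def generate_cohort(
    n_group_a: int = 7,
    n_group_b: int = 14,
    n_proteins: int = 6148,
    n_signature: int = 53,
    effect: float = 0.75,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[CohortMatrix, SyntheticTruth]:
    """Two-group cohort with planted signature features.

    Signature proteins carry a between-group mean shift of ``effect`` (log2);
    everything else is exchangeable Gaussian noise around per-protein
    baselines.  Defaults mirror a 7-normal vs 14-cancer tissue cohort with a
    53-protein compositional signature inside a universe of 6148 quantified
    proteins.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    proteins = [f"T{i:0{width}d}" for i in range(1, n_proteins + 1)]
    samples = [f"A{i:02d}" for i in range(1, n_group_a + 1)] + [
        f"B{i:02d}" for i in range(1, n_group_b + 1)
    ]
    groups = pd.Series(
        ["A"] * n_group_a + ["B"] * n_group_b, index=samples, name="group"
    )
    signature = sorted(rng.choice(proteins, size=n_signature, replace=False))
    baseline = rng.normal(10.0, 1.5, size=n_proteins)
    values = baseline[:, None] + rng.normal(
        0.0, noise_sd, size=(n_proteins, len(samples))
    )
    sig_pos = [proteins.index(p) for p in signature]
    b_cols = np.array([g == "B" for g in groups])
    signs = np.where(rng.random(len(sig_pos)) < 0.5, 1.0, -1.0)
    for k, i in enumerate(sig_pos):
        values[i, b_cols] += signs[k] * effect
    frame = pd.DataFrame(values, index=proteins, columns=samples)
    cm = CohortMatrix(frame, groups)
    truth = SyntheticTruth(
        signature_proteins=set(signature),
        cohort_effect=effect,
        params={
            "n_group_a": n_group_a, "n_group_b": n_group_b,
            "n_proteins": n_proteins, "n_signature": n_signature,
            "effect": effect, "noise_sd": noise_sd, "cohort_seed": seed,
        },
    )
    return cm, truth
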