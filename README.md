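# stoichiovar

Analysis of **protein complex stoichiometry variation** across cell types and
states from quantitative proteome profiles.

Protein complex members are strongly co-expressed: when a cell makes more of
a complex it makes more of every subunit, so raw differential expression
mostly reports whole-complex abundance shifts. The interesting biology often
lies elsewhere — in *compositional* changes, where one subunit deviates from
the complex's common trend (for instance a paralog switch, where two mutually
exclusive subunits change in opposite directions and swap complex variants).
`stoichiovar` implements a complex-centric workflow that isolates exactly
this signal:

1. **Complex resource handling** — GMT/TSV readers, source-ranked greedy
   redundancy filtering (drop a complex sharing ≥ 50 % of its members with a
   kept one), ortholog mapping, restriction to quantified members (≥ 5), and
   size-preserving **decoy** permutations as a null model.
2. **Complex-wise normalization** — per protein, the relative abundance
   r (log2 value minus its trimmed mean over condition means) is corrected by
   the mean of its co-complex members:
   `c_p = r_p − mean_{q≠p} r_q = (n·r_p − Σr)/(n−1)`,
   averaged over complexes for shared subunits. This removes overall complex
   abundance exactly (corrected values sum to zero per complex and sample)
   and leaves only compositional signal.
3. **Moderated differential testing** — each condition vs the mean of the
   rest, empirical-Bayes variance shrinkage
   `s̃² = (d0·s0² + d_g·s²)/(d0 + d_g)` with (d0, s0²) estimated by moment
   matching on log variances, per-condition Benjamini–Hochberg FDR; a member
   is *variable* at adjusted p < 0.05 in ≥ 1 condition, a complex is
   *variable* when ≥ 20 % of its quantified members are.
4. **Decoy benchmarking, co-expression statistics, paralog-switch
   detection, transcriptional (TRUE/TREND) classification with miRNA
   linking**, and **nearest-centroid leave-one-out classification** of
   two-group tissue cohorts using compositional signatures vs random
   features.
5. A **synthetic-data module** that generates every input with planted,
   exported ground truth (co-regulated complexes, variable members, paralog
   switches, matched mRNA/miRNA, signature cohorts), so each stage has a
   parameter-recovery test without external downloads.

Intended users: proteomics/computational-biology researchers who have a
proteins × samples log-abundance matrix (iBAQ/LFQ or log-ratios), replicate
annotations, and complex definitions, and want to call variable complex
members and complexes with a decoy-controlled, reproducible pipeline.

## Worked example

```python
import stoichiovar as sv
from stoichiovar import simulate as sim

# synthetic study: 40 complexes, 8 conditions x 3 replicates,
# 22 % of members carry a +/-1 log2 effect in one condition
res, truth = sim.generate_resource(n_complexes=40, seed=11)
design = sim.default_design(n_conditions=8, n_replicates=3)
truth.conditions = list(dict.fromkeys(design["condition"]))
m, truth = sim.generate_proteome(res, design, seed=12, truth=truth)

calls = sv.run_member_analysis(m, res)   # center -> normalize -> test -> call
called = set(calls.protein_variable[calls.protein_variable].index)
planted = truth.variable_proteins
tp = len(called & planted)
print(f"complexes: {len(res)}, members: {len(res.proteins)}")
print(f"planted variable members: {len(planted)}")
print(f"called variable members:  {len(called)}  "
      f"(sensitivity {tp/len(planted):.2f}, FDR {(len(called)-tp)/len(called):.3f})")
verdicts = calls.complexes["verdict"].value_counts()
print(f"variable complexes: {verdicts.get('variable', 0)} / {len(calls.complexes)}")
print(calls.members.sort_values("p_adj").head(3)
      [["protein", "condition", "log2fc", "t_mod", "p_adj"]].to_string(index=False))
```

Output:

```
complexes: 40, members: 672
planted variable members: 148
called variable members:  154  (sensitivity 0.99, FDR 0.052)
variable complexes: 28 / 40
protein condition    log2fc     t_mod        p_adj
   P414       C02 -1.415684 -8.359023 2.499474e-09
   P029       C04  1.262353  7.877601 6.481095e-09
   P465       C04 -1.268252 -7.910616 6.481095e-09
```

Nearly all planted members are recovered (sensitivity 0.99) at a controlled
false-discovery rate (0.052 against the nominal 0.05), and the strongest
calls are the planted ~1 log2 member effects. `calls.complexes` carries the
per-complex verdicts (28 of 40 complexes cross the 20 % variable-member
threshold under this planting density).

The same pipeline is available from the shell:

```bash
stoichiovar simulate proteome --seed 11 --out-dir sim/
stoichiovar diffexp --matrix sim/matrix.tsv --design sim/design.tsv \
    --resource sim/resource.gmt --alpha 0.05 --out calls.tsv
stoichiovar run --config config.yaml --out-dir out/   # full pipeline
```

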