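"""End-to-end orchestration with a YAML configuration.

The pipeline runs the stages in dependency order on either user-supplied
files or the built-in synthetic generator, and writes one TSV per stage into
an output directory.  Every output carries a provenance header (tool
version, configuration hash, seeds) and deterministic stages are
byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import stoichiovar
from stoichiovar.coexpression import member_co_expression
from stoichiovar.differential import decoy_benchmark, run_member_analysis
from stoichiovar.expression import read_matrix
from stoichiovar.paralog import (
    classify_switches,
    find_coregulated_pairs,
    read_pairs,
    rollup_pairs,
)
from stoichiovar.regulation import classify_regulation, link_mirna
from stoichiovar.resource import read_complexes, filter_redundant
from stoichiovar.signature import feature_sampling_eval
from stoichiovar.simulate import (
    default_design,
    generate_cohort,
    generate_paralog_switches,
    generate_proteome,
    generate_resource,
    generate_transcriptome,
)


@dataclass
class PipelineConfig:
    """All thresholds and inputs of the pipeline, with documented ranges.

    With ``synthetic: true`` the input paths are ignored and the synthetic
    generator supplies every stage's inputs.
    """

    synthetic: bool = True
    matrix: str | None = None
    design: str | None = None
    resource: str | None = None
    pairs: str | None = None
    mrna: str | None = None
    mirna: str | None = None
    mirna_targets: str | None = None
    gene_mapping: str | None = None
    member_alpha: float = 0.05
    complex_threshold: float = 0.20
    fc_floor: float = 0.5
    mirna_alpha: float = 0.01
    overlap_threshold: float = 0.5
    min_members: int = 5
    trim_fraction: float = 0.2
    seed: int = 0
    decoy_seeds: int = 5
    n_conditions: int = 16
    n_replicates: int = 3
    n_complexes: int = 60
    n_paralog_pairs: int = 10
    signature_n_samples: int = 25
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        checks = [
            ("member_alpha", 0.0, 1.0), ("complex_threshold", 0.0, 1.0),
            ("mirna_alpha", 0.0, 1.0), ("overlap_threshold", 0.0, 1.0),
            ("trim_fraction", 0.0, 0.5),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.fc_floor < 0:
            raise ValueError("fc_floor must be >= 0")
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")
        if not self.synthetic:
            for name in ("matrix", "design", "resource"):
                if getattr(self, name) is None:
                    raise ValueError(f"file-based run requires {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str) -> None:
    header = (
        f"# stoichiovar {stoichiovar.__version__} | stage={stage} "
        f"| config={cfg.digest()} | seed={cfg.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: PipelineConfig, out_dir, log=None) -> dict:
    """Run every stage in dependency order; returns the output paths.

    Artifacts: member calls, complex verdicts, paralog switches, regulation
    classes, signature evaluation, decoy benchmark, and a run log.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def say(msg):
        log_lines.append(msg)
        print(msg, file=log or sys.stderr)

    if config.synthetic:
        say(f"generating synthetic inputs (seed={config.seed})")
        resource, truth = generate_resource(
            n_complexes=config.n_complexes, seed=config.seed
        )
        design = default_design(config.n_conditions, config.n_replicates)
        truth.conditions = list(dict.fromkeys(design["condition"]))
        n_pairs = min(config.n_paralog_pairs, config.n_complexes // 2)
        pair_table, truth = generate_paralog_switches(
            truth, n_pairs=n_pairs, seed=config.seed + 1
        )
        m, truth = generate_proteome(
            resource, design=design, seed=config.seed + 2, truth=truth
        )
        mrna, mirna, targets, mapping, truth = generate_transcriptome(
            truth, fc_floor=config.fc_floor, seed=config.seed + 3
        )
        from stoichiovar.paralog import ParalogPair

        pairs = [
            ParalogPair(r["protein_a"], r["protein_b"], r["family_id"])
            for _, r in pair_table.iterrows()
        ]
        truth.effects_frame().to_csv(out / "truth_effects.tsv", sep="\t", index=False)
    else:
        say("loading user inputs")
        for name in ("matrix", "design", "resource"):
            p = Path(getattr(config, name))
            if not p.exists():
                raise FileNotFoundError(f"missing input file for {name!r}: {p}")
        for name in ("pairs", "mrna", "mirna", "mirna_targets", "gene_mapping"):
            v = getattr(config, name)
            if v is not None and not Path(v).exists():
                raise FileNotFoundError(f"missing input file for {name!r}: {v}")
        resource = read_complexes(config.resource)
        resource = filter_redundant(
            resource, config.overlap_threshold, config.min_members
        )
        m = read_matrix(config.matrix, config.design)
        pairs = read_pairs(config.pairs) if config.pairs else None
        mrna = pd.read_csv(config.mrna, sep="\t") if config.mrna else None
        mirna = pd.read_csv(config.mirna, sep="\t") if config.mirna else None
        targets = (
            pd.read_csv(config.mirna_targets, sep="\t") if config.mirna_targets else None
        )
        mapping = (
            pd.read_csv(config.gene_mapping, sep="\t") if config.gene_mapping else None
        )

    say("stage 1/6: differential member analysis")
    calls = run_member_analysis(
        m, resource,
        trim_fraction=config.trim_fraction,
        member_alpha=config.member_alpha,
        complex_threshold=config.complex_threshold,
        min_members=config.min_members,
    )
    paths = {}
    _write_tsv(calls.members, out / "member_calls.tsv", config, "member_calls")
    _write_tsv(calls.complexes, out / "complex_verdicts.tsv", config, "complex_verdicts")
    paths["member_calls"] = out / "member_calls.tsv"
    paths["complex_verdicts"] = out / "complex_verdicts.tsv"

    say("stage 2/6: decoy benchmark")
    bench = decoy_benchmark(
        m, resource, n_seeds=config.decoy_seeds,
        member_alpha=config.member_alpha,
        complex_threshold=config.complex_threshold,
        min_members=config.min_members,
        base_seed=config.seed,
    )
    _write_tsv(bench, out / "decoy_benchmark.tsv", config, "decoy_benchmark")
    paths["decoy_benchmark"] = out / "decoy_benchmark.tsv"

    say("stage 3/6: co-expression statistics")
    from stoichiovar.expression import median_center
    from stoichiovar.resource import restrict_to_quantified

    centered = median_center(m)
    res_q = restrict_to_quantified(
        resource, set(m.values.index), min_members=config.min_members
    )
    co = member_co_expression(centered, res_q)
    co_frame = co.rename("mean_co_r").reset_index().rename(columns={"index": "protein"})
    _write_tsv(co_frame, out / "member_coexpression.tsv", config, "member_coexpression")
    paths["member_coexpression"] = out / "member_coexpression.tsv"

    if pairs:
        say("stage 4/6: paralog switches")
        coreg = find_coregulated_pairs(calls, pairs, alpha=config.member_alpha)
        switches = classify_switches(coreg)
        roll = rollup_pairs(switches)
        _write_tsv(switches, out / "paralog_switches.tsv", config, "paralog_switches")
        _write_tsv(roll, out / "paralog_pairs.tsv", config, "paralog_pairs")
        paths["paralog_switches"] = out / "paralog_switches.tsv"

    if config.synthetic or (mrna is not None and mapping is not None):
        say("stage 5/6: transcriptional regulation classes")
        reg = classify_regulation(
            calls, mrna, mapping, fc_floor=config.fc_floor,
            alpha=config.member_alpha,
        )
        if mirna is not None and targets is not None and not targets.empty:
            reg = link_mirna(reg, mirna, targets, mirna_alpha=config.mirna_alpha)
        _write_tsv(reg, out / "regulation_classes.tsv", config, "regulation_classes")
        paths["regulation_classes"] = out / "regulation_classes.tsv"

    if config.synthetic:
        say("stage 6/6: signature classification")
        cohort, ctruth = generate_cohort(seed=config.seed + 4)
        ev = feature_sampling_eval(
            cohort, ctruth.signature_proteins,
            n_samples=config.signature_n_samples, seed=config.seed + 5,
        )
        _write_tsv(ev.comparisons, out / "signature_eval.tsv", config, "signature_eval")
        paths["signature_eval"] = out / "signature_eval.tsv"

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = out / "run_log.txt"
    return {k: str(v) for k, v in paths.items()}
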