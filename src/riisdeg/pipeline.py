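"""End-to-end orchestration: simulate -> quantify -> DE -> overlap -> classify.

A single :class:`RunConfig` drives the whole analysis; one master seed spawns
per-stage child seeds, every threshold and rule used is echoed into the summary,
and all intermediates are persisted as TSV/JSON so each stage can be re-run and
inspected independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from . import simulate as sim
from .quant import CountMatrix, load_dataset, qc_summary, write_dataset
from .detest import (CALL_ACTIVATED, CALL_REPRESSED, ComparisonSpec,
                     differential_expression)
from .overlap import (detected_genes, common_genes, overlap_test,
                      venn_partition, pct_half_up)
from .classify import (riis_dependence_crosstab, reversal_analysis,
                       quadrant_classify, dominance_patterns)

#: the study's five oriented comparisons (test group first)
DEFAULT_COMPARISONS = (
    {"name": "riis", "test": "rIIS-C", "baseline": "C"},
    {"name": "riis_hs", "test": "rIIS-C-HS", "baseline": "C-HS"},
    {"name": "daf16", "test": "rIIS-C", "baseline": "rIIS-daf16i"},
    {"name": "skn1", "test": "rIIS-C", "baseline": "rIIS-skn1i"},
    {"name": "hsf1", "test": "rIIS-C-HS", "baseline": "rIIS-hsf1i-HS"},
)

#: which rIIS-context DE table and knockdown/control groups belong to each TF
TF_CONTEXT = {
    "daf16": {"riis_comparison": "riis", "kd_group": "rIIS-daf16i", "control": "C"},
    "skn1": {"riis_comparison": "riis", "kd_group": "rIIS-skn1i", "control": "C"},
    "hsf1": {"riis_comparison": "riis_hs", "kd_group": "rIIS-hsf1i-HS",
             "control": "C-HS"},
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serialized verbatim into the output."""

    seed: int = 0
    n_genes: int = 16000
    simulation: dict = field(default_factory=dict)  # GeneratorConfig overrides
    design: dict = field(default_factory=dict)      # default_design overrides
    combination_rule: str = "daf16_dominant"
    input_paths: dict | None = None  # counts/samples/lengths TSVs instead of simulating
    comparisons: tuple = DEFAULT_COMPARISONS
    fc_threshold: float = 1.5
    alpha: float = 0.05
    rpkm_floor: float = 10.0
    detection_rule: str = "all_replicates_nonzero"
    reversal_rule: str = "not_de"
    universe: int | None = None
    focus_tf: str = "daf16"
    dominance_margin: float = 0.9
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.fc_threshold <= 0 or self.alpha <= 0 or self.rpkm_floor < 0:
            raise ConfigurationError("thresholds must be positive")
        if self.universe is not None and self.universe < 1:
            raise ConfigurationError("universe must be >= 1")
        names = [c["name"] for c in self.comparisons]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate comparison names")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [dict(c) for c in self.comparisons]
        return d


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds spawned from the master seed (< 2**31)."""
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _obtain_dataset(config: RunConfig) -> tuple[CountMatrix, sim.SimulatedDataset | None, dict]:
    if config.input_paths:
        cm = load_dataset(config.input_paths["counts"],
                          config.input_paths["samples"],
                          config.input_paths["lengths"])
        return cm, None, {"source": "files", "paths": dict(config.input_paths)}
    truth_seed, count_seed = _child_seeds(config.seed, 2)
    gen_cfg = sim.GeneratorConfig(**config.simulation)
    design = sim.default_design(**config.design)
    truth = sim.generate_truth(config.n_genes, gen_cfg, seed=truth_seed)
    dataset = sim.simulate_counts(truth, design, config.combination_rule,
                                  seed=count_seed)
    seeds = {"master": config.seed, "truth": truth_seed, "counts": count_seed}
    return dataset.counts, dataset, {"source": "simulation", "seeds": seeds}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and optionally persist) the run summary."""
    config.validate()
    cm, dataset, provenance = _obtain_dataset(config)

    groups = set(cm.sample_meta["group"])
    specs = {}
    for c in config.comparisons:
        for g in (c["test"], c["baseline"]):
            if g not in groups:
                raise ValidationError(
                    f"comparison {c['name']!r} references unknown group {g!r}")
        specs[c["name"]] = ComparisonSpec(c["name"], c["test"], c["baseline"])

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset(cm, outdir / "data")
        if dataset is not None:
            sim.write_simulated(dataset, outdir / "data")

    universe = config.universe if config.universe is not None else cm.n_genes
    summary: dict = {
        "config": config.to_dict(),
        "provenance": provenance,
        "n_genes": cm.n_genes,
        "universe": universe,
        "comparisons": {},
    }

    qc_report, _dist = qc_summary(cm)
    summary["qc"] = {
        "explained_variance": [float(v) for v in qc_report.explained_variance[:5]],
        "n_genes_used": qc_report.n_genes_used,
    }
    if outdir:
        (outdir / "qc.json").write_text(
            json.dumps(qc_report.to_dict(), indent=2, sort_keys=True) + "\n")

    # --- detection, common-gene filtering, DE per comparison ---------------
    detected = {g: detected_genes(cm, g, rule=config.detection_rule,
                                  rpkm_floor=config.rpkm_floor)
                for g in groups}
    de_tables: dict[str, pd.DataFrame] = {}
    common_by_comp: dict[str, set] = {}
    for name, spec in specs.items():
        common, excl_t, excl_b = common_genes(detected[spec.test_group],
                                              detected[spec.baseline_group])
        common_by_comp[name] = common
        ov = overlap_test(detected[spec.test_group], detected[spec.baseline_group],
                          universe=universe)
        de_full = differential_expression(cm, spec, config.fc_threshold,
                                          config.alpha)
        de = de_full.loc[sorted(common)]
        de_tables[name] = de
        n_act = int((de["call"] == CALL_ACTIVATED).sum())
        n_rep = int((de["call"] == CALL_REPRESSED).sum())
        summary["comparisons"][name] = {
            "test": spec.test_group,
            "baseline": spec.baseline_group,
            "n_detected_test": len(detected[spec.test_group]),
            "n_detected_baseline": len(detected[spec.baseline_group]),
            "n_common": len(common),
            "n_exclusive_discarded": len(excl_t) + len(excl_b),
            "detected_overlap": ov.to_dict(),
            "n_activated": n_act,
            "n_repressed": n_rep,
            "pct_activated_of_common": pct_half_up(n_act, len(common)) if common else 0.0,
            "pct_repressed_of_common": pct_half_up(n_rep, len(common)) if common else 0.0,
        }
        if outdir:
            de.to_csv(outdir / f"de_{name}.tsv", sep="\t")

    tfs = [tf for tf in TF_CONTEXT if tf in de_tables
           and TF_CONTEXT[tf]["riis_comparison"] in de_tables]

    # --- rIIS-dependence cross-tabulation ----------------------------------
    summary["crosstab"] = {}
    for tf in tfs:
        ctx = TF_CONTEXT[tf]
        de_riis = de_tables[ctx["riis_comparison"]]
        de_tf = de_tables[tf]
        shared = sorted(set(de_riis.index) & set(de_tf.index))
        ct = riis_dependence_crosstab(de_riis.loc[shared], de_tf.loc[shared],
                                      universe=universe)
        summary["crosstab"][tf] = ct.to_dict()

    # --- reversal ----------------------------------------------------------
    summary["reversal"] = {}
    for tf in tfs:
        ctx = TF_CONTEXT[tf]
        rev = reversal_analysis(
            cm, de_tables[ctx["riis_comparison"]], tf_group=ctx["kd_group"],
            control_group=ctx["control"], rule=config.reversal_rule,
            fc_threshold=config.fc_threshold, alpha=config.alpha,
            rpkm_floor=config.rpkm_floor,
        )
        summary["reversal"][tf] = rev.to_dict()

    # --- Venn partitions of TF-regulated genes -----------------------------
    if len(tfs) >= 2:
        tf_de_sets = {tf: set(de_tables[tf].index[de_tables[tf]["call"] != "unchanged"])
                      for tf in tfs}
        part = venn_partition(tf_de_sets)
        summary["venn_genomewide"] = part.summary()
        riis_de_all = set()
        for tf in tfs:
            comp = TF_CONTEXT[tf]["riis_comparison"]
            de_r = de_tables[comp]
            riis_de_all |= set(de_r.index[de_r["call"] != "unchanged"])
        part_r = venn_partition({tf: s & riis_de_all for tf, s in tf_de_sets.items()})
        summary["venn_riis_restricted"] = part_r.summary()

    # --- quadrant classification -------------------------------------------
    summary["quadrants"] = {}
    for tf in tfs:
        ctx = TF_CONTEXT[tf]
        de_riis = de_tables[ctx["riis_comparison"]]
        de_tf = de_tables[tf]
        genes = sorted((set(de_riis.index[de_riis["call"] != "unchanged"])
                        & set(de_tf.index[de_tf["call"] != "unchanged"])))
        if genes:
            qt = quadrant_classify(de_riis["log2fc"], de_tf["log2fc"], genes)
            summary["quadrants"][f"{tf}_vs_riis"] = qt.to_dict()
    for a, b in (("daf16", "skn1"), ("daf16", "hsf1"), ("skn1", "hsf1")):
        if a in de_tables and b in de_tables:
            de_a, de_b = de_tables[a], de_tables[b]
            genes = sorted((set(de_a.index[de_a["call"] != "unchanged"])
                            & set(de_b.index[de_b["call"] != "unchanged"])))
            if genes:
                qt = quadrant_classify(de_a["log2fc"], de_b["log2fc"], genes)
                summary["quadrants"][f"{a}_vs_{b}"] = qt.to_dict()

    # --- dominance ----------------------------------------------------------
    if len(tfs) >= 2 and config.focus_tf in tfs:
        focus_ctx = TF_CONTEXT[config.focus_tf]
        dom = dominance_patterns(
            {tf: de_tables[tf] for tf in tfs},
            de_tables[focus_ctx["riis_comparison"]],
            focus_tf=config.focus_tf, margin=config.dominance_margin,
        )
        summary["dominance"] = dom.to_dict()
        summary["dominance"]["verdict"] = (
            config.focus_tf if dom.dominant else "none")
        if outdir:
            dom.patterns.to_csv(outdir / "dominance_patterns.tsv", sep="\t",
                                index=False)

    if outdir:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
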