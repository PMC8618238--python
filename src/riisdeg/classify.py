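"""Comparative classification of TF dependence under reduced insulin signaling.

Four analyses sit on top of the per-comparison DE tables:

* cross-tabulation — how many rIIS-dependent genes (rIIS-C vs C) are also
  TF-regulated (rIIS-C vs rIIS;TFi), split by direction, with overlap
  enrichment statistics;
* reversal — does knocking down a TF return rIIS-altered genes to control
  levels (gene no longer DE in knockdown vs control);
* quadrant classification — sign concordance of log2 fold changes between two
  comparisons for their common DE genes;
* dominance — for genes shared by two or more TFs, whether one TF's direction
  (by default DAF-16's) sets the gene's direction under rIIS regardless of the
  others.

All steps join on gene identifiers, never on row positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .detest import (CALL_ACTIVATED, CALL_REPRESSED, CALL_UNCHANGED,
                     ComparisonSpec, differential_expression)
from .overlap import OverlapResult, overlap_test, pct_half_up
from .quant import CountMatrix, mean_rpkm_by_group

REVERSAL_RULES = ("not_de", "fc_window")


# ---------------------------------------------------------------------------
# rIIS-dependence cross-tabulation


@dataclass
class DirectionTab:
    """Overlap of one call direction between the rIIS and TF comparisons."""

    direction: str
    n_riis: int
    n_tf: int
    k: int
    overlap: OverlapResult

    @property
    def fraction_of_tf(self) -> float:
        return self.k / self.n_tf if self.n_tf else 0.0

    @property
    def fraction_of_riis(self) -> float:
        return self.k / self.n_riis if self.n_riis else 0.0


@dataclass
class CrossTab:
    activated: DirectionTab
    repressed: DirectionTab

    @property
    def combined_fraction(self) -> float:
        """(k_act + k_rep) / (|rIIS act| + |rIIS rep|), as a fraction."""
        denom = self.activated.n_riis + self.repressed.n_riis
        if denom == 0:
            return 0.0
        return (self.activated.k + self.repressed.k) / denom

    @property
    def combined_fraction_pct(self) -> float:
        denom = self.activated.n_riis + self.repressed.n_riis
        if denom == 0:
            return 0.0
        return pct_half_up(self.activated.k + self.repressed.k, denom)

    def to_dict(self) -> dict:
        out = {}
        for tab in (self.activated, self.repressed):
            out[tab.direction] = {
                "n_riis": tab.n_riis, "n_tf": tab.n_tf, "k": tab.k,
                "fraction_of_tf": tab.fraction_of_tf,
                "fraction_of_riis": tab.fraction_of_riis,
                "overlap": tab.overlap.to_dict(),
            }
        out["combined_fraction_pct"] = self.combined_fraction_pct
        return out


def combined_dependence_pct(k_act: int, k_rep: int,
                            n_riis_act: int, n_riis_rep: int) -> float:
    """Share of rIIS-dependent genes regulated by a TF, in percent (half-up, 1 dp).

    (k_act + k_rep) / (n_riis_act + n_riis_rep) * 100 — the integer arithmetic
    used when only published overlap counts are available.
    """
    return pct_half_up(k_act + k_rep, n_riis_act + n_riis_rep)


def riis_dependence_crosstab(de_riis: pd.DataFrame, de_tf: pd.DataFrame,
                             universe: int | None = None) -> CrossTab:
    """Cross-tabulate rIIS-dependent and TF-regulated genes by direction.

    Both DE tables must cover the same gene universe; the hypergeometric
    background defaults to that universe's size.
    """
    if set(de_riis.index) != set(de_tf.index):
        raise ValidationError(
            "DE tables computed on different gene universes "
            f"({len(de_riis)} vs {len(de_tf)} genes, "
            f"{len(set(de_riis.index) ^ set(de_tf.index))} ids differ)"
        )
    N = universe if universe is not None else len(de_riis)
    tabs = {}
    for direction in (CALL_ACTIVATED, CALL_REPRESSED):
        riis_set = set(de_riis.index[de_riis["call"] == direction])
        tf_set = set(de_tf.index[de_tf["call"] == direction])
        ov = overlap_test(riis_set, tf_set, universe=N) if riis_set and tf_set \
            else OverlapResult(k=0, m=len(riis_set), n=len(tf_set), N=N,
                               rf=0.0, log10_p=0.0)
        tabs[direction] = DirectionTab(
            direction=direction, n_riis=len(riis_set), n_tf=len(tf_set),
            k=len(riis_set & tf_set), overlap=ov,
        )
    return CrossTab(activated=tabs[CALL_ACTIVATED], repressed=tabs[CALL_REPRESSED])


# ---------------------------------------------------------------------------
# Reversal analysis


@dataclass
class ReversalSummary:
    """Per-direction counts of rIIS-DE genes whose knockdown profile is
    back at control levels (restricted to well-expressed genes)."""

    tf_group: str
    rule: str
    analyzed_activated: int
    reverted_activated: int
    analyzed_repressed: int
    reverted_repressed: int
    rpkm_floor: float = 10.0

    @property
    def fraction_activated(self) -> float:
        return (self.reverted_activated / self.analyzed_activated
                if self.analyzed_activated else 0.0)

    @property
    def fraction_repressed(self) -> float:
        return (self.reverted_repressed / self.analyzed_repressed
                if self.analyzed_repressed else 0.0)

    def to_dict(self) -> dict:
        return {
            "tf_group": self.tf_group, "rule": self.rule,
            "rpkm_floor": self.rpkm_floor,
            "activated": {"analyzed": self.analyzed_activated,
                          "reverted": self.reverted_activated,
                          "fraction": self.fraction_activated},
            "repressed": {"analyzed": self.analyzed_repressed,
                          "reverted": self.reverted_repressed,
                          "fraction": self.fraction_repressed},
        }


def reversal_analysis(cm: CountMatrix, de_riis: pd.DataFrame, tf_group: str,
                      control_group: str = "C", rule: str = "not_de",
                      fc_threshold: float = 1.5, alpha: float = 0.05,
                      rpkm_floor: float = 10.0,
                      fc_window: float = 1.25) -> ReversalSummary:
    """Score how completely TF knockdown reverts rIIS-driven expression.

    A gene enters the analysis if it is rIIS-DE (per ``de_riis``) and has mean
    RPKM >= ``rpkm_floor`` in every compared group (control, the rIIS group the
    DE table was built against, and the knockdown group).  Under the default
    ``not_de`` rule a gene counts as reverted when it is no longer DE between
    knockdown and control at the same thresholds; the ``fc_window`` rule
    instead requires |log2 FC(knockdown vs control)| < log2(``fc_window``).
    """
    if rule not in REVERSAL_RULES:
        raise ValidationError(f"unknown reversal rule {rule!r}")
    for g in (tf_group, control_group):
        cm.samples_in_group(g)  # raises on unknown group

    kd_vs_ctrl = differential_expression(
        cm, ComparisonSpec(f"{tf_group}_vs_{control_group}", tf_group, control_group),
        fc_threshold=fc_threshold, alpha=alpha,
    )
    # RPKM floor over every compared group; the rIIS group is the one the
    # supplied DE table used as its test side (recorded via mean_rpkm_test).
    floors = (de_riis["mean_rpkm_test"] >= rpkm_floor) \
        & (de_riis["mean_rpkm_baseline"] >= rpkm_floor) \
        & (mean_rpkm_by_group(cm, tf_group).reindex(de_riis.index) >= rpkm_floor)

    if rule == "not_de":
        reverted_mask = kd_vs_ctrl["call"].reindex(de_riis.index) == CALL_UNCHANGED
    else:
        reverted_mask = (
            kd_vs_ctrl["log2fc"].reindex(de_riis.index).abs() < np.log2(fc_window)
        )

    counts = {}
    for direction in (CALL_ACTIVATED, CALL_REPRESSED):
        analyzed = (de_riis["call"] == direction) & floors
        counts[direction] = (int(analyzed.sum()),
                             int((analyzed & reverted_mask).sum()))
    return ReversalSummary(
        tf_group=tf_group, rule=rule, rpkm_floor=rpkm_floor,
        analyzed_activated=counts[CALL_ACTIVATED][0],
        reverted_activated=counts[CALL_ACTIVATED][1],
        analyzed_repressed=counts[CALL_REPRESSED][0],
        reverted_repressed=counts[CALL_REPRESSED][1],
    )


# ---------------------------------------------------------------------------
# Quadrant classification


@dataclass
class QuadrantTable:
    """Sign-pair assignment of common genes across two comparisons.

    Quadrants: 1 (+,+), 2 (-,+), 3 (-,-), 4 (+,-); genes with a log2 FC of
    exactly 0 on either axis are excluded from percentages and reported
    separately.
    """

    per_gene: pd.DataFrame  # columns log2fc_x, log2fc_y, quadrant (0 = tie)
    counts: dict
    n_classified: int
    n_ties: int

    @property
    def percentages(self) -> dict:
        if self.n_classified == 0:
            return {q: 0.0 for q in (1, 2, 3, 4)}
        return {q: pct_half_up(self.counts[q], self.n_classified)
                for q in (1, 2, 3, 4)}

    @property
    def same_direction_fraction(self) -> float:
        """Fraction of classified genes in quadrants 1 and 3 (co-regulation)."""
        if self.n_classified == 0:
            return 0.0
        return (self.counts[1] + self.counts[3]) / self.n_classified

    def to_dict(self) -> dict:
        return {
            "counts": {str(q): self.counts[q] for q in (1, 2, 3, 4)},
            "percentages": {str(q): self.percentages[q] for q in (1, 2, 3, 4)},
            "n_classified": self.n_classified,
            "n_ties": self.n_ties,
            "same_direction_fraction": self.same_direction_fraction,
        }


def quadrant_classify(log2fc_x: pd.Series, log2fc_y: pd.Series,
                      genes) -> QuadrantTable:
    """Assign each common gene to a fold-change sign quadrant."""
    genes = pd.Index(genes)
    missing = genes.difference(log2fc_x.index).union(genes.difference(log2fc_y.index))
    if len(missing):
        raise ValidationError(f"genes absent from a comparison: {list(missing[:5])}")
    x = log2fc_x.reindex(genes).to_numpy(float)
    y = log2fc_y.reindex(genes).to_numpy(float)
    quadrant = np.zeros(len(genes), dtype=int)
    quadrant[(x > 0) & (y > 0)] = 1
    quadrant[(x < 0) & (y > 0)] = 2
    quadrant[(x < 0) & (y < 0)] = 3
    quadrant[(x > 0) & (y < 0)] = 4
    per_gene = pd.DataFrame(
        {"log2fc_x": x, "log2fc_y": y, "quadrant": quadrant}, index=genes
    )
    counts = {q: int((quadrant == q).sum()) for q in (1, 2, 3, 4)}
    n_ties = int((quadrant == 0).sum())
    return QuadrantTable(per_gene=per_gene, counts=counts,
                         n_classified=len(genes) - n_ties, n_ties=n_ties)


# ---------------------------------------------------------------------------
# Combinatorial dominance


@dataclass
class DominanceTable:
    """Sign patterns of multi-TF genes crossed with their rIIS direction.

    ``patterns`` rows: one per observed (TF-sign combination, rIIS direction)
    with its gene count.  ``concordance[tf]`` is the fraction of that TF's
    genes (among the multi-TF, rIIS-DE genes considered) whose rIIS direction
    matches the TF's own direction.
    """

    per_gene: pd.DataFrame
    patterns: pd.DataFrame
    concordance: dict
    focus_tf: str
    margin: float
    dominant: bool

    def to_dict(self) -> dict:
        return {
            "focus_tf": self.focus_tf,
            "margin": self.margin,
            "dominant": self.dominant,
            "concordance": {tf: float(v) for tf, v in self.concordance.items()},
            "n_genes": int(self.per_gene.shape[0]),
            "patterns": self.patterns.to_dict(orient="records"),
        }


_SIGN = {CALL_ACTIVATED: "+", CALL_REPRESSED: "-", CALL_UNCHANGED: "."}


def dominance_patterns(de_by_tf: dict, de_riis: pd.DataFrame,
                       focus_tf: str = "daf16", margin: float = 0.9) -> DominanceTable:
    """Tabulate direction patterns for genes shared by >= 2 TFs and DE under rIIS.

    Each qualifying gene contributes one row: its call sign per TF ("." where
    not DE for that TF) plus its rIIS direction.  A TF's concordance is the
    fraction of its own targets among these genes whose rIIS direction equals
    the TF's direction; ``focus_tf`` is flagged dominant when its concordance
    is the strict maximum and at least ``margin``.
    """
    if len(de_by_tf) < 2:
        raise ValidationError("dominance analysis needs at least 2 TFs")
    if focus_tf not in de_by_tf:
        raise ValidationError(f"focus TF {focus_tf!r} not among supplied TFs")
    tfs = list(de_by_tf)
    riis_de = de_riis[de_riis["call"] != CALL_UNCHANGED]
    rows = []
    for gene, riis_call in riis_de["call"].items():
        calls = {}
        for tf, de in de_by_tf.items():
            call = de["call"].get(gene, CALL_UNCHANGED)
            if call != CALL_UNCHANGED:
                calls[tf] = call
        if len(calls) < 2:
            continue
        row = {"gene_id": gene, "riis": _SIGN[riis_call]}
        for tf in tfs:
            row[tf] = _SIGN[calls.get(tf, CALL_UNCHANGED)]
        rows.append(row)
    per_gene = pd.DataFrame(rows, columns=["gene_id", *tfs, "riis"])
    if per_gene.empty:
        per_gene = per_gene.set_index(pd.Index([], name="gene_id"))
        patterns = pd.DataFrame(columns=[*tfs, "riis", "n_genes"])
        concordance = {tf: float("nan") for tf in tfs}
        return DominanceTable(per_gene=per_gene, patterns=patterns,
                              concordance=concordance, focus_tf=focus_tf,
                              margin=margin, dominant=False)
    per_gene = per_gene.set_index("gene_id")
    patterns = (per_gene.groupby([*tfs, "riis"], sort=True).size()
                .reset_index(name="n_genes")
                .sort_values("n_genes", ascending=False, kind="stable")
                .reset_index(drop=True))
    concordance = {}
    for tf in tfs:
        involved = per_gene[per_gene[tf] != "."]
        concordance[tf] = (float((involved[tf] == involved["riis"]).mean())
                           if len(involved) else float("nan"))
    focus = concordance[focus_tf]
    others = [v for tf, v in concordance.items() if tf != focus_tf and np.isfinite(v)]
    dominant = bool(np.isfinite(focus) and focus >= margin
                    and all(focus >= v for v in others))
    return DominanceTable(per_gene=per_gene, patterns=patterns,
                          concordance=concordance, focus_tf=focus_tf,
                          margin=margin, dominant=dominant)
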