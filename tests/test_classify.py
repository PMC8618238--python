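"""Cross-tabulation, reversal, quadrant and dominance classification."""

import numpy as np
import pandas as pd
import pytest

from riisdeg import (ComparisonSpec, ValidationError, combined_dependence_pct,
                     default_design, differential_expression,
                     dominance_patterns, generate_truth, quadrant_classify,
                     reversal_analysis, riis_dependence_crosstab,
                     simulate_counts, true_riis_log2fc)
from riisdeg.simulate import GeneratorConfig, TruthTable
from conftest import build_count_matrix


def de_frame(calls: dict, log2fc: dict | None = None,
             rpkm: float = 50.0) -> pd.DataFrame:
    genes = list(calls)
    fc = {g: (log2fc or {}).get(g, {"activated": 2.0, "repressed": -2.0,
                                    "unchanged": 0.0}[calls[g]])
          for g in genes}
    return pd.DataFrame({
        "fc": [2.0 ** fc[g] for g in genes],
        "log2fc": [fc[g] for g in genes],
        "p": [0.001 if calls[g] != "unchanged" else 0.8 for g in genes],
        "call": [calls[g] for g in genes],
        "mean_rpkm_test": rpkm,
        "mean_rpkm_baseline": rpkm,
    }, index=pd.Index(genes, name="gene_id"))


class TestCrossTab:
    @pytest.mark.parametrize("k_act,k_rep,n_act,n_rep,expected", [
        (601, 696, 1127, 1499, 49.4),   # DAF-16
        (928, 989, 1960, 2568, 42.3),   # HSF-1
    ])
    def test_published_combined_fractions(self, k_act, k_rep, n_act, n_rep,
                                          expected):
        assert combined_dependence_pct(k_act, k_rep, n_act, n_rep) == expected

    def test_counts_and_fractions_on_small_fixture(self):
        universe = [f"g{i}" for i in range(12)]
        de_riis = de_frame({g: c for g, c in zip(universe, [
            "activated", "activated", "activated", "repressed", "repressed",
            "unchanged", "unchanged", "unchanged", "unchanged", "unchanged",
            "unchanged", "unchanged"])})
        de_tf = de_frame({g: c for g, c in zip(universe, [
            "activated", "activated", "unchanged", "repressed", "unchanged",
            "repressed", "activated", "unchanged", "unchanged", "unchanged",
            "unchanged", "unchanged"])})
        ct = riis_dependence_crosstab(de_riis, de_tf)
        assert ct.activated.k == 2 and ct.activated.n_riis == 3
        assert ct.repressed.k == 1 and ct.repressed.n_tf == 2
        # (2 + 1) / (3 + 2) = 60%
        assert ct.combined_fraction_pct == 60.0
        assert ct.activated.fraction_of_tf == pytest.approx(2 / 3)

    def test_empty_tf_side_gives_zero_fractions(self):
        genes = [f"g{i}" for i in range(5)]
        de_riis = de_frame(dict.fromkeys(genes, "activated"))
        de_tf = de_frame(dict.fromkeys(genes, "unchanged"))
        ct = riis_dependence_crosstab(de_riis, de_tf)
        assert ct.activated.k == 0 and ct.combined_fraction == 0.0

    def test_universe_mismatch_rejected(self):
        de_a = de_frame({"g1": "activated"})
        de_b = de_frame({"g2": "activated"})
        with pytest.raises(ValidationError, match="universe"):
            riis_dependence_crosstab(de_a, de_b)


def _reversal_fixture(kd_equals: str):
    """Three groups x 2 reps; 6 genes strongly perturbed in rIIS; the knockdown
    group copies either the control or the rIIS columns."""
    genes = {}
    for i in range(3):
        genes[f"up{i}"] = {"ctrl": 100, "riis": 1000}
        genes[f"dn{i}"] = {"ctrl": 1000, "riis": 100}
    counts = {}
    for g, v in genes.items():
        kd = v[{"control": "ctrl", "riis": "riis"}[kd_equals]]
        counts[g] = {"C_1": v["ctrl"], "C_2": v["ctrl"],
                     "R_1": v["riis"], "R_2": v["riis"],
                     "K_1": kd, "K_2": kd}
    libs = {s: 10**6 for s in ("C_1", "C_2", "R_1", "R_2", "K_1", "K_2")}
    groups = {"C_1": "C", "C_2": "C", "R_1": "R", "R_2": "R",
              "K_1": "K", "K_2": "K"}
    return build_count_matrix(counts, library_sizes=libs, groups=groups)


class TestReversal:
    def test_knockdown_identical_to_control_fully_reverts(self):
        cm = _reversal_fixture("control")
        de_riis = differential_expression(cm, ComparisonSpec("riis", "R", "C"))
        assert (de_riis["call"] != "unchanged").sum() == 6
        rev = reversal_analysis(cm, de_riis, tf_group="K", control_group="C")
        assert rev.fraction_activated == 1.0
        assert rev.fraction_repressed == 1.0

    def test_knockdown_identical_to_riis_reverts_nothing(self):
        cm = _reversal_fixture("riis")
        de_riis = differential_expression(cm, ComparisonSpec("riis", "R", "C"))
        rev = reversal_analysis(cm, de_riis, tf_group="K", control_group="C")
        assert rev.fraction_activated == 0.0
        assert rev.fraction_repressed == 0.0
        assert rev.analyzed_activated == 3 and rev.analyzed_repressed == 3

    def test_unknown_group_rejected(self):
        cm = _reversal_fixture("control")
        de_riis = differential_expression(cm, ComparisonSpec("riis", "R", "C"))
        with pytest.raises(ValidationError):
            reversal_analysis(cm, de_riis, tf_group="missing", control_group="C")

    def test_true_daf16_targets_revert_on_daf16_knockdown(self, default_sim):
        """With efficient RNAi (residual 0.1) nearly all true DAF-16 targets
        return to control levels."""
        cm = default_sim.counts
        de_riis = differential_expression(cm, ComparisonSpec("riis", "rIIS-C", "C"))
        truth = default_sim.truth.table.set_index("gene_id")
        targets = truth.index[truth["effect_daf16"] != 0]
        rev = reversal_analysis(cm, de_riis.loc[de_riis.index.intersection(targets)],
                                tf_group="rIIS-daf16i", control_group="C")
        assert rev.analyzed_activated + rev.analyzed_repressed > 200
        assert rev.fraction_activated >= 0.8
        assert rev.fraction_repressed >= 0.8

    def test_reversal_monotone_in_knockdown_residual(self):
        """A cleaner knockdown (residual 0) reverts at least as large a
        fraction as a leaky one (residual 0.5), other things equal."""
        truth = generate_truth(4000, GeneratorConfig(), seed=21)
        fractions = {}
        for residual in (0.0, 0.5):
            design = default_design(residual_knockdown=residual)
            ds = simulate_counts(truth, design, "daf16_dominant", seed=22)
            de_riis = differential_expression(
                ds.counts, ComparisonSpec("riis", "rIIS-C", "C"))
            rev = reversal_analysis(ds.counts, de_riis, tf_group="rIIS-daf16i",
                                    control_group="C")
            total_analyzed = rev.analyzed_activated + rev.analyzed_repressed
            fractions[residual] = (rev.reverted_activated
                                   + rev.reverted_repressed) / total_analyzed
        assert fractions[0.0] >= fractions[0.5]


class TestQuadrants:
    def test_all_positive_pairs_land_in_q1(self):
        genes = [f"g{i}" for i in range(10)]
        x = pd.Series(1.0, index=genes)
        y = pd.Series(2.0, index=genes)
        qt = quadrant_classify(x, y, genes)
        assert qt.counts[1] == 10 and qt.percentages[1] == 100.0

    def test_one_gene_per_quadrant(self):
        genes = ["q1", "q2", "q3", "q4"]
        x = pd.Series([1.0, -1.0, -1.0, 1.0], index=genes)
        y = pd.Series([1.0, 1.0, -1.0, -1.0], index=genes)
        qt = quadrant_classify(x, y, genes)
        assert all(qt.percentages[q] == 25.0 for q in (1, 2, 3, 4))
        assert qt.same_direction_fraction == 0.5

    def test_exact_zero_fold_changes_excluded(self):
        genes = ["a", "b", "c"]
        x = pd.Series([1.0, 0.0, -1.0], index=genes)
        y = pd.Series([1.0, 1.0, -1.0], index=genes)
        qt = quadrant_classify(x, y, genes)
        assert qt.n_ties == 1 and qt.n_classified == 2
        assert sum(qt.percentages.values()) == pytest.approx(100.0, abs=0.1)

    def test_missing_gene_rejected(self):
        x = pd.Series([1.0], index=["a"])
        with pytest.raises(ValidationError):
            quadrant_classify(x, x, ["a", "zz"])

    def test_shared_targets_with_identical_signs_co_classify(self):
        """Two TFs regulating shared targets with the same sign put >= 95% of
        their common DE genes into quadrants 1 and 3 (mass-paired baselines)."""
        n = 3000
        rng = np.random.default_rng(30)
        eff = np.zeros(n)
        base = rng.normal(9.0, 1.5, n)
        for i in range(0, 400, 2):
            mag = rng.uniform(1.0, 3.0)
            eff[i] = mag
            eff[i + 1] = -mag
            base[i + 1] = base[i] + mag
        table = pd.DataFrame({
            "gene_id": [f"g{i:04d}" for i in range(n)],
            "baseline_log2": base,
            "effect_daf16": eff, "effect_skn1": eff, "effect_hsf1": 0.0,
            "riis_direct_log2": 0.0, "hs_direct_log2": 0.0,
            "dispersion": 0.05, "length_bp": 1000,
        })
        ds = simulate_counts(TruthTable(table=table), default_design(),
                             "additive", seed=31)
        de_d = differential_expression(ds.counts,
                                       ComparisonSpec("daf16", "rIIS-C", "rIIS-daf16i"))
        de_s = differential_expression(ds.counts,
                                       ComparisonSpec("skn1", "rIIS-C", "rIIS-skn1i"))
        genes = sorted(set(de_d.index[de_d["call"] != "unchanged"])
                       & set(de_s.index[de_s["call"] != "unchanged"]))
        assert len(genes) > 100
        qt = quadrant_classify(de_d["log2fc"], de_s["log2fc"], genes)
        assert qt.same_direction_fraction >= 0.95


class TestDominance:
    def test_unanimous_gene_single_pattern_full_concordance(self):
        de_by_tf = {tf: de_frame({"g1": "activated"})
                    for tf in ("daf16", "skn1", "hsf1")}
        de_riis = de_frame({"g1": "activated"})
        dom = dominance_patterns(de_by_tf, de_riis, focus_tf="daf16")
        assert len(dom.patterns) == 1
        row = dom.patterns.iloc[0]
        assert (row["daf16"], row["skn1"], row["hsf1"], row["riis"]) == \
            ("+", "+", "+", "+")
        assert all(c == 1.0 for c in dom.concordance.values())
        assert dom.dominant

    def test_focus_tf_opposing_riis_scores_zero(self):
        genes = {f"g{i}": "activated" for i in range(4)}
        de_by_tf = {
            "daf16": de_frame(genes),                       # TF says up
            "skn1": de_frame(dict.fromkeys(genes, "repressed")),
        }
        de_riis = de_frame(dict.fromkeys(genes, "repressed"))  # rIIS says down
        dom = dominance_patterns(de_by_tf, de_riis, focus_tf="daf16")
        assert dom.concordance["daf16"] == 0.0
        assert dom.concordance["skn1"] == 1.0
        assert not dom.dominant

    def test_fewer_than_two_tfs_rejected(self):
        with pytest.raises(ValidationError):
            dominance_patterns({"daf16": de_frame({"g1": "activated"})},
                               de_frame({"g1": "activated"}))

    def test_genes_must_be_shared_and_riis_de(self):
        de_by_tf = {
            "daf16": de_frame({"g1": "activated", "g2": "activated"}),
            "skn1": de_frame({"g1": "activated", "g2": "unchanged"}),
        }
        de_riis = de_frame({"g1": "activated", "g2": "activated"})
        dom = dominance_patterns(de_by_tf, de_riis, focus_tf="daf16")
        assert list(dom.per_gene.index) == ["g1"]  # g2 is single-TF

    def test_daf16_dominates_on_generative_dominance_rule(self, default_sim):
        """Under the daf16-dominant generative rule DAF-16's direction sets the
        rIIS direction of shared targets: concordance >= 0.9 and strictly above
        SKN-1 and HSF-1."""
        cm = default_sim.counts
        de_riis = differential_expression(cm, ComparisonSpec("riis", "rIIS-C", "C"))
        de_by_tf = {
            "daf16": differential_expression(cm, ComparisonSpec("daf16", "rIIS-C", "rIIS-daf16i")),
            "skn1": differential_expression(cm, ComparisonSpec("skn1", "rIIS-C", "rIIS-skn1i")),
            "hsf1": differential_expression(cm, ComparisonSpec("hsf1", "rIIS-C-HS", "rIIS-hsf1i-HS")),
        }
        dom = dominance_patterns(de_by_tf, de_riis, focus_tf="daf16")
        assert dom.per_gene.shape[0] > 300
        assert dom.concordance["daf16"] >= 0.9
        assert dom.concordance["daf16"] > dom.concordance["skn1"]
        assert dom.concordance["daf16"] > dom.concordance["hsf1"]
        assert dom.dominant
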