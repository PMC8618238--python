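"""Synthetic RNA-seq counts with known transcription-factor regulatory structure.

The generator emulates a seven-condition RNAi knockdown design in a reduced
insulin/IGF-1-signaling (rIIS) *C. elegans* background: empty-vector Control (C),
rIIS-Control, rIIS with daf-16 or skn-1 RNAi, and the three heat-shock (HS)
conditions used to probe HSF-1 (C-HS, rIIS-C-HS, rIIS with hsf-1 RNAi under HS),
two biological replicates each.

Each gene carries signed log2 effect sizes for DAF-16, SKN-1 and HSF-1 (positive
= the TF activates the gene), an optional TF-independent rIIS effect, a log2
baseline at reference sequencing depth, and a negative-binomial dispersion.
Per-sample TF activities (0..1) scale the effects; counts are drawn NB with
variance mu + d*mu^2.  Ground truth is retained so every downstream statistic
(differential calls, reversal, dominance) can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .quant import CountMatrix, write_dataset

TFS = ("daf16", "skn1", "hsf1")
TF_PAIRS = (("daf16", "skn1"), ("daf16", "hsf1"), ("skn1", "hsf1"))

GROUPS = (
    "C", "rIIS-C", "rIIS-daf16i", "rIIS-skn1i",
    "C-HS", "rIIS-C-HS", "rIIS-hsf1i-HS",
)
COMBINATION_RULES = ("additive", "daf16_dominant")


@dataclass
class GeneratorConfig:
    """Tunable knobs of the regulatory-architecture generator.

    Fractions refer to the share of genes targeted by exactly one, two, or all
    three TFs; the remainder is untargeted.  Effect magnitudes are |log2 FC|
    drawn Uniform(effect_low_log2, effect_high_log2) — the default spans
    FC 1.5 to FC 8, so true targets are detectable at the FC >= 1.5 call
    threshold.  Baselines are log2 expected counts at reference depth.
    """

    frac_single: float = 0.15
    frac_double: float = 0.08
    frac_triple: float = 0.04
    activator_fraction: float = 0.5
    effect_low_log2: float = float(np.log2(1.5))
    effect_high_log2: float = 3.0  # log2 8
    baseline_mean_log2: float = 9.0
    baseline_sd_log2: float = 2.0
    # Genes regulated jointly by several TFs form a small, lowly expressed
    # stress module; the offset keeps their induction from moving total
    # library composition (single-TF targets are mass-paired instead).
    shared_target_baseline_offset_log2: float = -3.0
    dispersion: float = 0.05
    riis_direct_fraction: float = 0.05
    length_log_mean: float = float(np.log(1300.0))
    length_log_sd: float = 0.6
    assignment: str = "deterministic"  # or "stochastic"
    hs_direct_fraction: float = 0.0  # optional HS response beyond HSF-1; off

    def validate(self) -> None:
        fr = (self.frac_single, self.frac_double, self.frac_triple,
              self.riis_direct_fraction, self.hs_direct_fraction)
        if any(f < 0 for f in fr):
            raise ConfigurationError(f"negative target fraction in {fr}")
        if self.frac_single + self.frac_double + self.frac_triple > 1.0 + 1e-12:
            raise ConfigurationError("target fractions sum to more than 1")
        if not 0.0 <= self.activator_fraction <= 1.0:
            raise ConfigurationError("activator_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.assignment not in ("deterministic", "stochastic"):
            raise ConfigurationError(f"unknown assignment mode {self.assignment!r}")
        if self.effect_low_log2 <= 0 or self.effect_high_log2 < self.effect_low_log2:
            raise ConfigurationError("effect magnitude range must be positive and ordered")


@dataclass
class TruthTable:
    """Per-gene generative ground truth; ``table`` columns:

    gene_id, baseline_log2, effect_daf16, effect_skn1, effect_hsf1 (signed log2
    magnitudes; 0 = not a target), riis_direct_log2, hs_direct_log2, dispersion,
    length_bp.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t["dispersion"] < 0).any():
            raise GenerationError("negative dispersion in truth table")
        if (t["length_bp"] < 1).any():
            raise GenerationError("length_bp < 1 in truth table")
        if not np.isfinite(t.select_dtypes("number").to_numpy()).all():
            raise GenerationError("non-finite value in truth table")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    def effect(self, tf: str) -> pd.Series:
        return self.table[f"effect_{tf}"]

    def n_targets(self, tf: str) -> int:
        return int((self.table[f"effect_{tf}"] != 0).sum())

    def targeted_by(self) -> pd.Series:
        """Number of TFs (0-3) targeting each gene."""
        return sum((self.table[f"effect_{tf}"] != 0).astype(int) for tf in TFS)


@dataclass
class DesignMatrix:
    """Sample sheet with per-TF activity coefficients and expected depth.

    ``table`` columns: sample_id, group, replicate, heat_shock, riis,
    activity_daf16, activity_skn1, activity_hsf1, library_size.
    """

    table: pd.DataFrame
    reference_depth: float = 2e7

    def __post_init__(self) -> None:
        for col in ("sample_id", "group", "replicate", "library_size"):
            if col not in self.table.columns:
                raise ConfigurationError(f"design matrix missing column {col!r}")
        acts = self.table[[f"activity_{tf}" for tf in TFS]].to_numpy()
        if ((acts < 0) | (acts > 1)).any():
            raise ConfigurationError("TF activities must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def activities(self, tf: str) -> np.ndarray:
        return self.table[f"activity_{tf}"].to_numpy(float)

    def group_activities(self, group: str) -> dict[str, float]:
        rows = self.table[self.table["group"] == group]
        if rows.empty:
            raise ConfigurationError(f"unknown group {group!r}")
        return {tf: float(rows[f"activity_{tf}"].iloc[0]) for tf in TFS}

    def sample_meta(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "group": list(self.table["group"]),
                "replicate": list(self.table["replicate"]),
                "heat_shock": list(self.table["heat_shock"].astype(int)),
                "rnai_target": [
                    {"rIIS-daf16i": "daf-16", "rIIS-skn1i": "skn-1",
                     "rIIS-hsf1i-HS": "hsf-1"}.get(g, "")
                    for g in self.table["group"]
                ],
            },
            index=pd.Index(self.table["sample_id"], name="sample_id"),
        )
        return meta


def default_design(n_replicates: int = 2, library_size: float = 2e7,
                   hsf1_basal: float = 0.2, residual_knockdown: float = 0.1,
                   reference_depth: float | None = None) -> DesignMatrix:
    """The seven-group RNAi design with two replicates per group.

    DAF-16 and SKN-1 are nuclear-active (activity 1) only under rIIS; HSF-1 has
    basal activity 0.2 that rises to 1 on heat shock.  RNAi knockdown leaves
    ``residual_knockdown`` (default 0.1) of the targeted TF's activity.
    """
    if n_replicates < 2:
        raise ConfigurationError("default design requires >= 2 replicates per group")
    res = residual_knockdown
    spec = {
        # group: (riis, hs, a_daf16, a_skn1, a_hsf1)
        "C":             (0, 0, 0.0, 0.0, hsf1_basal),
        "rIIS-C":        (1, 0, 1.0, 1.0, hsf1_basal),
        "rIIS-daf16i":   (1, 0, res, 1.0, hsf1_basal),
        "rIIS-skn1i":    (1, 0, 1.0, res, hsf1_basal),
        "C-HS":          (0, 1, 0.0, 0.0, 1.0),
        "rIIS-C-HS":     (1, 1, 1.0, 1.0, 1.0),
        "rIIS-hsf1i-HS": (1, 1, 1.0, 1.0, res),
    }
    rows = []
    for group in GROUPS:
        riis, hs, ad, as_, ah = spec[group]
        for rep in range(1, n_replicates + 1):
            rows.append({
                "sample_id": f"{group}_r{rep}",
                "group": group,
                "replicate": rep,
                "heat_shock": hs,
                "riis": riis,
                "activity_daf16": ad,
                "activity_skn1": as_,
                "activity_hsf1": ah,
                "library_size": float(library_size),
            })
    return DesignMatrix(
        table=pd.DataFrame(rows),
        reference_depth=float(library_size if reference_depth is None else reference_depth),
    )


# ---------------------------------------------------------------------------
# Truth generation


def generate_truth(n_genes: int, config: GeneratorConfig | None = None,
                   seed: int = 0) -> TruthTable:
    """Draw a regulatory truth table for ``n_genes`` genes.

    In ``deterministic`` assignment mode the numbers of genes targeted by
    exactly 1/2/3 TFs equal round(fraction * n_genes); single-TF genes are split
    evenly over the three TFs and double-TF genes over the three pairs.  In
    ``stochastic`` mode each gene's class is a categorical draw.  Effect signs
    alternate activator/repressor per TF so a 1:1 ratio is exact (within one
    gene for odd totals); magnitudes are Uniform(effect_low, effect_high).
    """
    config = config or GeneratorConfig()
    config.validate()
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)

    if config.assignment == "deterministic":
        n1 = int(round(config.frac_single * n_genes))
        n2 = int(round(config.frac_double * n_genes))
        n3 = int(round(config.frac_triple * n_genes))
        if n1 + n2 + n3 > n_genes:
            raise ConfigurationError("rounded target counts exceed n_genes")
        classes = np.zeros(n_genes, dtype=int)
        classes[:n1] = 1
        classes[n1:n1 + n2] = 2
        classes[n1 + n2:n1 + n2 + n3] = 3
    else:
        probs = [1.0 - config.frac_single - config.frac_double - config.frac_triple,
                 config.frac_single, config.frac_double, config.frac_triple]
        classes = rng.choice(4, size=n_genes, p=probs)

    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, n_genes)

    effects = {tf: np.zeros(n_genes) for tf in TFS}
    # per-TF running parity for the activator:repressor alternation; single-TF
    # repressors are mass-paired with queued single-TF activators so expected
    # transcriptional mass is conserved between full and zero TF activity
    parity = {tf: 0 for tf in TFS}
    unpaired_single_activators: dict[str, list[tuple[int, float]]] = {tf: [] for tf in TFS}

    def draw_signed(tf: str, idx: int, single: bool) -> None:
        if config.assignment == "deterministic":
            if config.activator_fraction == 0.5:
                positive = parity[tf] % 2 == 0
            else:
                quota = config.activator_fraction * (parity[tf] + 1)
                prior = config.activator_fraction * parity[tf]
                positive = int(quota) > int(prior)
            parity[tf] += 1
        else:
            positive = rng.random() < config.activator_fraction
        mag = rng.uniform(config.effect_low_log2, config.effect_high_log2)
        if positive:
            effects[tf][idx] = mag
            if single:
                unpaired_single_activators[tf].append((idx, mag))
        else:
            if single and unpaired_single_activators[tf]:
                j, mag_j = unpaired_single_activators[tf].pop()
                effects[tf][idx] = -mag_j
                # a repressed growth gene whose switched-off mass equals the
                # paired stress gene's induced mass: 2^b (2^e - 1) on each side
                baseline[idx] = baseline[j] + mag_j
            else:
                effects[tf][idx] = -mag

    single_rr = 0
    double_rr = 0
    # multi-TF genes are mirror-paired: the second gene of a bucket negates the
    # first's sign pattern at equal magnitudes, with its baseline offset by the
    # net log2 effect, so the pair's expected mass at full TF activity equals
    # its mass at zero activity
    pending_multi: dict[tuple, int] = {}
    for idx in range(n_genes):
        c = classes[idx]
        if c == 1:
            if config.assignment == "deterministic":
                tf = TFS[single_rr % 3]
                single_rr += 1
            else:
                tf = TFS[rng.integers(3)]
            draw_signed(tf, idx, single=True)
        elif c >= 2:
            if c == 2:
                if config.assignment == "deterministic":
                    bucket = TF_PAIRS[double_rr % 3]
                    double_rr += 1
                else:
                    bucket = TF_PAIRS[rng.integers(3)]
            else:
                bucket = TFS
            if bucket in pending_multi:
                j = pending_multi.pop(bucket)
                net = 0.0
                for tf in bucket:
                    effects[tf][idx] = -effects[tf][j]
                    net += effects[tf][j]
                baseline[idx] = baseline[j] + net
            else:
                for tf in bucket:
                    draw_signed(tf, idx, single=False)
                pending_multi[bucket] = idx

    multi = classes >= 2
    baseline[multi] += config.shared_target_baseline_offset_log2

    def overlay_paired(fraction: float, taken: np.ndarray) -> np.ndarray:
        """Signed paired effects on a fresh subset of unregulated genes."""
        out = np.zeros(n_genes)
        if fraction <= 0:
            return out
        pool = np.flatnonzero(~taken)
        n_sel = min(int(round(fraction * n_genes)), len(pool))
        idx = rng.choice(pool, size=n_sel, replace=False)
        mags = rng.uniform(config.effect_low_log2, config.effect_high_log2, n_sel)
        for pos in range(0, n_sel - 1, 2):
            i, j = idx[pos], idx[pos + 1]
            out[i] = mags[pos]
            out[j] = -mags[pos]
            baseline[j] = baseline[i] + mags[pos]
        if n_sel % 2:
            out[idx[-1]] = mags[-1]  # odd tail stays an unpaired activator
        return out

    targeted = (effects["daf16"] != 0) | (effects["skn1"] != 0) | (effects["hsf1"] != 0)
    riis_direct = overlay_paired(config.riis_direct_fraction, targeted)
    hs_direct = overlay_paired(config.hs_direct_fraction, targeted | (riis_direct != 0))
    lengths = np.maximum(
        200, np.round(rng.lognormal(config.length_log_mean, config.length_log_sd, n_genes))
    ).astype(int)

    width = len(str(n_genes))
    table = pd.DataFrame({
        "gene_id": [f"g{idx:0{width}d}" for idx in range(n_genes)],
        "baseline_log2": baseline,
        "effect_daf16": effects["daf16"],
        "effect_skn1": effects["skn1"],
        "effect_hsf1": effects["hsf1"],
        "riis_direct_log2": riis_direct,
        "hs_direct_log2": hs_direct,
        "dispersion": np.full(n_genes, float(config.dispersion)),
        "length_bp": lengths,
    })
    return TruthTable(table=table)


# ---------------------------------------------------------------------------
# Count simulation


def regulatory_log2_effect(truth: TruthTable, activities: dict[str, float],
                           riis: int, hs: int = 0,
                           combination_rule: str = "daf16_dominant",
                           dominance_cap: float = 0.5) -> np.ndarray:
    """Total per-gene log2 deviation from baseline for one condition.

    Under ``additive`` the TF contributions a_TF * effect_TF simply sum.  Under
    ``daf16_dominant`` the summed SKN-1 + HSF-1 contribution of every DAF-16
    target is clipped to at most ``dominance_cap`` times the magnitude of the
    DAF-16 contribution, so DAF-16 always sets the sign of the net regulation —
    the generative counterpart of DAF-16 dominance over shared targets.
    """
    if combination_rule not in COMBINATION_RULES:
        raise ConfigurationError(f"unknown combination rule {combination_rule!r}")
    t = truth.table
    c_d = activities["daf16"] * t["effect_daf16"].to_numpy()
    c_other = (activities["skn1"] * t["effect_skn1"].to_numpy()
               + activities["hsf1"] * t["effect_hsf1"].to_numpy())
    if combination_rule == "daf16_dominant":
        is_target = t["effect_daf16"].to_numpy() != 0
        cap = dominance_cap * np.abs(c_d)
        c_other = np.where(is_target, np.clip(c_other, -cap, cap), c_other)
    total = c_d + c_other
    total = total + riis * t["riis_direct_log2"].to_numpy()
    total = total + hs * t["hs_direct_log2"].to_numpy()
    return total


def expected_means(truth: TruthTable, design: DesignMatrix,
                   combination_rule: str = "daf16_dominant",
                   dominance_cap: float = 0.5) -> pd.DataFrame:
    """Expected NB mean mu(g, s) for every gene and sample."""
    cols = {}
    base = truth.table["baseline_log2"].to_numpy()
    for _, row in design.table.iterrows():
        acts = {tf: float(row[f"activity_{tf}"]) for tf in TFS}
        eff = regulatory_log2_effect(
            truth, acts, riis=int(row["riis"]), hs=int(row["heat_shock"]),
            combination_rule=combination_rule, dominance_cap=dominance_cap,
        )
        log2mu = base + np.log2(row["library_size"] / design.reference_depth) + eff
        cols[row["sample_id"]] = np.exp2(log2mu)
    mu = pd.DataFrame(cols, index=truth.gene_ids)
    if not np.isfinite(mu.to_numpy()).all():
        raise GenerationError("non-finite expected mean; check effect magnitudes")
    return mu


def true_riis_log2fc(truth: TruthTable, design: DesignMatrix,
                     combination_rule: str = "daf16_dominant",
                     dominance_cap: float = 0.5,
                     riis_group: str = "rIIS-C", control_group: str = "C") -> pd.Series:
    """Ground-truth log2 fold change of the rIIS condition over control."""
    hs = 1 if riis_group.endswith("HS") else 0
    e_r = regulatory_log2_effect(truth, design.group_activities(riis_group), riis=1,
                                 hs=hs, combination_rule=combination_rule,
                                 dominance_cap=dominance_cap)
    e_c = regulatory_log2_effect(truth, design.group_activities(control_group), riis=0,
                                 hs=hs, combination_rule=combination_rule,
                                 dominance_cap=dominance_cap)
    return pd.Series(e_r - e_c, index=truth.gene_ids)


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    truth: TruthTable
    design: DesignMatrix
    seed: int
    combination_rule: str = "daf16_dominant"


def simulate_counts(truth: TruthTable, design: DesignMatrix,
                    combination_rule: str = "daf16_dominant", seed: int = 0,
                    dominance_cap: float = 0.5) -> SimulatedDataset:
    """Draw the full count matrix: NB(mu, dispersion), Poisson when d = 0.

    The draw order (gene-major, sample-minor, one matrix call per dispersion
    regime) is fixed, so identical (truth, design, rule, seed) reproduce the
    counts bit-identically.
    """
    mu = expected_means(truth, design, combination_rule, dominance_cap)
    d = truth.table["dispersion"].to_numpy()[:, None]
    rng = np.random.default_rng(seed)
    m = mu.to_numpy()
    counts = np.empty(m.shape, dtype=np.int64)
    pois = (d == 0) | (m == 0)
    pois_rows = np.broadcast_to(pois, m.shape)
    counts[pois_rows] = rng.poisson(m[pois_rows])
    nb_mask = ~pois_rows
    if nb_mask.any():
        r = np.broadcast_to(1.0 / np.where(d == 0, 1.0, d), m.shape)[nb_mask]
        mm = m[nb_mask]
        counts[nb_mask] = rng.negative_binomial(r, r / (r + mm))
    count_df = pd.DataFrame(counts, index=truth.gene_ids, columns=design.sample_ids)
    cm = CountMatrix(
        counts=count_df,
        lengths=pd.Series(truth.table["length_bp"].to_numpy(),
                          index=truth.gene_ids, name="length_bp"),
        sample_meta=design.sample_meta(),
    )
    return SimulatedDataset(counts=cm, truth=truth, design=design, seed=seed,
                            combination_rule=combination_rule)


def simulate_dataset(n_genes: int = 16000, config: GeneratorConfig | None = None,
                     design: DesignMatrix | None = None,
                     combination_rule: str = "daf16_dominant",
                     seed: int = 0) -> SimulatedDataset:
    """Convenience wrapper: truth + default design + counts from one seed.

    Child seeds for the truth and count stages are spawned deterministically
    from ``seed`` via :class:`numpy.random.SeedSequence`.
    """
    ss = np.random.SeedSequence(seed)
    truth_seed, count_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    truth = generate_truth(n_genes, config, seed=truth_seed)
    design = design or default_design()
    dataset = simulate_counts(truth, design, combination_rule, seed=count_seed)
    dataset.seed = seed  # record the master seed, not the spawned child
    return dataset


def write_simulated(dataset: SimulatedDataset, outdir,
                    config: GeneratorConfig | None = None) -> dict[str, Path]:
    """Write counts/samples/lengths TSVs plus the truth table and run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_dataset(dataset.counts, outdir)
    truth_path = outdir / "truth.tsv"
    dataset.truth.table.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    meta = {
        "seed": dataset.seed,
        "combination_rule": dataset.combination_rule,
        "n_genes": int(dataset.truth.table.shape[0]),
        "reference_depth": dataset.design.reference_depth,
    }
    if config is not None:
        meta["generator_config"] = asdict(config)
    meta_path = outdir / "simulation.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["meta"] = meta_path
    return paths
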