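"""Oriented two-group differential expression on count data.

Fold changes are library-size-corrected ratios of group mean proportions — the
closed-form maximum-likelihood mean ratio of a two-group negative-binomial GLM
with a log link, library-size offsets and shared dispersion.  Significance comes
from a weighted two-proportion z-test in the style of Baggerly's beta-binomial
SAGE test: replicate proportions are combined with weights 1/(1/n_i + phi), with
the overdispersion phi estimated per gene by the method of moments, so at
phi = 0 the statistic reduces exactly to the classical pooled two-proportion
z-test.  Calls are thresholded at |FC| >= 1.5 and p <= 0.05 by default, with
boundary values included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ValidationError
from .quant import CountMatrix, mean_rpkm_by_group

CALL_ACTIVATED = "activated"
CALL_REPRESSED = "repressed"
CALL_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class ComparisonSpec:
    """An oriented comparison: ``test_group`` vs ``baseline_group``.

    Orientation contract: FC > 1 means higher expression in the test group, and
    such genes are called "activated".  Comparisons never mix heat-shock and
    normal-temperature groups.
    """

    name: str
    test_group: str
    baseline_group: str

    def validate(self, cm: CountMatrix) -> None:
        if self.test_group == self.baseline_group:
            raise ValidationError(f"{self.name}: test and baseline groups are equal")
        groups = set(cm.sample_meta["group"])
        for g in (self.test_group, self.baseline_group):
            if g not in groups:
                raise ValidationError(f"{self.name}: unknown group {g!r}")
        hs = {
            g: set(cm.sample_meta.loc[cm.sample_meta["group"] == g, "heat_shock"])
            for g in (self.test_group, self.baseline_group)
        }
        flags = hs[self.test_group] | hs[self.baseline_group]
        if len(flags) > 1:
            raise ValidationError(
                f"{self.name}: comparison mixes heat-shock and normal-temperature "
                f"groups ({self.test_group!r} vs {self.baseline_group!r})"
            )

    def swapped(self) -> "ComparisonSpec":
        return ComparisonSpec(name=f"{self.name}_swapped",
                              test_group=self.baseline_group,
                              baseline_group=self.test_group)


def _group_arrays(cm: CountMatrix, group: str) -> tuple[np.ndarray, np.ndarray]:
    samples = cm.samples_in_group(group)
    if not samples:
        raise ValidationError(f"group {group!r} has no samples")
    y = cm.counts[samples].to_numpy(np.float64)
    n = cm.library_sizes()[samples].to_numpy(np.float64)
    if (n <= 0).any():
        raise ValidationError(f"zero library size in group {group!r}")
    return y, n


# ---------------------------------------------------------------------------
# Fold change


def nbglm_fold_change(cm: CountMatrix, spec: ComparisonSpec,
                      pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene library-corrected fold change, test over baseline.

    fc(g) = (S_test / L_test) / (S_base / L_base) with S the group count sum and
    L the group library-size sum.  ``pseudocount`` is added to a group's sum
    only when that sum is zero, keeping typical genes unbiased while all fold
    changes stay finite and positive.
    """
    spec.validate(cm)
    y_t, n_t = _group_arrays(cm, spec.test_group)
    y_b, n_b = _group_arrays(cm, spec.baseline_group)
    s_t = y_t.sum(axis=1)
    s_b = y_b.sum(axis=1)
    if pseudocount > 0:
        s_t = np.where(s_t == 0, pseudocount, s_t)
        s_b = np.where(s_b == 0, pseudocount, s_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (s_t / n_t.sum()) / (s_b / n_b.sum())
        log2fc = np.log2(fc)
    return pd.DataFrame({"fc": fc, "log2fc": log2fc}, index=cm.gene_ids)


# ---------------------------------------------------------------------------
# Weighted-proportions (Baggerly-style) test


def _weighted_group_stats(y: np.ndarray, n: np.ndarray,
                          n_moment_iters: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean proportion and its variance for one group.

    y: genes x replicates counts; n: per-replicate library sizes.  Replicate
    proportions carry extra-binomial variance Var(p_i) = p(1-p)(1/n_i + phi_g)
    with phi_g = d * p_g under a shared NB dispersion d (Var(y) = mu + d mu^2).
    d is estimated by the method of moments POOLED across genes — a per-gene
    moment estimate from two replicates would make the statistic t-like and
    badly anti-conservative — and refined over ``n_moment_iters`` rounds
    (weighted means -> pooled residual variance -> weights), clamped at 0.
    The weights are w_i = 1/(1/n_i + phi_g); with equal replicate proportions
    in every gene d = 0 and the estimator collapses exactly to the pooled
    proportion sum(y)/sum(n) with binomial variance.
    """
    n_rep = y.shape[1]
    p = y / n  # genes x reps
    inv_n = 1.0 / n
    p_hat = y.sum(axis=1) / n.sum()
    if n_rep < 2:
        sw = np.full(y.shape[0], n.sum())
        return p_hat, np.maximum(p_hat * (1.0 - p_hat) / sw, 0.0)
    c = inv_n.mean()
    d = 0.0
    sw = np.full(y.shape[0], n.sum())
    for _ in range(max(1, n_moment_iters)):
        s2 = ((p - p_hat[:, None]) ** 2).sum(axis=1) / (n_rep - 1)
        pq = p_hat * (1.0 - p_hat)
        valid = pq > 0
        denom = (pq * p_hat)[valid].sum()
        d = max(0.0, float((s2 - pq * c)[valid].sum() / denom)) if denom > 0 else 0.0
        w = 1.0 / (inv_n[None, :] + d * p_hat[:, None])
        sw = w.sum(axis=1)
        p_hat = (w * p).sum(axis=1) / sw
    var = p_hat * (1.0 - p_hat) / sw
    return p_hat, np.maximum(var, 0.0)


def baggerley_test(cm: CountMatrix, spec: ComparisonSpec,
                   use_t: bool = False,
                   n_moment_iters: int = 2) -> pd.DataFrame:
    """Two-sided weighted-proportions test per gene; columns z, p.

    With a single replicate per group the test degrades to the phi = 0
    two-proportion z-test (with a warning).  When both groups have degenerate
    equal proportions the statistic is 0 and p = 1.  ``use_t`` swaps the normal
    reference for a t with (total replicates - 2) degrees of freedom.
    """
    spec.validate(cm)
    y_t, n_t = _group_arrays(cm, spec.test_group)
    y_b, n_b = _group_arrays(cm, spec.baseline_group)
    if y_t.shape[1] < 2 or y_b.shape[1] < 2:
        warnings.warn(
            "fewer than 2 replicates in a group: overdispersion cannot be "
            "estimated; falling back to the pooled two-proportion z-test",
            stacklevel=2,
        )
    p_t, v_t = _weighted_group_stats(y_t, n_t, n_moment_iters)
    p_b, v_b = _weighted_group_stats(y_b, n_b, n_moment_iters)
    se = np.sqrt(v_t + v_b)
    diff = p_t - p_b
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    if use_t:
        df = y_t.shape[1] + y_b.shape[1] - 2
        p = 2.0 * stats.t.sf(np.abs(z), df=df)
    else:
        p = 2.0 * special.ndtr(-np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame({"z": z, "p": p}, index=cm.gene_ids)


def pooled_two_proportion_z(y_test: np.ndarray, n_test: np.ndarray,
                            y_base: np.ndarray, n_base: np.ndarray) -> float:
    """Classical two-proportion z on replicate-pooled counts (no overdispersion).

    Reference statistic the weighted test must reproduce when the replicate
    proportions within each group are equal (phi-hat = 0).
    """
    p_t = y_test.sum() / n_test.sum()
    p_b = y_base.sum() / n_base.sum()
    v = p_t * (1 - p_t) / n_test.sum() + p_b * (1 - p_b) / n_base.sum()
    if v == 0:
        return 0.0 if p_t == p_b else float(np.sign(p_t - p_b) * np.inf)
    return float((p_t - p_b) / np.sqrt(v))


# ---------------------------------------------------------------------------
# Calls


def call_de(fc: pd.Series | np.ndarray, p: pd.Series | np.ndarray,
            fc_threshold: float = 1.5, alpha: float = 0.05) -> pd.Series | np.ndarray:
    """Classify genes as activated / repressed / unchanged.

    Activated iff fc >= fc_threshold and p <= alpha; repressed iff
    fc <= 1/fc_threshold and p <= alpha.  Boundary values are included
    ("at least 1.5", "p <= 0.05").
    """
    if fc_threshold <= 0 or alpha <= 0:
        raise ValidationError("thresholds must be positive")
    fc_arr = np.asarray(fc, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    call = np.full(fc_arr.shape, CALL_UNCHANGED, dtype=object)
    sig = p_arr <= alpha
    call[sig & (fc_arr >= fc_threshold)] = CALL_ACTIVATED
    call[sig & (fc_arr <= 1.0 / fc_threshold)] = CALL_REPRESSED
    if isinstance(fc, pd.Series):
        return pd.Series(call, index=fc.index, name="call")
    return call


def differential_expression(cm: CountMatrix, spec: ComparisonSpec,
                            fc_threshold: float = 1.5, alpha: float = 0.05,
                            pseudocount: float = 0.5, use_t: bool = False,
                            bh_correct: bool = False) -> pd.DataFrame:
    """Full DE table for one comparison.

    Columns: gene_id (index), fc, log2fc, z, p, call, mean_rpkm_test,
    mean_rpkm_baseline.  ``bh_correct`` applies Benjamini-Hochberg to the
    p-values before calling (off by default: calls use standard p-values).
    """
    fc_df = nbglm_fold_change(cm, spec, pseudocount=pseudocount)
    test_df = baggerley_test(cm, spec, use_t=use_t)
    p = test_df["p"]
    if bh_correct:
        p = pd.Series(stats.false_discovery_control(p.to_numpy(), method="bh"),
                      index=p.index, name="p")
    out = pd.DataFrame({
        "fc": fc_df["fc"],
        "log2fc": fc_df["log2fc"],
        "z": test_df["z"],
        "p": p,
        "call": call_de(fc_df["fc"], p, fc_threshold, alpha),
        "mean_rpkm_test": mean_rpkm_by_group(cm, spec.test_group),
        "mean_rpkm_baseline": mean_rpkm_by_group(cm, spec.baseline_group),
    })
    out.index.name = "gene_id"
    return out


def de_gene_sets(de: pd.DataFrame) -> dict[str, set]:
    """Gene-id sets for each call direction of a DE table."""
    return {
        CALL_ACTIVATED: set(de.index[de["call"] == CALL_ACTIVATED]),
        CALL_REPRESSED: set(de.index[de["call"] == CALL_REPRESSED]),
        "de": set(de.index[de["call"] != CALL_UNCHANGED]),
    }
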