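"""Gene-set overlap statistics: detection, common-gene filtering, Venn
partitions, representation factors and log-space hypergeometric tail p-values.

Overlap significance is the upper-tail probability P(X >= k) for
X ~ Hypergeometric(N, m, n).  The published overlaps reach p-values of order
10**-2700, far below double-precision underflow, so the tail sum is evaluated
entirely in log space with log-gamma terms and a log-sum-exp reduction and
reported as log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ValidationError
from .quant import CountMatrix, rpkm

DETECTION_RULES = ("all_replicates_nonzero", "mean_rpkm")
LN10 = np.log(10.0)


def pct_half_up(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded half-up at ``digits`` decimals (reporting convention)."""
    if denominator == 0:
        raise ValidationError("percentage with zero denominator")
    q = Decimal(100 * numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-digits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Detection and common-gene filtering


def detected_genes(cm: CountMatrix, group: str,
                   rule: str = "all_replicates_nonzero",
                   rpkm_floor: float = 10.0) -> set:
    """Genes considered expressed ("detected") in one sample group.

    ``all_replicates_nonzero``: at least one read in every replicate (default).
    ``mean_rpkm``: group mean RPKM >= ``rpkm_floor``.
    """
    if rule not in DETECTION_RULES:
        raise ValidationError(f"unknown detection rule {rule!r}")
    samples = cm.samples_in_group(group)
    if rule == "all_replicates_nonzero":
        mask = (cm.counts[samples] >= 1).all(axis=1)
    else:
        mask = rpkm(cm).values[samples].mean(axis=1) >= rpkm_floor
    return set(cm.gene_ids[mask])


def common_genes(set_a: set, set_b: set) -> tuple[set, set, set]:
    """(A intersect B, A-only, B-only); exclusives are dropped downstream."""
    common = set_a & set_b
    return common, set_a - common, set_b - common


# ---------------------------------------------------------------------------
# Hypergeometric tail in log space


def _check_hypergeom_args(k: int, m: int, n: int, N: int) -> None:
    if not (0 <= k <= min(m, n) <= N) or m > N or n > N or min(m, n) < 0:
        raise ValidationError(
            f"invalid hypergeometric arguments: k={k}, m={m}, n={n}, N={N} "
            "(require 0 <= k <= min(m, n) <= N)"
        )


def log_hypergeom_sf(k: int, m: int, n: int, N: int) -> float:
    """log10 P(X >= k) for X ~ Hypergeometric(N, m, n), underflow-free.

    The tail sum over j = k..min(m, n) uses log C(m, j) + log C(N-m, n-j) -
    log C(N, n) via ``gammaln`` combined with ``logsumexp``; values as small as
    log10 p ~ -3000 are returned exactly where a direct survival function
    would underflow to 0.
    """
    _check_hypergeom_args(k, m, n, N)
    j_lo = max(k, m + n - N, 0)
    j_hi = min(m, n)
    if k <= max(0, m + n - N):
        return 0.0  # the tail is the whole support
    j = np.arange(j_lo, j_hi + 1)

    def log_c(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_pmf = log_c(m, j) + log_c(N - m, n - j) - log_c(N, n)
    log_p = logsumexp(log_pmf)
    return float(min(log_p / LN10, 0.0))


def representation_factor(k: int, m: int, n: int, N: int) -> float:
    """Observed overlap over the overlap expected by chance: k*N / (m*n)."""
    if m <= 0 or n <= 0 or N <= 0:
        raise ValidationError(f"representation factor needs m, n, N > 0 (got {m}, {n}, {N})")
    return k * N / (m * n)


@dataclass(frozen=True)
class OverlapResult:
    """Enrichment summary of one pairwise gene-set overlap."""

    k: int
    m: int
    n: int
    N: int
    rf: float
    log10_p: float

    def to_dict(self) -> dict:
        return {"k": self.k, "m": self.m, "n": self.n, "N": self.N,
                "rf": self.rf, "log10_p": self.log10_p}


def overlap_test(set_a: set, set_b: set, universe: int,
                 tail: str = "over") -> OverlapResult:
    """Representation factor and hypergeometric tail for two gene sets.

    ``tail="over"`` (default) reports P(X >= k), the enrichment direction the
    study quotes; ``tail="under"`` reports P(X <= k) for depletion.
    """
    k, m, n = len(set_a & set_b), len(set_a), len(set_b)
    if max(m, n) > universe:
        raise ValidationError("universe smaller than a gene set")
    rf = representation_factor(k, m, n, universe) if m and n else 0.0
    if tail == "over":
        log10_p = log_hypergeom_sf(k, m, n, universe)
    elif tail == "under":
        # P(X <= k) = 1 - P(X >= k+1); evaluated via the complement tail
        upper = log_hypergeom_sf(min(k + 1, min(m, n)), m, n, universe) \
            if k < min(m, n) else None
        if upper is None:
            log10_p = 0.0
        else:
            log10_p = float(np.log10(max(1.0 - 10**upper, np.finfo(float).tiny)))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return OverlapResult(k=k, m=m, n=n, N=universe, rf=rf, log10_p=log10_p)


# ---------------------------------------------------------------------------
# Venn partitions


@dataclass
class VennPartition:
    """Exact region membership for 2 or 3 gene sets.

    ``regions`` maps a membership tuple over the set labels (e.g.
    ("daf16", "skn1")) to the genes found in exactly those sets.  Regions are
    pairwise disjoint and union to the union of the inputs.
    """

    labels: tuple
    regions: dict
    union: set

    def region_sizes(self) -> dict:
        return {key: len(genes) for key, genes in self.regions.items()}

    def summary(self) -> dict:
        """Counts and half-up percentages of the union by sharing degree."""
        by_degree = {1: 0, 2: 0, 3: 0}
        for key, genes in self.regions.items():
            by_degree[len(key)] += len(genes)
        total = len(self.union)
        out = {
            "union": total,
            "specific_to_one": by_degree[1],
            "shared_by_exactly_two": by_degree[2],
        }
        if len(self.labels) == 3:
            out["shared_by_all_three"] = by_degree[3]
            out["shared_by_at_least_two"] = by_degree[2] + by_degree[3]
        if total > 0:
            out["pct_specific_to_one"] = pct_half_up(by_degree[1], total)
            out["pct_shared_by_exactly_two"] = pct_half_up(by_degree[2], total)
            if len(self.labels) == 3:
                out["pct_shared_by_all_three"] = pct_half_up(by_degree[3], total)
                out["pct_shared_by_at_least_two"] = pct_half_up(
                    by_degree[2] + by_degree[3], total)
        return out


def venn_partition(sets: dict) -> VennPartition:
    """Partition 2 or 3 labelled gene sets into their exclusive Venn regions."""
    labels = tuple(sets)
    if len(labels) not in (2, 3):
        raise ValidationError("venn_partition takes exactly 2 or 3 sets")
    union = set().union(*sets.values())
    regions = {}
    for r in range(1, len(labels) + 1):
        for key in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in key))
            outside = set().union(*(sets[l] for l in labels if l not in key), set())
            regions[key] = inside - outside
    return VennPartition(labels=labels, regions=regions, union=union)


def partition_summary_from_counts(single: int, exactly_two: int, all_three: int) -> dict:
    """Sharing-degree summary straight from printed region totals.

    Lets published partition tables be re-expressed as percentages without the
    underlying gene lists.
    """
    union = single + exactly_two + all_three
    return {
        "union": union,
        "specific_to_one": single,
        "shared_by_exactly_two": exactly_two,
        "shared_by_all_three": all_three,
        "shared_by_at_least_two": exactly_two + all_three,
        "pct_specific_to_one": pct_half_up(single, union),
        "pct_shared_by_exactly_two": pct_half_up(exactly_two, union),
        "pct_shared_by_all_three": pct_half_up(all_three, union),
        "pct_shared_by_at_least_two": pct_half_up(exactly_two + all_three, union),
    }
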