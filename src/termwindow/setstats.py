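"""Set-overlap and proportion statistics for unit-id cohorts.

Overlaps are tested against the hypergeometric null (draw |A| units from
the universe, count hits in B); proportions are compared with Fisher's
exact test.  Both carry exhaustive-enumeration oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class OverlapResult:
    universe_size: int
    size_a: int
    size_b: int
    intersection: int
    overlap_fraction: float  #: |A n B| / |A|
    p_enrichment: float  #: P(X >= observed) under the hypergeometric null
    p_depletion: float  #: P(X <= observed)
    method: str = "exact hypergeometric"


def _check_subsets(a: set, b: set, universe: set) -> None:
    stray_a = a - universe
    stray_b = b - universe
    if stray_a or stray_b:
        raise ValidationError(
            f"sets not contained in universe; offenders: "
            f"A-only {sorted(stray_a)[:5]}, B-only {sorted(stray_b)[:5]}"
        )


def overlap_test(a: Iterable, b: Iterable, universe: Iterable) -> OverlapResult:
    """Hypergeometric enrichment/depletion test for two unit-id sets."""
    a, b, universe = set(a), set(b), set(universe)
    _check_subsets(a, b, universe)
    n, ka, kb = len(universe), len(a), len(b)
    k = len(a & b)
    dist = stats.hypergeom(n, kb, ka)  # hits in a draw of |A| from universe
    p_enr = float(dist.sf(k - 1))
    p_dep = float(dist.cdf(k))
    return OverlapResult(
        universe_size=n,
        size_a=ka,
        size_b=kb,
        intersection=k,
        overlap_fraction=k / ka if ka else float("nan"),
        p_enrichment=min(p_enr, 1.0),
        p_depletion=min(p_dep, 1.0),
    )


def overlap_test_permutation(
    a: Iterable,
    b: Iterable,
    universe: Iterable,
    strata: Optional[dict] = None,
    n_perm: int = 9999,
    seed: Optional[int] = None,
) -> OverlapResult:
    """Label-permutation variant; supports stratified universes (e.g. by class).

    A's membership labels are shuffled within each stratum; p includes the
    identity permutation so it is never 0.
    """
    a, b, universe = set(a), set(b), set(universe)
    _check_subsets(a, b, universe)
    members = sorted(universe)
    strata = strata or {m: 0 for m in members}
    rng = np.random.default_rng(seed)
    observed = len(a & b)
    labels = np.array([m in a for m in members])
    in_b = np.array([m in b for m in members])
    groups = np.array([strata[m] for m in members])
    hits = 0
    for _ in range(n_perm):
        permuted = labels.copy()
        for g in np.unique(groups):
            sel = groups == g
            permuted[sel] = rng.permutation(permuted[sel])
        if int((permuted & in_b).sum()) >= observed:
            hits += 1
    p_enr = (1 + hits) / (1 + n_perm)
    return OverlapResult(
        universe_size=len(universe),
        size_a=len(a),
        size_b=len(b),
        intersection=observed,
        overlap_fraction=observed / len(a) if a else float("nan"),
        p_enrichment=p_enr,
        p_depletion=float("nan"),
        method=f"permutation (n={n_perm})",
    )


class ProportionComparison(NamedTuple):
    p_value: float  #: two-sided Fisher exact p
    odds_ratio: float  #: Haldane-corrected when any cell is zero


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> ProportionComparison:
    """Fisher's exact two-sided test on the 2x2 table (k1/n1 vs k2/n2)."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n <= 0:
            raise ValidationError(f"invalid proportion {k}/{n}")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    result = stats.fisher_exact(table, alternative="two-sided")
    cells = (k1, n1 - k1, k2, n2 - k2)
    if 0 in cells:
        a, b, c, d = (x + 0.5 for x in cells)  # Haldane correction
        odds = (a * d) / (b * c)
    else:
        a, b, c, d = cells
        odds = (a * d) / (b * c)
    return ProportionComparison(p_value=float(result.pvalue), odds_ratio=float(odds))


class VennCounts(NamedTuple):
    only_a: int
    only_b: int
    both: int
    neither: int


def venn_counts(a: Iterable, b: Iterable, universe: Iterable) -> VennCounts:
    """Four-way partition of the universe by membership in A and B."""
    a, b, universe = set(a), set(b), set(universe)
    _check_subsets(a, b, universe)
    both = len(a & b)
    return VennCounts(
        only_a=len(a) - both,
        only_b=len(b) - both,
        both=both,
        neither=len(universe) - len(a | b),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Single BH pass over an emitted battery of p-values."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if n == 0:
        return []
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adjusted[idx] = running
    return adjusted.tolist()
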