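"""Site-level gamete/zygote combinatorics and compatibility predicates.

At a single SNP site, a parent with genotype multiset G can transmit any
size-k multiset drawn *with repetition* from the distinct alleles of G (so a
parent ATT can give diploid gametes AA, AT or TT). A (child, parent1, parent2)
trio is compatible under a gamete-ploidy split (k1, k2) when the child's
multiset equals some union of a k1-gamete from parent1 with a k2-gamete from
parent2. Duo tests ask whether *some* 1x or 2x gamete of the parent fits
inside the child, and the full-restitution test whether the parent's entire
genotype is contained in the child — the genome-wide signature of an
un-recombined unreduced (2x^c / 3x^c) gamete.

Alleles are small integers (indices into a site's allele list); genotypes are
sorted tuples. Everything here is pure and memoised so that genome-wide scans
reduce to dictionary lookups over the few distinct genotype patterns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations_with_replacement
from math import comb

__all__ = [
    "GameteSet",
    "SiteVerdict",
    "enumerate_gametes",
    "enumerate_zygotes",
    "site_trio_compatible",
    "site_duo_1x",
    "site_duo_2x",
    "site_full_restitution",
    "legal_configurations",
]

Multiset = tuple[int, ...]


@dataclass(frozen=True)
class GameteSet:
    """All allele multisets of size k transmissible by one parent at one site."""

    k: int
    multisets: frozenset[Multiset]


@dataclass(frozen=True)
class SiteVerdict:
    compatible: bool
    configuration: tuple[int, int]


@lru_cache(maxsize=None)
def enumerate_gametes(parent_genotype: Multiset, k: int) -> GameteSet:
    """All combinations of k alleles, with repetition and without order,
    sampled among the distinct alleles of the parent genotype.

    The count is C(n+k-1, k) for n distinct parental alleles: an allele
    present once in the parent may still fill the whole gamete.
    """
    if k < 1:
        raise ValueError(f"gamete ploidy k must be >= 1, got {k}")
    if not parent_genotype:
        raise ValueError("parent genotype must be non-missing")
    distinct = sorted(set(parent_genotype))
    multisets = frozenset(combinations_with_replacement(distinct, k))
    assert len(multisets) == comb(len(distinct) + k - 1, k)
    return GameteSet(k=k, multisets=multisets)


@lru_cache(maxsize=None)
def _zygotes(g1: GameteSet, g2: GameteSet) -> frozenset[Multiset]:
    out = set()
    for a in g1.multisets:
        for b in g2.multisets:
            out.add(tuple(sorted(a + b)))
    return frozenset(out)


def enumerate_zygotes(g1: GameteSet, g2: GameteSet) -> frozenset[Multiset]:
    """All multiset unions of one gamete from each set (size k1+k2 each)."""
    return _zygotes(g1, g2)


@lru_cache(maxsize=None)
def site_trio_compatible(
    child: Multiset, p1: Multiset, p2: Multiset, k1: int, k2: int
) -> SiteVerdict:
    """Is the child's allele multiset among the zygotes producible by a
    k1-gamete of p1 combined with a k2-gamete of p2?"""
    if k1 + k2 != len(child):
        raise ValueError(
            f"gamete ploidies {k1}+{k2} do not sum to child ploidy {len(child)}"
        )
    child = tuple(sorted(child))
    zyg = _zygotes(enumerate_gametes(tuple(sorted(p1)), k1),
                   enumerate_gametes(tuple(sorted(p2)), k2))
    return SiteVerdict(compatible=child in zyg, configuration=(k1, k2))


def _contains(outer: Multiset, inner: Multiset) -> bool:
    return not Counter(inner) - Counter(outer)


@lru_cache(maxsize=None)
def site_duo_1x(child: Multiset, parent: Multiset) -> bool:
    """True iff at least one distinct parental allele occurs in the child."""
    return bool(set(parent) & set(child))


@lru_cache(maxsize=None)
def site_duo_2x(child: Multiset, parent: Multiset) -> bool:
    """True iff some diploid gamete of the parent (recombined or not) fits
    inside the child multiset. Child must be at least triploid."""
    if len(child) < 3:
        raise ValueError(f"2x test needs child ploidy >= 3, got {len(child)}")
    return any(
        _contains(child, g) for g in enumerate_gametes(parent, 2).multisets
    )


@lru_cache(maxsize=None)
def site_full_restitution(child: Multiset, parent: Multiset) -> bool:
    """True iff the parent's full genotype multiset is contained in the child's
    — per-site support for an un-recombined unreduced gamete (2x^c / 3x^c)."""
    return _contains(child, parent)


def legal_configurations(
    child_ploidy: int, p1_ploidy: int, p2_ploidy: int
) -> list[tuple[int, int]]:
    """Gamete-ploidy splits (k1, k2) tested for a child of given ploidy.

    A parent can give a gamete of ploidy 1..its own ploidy; 3x gametes are
    only tested for tetraploid children (triploid x triploid crosses test the
    {1,2} splits, not 3+0 — a zygote needs two gametes).
    """
    out = []
    for k1 in range(1, min(p1_ploidy, 3) + 1):
        k2 = child_ploidy - k1
        if not 1 <= k2 <= min(p2_ploidy, 3):
            continue
        if (k1 == 3 or k2 == 3) and child_ploidy != 4:
            continue
        out.append((k1, k2))
    return out
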