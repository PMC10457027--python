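"""Independent brute-force oracles for site-level compatibility predicates.

These enumerate ordered allele draws exhaustively (itertools.product over the
distinct parental alleles) and compare raw sorted tuples — deliberately
sharing no code with the package's combinatorics.
"""

from collections import Counter
from itertools import product


def brute_gametes(genotype, k):
    return {tuple(sorted(t)) for t in product(sorted(set(genotype)), repeat=k)}


def brute_zygotes(p1, p2, k1, k2):
    return {
        tuple(sorted(g1 + g2))
        for g1 in brute_gametes(p1, k1)
        for g2 in brute_gametes(p2, k2)
    }


def brute_trio_compatible(child, p1, p2, k1, k2):
    return tuple(sorted(child)) in brute_zygotes(p1, p2, k1, k2)


def contains(outer, inner):
    return not Counter(inner) - Counter(outer)


def brute_duo_1x(child, parent):
    return any(contains(child, g) for g in brute_gametes(parent, 1))


def brute_duo_2x(child, parent):
    return any(contains(child, g) for g in brute_gametes(parent, 2))


def brute_full_restitution(child, parent):
    return contains(child, parent)
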