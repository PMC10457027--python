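"""Genome-wide trio/duo concordance statistics and selection rules.

For every candidate (child, parent pair) and every legal gamete-ploidy split,
the trio statistic is the proportion of SNP sites at which the child's allele
multiset is among the zygotes producible by the parents. Trios are accepted
when that proportion reaches a calibrated threshold (default 0.999, the
minimum observed for synthetic first-generation hybrids with known parents)
and, among accepted pairs for one child, only those with minimal cumulative
parental ploidy are kept — diploids are more plausible parents than
triploids. Duo statistics test a single parent's 1x, 2x, and complete-genome
(un-recombined unreduced gamete) contribution.

Scans are vectorised by packing each site's genotype pattern into an integer
key and evaluating each distinct pattern once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from . import parentage_core as pc
from .vcfio import GenotypeMatrix, relation_polymorphic_filter

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "TrioResult",
    "DuoResult",
    "trio_statistic",
    "scan_all_trios",
    "select_trios",
    "duo_statistic",
    "scan_all_duos",
    "label_gamete_types",
    "verdict_vector_trio",
    "verdict_vector_duo",
    "verdict_vector_restitution",
]


@dataclass
class ScanConfig:
    """Selection thresholds for genome-wide scans."""

    trio_threshold: float = 0.999
    duo_threshold: float = 0.99
    apply_min_ploidy_rule: bool = True

    def __post_init__(self) -> None:
        for name in ("trio_threshold", "duo_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1], got {v}")


@dataclass
class TrioResult:
    child: str
    p1: str
    p2: str
    # (k1, k2) -> (n_tested, n_compatible)
    configurations: dict[tuple[int, int], tuple[int, int]]

    def proportion(self, k1: int, k2: int) -> float:
        n_tested, n_comp = self.configurations[(k1, k2)]
        return n_comp / n_tested if n_tested else float("nan")

    def best(self) -> tuple[tuple[int, int], float]:
        best_cfg = max(
            self.configurations,
            key=lambda c: (self.proportion(*c) if self.configurations[c][0] else -1.0),
        )
        return best_cfg, self.proportion(*best_cfg)


@dataclass
class DuoResult:
    child: str
    parent: str
    n_tested: int
    prop_1x: float
    prop_2x: float | None          # None for diploid children
    prop_full: float | None        # complete-genome (unreduced) restitution


# ---------------------------------------------------------------------------
# Vectorised per-site verdicts
# ---------------------------------------------------------------------------

def _decode(code: int) -> tuple[int, ...]:
    out = []
    for _ in range(4):
        v = code & 0x7
        code >>= 3
        if v:
            out.append(v - 1)
    return tuple(out)


def verdict_vector_trio(
    m: GenotypeMatrix, child: str, p1: str, p2: str, k1: int, k2: int
) -> np.ndarray:
    """Per-site verdict: 1.0 compatible, 0.0 incompatible, NaN untested
    (any member missing, or the child's effective ploidy != k1+k2)."""
    cc = m.genotype_codes(child).astype(np.uint64)
    c1 = m.genotype_codes(p1).astype(np.uint64)
    c2 = m.genotype_codes(p2).astype(np.uint64)
    key = (cc << np.uint64(24)) | (c1 << np.uint64(12)) | c2
    valid = (cc != 0) & (c1 != 0) & (c2 != 0)
    out = np.full(m.n_sites, np.nan)
    if not valid.any():
        return out
    keys = key[valid]
    uniq, inv = np.unique(keys, return_inverse=True)
    verdicts = np.empty(len(uniq))
    for i, k in enumerate(uniq):
        child_ms = _decode(int(k) >> 24)
        if len(child_ms) != k1 + k2:
            verdicts[i] = np.nan
            continue
        p1_ms = _decode((int(k) >> 12) & 0xFFF)
        p2_ms = _decode(int(k) & 0xFFF)
        v = pc.site_trio_compatible(child_ms, p1_ms, p2_ms, k1, k2)
        verdicts[i] = 1.0 if v.compatible else 0.0
    out[valid] = verdicts[inv]
    return out


def _verdict_vector_pair(m, child, parent, predicate) -> np.ndarray:
    cc = m.genotype_codes(child).astype(np.uint32)
    cp = m.genotype_codes(parent).astype(np.uint32)
    key = (cc << np.uint32(12)) | cp
    valid = (cc != 0) & (cp != 0)
    out = np.full(m.n_sites, np.nan)
    if not valid.any():
        return out
    uniq, inv = np.unique(key[valid], return_inverse=True)
    verdicts = np.empty(len(uniq))
    for i, k in enumerate(uniq):
        child_ms = _decode(int(k) >> 12)
        parent_ms = _decode(int(k) & 0xFFF)
        verdicts[i] = predicate(child_ms, parent_ms)
    out[valid] = verdicts[inv]
    return out


def verdict_vector_duo(m: GenotypeMatrix, child: str, parent: str, k: int) -> np.ndarray:
    """Per-site duo verdict for a gamete of ploidy k in {1, 2}."""
    if k == 1:
        pred = lambda c, p: 1.0 if pc.site_duo_1x(c, p) else 0.0
    elif k == 2:
        def pred(c, p):
            if len(c) < 3:
                return np.nan
            return 1.0 if pc.site_duo_2x(c, p) else 0.0
    else:
        raise ValueError(f"duo gamete ploidy must be 1 or 2, got {k}")
    return _verdict_vector_pair(m, child, parent, pred)


def verdict_vector_restitution(m: GenotypeMatrix, child: str, parent: str) -> np.ndarray:
    """Per-site verdict for complete parental-genome restitution (2x^c / 3x^c)."""
    def pred(c, p):
        if len(c) <= len(p):
            return np.nan
        return 1.0 if pc.site_full_restitution(c, p) else 0.0
    return _verdict_vector_pair(m, child, parent, pred)


# ---------------------------------------------------------------------------
# Trio scan
# ---------------------------------------------------------------------------

def trio_statistic(
    m: GenotypeMatrix,
    child: str,
    p1: str,
    p2: str,
    configs: list[tuple[int, int]] | None = None,
) -> TrioResult:
    """Genome-wide concordance for one candidate trio, per gamete-ploidy split.

    Both orderings of asymmetric splits are reported (parent 1 as the 1x donor
    and parent 2 as the 2x donor, and the reverse). The caller is expected to
    pre-filter the matrix to the relevant polymorphic site set.
    """
    if child in (p1, p2):
        raise ValueError(f"child {child!r} cannot be one of its own tested parents")
    cp = m.accession(child).ploidy
    if configs is None:
        configs = pc.legal_configurations(
            cp, m.accession(p1).ploidy, m.accession(p2).ploidy
        )
    result: dict[tuple[int, int], tuple[int, int]] = {}
    for k1, k2 in configs:
        v = verdict_vector_trio(m, child, p1, p2, k1, k2)
        tested = np.isfinite(v)
        result[(k1, k2)] = (int(tested.sum()), int(np.nansum(v)))
    return TrioResult(child=child, p1=p1, p2=p2, configurations=result)


def scan_all_trios(
    m: GenotypeMatrix,
    children: list[str],
    parents: list[str],
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Scan every (child, unordered parent pair) including self-pairs
    (selfing hypothesis), one representative per clone set, in deterministic
    order. Returns one row per configuration."""
    cfg = cfg or ScanConfig()
    children = m.clone_representatives(children)
    parents = m.clone_representatives(parents)
    rows = []
    for child in sorted(children):
        cands = [p for p in sorted(parents) if p != child]
        for p1, p2 in combinations_with_replacement(cands, 2):
            res = trio_statistic(m, child, p1, p2)
            for (k1, k2), (n_t, n_c) in sorted(res.configurations.items()):
                rows.append(
                    {
                        "child": child,
                        "child_ploidy": m.accession(child).ploidy,
                        "p1": p1,
                        "p2": p2,
                        "p1_ploidy": m.accession(p1).ploidy,
                        "p2_ploidy": m.accession(p2).ploidy,
                        "k1": k1,
                        "k2": k2,
                        "n_tested": n_t,
                        "n_compatible": n_c,
                        "proportion": n_c / n_t if n_t else np.nan,
                    }
                )
    df = pd.DataFrame(rows)
    logger.info("scan_all_trios: %d rows (%d children x %d parents)",
                len(df), len(children), len(parents))
    return df


def select_trios(table: pd.DataFrame, cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Apply the acceptance threshold, then the minimal-cumulative-ploidy rule
    per child. Ties (several equally supported pairs) are all reported."""
    cfg = cfg or ScanConfig()
    if table.empty:
        return table.copy()
    passed = table[table["proportion"] >= cfg.trio_threshold].copy()
    if passed.empty or not cfg.apply_min_ploidy_rule:
        return passed.reset_index(drop=True)
    passed["cum_ploidy"] = passed["p1_ploidy"] + passed["p2_ploidy"]
    keep = []
    for child, grp in passed.groupby("child", sort=True):
        min_cp = grp["cum_ploidy"].min()
        keep.append(grp[grp["cum_ploidy"] == min_cp])
    out = pd.concat(keep).drop(columns="cum_ploidy").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Duo scan
# ---------------------------------------------------------------------------

def duo_statistic(m: GenotypeMatrix, child: str, parent: str) -> DuoResult:
    """Proportions of sites validating a 1x, 2x, and complete-genome
    contribution of the parent. The caller applies the per-duo polymorphic
    filter first. 2x and restitution tests apply only to polyploid children."""
    child_ploidy = m.accession(child).ploidy
    v1 = verdict_vector_duo(m, child, parent, 1)
    tested = np.isfinite(v1)
    n = int(tested.sum())
    prop_1x = float(np.nansum(v1) / n) if n else float("nan")
    prop_2x = prop_full = None
    if child_ploidy >= 3:
        v2 = verdict_vector_duo(m, child, parent, 2)
        n2 = int(np.isfinite(v2).sum())
        prop_2x = float(np.nansum(v2) / n2) if n2 else float("nan")
        vf = verdict_vector_restitution(m, child, parent)
        nf = int(np.isfinite(vf).sum())
        prop_full = float(np.nansum(vf) / nf) if nf else float("nan")
    return DuoResult(
        child=child, parent=parent, n_tested=n,
        prop_1x=prop_1x, prop_2x=prop_2x, prop_full=prop_full,
    )


def scan_all_duos(
    m: GenotypeMatrix,
    parent: str,
    children: list[str],
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Duo scan of one focal parent against candidate children; the per-duo
    polymorphic filter is applied for each duo."""
    cfg = cfg or ScanConfig()
    rows = []
    for child in m.clone_representatives(children):
        if child == parent:
            continue
        sub = relation_polymorphic_filter(m, [child, parent])
        d = duo_statistic(sub, child, parent)
        rows.append(
            {
                "child": child,
                "parent": parent,
                "child_ploidy": m.accession(child).ploidy,
                "n_tested": d.n_tested,
                "prop_1x": d.prop_1x,
                "prop_2x": np.nan if d.prop_2x is None else d.prop_2x,
                "prop_full": np.nan if d.prop_full is None else d.prop_full,
                "selected": d.prop_1x >= cfg.duo_threshold
                or (d.prop_2x is not None and d.prop_2x >= cfg.duo_threshold),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gamete-type labelling
# ---------------------------------------------------------------------------

def label_gamete_types(
    m: GenotypeMatrix,
    child: str,
    p1: str,
    p2: str,
    k1: int,
    k2: int,
    cfg: ScanConfig | None = None,
) -> tuple[str, str]:
    """Label each parent's gamete as 1x / 2x_recombined / 2x_complete /
    3x_complete. A gamete of ploidy >= 2 is 'complete' when the duo-filtered
    complete-genome restitution proportion reaches the duo threshold."""
    cfg = cfg or ScanConfig()
    labels = []
    for parent, k in ((p1, k1), (p2, k2)):
        if k == 1:
            labels.append("1x")
            continue
        sub = relation_polymorphic_filter(m, [child, parent])
        vf = verdict_vector_restitution(sub, child, parent)
        nf = np.isfinite(vf).sum()
        prop_full = np.nansum(vf) / nf if nf else 0.0
        if k == 3:
            labels.append("3x_complete" if prop_full >= cfg.duo_threshold else "3x_recombined")
        else:
            labels.append("2x_complete" if prop_full >= cfg.duo_threshold else "2x_recombined")
    return labels[0], labels[1]
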