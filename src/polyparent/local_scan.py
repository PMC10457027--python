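"""Windowed validation along chromosomes, haplotype subtraction, coverage.

Genome-wide proportions can hide locally incompatible regions (a relative
sharing one parent, an aneuploid segment). Relations are therefore re-tested
in sliding windows of 201 SNPs (step 1, value anchored at the central SNP)
along each chromosome: trios as windowed discordance (1 - compatible/tested),
single parents as windowed 1x/2x validation, and un-recombined unreduced
gametes as windowed complete-genome restitution. When a parent's complete
genome is confirmed inside a child, subtracting its alleles from the child's
multisets exposes the gamete contributed by the other parent, ready for
ancestry painting. Read-depth profiles along chromosomes flag whole-
chromosome gains and segmental losses.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import global_scan as gs
from .vcfio import GenotypeMatrix, MAX_PLOIDY, FILL

logger = logging.getLogger(__name__)

__all__ = [
    "Relation",
    "WindowTrack",
    "DeducedGamete",
    "CoverageTrack",
    "AneuploidCall",
    "windowed_discordance",
    "windowed_full_restitution",
    "subtract_parent",
    "coverage_profile",
    "export_tracks",
    "read_track",
]

WINDOW_DEFAULT = 201


@dataclass(frozen=True)
class Relation:
    """A tested trio or duo with its gamete ploidies.

    ``kind`` is "trio" (child, p1, p2 with split (k1, k2)) or "duo"
    (child, p1 with gamete ploidy k1).
    """

    kind: str
    child: str
    p1: str
    k1: int
    p2: str | None = None
    k2: int | None = None

    def describe(self) -> str:
        if self.kind == "trio":
            return f"{self.child}~{self.p1}[{self.k1}x]+{self.p2}[{self.k2}x]"
        return f"{self.child}~{self.p1}[{self.k1}x]"

    def members(self) -> list[str]:
        return [self.child, self.p1] + ([self.p2] if self.p2 else [])


@dataclass
class WindowTrack:
    relation: str
    chrom: str
    centers: np.ndarray     # 1-based position of each window's central SNP
    values: np.ndarray
    n_tested: np.ndarray    # informative (non-missing, applicable) sites per window
    window: int
    starts: np.ndarray | None = None  # 1-based position of each window's first SNP
    ends: np.ndarray | None = None    # ... and last SNP


@dataclass
class DeducedGamete:
    """Residual allele multisets after removing a confirmed parent's genotype
    from the child. CONFLICT sites (parent not contained in child) and sites
    with a missing member carry no residual."""

    child: str
    parent: str
    chroms: np.ndarray
    pos: np.ndarray
    residual: np.ndarray    # (n_sites, MAX_PLOIDY) padded sorted allele indices
    conflict: np.ndarray    # bool per site
    missing: np.ndarray     # bool per site

    def residual_tuple(self, i: int) -> tuple[int, ...] | None:
        if self.conflict[i] or self.missing[i]:
            return None
        row = self.residual[i]
        return tuple(int(a) for a in row[row >= 0])

    def residual_sizes(self) -> np.ndarray:
        """Residual multiset size per site (-1 at conflict/missing sites)."""
        sizes = (self.residual >= 0).sum(axis=1).astype(np.int64)
        sizes[self.conflict | self.missing] = -1
        return sizes


@dataclass
class AneuploidCall:
    chrom: str
    start_window: int
    end_window: int          # exclusive
    start_pos: int
    end_pos: int
    copy_ratio: float


@dataclass
class CoverageTrack:
    accession: str
    chrom: str
    window_starts: np.ndarray   # positions (1-based, inclusive)
    window_ends: np.ndarray
    ratios: np.ndarray          # windowed mean depth / genome-wide mean depth
    calls: list[AneuploidCall] = field(default_factory=list)
    window: int = 50


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def _sliding_tracks(
    m: GenotypeMatrix, verdict: np.ndarray, relation_desc: str, window: int,
    discordance: bool,
) -> list[WindowTrack]:
    """Turn a per-site verdict vector (1/0/NaN) into per-chromosome tracks.

    Full windows only (centres run from SNP ``(w+1)/2`` to ``S-w/2``); a
    chromosome shorter than the window collapses to a single whole-chromosome
    window (with a warning)."""
    tracks = []
    half = window // 2
    for chrom, idx in m.chrom_site_index().items():
        v = verdict[idx]
        pos = m.pos[idx]
        tested = np.isfinite(v)
        ok = np.where(tested, np.nan_to_num(v), 0.0)
        if len(idx) < window:
            logger.warning(
                "%s: chromosome %s has %d < %d sites; using one whole-chromosome window",
                relation_desc, chrom, len(idx), window,
            )
            n_t = tested.sum()
            val = ok.sum() / n_t if n_t else np.nan
            tracks.append(
                WindowTrack(
                    relation=relation_desc, chrom=chrom,
                    centers=np.array([pos[len(pos) // 2]]),
                    values=np.array([1.0 - val if discordance else val]),
                    n_tested=np.array([int(n_t)]),
                    window=window,
                    starts=pos[:1].copy(), ends=pos[-1:].copy(),
                )
            )
            continue
        c_ok = np.concatenate([[0.0], np.cumsum(ok)])
        c_n = np.concatenate([[0], np.cumsum(tested.astype(np.int64))])
        n_win = len(idx) - window + 1
        starts = np.arange(n_win)
        n_t = c_n[starts + window] - c_n[starts]
        s_ok = c_ok[starts + window] - c_ok[starts]
        with np.errstate(invalid="ignore"):
            val = np.where(n_t > 0, s_ok / np.maximum(n_t, 1), np.nan)
        tracks.append(
            WindowTrack(
                relation=relation_desc, chrom=chrom,
                centers=pos[starts + half],
                values=1.0 - val if discordance else val,
                n_tested=n_t.astype(np.int64),
                window=window,
                starts=pos[starts], ends=pos[starts + window - 1],
            )
        )
    return tracks


def windowed_discordance(
    m: GenotypeMatrix, relation: Relation, window: int = WINDOW_DEFAULT
) -> list[WindowTrack]:
    """Per-window proportion of sites in *discordance* with the relation.

    The matrix should already carry the per-relation polymorphic filter.
    Sites where the child's (override-aware) effective ploidy does not match
    the tested split are excluded, so aneuploid chromosomes recalled at a
    different ploidy are analysed at that ploidy and pooled with the rest.
    """
    if relation.kind == "trio":
        v = gs.verdict_vector_trio(
            m, relation.child, relation.p1, relation.p2, relation.k1, relation.k2
        )
    elif relation.kind == "duo":
        v = gs.verdict_vector_duo(m, relation.child, relation.p1, relation.k1)
    else:
        raise ValueError(f"unknown relation kind {relation.kind!r}")
    return _sliding_tracks(m, v, relation.describe(), window, discordance=True)


def windowed_full_restitution(
    m: GenotypeMatrix, child: str, parent: str, window: int = WINDOW_DEFAULT
) -> list[WindowTrack]:
    """Per-window proportion of sites where the parent's complete genotype is
    contained in the child — flat at 1.0 for an un-recombined unreduced
    gamete, depressed across recombined or lost segments."""
    if m.accession(child).ploidy <= m.accession(parent).ploidy:
        raise ValueError("restitution test needs child ploidy > parent ploidy")
    v = gs.verdict_vector_restitution(m, child, parent)
    return _sliding_tracks(
        m, v, f"{child}-minus-{parent}", window, discordance=False
    )


# ---------------------------------------------------------------------------
# Haplotype subtraction
# ---------------------------------------------------------------------------

def subtract_parent(m: GenotypeMatrix, child: str, parent: str) -> DeducedGamete:
    """Remove the parent's allele multiset from the child's at every site.

    The residual is the gamete contributed by the other parent. Sites where
    the parent's multiset is not contained in the child's are flagged CONFLICT
    rather than raising; the caller should have confirmed complete restitution
    globally first.
    """
    ci = m.acc_index(child)
    pi = m.acc_index(parent)
    n = m.n_sites
    residual = np.full((n, MAX_PLOIDY), FILL, dtype=np.int8)
    conflict = np.zeros(n, dtype=bool)
    missing = np.zeros(n, dtype=bool)
    cc = m.genotype_codes(ci).astype(np.uint32)
    cp = m.genotype_codes(pi).astype(np.uint32)
    key = (cc << np.uint32(12)) | cp
    miss = (cc == 0) | (cp == 0)
    missing[miss] = True
    uniq, inv = np.unique(key[~miss], return_inverse=True)
    res_rows = np.empty((len(uniq), MAX_PLOIDY), dtype=np.int8)
    confl = np.empty(len(uniq), dtype=bool)
    for i, k in enumerate(uniq):
        child_ms = list(gs._decode(int(k) >> 12))
        parent_ms = gs._decode(int(k) & 0xFFF)
        ok = True
        for a in parent_ms:
            if a in child_ms:
                child_ms.remove(a)
            else:
                ok = False
                break
        confl[i] = not ok
        row = np.full(MAX_PLOIDY, FILL, dtype=np.int8)
        if ok:
            row[: len(child_ms)] = sorted(child_ms)
        res_rows[i] = row
    idx = np.flatnonzero(~miss)
    residual[idx] = res_rows[inv]
    conflict[idx] = confl[inv]
    n_confl = int(conflict.sum())
    if n_confl:
        logger.info("subtract_parent(%s - %s): %d conflict sites", child, parent, n_confl)
    return DeducedGamete(
        child=child, parent=parent, chroms=m.chroms.copy(), pos=m.pos.copy(),
        residual=residual, conflict=conflict, missing=missing,
    )


# ---------------------------------------------------------------------------
# Coverage profiling
# ---------------------------------------------------------------------------

def coverage_profile(
    m: GenotypeMatrix,
    accession: str,
    window: int = 50,
    margin: float = 0.2,
    min_run: int = 20,
) -> list[CoverageTrack]:
    """Windowed SNP read-depth relative to the accession's baseline, with
    calls of aneuploid segments: runs of >= ``min_run`` consecutive windows
    whose ratio deviates from 1 by more than ``margin`` on the same side.

    The baseline is the *median* of the windowed mean depths rather than the
    genome-wide mean: an aneuploid chromosome would inflate the mean and mask
    its own copy-ratio signal on compact genomes.
    """
    if m.depth is None:
        raise ValueError("coverage_profile requires per-site depth (DP)")
    j = m.acc_index(accession)
    depth = m.depth[:, j].astype(float)
    depth[depth < 0] = np.nan
    per_chrom = {}
    all_means = []
    for chrom, idx in m.chrom_site_index().items():
        d = depth[idx]
        pos = m.pos[idx]
        n_win = max(len(idx) // window, 1)
        starts, ends, means = [], [], []
        for w in range(n_win):
            lo = w * window
            hi = len(idx) if w == n_win - 1 else (w + 1) * window
            means.append(np.nanmean(d[lo:hi]))
            starts.append(pos[lo])
            ends.append(pos[hi - 1])
        per_chrom[chrom] = (np.array(starts), np.array(ends), np.array(means))
        all_means.extend(means)
    baseline = float(np.nanmedian(all_means))
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError(f"no usable depth for accession {accession!r}")
    tracks = []
    for chrom, (starts, ends, means) in per_chrom.items():
        ratios = means / baseline
        calls: list[AneuploidCall] = []
        state = np.zeros(len(ratios), dtype=np.int8)
        state[ratios > 1 + margin] = 1
        state[ratios < 1 - margin] = -1
        w0 = 0
        for w in range(1, len(state) + 1):
            if w == len(state) or state[w] != state[w0]:
                if state[w0] != 0 and (w - w0) >= min_run:
                    calls.append(
                        AneuploidCall(
                            chrom=chrom, start_window=w0, end_window=w,
                            start_pos=int(starts[w0]), end_pos=int(ends[w - 1]),
                            copy_ratio=float(np.mean(ratios[w0:w])),
                        )
                    )
                w0 = w
        tracks.append(
            CoverageTrack(
                accession=accession, chrom=chrom,
                window_starts=np.array(starts), window_ends=np.array(ends),
                ratios=ratios, calls=calls, window=window,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Track export
# ---------------------------------------------------------------------------

def export_tracks(
    tracks: list[WindowTrack], out_dir, plot: bool = True
) -> list[Path]:
    """Write each track as a BED-like 4-column TSV (chrom, start, end, value;
    0-based half-open, one row per window anchored at its central SNP) plus a
    simple per-relation linear plot. Returns the manifest of written files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    by_relation: dict[str, list[WindowTrack]] = {}
    for t in tracks:
        by_relation.setdefault(t.relation, []).append(t)
    for relation, group in by_relation.items():
        slug = hashlib.sha1(relation.encode()).hexdigest()[:8]
        safe = "".join(c if c.isalnum() or c in "-_." else "_" for c in relation)
        path = out_dir / f"track_{safe}_{slug}.tsv"
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tvalue\n")
            for t in sorted(group, key=lambda t: t.chrom):
                for c, v in zip(t.centers, t.values):
                    fh.write(f"{t.chrom}\t{c - 1}\t{c}\t{v:.6g}\n")
        manifest.append(path)
        if plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(
                len(group), 1, figsize=(8, 2 * len(group)), squeeze=False
            )
            for ax, t in zip(axes[:, 0], sorted(group, key=lambda t: t.chrom)):
                ax.plot(t.centers, t.values, lw=0.8)
                ax.set_ylim(-0.05, 1.05)
                ax.set_ylabel(t.chrom)
            axes[-1, 0].set_xlabel("position (bp)")
            fig.suptitle(relation)
            fig.tight_layout()
            png = out_dir / f"track_{safe}_{slug}.png"
            fig.savefig(png, dpi=100)
            plt.close(fig)
            manifest.append(png)
    return manifest


def read_track(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-read an exported track file: (chroms, centers, values)."""
    chroms, centers, values = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            c, s, e, v = line.rstrip("\n").split("\t")
            chroms.append(c)
            centers.append(int(e))
            values.append(float(v))
    return np.array(chroms, dtype=object), np.array(centers), np.array(values)
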