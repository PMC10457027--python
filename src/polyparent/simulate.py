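"""Pedigree simulator with known gamete transmissions and ancestry mosaics.

The generator emulates the structure of a clonal-crop resequencing panel:
founder genomes are inter(sub)specific mosaics over a small set of divergent
ancestral groups (think *M. acuminata* subspecies plus *M. balbisiana*), and
offspring of ploidy 2-4 are formed by combining gametes of explicit types:

``1x``             ordinary reduced gamete (recombinant haploid)
``1x+1``           haploid gamete with a supernumerary chromosome
``2x_recombined``  unreduced gamete with recombined chromosomes
``2x_complete``    un-recombined unreduced gamete: the parent's entire
                   diploid genotype is transmitted (full heterozygosity kept)
``3x_complete``    un-recombined triploid gamete from a triploid parent

Every transmission is recorded in a truth object (gamete haplotypes, planted
crossovers, ancestry mosaics, aneuploid regions) so each downstream statistic
can be checked against ground truth. Genotyping error, missing calls and
read-depth are layered on top.

Each ancestral group has one haploid reference profile; at a *diagnostic*
site (probability ``ancestry_divergence``) the derived allele is carried by
exactly one group, at the remaining sites by exactly two groups, so every
site is polymorphic across the panel and the group-private allele set is
known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .vcfio import AccessionMeta, GenotypeMatrix, Site, FILL, MAX_PLOIDY, MISSING_CODE

__all__ = [
    "SimConfig",
    "FounderSpec",
    "CrossSpec",
    "PedigreeDesign",
    "GameteTruth",
    "ChildTruth",
    "AneuploidRegion",
    "PedigreeTruth",
    "simulate_pedigree",
    "meiosis_1x",
    "gamete_2x",
    "gamete_3x_complete",
    "add_noise",
    "expected_unbalanced_fraction",
    "standard_design",
    "ANCESTRY_NAMES",
]

ANCESTRY_NAMES = ("banksii", "zebrina", "malaccensis", "balbisiana", "schizocarpa")

GAMETE_PLOIDY = {
    "1x": 1,
    "1x+1": 1,
    "2x_recombined": 2,
    "2x_complete": 2,
    "3x_complete": 3,
}


@dataclass
class SimConfig:
    """Simulation parameters.

    ``ancestry_divergence`` is the per-site probability that a site is
    diagnostic of a single ancestral group; ``crossover_rate`` is the expected
    number of crossovers per chromosome per meiosis (Poisson);
    ``segment_mean_sites`` the mean founder-mosaic segment length in sites.
    ``within_group_diversity`` is the per-site probability that a cultivar
    founder haplotype deviates from its ancestral reference profile —
    unsampled within-(sub)species variation plus mutations accumulated over
    centuries of clonal propagation. Without it, any two haplotypes of the
    same ancestry would be identical and one accession's alleles could always
    be substituted by another's.
    """

    n_chroms: int = 2
    sites_per_chrom: int = 600
    n_ancestries: int = 4
    ancestry_divergence: float = 0.2
    crossover_rate: float = 1.0
    error_rate: float = 5e-4
    missing_rate: float = 1e-2
    seed: int = 0
    segment_mean_sites: int = 200
    within_group_diversity: float = 0.1
    mean_depth: float = 30.0
    bp_per_site: int = 1000

    def __post_init__(self) -> None:
        for name in ("ancestry_divergence", "error_rate", "missing_rate",
                     "within_group_diversity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.sites_per_chrom < 402:
            raise ValueError("sites_per_chrom must be >= 402 (two full 201-SNP windows)")
        if not 3 <= self.n_ancestries <= 5:
            raise ValueError("n_ancestries must be in 3..5")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chroms)]

    @property
    def ancestries(self) -> list[str]:
        return list(ANCESTRY_NAMES[: self.n_ancestries])


@dataclass
class FounderSpec:
    id: str
    ploidy: int = 2
    ancestries: list[str] = field(default_factory=list)
    is_wild: bool = False
    group: str = "cultivar"
    clone_set: str | None = None
    clone_of: str | None = None  # exact genomic copy of another founder


@dataclass
class CrossSpec:
    child_id: str
    parent1: str
    parent2: str
    gamete1: str
    gamete2: str
    child_ploidy: int
    extra_chrom: str | None = None          # for a 1x+1 gamete
    terminal_loss: tuple[str, float] | None = None  # (chrom, lost terminal fraction)
    group: str = "cultivar"


@dataclass
class PedigreeDesign:
    founders: list[FounderSpec]
    crosses: list[CrossSpec]

    def to_dict(self) -> dict:
        return {"founders": [asdict(f) for f in self.founders],
                "crosses": [asdict(c) for c in self.crosses]}

    @classmethod
    def from_dict(cls, d: dict) -> "PedigreeDesign":
        crosses = []
        for c in d["crosses"]:
            c = dict(c)
            if c.get("terminal_loss"):
                c["terminal_loss"] = (c["terminal_loss"][0], float(c["terminal_loss"][1]))
            crosses.append(CrossSpec(**c))
        return cls(founders=[FounderSpec(**f) for f in d["founders"]],
                   crosses=crosses)


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass
class GameteTruth:
    parent_id: str
    gamete_type: str
    # haplotypes[h][chrom] -> (S,) allele array; ancestries likewise
    haplotypes: list[dict[str, np.ndarray]]
    ancestries: list[dict[str, np.ndarray]]
    breakpoints: list[tuple[str, int]]  # (chrom, j): crossover between sites j-1 and j
    extra_chrom: str | None = None
    extra_haplotype: dict[str, np.ndarray] | None = None
    extra_ancestry: dict[str, np.ndarray] | None = None

    def mosaic(self, h: int) -> list[tuple[str, int, int, str]]:
        """Run-length segments (chrom, start, end_exclusive, ancestry) of haplotype h."""
        return _segments_from_ancestry(self.ancestries[h])


@dataclass
class ChildTruth:
    child_id: str
    parents: tuple[str, str]
    gamete_types: tuple[str, str]
    gametes: tuple[GameteTruth, GameteTruth]


@dataclass
class AneuploidRegion:
    accession: str
    chrom: str
    start_site: int       # site index within the chromosome
    end_site: int         # exclusive
    kind: str             # "gain" | "loss"
    copy_ratio: float


@dataclass
class PedigreeTruth:
    config: SimConfig
    design: PedigreeDesign
    children: dict[str, ChildTruth]
    founder_haplotypes: dict[str, list[dict[str, np.ndarray]]]
    founder_ancestries: dict[str, list[dict[str, np.ndarray]]]
    aneuploid_regions: list[AneuploidRegion]
    # (chrom, site_idx, allele, ancestry): alleles carried by exactly one group
    private_alleles: set[tuple[str, int, int, str]]
    clean_matrix: GenotypeMatrix | None = None

    def mosaic(self, acc_id: str, h: int) -> list[tuple[str, int, int, str]]:
        return _segments_from_ancestry(self.founder_ancestries[acc_id][h])

    def summary_dict(self) -> dict:
        """JSON-serialisable summary (gamete types, parents, aneuploidy)."""
        return {
            "children": {
                c.child_id: {
                    "parents": list(c.parents),
                    "gamete_types": list(c.gamete_types),
                }
                for c in self.children.values()
            },
            "aneuploid_regions": [asdict(a) for a in self.aneuploid_regions],
            "n_private_alleles": len(self.private_alleles),
        }


def _segments_from_ancestry(anc: dict[str, np.ndarray]) -> list[tuple[str, int, int, str]]:
    segs = []
    for chrom in sorted(anc):
        arr = anc[chrom]
        start = 0
        for j in range(1, len(arr) + 1):
            if j == len(arr) or arr[j] != arr[start]:
                segs.append((chrom, start, j, ANCESTRY_NAMES[int(arr[start])]))
                start = j
    return segs


# ---------------------------------------------------------------------------
# Meiosis primitives. A haplotype is a pair of dicts chrom -> (S,) int8/int16
# arrays: allele indices and ancestry indices, kept in lockstep.
# ---------------------------------------------------------------------------

Hap = tuple[dict[str, np.ndarray], dict[str, np.ndarray]]


def _recombine(
    haps: list[Hap], crossover_rate: float, rng: np.random.Generator
) -> tuple[Hap, list[tuple[str, int]]]:
    """One recombinant haplotype from a diploid pair of haplotypes.

    Crossovers per chromosome ~ Poisson(crossover_rate); breakpoints uniform
    over the S-1 site intervals; the starting phase is fair.
    """
    alleles: dict[str, np.ndarray] = {}
    ancs: dict[str, np.ndarray] = {}
    breakpoints: list[tuple[str, int]] = []
    (a0, n0), (a1, n1) = haps
    for chrom in sorted(a0):
        size = len(a0[chrom])
        n_co = rng.poisson(crossover_rate)
        bps = np.sort(rng.choice(np.arange(1, size), size=min(n_co, size - 1), replace=False))
        phase = np.full(size, rng.integers(2), dtype=np.int8)
        for b in bps:
            phase[b:] = 1 - phase[b]
            breakpoints.append((chrom, int(b)))
        alleles[chrom] = np.where(phase == 0, a0[chrom], a1[chrom])
        ancs[chrom] = np.where(phase == 0, n0[chrom], n1[chrom])
    return (alleles, ancs), breakpoints


def meiosis_1x(
    parent_haplotypes: list[Hap], crossover_rate: float, rng: np.random.Generator
) -> tuple[Hap, list[tuple[str, int]]]:
    """Standard reduced gamete from a diploid parent."""
    if len(parent_haplotypes) != 2:
        raise ValueError("meiosis_1x requires a diploid parent (2 haplotypes)")
    return _recombine(parent_haplotypes, crossover_rate, rng)


def gamete_2x(
    parent_haplotypes: list[Hap],
    mode: str,
    crossover_rate: float,
    rng: np.random.Generator,
) -> tuple[list[Hap], list[tuple[str, int]]]:
    """Unreduced gamete from a diploid parent.

    ``complete``: exact copies of both parental haplotypes (no recombination,
    the meiosis-I-failure signature). ``recombined``: two haplotypes with
    independently placed crossovers; at least one breakpoint is enforced
    genome-wide so the gamete is distinguishable from a complete one.
    """
    if len(parent_haplotypes) != 2:
        raise ValueError("gamete_2x requires a diploid parent")
    if mode == "complete":
        copies = [({c: a.copy() for c, a in h[0].items()},
                   {c: a.copy() for c, a in h[1].items()}) for h in parent_haplotypes]
        return copies, []
    if mode != "recombined":
        raise ValueError(f"unknown 2x gamete mode: {mode!r}")
    h1, bp1 = _recombine(parent_haplotypes, crossover_rate, rng)
    h2, bp2 = _recombine(parent_haplotypes, crossover_rate, rng)
    bps = bp1 + bp2
    if not bps:
        # force one crossover so the gamete is genuinely recombined
        chrom = rng.choice(sorted(h1[0]))
        size = len(h1[0][chrom])
        b = int(rng.integers(1, size))
        h1[0][chrom][b:] = parent_haplotypes[1][0][chrom][b:]
        h1[1][chrom][b:] = parent_haplotypes[1][1][chrom][b:]
        h1[0][chrom][:b] = parent_haplotypes[0][0][chrom][:b]
        h1[1][chrom][:b] = parent_haplotypes[0][1][chrom][:b]
        bps = [(chrom, b)]
    return [h1, h2], bps


def gamete_3x_complete(parent_haplotypes: list[Hap]) -> tuple[list[Hap], list]:
    """Un-recombined triploid gamete: exact copies of all three haplotypes."""
    if len(parent_haplotypes) != 3:
        raise ValueError("gamete_3x_complete requires a triploid parent")
    copies = [({c: a.copy() for c, a in h[0].items()},
               {c: a.copy() for c, a in h[1].items()}) for h in parent_haplotypes]
    return copies, []


def expected_unbalanced_fraction(t: int) -> float:
    """Expected fraction of unbalanced (non-viable) gametes from a carrier of
    ``t`` independent heterozygous reciprocal translocations.

    Each translocation segregates balanced gametes with probability 1/2, so
    the unbalanced fraction is 1 - (1/2)^t — e.g. 0.75 for two translocations,
    the situation favouring transmission of unreduced gametes in clonal crops.
    """
    if t < 0 or int(t) != t:
        raise ValueError(f"t must be a non-negative integer, got {t}")
    return 1.0 - 0.5 ** int(t)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def add_noise(
    m: GenotypeMatrix,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Independently flip each allele call to another site allele with
    probability ``error_rate``; set whole genotypes missing with
    ``missing_rate``. Returns a new matrix."""
    if not 0 <= error_rate <= 1 or not 0 <= missing_rate <= 1:
        raise ValueError("rates must be in [0,1]")
    geno = m.genotypes.copy()
    n_alleles = np.array([len(s.alleles) for s in m.sites], dtype=np.int16)
    valid = geno >= 0
    if error_rate > 0:
        flip = valid & (rng.random(geno.shape) < error_rate)
        if flip.any():
            na = np.broadcast_to(n_alleles[:, None, None], geno.shape)
            shift = rng.integers(1, np.maximum(na, 2), size=geno.shape)
            flipped = (geno.astype(np.int32) + shift) % np.maximum(na, 2)
            geno = np.where(flip & (na > 1), flipped.astype(np.int8), geno)
            # re-sort each multiset, keeping pads at the end of the slots
            tmp = np.where(geno >= 0, geno, 127).astype(np.int8)
            tmp.sort(axis=2)
            pad = np.where(
                (m.genotypes[:, :, :1] == MISSING_CODE), MISSING_CODE, FILL
            ).astype(np.int8)
            geno = np.where(tmp == 127, pad, tmp)
    if missing_rate > 0:
        miss = rng.random(geno.shape[:2]) < missing_rate
        geno[miss] = MISSING_CODE
    return GenotypeMatrix(list(m.sites), list(m.accessions), geno, m.depth)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def _ancestral_profiles(cfg: SimConfig, rng: np.random.Generator):
    """Haploid reference profile per ancestry and the exact private-allele truth.

    Returns (profiles[(n_anc, n_chroms, S)] in {0,1}, private set).
    """
    n_anc, n_chr, S = cfg.n_ancestries, cfg.n_chroms, cfg.sites_per_chrom
    profiles = np.zeros((n_anc, n_chr, S), dtype=np.int8)
    for c in range(n_chr):
        diag = rng.random(S) < cfg.ancestry_divergence
        owner = rng.integers(n_anc, size=S)
        for s in range(S):
            if diag[s]:
                profiles[owner[s], c, s] = 1
            else:
                pair = rng.choice(n_anc, size=2, replace=False)
                profiles[pair, c, s] = 1
    private: set[tuple[str, int, int, str]] = set()
    chrom_names = cfg.chrom_names
    for c in range(n_chr):
        for s in range(S):
            for allele in (0, 1):
                owners = np.flatnonzero(profiles[:, c, s] == allele)
                if len(owners) == 1:
                    private.add(
                        (chrom_names[c], s, allele, ANCESTRY_NAMES[int(owners[0])])
                    )
    return profiles, private


def _founder_haplotype(
    cfg: SimConfig, profiles: np.ndarray, palette: list[int], rng: np.random.Generator
) -> Hap:
    """Mosaic haplotype: geometric-length segments over the ancestry palette."""
    alleles: dict[str, np.ndarray] = {}
    ancs: dict[str, np.ndarray] = {}
    S = cfg.sites_per_chrom
    for c, chrom in enumerate(cfg.chrom_names):
        anc_row = np.empty(S, dtype=np.int16)
        pos = 0
        current = int(rng.choice(palette))
        while pos < S:
            seg = int(rng.geometric(1.0 / cfg.segment_mean_sites))
            anc_row[pos: pos + seg] = current
            pos += seg
            if len(palette) > 1:
                others = [a for a in palette if a != current]
                current = int(rng.choice(others))
        alleles[chrom] = profiles[anc_row, c, np.arange(S)].astype(np.int8)
        ancs[chrom] = anc_row
    return alleles, ancs


def _genotype_array(cfg: SimConfig, haps: list[Hap]) -> np.ndarray:
    """(n_sites, MAX_PLOIDY) padded sorted multiset array from haplotypes."""
    S, chroms = cfg.sites_per_chrom, cfg.chrom_names
    n_sites = S * len(chroms)
    out = np.full((n_sites, MAX_PLOIDY), -2, dtype=np.int8)
    for ci, chrom in enumerate(chroms):
        block = np.stack([h[0][chrom] for h in haps], axis=1)  # (S, n_haps)
        block = np.sort(block, axis=1)
        out[ci * S: (ci + 1) * S, : block.shape[1]] = block
    return out


def simulate_pedigree(
    cfg: SimConfig, design: PedigreeDesign
) -> tuple[GenotypeMatrix, PedigreeTruth]:
    """Simulate founders and crosses; return the noisy genotype matrix and the
    complete truth record (the noise-free matrix rides along in the truth)."""
    rng = np.random.default_rng(cfg.seed)
    anc_index = {name: i for i, name in enumerate(cfg.ancestries)}
    profiles, private = _ancestral_profiles(cfg, rng)

    individuals: dict[str, list[Hap]] = {}
    metas: dict[str, AccessionMeta] = {}
    founder_anc: dict[str, list[dict[str, np.ndarray]]] = {}

    for f in design.founders:
        if f.clone_of is not None:
            src = individuals[f.clone_of]
            haps = [({c: a.copy() for c, a in h[0].items()},
                     {c: a.copy() for c, a in h[1].items()}) for h in src]
            ploidy = len(haps)
        else:
            palette = [anc_index[a] for a in f.ancestries]
            if not palette:
                raise ValueError(f"founder {f.id}: empty ancestry palette")
            if f.is_wild and f.ploidy == 2 and len(palette) == 1:
                # pure wild reference: two copies of the ancestral profile
                h = _founder_haplotype(cfg, profiles, palette, rng)
                haps = [h, ({c: a.copy() for c, a in h[0].items()},
                            {c: a.copy() for c, a in h[1].items()})]
            else:
                haps = [
                    _founder_haplotype(cfg, profiles, palette, rng)
                    for _ in range(f.ploidy)
                ]
                if not f.is_wild and cfg.within_group_diversity > 0:
                    # haplotype-private deviations from the group profiles
                    for alleles, _anc in haps:
                        for chrom in alleles:
                            flip = rng.random(len(alleles[chrom])) < cfg.within_group_diversity
                            alleles[chrom] = np.where(
                                flip, 1 - alleles[chrom], alleles[chrom]
                            ).astype(np.int8)
            ploidy = f.ploidy
        individuals[f.id] = haps
        metas[f.id] = AccessionMeta(
            id=f.id, ploidy=ploidy, group=f.group,
            is_wild=f.is_wild, clone_set=f.clone_set,
        )
        founder_anc[f.id] = [h[1] for h in haps]

    children: dict[str, ChildTruth] = {}
    aneuploid: list[AneuploidRegion] = []
    loss_regions: dict[str, tuple[str, int, int, int]] = {}  # child -> (chrom, start, end, lost hap)

    for cross in design.crosses:
        gametes: list[GameteTruth] = []
        for parent_id, gtype in ((cross.parent1, cross.gamete1),
                                 (cross.parent2, cross.gamete2)):
            if gtype not in GAMETE_PLOIDY:
                raise ValueError(f"unknown gamete type {gtype!r}")
            phaps = individuals[parent_id]
            extra_h = extra_a = None
            if gtype in ("1x", "1x+1"):
                hap, bps = meiosis_1x(phaps, cfg.crossover_rate, rng)
                haps = [hap]
                if gtype == "1x+1":
                    if cross.extra_chrom is None:
                        raise ValueError(f"{cross.child_id}: 1x+1 gamete needs extra_chrom")
                    hap2, bp2 = meiosis_1x(phaps, cfg.crossover_rate, rng)
                    extra_h = {cross.extra_chrom: hap2[0][cross.extra_chrom]}
                    extra_a = {cross.extra_chrom: hap2[1][cross.extra_chrom]}
                    bps = bps + [b for b in bp2 if b[0] == cross.extra_chrom]
            elif gtype in ("2x_recombined", "2x_complete"):
                mode = "recombined" if gtype == "2x_recombined" else "complete"
                haps, bps = gamete_2x(phaps, mode, cfg.crossover_rate, rng)
            else:  # 3x_complete
                haps, bps = gamete_3x_complete(phaps)
            gametes.append(
                GameteTruth(
                    parent_id=parent_id, gamete_type=gtype,
                    haplotypes=[h[0] for h in haps],
                    ancestries=[h[1] for h in haps],
                    breakpoints=bps,
                    extra_chrom=cross.extra_chrom if gtype == "1x+1" else None,
                    extra_haplotype=extra_h, extra_ancestry=extra_a,
                )
            )
        base_ploidy = GAMETE_PLOIDY[cross.gamete1] + GAMETE_PLOIDY[cross.gamete2]
        if base_ploidy != cross.child_ploidy:
            raise ValueError(
                f"{cross.child_id}: gamete ploidies {cross.gamete1}+{cross.gamete2} "
                f"inconsistent with declared child ploidy {cross.child_ploidy}"
            )
        child_haps: list[Hap] = []
        for g in gametes:
            for h_all, h_anc in zip(g.haplotypes, g.ancestries):
                child_haps.append((h_all, h_anc))
        overrides: dict[str, int] = {}
        for g in gametes:
            if g.extra_chrom is not None:
                overrides[g.extra_chrom] = base_ploidy + 1
                aneuploid.append(
                    AneuploidRegion(
                        accession=cross.child_id, chrom=g.extra_chrom,
                        start_site=0, end_site=cfg.sites_per_chrom,
                        kind="gain", copy_ratio=(base_ploidy + 1) / base_ploidy,
                    )
                )
        if cross.terminal_loss is not None:
            chrom, frac = cross.terminal_loss
            start = int(round(cfg.sites_per_chrom * (1 - frac)))
            lost_hap = int(rng.integers(len(child_haps)))
            loss_regions[cross.child_id] = (chrom, start, cfg.sites_per_chrom, lost_hap)
            aneuploid.append(
                AneuploidRegion(
                    accession=cross.child_id, chrom=chrom,
                    start_site=start, end_site=cfg.sites_per_chrom,
                    kind="loss", copy_ratio=(base_ploidy - 1) / base_ploidy,
                )
            )
        individuals[cross.child_id] = child_haps
        metas[cross.child_id] = AccessionMeta(
            id=cross.child_id, ploidy=base_ploidy, group=cross.group,
            is_wild=False, chrom_ploidy_overrides=overrides,
        )
        children[cross.child_id] = ChildTruth(
            child_id=cross.child_id,
            parents=(cross.parent1, cross.parent2),
            gamete_types=(cross.gamete1, cross.gamete2),
            gametes=(gametes[0], gametes[1]),
        )

    # --- assemble the matrix ------------------------------------------------
    S, chroms = cfg.sites_per_chrom, cfg.chrom_names
    sites = [
        Site(chrom=chrom, pos=(s + 1) * cfg.bp_per_site, alleles=("A", "T"))
        for chrom in chroms
        for s in range(S)
    ]
    acc_ids = list(individuals)
    geno = np.stack([_genotype_array(cfg, individuals[a]) for a in acc_ids], axis=1)

    # supernumerary chromosomes: append the extra copy on the override chrom
    for child_id, ct in children.items():
        for g in ct.gametes:
            if g.extra_chrom is not None:
                ci = chroms.index(g.extra_chrom)
                j = acc_ids.index(child_id)
                block = geno[ci * S: (ci + 1) * S, j, :]
                base = metas[child_id].ploidy
                extra = g.extra_haplotype[g.extra_chrom]
                stacked = np.concatenate([block[:, :base], extra[:, None]], axis=1)
                stacked = np.sort(stacked, axis=1)
                block[:, : base + 1] = stacked

    # terminal losses: one haplotype lost; caller's ploidy kept, so the call
    # shows a dosage error (a remaining allele is duplicated)
    for child_id, (chrom, start, end, lost_hap) in loss_regions.items():
        ci = chroms.index(chrom)
        j = acc_ids.index(child_id)
        ploidy = metas[child_id].ploidy
        haps = individuals[child_id]
        kept = [h for i, h in enumerate(haps) if i != lost_hap]
        region = slice(ci * S + start, ci * S + end)
        block = np.stack([h[0][chrom][start:end] for h in kept], axis=1)
        dup_idx = rng.integers(len(kept), size=end - start)
        dup = block[np.arange(end - start), dup_idx]
        filled = np.concatenate([block, dup[:, None]], axis=1)
        filled = np.sort(filled, axis=1)
        geno[region, j, :ploidy] = filled

    # read depth: Poisson(mean_depth * copy ratio)
    ratio = np.ones((len(sites), len(acc_ids)))
    for a in aneuploid:
        ci = chroms.index(a.chrom)
        j = acc_ids.index(a.accession)
        ratio[ci * S + a.start_site: ci * S + a.end_site, j] = a.copy_ratio
    depth = rng.poisson(cfg.mean_depth * ratio).astype(np.int32)

    meta_list = [metas[a] for a in acc_ids]
    clean = GenotypeMatrix(sites, meta_list, geno, depth)
    noisy = add_noise(clean, cfg.error_rate, cfg.missing_rate, rng)
    truth = PedigreeTruth(
        config=cfg, design=design, children=children,
        founder_haplotypes={a: [h[0] for h in individuals[a]] for a in acc_ids},
        founder_ancestries={a: [h[1] for h in individuals[a]] for a in acc_ids},
        aneuploid_regions=aneuploid, private_alleles=private,
        clean_matrix=clean,
    )
    return noisy, truth


# ---------------------------------------------------------------------------
# Canonical study-structure design
# ---------------------------------------------------------------------------

def standard_design(with_aneuploidy: bool = False) -> PedigreeDesign:
    """A pedigree mirroring the gamete-type vocabulary of the study system:
    wild references for each ancestral group, heterozygous mosaic cultivar
    founders, and children formed by 1x, recombined 2x, complete 2x and
    complete 3x gametes (plus, optionally, 1x+1 and terminal-loss aneuploids).
    """
    founders = [
        FounderSpec("W_banksii", 2, ["banksii"], is_wild=True, group="banksii",
                    clone_set="w_bank"),
        FounderSpec("W_banksii2", 2, ["banksii"], is_wild=True, group="banksii",
                    clone_set="w_bank"),
        FounderSpec("W_zebrina", 2, ["zebrina"], is_wild=True, group="zebrina",
                    clone_set="w_zebr"),
        FounderSpec("W_zebrina2", 2, ["zebrina"], is_wild=True, group="zebrina",
                    clone_set="w_zebr"),
        FounderSpec("W_malacc", 2, ["malaccensis"], is_wild=True,
                    group="malaccensis", clone_set="w_mala"),
        FounderSpec("W_malacc2", 2, ["malaccensis"], is_wild=True,
                    group="malaccensis", clone_set="w_mala"),
        FounderSpec("W_balbis", 2, ["balbisiana"], is_wild=True,
                    group="balbisiana", clone_set="w_balb"),
        FounderSpec("W_balbis2", 2, ["balbisiana"], is_wild=True,
                    group="balbisiana", clone_set="w_balb"),
        FounderSpec("M1", 2, ["banksii", "zebrina"], clone_set="mchare"),
        FounderSpec("M1c", clone_of="M1", clone_set="mchare"),
        FounderSpec("M2", 2, ["banksii", "malaccensis"]),
        FounderSpec("M3", 2, ["zebrina", "malaccensis"]),
        FounderSpec("M4", 2, ["banksii", "balbisiana"]),
        FounderSpec("T1", 3, ["banksii", "zebrina", "malaccensis"]),
    ]
    crosses = [
        CrossSpec("C_F1", "M1", "M2", "1x", "1x", 2),
        CrossSpec("C_TRI_REC", "M1", "M3", "2x_recombined", "1x", 3),
        CrossSpec("C_TRI_CPL", "M2", "M4", "2x_complete", "1x", 3),
        CrossSpec("C_TET", "T1", "M3", "3x_complete", "1x", 4),
    ]
    if with_aneuploidy:
        crosses.append(
            CrossSpec("C_ANEU", "M2", "M4", "2x_complete", "1x+1", 3,
                      extra_chrom="chr02")
        )
        crosses[3] = CrossSpec("C_TET", "T1", "M3", "3x_complete", "1x", 4,
                               terminal_loss=("chr01", 0.3))
    return PedigreeDesign(founders=founders, crosses=crosses)
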