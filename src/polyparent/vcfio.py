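"""Genotype model and VCF / metadata I/O for multi-ploidy parentage analysis.

Genotypes are modelled as *unordered allele multisets*: cultivated banana-type
data are unphased, so a triploid call ``0/1/1`` is simply the multiset
{ref, alt, alt}. Ploidy may vary between accessions (2-4) and, for aneuploids,
between chromosomes of one accession (per-chromosome overrides).

Internally genotypes live in a dense ``(n_sites, n_accessions, 4)`` int8 array
holding sorted allele indices, padded with :data:`FILL`; a missing call has all
slots set to :data:`MISSING_CODE`. This keeps the genome-wide scans vectorised
while site-level predicates work on plain sorted tuples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_PLOIDY = 4
FILL = -2          # pad value beyond the accession's ploidy
MISSING_CODE = -1  # all slots == MISSING_CODE -> missing genotype

__all__ = [
    "AccessionMeta",
    "Site",
    "GenotypeMatrix",
    "PrivateAlleleSet",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "select_polymorphic",
    "find_private_alleles",
    "remove_private_allele_sites",
    "relation_polymorphic_filter",
]


@dataclass(frozen=True)
class AccessionMeta:
    """Per-accession metadata: ploidy, group label, wild status, clone set.

    ``chrom_ploidy_overrides`` handles aneuploids genotyped at a different
    ploidy on specific chromosomes (e.g. a triploid with a supernumerary
    chromosome recalled at ploidy 4 there).
    """

    id: str
    ploidy: int
    group: str = ""
    is_wild: bool = False
    clone_set: str | None = None
    chrom_ploidy_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 2 <= self.ploidy <= MAX_PLOIDY:
            raise ValueError(f"accession {self.id}: ploidy {self.ploidy} not in 2..4")
        for chrom, p in self.chrom_ploidy_overrides.items():
            if not 1 <= p <= MAX_PLOIDY:
                raise ValueError(f"accession {self.id}: override ploidy {p} on {chrom}")

    def effective_ploidy(self, chrom: str) -> int:
        return self.chrom_ploidy_overrides.get(chrom, self.ploidy)


@dataclass(frozen=True)
class Site:
    """One variant site: chromosome, 1-based position, ordered alleles (ref first)."""

    chrom: str
    pos: int
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: positions are 1-based")
        if len(self.alleles) < 1 or len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.chrom}:{self.pos}: alleles must be non-empty and unique")


class GenotypeMatrix:
    """Sites x accessions table of unordered allele multisets.

    Parameters
    ----------
    sites
        Site records sorted by (chrom, pos); sorting is enforced.
    accessions
        Accession metadata, one per genotype column.
    genotypes
        ``(n_sites, n_accessions, MAX_PLOIDY)`` int8 array of sorted allele
        indices padded with FILL; missing calls all MISSING_CODE.
    depth
        Optional ``(n_sites, n_accessions)`` read-depth array (-1 = absent).
    """

    def __init__(
        self,
        sites: list[Site],
        accessions: list[AccessionMeta],
        genotypes: np.ndarray,
        depth: np.ndarray | None = None,
    ) -> None:
        order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
        if order != list(range(len(sites))):
            sites = [sites[i] for i in order]
            genotypes = genotypes[order]
            if depth is not None:
                depth = depth[order]
        self.sites = sites
        self.accessions = accessions
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.depth = None if depth is None else np.asarray(depth)
        if self.genotypes.shape != (len(sites), len(accessions), MAX_PLOIDY):
            raise ValueError("genotype array shape does not match sites/accessions")
        self._acc_index = {a.id: i for i, a in enumerate(accessions)}
        self.chroms = np.array([s.chrom for s in sites], dtype=object)
        self.pos = np.array([s.pos for s in sites], dtype=np.int64)

    # -- basic access -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def acc_index(self, acc_id: str) -> int:
        try:
            return self._acc_index[acc_id]
        except KeyError:
            raise KeyError(f"unknown accession id: {acc_id!r}") from None

    def accession(self, acc_id: str) -> AccessionMeta:
        return self.accessions[self.acc_index(acc_id)]

    def genotype(self, site_idx: int, acc: int | str) -> tuple[int, ...] | None:
        """Sorted allele-index tuple at a site, or None if missing."""
        j = acc if isinstance(acc, int) else self.acc_index(acc)
        row = self.genotypes[site_idx, j]
        if row[0] == MISSING_CODE:
            return None
        return tuple(int(a) for a in row[row >= 0])

    def missing_mask(self, acc: int | str) -> np.ndarray:
        j = acc if isinstance(acc, int) else self.acc_index(acc)
        return self.genotypes[:, j, 0] == MISSING_CODE

    def allele_presence(self, acc: int | str) -> np.ndarray:
        """(n_sites, 4) bool: does the accession carry allele index a at each site?"""
        j = acc if isinstance(acc, int) else self.acc_index(acc)
        g = self.genotypes[:, j, :]
        return np.stack([(g == a).any(axis=1) for a in range(MAX_PLOIDY)], axis=1)

    def genotype_codes(self, acc: int | str) -> np.ndarray:
        """Pack each genotype into a uint16 (0 = missing) for vectorised scans.

        Codes are injective over sorted multisets of <=4 alleles with indices
        0..3: each slot contributes (allele+1) in a 3-bit field.
        """
        j = acc if isinstance(acc, int) else self.acc_index(acc)
        g = self.genotypes[:, j, :].astype(np.int32)
        vals = np.where(g >= 0, g + 1, 0).astype(np.uint16)
        code = (
            vals[:, 0]
            | (vals[:, 1] << np.uint16(3))
            | (vals[:, 2] << np.uint16(6))
            | (vals[:, 3] << np.uint16(9))
        )
        return code

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return GenotypeMatrix(
            [self.sites[i] for i in idx],
            self.accessions,
            self.genotypes[idx],
            None if self.depth is None else self.depth[idx],
        )

    def subset_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        """Column subset (e.g. restrict to reference panels); site set unchanged."""
        idx = [self.acc_index(i) for i in ids]
        return GenotypeMatrix(
            list(self.sites),
            [self.accessions[j] for j in idx],
            self.genotypes[:, idx],
            None if self.depth is None else self.depth[:, idx],
        )

    def chrom_site_index(self) -> dict[str, np.ndarray]:
        """Map chromosome -> array of site indices (sites are sorted)."""
        out: dict[str, np.ndarray] = {}
        for chrom in pd.unique(self.chroms):
            out[chrom] = np.flatnonzero(self.chroms == chrom)
        return out

    def effective_ploidies(self, acc: int | str) -> np.ndarray:
        """Per-site effective ploidy of one accession (override-aware)."""
        meta = self.accessions[acc] if isinstance(acc, int) else self.accession(acc)
        out = np.full(self.n_sites, meta.ploidy, dtype=np.int8)
        for chrom, p in meta.chrom_ploidy_overrides.items():
            out[self.chroms == chrom] = p
        return out

    def clone_representatives(self, ids: list[str]) -> list[str]:
        """One representative per clone set (lexicographically first id); singletons kept."""
        chosen: dict[str, str] = {}
        singles: list[str] = []
        for i in sorted(ids):
            cs = self.accession(i).clone_set
            if cs is None:
                singles.append(i)
            elif cs not in chosen:
                chosen[cs] = i
        kept = sorted(singles + list(chosen.values()))
        return kept

    @staticmethod
    def pack_genotype(alleles: tuple[int, ...] | None) -> np.ndarray:
        row = np.full(MAX_PLOIDY, MISSING_CODE if alleles is None else FILL, dtype=np.int8)
        if alleles is not None:
            srt = sorted(alleles)
            row[: len(srt)] = srt
        return row


@dataclass(frozen=True)
class PrivateAlleleSet:
    """Alleles observed only inside one owner group: (site index, allele index, group)."""

    entries: frozenset[tuple[int, int, str]]

    @property
    def site_indices(self) -> np.ndarray:
        return np.array(sorted({s for s, _, _ in self.entries}), dtype=np.int64)


# ---------------------------------------------------------------------------
# Metadata I/O (TSV: id, ploidy, group, is_wild, clone_set, overrides)
# ---------------------------------------------------------------------------

def read_metadata(path) -> list[AccessionMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    metas = []
    for _, row in df.iterrows():
        overrides = {}
        if row.get("overrides", ""):
            for item in row["overrides"].split(";"):
                chrom, p = item.split(":")
                overrides[chrom] = int(p)
        metas.append(
            AccessionMeta(
                id=row["id"],
                ploidy=int(row["ploidy"]),
                group=row.get("group", ""),
                is_wild=row.get("is_wild", "false").lower() in ("true", "1", "yes"),
                clone_set=row.get("clone_set") or None,
                chrom_ploidy_overrides=overrides,
            )
        )
    return metas


def write_metadata(metas: list[AccessionMeta], path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "id": m.id,
                "ploidy": m.ploidy,
                "group": m.group,
                "is_wild": str(m.is_wild).lower(),
                "clone_set": m.clone_set or "",
                "overrides": ";".join(f"{c}:{p}" for c, p in sorted(m.chrom_ploidy_overrides.items())),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path, meta: list[AccessionMeta]) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Every sample column must have a metadata row, and each GT call's ploidy
    must match the accession's (override-aware) effective ploidy; phasing
    separators are ignored. Per-sample DP is loaded when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    meta_by_id = {m.id: m for m in meta}
    for s in vcf.samples:
        if s not in meta_by_id:
            raise ValueError(f"sample {s!r} in VCF has no metadata row")
    metas = [meta_by_id[s] for s in vcf.samples]

    sites: list[Site] = []
    geno_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    has_depth = False
    for var in vcf:
        alleles = tuple([var.REF] + list(var.ALT))
        site = Site(chrom=var.CHROM, pos=var.POS, alleles=alleles)
        row = np.empty((len(metas), MAX_PLOIDY), dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            calls = [a for a in gt[:-1] if a != -2]  # strip cyvcf2 ploidy padding
            if all(a == -1 for a in calls):
                row[j] = GenotypeMatrix.pack_genotype(None)
                continue
            expected = metas[j].effective_ploidy(var.CHROM)
            if len(calls) != expected or any(a < 0 for a in calls):
                raise ValueError(
                    f"ploidy mismatch for sample {vcf.samples[j]!r} at "
                    f"{var.CHROM}:{var.POS}: GT has {len(calls)} alleles, "
                    f"metadata says {expected}"
                )
            row[j] = GenotypeMatrix.pack_genotype(tuple(calls))
        geno_rows.append(row)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_depth = True
            depth_rows.append(np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32))
        else:
            depth_rows.append(np.full(len(metas), -1, dtype=np.int32))
        sites.append(site)
    geno = (
        np.stack(geno_rows)
        if geno_rows
        else np.empty((0, len(metas), MAX_PLOIDY), dtype=np.int8)
    )
    depth = np.stack(depth_rows) if (geno_rows and has_depth) else None
    m = GenotypeMatrix(sites, metas, geno, depth)
    logger.info("read_vcf: %d sites, %d accessions from %s", m.n_sites, m.n_accessions, path)
    return m


def write_vcf(m: GenotypeMatrix, path) -> None:
    """Write the matrix back to an (uncompressed) VCF via pysam."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "polyparent")
    chrom_max: dict[str, int] = {}
    for s in m.sites:
        chrom_max[s.chrom] = max(chrom_max.get(s.chrom, 0), s.pos)
    for chrom, end in chrom_max.items():
        header.contigs.add(chrom, length=end + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    if m.depth is not None:
        header.formats.add("DP", 1, "Integer", "Read depth")
    for a in m.accessions:
        header.add_sample(a.id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, site in enumerate(m.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos,
                alleles=site.alleles,
            )
            for j, a in enumerate(m.accessions):
                g = m.genotype(i, j)
                if g is None:
                    rec.samples[a.id]["GT"] = (None,) * a.effective_ploidy(site.chrom)
                else:
                    rec.samples[a.id]["GT"] = g
                if m.depth is not None and m.depth[i, j] >= 0:
                    rec.samples[a.id]["DP"] = int(m.depth[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def _observed_allele_mask(m: GenotypeMatrix, acc_idx: list[int]) -> np.ndarray:
    """(n_sites, 4) bool: allele observed in >=1 non-missing genotype of the subset."""
    pres = np.zeros((m.n_sites, MAX_PLOIDY), dtype=bool)
    for j in acc_idx:
        pres |= m.allele_presence(j)
    return pres


def select_polymorphic(m: GenotypeMatrix, subset: list[str]) -> GenotypeMatrix:
    """Keep sites with >=2 distinct alleles observed among the subset's calls.

    Within-accession heterozygosity counts: a single {A,T} call makes a site
    polymorphic. The accession set is unchanged.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    idx = [m.acc_index(i) for i in subset]
    pres = _observed_allele_mask(m, idx)
    keep = pres.sum(axis=1) >= 2
    out = m.subset_sites(keep)
    logger.info("select_polymorphic: kept %d / %d sites", out.n_sites, m.n_sites)
    return out


def find_private_alleles(
    m: GenotypeMatrix,
    groups: dict[str, str],
    targets: list[str],
    min_in_group: int = 1,
    max_outside: int = 0,
) -> PrivateAlleleSet:
    """Alleles observed in >= ``min_in_group`` accessions of a target group and
    in <= ``max_outside`` accessions outside it (missing calls are no evidence)."""
    if not targets:
        raise ValueError("targets must be non-empty")
    for acc in m.accessions:
        if acc.id not in groups:
            raise ValueError(f"accession {acc.id!r} has no group assignment")
    # carrier counts per (site, allele) for each group and overall
    group_counts: dict[str, np.ndarray] = {}
    total = np.zeros((m.n_sites, MAX_PLOIDY), dtype=np.int32)
    for j, acc in enumerate(m.accessions):
        pres = m.allele_presence(j).astype(np.int32)
        total += pres
        g = groups[acc.id]
        group_counts.setdefault(g, np.zeros_like(total))
        group_counts[g] += pres
    entries = set()
    for g in targets:
        if g not in group_counts:
            continue
        inside = group_counts[g]
        outside = total - inside
        s_idx, a_idx = np.nonzero((inside >= min_in_group) & (outside <= max_outside))
        entries.update((int(s), int(a), g) for s, a in zip(s_idx, a_idx))
    return PrivateAlleleSet(entries=frozenset(entries))


def remove_private_allele_sites(m: GenotypeMatrix, p: PrivateAlleleSet) -> GenotypeMatrix:
    """Drop every site that carries at least one private-allele entry."""
    keep = np.ones(m.n_sites, dtype=bool)
    if len(p.entries):
        keep[p.site_indices] = False
    out = m.subset_sites(keep)
    logger.info("remove_private_allele_sites: kept %d / %d sites", out.n_sites, m.n_sites)
    return out


def relation_polymorphic_filter(m: GenotypeMatrix, members: list[str]) -> GenotypeMatrix:
    """Per-duo/trio filter: keep sites polymorphic within and/or between the
    members' genotypes; drop sites where any member is missing."""
    if len(members) not in (2, 3):
        raise ValueError("relation must have 2 or 3 members")
    idx = [m.acc_index(i) for i in members]
    any_missing = np.zeros(m.n_sites, dtype=bool)
    for j in idx:
        any_missing |= m.missing_mask(j)
    pres = _observed_allele_mask(m, idx)
    keep = (pres.sum(axis=1) >= 2) & ~any_missing
    out = m.subset_sites(keep)
    logger.info(
        "relation_polymorphic_filter(%s): kept %d / %d sites",
        ",".join(members), out.n_sites, m.n_sites,
    )
    return out
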