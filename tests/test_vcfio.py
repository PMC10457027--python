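"""Genotype model, VCF round-trips, and site filters."""

import numpy as np
import pytest

from polyparent import vcfio
from polyparent.vcfio import AccessionMeta

from conftest import build_matrix


def _write_vcf_text(path, body, samples):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr01,length=100000>\n"
        "##contig=<ID=chr02,length=100000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + body)


def test_read_vcf_decodes_multiploid_unphased_genotypes(tmp_path):
    """0/1/1 for a triploid is the multiset {ref,alt,alt}; ./. is missing;
    phased 0|1 reads the same as 0/1."""
    vcf = tmp_path / "t.vcf"
    _write_vcf_text(
        vcf,
        "chr01\t100\t.\tA\tT\t.\t.\t.\tGT\t0/1/1\t./.\t0|1\n"
        "chr01\t200\t.\tA\tT\t.\t.\t.\tGT\t1/1/1\t0/0\t0/1\n",
        ["trip", "dipA", "dipB"],
    )
    meta = [
        AccessionMeta("trip", 3),
        AccessionMeta("dipA", 2),
        AccessionMeta("dipB", 2),
    ]
    m = vcfio.read_vcf(vcf, meta)
    assert m.n_sites == 2
    assert m.genotype(0, "trip") == (0, 1, 1)
    assert m.genotype(0, "dipA") is None
    assert m.genotype(0, "dipB") == (0, 1)
    assert m.sites[0].alleles == ("A", "T")


def test_read_vcf_ploidy_mismatch_names_sample_and_site(tmp_path):
    vcf = tmp_path / "t.vcf"
    _write_vcf_text(vcf, "chr01\t100\t.\tA\tT\t.\t.\t.\tGT\t0/1\n", ["trip"])
    with pytest.raises(ValueError, match="trip.*chr01:100"):
        vcfio.read_vcf(vcf, [AccessionMeta("trip", 3)])


def test_read_vcf_missing_metadata_row_is_an_error(tmp_path):
    vcf = tmp_path / "t.vcf"
    _write_vcf_text(vcf, "chr01\t100\t.\tA\tT\t.\t.\t.\tGT\t0/1\n", ["dipA"])
    with pytest.raises(ValueError, match="dipA"):
        vcfio.read_vcf(vcf, [AccessionMeta("other", 2)])


def test_vcf_round_trip_preserves_genotypes_order_and_depth(tmp_path, clean_sim):
    m, _ = clean_sim
    out = tmp_path / "rt.vcf"
    vcfio.write_vcf(m, out)
    m2 = vcfio.read_vcf(out, list(m.accessions))
    assert [s.chrom for s in m2.sites] == [s.chrom for s in m.sites]
    assert [s.pos for s in m2.sites] == [s.pos for s in m.sites]
    assert np.array_equal(m2.genotypes, m.genotypes)
    assert np.array_equal(m2.depth, m.depth)
    assert [a.ploidy for a in m2.accessions] == [a.ploidy for a in m.accessions]


def test_metadata_round_trip(tmp_path):
    metas = [
        AccessionMeta("a", 3, group="cultivar", is_wild=False, clone_set="cs1",
                      chrom_ploidy_overrides={"chr02": 4}),
        AccessionMeta("b", 2, group="banksii", is_wild=True),
    ]
    path = tmp_path / "meta.tsv"
    vcfio.write_metadata(metas, path)
    back = vcfio.read_metadata(path)
    assert back == metas


def _toy_for_filters():
    sites = [("chr01", (i + 1) * 10, ("A", "T")) for i in range(4)]
    ma = AccessionMeta("a", 2)
    mb = AccessionMeta("b", 2)
    return build_matrix(
        sites,
        [
            # site0 monomorphic AA/AA; site1 het within a; site2 between;
            # site3 has a missing call in b
            (ma, [(0, 0), (0, 1), (0, 0), (0, 1)]),
            (mb, [(0, 0), (0, 0), (1, 1), None]),
        ],
    )


def test_select_polymorphic_examples():
    m = _toy_for_filters()
    out = vcfio.select_polymorphic(m, ["a", "b"])
    kept = [s.pos for s in out.sites]
    assert kept == [20, 30, 40]  # site0 dropped; within-accession het counts
    with pytest.raises(KeyError):
        vcfio.select_polymorphic(m, ["nope"])
    with pytest.raises(ValueError):
        vcfio.select_polymorphic(m, [])


def test_relation_polymorphic_filter_examples():
    m = _toy_for_filters()
    out = vcfio.relation_polymorphic_filter(m, ["a", "b"])
    # site3 dropped (missing member) even though polymorphic within a
    assert [s.pos for s in out.sites] == [20, 30]
    with pytest.raises(ValueError):
        vcfio.relation_polymorphic_filter(m, ["a"])


def _brute_polymorphic(m, ids):
    keep = []
    for i in range(m.n_sites):
        alleles = set()
        for acc in ids:
            g = m.genotype(i, acc)
            if g is not None:
                alleles.update(g)
        keep.append(len(alleles) >= 2)
    return keep


def test_filters_match_bruteforce_on_random_matrix(rng):
    sites = [("chr01", (i + 1) * 7, ("A", "T", "C")) for i in range(50)]
    specs = []
    for name in "abcd":
        meta = AccessionMeta(name, 2)
        gts = []
        for _ in range(50):
            if rng.random() < 0.1:
                gts.append(None)
            else:
                gts.append(tuple(sorted(rng.integers(0, 3, size=2))))
        specs.append((meta, gts))
    m = build_matrix(sites, specs)
    out = vcfio.select_polymorphic(m, ["a", "b", "c", "d"])
    expect = _brute_polymorphic(m, ["a", "b", "c", "d"])
    assert [s.pos for s in out.sites] == [
        s.pos for s, k in zip(m.sites, expect) if k
    ]
    # idempotence
    again = vcfio.select_polymorphic(out, ["a", "b", "c", "d"])
    assert [s.pos for s in again.sites] == [s.pos for s in out.sites]
    # relation filter against brute force
    duo = vcfio.relation_polymorphic_filter(m, ["a", "b"])
    expect_duo = [
        k and m.genotype(i, "a") is not None and m.genotype(i, "b") is not None
        for i, k in enumerate(_brute_polymorphic(m, ["a", "b"]))
    ]
    assert [s.pos for s in duo.sites] == [
        s.pos for s, k in zip(m.sites, expect_duo) if k
    ]
    dd = vcfio.relation_polymorphic_filter(duo, ["a", "b"])
    assert dd.n_sites == duo.n_sites


def test_private_alleles_trivial_cases():
    sites = [("chr01", 10, ("A", "T")), ("chr01", 20, ("A", "T"))]
    mA = AccessionMeta("wA", 2, group="A")
    mB = AccessionMeta("wB", 2, group="B")
    mX = AccessionMeta("xA", 2, group="A")
    # site0: T only in B; site1: T in B and in an A accession
    m = build_matrix(
        sites,
        [(mA, [(0, 0), (0, 0)]), (mB, [(0, 1), (0, 1)]), (mX, [(0, 0), (1, 1)])],
    )
    groups = {"wA": "A", "wB": "B", "xA": "A"}
    p = vcfio.find_private_alleles(m, groups, ["B"])
    assert p.entries == {(0, 1, "B")}
    with pytest.raises(ValueError):
        vcfio.find_private_alleles(m, groups, [])
    out = vcfio.remove_private_allele_sites(m, p)
    assert [s.pos for s in out.sites] == [20]
    # empty set is the identity; all-flagged leaves a valid empty matrix
    empty = vcfio.remove_private_allele_sites(m, vcfio.PrivateAlleleSet(frozenset()))
    assert empty.n_sites == m.n_sites
    allp = vcfio.find_private_alleles(m, groups, ["A", "B"])
    rest = vcfio.remove_private_allele_sites(m, allp)
    assert rest.n_sites == m.n_sites - len({s for s, _, _ in allp.entries})


def test_planted_private_alleles_recovered_exactly(clean_sim):
    """On the wild reference panel, recovered private alleles equal the
    simulator's planted single-owner alleles."""
    m, truth = clean_sim
    wild = sorted(a.id for a in m.accessions if a.is_wild)
    sub = m.subset_accessions(wild)
    groups = {a.id: a.group for a in sub.accessions}
    p = vcfio.find_private_alleles(sub, groups, sorted({g for g in groups.values()}))
    got = {(sub.sites[s].chrom, s % truth.config.sites_per_chrom, a, g)
           for s, a, g in p.entries}
    assert got == truth.private_alleles
    # after removal, no target-group-private allele remains observable
    cleaned = vcfio.remove_private_allele_sites(sub, p)
    p2 = vcfio.find_private_alleles(
        cleaned, groups, sorted({g for g in groups.values()})
    )
    assert not p2.entries


def test_clone_representatives(clean_sim):
    m, _ = clean_sim
    reps = m.clone_representatives([a.id for a in m.accessions])
    assert "M1" in reps and "M1c" not in reps


def test_effective_ploidy_overrides(clean_sim):
    m, _ = clean_sim
    eff = m.effective_ploidies("C_ANEU")
    assert set(eff[m.chroms == "chr02"]) == {4}
    assert set(eff[m.chroms == "chr01"]) == {3}
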