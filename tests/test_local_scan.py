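"""Windowed tracks, haplotype subtraction, coverage calls, track export."""

import numpy as np
import pytest

from polyparent import local_scan as ls
from polyparent import vcfio
from polyparent.simulate import SimConfig, simulate_pedigree, standard_design
from polyparent.vcfio import AccessionMeta

from conftest import build_matrix, flat_hap


def _filtered(m, members):
    mp = vcfio.select_polymorphic(m, [a.id for a in m.accessions])
    return vcfio.relation_polymorphic_filter(mp, members)


def test_window_count_is_sites_minus_window_plus_one(clean_plain_sim):
    m, truth = clean_plain_sim
    sub = _filtered(m, ["C_F1", "M1", "M2"])
    rel = ls.Relation("trio", "C_F1", "M1", 1, "M2", 1)
    tracks = ls.windowed_discordance(sub, rel, window=201)
    for t in tracks:
        s = int((sub.chroms == t.chrom).sum())
        assert len(t.values) == s - 200
        # centres start at the 101st SNP and end at the (S-100)th
        idx = np.flatnonzero(sub.chroms == t.chrom)
        assert t.centers[0] == sub.pos[idx[100]]
        assert t.centers[-1] == sub.pos[idx[-101]]


def test_true_trio_discordance_is_zero_at_zero_noise(clean_plain_sim):
    m, _ = clean_plain_sim
    sub = _filtered(m, ["C_F1", "M1", "M2"])
    rel = ls.Relation("trio", "C_F1", "M1", 1, "M2", 1)
    for t in ls.windowed_discordance(sub, rel):
        assert np.all(t.values == 0.0)


def test_false_trio_shows_contiguous_high_discordance(clean_plain_sim):
    m, _ = clean_plain_sim
    sub = _filtered(m, ["C_F1", "M3", "W_balbis"])
    rel = ls.Relation("trio", "C_F1", "M3", 1, "W_balbis", 1)
    tracks = ls.windowed_discordance(sub, rel)
    run = max(
        int(r)
        for t in tracks
        for r in _run_lengths(t.values > 0.2)
    )
    assert run >= 10  # a contiguous stretch of clearly discordant windows


def _run_lengths(mask):
    runs, n = [], 0
    for v in mask:
        n = n + 1 if v else 0
        runs.append(n)
    return runs or [0]


def test_short_chromosome_falls_back_to_single_window(clean_plain_sim, caplog):
    m, _ = clean_plain_sim
    sub = _filtered(m, ["C_F1", "M1", "M2"])
    tiny = sub.subset_sites(np.arange(50))
    rel = ls.Relation("trio", "C_F1", "M1", 1, "M2", 1)
    tracks = ls.windowed_discordance(tiny, rel)
    assert all(len(t.values) == 1 for t in tracks)


def test_windowed_restitution_flat_for_complete_gamete(clean_plain_sim):
    m, _ = clean_plain_sim
    sub = _filtered(m, ["C_TRI_CPL", "M2"])
    for t in ls.windowed_full_restitution(sub, "C_TRI_CPL", "M2"):
        assert np.all(t.values == 1.0)


def test_windowed_restitution_dips_at_planted_crossovers(clean_plain_sim):
    m, truth = clean_plain_sim
    sub = _filtered(m, ["C_TRI_REC", "M1"])
    tracks = {t.chrom: t for t in ls.windowed_full_restitution(sub, "C_TRI_REC", "M1")}
    gam = truth.children["C_TRI_REC"].gametes[0]
    S = truth.config.sites_per_chrom
    bp_per_site = truth.config.bp_per_site
    for chrom, b in gam.breakpoints:
        t = tracks[chrom]
        pos = (b + 0.5) * bp_per_site  # between raw sites b-1 and b
        overlapping = (t.starts <= pos) & (t.ends >= pos)
        assert np.any(t.values[overlapping] < 1.0)


def test_restitution_requires_higher_child_ploidy(clean_plain_sim):
    m, _ = clean_plain_sim
    with pytest.raises(ValueError):
        ls.windowed_full_restitution(m, "C_F1", "M1")


def test_subtract_parent_small_examples():
    sites = [("chr01", 10, ("A", "T")), ("chr01", 20, ("A", "T")),
             ("chr01", 30, ("A", "T"))]
    child = AccessionMeta("c", 3)
    par = AccessionMeta("p", 2)
    m = build_matrix(
        sites,
        [(child, [(0, 1, 1), (0, 0, 1), (0, 0, 0)]),
         (par, [(0, 1), (0, 1), (1, 1)])],
    )
    d = ls.subtract_parent(m, "c", "p")
    assert d.residual_tuple(0) == (1,)   # ATT - AT = T
    assert d.residual_tuple(1) == (0,)   # AAT - AT = A
    assert d.conflict[2]                 # AAA cannot contain TT


def test_subtraction_recovers_second_gamete_and_readds(clean_plain_sim):
    m, truth = clean_plain_sim
    d = ls.subtract_parent(m, "C_TRI_CPL", "M2")
    assert not d.conflict.any() and not d.missing.any()
    want = flat_hap(truth.children["C_TRI_CPL"].gametes[1].haplotypes[0])
    sizes = d.residual_sizes()
    assert np.all(sizes == 1)
    got = d.residual[:, 0]
    assert np.array_equal(got, want)
    # re-adding the parent reconstructs the child exactly
    pj = m.acc_index("M2")
    cj = m.acc_index("C_TRI_CPL")
    for i in range(0, m.n_sites, 97):
        readd = tuple(sorted(m.genotype(i, pj) + d.residual_tuple(i)))
        assert readd == m.genotype(i, cj)


def _aneuploid_sim():
    cfg = SimConfig(seed=21, n_chroms=3, sites_per_chrom=2000, error_rate=0.0,
                    missing_rate=0.0)
    return simulate_pedigree(cfg, standard_design(with_aneuploidy=True))


@pytest.fixture(scope="module")
def aneuploid_sim():
    return _aneuploid_sim()


def test_coverage_profile_flat_without_aneuploidy(aneuploid_sim):
    m, _ = aneuploid_sim
    tracks = ls.coverage_profile(m, "M1", window=25)
    for t in tracks:
        assert not t.calls
        assert np.allclose(t.ratios, 1.0, atol=0.15)


def test_coverage_profile_detects_whole_chromosome_gain(aneuploid_sim):
    m, truth = aneuploid_sim
    tracks = {t.chrom: t for t in ls.coverage_profile(m, "C_ANEU", window=100)}
    gained = tracks["chr02"]
    assert gained.calls, "supernumerary chromosome not called"
    call = gained.calls[0]
    assert call.copy_ratio == pytest.approx(4 / 3, abs=0.05)
    assert call.start_window == 0 and call.end_window == len(gained.ratios)
    assert not tracks["chr01"].calls


def test_coverage_profile_terminal_loss_boundary(aneuploid_sim):
    m, truth = aneuploid_sim
    region = next(a for a in truth.aneuploid_regions if a.kind == "loss")
    window = 100
    tracks = {t.chrom: t
              for t in ls.coverage_profile(m, region.accession, window=window,
                                           margin=0.15, min_run=5)}
    calls = tracks[region.chrom].calls
    assert calls
    call = calls[0]
    assert call.copy_ratio == pytest.approx(3 / 4, abs=0.05)
    true_start_window = region.start_site // window
    assert abs(call.start_window - true_start_window) <= 2
    assert call.end_window == len(tracks[region.chrom].ratios)


def test_coverage_requires_depth(clean_plain_sim):
    m, _ = clean_plain_sim
    bare = vcfio.GenotypeMatrix(list(m.sites), list(m.accessions), m.genotypes, None)
    with pytest.raises(ValueError):
        ls.coverage_profile(bare, "M1")


def test_export_tracks_round_trip(tmp_path, clean_plain_sim):
    m, _ = clean_plain_sim
    sub = _filtered(m, ["C_F1", "M1", "M2"])
    rel = ls.Relation("trio", "C_F1", "M1", 1, "M2", 1)
    tracks = ls.windowed_discordance(sub, rel)
    files = ls.export_tracks(tracks, tmp_path, plot=False)
    assert len(files) == 1
    chroms, centers, values = ls.read_track(files[0])
    got_centers = np.concatenate([t.centers for t in sorted(tracks, key=lambda t: t.chrom)])
    got_values = np.concatenate([t.values for t in sorted(tracks, key=lambda t: t.chrom)])
    assert np.array_equal(centers, got_centers)
    assert np.allclose(values, got_values, atol=1e-6)
    assert np.all((values >= 0) & (values <= 1))
    # empty track list -> empty manifest
    assert ls.export_tracks([], tmp_path / "empty") == []


def test_windowed_mean_consistent_with_global_proportion(noisy_sim):
    """Mean of windowed discordance over a chromosome tracks the global
    chromosome-wide discordance to within 0.01 (global vs local agreement)."""
    from polyparent import global_scan as gs

    m, truth = noisy_sim
    sub = _filtered(m, ["C_F1", "M1", "M2"])
    v = gs.verdict_vector_trio(sub, "C_F1", "M1", "M2", 1, 1)
    rel = ls.Relation("trio", "C_F1", "M1", 1, "M2", 1)
    for t in ls.windowed_discordance(sub, rel):
        idx = np.flatnonzero(sub.chroms == t.chrom)
        global_disc = 1.0 - np.nanmean(v[idx])
        assert abs(np.nanmean(t.values) - global_disc) < 0.01
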