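import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from polyparent.simulate import SimConfig, simulate_pedigree, standard_design
from polyparent.vcfio import AccessionMeta, GenotypeMatrix, Site


def build_matrix(site_specs, accession_specs, depth=None) -> GenotypeMatrix:
    """Hand-build a matrix from compact specs.

    site_specs: list of (chrom, pos, alleles tuple)
    accession_specs: list of (AccessionMeta, [genotype tuple or None per site])
    """
    sites = [Site(chrom=c, pos=p, alleles=a) for c, p, a in site_specs]
    metas = [m for m, _ in accession_specs]
    geno = np.stack(
        [
            np.stack([GenotypeMatrix.pack_genotype(g) for g in gts])
            for _, gts in accession_specs
        ],
        axis=1,
    )
    return GenotypeMatrix(sites, metas, geno, depth)


def flat_hap(hap_by_chrom: dict, n_sites_per_chrom: int | None = None) -> np.ndarray:
    """Concatenate a per-chromosome haplotype dict in site-grid order."""
    return np.concatenate([hap_by_chrom[c] for c in sorted(hap_by_chrom)])


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation of the standard pedigree (incl. aneuploids)."""
    cfg = SimConfig(seed=11, error_rate=0.0, missing_rate=0.0)
    return simulate_pedigree(cfg, standard_design(with_aneuploidy=True))


@pytest.fixture(scope="session")
def clean_plain_sim():
    """Noise-free simulation without planted aneuploidy."""
    cfg = SimConfig(seed=13, error_rate=0.0, missing_rate=0.0)
    return simulate_pedigree(cfg, standard_design(with_aneuploidy=False))


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise simulation of the standard pedigree (no aneuploids)."""
    cfg = SimConfig(seed=12)
    return simulate_pedigree(cfg, standard_design())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
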