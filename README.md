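# polyparent

Parentage inference and gamete-type detection for polyploid, clonally
propagated crops, from unphased multi-sample SNP genotypes.

Banana-like cultivars are diploid to tetraploid inter(sub)specific hybrids,
frozen by centuries of vegetative propagation. Because a cultivar's genotype
is fixed, direct parent–child relationships from hybridisations that happened
long ago are still detectable — if the test handles mixed ploidies, unreduced
gametes, and aneuploidy. `polyparent` implements that test and everything
around it, exercised end-to-end on a built-in pedigree simulator with full
ground truth.

## The statistic

At a SNP site, a parent with genotype multiset *G* can transmit any multiset
of *k* alleles drawn with repetition from the distinct alleles of *G* (a
parent A/T/T can give the diploid gametes AA, AT, TT). For a candidate trio
(child *c*; parents *p₁*, *p₂*) and a gamete-ploidy split (*k₁*, *k₂*) with
*k₁ + k₂* = ploidy(*c*), the site is **compatible** when

> *c* ∈ { g₁ ⊎ g₂ : g₁ ∈ Γ(p₁, k₁), g₂ ∈ Γ(p₂, k₂) }

where Γ(p, k) is the gamete set and ⊎ multiset union. The genome-wide
**concordance** is the fraction of compatible sites; trios reaching a
calibrated threshold (default 0.999) are accepted, and among accepted parent
pairs for one child only those of minimal cumulative ploidy are kept.
Single-parent (duo) tests ask whether some 1x or 2x gamete fits inside the
child, and whether the parent's **complete genotype** is contained in the
child at (nearly) every site — the genome-wide signature of an un-recombined
unreduced gamete (2x^c from a diploid, 3x^c from a triploid). The same
predicates evaluated in sliding 201-SNP windows localise discordant regions;
subtracting a confirmed complete-gamete donor from the child exposes the
other parent's gamete, whose ancestry mosaic is painted window-by-window
with group-diagnostic alleles from wild reference panels. Read-depth
profiles along chromosomes flag supernumerary chromosomes (1x+1 gametes)
and segmental losses, with per-chromosome ploidy overrides feeding back
into the genotype model.

The package also provides the closed-form expectation for unbalanced-gamete
production by a reciprocal-translocation heterozygote
(1 − (1/2)^t; 75 % for t = 2), which explains why unreduced gametes are
over-represented among the viable gametes of structurally heterozygous
cultivars.

## Worked example

```python
from polyparent import (SimConfig, simulate_pedigree, standard_design,
                        select_polymorphic, trio_statistic, duo_statistic,
                        relation_polymorphic_filter, subtract_parent)

cfg = SimConfig(seed=7, error_rate=0.0, missing_rate=0.0)
matrix, truth = simulate_pedigree(cfg, standard_design())
poly = select_polymorphic(matrix, [a.id for a in matrix.accessions])

res = trio_statistic(poly, "C_TRI_CPL", "M2", "M4")
for (k1, k2), (n, c) in res.configurations.items():
    print(f"config {k1}x+{k2}x: {c}/{n} = {c/n:.4f}")

duo = duo_statistic(relation_polymorphic_filter(poly, ["C_TRI_CPL", "M2"]),
                    "C_TRI_CPL", "M2")
print(f"duo: 1x={duo.prop_1x:.4f} 2x={duo.prop_2x:.4f} full={duo.prop_full:.4f}")
ded = subtract_parent(poly, "C_TRI_CPL", "M2")
print("conflicts:", int(ded.conflict.sum()))
```

prints

```
config 1x+2x: 1159/1200 = 0.9658
config 2x+1x: 1200/1200 = 1.0000
duo: 1x=1.0000 2x=1.0000 full=1.0000
conflicts: 0
```

The simulated triploid `C_TRI_CPL` was formed from an un-recombined 2x
gamete of `M2` plus a 1x gamete of `M4`: the trio is perfectly concordant
only in the configuration where `M2` donates the 2x gamete, the duo test
confirms a complete `M2` genome inside the child (`full=1.0`), and
subtraction leaves a clean one-copy residual — the `M4` gamete — at every
site, ready for ancestry painting.

The same stages are available from a shell:

```bash
polyparent run --demo --out demo_out --seed 7
```

writes the simulated VCF, trio/duo scan tables, selected trios, windowed
discordance tracks, deduced-gamete mosaics, coverage calls and a
checksummed manifest.

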