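# Methods

## Genotype model

Genotypes are unordered allele multisets: data of this kind are unphased, so
a triploid call `0/1/1` carries no more information than {ref, alt, alt}.
Ploidy is per accession (2–4) with per-chromosome overrides for aneuploids
(e.g. a triploid re-called at ploidy 4 on a supernumerary chromosome); every
statistic resolves the effective ploidy at each site through the override.
Missing genotypes are treated as absence of evidence everywhere: a site with
a missing member is excluded from both numerator and denominator of any
proportion, and a missing call contributes nothing to polymorphism or
private-allele evidence. This is the conservative choice; no imputation is
attempted.

Multiallelic sites are handled natively — the multiset machinery never
assumes two alleles — although the simulator emits biallelic SNPs.

## Compatibility predicates

Gametes of ploidy k are all k-multisets drawn **with repetition from the
distinct alleles** of the parent genotype, so an allele present once may
fill the whole gamete (AA is a legal diploid gamete of an A/T/T parent).
This deliberately admits cytologically exotic gametes; it is the convention
under which the concordance statistic is defined, and the brute-force
oracles in the test suite enumerate ordered draws independently to pin it
down. Trio compatibility asks for exact multiset identity between the child
and some union of one gamete per parent. For a triploid child both
orderings of the (1,2) split are evaluated and reported separately. Gamete
ploidies are capped at the parent's own ploidy and at 3; 3x gametes are
tested only for tetraploid children (a triploid×triploid cross is tested as
1+2/2+1, never 3+0).

Duo tests are containment tests: a 1x contribution holds if the parent and
child share an allele; a 2x contribution if some diploid gamete of the
parent fits inside the child; complete restitution if the parent's entire
genotype multiset is contained in the child. Containment gives the logical
chain restitution ⇒ 2x ⇒ 1x, which the suite asserts as a property.

## Selection rules

Trios are accepted at concordance ≥ `trio_threshold` (default 0.999) and
then filtered per child to the minimal cumulative parental ploidy —
diploids are more plausible parents than triploids. Ties are all reported;
the statistic genuinely cannot distinguish certain configurations (a child
whose complete genome sits inside a relative produces systematically
conflicting trios), so tie reporting is a feature, not a fallback. Duos use
a fixed 0.99 threshold rather than a data-driven change-point on the
statistic's distribution; both thresholds are configuration values.

A note on the 0.999 default and genotyping error: a trio involves 6–8
allele calls per site, and with a per-allele error rate e the expected
per-site discordance of a *true* trio is roughly 1–3 e (measured ≈0.8–1.4e-3
at e = 5·10⁻⁴ on simulated pedigrees, the complete-2x configuration being
the most error-sensitive because every parental allele must be present in
the child). The fixed 0.999 threshold therefore sits inside the noise band
of true trios at that error rate, and per-trio acceptance becomes a coin
toss regardless of the number of sites. The robust procedure — implemented
in `scripts/acceptance.py` alongside the fixed threshold — is the
calibration the statistic was designed for: set the threshold to the
minimum concordance observed across synthetic first-generation trios with
known parents, which adapts it to the effective error rate of the dataset.
Separation from non-parents is not the issue: unrelated founder pairs top
out near 0.93, far below either threshold.

Accessions belonging to one clone set (somaclones, duplicates) are
represented by their lexicographically first member in all scans.

## Windowed validation

Local validation slides a 201-SNP window (step 1) along each chromosome of
the relation-filtered site set and reports the discordance (or restitution)
proportion at the window's central SNP. Step 1 is chosen because the
statistic is cheap and maximally overlapping windows give the smooth curves
needed to localise breakpoints; the odd window size defines an exact
centre. Windows are never truncated — the first and last centres are SNPs
101 and S−100 — and a chromosome shorter than the window collapses to a
single whole-chromosome window with a logged warning. Sites whose effective
child ploidy does not match the tested gamete split are skipped, which lets
an aneuploid chromosome analysed at its override ploidy pool with the rest
of the genome.

A complete (un-recombined) unreduced gamete yields a restitution track
pinned at 1.0; each crossover of a recombined gamete flips the
same-parental-haplotype state on one side of the breakpoint, so every
crossover borders a depressed run and windows overlapping the breakpoint
dip below 1. Detection fails only when the depressed side contains no
informative heterozygous site within window reach — rare at realistic
heterozygosity.

## Haplotype subtraction and painting

When a parent's complete genome is confirmed inside a child, subtracting
its multiset per site leaves the gamete contributed by the other parent.
Sites where the parent is not contained are flagged CONFLICT (never
exceptions — downstream stages skip them); re-adding the parent at
non-conflict sites reconstructs the child exactly.

Ancestry painting uses group-diagnostic alleles learned from wild reference
accessions: an allele is diagnostic of a group when carried by ≥ 80 % of
that group's references and by none of the others (`f_min=0.8`,
`f_out=0`). Painting windows tile the *diagnostic* sites (default 100 per
window, the trailing remainder joining the last window); per window each
group's ratio is the fraction of its diagnostic sites whose allele the
haplotype carries, and the label is the argmax group if its ratio reaches
`min_ratio` (default 0.5), else "unknown". Mosaic agreement between two
paintings counts identically labelled windows, excluding "unknown" from the
denominator. When painted mosaics are compared with simulation truth, the
truth is projected onto the same window grid with the same ratio
definition, and windows that straddle a true ancestry-segment boundary are
excluded: at window resolution either label is defensible there.

## Coverage profiling

Aneuploid segments are called from windowed mean SNP depth normalised by
the **median** of all windowed means for the accession (the genome-wide
mean would be inflated by the aneuploid chromosome itself on the compact
simulated genomes used here; at real chromosome counts the two baselines
coincide). A call is a run of at least `min_run` (default 20) consecutive
windows deviating from 1 by more than `margin` (default 0.2) on the same
side, reported with its mean copy ratio. With Poisson-distributed depth d
and w sites per window the ratio's standard error is √(d·w)⁻¹·√d ≈
√(d/w)/d, so windows of ≥ ~100 sites are needed at 30× depth before the
0.75-vs-0.8 gap of a one-copy loss in a tetraploid is resolved reliably;
the defaults assume that regime and both knobs are exposed.

## The simulator

The generator emulates the structure of a clonal-crop resequencing panel:

- **Ancestral groups** (3–5; default 4, named after *Musa* taxa). Each has
  one haploid reference profile. A site is diagnostic of one group with
  probability `ancestry_divergence` (default 0.2); every other site carries
  the derived allele in exactly two groups, so all sites are polymorphic
  across the panel and the set of group-private alleles is known exactly.
- **Wild references** sit at their group consensus (two per group in the
  standard design, as clone sets — a single reference per group would turn
  one missing call into a false private allele).
- **Cultivar founders** are mosaics over 2–3 groups with geometric segment
  lengths (`segment_mean_sites`, default 200) and carry haplotype-private
  deviations from the profiles at rate `within_group_diversity` (default
  0.1) — unsampled within-(sub)species variation plus mutations accumulated
  over clonal propagation. Without this term, two haplotypes of the same
  ancestry would be identical and one accession's alleles could always be
  substituted by another's, making crossovers in unreduced gametes
  undetectable and non-parents artificially compatible.
- **Gametes**: 1x (Poisson crossovers, default 1 per chromosome), 1x+1
  (a second independently recombined copy of one chromosome), recombined 2x
  (two independently recombined haplotypes, ≥1 breakpoint enforced
  genome-wide), complete 2x and complete 3x (exact copies — the
  meiosis-I-failure signature, full parental heterozygosity retained).
- **Aneuploidy**: whole-chromosome gain through the 1x+1 gamete (child
  re-called at ploidy +1 there, mirrored in depth) and terminal segmental
  loss (one haplotype removed; the genotype caller is emulated as forced to
  the declared ploidy, duplicating a remaining allele — a dosage error —
  and depth drops to (p−1)/p).
- **Noise**: each allele call flips to another site allele independently
  with `error_rate` (default 5·10⁻⁴); whole genotypes go missing with
  `missing_rate` (default 10⁻²). Depth is Poisson(30 × copy ratio).

All randomness derives from one integer seed; simulation is
bit-reproducible. Truth records include every gamete haplotype, crossover
breakpoint, ancestry mosaic, aneuploid region and group-private allele.

What the simulator does **not** model: within-accession sequencing
artefacts correlated across samples, linkage-disequilibrium structure and
realistic recombination maps, selection or gamete viability (beyond the
closed-form translocation expectation), segregating variation *within* the
wild reference panels, and genotype-likelihood uncertainty. Passing tests
therefore demonstrate the statistics' behaviour under idealised error,
not performance on any real resequencing panel.

## Problem sizes

The default simulated panel is 2 chromosomes × 600 SNPs (the demo
pipeline's scale; it completes in seconds). Experiments that probe
thresholds near 10⁻³ use 2 × 5000 SNPs over 50 (tests) or 20 (acceptance
script) pedigrees — a 0.999 threshold needs thousands of sites to resolve.
Painting fidelity uses 2 × 6000 SNPs with 3000-site ancestry segments so
that segments span several painting windows, and coverage calling uses
3 × 12000 SNPs with 150-site windows so a 30 % terminal loss spans the
20-window minimum run. These sizes are stated here so results can be
reproduced exactly; scaling any of them up changes precision, not
behaviour.

## Known limitations

- The concordance statistic has no error model; near-threshold decisions
  inherit the genotyping error rate (see the calibration note above).
- Painting is single-haplotype ratio painting, sufficient for deduced 1x
  (or disomic 1x+1) gametes; dosage-aware painting of full polyploid
  accessions is an extension point, not implemented.
- Duo selection uses a fixed threshold; the change-point procedure on the
  empirical distribution of duo statistics is not implemented.
- Coverage calling is a fixed-margin run-length rule, not a segmentation
  model; boundaries are resolved to the window, not the site.
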