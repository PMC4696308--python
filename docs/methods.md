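# Methods

This note documents the models and procedures implemented in `ssrscape`,
the numerical conventions chosen where several were defensible, and what
the synthetic data generators do and do not emulate.

## Perfect SSR detection

A perfect SSR is a maximal uninterrupted tandem run of a 1–6 bp motif.
The scanner reports, for each period *p* = 1..6, every maximal run (a
stretch where `s[i] == s[i-p]`), subject to:

* **Smallest-period rule.** A run is reported once, at the smallest
  period that explains its full extent. `ATATATAT…` is a dinucleotide
  run, never a tetranucleotide one; `ACGACG…` is never reported at
  period 6. This matches the behaviour of the classic perfect-mode
  repeat finders.
* **Complete copies only.** The reported span is truncated to whole
  motif copies; a trailing partial copy is excluded from both span and
  count. `end − start + 1 == unit_length × repeat_count` always holds.
* **Left-maximality.** Runs are extended as far left as the sequence
  allows, which fixes the reported motif phase (e.g. a `G` preceding a
  `CAG` tract yields a `GCA` run one base earlier).
* **Thresholds.** Minimum complete-copy counts per unit length default
  to 14 (mono), 7 (di), 5 (tri), 4 (tetra/penta/hexa). These are the
  standard perfect-search settings for compact fungal genomes.
* `N` and any other non-ACGT character break runs; soft-masked
  lowercase is uppercased and scanned. Adjacent distinct repeats are
  reported as independent loci (no compound-SSR merging).

Coordinates are 1-based inclusive everywhere (GFF3 convention).

**Motif canonicalization.** Two motifs are equivalent when one is a
cyclic rotation of the other or of its reverse complement, since a
repeat tract can be read in any phase and from either strand. The
canonical representative is the lexicographically smallest string over
the equivalence class. Primitive trinucleotides fall into exactly ten
classes (AAC, AAG, AAT, ACC, ACG, ACT, AGC, AGG, ATC, CCG).

The scanner is validated against a brute-force oracle that tests every
(start, period) pair on random sequences, and by an exact-recovery check
on genomes with planted repeats.

## Positional categories

Nine categories tile every scaffold position exactly once: EXON
(CDS-overlapping), UTR5, UTR3, INTRON (transcript minus the former),
UP_0_50 / UP_50_500 (1–50 and 51–500 bp upstream of the transcript in
its transcription direction), DOWN_0_50 / DOWN_50_500 (downstream
analogues), and DISTAL (further than 500 bp from any transcript).

Conventions, chosen where a judgment call was needed:

* Genic categories always beat a neighbouring gene's flank; within genic
  features precedence is EXON > UTR5 > UTR3 > INTRON.
* When UTR features are absent from the annotation, UTRs are derived as
  exon-minus-CDS, sided by strand.
* Flank distance is measured from the transcript's outermost coordinate
  (outer UTR edge); the bins are closed, d ∈ [1, 50] and d ∈ [51, 500].
* Where the flanks of two genes overlap, the nearer gene wins; at equal
  distance the upstream bin wins.
* An SSR is assigned the category containing its midpoint — a
  deterministic, strand-symmetric rule for boundary-spanning loci.
  Intragenic means EXON ∪ INTRON ∪ UTR5 ∪ UTR3; intergenic is the rest.

Densities are size-standardized as loci per Mbp of category (and total
SSR bp per Mbp), so categories of very different extent are comparable.
Departure from random placement is tested with a chi-square
goodness-of-fit test whose expected counts are proportional to category
sizes (df = k − 1 over the k non-empty categories).

Gene-term over-representation among SSR-bearing coding genes uses a
one-sided Fisher's exact test (hypergeometric upper tail) per term, with
Benjamini–Hochberg control of the false discovery rate across terms.
The gene→term mapping is consumed as input, never computed.

## Haplotypic population genetics

Individuals are haploid multilocus genotypes; each genotype is one
haplotype. The genetic distance between two individuals is the number
of loci at which their alleles differ, which is the sum of per-locus 0/1
distances and is used directly as the squared distance in the AMOVA sums
of squares. Missing alleles are handled by pairwise deletion in
distances and by available-count frequencies in allele statistics.

**Hierarchical AMOVA.** With N individuals in P populations nested in G
species, sums of squares follow the standard distance formulation
(`SS_total = Σ_{i<j} δ_ij / N`, within-stratum terms analogous per
group, among-strata terms by subtraction) with d.f. (G−1, P−G, N−P).
Variance components use the unbalanced-design coefficients

    n   = (N − Σ_g Σ_{p∈g} n_p²/N_g) / (P − G)
    n′  = (Σ_g Σ_{p∈g} n_p²/N_g − Σ_p n_p²/N) / (G − 1)
    n″  = (N − Σ_g N_g²/N) / (G − 1)

giving σc² = MS_WP, σb² = (MS_AP − σc²)/n, σa² = (MS_AG − σc² −
n′σb²)/n″, and Φ_CT = σa²/σ², Φ_SC = σb²/(σb²+σc²), Φ_ST =
(σa²+σb²)/σ². On balanced designs n′ = n and n″ = nP, recovering the
textbook expected mean squares. Negative components are reported as-is
(the usual AMOVA convention); an opt-in mode truncates them at zero.
When total variance is zero the Φ statistics are undefined and reported
as NaN, never as 0. The implementation is checked against an
independent brute-force oracle using exact rational arithmetic.

**Permutation tests** use the schemes appropriate to each statistic:
individuals among all populations for Φ_ST, individuals among
populations within species for Φ_SC, and whole populations among
species for Φ_CT, with p = (#{perm ≥ obs} + 1)/(n_perm + 1) and a
mandatory seed. The default is 10,000 permutations. Note a structural
resolution limit: permuting whole populations over a 2+3 design admits
only C(5,2) = 10 distinct assignments, so the Φ_CT p-value cannot fall
below ≈ 0.1 regardless of signal strength; designs with more populations
are needed for that test to resolve at α = 0.05.

**Per-locus statistics.** The per-locus Fst is the two-level Φ_ST
across all populations (species grouping ignored); the three-level
per-locus variance percentages are emitted alongside. Gene flow is
derived via the island-model relation Fst = 1/(4Nm + 1), reported as
2Nm = (1/Fst − 1)/2, defined for 0 < Fst ≤ 1.

**Allelic diversity.** Na is the count of distinct alleles, Ne = 1/Σp_i²
the effective number of alleles; private and shared alleles are defined
at the species level (observed in exactly one species vs in both).
Summaries report mean ± s.e. across loci within each locus category.

**PCoA.** Principal coordinates are computed by Gower-centering the
element-wise squared distance matrix (B = −½ J D² J) and
eigendecomposing. Coordinates are eigenvectors scaled by √λ for
positive eigenvalues; negative eigenvalues (non-Euclidean distances,
common for allele-identity counts) are dropped with a warning, and
proportions explained are relative to the sum of positive eigenvalues.
The implementation is cross-checked against scikit-bio's PCoA in the
test suite.

**Variance comparison across locus categories** uses pairwise two-sample
variance-ratio F-tests (larger variance over smaller, two-tailed p,
Benjamini–Hochberg across pairs), with a compact-letter-display helper
derived from the non-significance graph. A locus category needs at
least two loci for the test to be defined; zero variance in both samples
is flagged as undefined.

## Synthetic data

**Genome generator.** Scaffolds carry evenly spaced gene models (UTR5 —
CDS exons with introns — UTR3, random strand) with > 500 bp distal gaps.
Background sequence is drawn at a configurable GC content and
rejection-scanned: any accidental SSR at detection thresholds is
re-randomized until the scan is clean. Requested loci are then planted
wholly inside intervals of their target category, with guard bases
preventing run extension, and the result is re-verified so that the
detectable loci are exactly the planted ones. Planting below detection
thresholds, or into categories too small to host the locus, is an error.
Generation is deterministic given the spec (seed included).

**Population generator.** Each locus evolves under a bounded strict
stepwise mutation model: a lineage of length t accumulates
Poisson(μ·t) mutations of ±1 repeat, reflecting at the repeat-count
bounds [r_min, r_max]. The lineage structure per locus is:

1. an ancestral repeat count per locus category;
2. two species branches diverging `t_species` generations ago and
   evolving independently until `t_populations`;
3. a founder pool per species (size = `founders`, small for the
   invasive/bottlenecked species) whose lineages diverge at
   `t_populations` and evolve until `t_individuals`;
4. each population draws a with-replacement subsample of
   `pop_founders` pool lineages (founder drift, the source of
   among-population differentiation), individuals draw their ancestor
   from that subsample and evolve independently for `t_individuals`
   generations (star genealogy within populations).

Genealogies are independent across loci, i.e. loci recombine freely
between sexual generations. Allele sizes are emitted as
`repeats × unit_length + flank` bp, as a fragment-size genotyping assay
would report them, so all sizes at a locus are congruent modulo the unit
length. A truth table records each individual's pool lineage and
mutation count per locus, which distinguishes identity-by-descent from
size homoplasy.

Default design and parameters (the conditions all downstream tests run
under): 39 trinucleotide loci — 11 OUT, 9 UP, 13 IN, 6 DOWN; an
invasive species with 2 populations of 10 individuals founded from a
pool of 2, and a native species with 3 populations (10+10+11) and a pool
of 20; `t_species` = 30,000, `t_populations` = 4,000, `t_individuals` =
150 generations; μ = 10⁻³ steps/generation at all loci; repeat-count
bounds (5, 45) for OUT/DOWN, (8, 22) for UP, (8, 12) for IN — the
narrow exonic/upstream bounds model length constraint, the small founder
pool the introduction bottleneck of an invasive species. These values
were chosen once so that the simulated data reproduce the qualitative
regime reported for two-species fungal microsatellite panels: roughly a
quarter to a third of variance between species, a few percent among
populations within species, the balance among genotypes within
populations, multilocus Φ_ST around 0.35, and clearly reduced allelic
diversity at bounded loci and in the bottlenecked species.

**What the generators do not emulate.** No coalescent within
populations (star genealogies underestimate within-population identity
structure); no migration or admixture between species; no linkage
between loci; no multi-step mutations or indels in flanks; gene models
have fixed-size features; background sequence composition is i.i.d.
Tests passing on these data therefore validate the statistical
machinery and its contracts, not the realism of any particular
biological inference.

## Problem sizes

Unit and acceptance tests run on synthetic genomes of 25–55 kb with
10–18 planted loci, genotype datasets of 51 individuals × 39 loci, up to
200 simulation replicates for directional checks, and 99–999
permutations where significance is assessed (10,000 remains the CLI
default). The brute-force SSR oracle runs on 2–3 kb random sequences;
the exact-rational AMOVA oracle on designs of ≤ 10 individuals. The
Φ_CT power check uses five populations per species so the
whole-population permutation scheme can resolve p < 0.05 (see above).

## Known limitations

* The scanner is designed for perfect repeats only; imperfect,
  interrupted or compound SSR models are out of scope.
* Region classification assumes a well-formed GFF3 with transcripts and
  CDS; transcripts without exons are skipped with a warning.
* AMOVA assumes populations nested in species; a population spanning
  species is rejected at construction.
* The per-locus Fst convention (two-level Φ_ST across all populations)
  is one of several defensible readings; the three-level decomposition
  is emitted alongside so either can be used.
* Permutation p-values are lower-bounded by 1/(n_perm + 1) and, for
  Φ_CT, by the combinatorics of the population-permutation scheme.
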