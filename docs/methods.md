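# Methods

## Cross model and synthetic pedigrees

The generative model is a two-parent outbred cross in a female-heterogametic
(ZW) species.  The mother is W/Z at the sex-determining region, the father
Z/Z; an offspring is female iff the maternal gamete carries W at the SD
locus.  A sex-ratio-distorter (SR) locus, placed on the same chromosome, may
declare any set of unordered (maternal haplotype, paternal haplotype)
combinations lethal; zygotes drawing a lethal combination are rejected and
sampling continues until the requested number of survivors is reached.
Rejection is implemented post-zygotically, but the surviving-genotype
distribution is identical under pre-zygotic elimination, which marker data
cannot distinguish — the package therefore makes no claim about timing.

Meiosis has no crossover interference: a crossover falls between adjacent
loci independently with the recombination fraction implied by their cM gap,
`r = (1 − e^(−2d))/2` (Haldane, default) or `r = tanh(2d)/2` (Kosambi);
chromosomes segregate independently.  The SD and SR positions are carried as
virtual loci through the same crossover process as the markers, so
recombination between markers and either locus is modelled exactly.

Two presets emulate the study conditions:

- **S5** — 271 survivors (expected 2:1 F:M), mother `78021`, father `81084`,
  lethal pair (Z₃, Z₁); SD = SR = 60.7 cM on chromosome 15.
- **S3** — 516 survivors (even ratio), different mother (`78195`), same
  father and paternal haplotypes, no lethal pair.

The shared marker map puts 40 maternally and 16 paternally informative
markers plus 4 biparental ones on the 54.5–75.8 cM focal region of
chromosome 15 (the marker counts used for haplotype inference in the
emulated cross; one maternal and one paternal marker sit exactly at
60.7 cM, mirroring the mapped position of the morphological sex marker), a
second chromosome of unlinked markers as a null set, and a small "unknown"
chromosome group so that region summaries exercise all three buckets.
Marker density and the informativeness mix outside these counts are free
parameters of the generator; positions are drawn uniformly once with a fixed
construction seed, so the presets are constants.

Genotyping noise emulates GBS-style data: each call is dropped to missing
with rate 0.1 and each surviving call replaced by a different valid code
with rate 0.005 (defaults, overridable).  These are typical magnitudes for
the marker matrices this pipeline targets, not estimates from any particular
dataset.  What the generator does **not** emulate: read-level sequencing
error structure, allele-dropout asymmetry (errors here are symmetric across
codes), linked error correlation, segregation-distorted regions beyond the
single SR locus, and genotyping batch effects.  Passing tests therefore
demonstrate correctness of the inference chain under a clean meiotic model
with unstructured noise, not robustness to every artefact of real GBS data.

## Segregation-distortion scan

Markers are classified from the parental genotypes (maternal = mother
heterozygous, father homozygous; paternal = converse; both heterozygous =
biparental; otherwise uninformative).  After an optional per-marker
completeness filter (default 70%), each single-parent-informative marker's
sex × genotype table is tested with the two-sided exact conditional test —
Fisher's 2×2, or the Freeman–Halton extension when genotyping error
introduces a third genotype class.  The test is implemented by enumeration
in exact integer arithmetic: every table with the observed margins whose
conditional probability does not exceed the observed one contributes, with
ties decided by integer comparison, so the returned double is exact.
Markers with no non-missing call in one sex have an undefined p and are
excluded from the Bonferroni multiplier; correction is applied within the
maternal and paternal groups separately (multiplier = markers with a defined
p in the group).

Region summaries bucket significant markers into {focal chromosome,
unknown, other}.  The focal percentage is reported as the integer-truncated
value of 100·k/n, the convention that reproduces the study table's printed
percentages (28/38 → 73, 63/87 → 72); plain nearest-integer rounding would
print 74 for the first.

## Minimum-recombination phasing

For ordered pseudo-testcross markers, the per-offspring transmitted-allele
indicators are known up to one unknown orientation bit per marker.  The
phaser chooses orientations minimizing the population total of
inheritance-state changes between each offspring's consecutive non-missing
markers.  This objective is a sum over (marker, marker) adjacency edges —
consecutive pairs when data are complete, plus "skip" edges where missing
calls bridge a gap — of a cost depending only on the XOR of the two
orientations.  It is minimized **exactly** by a sliding-window dynamic
programme whose frontier holds the markers that still have pending edges to
the right: with complete data the frontier has width one (the DP reduces to
chaining pairwise majority votes), and missing data widens it by at most the
longest per-offspring gap.  The tests verify equality with exhaustive search
over all 2^M orientation vectors on hundreds of random instances.  The
global H1/H2 swap is an inherent symmetry, fixed by orienting the first
informative marker of each connected component; truth comparisons are
modulo this swap.

Degenerate cases: markers with no non-missing adjacency to any neighbour
get an arbitrary orientation and an `undetermined` flag; markers whose
orientation can be flipped without changing the optimum are flagged
`ambiguous`, detected exactly by re-solving with the orientation pinned
opposite (optional, on by default; bulk simulation runs disable it).

Breakpoints are transitions between consecutive non-missing states, with
the interval given by the flanking markers; missing-state gaps never count
as transitions.  Offspring are classed non-/single-/multi-recombinant by
transition count.  The state at an arbitrary map position is resolved from
the nearest non-missing flanking markers and left unresolved when they
disagree (a breakpoint spans the position).

### Genotype-class census

The census counts (maternal haplotype × paternal haplotype × sex) among
offspring resolved on both sides at the queried position.  Because the
maternal gametolog determines sex exactly, the Mendelian expectation is
conditioned on the observed (maternal, sex) stratum totals, leaving the 1:1
paternal split as the only tested dimension: each cell's expectation is half
its stratum and carries the exact two-sided binomial p of the split.  Cells
with zero count but positive expectation are flagged as missing classes.
Multi-recombinant offspring are excluded by default: an isolated genotyping
error in an interior marker manifests as a double transition, so this
exclusion shields the census against single miscalls without touching
genuine single recombinants.  The maternal haplotype carried by the majority
of females is labelled W.

### SD–SR linkage scan

Single-recombinant females are grouped by their maternal breakpoint and each
group's paternal-haplotype counts are compared with all remaining resolved
females by the exact test, uncorrected (each group is small and the question
is per-group evidence of over-representation).  Group membership follows
"grouping by recombination point": a female belongs to the group given by
her observed breakpoint flanks.  The alternative cumulative reading — every
(n, m) prefix/suffix window containing her breakpoint — is available as
`membership="nested"`; it creates deeply nested, highly correlated groups
whose maximum over many tests inflates the family-wise false-positive rate,
which is why the partition reading is the default.  The comparison set
(all other genotyped females) maximizes power and is recorded in the output.

## Balancing-selection recurrences

Both models assume an infinite population, random mating, discrete
generations and complete linkage between the SD and incompatibility loci.
States track the Z-gametolog frequency vectors of breeding females (μ) and
the male gamete pool (φ); sex-neutral versions collapse both to one
autosomal-style pool.

**Overdominance** (K alleles, every homozygote inviable):
sex-neutral `S = 1 − Σpᵢ²`, `pₖ′ = pₖ(1−pₖ)/S`; sex-dependent daughters are
W/Z and always viable with `μ′ = φ`, sons survive iff maternal i ≠ paternal
j, giving `S = 1 − Σμᵢφᵢ` and `φₖ′ = [μₖ(1−φₖ) + φₖ(1−μₖ)]/(2S)`.  The
female fraction among survivors is ½ (neutral) or `1/(1+S)` (dependent):
2/3 → 67% for two alleles at equal frequencies, 1/1.9 → 53% for ten.

**Pseudooverdominance** (L linked biallelic loci with recessive lethals):
haplotypes are bit vectors; a genotype is viable iff the bitwise
intersection of its haplotypes is empty.  Gamete formation walks the loci
left to right, switching template with probability r per interval, computed
by a per-pair dynamic programme and assembled into a sparse transmission
matrix over the subset lattice generated by the initial haplotypes' lethal
bits.  The lattice is enumerated exactly with no truncation (practical up to
12 segregating lethal loci when r > 0; the single-pair gamete distribution
itself supports up to 16).  Default r = 0.01 per interval (rare
recombination between tightly linked loci); the default ten-haplotype layout
is nine single-lethal haplotypes at distinct loci plus one harmless
all-wildtype haplotype.

With one locus the neutral recurrence reduces to the classic recessive
lethal purge `q_t = q0/(1 + t·q0)`, which the implementation reproduces to
1e-12 and the package also exposes in closed form.  With r = 0 and
pairwise-disjoint lethals and no harmless haplotype, the model coincides
with K-allele overdominance, another tested equivalence.

Reporting discounts the W gametolog: the combined Z frequency weighs each
female's single Z (= μ) and each male's two Z's (per-Z distribution from the
viable zygote classes) by the class masses ½ and S/2.  This weighting is a
package convention — the source analyses state only that W is discounted —
and it makes sex-neutral and sex-dependent overdominance trajectories
coincide under symmetric initialization, as expected.  The female fraction
is reported both raw and as a rounded integer percent.

The varied-initial-frequency scenario (`fig3c`) uses an evenly spaced grid
over [0.01, 0.3] renormalized onto the simplex, since frequencies must sum
to one; the assignment of grid values to alleles is immaterial by symmetry.

Numerical choices: state vectors are validated to sum to 1 within 1e-9 and
then renormalized exactly each generation, so thousand-generation runs stay
on the simplex without altering any short-run value beyond double rounding;
extinction (zero viable mass) raises an error carrying the generation index.

## Problem sizes in the test-suite and acceptance runs

The deterministic recurrences run their standard 100 generations (the
convergence check extends one scenario to 2000).  Stochastic properties use
the preset population sizes (271 / 516 offspring) with: 10 seeds for the
S5 sex-ratio mean, 50 seeds for the switch-error bound, 60 seeds for the
scan's type-I rate, and 200 seeds for the end-to-end missing-class /
tight-linkage property; the Monte Carlo cross-check of the closed-form cross
model uses ~10⁴ zygotes.  Phasing optimality is verified against exhaustive
search on 200 random instances of up to 12 markers, and exact-test p-values
against rational-arithmetic enumeration for tables with N ≤ 60 (plus scipy
and R `fisher.test` oracles on spot checks).

## Known limitations

- The phasing DP is exponential in the adjacency-edge span; with extreme
  missingness (long per-offspring gaps) the frontier can grow.  At the
  missingness levels the generator produces (≤ ~30%) the window stays small.
- The census's multi-recombinant exclusion discards a few percent of
  offspring under the default error rate; with error-free data it is a
  no-op.
- The linkage scan's exact tests are conservative for small groups; groups
  of fewer than ~6 members cannot reach significance at 0.05, which is a
  property of the data size, not of the implementation.
- The recurrences are infinite-population: no drift, mutation or inbreeding;
  stability statements are about the deterministic map only.
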