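# Methods

`radprint` reconstructs per-individual RAD alleles from a multiplexed
paired-end library and turns their presence/absence segregation in a
lepidopteran backcross into chromosome assignments and a genetic map.
This note records the models, the tunable parameters, and the design
decisions behind each stage.

## Library model and demultiplexing

Every forward read is assumed library-conformant: a 5-base inline MID
(molecular identifier) naming the individual, the 6-base residual SbfI
footprint `TGCAGG`, and 40 locus-specific bases (51 bases total on a GAIIx-era
instrument).  MID matching is **exact**: the published barcodes are not
error-correcting, and a 1-mismatch rescue would risk cross-individual
contamination, which is far more damaging downstream (a single misassigned
allele can flip a presence call) than losing ~1% of reads.  The footprint
check is likewise exact, and reads whose 40-base tag contains an N are
discarded and counted — the clustering distance below has no N semantics.
Qualities decode with phred offset 33 by default (64 selectable) and are
capped at 41.  Conservation holds by construction: assigned + discarded
equals the number of input pairs.

## Allele calling within an individual

1. **Uniques.** Identical tags collapse into unique sequences carrying the
   per-position *median* quality and a read count; singletons (1 read) are
   unverifiable and discarded.
2. **Loci.** Uniques cluster into candidate loci by single linkage under the
   quality-weighted distance
   `d(u1, u2) = Σ_j [u1_j ≠ u2_j] · P(u1_j correct) · P(u2_j correct)` with
   `P = 1 − 10^(−Q/10)` from the median qualities.  The threshold is 7: two
   high-quality uniques separate only when they disagree at more than ~7
   reliable positions, a deliberately liberal radius that keeps diverged
   alleles of one locus together and leaves cleanup to later filters.  The
   distance is bounded above by the Hamming distance and approaches it as
   Q → ∞.
3. **Error correction.** For each position and base, the mean of the
   per-unique median qualities is taken across the uniques carrying that
   base.  A base carried by exactly one unique is rejected (masked) as a
   likely sequencing/PCR error **only when that unique's read support is at
   most `error_read_ratio` (default 0.1) times the strongest unique carrying
   a different base there**.  The support condition is essential: at a clean
   heterozygous locus with exactly two well-covered uniques, every
   distinguishing base is carried by exactly one unique, and an
   unconditional rejection rule would merge every such pair and erase all
   heterozygosity.  An isolated but strongly supported base marks a genuine
   second haplotype; an isolated base on a 2–3-read unique under a 40-read
   sibling is an error signature.  Error alleles that escape the rule are
   still removed later by the single-individual filter, since identical
   errors recurring in two individuals are vanishingly rare.
4. **Alleles.** Uniques identical after masking rejected bases and ignoring
   bases whose mean quality falls below Q20 merge into one candidate allele:
   sequence from the highest-read-count member (ties: lexicographically
   smallest), read counts summed, paired-end mates pooled.
5. **Fragment counts.** Distinct mate sequences per allele approximate the
   number of sheared DNA fragments sampled (PCR duplicates share a shear
   point and collapse), giving a depth proxy robust to amplification bias.

## Cross-individual catalog and normalization

Loci from different individuals merge (single linkage) whenever any allele
pair across them is within `allele_mismatches` = 3 Hamming mismatches — the
radius within which two haplotypes are considered *allelic* (same locus).
Allele *identity* across individuals is a separate, stricter relation:
after per-individual error correction, the same haplotype should be
letter-identical everywhere, so `identity_mismatches` defaults to 0.
Keeping the two radii distinct is what makes the paternal anchoring step
possible at all: a paternal allele 1–3 mismatches from a maternal one must
remain a *distinct* catalog allele (absent from the mother) while still
testifying that the two loci are one.

Sequencing depth varies by an order of magnitude between multiplexed
individuals, so fragment counts are scaled before thresholds.  Each
individual's histogram of fragments-per-allele shows an error peak at 1–2
fragments, a trough, and a main single-copy peak (with a long repeat tail).
With trough and peak positions `min_i`, `max_i`, the scale factor against
the reference mother *m* is `SF_i = (min_m/min_i + max_m/max_i)/2`, the
mother fixed at exactly 1.  Trough/peak detection is automated (the curves
were judged by eye in the original workflow): the histogram is smoothed
with a centered 3-bin moving average; the trough is the first local minimum
at x ≥ 2 (plateaus resolve to their leftmost bin, and x = 2 qualifies as a
boundary minimum when the curve rises to its right — the error peak, when
present, always sits at x ≤ 2); the peak is the global maximum beyond the
trough, which also ignores the long tail.  A monotone histogram has no
automatic answer and raises an error pointing to the per-individual manual
override.  Automation trades a little fidelity for reproducibility; the
per-individual values the original analysts chose by eye are not
recoverable, so absolute SFs may differ while remaining scale-equivariant
(scaling an individual's counts by c scales SF by 1/c exactly at the level
of the formula).

Presence of an allele in individual i requires `raw × SF_i ≥ min_fragments`
(default 3), applied **after** normalization; alleles present in fewer than
`min_individuals` (default 2) individuals are dropped.  Individual counting
happens after the fragment threshold.  Both radii and thresholds are
exposed on the CLI for sensitivity analysis (0–6 mismatch radii, fragment
thresholds 1–6 are the plausible exploration range).

## Chromosome prints

Female Lepidoptera undergo achiasmatic meiosis: no crossing over, so each
progeny of a backcross receives one *intact* maternal homolog per
chromosome.  Every maternal-specific allele (present in the mother, absent
from the father) is then present in exactly the progeny that drew its
homolog: over n progeny its presence bit-vector — the segregation pattern —
takes one of two complementary values per chromosome, out of 2^n possible.
Grouping maternal-specific alleles by exact pattern and pairing each
pattern with its exact bitwise complement yields one *chromosome print* per
chromosome.  Pairs are ranked by total supporting alleles (ties by
lexicographic pattern) and, when the karyotype is known, the top-k pairs
are reported as prints and the rest as residuals.  Alleles present in the
mother and *all* progeny are classified homozygous-maternal and set aside —
they segregate nowhere and cannot be placed.  Residual patterns in noisy
data sit characteristically at Hamming distance 1 from a print (single
false-negative presence calls).

Any binary progeny labelling — sex, or a phenotype such as insecticide
survival — can be matched against the prints; a side whose pattern equals
the label indicator identifies the labelled chromosome.  For sexes, the
female-matching side is the W chromosome (females are WZ, males ZZ) and its
complement the Z.

Low-coverage individuals corrupt every pattern bit they touch, so progeny
can be excluded via the manifest (`status=excluded`) or by the automatic
rule *read count < 25% of the library median*, chosen to reproduce the
judgement call made for the two dropped individuals of the motivating
experiment (4% and 11% of the median; the next-lowest retained individual
sits at 36%).

## Paternal map

Crossing over does occur in males, so paternal segregating alleles
(father-present, mother-absent, non-constant pattern) carry linkage
information.  Chromosome assignment proceeds in two stages:

1. **Allelism.** A paternal allele whose sequence is within 3 mismatches of
   maternal chromosome-assigned alleles takes their chromosome — but only
   if *all* such matches agree; multi-chromosome or zero matches leave it
   unassigned.
2. **Pattern propagation.** Three passes assign unassigned alleles whose
   pattern is (a) identical to, (b) the exact complement of, (c) one
   genotype away from an anchored pattern, each pass requiring a unique
   candidate chromosome and logging conflicts.  Phase is arbitrary
   (an allele on either paternal homolog reports the same locus), hence the
   complement pass and the phase-folded distance in (c).

Patterns supported by ≥ 3 alleles become markers — the deliberate
redundancy criterion that keeps singleton error patterns out of the map; a
pattern and its complement are one marker observed in two phases.  For two
markers over N progeny with folded recombinant count `R = min(H, N−H)`, the
two-point backcross LOD at the MLE `r = R/N` is

    LOD = log10( (1−r)^(N−R) · r^R / 0.5^N ),    LOD(R=0) = N·log10 2.

The original analysis delegated grouping/ordering to a closed-source
program whose internal settings are not reproducible; here markers link
when LOD > 2 **and** R ≤ 5 (more than 5 recombinants in 20 progeny is
considered unreliable at this sample size), components are ordered to
minimize total adjacent recombinants — exhaustively for ≤ 8 markers, greedy
nearest-neighbour with 2-opt refinement above that — and adjacent distances
use the small-sample convention `100/N` cM per recombinant (5 cM at
N = 20); Haldane/Kosambi mapping functions are deliberately not applied, to
keep distances in the convention the printed map uses.  Multiple components
per chromosome are allowed; markers linking to nothing are emitted as
singleton groups.  Total map length over a genome of G bp yields the
physical density `G/1000/total_cM` kb/cM, reported to one decimal.

## Simulator

The generator emulates the study design rather than an arbitrary genome:

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes` | 31 | karyotype of the mapped genome |
| `loci_per_chromosome` | Poisson mean 100 | restriction loci per chromosome |
| `n_progeny` | 20 | retained backcross progeny |
| `maternal_het_rate`, `paternal_het_rate` | 0.4 | per-locus heterozygosity |
| `shared_allele_mismatch_rate` | 0.05/base | divergence of variant alleles (≈1–3 mismatches/40) |
| `male_crossovers` | 0.417 | Poisson crossovers per chromosome per gamete |
| `fragments_per_allele` | 30 | mean sheared fragments per allele copy |
| `reads_per_fragment` | 1.4 | 1 + Poisson: PCR duplication |
| `per_base_error` | 0.001 | substitution rate, qualities emitted to match (Q30) |
| `depth_sigma`, `depth_clip` | 0.35, [0.5, 2] | log-normal per-individual depth spread |

Loci are abstract positions with random 40-base haplotypes kept ≥ 10
mismatches apart so distinct loci never merge spuriously; variant alleles
derive from a shared base haplotype by 1–3 substitutions, placing parental
alleles within the allelism radius.  Chromosome 1 doubles as the Z/W pair:
progeny sex follows the maternal homolog drawn there, so sex-linkage
detection is exercised for free.  Maternal homologs transmit intact (fair
coin per chromosome); paternal gametes carry Poisson crossovers at uniform
positions with no interference modelled.  `male_crossovers = 0.417` makes
the expected observed map ≈ 31 × 100 × 0.417 ≈ 1292 cM at the 5 cM/event
convention, matching the scale of real lepidopteran maps.  The depth spread
mirrors the retained individuals of a real multiplexed lane (0.36–1.8× the
mean); the floor is clipped at 0.5 so that, under error-free settings,
coverage-induced allele dropout is negligible and recovery tests are exact
— the ultra-low-coverage failure mode is exercised by passing explicit
multipliers (e.g. 0.04) instead.  Every read traces to its allele,
individual and fragment through the truth table, which round-trips through
plain TSVs.

What the simulator does **not** model — indels, paralogous repeat families,
restriction-site polymorphism (allele dropout), base-composition biased
error, crossover interference — bounds what passing tests show: they
validate the inference machinery under the stated generative model, not
robustness to repeat-rich real genomes, where liberal clustering radii are
known to admit error patterns that the ≥3-allele marker criterion must then
absorb.

## Numerical and tie-breaking conventions

- Median qualities stored as integers (floor of the true median for even
  counts); mean base quality is the mean of per-unique medians.
- Representative sequences (allele calling, catalog identity): highest read
  support, then lexicographically smallest.
- Print orientation: pattern 1 is the side with more alleles; pair ranking
  by support, then lexicographic pattern.
- Marker phase: the lexicographically smaller of pattern/complement.
- Report means round half-to-even.
- Degenerate inputs: empty tag lists yield empty outputs; an empty manifest,
  mismatched FASTQ pair lengths, a missing parent in the catalog, and a
  trough-less histogram are hard errors.

## Problem sizes used in the checks

The acceptance computation simulates the full design (31 chromosomes,
~100 loci each with at least 49 informative maternal alleles enforced, 20
progeny, ~5.7M read pairs) once, error-free, and runs the complete pipeline
on it; the noisy five-seed recovery check uses 5 chromosomes at the same
per-chromosome density, which preserves the anchoring/propagation behaviour
that density controls while keeping each replicate light.  Module tests use
3–6 chromosome genomes.

## Known limitations

- Trough/peak automation can disagree with a human reading on ragged
  histograms; the override exists for exactly that case.
- With 20 progeny, two chromosomes could share a segregation pattern by
  chance (~2⁻²⁰ per pair); a collision would fuse two prints and is only
  detectable as a deficit in the print count.
- Greedy+2-opt ordering is exact only where exhaustive search takes over
  (≤ 8 markers); larger components may be locally optimal orders.
- The two-point map underestimates length where marker support is sparse
  (patterns with < 3 alleles are discarded, and LOD > 2 at N = 20
  effectively requires ≤ 3 recombinants between neighbours).
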