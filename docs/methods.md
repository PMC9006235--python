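# Methods

This note records the models implemented in `introscan`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducing its output.

## Ancestry mapping model

The pipeline assumes each sequenced strain is a pool of near-homozygous
individuals from an isofemale-derived line, so pooled allele
frequencies can be collapsed ("extrapolated") to a two-allele diploid
genotype per site.

**Genotype calling** (`poolgeno.call_diploid`). Depth is the sum of
A/T/C/G counts only; N and deletion columns are parsed but never count
toward depth, since indels and ambiguous bases are not callable alleles
under this model. Filters, in order: depth < 10 ⇒ no call; alleles
with frequency < 25% of depth discarded; more than two survivors ⇒
tri-allelic, no call. Two survivors are called (1,1) regardless of
their ratio beyond the 25% rule — the strains are expected homozygous
and the frequency floor already absorbs sequencing error, so modelling
fractional dosage would add parameters without information. Boundary
behaviour is exact: depth = 10 passes ("less than 10" excluded), a
frequency of exactly 25% survives. Filtering precedes the
surviving-allele count, so a site with three raw alleles where one is
sub-threshold is *not* tri-allelic.

**Divergent sites.** Only positions where both parents are called,
homozygous, and different are diagnostic. Sites lost to depth,
tri-allelism or heterozygosity are dropped silently from ascertainment
(they carry no ancestry information); the count of divergent sites is
reported by the CLI for reproducibility.

**Windowing and classification.** Windows tile each chromosome from
position 1 in fixed 50-kb steps. The tiling phase is a convention the
data cannot pin down; starting at 1 makes output deterministic and the
track resolution is coarser than any phase effect. A window's value is
the unweighted mean of site donor dosages; the default minimum is one
site per window (no floor is implied by the model; it is configurable).
Thresholds: mean ≥ 0.75 fixed, ≥ 0.40 intermediate, both inclusive.

**Locus merging.** Runs of consecutive fixed/intermediate windows merge
into loci; up to one missing window inside a run is bridged
(divergent-site deserts should not split one biological tract —
configurable), while background windows always split. A locus is FIXED
when at least one window is fixed and fixed windows are at least half
of its labelled windows, else INTERMEDIATE. Locus bounds are clipped
from window resolution to the outermost informative sites inside the
run; this is why locus coordinates are not multiples of 50 kb, and it
is the convention under which length = end − start reproduces the
reference locus table arithmetic (X:15,000–226,000 ⇒ 211 kb). How the
original coordinates were refined below window resolution is not
documented anywhere authoritative; clipping-to-site is this package's
choice.

**Contig attribution** (`liftover`). A contig ≥ 100 kb is assigned to
the chromosome arm with the largest summed query-side alignment length
across its PAF records. Summing per arm (rather than taking the single
longest block) is the robust reading when aligners split homology into
many blocks. Overlapping query blocks on the same arm are not
deduplicated — at 100-kb scale the effect is negligible. Exact ties are
left unplaced with a warning rather than guessed.

## Statistics

**PCA** operates on the covariance matrix of the raw 0–10 class scores:
all six variables share one scale, so standardising to correlations
would discard real between-segment variance differences; a
`mode="correlation"` switch exists. Signs are fixed deterministically
(PC1 correlates positively with mean pigmentation; each later component
has its largest-|r| segment loading positive). Constant input raises
"no variance" rather than returning a degenerate result.

Females' tergites 2–7 + epigynium and males' tergites 2–6 + epandrium
are aligned positionally as six analysis segments so the sexes share
one PCA space; the ultimate segment of each sex occupies column six.
This positional alignment is a documented package choice.

**t tests** default to Welch (unequal variances) — the convention of
R's `t.test`, the environment in which such scores are conventionally
analysed. Both groups constant with equal means returns t = 0, p = 1;
constant with different means raises "degenerate variance" (the
statistic is infinite and carries no usable information).

**No-choice χ²** is a one-sample goodness-of-fit against the homogamic
*D. yakuba* reference proportion (17/20), df = 1, no continuity
correction — matching R's `chisq.test` goodness-of-fit path, which
applies no Yates correction. **Two-choice** significance uses the
two-sided Fisher exact test on the 2×2 focal × chosen table; a
contingency-χ² variant is retained behind a flag because both analyses
are defensible for this design, but the exact test is the default
reported statistic. No multiple-testing correction is applied across
assay tables. Star cutpoints are strict: p < .05/.01/.001.

## Forward simulator

**What it models.** The breeding design: F1 from a *yak* × *san* cross
(fertile females, sterile males), BC1 to recurrent *yak* males, then
mass culture where each generation every female mates once with a
uniformly random male *before* phenotypes are scored, and the
`select_n` lightest females are transferred; females whose single mate
was sterile leave no offspring. This mating-before-selection order is
the experiment's documented inefficiency mechanism and is the default
(a switch allows selection-before-mating for contrast runs). Sterile
males competing for matings without siring is likewise deliberate: it
is how sterile males blunt selection.

**Genetics.** Chromosomes X, 2L, 2R, 3L, 3R with lengths approximating
the *D. yakuba* arms (21.8/23.5/21.1/24.2/28.1 Mb). Female meiosis:
crossover count ~ Poisson(1) per chromosome, positions uniform, no
interference (Haldane) — standard in the absence of a linkage map. Male
meiosis is achiasmate (*Drosophila* biology): males transmit intact
haplotypes, which matters for how paternal genomes persist. Males are
X-hemizygous; sons receive only the maternal (recombinant) X.

**Sterility.** A male is sterile if any chromosome copy is donor at any
incompatibility locus. Defaults (illustrative — the real number and
strength are unknown): two X-linked loci placed near the major
pigmentation genes, reflecting both the disproportionate X-linkage of
hybrid male sterility in *Drosophila* and the initial linkage between
pigmentation and incompatibility factors whose recombinational
breakdown eventually lets selection proceed; plus one autosomal locus,
which makes F1 males (heterozygous genome-wide) sterile in both cross
directions. An X-only rule could not sterilise F1 sons of a recipient
mother, whose X is pure recipient.

**Phenotype.** Six segment scores per fly: baseline per segment and sex
(recipient-species values), plus additive per-copy locus effects scaled
by a sex factor (female 1.0, male 0.5 by default — female pigmentation
was the more variable, selected trait), plus Gaussian noise
(sd 0.75 classes), rounded and clipped to 0–10. A hemizygous male X
locus counts as two doses by default (dosage compensation;
switchable). Default trait loci sit at the map positions of *y*, *t*
(X) and *pdm3* (2L) with lightening (negative) donor effects.

**Emitters.** Divergent sites are drawn uniformly at 0.5/kb (a desk
scale chosen to give several informative sites per 50-kb window at
every realistic depth). Pool counts: donor reads ~ Binomial(depth,
population donor frequency), then each read is corrupted with
probability `error_rate` (default 10⁻³) to a uniformly random other
base. Parents are emitted as fixed for alternative alleles. Assay
counts come from a (female strain × male strain) acceptance matrix:
no-choice successes are Binomial(trials, acceptance); two-choice trials
copulate with probability equal to the mean of the two acceptances and
then choose proportionally to them. All emitters are bit-reproducible
given (config, seed); every random draw flows from one
`numpy.random.Generator`.

**What it does not emulate.** Read-level artefacts (mapping error,
reference bias, depth heterogeneity), mutation, linkage maps with
interference or heterogeneous recombination, viability selection,
overlapping generations, and any sequence content — sites are abstract
diagnostic markers. Passing recovery tests therefore demonstrates the
pipeline's arithmetic and calling logic under clean binomial sampling,
not robustness to alignment artefacts in real pools.

## Validation design and problem sizes

Two properties of the simulator are validated separately because they
answer different questions:

- **Selection response:** under truncation selection with the default
  architecture, donor frequency at the trait loci exceeds the
  genome-wide mean by generation 15 in ≥ 95% of seeded replicates
  (census 120, select 20 — sizes chosen to keep the suite fast while
  leaving drift visible).
- **Planted-tract recovery:** the pooled-count pipeline must call FIXED
  loci over both X-linked donor tracts (the *y* and *t* tract
  coordinates) with ≤ 1 window boundary error, plus an INTERMEDIATE
  call over a half-frequency autosomal tract, at depth 50, in ≥ 95% of
  20 seeds. The test strain is constructed directly — recipient
  background, planted tracts, Poisson residual private donor segments —
  because exactly known tract boundaries are only possible by
  construction. A population taken straight out of 15 generations of
  truncation selection instead carries megabase-scale hitchhiking
  halos around the selected loci (observed in this simulator: a quarter
  to half of X windows above the intermediate threshold), so its tract
  "boundaries" are not defined to within a window; the tight-bounded
  state corresponds to a line sharpened by many further generations of
  recombination and purging, which is what the constructed strain
  emulates.
- **Neutrality:** with selection and sterility disabled, mean autosomal
  donor ancestry after BC1 is a martingale at 0.25; a pooled regression
  over 20 seeded replicates (census 100, 10 generations) must have a
  slope CI covering zero.

Statistical kernels are checked against independent oracles: the
genotype filter against a brute-force reimplementation on 10,000 random
count vectors; Fisher's exact test against full hypergeometric
enumeration on all 2×2 tables with row margins ≤ 15; the goodness-of-fit
χ² against its closed form on 1,000 random inputs; binomial read
sampling against the exact PMF by χ² goodness of fit over 10,000 sites.

## Known limitations

- Locus status uses a simple majority-of-windows rule; a long
  intermediate shoulder attached to a short fixed core can demote a
  locus to INTERMEDIATE. The per-window means are always emitted so
  users can post-classify.
- The simulator's mass-culture census and effective breeder numbers are
  config knobs (defaults 1000 and 50); real bottle demography is
  unknown.
- `attribute_contigs` measures homology on query coordinates; target
  coordinates would differ in the presence of large indels.
- The two-choice emitter's no-copulation rate is a modelling
  convenience (mean acceptance), not a fitted quantity.
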