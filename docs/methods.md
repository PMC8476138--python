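# Methods

## The biological setting

Karyotype change by chromosome fusion alters the recombination landscape.
In taxa with an (approximately) fixed genetic map length per chromosome —
one obligate crossover per bivalent per meiosis, as reported for
heliconiine butterflies — fusing two chromosomes roughly halves the per-bp
recombination rate of both components: the fused chromosome still recombines
about 50 cM worth, but over the summed physical length.  Lower per-bp
recombination strengthens background selection and hitchhiking, depressing
neutral diversity, and over macroevolutionary time it is expected to raise
the turnover rate of functional elements.  `karyofuse` implements the full
analysis chain for this question: locating fusion points from ortholog
synteny, splitting fused chromosomes back into their ancestral components,
contrasting composition between chromosome classes, measuring neutral
diversity at 4-fold degenerate (4D) sites, modelling the recombination-rate
change, and scoring cross-species retention of functional elements.

## Fusion mapping

An **anchor** is an ortholog with a known ancestral-homolog identity and a
position on a derived chromosome.  A single fusion produces a two-block
arrangement of anchors.  The junction is found by an exhaustive
single-changepoint scan minimizing the number of anchors on the wrong side
of the cut; ties prefer the widest gap between flanking anchors.  The
breakpoint is the floor of the midpoint between the two anchors flanking
the chosen cut, and that gap is retained as the estimate's uncertainty —
the midpoint rule gives no finer resolution, so recovery is judged against
the gap, not a fixed bp tolerance.  Discordant anchors are counted, not
modelled: no inversion-aware segmentation is attempted, and events whose
best cut still misassigns more than 10% of anchors are flagged
low-confidence.  Chromosomes carrying anchors from more than two homologs
are segmented pairwise between consecutive homolog blocks and flagged.

Classification follows the outgroup: for each fusion the component whose
*ancestral* homolog is shorter is the SFC (short-fused chromosome), the
other the LFC; everything unfused is NFC.  Equal lengths (possible only in
toy data) break lexicographically with a warning.

## Composition and scaling

Windowed GC, repeat and coding content use merged (union) intervals so
overlapping features are never double-counted; GC is a percentage of non-N
bases.  The window size defaults to 100 kb with an override — published
window choices for this kind of profile vary (100 kb and 500 kb are both in
circulation for the system this emulates), so the parameter is explicit
rather than silently fixed.  "Coding" counts CDS bp by default, with a
flag-like `coding_kind` argument to count exon bp instead.

Fusion-centred profiles map each fused chromosome piecewise-linearly so the
breakpoint sits at exactly 0.5; the map is measure-preserving within each
component.  A residual repeat peak at 0.5 (the remnant of two ancestral
chromosome tails) is diagnosed by `fusion_point_contrast`, which compares
window means near 0.5 against flanking regions (0.25/0.75) and the
chromosome edges.

Scaling analyses use standardized major axis (SMA) regression — the
appropriate line when both variables carry error — with the closed form
slope = sign(r)·sd(y)/sd(x).  Group comparisons (common slope, elevation)
replace SMATR-style likelihood-ratio tests with seeded permutation tests:
the common-slope statistic is the variance of per-group SMA slopes under
label permutation; the elevation statistic permutes residual scores
y − b_common·x between two groups.  Permutation tests are assumption-light
and exactly calibratable, which the test suite verifies (≤1% rejections at
α = 0.005 under the null; ≥90% power at a 3-residual-SD elevation shift
with n = 10 per group).  Class contrasts use one-sided
Wilcoxon–Mann–Whitney tests (exact where sample sizes permit) at the
stringent α = 0.005 used throughout.

## 4D-site diversity

Coding intervals are first reduced to one transcript per gene (longest
total CDS, ties by id — the isoform rule is a package choice, as is common
when the upstream convention is unstated) and any CDS interval overlapping
a different gene's CDS is wholly removed.  The 4D caller is deliberately
conservative:

- codons containing N are discarded;
- a codon with *observed* alternate alleles (i.e. called in at least one
  filtered genotype) at more than one of its three positions is discarded;
- with one variant position, the third position must be 4-fold degenerate
  under **every** observed allele, not just the reference;
- strand and phase are honoured (minus-strand codons are read from the
  reverse complement; partial trailing codons are dropped).

Genotypes pass the filter only on strict inequalities DP > 10 and GQ > 30
(profile "default"); a "low-coverage" profile uses DP > 5, GQ > 20.

Per site, π is the standard mean pairwise difference among all called
alleles (within plus between individuals).  Sites with a called-allele
fraction below 0.5 (default; the upstream convention specifies only the
per-genotype filter) are excluded from the window mean.  Windows hold a
fixed number of 4D sites (default 500); the trailing window is kept if at
least half full.  A pairwise mode scores only the cross-sample allele pairs
of two designated individuals, for call sets where within-population
diversity is not estimable.  Sites absent from the variant table are
treated as invariant and fully called; this matches call sets produced over
all coding sites where invariant records are omitted.

Per ancestral homolog, π is the unweighted mean of its windows (weights are
a documented choice; window counts are nearly proportional to site counts
anyway), normalized by the mean over NFC homologs to cancel
effective-population-size differences between species.  The relative change
is the ratio form Δπ_rel = (π_norm,extant − π_norm,ancestor)/π_norm,ancestor,
mirroring the recombination side; the ratio-vs-difference choice is
recorded in output metadata.

## Recombination model

With fixed map length M (default 50 cM, overridable per chromosome from a
linkage-map table), the per-bp rate is r = M/L in cM/Mb.  For each homolog,
r_anc uses the outgroup length and r_extant uses the full length of the
chromosome the homolog now resides on (the fused chromosome for SFC/LFC).
Δr_rel = 1 − r_extant/r_anc is positive for a rate decrease and negative
when a genome-wide size reduction *increases* the rate on unfused
chromosomes.  The Δπ_rel–Δr_rel association uses Spearman rank correlation
(average ranks on ties; exact permutation P for n ≤ 10, normal
approximation otherwise), with the orientation convention recorded in the
output.

## Functional-element turnover

Conservation of an element set against a target genome is the percentage of
source elements recovered as reciprocal best hits at e ≤ 1e-10.  Best hits
are deterministic: lowest e-value, then highest bitscore, then
lexicographically smallest subject id.  The alignment engine is pluggable —
any producer of the 12-column tabular format, including the synthetic hit
generator; no aligner is implemented because the analysis starts at the hit
table.  Per-chromosome conservation is regressed on chromosome length (Mb)
and divergence time (Myr) by OLS, pooling targets; per-target simple length
slopes feed a paired t-test comparing the length effect between two element
sources, with the ratio of mean |slopes| reported.  Element kinds (CRE,
exon) are pooled in the default regression; passing a single-kind subset
fits them separately.

## The synthetic study system

The generator builds a known-truth system, not a biologically faithful
genome.  What it emulates:

- **Karyotype**: 31 ancestral chromosomes, lengths log-uniform over
  `length_range`; the 10 shortest each fuse onto a distinct long partner
  (k-th shortest with k-th longest; a `random_pairing` flag gives null
  pairings), random head/tail orientation, truth recorded.  Default lengths
  (0.5–4 Mb) are roughly an order of magnitude below real lepidopteran
  chromosomes so whole-system runs stay cheap; every analysis depends on
  the length *contrast*, which log-uniform sampling preserves.  Tests use
  smaller ranges again (stated per test); the scripts/acceptance.py run
  uses 0.15–1.2 Mb.
- **Composition**: repeat intervals follow a Poisson process with intensity
  λ(x) = λ0·(1 + (tail_enrichment−1)·(2|x/L−0.5|)²), elevated at
  chromosome tails; GC of the background sequence follows the same tail
  shape.  Shorter chromosomes get denser repeats
  (λ0 ∝ (L_ref/L)^0.5) and slightly higher GC, emulating the observed
  excess on small chromosomes.  Genes (2–6 exons, both strands, CDS a
  multiple of 3) are placed first with exponential spacing; repeats are
  then thinned wherever they would overlap a gene, preserving the tail
  shape.  After fusion, repeats near the junction are eroded with
  probability `breakpoint_repeat_loss` (default 0.8), emulating
  post-fusion repeat loss; setting it to 0 gives the
  ancestral-concatenation control whose profile keeps a repeat peak at 0.5.
- **Diversity**: variation is planted only at 4D-eligible third codon
  positions, so the diversity stage's estimate is interpretable against
  truth without ascertainment correction.  Each eligible site segregates
  with probability π(L)/0.365, where π(L) = a − b·log10(L) (floored) is
  keyed to the length of the chromosome the site currently resides on, and
  0.365 = E[2f(1−f)] for allele frequencies f ~ U(0.05, 0.95).  Diploid
  genotypes are binomial draws at f; DP is Poisson(30) and GQ high, with a
  5% fraction of low-DP/GQ genotypes to exercise the filters.  Because the
  derived genome's π is keyed to fused lengths while the ancestral genome
  keeps component lengths, fusions plant exactly the diversity–recombination
  coupling the pipeline is supposed to recover.
- **Turnover**: element retention in a target is Bernoulli with probability
  sigmoid(c0 − c_len·L_Mb − c_time·T_Myr).  Retained elements yield a
  reciprocal hit pair far below the e-value threshold; lost elements yield
  nothing, a one-directional decoy, or a reciprocal pair at e = 1e-5 that a
  compliant threshold must reject.  Divergence is book-kept through hit
  rows — no sequences are mutated or aligned.  Default element counts
  (≥600 per chromosome) match the *per-chromosome* counts of real CRE/exon
  sets rather than per-Mb density, because conservation-percentage
  precision is count-limited.  In the end-to-end pipeline the
  derived-lineage source gets c_len scaled by 1/7 with the intercept
  re-centred at the mean chromosome length, planting the source contrast
  (a strong ancestral-lineage length effect, a much weaker derived-lineage
  one) that `compare_effect_sizes` recovers.

What it does **not** emulate: coalescent linkage structure (sites are
independent), indels and structural variation other than the fusions
themselves, TE sequence evolution and families, inversions near junctions,
isoform complexity, sex chromosomes (all simulated chromosomes are
autosome-like; on real data a Z chromosome should be excluded from
NFC/LFC/SFC statistics), and alignment noise.  Passing recovery tests
therefore demonstrates the correctness of the estimators and the
identifiability of the planted effects at realistic sizes — not robustness
to every property of real data.

## Numerical choices and degenerate inputs

- Internal coordinates are uniformly 0-based half-open; conversions happen
  only at format boundaries (GFF3/VCF/hit tables are 1-based on disk).
- Multiallelic VCF records are kept whole; the 4D logic needs the full
  observed allele set.
- Soft-masked lowercase bases are uppercased and carry no repeat meaning;
  repeat evidence comes only from interval input.
- All randomness flows from one seed through named substreams (SHA-256 of
  "seed:stage", reduced below 2^31), so toggling a stage never shifts
  another stage's draws and reruns are byte-identical.
- Permutation P-values use the add-one rule (1 + #extreme)/(1 + n_perm);
  Holm adjustment across elevation pairs.
- Empty inputs: an empty anchor map refuses detection; a chromosome with
  no windows yields an NA diversity row; a class with < 3 members yields NA
  contrasts; zero-variance SMA inputs raise.

## Problem sizes

Default test-suite runs use 8–31 chromosomes of 40–700 kb; the end-to-end
recovery experiments use 50 replicates per condition at 31 chromosomes of
120–400 kb.  That range keeps the smallest:largest length ratio near the
real karyotype's ~3:1.  The ratio matters for one subtle reason: the
per-homolog π estimate's standard error scales as 1/√(number of 4D sites),
i.e. with 1/√L, so under a flat π model the *magnitude* |Δπ_rel| is largest
for exactly the short homologs that carry the largest Δr_rel.  With an
exaggerated length spread this variance gradient alone induces a spurious
positive rank correlation of the folded statistic; at the faithful ~3:1
spread the folded statistic is null-calibrated while retaining saturating
power under a length-dependent π model.  The signed Δπ_rel correlation does
not suffer from this artifact at any spread and is reported alongside the
folded one.
`scripts/acceptance.py` runs one full realization at 31 chromosomes of
0.15–1.2 Mb with all stages enabled.  These sizes were chosen so the whole
suite completes comfortably on a single CPU while keeping every planted
effect comfortably identifiable.
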