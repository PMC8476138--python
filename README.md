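# karyofuse

Analysis toolkit for the evolutionary consequences of chromosome fusion:
fusion-point detection from ortholog synteny, chromosome splitting and
classification, composition profiling, 4-fold-degenerate-site nucleotide
diversity, a fixed-map-length recombination model, and reciprocal-best-hit
turnover of functional elements — plus a synthetic-genome generator with
known ground truth so every stage is verifiable without external data.

## Who this is for

Comparative and population genomicists studying karyotype evolution in
clades where chromosome number changes by fusion/fission — e.g. Lepidoptera,
where an ancestral karyotype of n = 31 was reduced to n = 21 in *Heliconius*
by ten fusions, each joining a short chromosome to a longer partner.  The
package takes standard inputs (FASTA, GFF3, VCF with GT/DP/GQ, BED,
12-column tabular similarity hits, TSV linkage maps) and produces tidy
tables and a flat JSON summary.

## The model in brief

With one obligate crossover per bivalent per meiosis, every chromosome has a
genetic map length M ≈ 50 cM regardless of physical length L, so the per-bp
recombination rate is r = M/L (cM/Mb).  A fusion leaves M fixed while L
becomes the summed component length, giving each component a relative rate
decrease

    Δr_rel = 1 − r_extant / r_anc = 1 − L_anc / L_fused.

Lower r strengthens background selection, depressing diversity at linked
near-neutral sites.  Diversity is measured as π at 4-fold degenerate third
codon positions (π_4D), called conservatively: a codon is discarded if more
than one of its positions carries an observed alternate allele, and with one
variant position the third position must be 4-fold degenerate under every
observed allele.  Per ancestral homolog, π_4D is normalized by the mean over
not-fused chromosomes (NFC) and compared between an extant species and an
outgroup proxy for the ancestral state; the relative diversity change is
then correlated with Δr_rel.  Fused components are classified by outgroup
length into long-fused (LFC) and short-fused (SFC) chromosomes.  Functional
turnover is the percentage of a source species' elements (ATAC-seq-style
CREs, exons) recovered in a target genome as reciprocal best hits at
e ≤ 1e-10, regressed on chromosome length and divergence time.

## Worked example

Run the full synthetic pipeline (31 ancestral chromosomes, 10 planted
fusions, diploid variants, functional elements) and print the summary:

```
karyofuse simulate --seed 1 --out runs/demo \
    --n-chromosomes 31 --n-fusions 10 \
    --min-length 150000 --max-length 1200000 --window 20000
```

or equivalently from Python:

```python
from karyofuse import RunConfig, SimulationConfig, run_all

cfg = RunConfig(sim=SimulationConfig(n_chromosomes=31, n_fusions=10,
                                     length_range=(150_000, 1_200_000),
                                     seed=1),
                window_size=20_000)
summary = run_all(cfg)["summary"]
```

Selected output for seed 1 (your numbers will match exactly — the run is
deterministic):

```
n_derived_chromosomes                21        # 31 − 10 fusions
breakpoint_within_gap_pct            100.0     # every junction inside its
                                               # flanking-anchor gap
classification_accuracy_pct          100.0     # SFC/LFC match planted truth
pi_length_r2_ancestor                0.903     # pi_4D declines with log L
abs_dpi_dr_spearman_rho              0.730     # diversity loss tracks the
abs_dpi_dr_spearman_p                3.1e-06   # recombination-rate decrease
mean_delta_r_rel_sfc                 0.788     # SFCs lose ~79% of their rate
conservation_length_rho_mean         -0.935    # element retention falls
                                               # with chromosome length
effect_size_ratio                    5.2       # ancestral-source length
effect_size_paired_p                 0.0017    # effect ≫ derived-source
```

Reading it: the ten junctions are recovered exactly to within the midpoint
rule's resolution; per-homolog π_4D declines strongly with chromosome
length; short-fused components lose most of their per-bp recombination rate
and show the largest relative diversity loss, so |Δπ_rel| correlates with
Δr_rel across the 31 homologs; element conservation declines with
chromosome length, and the planted 7:1 contrast in the length effect
between the two element sources is recovered by the paired slope test.

Individual stages are available as library functions
(`detect_fusions`, `call_fourfold_sites`, `pi_windows`,
`recombination_model`, `reciprocal_best_hits`, `sma_fit`, …) and as CLI
subcommands (`karyofuse fusionmap | composition | diversity | recomb |
turnover`) operating on standard files.

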