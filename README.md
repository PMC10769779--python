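# commfba

Community flux balance analysis of gut microbiomes: from 16S-derived taxon
abundances and per-species metabolic models to a per-sample **predicted
butyrate production capacity**, with the longitudinal responder/nonresponder
statistics needed to compare treatment groups across two visits.

## Who this is for

Microbiome researchers who have (a) OTU representative 16S sequences and
per-sample relative abundances, (b) genome-scale metabolic models for a
reference genome catalogue, and (c) two-visit clinical metadata, and who want
to ask whether a clinical response is accompanied by a change in the gut
community's capacity to synthesize the short-chain fatty acid butyrate.  A
synthetic-data generator ships with the package so the entire pipeline runs,
and is tested, without any external download.

## The model

For each sample, species models of all taxa above 0.1% relative abundance are
merged into one multispecies model: species internals are namespaced, a
shared *lumen* compartment carries cross-feeding metabolites, and one
community exchange reaction per lumen metabolite (outflow-positive) forms the
system boundary.  Each member's biomass flux is hard-coupled to a single
community growth rate in proportion to its abundance weight `w_i`:

```
max   mu − λ · Σ_j |v_j|               (λ = 1e-5)
s.t.  S v = 0
      v_biomass,i = w_i · mu           for every member i
      l_j ≤ v_j ≤ u_j,   mu ≥ 0
```

This parsimonious FBA is solved as a single LP (absolute values via exact
flux splitting, HiGHS backend).  The per-sample statistic is the **butyrate
production rate** `r = b / mu`, the community butyrate outflow per unit of
community biomass formed.

OTUs are matched to reference genomes by exact Smith–Waterman alignment under
BLASTN-like scoring with a minimum sequence identity of 97% and a minimum
query coverage of 95%; among surviving hits only the maximum-identity ones
are retained.  Patients are labelled responders when their Lichtiger score
drops by ≥50% between baseline (V1) and week 4 (V2); rates are then compared
with exact Wilcoxon rank-sum tests (between groups, per visit) and exact
paired signed-rank tests (between visits, per group).

## Worked example

```
commfba simulate --outdir inputs --seed 1
commfba run --models-dir inputs/models --reference-fasta inputs/references.fasta \
    --otu-fasta inputs/otus.fasta --abundance-tsv inputs/abundances.tsv \
    --metadata-tsv inputs/metadata.tsv --output-dir results
commfba report --results-dir results
```

The simulated cohort has 69 responders and 24 nonresponders (93 baseline
samples, 85 at week 4); responders gain 15% absolute abundance mass on
butyrate-producing taxa at the second visit.  `report` prints:

```
Predicted butyrate production capacity
========================================
median rate,  nonresponder V1: 0.4293 (n=22)
median rate,  nonresponder V2: 0.4533 (n=22)
median rate,     responder V1: 0.4117 (n=63)
median rate,     responder V2: 0.5325 (n=63)
----------------------------------------
responders vs nonresponders at V1 (rank sum): P = 0.94 (n=85, approx)
responders vs nonresponders at V2 (rank sum): P = 0.0006114 (n=85, approx)
V1 vs V2 within responders (signed rank): P = 4.417e-11 (n=63, approx)
V1 vs V2 within nonresponders (signed rank): P = 0.8202 (n=22, approx)
```

Reading: groups are indistinguishable at baseline; after treatment the
responder group's predicted butyrate capacity has risen (strongly significant
within responders, null within nonresponders) — the planted effect is
recovered in the right direction and nowhere else.  Each stage (`map`,
`solve`, `stats`) can also be run separately on intermediate files.

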