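# clademiner

**clademiner** is a Python library for lineage-specific gene-family mining —
the comparative-genomics strategy used to find candidate pathway enzymes in
non-model plants. The motivating setting is the hunt for flavonoid pathway
enzymes (a flavone-6-hydroxylase among cytochrome P450s, a
flavonoid-7-*O*-glucuronosyltransferase among UDP-glycosyltransferases) in
*Erigeron breviscapus*, the source plant of the cardiovascular drug
breviscapine: superfamily members are mined from multi-species proteomes with
a profile domain search, partitioned into subfamilies, tested for restriction
to a focal clade (Asteraceae) against an outgroup, and prioritized by
expression. The package also implements the downstream quantitative
bookkeeping of such projects: Michaelis–Menten kinetics fitting and
fermentation yield arithmetic.

Everything runs without downloads: a first-class synthetic-data module
generates proteomes, expression tables and kinetic datasets with *planted
ground truth*, so every stage of the analysis can be scored for sensitivity,
specificity and exact recovery.

## The method

1. **Domain mining** (`clademiner.domains`) — a position-specific log-odds
   profile is slid along each protein (best ungapped window). Significance is
   an empirical E-value from residue-shuffled nulls, with a Gumbel tail fitted
   to the shuffled score distribution so that genuine matches can clear a
   stringent cutoff. Hits are kept when E < 10⁻¹⁰ and the whole protein length
   *L* satisfies 350 < *L* < 650 (both strict). hmmsearch `--domtblout` tables
   can be imported instead.
2. **Subfamily partitioning** (`clademiner.phylo`) — pairwise identity from
   Needleman–Wunsch global alignment (BLOSUM62, gap 10/1, free end gaps;
   identity = identical pairs / columns excluding terminal gaps); a
   neighbor-joining tree on *d* = 1 − identity, midpoint-rooted; subfamilies
   are the maximal clades in which **every** member pair exceeds τ = 0.55.
   The module also provides reciprocal-best-hit one-to-one orthologs and a
   bootstrapped (gene-resampling) species tree.
3. **Clade-specificity** (`clademiner.specificity`) — a subfamily is
   clade-specific iff all member species lie in the declared ingroup; class
   counts for a focal species are conserved by construction (e.g. the
   published 178 shared + 134 specific = 312 focal P450 genes).
4. **Expression prioritization** (`clademiner.expression`) — per-group mean
   expression (wild vs cultivated samples), a Wilcoxon rank-sum comparison of
   specific vs shared members on log₂(mean + 1), and a top-*k* shortlist
   (default *k* = 36) of clade-specific genes by mean expression.
5. **Quantitation** (`clademiner.kinetics`) — Michaelis–Menten
   v = V·S/(Kₘ+S) by Levenberg–Marquardt with Lineweaver–Burk initialization,
   k_cat = V/[E]₀; yield summaries (specific yield mg/gDCW, fold change,
   secretion split, titer totals).

`clademiner.pipeline.run_pipeline` composes stages 1–4 from a single config
(YAML-loadable) and writes TSV/Newick artifacts plus a deterministic JSON +
text report.

## Worked example

```bash
python examples/06_full_pipeline.py
```

prints (abridged):

```
[mine] proteins_scanned=102, hits=86, hits_kept=62
[cluster] members=62, subfamilies=6
[specificity] subfamilies=6, specific=2, shared=4
[rank] candidates=10, shortlist=10
classes: 2 specific / 4 shared subfamilies; focal genes 2 specific + 4 shared = 6
rank-sum specific vs shared: U=394, p=0.0106 (wilcoxon-rank-sum/asymptotic)
shortlist (10 genes):
    1. g00053 [SF0005] mean=289.81
    2. g00058 [SF0006] mean=93.06
    ...
```

Reading: of 102 simulated proteins, the profile scan plus E-value/length
filters kept exactly the 62 planted family members (no decoys); they fall
into 6 subfamilies matching the planted design, 2 of which occur only in the
5 ingroup species; the shortlist is every gene of those clade-specific
subfamilies ordered by mean expression, and its top entries are the planted
"pathway" genes. The other examples (`examples/01…05`) exercise each stage
separately — `05_kinetics_and_yield.py` refits the published EbF7GAT
parameters (Kₘ 9.24 µM / k_cat 0.57 s⁻¹ for apigenin, 70.15 µM / 0.24 s⁻¹
for scutellarein) from noise-free synthetic assays and reproduces the yield
arithmetic (1.68-fold improvement, ≈300 mg/L total titer, 26.6%/73.4%
intracellular/extracellular split).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates noise-free Michaelis–Menten initial-rate data over each
substrate's published assay concentration range, refits the model from
scratch, and writes the recovered Kₘ (both substrates) and k_cat (apigenin)
as JSON.

## Layout

```
src/clademiner/   simulate, domains, phylo, specificity, expression,
                  kinetics, pipeline
examples/         one narrative script per capability
tests/            pytest suite (unit, property-based, acceptance)
docs/methods.md   models, assumptions, parameter choices, limitations
```
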