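# plasfit

Quantitative analysis of the fitness cost a conjugative plasmid imposes on
its bacterial host, and of the compensatory evolution that ameliorates it.
The package grew out of a serial-transfer competition experiment between
plasmid-bearing and plasmid-free *Pseudomonas putida* KT2440 (IncP-1 plasmid
RP4), and covers every quantitative step of that experimental design:

* **Relative fitness from competition assays** (`plasfit.fitness`).
  Plasmid-bearing and plasmid-free strains are co-cultured through daily
  1:100 transfers; both subpopulations are tracked by dilution plating and
  colony screening. Fitness of the bearing strain is the ratio of realized
  log fold-changes,

  `W = ln(N_t,bearing / N_0,bearing) / ln(N_t,free / N_0,free)`,

  with W = 1 neutrality, W < 1 a plasmid cost and W > 1 a bearing-strain
  advantage. Plasmid persistence, conjugation frequency
  (transconjugants/donors) and the PCR band-intensity competition readout
  are covered too.
* **Plasmid copy number from sequencing coverage** (`plasfit.coverage`):
  mean plasmid depth / mean chromosome depth, rounded to one decimal.
* **Colony-size morphotypes** (`plasfit.morphology`): diameter summaries
  and threshold fractions separating small (costly) from large
  (compensated) colony classes.
* **Fold-change DE calling** (`plasfit.rnaseq`): RPKM, replicate-correlation
  QC, and the replicate-consistent rule that calls an ORF differentially
  expressed only when all four cross-replicate ratios exceed 2.0 (or fall
  below 0.5).
* **COG enrichment** (`plasfit.enrichment`): one-sided hypergeometric
  (Fisher exact) overrepresentation of COG categories in a DE set against
  the genome background.
* **Synthetic data for every input stream** (`plasfit.simdata`): a
  three-genotype logistic serial-transfer model (ancestral carrier,
  compensated carrier, plasmid-free) with conjugation, segregational loss
  and compensation; binomial read allocation across replicons; lognormal
  expression with planted fold-changes; truncated-normal colony diameters;
  band-intensity series.

Three small published summary tables (the 13-strain sequencing-coverage
panel, the 33 DE ORFs with COG codes, and genome-wide COG counts for the
5,350 KT2440 ORFs) ship as package data (`plasfit.datasets`), so the
headline analyses run with no downloads.

## Worked example

```python
from plasfit.datasets import load_wgs_coverage, de_cog_tally
from plasfit.coverage import copy_number_table
from plasfit.enrichment import enrich_table

for est in copy_number_table(load_wgs_coverage())[:3]:
    print(est.strain_id, est.copy_number_rounded)
for r in enrich_table(de_cog_tally()):
    if r.significant:
        print(r.cog_code, f"{r.k}/{r.K}", f"p={r.p_value:.2e}")
```

prints

```
KT2440(RP4) 3.1
1-L1 1.6
1-L2 2.0
L 4/200 p=3.32e-02
U 3/37 p=1.44e-03
O 5/165 p=3.09e-03
```

— the ancestral strain carries ~3.1 plasmid copies per chromosome while the
evolved (cost-ameliorated) isolates carry fewer (1.6–2.0 here), and the DE
set is significantly enriched for COG categories L
(replication/recombination), U (secretion/trafficking) and O (protein
turnover/chaperones) at α = 0.05.

The numbered drivers under `analysis/` run each stage end to end and write
their tables to `results/`:

```
python analysis/01_competition_fitness.py   # W trajectories, compensatory sweep
python analysis/02_plasmid_copy_number.py   # copy-number panel + calibration
python analysis/03_colony_morphology.py     # morphotype summaries
python analysis/04_differential_expression.py
python analysis/05_cog_enrichment.py
```

A `plasfit` CLI exposes the same stages (`plasfit fitness`, `copynum`,
`colony-stats`, `decall`, `enrich`, `band-ratio`, `simulate ...`) over the
TSV dialects described in `plasfit.tables`.

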