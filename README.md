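# residose

From regulatory residue limits to an administered animal dose — and the
statistics around a chronic-exposure mouse study.

`residose` is a Python toolkit for food-safety risk assessors and
preclinical study teams who need to answer, reproducibly: *if every
animal-origin food a consumer eats carried a veterinary antimicrobial
residue exactly at its legal Maximum Residue Limit (MRL), what daily dose
would that consumer ingest — and what dose should a mouse receive to model
that exposure?*  It also ships the downstream analytics such a study
needs: engraftment ("rooting") tables, humane-endpoint detection, ANOVA
power / sample size, liver histology grade distributions, IHC field-count
summaries, and compositional 16S microbiome summaries with exact
nonparametric tests — plus seeded synthetic-data generators so the whole
chain is testable without any animal or sequencing data.

## The model

**Worst-case dietary exposure.**  A one-day diet of animal-origin foods is
anchored to the EFSA protein reference intake (PRI = 0.83 g protein /kg
body weight/day for a 30-year-old adult).  Assuming every matrix is
contaminated exactly at its MRL (Reg. 37/2010 values bundled),

```
intake_s  = Σ_portions  MRL(s, matrix) [µg/kg] × mass [kg]      (µg/day)
dose_s    = intake_s / bw                                       (µg/kg bw/day)
```

Only matrices commonly eaten enter the exposure (muscle, milk, eggs;
liver, fat and kidney are excluded at the diet layer).  Sulfonamides have
no egg MRL — they are barred from egg-producing animals — so the egg
portion is non-applicable for that class rather than an error.

**Interspecies translation.**  Human ↔ mouse doses are converted by
body-surface-area (Km) scaling, Km mouse = 3, Km human = 37:

```
HED = dose_animal × Km_animal / Km_human        mouse dose = HED × 37/3
```

**Microbiome summaries.**  Taxa count tables (samples × ASVs with
taxonomy) are closed to relative abundances, collapsed to phylum or genus,
summarised as group mean ± SD percent (with the conventional > 1 % mean
filter), and compared with exact Wilcoxon signed-rank (paired) and
Mann–Whitney U (unpaired) tests — full-enumeration null distributions up
to a configurable size, tie-corrected normal approximation beyond.
Shannon, observed richness, Bray–Curtis and the Firmicutes/Bacteroidota
(F/B) ratio cover alpha/beta diversity and dysbiosis.

## Worked example

The bundled standard diet (milk 200 g, one 53 g egg, chicken breast
100 g, cod 100 g; 60 kg consumer):

```
$ residose exposure
Protein: total 53.872 g/day, requirement 49.8 g/day, surplus +4.072 g/day
        substance  total_ug_per_day  per_kg_dose_ug
chlortetracycline              50.6            0.84
     sulfonamides              40.0            0.67
Grand total: 90.6 µg/day for a 60 kg consumer
```

The diet's protein (53.872 g) slightly exceeds the 49.8 g requirement
(0.83 × 60); at the MRLs it carries 50.6 µg chlortetracycline and 40 µg
sulfonamides per day, i.e. 0.84 and 0.67 µg/kg bw/day.  Translating to
the mouse:

```
$ residose hed --dose 0.84        # human -> mouse, 0.84 × 37/3
10.4 µg/kg mouse bw/day
$ residose hed --dose 0.67
8.3 µg/kg mouse bw/day
$ residose water-dose --dose 10.4 # administered via drinking water
daily amount per animal: 0.26 µg
concentration: 0.052 µg/mL
per bottle (200 mL): 10.4 µg
```

A mouse drinking 5 mL/day at 25 g body weight receives 10.4 µg/kg/day
from a 0.052 µg/mL bottle.  Study design side:

```
$ residose cohort power           # one-way ANOVA, f=0.40, alpha=.05, power=.8
n per group: 22  total N: 66  achieved power: 0.8181
```

From Python the same chain is three calls:

```python
from residose import bundled_diet, bundled_food_table, bundled_registry
from residose import worst_case_intake, animal_from_hed

diet, pri = bundled_diet()
report = worst_case_intake(diet, bundled_food_table(), bundled_registry(),
                           ["chlortetracycline", "sulfonamides"])
doses = report.per_kg_dose_rounded()          # {'chlortetracycline': 0.84, ...}
mouse = animal_from_hed(doses["chlortetracycline"])   # DoseSpec(dose=10.4)
```

Synthetic cohorts and taxa tables (`residose simulate cohort|taxa|ihc|grades`)
are seeded and bit-reproducible; see `docs/methods.md` for the generative
models and their limits.

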