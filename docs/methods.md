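# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `residose`, module by module.

## Worst-case exposure model (`mrl`, `diet`)

The exposure estimate is deliberately an upper bound: every consumed
matrix is assumed contaminated exactly at its Maximum Residue Limit.  No
occurrence data, residue depletion, cooking loss or probabilistic intake
modelling enters the calculation; the result is a screening-level
worst case, not an expected exposure.

**Registry.**  The bundled MRL table is the Reg. 37/2010 extract for
chlortetracycline (muscle 100, liver 300, kidney 600, milk 100, eggs
200 µg/kg) and the sulfonamide class (100 µg/kg as a *class total* in
muscle, fat, liver, kidney).  Two modelling choices:

* Sulfonamides are a single class-level substance carrying the
  `class_combined_total` flag, because the regulation caps the summed
  residues of the group rather than each congener.
* The regulation extract lists no sulfonamide milk MRL, but the exposure
  tables this package mirrors apply 100 µg/kg to milk; the bundled fixture
  includes that milk row so the worked example closes.  Users can load a
  stricter table if they disagree.

The registry itself stays faithful to the regulation — liver, fat and
kidney entries are present and retrievable.  The *diet layer* excludes
them from exposure through a matrix whitelist (muscle, milk, eggs),
reflecting the dietary argument that offal is rarely eaten; this keeps
regulatory data and study-specific exclusions separable.

**Diet.**  The standard diet is protein-anchored: PRI = 0.83 g/kg bw/day
for a 30-year-old, 60 kg consumer → 49.8 g/day, met by milk 200 g + egg
53 g + chicken breast 100 g + cod 100 g = 53.872 g protein (CREA
food-composition values).  The egg portion is mass-based (53 g, the CREA
portion unit); a `count` multiplier is a convenience only.  Carbohydrate
and fat requirements are not modelled — nothing downstream uses them.

**Rounding.**  All internal arithmetic is unrounded; display rounding is
half-up (`decimal.ROUND_HALF_UP` on the shortest decimal repr), 2 decimals
for per-kg doses, 1 decimal for µg totals and percentages.  Half-up is the
convention consistent with 50.6/60 → 0.84.  The *rounded* per-kg dose is
what feeds dose translation, because an administered dose is prepared from
the reported (rounded) figure; with unrounded input the sulfonamide mouse
dose would be 8.2 rather than the administered 8.3 µg/kg/day.

## Dose translation (`allometry`)

HED = animal dose × Km_animal/Km_human (Km mouse 3, human 37) — the
standard body-surface-area convention.  Source texts sometimes label the
ratio ambiguously ("Km human/Km mouse" next to a printed ×3/37); the
implementation follows the numbers, which are self-consistent only under
the standard convention.  The inverse (mouse dose = HED × 37/3) rounds
half-up to 1 decimal by default; `round_to=None` gives the exact value and
makes the round-trip an identity to machine precision.

The drinking-water calculator needs a mean body weight and daily water
intake that dosing reports rarely state; defaults are 25 g and 5 mL/day —
typical adult-mouse values — and both are mandatory-overridable on the
CLI.  It flags infeasibility when cage consumption over the refill
interval (intake × days × animals) exceeds the bottle volume.

## Cohort analytics (`cohort`)

* **Rooting percentages** are engrafted/n per (group, day), carrying the
  last observation forward between visits (valid because engraftment is
  monotone).  Rounding is uniformly half-up to 1 decimal.  Published
  rooting tables sometimes truncate instead (1/7 printed as 14.2, 3/7 as
  42.8); the test suite documents these per-cell deviations as strict
  expected failures rather than mixing rounding policies.  A printed 90 %
  for n = 7 is unreachable under any policy (6/7 = 85.7) and is asserted
  nowhere.
* **Humane endpoints**: first day tumor volume ≥ 1500 mm³; first day
  weight ≤ 80 % of baseline, baseline being the first recorded weight —
  the simplest auditable choice where no run-in average is defined.
* **Student's t** defaults to the pooled (equal-variance) variant, with
  Welch by flag; the degenerate both-samples-constant-and-equal case
  returns p = 1 by convention and is logged.
* **ANOVA power** uses the exact noncentral-F formulation (λ = f²N) and
  searches the smallest balanced n/group reaching the target power.  At
  α = 0.05, power 0.8, f = 0.40, k = 3 this gives 22/group (66 total),
  with achieved power ≈ 0.818.  Note the tension worth knowing about:
  studies quoting exactly these settings often run far smaller groups
  (e.g. 7/group), implicitly relying on prior work rather than the
  computed n; the calculator reports the computed answer.
* **IHC summaries** average each animal's per-field positive-cell counts
  (10 fields of 0.7 mm² is the conventional design) and report the min
  and max of per-animal means per (group, marker) — the same summary
  shape used in histopathology tables.

## Microbiome summaries (`microbiota`)

* Relative abundance closes each sample to 1; zero-sum samples are
  excluded with a warning, never silently imputed.
* Collapsing sums counts by lineage label and conserves per-sample totals.
  Unclassified genera are labelled "unclassified *parent*" (family, else
  class), so categories like "unclassified Lachnospiraceae" are first-class
  taxa.
* Group summaries are mean ± sample SD (ddof = 1) of percent abundance;
  the > 1 % filter applies to the *group mean*, and filtered taxa are
  pooled into "other".  Size-1 groups report SD 0 with a warning.
* Phylum synonyms (Bacteroidetes/Bacteroidota, Firmicutes/Bacillota) are
  canonicalised before the F/B ratio, which is scale-invariant and
  undefined (error) at zero Bacteroidota.
* Alpha/beta metrics are the field-standard minimal set — Shannon (nats),
  observed richness, Bray–Curtis — chosen because the summaries they feed
  never specify alternatives.

**Exact tests.**  Wilcoxon signed-rank (paired) and Mann–Whitney U
(unpaired), two-sided, with exact null distributions: all 2ⁿ sign
assignments for Wilcoxon (zero differences dropped, average ranks on
ties); for Mann–Whitney a subset-sum count recursion over doubled ranks
gives the exact distribution of U over all C(n+m, n) labelings in
polynomial time, ties included.  The two-sided p is the probability of a
statistic at least as far from the null center as observed — identical to
the classical doubled one-tail value whenever the null distribution is
symmetric (always, without ties).  Default enumeration limit n = 12;
beyond it, a normal approximation with tie correction and continuity
correction, and the result records which mode ran.  All-zero differences
give p = 1 by convention.

## Synthetic data (`synthetic`)

The generators exist so that every analysis stage has a closed testing
loop; they emulate the *statistical shape* of a chronic-exposure mouse
study, not its biology.

* **Taxa tables**: Dirichlet-multinomial.  Composition ~ Dirichlet(c·p),
  p the renormalised target means, c moment-matched to the largest-SD
  taxon via SD² = p(1−p)/(c+1); unsatisfiable SD targets (c ≤ 0) fall
  back to c = 50 with a warning.  Depth ~ Gamma(shape = dispersion,
  mean = 159,067 reads — a realistic per-sample 16S yield), rounded,
  min 1.  Published control-group phylum profiles bundled as defaults
  include one whose printed percentages sum to > 100 %; it is renormalised
  (logged) and used as a shape target only.  The model captures
  overdispersed compositions; it does *not* capture phylogenetic
  correlation between taxa, animal-level longitudinal autocorrelation, or
  cage effects — so passing recovery tests show estimator correctness, not
  fidelity to real gut dynamics.
* **Cohorts**: engraftment uses one latent uniform per animal against the
  cumulative per-day probabilities — marginals are exact and monotonicity
  is structural.  Engrafted animals grow tumors exponentially
  (default 0.25/day from 100 mm³) with multiplicative log-normal noise
  (σ = 0.15); weights are baseline 25 g + 0.03 g/day drift + N(0, 0.4 g)
  noise.  The default scenario is 3 groups × 2 sexes × 7 animals with
  per-day engraftment probabilities set to the reported rooting fractions.
* **IHC / grades**: rounded truncated-normal field counts (field SD 0
  reproduces integer targets exactly); multinomial grade draws.
* All generators are pure functions of (parameters, seed) —
  `numpy.random.default_rng` throughout, bit-identical reruns.
* `mann_whitney_power` estimates, by Monte-Carlo under this same model,
  the power of the unpaired test to detect a between-profile shift; the
  test suite checks that an independent batch's empirical rejection rate
  matches it within 5 percentage points.

## Problem sizes in the test suite

Oracle and recovery tests are sized for tight Monte-Carlo error at
interactive runtimes: 10⁵ permutations for the t-test oracle, 4,000
simulated ANOVAs, n = 50 samples (depth 5,000) for composition recovery,
5,000 animals for engraftment recovery, 14,000 draws for grade recovery,
and 2 × 400 replicates for the power closure.  The whole suite runs in
well under a minute.

## Known limitations

* The exposure model is additive over portions at fixed MRLs; no
  uncertainty or variability propagation.
* Km scaling is a point conversion; no pharmacokinetics (absorption,
  clearance, tissue depletion).
* No survival analysis or growth-curve mixed modelling; group comparison
  is the named t-test only.
* The microbiome layer consumes a finished taxa table; read processing,
  denoising and taxonomy assignment are upstream concerns.
* Exact-test p-values below ~1/C(n+m, n) are unreachable by construction
  at small n; that granularity is a property of the tests, not a bug.
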