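# Methods

`phylometab` treats a patient's untargeted serum LC-MS profile as a set of
heritable-looking characters and applies cladistic machinery to stratify
specimens.  This note records the model, its assumptions, the tunable
parameters, and the design decisions taken where the procedure was genuinely
open.

## Character polarization

Each aligned feature (an (m/z, RT) pair with per-specimen intensities)
becomes one binary character.  The healthy outgroup defines the ancestral
condition: per feature, the outgroup intensities set a *normal range*
`[lo, hi]`, and a patient specimen is coded **0 (ancestral / plesiomorphic)**
inside the range and **1 (derived / apomorphic)** outside it.  The kind of
departure is retained as metadata — `up`, `down`, `novel` (peak absent from
every outgroup specimen), `vanished` (peak present in the outgroup,
undetected in the patient) — but the character itself stays binary: up- and
down-regulation are not distinct states, because the downstream parsimony
engine consumes two-state characters.

Coding order per cell (effective intensity x, with missing cells mapped to
0 — "peak not detected"):

1. `lo <= x <= hi` → (0, none)
2. `x > hi` → (1, up), reported as (1, novel) when the outgroup never
   detected the feature
3. `0 < x < lo` → (1, down)
4. `x = 0` with `lo > 0` → (1, vanished)
5. `x = 0` with `lo = 0` → (0, none)

Rule 1 takes precedence, so a zero intensity is ancestral whenever the
outgroup range reaches down to zero.

**Normal-range estimators.** Default `minmax` uses the outgroup min–max —
the most literal reading of a "normal range" from a reference panel;
`mean_k_sd` (mean ± k·sd, sample sd, clipped at 0, default k = 2.0) is
offered for larger outgroups where extreme donors would inflate the min–max
envelope.  At least 2 outgroup specimens are required; fewer than 3 triggers
a warning.  No outlier trimming of the outgroup is performed.  The
`min_intensity` floor (default 0) lets noisy instruments raise the detection
threshold.

By default **all characters are kept** — no a priori selection; dropping
constant or parsimony-uninformative columns is an opt-in speed switch whose
removed-character list allows autapomorphy accounting downstream.

## Maximum parsimony

Wagner parsimony on two unordered, freely reversible states is equivalent to
Fitch counting, so tree length is the Fitch score.  Two scorers are
implemented: set-based Fitch (search inner loop, binary trees) and a
vectorized two-state Sankoff dynamic program (public scorer; exact on
polytomies as well).  Tests cross-check both against brute-force enumeration
over all ancestral labelings and against dendropy's independent Fitch pass.

**Search.**  Stepwise addition followed by branch swapping:

* replicate 0 inserts taxa in matrix row order (the "nonrandomized input");
* replicates 1..R (default R = 10) use seeded random addition orders; all
  per-replicate seeds derive deterministically from one master seed;
* ties in stepwise placement go to the lowest-index attachment edge, for
  reproducibility;
* swapping is best-improvement hill climbing with `spr` (default) or `nni`
  neighborhoods until no move shortens the tree.

All distinct equally parsimonious trees found are retained up to a cap
(default 100); when more than one survives, the tree shipped downstream is
their strict consensus.  An exhaustive enumerator over all (2n−5)!!
topologies (guarded at 9 taxa, 135,135 topologies) provides the exact
optimum for validation; on 5–7-taxon random matrices the default heuristic
attains it in every tested instance.

**Rooting.**  A hypothetical all-ancestral taxon (every character 0) is
appended to the matrix and the tree is rooted on its edge, realizing the
outgroup polarity: derived states point away from the healthy condition.

## Synapomorphy accounting

* **strict** (default): character c annotates node v iff all leaves under v
  are derived and all other patients ancestral — "unique and unreversed",
  matching the definition of a synapomorphy as the shared derived character
  of exactly that group.  Characters derived in a single specimen are
  autapomorphies, reported per specimen and never as clade labels;
  characters whose derived set matches no clade are listed as unplaced
  (homoplasy under the chosen topology).
* **reconstructed**: ancestral states from the two-state Sankoff DP with the
  root fixed all-ancestral; ACCTRAN resolves ties away from the parent state
  (early changes), DELTRAN toward it (late changes).  A character annotates
  every node whose stem edge carries a 0→1 change, so homoplasious
  characters may label several nodes.  The number of implied changes always
  equals the Fitch length.

On homoplasy-free matrices the two modes coincide, and synapomorphies plus
autapomorphies exactly partition the variable characters.

## Clinical correlation

Prevalence percentages are rounded **half-up to one decimal** (7/11 → 63.6,
5/11 → 45.5, 13/55 → 23.6).  Clade-by-covariate association uses Fisher's
exact test (two-sided) for 2×2 tables and the chi-square test for larger
ones; degenerate tables (fewer than two non-empty rows or columns) are
flagged and carry no p-value.  No multiplicity correction is applied; the
number of tests is reported so users can apply one.  A mid-p Fisher variant
(`p_method="fisher_midp"`) is provided for simulation studies, where the
plain exact test's conservatism distorts calibration summaries.

The packaged 55-patient cohort fixture reproduces the printed marginal
counts exactly (race 15/37/3, T-stage 40/12/3, Gleason 20/30/4/1, risk
14/34/7, ADT 13/42, protocol 6/36/9/4, 11 metastatic patients of whom 3
low / 6 intermediate / 2 high risk and 4 with ADT); per-patient values never
printed (individual ages, PSA, cross-tabulations) are synthesized
deterministically inside the printed ranges (age 52–90, median 68; PSA
1.9–25.6, median 8.1) and are labelled synthetic — only the margins carry
information.  The biosignature fixture likewise reproduces the printed
carriage counts; where the source counts are internally inconsistent (a
6-of-7 carbamic-acid record alongside an 11-patient metastatic group), the
patient-level flags encode the 7-denominator reading and the verbatim
records are stored unreconciled.

## Putative annotation

Feature m/z values are matched to a user-supplied local compound table under
a ppm tolerance computed on the adduct m/z (default 5 ppm), for singly
charged adducts: proton mass 1.007276 Da, Na−H +21.981944, K−H +37.955881.
Matches are putative — many-to-many, ranked by ppm error.  No online
database retrieval, MS/MS matching or pathway analysis is performed.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not raw
chromatography:

* Baseline intensities are log-normal (per-feature location uniform on
  ln-scale ≈ e^9.2–e^13.8, i.e. ~10⁴–10⁶ counts; scale 0.3 ln-units) — the
  conventional LC-MS abundance model, stated here as an assumption.
* Planted clades form a hierarchy; each clade's synapomorphic features are
  shifted outside the outgroup min–max for every member (default effect 3×
  above the max for `up`, 1/3 below the min for `down`; `novel` features are
  zero in the outgroup, `vanished` zero in the clade).
* No-signal features stay inside the outgroup range for all patients up to a
  `noise_amplitude` fraction of the range (default 0), so at defaults
  polarization recovers the planted matrix cell-exactly and the planted tree
  is a perfect phylogeny.  The `caterpillar_plan` helper builds fully
  resolved ladders (m specimens → m−2 clades), for which the most
  parsimonious tree is unique.
* Null cohorts draw patients from the same distribution as the outgroup;
  under min–max polarization a fresh i.i.d. draw falls outside the range of
  n outgroup draws with probability 2/(n+1) (1/(n+1) per side, a rank
  statistic) — with the default 9-donor outgroup, a 20% derived-cell rate.
* Clinical covariates default to the study's margins (risk 14/34/7 of 55,
  ADT 13/55, metastasis 11/55) and are drawn independently of clade
  structure; an optional coupling knob plants a clade–metastasis association
  for power studies.

Not emulated: chromatographic drift, batch effects, adduct/isotope feature
redundancy, intensity-dependent missingness.  Passing tests on these cohorts
therefore demonstrate correctness of the algorithms under the stated noise
model, not robustness to real instrument artifacts.

## Calibration of the association test

The null-calibration study generates cohorts with no planted structure
(8-donor outgroup, 40 patients, 60 features), infers a cladogram (one
stepwise replicate + NNI), and tests the tree's **most balanced clade**
against the independent risk covariate.  Two design points matter:

* The ingroup-root split of a null-data tree is typically 1 vs n−1; such
  tables are degenerate or nearly so, and carry no information.  The most
  balanced clade is the natural "does this grouping mean anything" probe.
* With a binary covariate, the modal 2×2 table occurs with probability
  ≈ 0.25, so *any* deterministic p-value — exact, mid-p, or chi-square —
  has an atom of that size and no finite-sample p distribution can be
  uniform.  This is a property of discrete 2×2 tables, not of an
  implementation.  The three-level risk covariate spreads that mass over a
  much larger table support; its chi-square p-values are uniform to within
  Kolmogorov–Smirnov resolution at 200 runs.

## Problem sizes and numerical choices

Test and reproduction runs use exhaustive search up to 8 taxa, heuristic
search elsewhere; planted-recovery sweeps use 4–7-patient ladders over 20
seeds; the calibration study uses 200 null cohorts of 40 patients.  These
sizes make every oracle comparison exact while keeping full runs in the
minutes range on one core.  Mass filtering uses the closed interval
[50, 850] Da.  A zero-length tree has no defined consistency index (returned
as a flag, not a number).  CSV round trips are bitwise exact (floats written
with 17 significant digits and parsed cell-by-cell).

## Known limitations

* The heuristic search carries no optimality guarantee beyond the sizes
  where it was checked against the exhaustive oracle; on large, noisy
  matrices SPR from 11 starts can stop in local optima.
* Strict synapomorphy extraction deliberately leaves homoplasious characters
  unplaced; reconstructed mode re-attaches them at the cost of
  ACCTRAN/DELTRAN arbitrariness.
* The outgroup min–max range tightens as the outgroup grows, so the null
  derived rate depends on outgroup size (2/(n+1)); analyses comparing
  cohorts should hold the outgroup fixed.
* Patient-level values in the packaged clinical fixture are synthetic;
  only the printed margins are assertable facts.
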