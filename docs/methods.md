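# Methods

`hehsim` models how the high-hyperdiploid (HeH) karyotype of childhood
acute lymphoblastic leukaemia — 51–67 chromosomes, dominated by whole-
chromosome gains of a characteristic set — can arise, and provides the
cohort-level statistics used to discriminate between candidate origins.
This note records the model, its assumptions, the parameters that matter,
and the design choices made where the underlying description was genuinely
open.

## The population model

### State

A cell is a homologue-resolved karyotype over the 23 chromosome pairs
1–22 and X. The model is female (46,XX); chromosome Y is not represented
in the simulator (cohort tables may carry Y rows for male cases, which
are excluded from simulator-facing comparisons). Each chromosome carries
a pair of non-negative integers — the copy number of each parental
homologue — so states such as uniparental isodisomy (UPID, 2:0), 2:2
versus 3:1 tetrasomy, and heterodisomy (1:1) are distinguishable.
Populations are stored as an `(n, 23, 2)` integer matrix and every step
of the generation loop is vectorised over it.

### Initiation models

Five founder mechanisms are provided:

1. **diploid/sequential** — 46,XX founders; all aneuploidy accrues by
   later nondisjunction.
2. **tetraploid/sequential** — 92,XXXX founders; chromosomes are lost at
   35% per chromosome per division (a published per-division loss rate
   for tetraploid intermediates), with the aneuploidy penalty disabled
   for this model only, since no tetraploid founder would survive it.
3. **diploid/tripolar** — one tripolar mitosis of a diploid cell.
4. **tetraploid/tripolar** — one tripolar mitosis of a tetraploid cell.
5. **mitotic catastrophe** — complete loss of sister-chromatid cohesion:
   all 92 chromatids of a replicated diploid segregate independently to
   two daughters.

Tripolar mechanics are a modelling choice (the source description lives
at the cartoon level): each replicated homologue's sister-chromatid pair
disjoins to the two poles of a pole pair drawn uniformly from the three
possible pairs, independently per homologue. The diploid/tripolar
founder inherits the union of two fixed poles (bipolar cytokinesis of a
tripolar spindle); the tetraploid/tripolar founder inherits one pole.
This is the simplest rule that simultaneously yields (i) a near-HeH
diploid/tripolar founder (expected MCN 552/9 ≈ 61.3, per-chromosome
totals {2: 4/9, 3: 4/9, 4: 1/9}) with no losses and **zero** founder
UPIDs, and (ii) founder UPID frequencies well above the 2.5% stopping
threshold for the tetraploid/tripolar and catastrophe models. Founders
containing a nullisomy are redrawn, so the initial population size is
exact.

### Division and missegregation

Each generation every cell divides; both daughters enter the
pre-selection pool (the population transiently doubles). Per chromosome
the missegregation probability is `M_misseg × N` with `M_misseg =
15 × 10⁻⁴`/chromosome/mitosis and `N` the chromosome's copy number; at
most one event per chromosome per division, but multiple chromosomes may
missegregate in the same division. The missegregated copy — homologue
chosen proportionally to its counts — ends up +1 in a uniformly chosen
daughter and −1 in the other, conserving chromatids. Nullisomic cells
die unconditionally.

### Selection

Survival probability is the score

    S = 0.5 + (NT_g1 + 2·NT_g2 − NT_g3 − S_aneuploidy) / 23

clamped to [0, 1], where group 1 = {X, 4, 6, 10, 14, 17, 18} (strong
positive selection of gains), group 2 = {21} (strongest), and group 3 is
the remainder (negative selection of any deviation from disomy). The
extended four-group form replaces `NT_g3` with the strictly negative
subset (group 3b) and adds `+0.02·NT_g4` for the weakly selected
chromosomes {5, 8, 11, 12, 22}. By default `NT_g1`/`NT_g4` count
chromosomes with ≥3 copies, `NT_g2` is an any-gain indicator, and
`NT_g3` counts chromosomes with total ≠ 2 (a `trisomy_only` strict mode
counts exactly-3 states).

`S_aneuploidy` is a beta-law penalty in the excess-ploidy coordinate
`x = (MCN − 46)/46` with shape (a = 0.18, b = 0.65), location 0 and
scale 1.8, applied only above MCN 46. Two genuinely open choices are
exposed:

- **`penalty_form`** — `cumulative` (default): the beta CDF, which is
  monotone increasing in MCN, as an aneuploidy *burden* must be.  The
  alternative `density` evaluates the scaled beta density literally;
  with a = 0.18 that density diverges as MCN → 46⁺ and then *decreases*
  across the hyperdiploid range, so under it (or under the CDF applied
  outside the /23 normalisation) every aneuploid cell is less fit than
  a diploid and the population never leaves 46,XX — no hyperdiploid
  endpoint exists.
- **`penalty_inside_fraction`** — default `True`: the penalty shares the
  /23 normalisation of the group terms. This is the only combination
  (with the CDF) under which gains of positively selected chromosomes
  are net-beneficial and the simulated stopping times and endpoint
  karyotypes land where they should: with 10,000-cell populations the
  diploid/tripolar model reaches the 2.5% UPID stop at a median near
  50–70 generations and diploid/sequential near 470, an order-of-
  magnitude separation, with endpoint populations at HeH modal numbers.

A diploid cell scores exactly 0.5 under every mode.

### Culling, replenishment, stopping

After selection the population is restored to `pop_size` (default
50,000) by uniform subsampling, or topped up with fresh founder draws
from the model when fewer survive (a resampling mode is selectable). The
run stops when the UPID frequency of the 14 tracked chromosomes (1–3, 5,
7, 8, 11–13, 15, 16, 19, 20, 22 — those without positive selection)
reaches `upid_stop` (default 2.5%; 5% is the convention for high-MCN
analyses), or after 2,000 generations. The UPID frequency is
UPIDs / all disomies over tracked chromosome slots pooled across cells,
matching the patient-side UPIDs/all-disomies statistic; an
`all_tracked`-denominator mode is provided since the stop metric's
denominator is not pinned down by its source.

Reproducibility: one master seed per run; each generation draws from its
own spawned substream, so early-generation telemetry is independent of
run length. Identical (model, config, seed) gives bit-identical results.

### Why UPID frequency is the clock

Loss of one copy from a (2,1) trisomy leaves a heterodisomy with
probability 2/3 and a UPID with probability 1/3 (`loss_outcomes`
enumerates this exactly). UPIDs are selectively invisible (two copies)
and therefore ratchet up wherever trisomies transiently exist, making
the tracked-chromosome UPID fraction a monotone clock of cumulative
missegregation exposure. The diploid-origin models start at 0 UPIDs and
take tens (tripolar) to hundreds (sequential) of generations to reach
2.5%; the tetraploid/tripolar and catastrophe founders start far above
it (≈33% of founder disomies are UPIDs for both, by enumeration) and
plateau above 30% — the dichotomy that rules them out as HeH origins.

## Cohort statistics

`cohort_stats` consumes long-format tables (case, chromosome,
homologue-resolved counts, clonal fraction). Dominant records have
clonal fraction ≥ 0.5; statistics use them unless stated. Implemented:
copy-state spectra, tetrasomy 2:2/3:1 typing, per-chromosome
UPIDs/all-disomies ratios, per-MCN mean trisomy/tetrasomy curves with
the MCN-62 cohort split, and the loss-from-trisomy subclonality test —
a two-sided exact binomial test of the UPID/trisomy subclone count
against p = 1/3, using the minimum-likelihood two-sided convention
(`scipy.stats.binomtest`), validated against exhaustive enumeration for
n ≤ 25.

Model comparison reports two RMSE families per model — per-MCN
trisomy/tetrasomy curves and per-chromosome aberration-class frequency
profiles — against a cohort profile; MCN bins absent from the cohort are
skipped rather than zero-filled. Their sum yields a single rank and is
flagged in the report as this package's convention.

## Mutation timing

On a trisomy, an SNV on the duplicated homologue predating the gain
(BTRI) sits on 2 of 3 copies (expected VAF 2/3); a single-homologue SNV
(B/ATRI) on 1 of 3 (VAF 1/3). In a purity-`p` tumour/normal mixture a
variant on `k` of `C` tumour copies has expected VAF
`k·p / (C·p + 2(1−p))`. Classification is by binomial read-count
likelihood between the two hypotheses with an ambiguity band
(|log-LR| < 2 by default, minimum depth 10); a window mode splits at the
midpoint of the two expectations for threshold-style analyses. At
purity 1 and deep coverage the rule reduces to a VAF-0.5 split. The
likelihood rule is this package's documented stand-in for the original
allele-fraction cut-offs, which are not restated in the source.

Homologue assignment uses the 0.6/0.4 allele-fraction thresholds with a
dead zone between; diagnosis/relapse concordance is a majority vote of
informative variants, with a BAF > 0.8 screen for UPID chromosomes.

## Single-cell bookkeeping

Clones are ≥2 cells with identical whole-chromosome profiles; singletons
are unique genomes. Distances are Manhattan over chromosomes. The
heterogeneity score — mean per-cell Manhattan distance to the
per-chromosome modal profile, divided by 23 — is a surrogate summary and
is **not** numerically comparable to scores from external single-cell
copy-number callers.

## Synthetic data

The cohort generator reproduces the emulated cohort's marginal
frequencies: gains 21:100%, X:97%, 14:95%, 6:89%, 18:83%, 4:82%, 17:78%,
10:74%, 8:38%, 5:23%, 9:19%, 11:14%, 12:14%, 22:11%, 5% baseline for the
rest; tetrasomies 21:81%, X:20%, 14:17%, 18:12%, 10:8.3%, 8:2.6%,
4:1.7% with a 5% 3:1 share; pentasomy 21 in 4.5% of cases; UPID rate
2.5% per disomic chromosome with chromosome 9 at 17%; a 0.045% monosomy
rate. Chromosomes are sampled independently — the joint dependence
between gains in real cases is unknown, and this is an explicit
simplification: recovery tests validate marginal calibration, not joint
structure. Subclones (28% of cases, loss-from-trisomy structure,
fraction uniform on [0.1, 0.5]) below the 0.2 bulk-detectability floor
are merged into the major clone. Male cases (off by default; the
simulator and default cohort are female) add XXYY/XXXYY gains at 21% and
Y nullisomy at 4%. An optional rejection mode constrains case MCN to
51–67 to mimic diagnosis ascertainment.

Variant and cell-matrix generators retain ground-truth labels; the
recovery tests show ≥95% timing-classification accuracy at depth 60 and
purity ≥ 0.8, and clone-fraction recovery within binomial error. What
passing these tests does *not* show: robustness to segmental events,
sequencing artefacts, correlated gains, or copy-number caller noise —
none of which the generators emulate.

## Problem sizes and numerical choices

The package default population is 50,000 cells. The bundled test suite
and `scripts/acceptance.py` run the simulator at 10,000 cells with 10
replicates per model (founder statistics at 10,000–20,000 draws; the
1,000-generation plateau runs at 2,000–5,000 cells), sizes at which the
stopping-time medians and endpoint karyotype statistics are already
stable and the whole pipeline runs in minutes on one core. Integer
copy-number state is int16; the penalty's x is clamped to the beta
support; nullisomic founders are redrawn rather than admitted-then-
killed; empty disomy denominators return 0 for the stop metric and NaN
in cohort ratios; ties in clone ordering are broken by stable sort on
size.

## Known limitations

- No segmental/sub-chromosomal events in the simulator state;
  structural aberrations enter only as annotations in cohort and
  single-cell inputs.
- Generations are synchronous; no explicit cell-cycle timing, spatial
  structure, or death-by-age.
- The per-chromosome missegregation rate is constant over time and
  chromosomes; real rates likely vary.
- The tetrasomy-21 3:1 share of the diploid/tripolar endpoint runs above
  the patient cohort's value under the default counting rules (the
  sequential model's ≈2/3 share is reproduced); see the model-comparison
  report rather than this single statistic for ranking.
- Table-1-style heterogeneity scores from external callers are not
  reproducible here by construction (surrogate formula).
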