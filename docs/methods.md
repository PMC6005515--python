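# Methods

## The screen model

A pooled knockout sensitizer screen measures guide abundance by
sequencing at several timepoints under a vehicle arm and one or more
drug arms, against a shared day-0 reference. The package models guide
dynamics as exponential growth on the log2 scale: the cells carrying
guide *g* of gene *G* in arm *a* grow at a rate offset (doublings/day)

    r(g, a) = phi_G + delta_{G,a} + gamma_a

where `phi` is the knockout's drug-independent fitness cost or gain,
`delta` the drug × gene interaction (negative = sensitizer; zero in the
vehicle arm and for non-targeting controls), and `gamma` the drug's
growth penalty on all cells. Expected relative abundance at day *t* is

    p_g(t)  ∝  p_g(0) · 2^(r(g,a)·t)

A sensitizer with `delta = −0.1` log2/day therefore produces an
expected guide LFC of −2.1 at day 21 — the scale of the strong hits a
screen of this design reports.

### Noise model

- **Infection bottleneck.** `p(0)` per replicate is a multinomial draw
  of `bottleneck_cells_per_guide × n_guides` cells from a uniform
  plasmid pool (the Dirichlet-multinomial limit for a tightly
  concentrated plasmid library). The default 1000 cells/guide matches a
  screen run at 1000× representation; `inf` gives an exactly uniform
  start. Later passages are treated as deterministic in expectation —
  adequate when representation stays at ~1000×, where passage drift is
  dominated by sequencing noise.
- **Sequencing counts.** Negative binomial with mean
  `coverage × n_guides × p_g(t)` and a single global dispersion
  (variance = μ + φμ²; default φ = 0.05, a typical screen-count
  overdispersion). φ = 0 gives Poisson.
- **Day-0 sharing.** One day-0 sample per replicate, used by every arm,
  mirroring a screen that banks a reference pellet before splitting
  into arms.
- **Seeding.** One global seed; every random stream (library sequences,
  per-replicate bottleneck, per-sample counts, plate noise) is keyed by
  seed plus a SHA-256 hash of its name, so draws do not shift when
  arms, days or replicates are added.

What the generator does *not* emulate: Cas9 cutting-efficiency
heterogeneity across guides, multi-guide infection (MOI > 1), guide
off-targets, PCR jackpotting beyond the NB dispersion, or
passage-to-passage bottlenecks. A green recovery test therefore
establishes that the analysis recovers effects of a stated size under
realistic count noise — not that it is robust to guide-quality
artifacts real libraries contain.

## Differential abundance

The analysis contrast is **drug arm vs vehicle arm at the same harvest
day** (default 21); day 0 is kept for representation QC only. Before
testing, guides with fewer than 10 reads summed over *all* samples are
discarded (strict `< 10`, applied once).

- **TMM.** Factors follow the standard published defaults: 30%
  two-sided trim on M-values, 5% on A-values, inverse delta-method
  variance weights, reference = sample whose 75th-percentile count
  fraction is closest to the mean. Implementation cross-checked against
  the Bioconductor reference on a skewed fixture (agreement at 1e-6).
- **log2-CPM.** `log2((count + 0.5) / (factor·libsize + 1) · 1e6)`.
- **Precision weights.** Per-guide residual SDs from the two condition
  means; `sqrt(sd)` lowess-smoothed against mean log2-CPM (span 0.5;
  lowess `delta = 0.01 × range` for near-linear cost at screen scale);
  weight = predicted `sqrt(sd)^−4` at the observation's fitted
  log-abundance, clamped to [1e-6, 1e6].
- **Moderated t.** The prior (d0, s0²) is moment-matched to the
  log-variance distribution via digamma/trigamma identities (Newton
  inversion of trigamma); posterior variance
  `(d0·s0² + df·s²)/(d0 + df)`, t referred to d0 + df degrees of
  freedom, normal when d0 → ∞ (which occurs when the observed
  variances are no more dispersed than chi-square sampling predicts —
  common at 17k guides with well-behaved noise). If estimation fails
  (fewer than 10 usable variances, degenerate inputs) the prior falls
  back to d0 = 4, s0² = median(s²), logged.
- **FDR.** Benjamini–Hochberg across all guides within a contrast,
  two-sided p-values.

At the screen's stated geometry (2194×8 guides, 3v3, coverage 1000,
dispersion 0.05) the null guide-level p < 0.05 rate measures ≈ 0.045 —
slightly conservative, as voom-style weighting on NB counts tends to
be — and no gene passes |median LFC| > 1 in null runs.

## Hit calling

Gene score = median LFC over the gene's surviving guides (midpoint rule
for even counts), computed from the single fitted LFC per guide (not
per-replicate medians, matching the one-coefficient contrast fit).
Hits use strict inequalities: "2-fold" = |median LFC| > 1. NTC guides
aggregate to a pseudo-gene reported for QC and excluded from hit sets.
Cross-arm overlap is a per-direction Venn partition; concordance
between screens is the squared Pearson correlation of shared-guide
LFCs.

## Combination score

Fraction inhibition is implemented exactly as the ratio
`f = control/treatment` (≥ 1 = inhibition), not as 1 − viability;
predicted combination `f_guide · f_drug`; score
`delta = f_combo_observed − f_combo_predicted`. Delta = 0 is an
algebraic identity whenever effects are multiplicative, and the score
is invariant to rescaling all four inputs.

Decisions where the assay description is open:

- Replicate wells are averaged **before** ratio-taking (ratios of
  means), which is stable against near-zero wells.
- Non-positive well values: clamped to a configurable floor (default:
  half the smallest positive value on the plate) and the score flagged
  `censored`; with no floor configured they are an error.
- Gene summary = arithmetic mean of guide deltas per passage.
- siRNA plates are scored with identical formulas.

For pooled counts the wells are built from CPM normalized two ways:
each guide's abundance is divided by its own day-0 abundance (removing
library composition), and the no-guide reference is the aggregate NTC
abundance treated identically. A neutral guide then scores ≈ 0, the
NTC pseudo-guide exactly 0, and a guide depleting specifically under
drug scores positive — concordant with arrayed-assay expectations.
Note `f_drug` from pooled data only captures the drug's *differential*
effect visible in relative abundance, not absolute growth inhibition.

## Numerical / degenerate-input choices

- TMM pair with all M-values < 1e-6 in magnitude short-circuits to
  factor 1 (identical or purely depth-scaled samples).
- Dyadic-rational test fixtures are used where a property is asserted
  to hold *exactly* in floating point (e.g. zero delta on
  multiplicative quadruples); general random fixtures are asserted at
  1e-9 relative.
- CPM depth-invariance holds to < 0.01 log2 at counts ≥ 100 (the
  prior count contributes ~0.004 at count 100; exact invariance is not
  attainable with a nonzero prior).
- Medians use pandas' midpoint convention; ties need no special
  handling.
- p-values are clipped away from exact 0 to keep downstream −log10
  finite.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `coverage` | 1000 | reads/guide/sample | screen run at 1000× representation |
| `dispersion` | 0.05 | NB φ | typical pooled-screen overdispersion |
| `bottleneck_cells_per_guide` | 1000 | cells/guide | matches maintained representation |
| `analysis_day` | 21 | days | harvest timepoint of the contrast |
| `min_total` | 10 | reads | low-count guide filter (strict <) |
| `hit_cutoffs` | 1.0, 0.5 | log2 | 2-fold hit call; relaxed overlap call |
| voom `span` | 0.5 | lowess fraction | smooth trend at 10³–10⁴ guides |
| `prior_count` | 0.5 | pseudo-reads | keeps zero counts finite in log-CPM |

## Known limitations

- Only the two-condition contrast is modeled; no replicate blocking,
  no timecourse trajectory fits.
- FASTQ counting is exact-match, forward-strand, fixed window; no
  mismatch tolerance or demultiplexing.
- No permutation- or rank-aggregation-based gene p-values: the gene
  call is a median-LFC cutoff by design.
- No dose–response surface models (Loewe/ZIP/HSA); only the
  observed-minus-predicted multiplicative gap.
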