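# Methods

## Scales and conventions

Input intensities are normalized (RMA-scale) linear arbitrary units (AU),
as produced by standard microarray preprocessing; `stratiq` never touches
CEL files or performs normalization. All effect arithmetic happens on
log2 intensities; folds and AU floors are computed on the linear scale
because that is the scale the thresholds are stated on. Intensities are
floored at a configurable epsilon (default 1 AU) before any ratio — RMA
output is positive, so this only guards degenerate synthetic input.

Genomic coordinates are 1-based inclusive internally. BED input (0-based
half-open) is converted on read; one explicit convention avoids
off-by-one drift between the interval reader, the containment test and
the generator.

The signed fold change is `F/L` when `F ≥ L` and `−L/F` otherwise:
positive means higher in the Fat line, the magnitude is never below 1,
and `sfc(a, b) = −sfc(b, a)`. Display rounding (integers or one decimal)
is cosmetic; every comparison uses unrounded values.

## Snapshot filter cascade

The snapshot design pools RNA from several individuals into one chip per
tissue per line. There is no replication, hence no p-value at this stage;
inference is by fold thresholds only, and that limitation is by design.

Boundary conventions follow the criteria as printed per stage: the
relaxed filters use a strict `> 1.5`; the stringent stage uses an
inclusive `≥ 2`; non-adipose windows are strict (`|sfc| < w` in each of
liver, muscle, kidney). `FilterConfig(threshold_inclusive=...)` carries
the distinction. The per-depot filter can be run without the window
(`nonadipose_window=None`) to reproduce an unwindowed first pass; the
default reproduces the windowed per-depot counts.

The stringent stage's 100 AU floor applies to the higher-expressing
line's mean intensity over the three WAT chips (`floor_mode="mean_3wat"`;
`"higher_line"` requires every WAT chip of that line above the floor).
The mean 3-WAT fold reported for candidates is the arithmetic mean of the
three signed folds and is defined only for sign-consistent folds —
sign-discordant probes are an error rather than a silently meaningless
average.

Note one deliberate non-nesting: stringent candidates (window 2) are not
a subset of the relaxed coordinate list (window 1.5), because widening
the window can admit probes the tighter window rejected. Nesting holds at
matched windows, and the test suite asserts it there.

## QTL stratification

A gene is reduced to its midpoint coordinate; containment of the midpoint
in an interval (1-based, ends inclusive) decides membership. Midpoints
make membership deterministic and order-free where gene spans straddling
an interval boundary would be ambiguous. Overlapping intervals all
report. Probes without a gene identifier count toward "total" but not
"known" tallies; because published summaries of this shape are ambiguous
about the percentage base, both bases (known-in-QTL / known-genome-wide
and total/total) are computed and labelled.

The four QTL confidence intervals of the motivating mouse cross are not
public as machine-readable coordinates; intervals are therefore always
user-supplied (BED), and everything shipped in this repository uses
clearly synthetic placeholder coordinates.

## Moderated t and FDR

Per contrast, the pooled two-group variance `s²_g` has `df = n₁ + n₂ − 2`
degrees of freedom. The prior `(d₀, s₀²)` is fit by method of moments on
`z_g = log s²_g`: under a scaled inverse-chi-square model,
`Var(z) = ψ′(df/2) + ψ′(d₀/2)`, so the excess of the observed variance of
`z` over `ψ′(df/2)` identifies `d₀` via a Newton inversion of the
trigamma function, and the mean of `z` then identifies `s₀²` through
digamma corrections. If the observed spread does not exceed the
theoretical minimum, `d₀ = ∞` (single pooled variance) is returned; the
exactly-degenerate case (all variances identical) returns that common
value directly. `d₀ = 0` (the `NO_SHRINKAGE` sentinel) reduces exactly to
the ordinary pooled two-sample t, which is the parity the tests assert;
numeric parity with any external empirical-Bayes implementation is not a
design goal. By default all four contrasts share one prior, estimated
from the control-diet line contrast.

BH adjustment is the standard step-up procedure (delegated to
statsmodels' `fdr_bh`), applied per contrast; ties receive equal adjusted
values. The quantitative candidate filter retains a probe when the ratio
of the higher to the lower group mean (linear AU) exceeds the fold
threshold (default 2), the adjusted p is below alpha (default 0.05) and
the higher group's mean exceeds the AU floor (default 100). Folds come
from linear-AU means to match the floor's scale; significance comes from
the log2 scale where the normality assumption is reasonable. The fold
threshold is configuration: the relaxed ±1.5 screening convention and the
reported >2 convention are both one flag away, defaulting to 2.

### Diet-response classification

With group means FC/FF/LC/LF and per-contrast significance flags:

* `interaction_opposing` — line contrast significant on both diets with
  opposite signs;
* `diet_amplified` — line contrast significant on both diets, same sign,
  a within-line diet contrast significant, and |log2 FF−LF| > |log2
  FC−LC| (baseline divergence amplified by diet);
* `line_only` — line contrast significant on both diets, same sign, no
  within-line diet significance;
* `diet_only` — a within-line diet contrast significant, neither line
  contrast significant;
* `null` — anything else.

Classification significance defaults to adjusted-p alone (no fold or AU
floor): a candidate-filter flag would make a contrast whose true fold
sits exactly at the reporting threshold a coin flip and the labels
unstable. Callers can pass explicit flag sets (e.g. the candidate-filter
membership) to override.

## Over-representation analysis

One-sided hypergeometric upper tail `P(X ≥ k)` via `scipy.stats.hypergeom`.
The universe is the chip's annotated genes (the population the selected
list was drawn from), not the genome; categories are intersected with the
universe before testing and duplicate symbols collapse. Categories
smaller than `min_category` (default 3) after intersection are dropped.
Both raw and BH-adjusted p-values are reported, since conventions differ
on adjusting ORA tables.

## Synthetic-data generator

The generator emulates exactly the structure the cascade assumes:
per-probe log2 baselines `N(9, 1.5)` (linear baselines log-normal,
median ~512 AU), additive class effects, and i.i.d. per-chip noise
`N(0, noise_sd)` with `noise_sd = 0.2` by default. Snapshot pooling is
the mean of `pool_size` (default 3) individual log2 values — geometric-
mean pooling of RNA — chosen for its simple variance arithmetic
(`sd_pooled = noise_sd/√pool`); real pooling mixes RNA on the linear
scale, a second-order difference at these noise levels.

Default class counts on 2000 probes: 60 adipose-F-up, 30 adipose-L-up,
45 depot-specific (cyclically assigned to SC/EPI/MES), 30 all-tissue
bystanders, 40 diet-amplified, remainder null. Default effects are 2.0
log2 units (4-fold); diet-amplified probes carry (+1, +2) log2 line
effects on control and high-fat diets and no snapshot effect (they are a
quantitative-stage phenomenon). Effects are applied to the F line by
convention, mirrored for the L-up class. Class assignment is a
deterministic function of the config; placement, baselines, snapshot
noise and quantitative noise each draw from a separate substream of the
seed, so outputs are pure functions of (config, seed) and adding probes
to one stage does not perturb another.

Planted probes are placed inside QTL intervals with probability
`qtl_fraction` (default 0.3) and uniformly *outside* them otherwise, so
the configured fraction is exactly recoverable; null probes are uniform
on the genome and may fall inside QTLs by chance. A configurable share
(default 85%) of probes receives a gene identifier, creating the
total/known split the stratified summaries report.

What the generator does not emulate: probe-level hybridization physics,
saturation, background, correlated noise between tissues of one pooled
animal, probe-set redundancy per gene, and annotation error. Passing
recovery tests therefore demonstrates the statistical logic of the
cascade under its own assumptions, not robustness to array artefacts.

## Problem sizes and numerical choices

The validation suite runs the null-control at 10,000 probes × 10 seeds
and recovery at the default 2000-probe config × 10 seeds — sizes chosen
so the full suite completes in well under a minute while keeping binomial
sampling error far from the asserted margins. Monotonicity of filter
sensitivity in noise and effect size is checked on a 3×3 grid at 5 seeds
with a one-standard-error tolerance. The trigamma inversion uses Newton
iteration with the asymptotic start `x ≈ 1/y`, converging to 1e-10
relative tolerance in a handful of steps. Degenerate inputs are defined
explicitly throughout: identical groups give t = 0 and p = 1, an empty
candidate list has undefined false-discovery proportion (reported 0 with
a flag), zero-overlap categories report p = 1, and empty interval files
yield zero positional candidates rather than errors.

## Known limitations

* The snapshot stage inherits the design's confounds: pooled single
  chips cannot separate biological variance from line effects, so its
  lists are enrichment heuristics, not inference.
* The moderated-t stage assumes approximate log-normality and equal
  group variances per probe; it fits a single prior for all probes.
* ORA treats genes as exchangeable and ignores inter-gene correlation,
  as the plain hypergeometric model always does.
* The pipeline consumes normalized matrices only; upstream normalization
  choices (and batch structure) are out of scope.
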