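# Methods

## The assay and its decision problem

Competitive allele-specific TaqMan qPCR detects a point mutation with two
reactions per sample: a *mutant-allele assay*, in which an allele-specific
primer amplifies the mutant sequence while an MGB-blocker oligonucleotide
suppresses amplification of wild-type template, and a *gene-reference assay*
amplifying a region of the same gene outside the mutation.  The quantity of
interest is

    dCt = Ct(mutant assay) − Ct(reference assay),

the number of extra cycles the mutant assay needs to cross the fluorescence
threshold.  With perfect doubling each two-fold deficit of mutant template
costs one cycle, so dCt falls with the mutant allele fraction (MAF)
approximately as `log2(1/MAF)` plus a fixed assay offset.  Mutation-negative
samples still produce a late mutant-assay signal because blocker suppression
is imperfect, which puts a deep floor (many cycles) under their dCt; the
classification problem is choosing a cut-off between the mutant-bearing and
breakthrough regimes.

`castkit` stores dCt in the mutant-minus-reference convention throughout
(small dCt = abundant mutant template).  Published replicate tables sometimes
print the negated difference; the I/O layer normalizes this with an explicit
dialect flag (`negated_delta_ct`) rather than guessing the convention from
the data.

## Interpretation rules (`calling_engine`)

The rule constants live in `RuleSet`, defaulting to the validated
FFPE-tissue thresholds: reference assay Ct window `[18, 30]`, mutant assay
evaluable through Ct 37, detection cut-off `dCt < 8.1`, confirmation band
`[7, 8.1)` (detected, but repeated in duplicate before sign-off), IPC and NTC
bounds at 30 cycles.  Rules are evaluated in a fixed order per sample:
internal-positive-control failure, reference window (too much / too little
input DNA), then the dCt decision.  A failing no-template control (signal
before cycle 30 in either assay) voids the entire plate.

Boundary conventions, which the printed open ranges of such decision tables
leave unstated, are fixed as: reference window closed at both ends; mutant
bound inclusive (`Ct ≤ 37` routes toward a call, strictly beyond it toward
undetermined); detection strict (`dCt < 8.1`); confirmation band half-open
`[7, 8.1)`; NTC fails strictly below 30.  All are `RuleSet` parameters, so a
laboratory re-deriving its own thresholds is not bound by these choices.

Two degenerate corners need a convention:

* **No mutant-assay signal.**  Treated as unambiguously negative — unless the
  reference Ct is so late (`ct_ref > mut_ct_max − delta_ct_detect`, 28.9 with
  defaults) that even a mutant Ct just beyond the evaluable bound would still
  fall under the detection cut-off; then the sample is *undetermined* and
  repeated.  This is the only region where the printed "mutant Ct > 37, dCt
  < 8.1 → undetermined" row is geometrically reachable.
* **Repeat resolution.**  A confirmation run is two further replicate pairs.
  The final call is *mutation detected* only when **every** duplicate
  re-detects (the AND rule — the conservative choice when the assay's stated
  goal is zero false positives); the reported dCt of a confirmed call is the
  mean over the duplicates.  Duplicates with no evaluable signal escalate to
  assay failure; a persistent undetermined is reported after one repeat
  round rather than looped.

## Validation statistics (`validation_stats`)

* **Replicate summaries** use the sample (n−1) standard deviation and exclude
  censored runs (no mutant signal) rather than imputing them; the bundled
  replicate table's printed means/SDs are reproducible only under exclusion.
* **Cut-off derivation** returns `min |dCt|` over wild-type observations
  minus a guard margin: the largest threshold with zero observed wild-type
  positives.
* **Limit of blank** defaults to the parametric form `mean + z(0.95)·SD`
  (z = 1.645, one-sided) over a blank-specimen MAF panel; a nonparametric
  95th-percentile estimator (linear interpolation, n ≥ 20) is offered because
  small panels do not identify which form a given published LoB used.
* **Concordance** reports OPA/PPA/NPA with method A fixed as the comparator
  (recorded in the output metadata).
* **MAF regression** is ordinary least squares of method B on method A with
  R² the squared Pearson correlation.  For tables where the comparator was
  measured once per level and the evaluated method in triplicate, each
  replicate is paired with its level's comparator value, *including the blank
  level* — this replicate-to-level pairing with the blank is the convention
  that reproduces the published cross-method R² (0.965 on the bundled
  table; dropping the blank lowers it visibly), and it is switchable
  (`include_blank=False`).  Deming or Passing–Bablok regression is noted as
  future work; the slope's t-based p-value is reported but not a contract.

## Reference-standard design (`standards_design`)

To hit target MAF `m` by blending a mutant cell line of allelic fraction `f`
(0.5 for a heterozygous line) into wild-type DNA, a fraction `g = m/f` of
genomes must come from the line.  Masses use 3.3 pg per counted genomic
equivalent; whether counted "copies" are haploid locus copies or diploid
genomes is an explicit `copies_unit` switch that changes reported allele
counts only — blend fractions and masses are invariant, so both readings of
an ambiguous copies specification yield the same recipe.  Plasma spike-ins
additionally correct for wild-type locus copies already in the carrier
plasma: each level's admixture MAF is inflated by `target_total / spike` so
the final plasma MAF lands on the requested level.  The background
concentration must be supplied (default 0 with a logged warning).  The
~170 bp fragment size of ctDNA-mimicking standards is carried as metadata
and enters no arithmetic.  Every recipe and plan carries a forward
round-trip check (`achieved_maf`, `achieved_level`) that reproduces its
targets to 1e-12 relative error.

## Synthetic measurements (`synthetic_data`)

The qPCR generator is a log-linear idealization:
`Ct = intercept − log(copies)/log(1+E) + ε`, with `E` the per-cycle
efficiency (default 1.0), mutant template Poisson-distributed around
`MAF × copies`, wild-type breakthrough `λ` adding `λ·(copies − m)` to the
mutant reaction, Gaussian per-reaction noise, and censoring to "no signal"
beyond 40 cycles.  Defaults were calibrated once against the bundled
replicate table and then frozen:

| parameter | default | rationale |
|---|---|---|
| `assay_offset_delta` | 3.5 cycles | dCt ≈ 4.5 on 50% MAF material |
| `wt_breakthrough` | 6.3e-5 | blank dCt floor `log2(1/λ)+δ ≈ 17.45`, the deep-negative blank magnitude at high input |
| `ct_noise_sd_base` | 0.17 cycles/reaction | dCt is a two-reaction difference, SD = base·√2 ≈ 0.24 (high-quality dispersion) |
| `ffpe_noise_multiplier` | 2.1 | FFPE dCt SD ≈ 0.50 |
| `no_signal_ct` | 40 cycles | run length; produces censored entries |
| reaction load | 12,000 locus copies | 20 ng at 3.3 pg per haploid equivalent |

The five pre-amplification cycles of the real protocol shift both assays
equally and are absorbed into the intercepts.  When the noise SD is zero the
generator also uses expected (non-Poisson) template counts, making the
closed form `dCt = log2(1/MAF) + δ` exact — the deterministic limit used in
tests.  All randomness flows through one explicit `numpy.random.Generator`;
there is no global RNG state.

The digital-PCR generator converts each loaded molecule to mutant with
probability `MAF + (1−MAF)·error_rate`; `error_rate = 3.5e-5` emulates the
G>A-like polymerase-error floor (blank readings near 0.003–0.004%).  The
default load is 120,000 molecules (2 mL of plasma at 6e4 copies/mL).
Partition count is carried for completeness but does not enter the MAF
arithmetic, whose expectation the per-molecule model fixes exactly.

**What the generators do not emulate.**  Real FFPE dropout comes from
fragmentation and deamination damage, not just noise: the generator's
censoring reproduces missing entries only at very low template, not the
level-dependent dropout pattern of real FFPE standards, and it does not
attempt the non-monotone level means such tables sometimes show.  Blank
digital-PCR panels here vary only by binomial counting noise; real donor
panels add inter-donor variance, so a simulated 20-donor LoB (~0.006%)
sits below a published donor-panel LoB (~0.0098%).  Passing tests on
synthetic cohorts therefore demonstrates correctness of the calling and
statistics machinery under the stated measurement model, not clinical
performance of any assay.

## Problem sizes and numerical choices

Truth-table equivalence is checked on a ~9,000-point grid (reference Ct
10–40 and mutant Ct 10–45 in 0.5-cycle steps, plus absent values and both
IPC states).  Cohort-recovery checks use 50 seeded cohorts of n = 195 at
3.1% prevalence with spiked MAFs ≥ 10%; recovery of every spiked mutant with
zero false positives is the expected behaviour, with a residual ~2 in 10⁴
chance per cohort of a >2.5σ dCt outlier crossing the 8.1 cut-off near
MAF 10% — an honest property of the noise model, reported rather than
suppressed when it occurs.  Monte-Carlo LoB checks use 10⁴ blanks.  Ties and
boundaries: Ct values exactly on a bound follow the closed/strict conventions
listed above; quantiles use linear interpolation; comparisons to printed
two-decimal values use half-a-unit-in-the-last-place tolerance.
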