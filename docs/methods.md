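# Methods

This note records the statistical model behind `xcifish`, its
assumptions, the defaults that matter, and the design choices made
where more than one reasonable construction existed.

## Scoring model

The unit of observation is the nucleus.  For each gene (TLR7, TLR8) a
cell carries a focus count 0–2 — one per transcribing allele at harvest
time — and attribution flags tying at least one focus to the active X
(Xa) or to an inactive X (Xi).  Attribution relies on a pooled probe
for three non-escaping genes that labels the Xa: Xa co-localization
therefore requires a detected marker, and a *single* focus can only be
called Xi when it is seen separate from a patent Xa (bi-allelic cells
are Xi-attributable regardless, since the second focus itself implies
an Xi source).  XY cells carry one X: focus counts are capped at 1 and
Xi flags are forbidden.  These rules are enforced at record
construction, so no invalid cell enters any computation.

Three scoring regimes produce per-donor 2×2 tables of TLR8 × TLR7
positivity:

- `any_x`: all cells; positive = any focus;
- `xa_only`: cells with a detected Xa marker; positive = Xa-attributed
  focus;
- `xi_only`: all cells of the donor; positive = Xi-attributed focus.
  Keeping double-negative cells in the Xi denominator mirrors the 2×2
  layout used for Xi count tables; Xi-restricted analyses are sparse
  and chiefly served by the Monte Carlo χ² machinery below.

Escape for a gene is tallied per donor as cells with bi-allelic foci
plus cells with a lone Xi-attributed focus, divided by cells positive
for the gene.  Snapshot detection of transcriptional bursts means all
these frequencies are lower bounds on the fraction of
transcription-competent alleles; nothing in the package corrects for
burst kinetics.

## Association statistics

From a table (a, b, c, d) with N = a+b+c+d:

- Yule's Q = (ad − bc)/(ad + bc), undefined when ad + bc = 0;
- obs/exp = aN/((a+b)(a+c)), undefined on a zero margin;
- expected table under independence = margin products / N.

Undefined values propagate as explicit `None` with a reason code —
sparse Xi tables make them routine — and are never coerced to zero.  No
continuity correction is applied, matching the definitional formulas.
The two statistics satisfy sign(Q) = sign(obs/exp − 1) wherever both
are defined (both share the sign of ad − bc); the test suite verifies
this identity exhaustively over all ~1,800 tables with N ≤ 12.

## Confidence distributions

A CD is stored as a monotone cumulative-confidence curve on a sorted
parameter grid.

**Binomial (proportions).**  The exact mid-p CD
H(p) = P(X > x; n, p) + ½ P(X = x; n, p) on a 2,001-point grid over
[0, 1].  The mid-p form is the standard CD for a binomial proportion;
its median is the point estimate and equal-tail quantile pairs are the
intervals.  At x = 0 (or x = n) the curve starts at ½ on the boundary —
a property of the mid-p construction, not a defect.  Interval coverage
is checked by simulation (93–97% at n = 50, p = 0.2).

**Bootstrap (Q, obs/exp).**  The resampling unit is the cell within a
donor: each of R replications draws N cells from the four-category
multinomial given by the observed table, and the CD is the empirical
distribution of the replicated statistic.  Defaults: R = 10,000, with
50,000 available for final reporting.  Replicates on which the
statistic is undefined are redrawn so the nominal R is preserved; if
degenerate draws exceed 10% of R the table is declared too sparse and
the donor is reported not-testable rather than silently imputed.
Seeding is explicit and every CD is bit-reproducible.

**Quantiles and tail probabilities** are computed by monotone
interpolation on the curve (flat stretches of an empirical CD collapse
to their left edge, the lower-quantile convention).  Normal summary
CDs are tabulated over mean ± 8 SE, so two-sided p-values are
representable down to ~10⁻¹⁵ before clipping to 0.

## Random-effects combination

Each donor CD is reduced to its median m_i and an effective standard
error s_i = (95% interval width)/3.92.  DerSimonian–Laird:

    tau² = max(0, (Q_het − (k−1)) / (Σv_i − Σv_i²/Σv_i)),  v_i = 1/s_i²

with weights w_i = 1/(s_i² + tau²); the summary CD is normal with mean
Σw_i m_i/Σw_i and SE (Σw_i)^(−1/2).  The fixed-effects model sets
tau² = 0.  This normal-approximation combination is one concrete,
standard member of the CD-combining family; the model name is written
into every summary.  Degenerate donor CDs (zero-width intervals, e.g.
from a saturated proportion on small n) have s_i floored at half the
smallest nonzero s_i in the group so they cannot carry infinite weight.

obs/exp is combined on the log scale (positive support, asymmetric
intervals) and back-transformed; donor quantiles that hit 0 under the
log map are floored at half the CD's smallest positive grid value.  A
natural-scale switch exists for sensitivity checks.  Group "means" are
CD medians throughout.

**Tests.**  Null divergence: p = min(1, 2·min(H(null), 1 − H(null)))
on the group summary CD, with null Q = 0 and obs/exp = 1.  Between
groups: each group's mean is evaluated under the other group's summary
CD, and p = min(1, 2·max of the two one-tailed values) — symmetric by
construction.  The ×2 doubling can exceed 1, hence the cap.  No
multiple-testing correction is applied anywhere; reports label
p-values as unadjusted.

## Monte Carlo χ² tests

Pearson's statistic with expected counts from margin products; zero
margins make a table untestable and are reported as such.  The null
distribution is simulated by Patefield's algorithm (via
`scipy.stats.random_table`), i.e. conditioning on both margins — the
convention of R's `chisq.test(simulate.p.value=TRUE)` — with the
add-one estimator p = (1 + #{χ²_rep ≥ χ²_obs})/(R + 1), which is
strictly positive and valid.  The default R = 10⁶ matches final
reporting practice; the test suite uses 10³–10⁴.  The Xa-vs-Xi
comparison builds, per XX/XXY donor, the 3×2 table of
TLR7⁺TLR8⁺ / TLR7⁻TLR8⁺ / TLR7⁺TLR8⁻ counts on the Xa versus the Xi
(double negatives carry no chromosome-attributable signal and are
excluded by construction).

A note on oracles: at moderate N the exact margin-conditional
(hypergeometric) null differs from the asymptotic χ² tail by more than
Monte Carlo error — discreteness, not a bug — so the suite checks the
MC p against full hypergeometric enumeration on a 2×2, and against the
asymptotic tail only where the approximation is tight.

## Synthetic-data generator

The generator emulates exactly the structure the statistics assume,
with known ground truth:

- **Detection.**  Each Xa allele of gene g yields a focus with
  probability p_g; each Xi allele with escape probability e_g (0 for
  XY).  This Bernoulli snapshot is the minimal abstraction of bursty
  transcription; no on/off kinetics are modeled.
- **In-cis coupling.**  The two genes on one chromosome are coupled by
  a Plackett (constant odds ratio ψ) joint: p₁₁ is the admissible root
  of (ψ−1)p₁₁² − [1+(p₁+p₂)(ψ−1)]p₁₁ + ψp₁p₂ = 0, which always lies in
  the Fréchet bounds.  Yule's Q is a monotone transform of ψ, but the
  ground-truth Q of any derived 2×2 classification is computed
  numerically from the joint probabilities, never assumed equal to
  (ψ−1)/(ψ+1).
- **Attribution.**  The Xa marker is detected with probability
  m_xa = 0.35 (the observed average rate); focus flags are derived to
  satisfy every scoring invariant, so simulated data are valid by
  construction.
- **Heterogeneity.**  Each donor's probabilities are drawn from
  Beta(κp, κ(1−p)) around the group value — mean-preserving, always in
  range — with concentration κ = 50 by default (SD ≈ 0.07 at p = 0.5),
  producing donor spreads comparable to observed forests.

The `paper_like` preset (6 XX, 7 XY, 5 XXY monocyte donors, 300 cells
each) fixes ψ_xa = 4 in XX/XXY and ψ_xa = 0.3 in XY (cell-level Q near
±0.5), ψ_xi = 1, Xa positivities 0.30–0.55 and escape probabilities
0.06–0.10.  These values were calibrated once to the reported
magnitudes of the phenomena being modeled and are treated as fixed
study conditions, not tuning knobs.  What passing tests on these data
show is that the estimators recover known ground truth under the
model's own assumptions; they cannot show robustness to features the
generator omits — probe efficiency differences between genes, scoring
error, field-selection effects, XY/XXY mosaicism, or genuine burst
kinetics.

## Pipeline and reproducibility

The pipeline analyzes each (cell type × stratum × statistic × group)
cell independently and emits every requested combination exactly once,
either as a summary or as an explicit not-testable marker.  All
randomness derives from one run seed: per-stage substreams are spawned
with `SeedSequence(seed, spawn_key=crc32(stage, cell_type, stratum,
statistic, donor))`, recorded in the report, and independent of
iteration order — reruns are byte-identical.  Problem sizes in the
shipped tests and the acceptance script (300 cells/donor, 10³–10⁴
bootstrap replications in simulation loops, 500 null cohorts) were
chosen to give stable Monte Carlo estimates at interactive runtimes;
final-reporting defaults (10⁴ bootstrap, 10⁶ χ² replications) are used
where a single run is involved.

## Known limitations

- The CD combination is the normal-approximation/DL instance of the
  CD-combining family; exact-CD pooling variants (and BCa or
  studentized bootstraps) are out of scope.
- Per-donor bootstrap CDs of Q are unstable on very sparse Xi tables
  (expected double-positive counts below ~1 make Q estimates pile near
  ±1); the package reports these donors as not-testable, and the
  group-pooled Monte Carlo χ² path is the appropriate Xi analysis.
- DL tau² is noisy at k ≤ 6 donors; the type-I calibration test bounds
  the practical consequence (3–8% at nominal 5%) under the generator's
  conditions.
- Escape percentages inherit the snapshot bias of focus detection and
  are underestimates of transcription competence by construction.
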