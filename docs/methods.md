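# Methods

`m6akit` re-implements, at desk scale, the computational core of a paired
tumor/paratumor (or hypoxia/normoxia) m6A epitranscriptome analysis:
MeRIP-seq-style peak detection and differential methylation, joint
methylation x expression "quadrant" classification, a two-list
fold-change candidate screen, hypoxia-signature gene-set enrichment, RNA
decay kinetics, and standard-curve nucleoside quantification. Because the
original sequencing cohorts are not required, every stage is exercised on
a ground-truthed synthetic cohort whose generator is itself first-class,
tested code. This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic validation does
and does not demonstrate.

## The synthetic cohort

Each simulated transcript has a 5'UTR/CDS/3'UTR structure with segment
lengths drawn around configurable means (defaults 200/1200/800 nt,
typical of human mRNAs). A configurable fraction of transcripts (default
0.30) carries one contiguous m6A peak, two windows (100 nt) wide by
default, whose midpoint is placed by segment weights (default
0.10/0.35/0.55) and uniformly within the chosen segment — reproducing the
3'UTR/CDS placement bias of m6A without modelling sequence motifs. Half
of the methylated transcripts (default) are differential; their joint
(methylation, expression) direction is drawn from the quadrant mixture,
default (0.70, 0.10, 0.10, 0.10) over hyper-up/hyper-down/hypo-up/
hypo-down, matching the hyper-up-dominated landscape the pipeline is
meant to recover. The cohort is paired: 8 patients by default, each
contributing a tumor-like (condition B) and a normal-like (condition A)
sample that share a patient-level size factor.

### Count model

Window counts are negative binomial with mean `mu` and overdispersion `d`
(variance `mu + d mu^2`, default `d = 0.05`), realised hierarchically: a
gamma abundance factor with mean 1 and variance `d` is drawn per
transcript x sample and **shared by that sample's paired IP and input
fractions**, and reads are then Poisson-sampled per window. The factor
represents the transcript's abundance in that RNA sample — the IP aliquot
is taken from the same pool as the input aliquot, so the two fractions
see the same abundance. Conditionally on the factors, read sampling is
Poisson, which is exactly the sampling model under which the downstream
exact tests are calibrated; marginally every window count is still
NB(mean, `d`). Modelling the overdispersion as independent per-window,
per-fraction noise instead would make the exact tests anticonservative by
construction, which is neither how paired IP/input libraries behave nor a
property the pipeline claims to handle (see Limitations).

Input rates track expression only: transcript abundance (lognormal,
sigma 0.5, around `seq_depth` = 300 expected reads per transcript),
window length share, patient size factor (lognormal, sigma 0.15), and the
planted expression shift (x / divided by `expr_fc` = 2 in condition B for
"up"/"down" genes). IP rates are the input rates times `peak_enrichment`
(default 4) inside the planted peak, and additionally times `diff_shift`
(default 2.5) in the condition where the transcript gains methylation
(B for "gain", A for "loss"). Gene-level expression matrices use the same
NB model, one count per gene and sample. A second, knockdown-like
contrast plants a `kd_fc` = 4-fold increase on most (90%) of the hyper-up
genes plus a 2% background — emulating a reader knockdown that stabilises
the transcripts it would otherwise degrade — and is consumed only by the
screen. When `embed_hypoxia_signature` is on (default), 14 gene ids are
renamed to the hypoxia metagene symbols, preferring planted "up" genes,
so the simulated cohort carries a positive enrichment signal.

Choosing `expr_fc = 2` mirrors the 2-fold screen threshold; `diff_shift =
2.5` and `seq_depth = 300` give per-patient exact tests moderate power —
enough that per-patient quadrant calls are plentiful, while detection
remains imperfect, as in real cohorts. All draws flow through one
`numpy.random.Generator`, so a fixed seed gives bit-identical tables.

## Peak detection and differential methylation

All coordinates are transcript-space, 0-based, half-open (including BED
output). Windows (default 50 nt) tile each transcript end-to-end; a
transcript shorter than one window gets a single covering window.

*Window enrichment.* Counts are pooled (summed) over the supplied
samples. Each window is tested one-sided against its transcript's totals
via the upper hypergeometric tail of `[ip, total_ip - ip; input,
total_input - input]` — does the window hold a larger share of the IP
pool than of the input pool? Odds ratios are pseudocounted (alpha = 1 on
all four cells) so zero cells never divide by zero.

*Peak merging.* Windows with p < 0.05 are merged per transcript into
maximal runs allowing up to `max_gap` = 1 intervening non-significant
window; runs with fewer than `min_run` = 2 significant windows are
dropped. The peak p-value is the minimum window p; its enrichment is the
pooled odds ratio over the merged span. Merged peaks never overlap.

*Differential methylation.* Peaks are called on the pooled conditions,
then each peak is tested between conditions: IP/input counts summed over
the peak interval per condition, two-sided exact (Fisher) p for
`[IP_B, input_B; IP_A, input_A]` (computed by direct enumeration of the
conditional hypergeometric, with a 1e-7 relative tie guard), effect size
`log2(((IP_B+1)/(input_B+1)) / ((IP_A+1)/(input_A+1)))`, and
Benjamini-Hochberg q-values across peaks (delegated to statsmodels). A
direction (hyper/hypo) is assigned where p < 0.05 and q < 0.05, the
dual threshold used for highlighting differential peaks. A peak with zero
counts in both conditions gets p = 1 and no direction. Segment fractions
assign each peak by its integer midpoint `floor((start+end)/2)` to the
half-open segment intervals, so a midpoint exactly on the CDS/3'UTR
boundary counts as 3'UTR.

## Quadrants, high-frequency genes, screen

Expression changes are CPM-normalised per sample; the per-gene statistic
is `log2((meanCPM_B + 0.5) / (meanCPM_A + 0.5))`. For quadrant calls the
direction threshold is 0 (pure sign) — the quadrant landscape bins all
altered m6A-mRNAs — while the screen uses the stricter 2-fold rule. A
shrinkage DE model is deliberately not used: quadrant assignment needs a
direction, not a calibrated DE p-value.

The cohort workflow calls peaks once on all samples pooled, then tests
each patient's pair separately for differential methylation and
expression. A gene with several directional peaks takes the peak with the
smallest q (ties: largest |log2 fold change|, then leftmost start) — a
deterministic rule favouring the strongest evidence, needed because the
behaviour of a transcript carrying both hyper and hypo peaks is otherwise
undefined. Per-patient quadrant percentages always sum to 100; the cohort
average is the unweighted mean over patients with at least one call
(patients with none are excluded and logged), and the pooled percentage
over all calls is reported alongside since the two conventions can
differ. High-frequency hyper-up genes are those called hyper-up in at
least `min_share` = 3 patients, sorted by descending support then name.
The screen keeps genes with fold change strictly above the threshold
(default 2) in each list — list B additionally requires the
hypermethylation flag — and intersects them.

## Gene-set enrichment

The built-in gene set is the 14-gene hypoxia metagene signature (ALDOA,
MIF, TUBB6, P4HA1, SLC2A1, PGAM1, ENO1, LDHA, CDKN3, TPI1, NDRG1, VEGFA,
ACOT7, ADM). The statistic is the classic weighted Kolmogorov-Smirnov
running sum with weight p = 1: hits add `|score|^p / sum_set |score|^p`,
misses subtract `1/(N - N_hits)`, and the enrichment score is the
running-sum value of largest magnitude (first occurrence on ties; ties in
scores keep input order). ES is invariant to positive rescaling of the
scores and reaches exactly 1 for a set concentrated at the very top.

Significance uses a gene-label permutation null — size-matched random
sets drawn from the ranked list — because the package consumes a single
ranked list; phenotype permutation would need per-sample matrices and is
unsupported. With default 1000 permutations and a mandatory seed:
`NES = ES / mean(|null ES|)` over same-sign nulls (sign preserved), and
`p = (1 + #{same-sign nulls >= |ES|}) / (1 + #same-sign nulls)`, which is
never zero. If no null shares the sign, p is floored at
`1/(1 + n_permutations)` and NES reported as NaN with a warning. Rankings
built from count tables use the same CPM + 0.5 log2 fold change as the
expression module.

## Decay kinetics and nucleoside quantification

Decay follows the first-order shutoff model `N_t/N_0 = exp(-k t)` with
time in hours. Series are renormalised to `N_0 = 1`, so the fit is least
squares of `ln N_t` on `t` with the intercept fixed at zero — the closed
form `k = -sum(t ln N)/sum(t^2)` — matching the printed model exactly
rather than introducing a nonlinear fit with an extra free scale. R^2 is
computed on the log scale against the mean of `ln N`; a series fitted
with k <= 0 is returned flagged (`decaying=False`, infinite half-life)
rather than raising, since stabilised transcripts do occur. Half-life is
`t1/2 = ln2 / k`, computed from the fitted k and nowhere else. The
simulated series apply multiplicative mean-zero noise of coefficient of
variation `cv` at t > 0 only; the t = 0 point is the normalisation
reference and stays exactly 1.

Calibration curves are ordinary least squares with a free intercept
(instrument baselines are nonzero) per nucleoside channel; channels are
labelled by their ion mass transitions, `m6A:282>150` and `A:268>136`,
and validated. Sample responses convert through the fitted curve; a
calibrated concentration <= 0 is an error naming the offending channel,
never a negative ratio. The simulated instrument noise is additive on the
response (default SD 0.002 response units in the pipeline demo); because
the m6A channel operates near the bottom of the curve, absolute noise
translates into a much larger relative error on m6A than on A — visible
in the demo output and intentional. qPCR enrichment is
`percent_input = 100 * 2^((Ct_input - log2(dilution)) - Ct_IP)` with a
configurable input dilution factor (default 1, as the source protocol
does not state its input fraction and no housekeeping correction is
applied); fold enrichment is the ratio of percent-input values.

## Pipeline, seeding, determinism

The `run` pipeline executes simulate -> callpeaks -> diffpeaks ->
quadrants -> screen -> gsea -> decay -> msquant from one YAML config.
Inputs are validated before anything runs; a stage failure is recorded in
the JSON manifest and skips downstream stages. One global seed expands
into per-stage seeds by a fixed counter (`seed + 1000 * stage_index`,
mod 2^31), so any stage rerun in isolation reproduces its outputs. TSVs
have fixed column orders; JSON is written with sorted keys and floats at
6 significant digits; reruns with the same seed are byte-identical.

## Validation benchmarks and problem sizes

The statistical guarantees are checked by simulation at sizes chosen to
keep the whole suite comfortably on one CPU:

- **Type-I error**: ~10,000 null windows (no methylation, 2 patients);
  the fraction of one-sided p < 0.05 sits below 0.05 because the discrete
  exact test is conservative under the hierarchical count model.
- **FDR control**: 20 cohorts of 2,000 transcripts, 4 patients, 10% of
  transcripts carrying a true 2.5-fold methylation gain, an equal
  fraction carrying a stable (null) peak; the mean false-discovery
  proportion among directional differential calls at q < 0.05 — counting
  wrong-direction calls as false — stays below 5%.
- **Quadrant recovery**: 10 cohorts of 1,000 transcripts under the
  default mixture and effect sizes; the cohort-mean hyper-up percentage
  lands within a few points of the planted 70%.
- **Oracle equivalence**: both exact tests match exhaustive
  rational-arithmetic enumeration on every 2x2 table with margins <= 12
  to 1e-12; the ES matches an independent running-sum walk on 100 random
  instances; BH matches a direct step-up computation.
- **Round trips**: noiseless decay recovers k to 1e-9 for k in
  {0.05, 0.3, 1.0, 3.0} and noisy series (cv 0.05, 6 timepoints, 100
  series) recover k with < 5% mean relative error; noiseless calibration
  inverts the planted m6A/A ratio exactly; GSEA null p-values pass a
  Kolmogorov-Smirnov uniformity check over 200 repetitions.

## Limitations

- The generator plants positional peaks only; no DRACH motifs, no
  sequence, no read-level structure. Nothing downstream consumes
  sequence, so this costs no coverage, but motif-aware callers cannot be
  compared against it.
- Overdispersion is shared between a sample's IP and input fractions.
  Real MeRIP data additionally carry IP-efficiency variation between
  libraries, which would inflate the exact tests; handling it would
  require replicate-aware NB tests (the route packages like QNB or
  exomePeak2 take) and is out of scope. Passing error-control benchmarks
  here therefore demonstrates correctness of the implementation under its
  stated model, not robustness to un-modelled IP variability.
- Transcripts map 1:1 to genes; isoform-level deconvolution is not
  attempted.
- Expression changes are CPM fold changes without variance shrinkage;
  with one pair per patient this is a directional call, not a DE test.
- The cohort-level percentages printed by the original study derive from
  deposited patient data; the synthetic cohort emulates their structure,
  so recovered percentages validate the pipeline's behaviour, not the
  biological values themselves.
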