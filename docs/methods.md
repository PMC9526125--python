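# Methods

This note documents the models, statistics and design choices behind
`cmrextract`, and what the synthetic-data experiments do and do not show.

## Task and label space

Extraction is cast as token classification. A report is subword-tokenized;
each token receives one of 22 labels: 21 CMR measurement types (left/right
ventricular volumes and their indexed variants, diameters, ejection
fractions, stroke volumes, mass and mass index, cardiac output and index,
left atrial anterior-posterior dimension, pulmonary artery and aortic root
dimensions) plus a null label (id 0) for everything else. Gold annotations
are standoff numeric spans: the characters of the value itself, not the
measurement name. Every subword piece of an annotated value carries the
span's label; a token partially overlapping a span is labeled if any
overlap exists. Span-containment labeling plus the fact that the tokenizer
never merges digits with letters makes the gold pass-through exact: running
consolidation on gold labels reproduces the gold annotations bit-for-bit
(this invariant is tested in all five numerical representations).

The schema treats the duplicated right-ventricular stroke-volume entry of
the source inventory as right ventricular ejection fraction, since RVEF is
the quantity the outcome analyses use; the inventory is otherwise taken
as-is.

## Numerical representations

Subword vocabularies fragment decimal numbers (`51.01` → `5 1 . 0 1`),
which motivates four alternative surface forms, each rewriting only maximal
numeric tokens (optionally signed digits with at most one decimal point,
delimited by non-alphanumerics) and preserving all other characters:

| mode | `51.01` becomes | notes |
|---|---|---|
| `original` | `51.01` | identity |
| `replaced_decimal` | `51\|01` | pipe keeps the number a single token |
| `consistent_digits` | `051010` | 3 integer + 3 fractional digits, point removed |
| `scientific` | `5.10100e+01` | 5 digits after the point, 2-digit exponent |
| `words` | `fifty one point zero one` | lowercase, no hyphens, digitwise decimals |

The consistent-digits format is the unique 6-character fixed layout
consistent with the worked example pair (51.01, 051010); values that do not
fit (negative, or ≥ 1000 after rounding to 3 decimals) are left
untransformed and recorded as warnings rather than silently mangled.
Scientific notation follows the printed example `5.10100e+01` (six
significant digits) rather than the five its caption suggests; the example
is taken as normative. Hyphenated ranges such as `55-60` are treated as two
independent numbers; fractions and Roman numerals pass through.

Every rewrite is logged in an offset map supporting exact two-way span
projection. A boundary that lands inside a rewritten token expands to the
whole original token — this is what lets a model that labels only part of a
transformed number still recover the full value.

## Tokenizer

A deterministic vocabulary-based subword tokenizer stands in for a
pretrained wordpiece model: whole words from the training corpus are kept
as pieces with greedy longest-match and single-character fallback (so
unseen words never become unknowns), digit runs split into single-digit
tokens with the decimal point as its own token (reproducing the
fragmentation that motivates the representations above), and the
digits-pipe-digits pattern of the replaced-decimal mode maps to a dedicated
`<num>` id, keeping those numbers intact as single tokens. Offsets are
exact; the vocabulary is sorted and therefore reproducible.

## Encoder and training

The token classifier is a pre-LayerNorm transformer encoder with a linear
head producing a distribution over the 22 labels. The bundled
`tiny_scratch` profile is 2 layers, 64 hidden units, 4 heads,
feed-forward width 128, maximum window 128 tokens, implemented in float64
NumPy with hand-written reverse-mode gradients (verified against central
finite differences in the test suite) and a plain Adam optimizer. Two
details matter at this scale:

* **Zero-initialized head.** The classification head starts at zero, so an
  untrained model outputs the uniform distribution (1/22 per label) and
  early training is stable.
* **Relative-position attention bias.** Each layer adds a learned per-head
  bias b[h, clip(j−i, ±16)] to the attention logits. With only a few
  hundred reports, absolute position embeddings alone are not enough for
  attention to discover the "look a few tokens left for the measurement
  name" pattern; the relative bias makes that pattern directly expressible
  and is the difference between converging in ~50 epochs and not
  converging at all.

Training uses token-level cross-entropy. The standard fine-tuning recipe
for pretrained encoders (learning rate 5e-5, batch size 32, 20 epochs,
decode threshold 0.5) is kept as the `TrainConfig` default; the
from-scratch miniature profile uses learning rate 2e-3, batch size 8 and up
to 60 epochs (`TrainConfig.for_profile("tiny_scratch")`) — a from-scratch
model needs larger steps and more of them than a fine-tuned one, and
smaller batches buy more optimizer steps per epoch on a small corpus.
Profiles naming pretrained weights (`pretrained:<name>`) describe the
full-scale setting and raise a clear error where no deep-learning backend
is installed.

Per-epoch evaluation supports selecting the epoch that maximizes
macro-F1. By default selection happens on a held-out fraction of the
training reports (15%); selecting on the test set is possible
(`select_on_test`) for faithful replication of protocols that do so, with
the leakage documented here rather than hidden.

Reports longer than 128 tokens are cut into windows. During training the
windows are non-overlapping and a boundary that would split an annotated
run shifts back to the end of the preceding null stretch, so no gold span
is divided (a run longer than the window errors — impossible for realistic
numbers). At inference there are no gold runs; windows are cut at exactly
128 with a 16-token overlap and overlapping positions take the first
window's scores.

## Decoding and postprocessing

Threshold decoding assigns a label when its score exceeds 0.5 — since
scores are a normalized distribution at most one label can qualify — and
abstains to null otherwise; it is the evaluation decoding. Argmax decoding
always assigns the top label (ties to the lowest index, deterministically)
and is used when extracting at scale, where abstention would silently drop
measurements.

Consolidation turns maximal same-label runs into candidates: the run's
character span is projected back onto the original text, extended over any
adjacent digits of the same numeric token the model missed (digit merging;
whitespace stops the extension), and parsed to a float. Candidates without
a parseable number are flagged `non-numeric`. When a report yields several
candidates for one label the highest mean-score candidate is emitted and
the rest are flagged `duplicate` — nothing is deleted, so candidates =
emitted + flagged always holds. Finally, values outside the measurement's
physiologic range are flagged `out-of-range`. The packaged ranges are
broad literature-typical plausibility bounds (e.g. LVEF 5–90%, LVEDV
30–500 ml) intended to catch extraction errors, not to grade clinical
normality; they are configuration and should be reviewed per deployment.

## Evaluation

Scoring is token-level: per-label precision, recall and F1 from token
counts, and macro-F1 as the unweighted mean over measurement labels (null
never included). Labels absent from both gold and predictions are excluded
from the mean by default (they carry no information about the model);
`include_missing=True` counts them as zero instead. Bootstrap confidence
intervals resample whole reports with replacement (tokens within a report
are correlated; resampling tokens would understate variance) with
percentile bounds, B=1000 by default, deterministic given a seed.
One-vs-rest ROC curves and AUCs are computed per measurement from token
scores; a label with no gold positives has undefined AUC and is reported
as missing. Learning curves draw nested subsets (smaller ⊂ larger) from
one seeded shuffle so that curve points differ only by training-set size.

## Outcome statistics

Person-time for a person starts at the imaging date and ends at the first
of outcome event, death, or last clinical encounter; the event is counted
only when it is the earliest terminator, and prevalent cases (event on or
before the imaging date) must be excluded upstream. The incidence rate is
100·k/T per 100 person-years with the exact Garwood CI

    lower = χ²(α/2, 2k) / 2T,   upper = χ²(1−α/2, 2k+2) / 2T,

equivalent to inverting the Poisson CDF (the test suite checks this against
numeric inversion); k=0 gives a lower bound of exactly 0. Rates are
compared with a pooled-variance z-statistic on events per person-time,
z = (r₁−r₂)/√(p̂(1/T₁+1/T₂)) with p̂ the pooled rate — the natural
person-time analogue of the two-sample test of proportions, and identical
to the score test for a rate difference (cross-checked against
statsmodels). Whether per-person binary outcomes or person-time rates are
the right denominator is a genuine modelling choice; the person-time form
is used because follow-up varies strongly across a retrospective cohort,
and the function is swappable.

Stratification supports empirical quartiles (inclusive quantile
definition; a value equal to a cut point goes to the lower stratum) and
named clinical thresholds: abnormal LVEF is strictly below 50%, abnormal
RVEF strictly below 45%. With multiple reports per person the earliest
report carrying the feature is used for primary analyses and the latest for
sensitivity analyses, ties broken by report id.

The cohort simulator draws stratum-specific exponential event times,
an independent exponential death time, and uniform censoring — enough to
verify estimator consistency (hazard ratios recovered within sampling
error), CI coverage (≥93% observed over 2000 draws at nominal 95%;
exact Poisson intervals are conservative) and monotonicity of rates in the
underlying hazards. It does not model covariate-dependent censoring,
competing-risk dependence, or calendar-time effects.

## Synthetic corpus: what it does and does not show

The generator emulates the documented sources of report variability:
measurement order is shuffled per report; each measurement appears under
one of ≥3 aliases (abbreviation, full phrase, mixed); units are present or
absent at random; three styles (narrative sentences, colon lists, dense
tabular lines without units) mix per corpus; values mix integers with 1-
and 2-decimal numbers drawn uniformly within the physiologic range
(an `out_of_range_rate` knob places mass just outside the bounds to
exercise the filter, default 0); reports carry 1–21 measurements
(each included with probability 0.5 by default, resampled to at least
one); and Poisson-distributed distractor numbers (dates, heart rates,
slice thickness, sequence parameters, ages) appear with expectation 2 per
report and must remain unlabeled. Generation is bit-reproducible for a
fixed (config, seed).

Passing at this scale shows the workflow is correct end to end — the
representations invert, labels align, windows are lossless, the encoder
can learn the name→value dependency from a few hundred examples, and the
statistics match their closed forms. It does not show clinical-grade
accuracy: real reports have richer vocabulary, typos, negations, section
headers and institution-specific conventions that templates do not
reproduce, and the miniature encoder has none of the linguistic knowledge a
pretrained model brings. Numbers obtained on the synthetic corpus (e.g.
macro-F1 ≈ 0.95 with 200 training reports under the default seeds) measure
the pipeline, not the clinical problem.

## Problem sizes and numerical choices

The standard experiment trains on 200 synthetic reports and evaluates on
100 held-out reports, with learning curves over 25/100/200 — sizes chosen
to mirror a realistic annotation budget (a few hundred reports is what a
single clinician can label in hours) while keeping a full run in the
low minutes on one CPU core. Float64 arithmetic, seeded NumPy generators
for every stochastic step (corpus, initialization, shuffling, bootstrap,
simulator), sorted vocabularies, and lowest-index tie-breaks make every
reported number reproducible bit-for-bit from the run manifest.

## Known limitations

* No unit conversion: values are taken as printed, so a site reporting
  diameters in cm against mm-scaled ranges needs adjusted bounds.
* One value per measurement per report is assumed; repeated measurements
  (e.g. pre/post contrast) surface only through duplicate flags.
* The physiologic filter cannot catch in-range false positives — an
  incorrect value inside the plausible band passes; careful evaluation
  on gold labels remains necessary before trusting extractions.
* The pooled z-test treats event counts as Poisson with fixed person-time;
  very small event counts warrant the exact CIs, not the z approximation.
* The interannotator-agreement statistic is a matched proportion, not a
  chance-corrected coefficient; with 21 rare labels chance agreement is
  negligible, which is why the simple proportion is the field's custom.
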