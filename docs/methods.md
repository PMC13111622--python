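# Methods

This note documents the models, conventions and design choices behind
`voicelearn`: what each stage computes, which defaults matter, what the
synthetic data does and does not emulate, and where genuinely open choices
were resolved.

## Stimulus selection

**Inputs.** Per-speaker metadata (gender, mean F0 in Hz) and per-recording
embedding vectors from any speaker-verification model (the extractor is
pluggable; only the vectors matter). All pair computations are
within-gender.

**Consolidated similarity.** For a speaker pair {i, k}, `avg_cosine` is the
mean cosine similarity over all cross-speaker recording pairs — the
file-level similarity matrix averaged per speaker pair. `delta_f0` is
|mean F0(i) − mean F0(k)| in Hz.

**Distance fusion.** Two readings are implemented because the construction
is ambiguous:

* `row_vector` (default): each speaker's feature row is
  [avg_cosine to every other same-gender speaker, delta_f0 to every other
  same-gender speaker] — i.e. the ΔF0 values appended to the consolidated
  similarity matrix as additional columns — and the pair distance is the
  Euclidean distance between the two rows. By default the columns
  referring to either member of the pair are removed first (`drop_self`),
  so the distance measures how similarly the two speakers relate to the
  rest of the group rather than being dominated by their similarity to
  each other; the toggle is exposed.
* `pair_2d`: the distance is ‖(1 − avg_cosine, delta_f0)‖ for the pair
  itself. (Cosine similarity is converted to a dissimilarity so that
  "small distance = similar" holds in both modes.)

No standardisation is applied by default ("all features weighted
equally" read literally); `scaling="zscore"` is available because cosine
(≤ 1) and Hz (tens) are incommensurate, and zero-variance columns are
mapped to zero rather than divided out. Ranks are ascending in distance
(rank 1 = most similar) with lexicographic speaker-id tie-breaking, which
keeps rankings deterministic and auditable.

**Pair extraction.** The ranked list (genders merged) is scanned greedily
from the top, accepting a pair only when both speakers are unused; accepted
pairs alternate implicit, explicit, implicit, … so both tasks receive the
same spread of pair similarities. Within a pair, the learned-vs-impostor
role is a seeded random draw (no rule is prescribed by the design), and
one learning plus one distinct test sentence are drawn per pair with no
sentence index reused in the assignment.

## Experiment designs

Each plan has two exposure-plus-recognition phases with disjoint voice
sets, in order I→E or E→I (counterbalanced across participant groups by
alternating participant index; no allocation ratio is prescribed, so 1:1
is used). Versions: simple = 4 voices per task, challenging = 10.

* **Discrimination (implicit exposure):** per voice, 4 same-speaker trials
  and 4 different-speaker trial appearances (8 trial appearances, 12
  distinct snippets). Different trials pair voices within the exposure set
  via a balanced circulant pairing (offsets 1, 2, … around the voice
  cycle), so every voice gets exactly the configured appearance count and
  never meets itself; an odd appearance total is rejected. 10 voices →
  40 same + 20 different = 60 trials.
* **Memorization (explicit exposure):** one block of 12 snippets per voice,
  block order seeded-random, fixation intervals between blocks. Total
  presentation count per voice (12) matches the discrimination phase, so
  exposure time per voice is identical across tasks.
* **Recognition:** 3 trials per identity over learned ∪ impostors,
  truth "old" iff learned, order shuffled. 4+4 identities → 24 trials;
  10+10 → 60.

With 4 voices the per-voice structure yields 24 discrimination trials, not
the 30 sometimes quoted for small designs; the per-voice counts (4 same +
4 different appearances, 12 snippets) are treated as the binding
invariants, and both counts are exposed as `DesignParams` if a different
total is needed.

All snippets are drawn from a shared per-plan pool (256 sentences per
speaker by default) that never hands out the same snippet twice — this one
mechanism enforces both "each snippet used once" and the
exposure/test snippet disjointness. Nominal timing (1.2 s snippets, 1 s
discrimination ISI, 0.5 s memorization pauses, 3 s fixation) is carried as
metadata only; playback and self-pacing are not modelled.

## Audio preparation

Snippets are cut from the midpoint of a (pre-trimmed) recording
(default 1.2 s), RMS-normalised, and band-limited-resampled (polyphase) to
8 kHz — a telephone-band rate typical of casework material. "65 dB RMS"
has no absolute meaning in a digital file, so the target is interpreted
against a configurable full-scale reference (default `reference_db=100`,
i.e. 65 dB ≙ −35 dBFS RMS); both numbers are parameters. Praat-style
amplitude smoothing is out of scope (the algorithm is unspecified);
upsampling is refused unless explicitly allowed.

## Generative behavioural model

Equal-variance Gaussian signal detection with symmetric criterion
placement — chosen because it is the exact inverse of the d′ estimator, so
analysing simulated data is a well-posed parameter-recovery exercise:

* each participant draws a latent d′ per (task, phase, trial-kind) cell
  from Normal(cell mean, cell SD); the draw doubles as the participant
  random effect, and draws are independent across phases (supported by the
  near-zero learning↔test correlations observed empirically; the true
  between/within split of the cell SDs is unknown — see Limitations);
* per trial, P("signal") = Φ(±d′/2 − c) with "signal" = "old"
  (recognition) or "different" (discrimination); same–different
  discrimination is treated as yes/no on "different";
* no trial-level overdispersion beyond the binomial; memorization exposure
  produces no responses;
* `order_effect` (default 0) shifts phase-1 latent d′; `truncate_at_zero`
  (default off) clips negative recognition draws — off because near-zero
  observed cell medians imply genuinely negative individual sensitivities.

Default cell parameters are the study's observed condition statistics:
recognition d′ means (SD) 0.472 (0.653) simple-explicit, 0.592 (0.679)
simple-implicit, 0.056 (0.379) challenging-explicit, 0.341 (0.408)
challenging-implicit; discrimination means (SD) 1.96 (0.41) simple,
2.02 (0.45) challenging; 81 simple and 51 challenging participants. All
are overridable via `GenerativeConfig` / YAML.

**Synthetic speakers.** `gen_speakers` draws a unit-norm centroid per
speaker uniformly on the D-sphere (D = 16 by default — large enough for
well-separated clusters, small enough to be fast; real speaker-verification
embeddings are larger but only cosine geometry matters here), recordings as
centroid + isotropic Gaussian jitter (spread 0.3) renormalised, and mean F0
from gender-specific Gaussians (120 ± 20 Hz male, 210 ± 25 Hz female,
floored at 50 Hz). This reproduces the single property selection needs —
within-speaker similarity exceeding between-speaker similarity with a
realistic overlap — and nothing else about speech; passing tests therefore
validate the pipeline's logic and statistics, not any claim about real
voices or a specific embedding model.

## Sensitivity estimation and diagnostics

d′ = Z(hit rate) − Z(false-alarm rate). Boundary correction default is
**log-linear** ((k+0.5)/(N+1) on every cell): over the package's working
range of trial counts (12–60 per class) and sensitivities it passes the
generative mean through the estimator nearly unbiased, whereas the 1/(2N)
rule (also implemented, `method="halfN"`) inflates estimates noticeably at
these sizes because its boundary values are extreme relative to Φ⁻¹ of
nearby interior rates. The method used is recorded with every scored
table.

Per-speaker percent correct pools correct old/new judgments over
participants per (version, speaker), in percent; speakers absent from a
log are simply absent from the table.

**Soft ceiling.** The threshold is the empirical 90th percentile of the d′
distribution (linear-interpolation percentile convention, recorded in the
output). The observed at-or-above count is tested against an expected
count with a two-cell Pearson χ² (1 df):
χ² = (o−e)²/e + ((n−o)−(n−e))²/(n−e). The expected count defaults to the
Gaussian tail mass n·P(Normal(sample mean, sample SD) ≥ threshold)
(`normal_tail`), which approximately reproduces published worked examples
whose expected counts are not 10 % of n; a `fixed_fraction` mode
(0.10 · n) is provided since the exact provenance of such expected counts
is not always stated.

## Group statistics and the mixed model

Welch's unequal-variances t (with Welch–Satterthwaite df), Spearman rank
correlation with a Shapiro–Wilk normality gate reported alongside, and
Bonferroni adjustment over a family size that is always an explicit
argument, never inferred.

The recognition model `dprime ~ awareness + load + order +
(1|participant)` is fitted by ML through statsmodels' MixedLM. Factor
coding is explicit 0/1 indicators with the contrast direction printed in
every result (awareness: implicit − explicit; load: simple − challenging;
order: phase 1 − phase 2) — published tables sometimes label levels in a
way that conflicts with the stated direction of the effect, so the package
never leaves sign conventions implicit. Inference is Wald
(normal-approximation); the backend does not provide Satterthwaite df, and
the inference method is recorded in `FitResult.p_method` rather than
silently assumed. Boundary/singular fits (zero participant variance) are
flagged and returned, not dropped. With zero random-effect variance the
fit coincides with ordinary least squares (tested to 1e-6).

`recovery_harness` runs simulate → score → fit over many seeds and reports
per-term mean, empirical SD and per-seed estimates; fit failures are
counted, not fatal.

## Numerical conventions and degenerate inputs

Seeded `numpy.random.Generator` streams everywhere; a master seed fully
determines every stochastic output, and identical seeds reproduce outputs
byte for byte. Ties in ranking break lexicographically. Zero-variance
feature columns contribute nothing under z-scoring. All-zero audio, empty
logs, boundary rates without correction, constant correlation inputs,
non-varying model factors, overlapping learned/impostor sets and
insufficient snippet pools raise informative errors rather than degrading
silently.

## Problem sizes

The packaged defaults mirror the study's scale: 81 + 51 participants,
24/60-trial recognition tests, 24/60-trial discrimination blocks. The
recovery harness and the acceptance script average over 20–24 simulation
seeds; the acceptance test suite uses 120 replicates for the
coefficient-recovery checks so that the Monte-Carlo error of the summary
fractions is small relative to their thresholds.

## Limitations

* The split of the condition SDs into participant-level and
  trial/phase-level variance is unknown; the default attributes all of it
  to the per-phase latent draw. Printed condition SDs are SDs of
  *estimated* d′ (they already contain trial noise), so treating them as
  latent SDs slightly over-disperses simulated estimates; contrasts of
  means are unaffected.
* The simulator models no learning dynamics within a phase, no reaction
  times, no lapses or attention drift, and no item (speaker) random
  effects beyond what selection balances by design.
* Synthetic embeddings are isotropic spherical clusters; real embedding
  spaces are anisotropic and correlate with F0, so selection outcomes on
  synthetic features say nothing about which real voices would be chosen.
* The audio stage covers midpoint extraction, RMS level and resampling
  only; perceptual smoothing and speech/non-speech trimming are the
  caller's responsibility.
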