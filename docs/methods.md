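# Methods

`vocalearn` models how an infant can learn to pronounce first words without
ever judging the acoustic similarity between his own speech and an adult's.
The learner (a) discovers sound-producing motor patterns by intrinsically
rewarded exploration of an articulatory synthesizer, (b) keeps the patterns a
caregiver responds to and associates each with the caregiver's spoken
response (typically a *reformulation* into a well-formed native speech
sound), and (c) imitates words by recognizing their syllable-sized parts
among the stored caregiver responses and recalling the associated motor
patterns. All similarity judgments between infant and adult speech are made
by the caregiver; the learner only ever compares caregiver speech with
caregiver speech, so no speaker-normalization ability is assumed.

## Articulatory synthesis (`synth`)

Ten control parameters drive the vocal apparatus: seven articulatory (jaw,
tongue dorsum position and shape, tongue apex, lip aperture, lip protrusion,
larynx height), plus glottal area (P8), fundamental frequency (P9) and
velo-pharyngeal port opening (P10). All are dimensionless in [−1, 1].

The articulatory-to-area mapping is a linear-component model: each parameter
contributes a Gaussian deviation profile along the normalized tract axis to
a neutral area function over 20 sections, clipped at zero (`data/
articulatory_model.json`). The coefficients are this package's own
construction — chosen so that the neutral posture is an open tract, extreme
lip aperture closes the tract at the lips, the apex parameter can produce
alveolar closures and the dorsum-shape parameter velar ones — and are *not*
fitted to articulometry; they are shipped as data so measured coefficients
can be swapped in.

Acoustics use a Kelly–Lochbaum reflection line: per frame the area function
is resampled onto a lattice whose section count follows the physical tract
length at the sampling rate (so the default `tract_scale = 0.8`, which
shrinks the adult-female dimensions toward an infant's, automatically raises
all resonances), converted by the step-up recursion to an all-pole filter,
and excited by an LF-style glottal pulse train (derivative of a raised-
cosine flow pulse, open quotient fixed at 0.6). Mild pole damping (0.995
bandwidth expansion) gives realistic formant bandwidths; lip radiation is a
first difference. Frication is band-passed noise (2.5 kHz–0.42·fs) gated by
a supraglottal constriction narrower than `constriction_area_cm2` (0.15 cm²)
with an open glottis — an anterior-cavity approximation injected after the
tract filter. A fully occluded oral tract radiates almost nothing unless the
nasal port is open, in which case a fixed ~300 Hz murmur resonator runs
instead; a closure release adds a short decaying noise burst. Touch is
reported per frame wherever a section area reaches exactly zero.

Defaults: 24 kHz output, 5 ms control frames, F0 midrange 400 Hz with a
linear P9 mapping `f0 = 400·(1 + 0.5·P9)`, phonation amplitude peaking at
slight glottal adduction (P8 = −0.3) and vanishing at full closure or a wide
open glottis. The frame period, section count, noise thresholds and LF shape
are configuration values because no canonical values exist for them.

## Motor patterns and dynamics (`motor`)

A motor pattern holds one to three sub-patterns; each sub-pattern is a
10-element target vector, 10 start times, 10 hold durations and one speed
scaling — 31 scalars. Articulators move toward active targets along the
critically damped second-order step response
x(t) = x₁ + (x₀ − x₁)(1 + ωt)e^(−ωt), the fastest approach without
overshoot. The base rate constant is ω = 40 s⁻¹ (a typical articulation
speed; configurable, not a measured constant), switched to 160 s⁻¹ for the
frames following a detected closure release to produce realistic plosive
transitions. Parameters hold their previous value until their start time;
the initial state is the neutral resting posture (all zeros). The closed
form is verified in the test suite against an independent `solve_ivp`
integration of the underlying ODE (relative error < 10⁻³).

## Auditory front-end (`auditory`)

The spectrogram is gammatone-like: an STFT weighted by 4th-order gammatone
power responses at 64 ERB-spaced center frequencies (80 Hz to 0.45·fs),
100 frames/s, square-root compressed (so doubling the waveform amplitude
doubles every time–frequency value). F0 is frame-wise autocorrelation with
parabolic peak interpolation and a normalized-peak voicing threshold of 0.5.
Salience is `w_low·P_low + w_high·P_high + w_touch·mean(touch)` over mean
band powers split at 2.5 kHz (vocalic versus fricative energy). Activity
detection thresholds 10 ms short-term power against a noise floor
(estimated, when not given, as the median power of the leading 200 ms),
merging gaps shorter than `min_gap` and dropping segments shorter than
`min_len`. The DTW distance uses the symmetric step pattern
(1,0),(0,1),(1,1) over a Euclidean frame metric and divides the accumulated
cost by the optimal path length; the dynamic program is verified against
exhaustive path enumeration for all shapes up to five frames.

## Sound discovery (`discovery`)

Each candidate starts from uniform(−1, 1) articulatory targets and is
improved by 3 outer iterations of bounded L-BFGS-B (finite-difference
gradients) on the reward

R = w_sal·salience + w_div·diversity − w_eff·effort − w_sens·sensitivity.

* **Salience** — attention presets re-weight low-band power (vowels),
  high-band power (fricatives) or touch (plosives/nasals). Acoustic band
  powers are brought to order one by a fixed gain (2·10⁴) since raw powers
  are tiny relative to the touch indicator.
* **Diversity** — weighted minimum distance from the candidate to every
  pattern already kept, in acoustic (DTW), tactile (Euclidean on touch
  profiles resampled to 32 points) and motor (Euclidean on zero-padded
  serialized vectors) space; an empty memory returns the ceiling 1.0 so the
  first pattern is always novel.
* **Effort** — summed articulator speeds plus the phonation contribution of
  P8, preventing the optimizer from simply maximizing loudness.
* **Sensitivity** — parameters P1..P5 of the target posture are each
  perturbed by +0.1 (5 % of the range, clipped at +1), the perturbed
  postures are synthesized and analyzed, and sensitivity is the root sum of
  squares of the five auditory DTW distances (×100 gain). This penalizes
  articulations whose acoustics change sharply under small motor noise, the
  unstable regions that quantal theories of speech predict are avoided.

Voicing and nasality are toggled per candidate by the preset rather than
optimized (discovery runs alternate voiced/voiceless and oral/nasal
closures). The search covers the seven articulatory targets with timing
fixed (start 0, hold 0.25 s); every reward weight is a package calibration,
labeled non-canonical, since no published values exist. Kept patterns must
pass an automated artifact filter replacing manual curation: rejection on
clipping (> 0.1 % full-scale samples), mostly-silent non-contact output
(> 50 % near-zero frames without touch), or spectral-flux spikes (clicks).

Inventories are reduced by clustering — K-means (scikit-learn) on serialized
motor vectors for plosive configurations, k-medoids on DTW distances for
vocalic/fricative sounds — with caps of 15 vowels, 15 plosive-like and 10
fricative patterns. Composites are the CV (CvV, CuV, FvV, FuV, NV), VC and
VV template cross-products over the single-pattern inventory; VV self-pairs
are excluded (a same-vowel VV is not a diphthong-like token) and families
whose consonant class is empty are skipped with a warning.

## Caregiver interaction (`interaction`, `fixtures`)

In a response session every inventory pattern is synthesized and presented;
a detected response reinforces the pattern and stores the response audio,
its auditory representation and an optional label; silence deselects it.
Response detection is supra-threshold short-term power within a 3 s
listening window. A caregiver exception skips the pattern without
deselecting it, so each id ends associated, deselected or skipped.

The simulated caregiver holds a miniature native inventory of
formant-synthesized tokens (three-formant source-filter vowels; burst/
frication onsets for consonant classes) with seeded formant and F0 jitter.
It classifies the learner's output by DTW over *energy-normalized*
gammatone representations — the caregiver judges spectral shape, not
loudness, since the learner's voice is far quieter than hers — and, inside
its acceptance radius and response probability, answers with a stored token
of the winning category: a reformulation, not an acoustic copy. Synthetic
tokens emulate labeled caregiver speech with controllable category
structure; they do not reproduce natural prosody, coarticulation or
session-to-session variability, so passing tests show the learning
machinery is sound, not that results transfer quantitatively to human
caregivers.

## Word imitation (`imitation`)

Words are spoken with pauses between syllables; segmentation reuses the
activity detector. Recognition is two-pass: pass 1 scores the segment
against up to 100 cluster-center templates (DTW k-medoids over the stored
responses, cached per memory snapshot); pass 2 scores all members of the 5
best clusters and picks the global best; lower-ranked pass-2 candidates are
the alternates used on retry attempts. Because the learner matches
caregiver speech against caregiver speech only, no normalization problem
arises in the recognizer.

Intonation transfer fits a straight line to the segment's voiced F0 track;
the line's endpoints map affinely onto the source parameter range (−0.9,
0.9) ↔ 100–300 Hz (male caregiver) or 150–400 Hz (female), and the segment
duration is clamped to 250–600 ms. The recalled pattern's P9 targets take
the mapped start/end values at its sub-pattern boundaries (a single-gesture
pattern is split at its midpoint so the contour can glide) and hold
durations are rescaled proportionally to the clamped duration. A word
session allows up to 4 imitation attempts per spoken prompt before the
caregiver gives up on the word.

## Transcription analysis (`analysis`)

Caregiver responses are coded in SAMPA within a CVC/CVV frame ('#' silent,
'xxx' untranscribable, ',' empty slot, longer codes truncated to three
elements). Shipped per-language CSV tables consolidate phonemes into
pipe-notated archiphonemes (e.g. |pb| covers /p b/) for English, German and
French, with composite vowel entries expanded into explicit one-row-per-
phoneme form so lookup is total and testable. Pairwise dataset comparison
counts same-label incidence per archiphoneme and different-label incidence
per unordered pair; group comparisons are element-wise sums. Differences of
same-label proportions are tested with the pooled two-proportion Z statistic
under a two-sided rule at α = 0.05/0.01/0.001 (critical values 1.95996,
2.57583, 3.29053); no multiple-testing correction is applied, matching the
per-comparison reporting convention. Bar-graph intervals are normal-
approximation CIs truncated to [0, 1]. Both statistics are cross-checked
against statsmodels in the test suite.

## Problem sizes and limitations

Discovery runs in the test suite and the acceptance script use a handful of
candidates per preset and a caregiver inventory of ~50–60 tokens; these are
the package's chosen desk-scale study conditions, and the full-scale
inventory of many hundreds of patterns is reachable by raising
`n_candidates`. Known limitations: the articulatory coefficients are
schematic, so discovered categories are acoustically coarser than a tuned
Maeda implementation would give; the simulated caregiver's DTW classifier
is far weaker than human categorical perception, which depresses
word-acceptance rates relative to a human-in-the-loop run; nasal acoustics
are a single fixed murmur resonator; and printed human-subject results
(response percentages, words-learned counts, transcription Z values) depend
on human judgment and unpublished counts and are out of scope.
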