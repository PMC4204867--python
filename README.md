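# vocalearn

A computational model of how an infant can learn to pronounce first words
**without imitating the sound of adult speech**. The learner starts with no
articulatory or perceptual knowledge of language. Through unsupervised
babbling it discovers motor patterns that produce sounds; a caregiver's
natural willingness to respond — almost always by *reformulating* the
infant-like sound into a well-formed native speech sound — selects which
patterns survive and supplies, for each, an adult speech sound the caregiver
considers equivalent. With that inventory of motor-pattern ↔ caregiver-sound
correspondences, the learner can parse a spoken word into known sounds and
pronounce it by recalling the associated motor patterns in sequence. The
crucial equivalence judgment is made by the *caregiver*, never by the
learner, so the model needs no solution to the speaker-normalization
problem. The package includes a fully synthetic caregiver, so the entire
loop runs with no human and no data download.

For researchers in developmental speech modeling, developmental robotics
and child phonology.

## The model

* **Production** — a Maeda-style articulatory synthesizer: ten control
  parameters (seven articulators + glottal area P8, F0 P9, nasality P10)
  map to a vocal-tract area function filtered as a Kelly–Lochbaum
  reflection line at 24 kHz, scaled by 0.8 toward infant dimensions, F0
  midrange 400 Hz, with touch feedback wherever a tract section closes.
* **Motor patterns** — gestural scores of up to three 31-element
  sub-patterns; articulators follow critically damped trajectories
  x(t) = x₁ + (x₀ − x₁)(1 + ωt)e^(−ωt), ω = 40 s⁻¹ (160 s⁻¹ after closure
  release).
* **Discovery** — candidates drawn uniform(−1, 1), refined by 3 iterations
  of bounded quasi-Newton ascent on
  R = w_sal·salience + w_div·diversity − w_eff·effort − w_sens·sensitivity,
  with attention presets for vowels / fricatives / plosives and inventory
  caps 15/15/10; CV, VC and VV composites expand the repertoire.
* **Interaction** — present, listen 3 s, reinforce-and-associate on
  response, deselect on silence.
* **Imitation** — segment the word at pauses, recognize each chunk with a
  two-pass DTW recognizer (100 cluster-center templates, then all members
  of the best 5 clusters), recall the associated patterns, transfer the
  word's straight-line F0 contour ((−0.9, 0.9) ↔ 100–300 / 150–400 Hz for
  male/female caregivers) and duration (clamped 250–600 ms), up to 4
  attempts per prompt.
* **Analysis** — SAMPA transcriptions in a CVC/CVV frame, archiphoneme
  consolidation tables for English/German/French, same/different incidence
  comparison, pooled two-proportion Z-tests
  z = (p̂₁ − p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)) at α = 0.05/0.01/0.001, and 95 %
  normal CIs.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Discover a few vowel-like motor patterns, run a caregiver response session,
and teach two "words":

```sh
vocalearn discover --preset vowel --n-candidates 2 --seed 9 \
    --out inv.json --log-csv rewards.csv
# kept 2 patterns -> inv.json
vocalearn interact --inventory inv.json --out mem --log-csv session.csv
# associated 2, deselected 0
printf "a\nai\n" > words.txt
vocalearn teach --words words.txt --memory mem --inventory inv.json \
    --out teach --seed 3
# learned 2/2 words -> teach
```

`rewards.csv` logs the reward breakdown per kept pattern, e.g.

```
id,salience,diversity,effort,sensitivity,total
vowel-9-0,2.5171,1.0,0.6692,0.8354,2.0125
vowel-9-1,2.5941,0.2121,0.6686,0.8642,1.2734
```

— the first pattern earns the empty-memory diversity ceiling (1.0); the
second is scored for novelty against it (0.21), and both pay effort and
sensitivity penalties against their band-power salience. After the
interaction step, each surviving pattern id is linked to the caregiver's
reformulation audio and category label; the teach step then recognizes each
prompted word among those stored responses and recalls the linked patterns
to pronounce it, with the caregiver accepting or rejecting each attempt.

The statistics layer works the same way from the CLI:

```sh
vocalearn analyze ztest --x1 40 --n1 100 --x2 60 --n2 100
# z = -2.82843  p1 = 0.4000  p2 = 0.6000  significant at: [0.05, 0.01]
vocalearn analyze ci --x 50 --n 100
# [0.40200, 0.59800]
```

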