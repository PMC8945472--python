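# braycall

Analysis of **bray-call sequences** — the multi-unit rhythmic vocalisations of
common bottlenose dolphins (*Tursiops truncatus*) built from gulps (GU),
grunts (GR) and squeaks (SQ) — from per-element acoustic measurements
(selection tables), with no audio processing. The package targets the
repertoire comparison of two Mediterranean sub-populations (Tyrrhenian Sea
off Rome vs. Strait of Sicily off Mazara del Vallo) and ships a synthetic
generator reproducing the published catalogue structure, since the original
recordings are not deposited.

## What it computes

* **Element classification** — rule-based assignment of each measured unit to
  one of ten classes: four gulp variants (GU1–GU4, separated by contour
  shape, harmonic-like structure and frequency band), two grunt variants
  (GR1, GR2), squeaks, and the non-bray adjuncts pops (POP), cracks (CR) and
  low-frequency narrowband sounds (LFN). Rulesets are editable YAML.
* **Sequence assembly** — elements closer than 60 s (end-to-begin, strict)
  form one sequence; POP/CR/LFN join only within 60 s of a bray element and
  never form sequences on their own.
* **Typology grammar** — each sequence is matched against the 13 stereotyped
  patterns of the published catalogue (single-element runs, pair/triplet
  repetitions, alternations, prefix-then-run forms); no match ⇒ UNCLASSIFIED.
* **First-order Markov chain model (FOMM)** — within-sequence transition
  counts row-normalised into probabilities, at coarse-type and variant
  resolution, with optional additive smoothing.
* **Shannon entropy** — H1 = −Σᵢ pᵢ log₂ pᵢ (bits) over element-class
  frequencies, 0 ≤ H1 ≤ log₂ N.
* **Sørensen–Dice repertoire similarity** — SDC = 2(Nₛ + Nₑ)/(R₁ + R₂), where
  Nₛ/Nₑ are shared typologies/element classes and R₁, R₂ the repertoire sizes
  (distinct typologies + element classes per site).
* **Site comparison** — Shapiro–Wilk-gated protocol: Welch's *t* when both
  groups look normal, two-sided Mann–Whitney otherwise, Kruskal–Wallis for
  three or more groups.

## Worked example

```python
import braycall as bc

profile = bc.load_profile("tyrrhenian_like", seed=7)
observations, truth = bc.generate_site_dataset(profile)

labeled = bc.classify_batch(observations, bc.default_ruleset())
sequences = bc.segment_sequences(labeled)
for seq in sequences:
    bc.assign_typology(seq)

tm = bc.estimate_fomm(sequences, alphabet=bc.COARSE_ALPHABET, level="coarse")
h1 = bc.shannon_entropy(bc.element_probabilities(sequences, "coarse"))
print(len(sequences), round(tm.probability("GU", "GU"), 2), round(h1, 2))
```

prints `637 0.98 0.44`: the 637 generated sequences are all recovered intact;
gulp-to-gulp dominates the coarse transition matrix (the generator's long
single-gulp runs push it above the published 0.95), and the coarse repertoire
entropy is 0.44 bits — far below log₂ 6 ≈ 2.6 because gulps dominate the
element inventory.

The full analysis is scripted:

```
python analysis/01_simulate_sites.py --seed 1   # site datasets + ground truth
python analysis/02_classify_and_segment.py      # classification, sequences
python analysis/03_repertoire_analysis.py       # composition, H1, FOMM, SDC
python analysis/04_site_comparison.py           # gated between-site tests
```

Each script prints its findings and writes TSV tables under `results/`. On
the generated data the pipeline recovers 100% of element labels and sequence
typologies, and the site comparison detects the built-in frequency/duration
shift of the Sicilian profile (Welch or Mann–Whitney p ≪ 0.001 for minimum
frequency, maximum frequency and gulp duration).

## Layout

```
src/braycall/        library: io_model, element_classifier, sequence_builder,
                     repertoire_stats, site_comparison, synthetic_data
src/braycall/data/   default ruleset, typology patterns, site profiles,
                     survey inventory (all YAML, all editable)
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      models, parameter choices, limitations
```
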