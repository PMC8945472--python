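# Methods

## Scope and data model

The package analyses bray-call sequences of common bottlenose dolphins from
*per-element measurements*, never from audio. The unit of input is one
detected sound with begin/end time (s), low/high frequency (Hz), optionally a
peak frequency (Hz, measured for pops and cracks), and three analyst-logged
qualitative features: spectrogram contour (`downsweep`, `flat`, `upsweep`,
`none`), presence of harmonic-like structure, and a broad sound class
(`pulsed_continuous`, `pulsed_tonal`, `click`, `broadband_click`,
`narrowband_tonal`, `unknown`). Files are tab-separated selection tables with
Raven-style default column names, remappable via a dialect config; files
without the qualitative columns default to contour `none`, harmonic false,
sound class `unknown`. How qualitative features are logged is an artifact
decision of this package — source studies describe them only as visual
spectrogram judgements.

## Element classification

Ten element classes are recognised: gulp variants GU1–GU4, grunt variants
GR1–GR2, squeak SQ, and the non-bray adjuncts POP, CR and LFN. The published
variant definitions are qualitative first (GU1: downsweep, no harmonics; GU2:
flat, harmonics; GU3: downsweep, harmonics; GU4: flat, no harmonics) with
per-variant frequency/duration distributions reported as mean ± SD, not as
decision thresholds. The default ruleset therefore encodes:

* categorical gates per class (sound class, contour, harmonic), evaluated
  before any numeric gate;
* numeric interval gates at **mean ± 2 SD** of the published parameters — a
  convention of this package, since no quantitative boundaries are published;
* a fixed priority order (variants GU1…GU4, GR1, GR2 before the coarse
  classes SQ, POP, CR, LFN), first full match wins.

If no rule matches in full, an observation whose categorical signature
matches **exactly one** rule receives that class: a ± 2 SD band by
construction excludes ~5% of genuine class members per gated parameter, and
the qualitative signature, when unique, is the stronger evidence. Ambiguous
or unmatched observations fall to `UNCLASSIFIED`, which is a sink, never an
error. Classification is deterministic and element-wise independent.

Two published values required a reading decision: the GU3 minimum frequency
is printed as "2168 ± 45 Hz" against its own confidence interval of
210–221 Hz and a tabulated 223 ± 49 / 204 ± 35 Hz; the ruleset uses
216 ± 45 Hz. Grunts are broadband with no published frequency band, so the
GR rules gate only on signature and duration, and grunt recognition requires
an explicit `pulsed_continuous` sound class (a contour-less element of
unknown sound class is otherwise indistinguishable from background).

## Sequence assembly

Elements belong to the same sequence when the inter-element interval (end of
one element to beginning of the next) is **strictly shorter than 60 s**; the
rule's behaviour exactly at 60 s is unspecified in the source protocol, and
the strict reading was chosen. POP/CR/LFN (and `UNCLASSIFIED` elements,
treated uniformly with them) join a sequence only when within 60 s of a bray
element (GU/GR/SQ) of that sequence; clusters with no bray element, and
isolated single elements, form no sequence. Removing a distant adjunct can
only open an over-threshold gap, so the subsequent re-split never breaks an
under-threshold adjacency; every bray element ends up in exactly one
sequence.

## Typology grammar

The 13 stereotyped typologies are pattern records over label strings (order
only, timing ignored): single-element runs (1: GU1 × 3–105; 10: SQ × 2–14),
pair repetitions (2: GU3·GU1; 3: GU1·GU4), the triplet repetition (4:
GU1·GU2·GU3), alternations (7: GR1/GU1; 11: SQ/GU1; 13: LFN/GU1; accepted
starting with either member, as the published descriptions do not fix the
first element), the POP-run alternation (5: POP series alternating with 1–8
gulps, 9–27 pops in 1–16 series), prefix-then-run forms (6: GR1 then 6–35
GU1; 8: GR2 then 3–26 GU1; 12: SQ then 3–27 GU1) and the series-prefix form
(9: 2–11 CR, then GR1, then GU1). Count ranges follow the published
catalogue. Matching is most-specific-first (9 → 6, 8, 12 → 4 → 2, 3 → 5, 7,
11, 13 → 1, 10) so a pair repetition is never absorbed by a run; imperfect
motifs are left `UNCLASSIFIED` rather than fuzzy-matched, because the
catalogue describes stereotyped sequences only.

## Markov model, entropy, similarity

The first-order Markov chain model counts ordered adjacencies within
sequences only — no transitions across sequence boundaries and no artificial
start/end states, matching the published transition diagrams. Probabilities
are row-normalised; rows with no observations are flagged undefined (queried
probabilities raise, exports carry zero rows) rather than propagating NaN.
Additive smoothing is available (`pseudocount`, default 0, matching the
raw-looking published probabilities). The model runs at coarse resolution
(GU, GR, SQ, POP, CR, LFN) and at variant resolution. The published
transition values P(GU→GU) = 0.95, P(GU→GR) = 0.83, P(GU→SQ) = 0.43 sum past
one and therefore cannot be a row of a row-normalised matrix; this package
implements the standard estimator and makes no attempt to reverse-engineer
that convention.

Entropy is the standard H1 = −Σ pᵢ log₂ pᵢ in bits (the source's printed
formula lacks the minus sign, which would make every value non-positive).

The Sørensen–Dice coefficient is SDC = 2(Nₛ + Nₑ)/(R₁ + R₂) over shared
typologies and element classes. The published enumeration of "distinct
sequences + acoustic elements" is ambiguous, so two conventions are
implemented: **A** (default) counts element classes at variant level for both
sites — for the published inventories R₁ = 13 + 10 = 23, R₂ = 2 + 2 = 4,
SDC = 8/27 ≈ 0.296; **B** counts the variant-resolved site at coarse +
variant level (12 element labels) and the other site at coarse level —
R₁ = 25, R₂ = 4, SDC = 8/29 ≈ 0.276. Both straddle the published 0.27.

## Site-comparison protocol

Each parameter is tested per group with Shapiro–Wilk at α = 0.05 (the gating
α is not published; 0.05 is the conventional choice, and *both* groups must
pass for the parametric branch). Two groups: Welch's *t* if gated normal,
otherwise two-sided Mann–Whitney (exact when both n ≤ 20 and untied,
tie-corrected normal approximation otherwise — the method used is recorded in
the result metadata). Three or more groups: Kruskal–Wallis. No
multiple-testing correction is applied, matching the source protocol. A
constant sample is treated as failing the normality gate (Shapiro–Wilk is
undefined on it). The original recordings are not deposited, so the published
between-site p-values are not reproducible; the protocol is validated on
generated data instead.

## Synthetic data generator

The generator emulates the catalogue's statistical structure per site:

* **Typology mixture** — Tyrrhenian-like: the printed per-typology counts
  (340, 78, 36, 27, 26, 25, 25 for typologies 1, 2, 9, 5, 10, 7, 8) with the
  residual 80 of 637 sequences spread evenly over the six typologies reported
  only as "about 2.5% each" (the printed residuals do not reconcile exactly:
  six typologies remain where five are mentioned). Sicilian-like: 7 sequences
  at weights 6:1 over typologies 1 and 10.
* **Run lengths** — uniform over the published per-typology ranges
  (maximum-entropy choice; only ranges are published).
* **Element parameters** — truncated Gaussians at the per-class mean ± SD.
  The min/max frequency pair of an element shares a single standard deviate,
  so the band shifts as a whole: marginal means and SDs match the published
  values while min < max holds without rejection bias. Durations truncate at
  1 ms, frequencies at 10 Hz. Grunt frequency bands and pop/crack durations
  are unpublished; the shipped values are this package's choices consistent
  with the qualitative definitions (grunts broadband at low frequency, pops
  and cracks short).
* **Timing** — inter-element gaps are positive-truncated Gaussians from the
  per-typology interval values (printed "± 0" SDs replaced by small positive
  spreads); inter-sequence gaps default to 120 s, safely above the 60 s rule,
  so segmentation recovers every generated sequence intact.
* **Qualitative features** — deterministic per class (the signature table in
  `synthetic_data`'s docstring). Every class has a unique signature, which is
  what makes end-to-end label recovery exact; real spectrogram judgements
  would blur these, so the 100% recovery measures pipeline correctness, not
  expected field performance.
* **Site differences** — the Sicilian profile lowers GU1 and SQ frequencies
  and durations by ~15–20% relative to the Tyrrhenian profile. The source
  reports the direction (lower values in the Strait of Sicily) but no
  magnitudes; the shift is a one-time documented choice so the comparison
  protocol has a real effect to detect.
* Sequence duplication in the published per-typology parameter table
  (identical rows for typologies 11 and 12) is copied as printed.

What the generator does **not** emulate: within-sequence correlation of
element parameters (no covariances are published), overlapping vocalisers,
background noise or detection failure, and recording-effort structure — the
synthetic timeline is dense, so simulated emission rates are not comparable
to the published per-minute rates (those are recomputed from the shipped
effort inventory instead). Because typology-1 run lengths are uniform over
the full published range of 3–105 while the real per-sequence mean is ~5
elements, the simulated datasets contain proportionally more gulps than the
surveyed catalogue (gulp share ≈ 95% vs. 80%; coarse P(GU→GU) ≈ 0.99 vs.
0.95). Tests that target the published proportions therefore use the shipped
inventory, and tests on simulated data target the generator's own ground
truth.

## Numerical and interface choices

* Probability rows validate to 1 within 1e-12; probability vectors within
  1e-9.
* Times are seconds, frequencies Hz, no unit auto-detection; tables are
  UTF-8, tab-separated, "." decimal; written numbers carry six decimals, so
  round-trips are exact to 1e-6.
* Problem sizes in tests: full-size site simulations (637 sequences,
  ~20,000–25,000 elements) run in seconds; Markov recovery uses
  50,000-transition chains, where the dominant-row standard error is well
  under the 0.01 acceptance band.
* Seeds: all randomness flows through `numpy.random.default_rng`; site
  profiles carry a seed, and every script takes `--seed`.

## Known limitations

* The 13-pattern grammar is exact by design; field data with imperfect
  motifs will show a substantial `UNCLASSIFIED` fraction.
* The ± 2 SD interval gates and the categorical-fallback rule are
  conventions; with real measurement noise on contour/harmonic judgements,
  classification accuracy will be driven by those qualitative columns.
* Convention A/B for the Sørensen–Dice enumeration brackets, but cannot
  pinpoint, the published 0.27.
* "Sequences of sequences" (higher-order grouping) are out of scope, as are
  audio, spectrograms and any detection step.
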