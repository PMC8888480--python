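# Methods

## Model and assumptions

The workflow annotates glucuronidated compounds in data-dependent MS/MS
datasets by transforming conjugate spectra into aglycone pseudo-spectra
and searching them against aglycone reference libraries. It rests on
three assumptions:

1. **Diagnostic neutral loss.** CID/HCD of a glucuronide [M+H]⁺ cleaves
   the glycosidic bond, ejecting neutral anhydroglucuronic acid
   (C₆H₈O₆). The charged fragment at precursor − 176.0321 is therefore
   the protonated aglycone. Benzylic/acylic conjugates can additionally
   lose intact glucuronic acid (C₆H₁₀O₇, −194.0426), which is treated as
   an annotation, not an independent trigger.
2. **Superset fragmentation.** The conjugate's fragments below the
   aglycone mass approximate the aglycone's own fragment spectrum, so a
   truncated, precursor-reassigned spectrum is searchable against
   unconjugated references. This fails for compounds whose conjugation
   site changes the fragmentation (e.g. ether cleavage in beta blockers,
   [Gluc+NH]-type losses in sulfonamides); the synthetic generator
   emulates these as *interference fragments* and the scores degrade
   accordingly rather than producing false positives.
3. **Chromatographic coupling.** On reversed phase the glucuronide
   elutes in a linear relationship with its aglycone, enabling an RT
   plausibility filter.

Only singly protonated positive-mode ions are screened by default;
multiply charged precursors are skipped (an override divides the loss
delta by the charge, but the workflow makes no claim for z > 1).

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| neutral-loss window | 0.001 | Th | absolute window around precursor − Δ |
| min. NL fragment intensity | 0 | % base peak | screening floor; any centroided peak counts |
| truncation tolerance | 0.01 | Th | retain m/z ≤ new precursor + tol |
| fragment-match window | 0.01 | Th | library-search peak pairing |
| intensity cut-off factor | 0.01 | fraction of base peak | applied before scoring |
| precursor window | 0.01 | Th | candidate selection |
| AMP acceptance threshold | 5.0 | score | accepted iff AMP > 5.0 |
| RT band | 3 | residual SD | consistency flag width |

The screening window is absolute (Th), not ppm. The truncation boundary
is inclusive with tolerance because the aglycone pseudo-molecular ion —
the neutral-loss fragment itself — sits exactly at the new precursor and
must survive; a strict "below the precursor" cut would delete the most
diagnostic fragment. Removed peaks are kept in an audit field for
head-to-tail review. GlucA-fragment removal removes *all* peaks in its
window (0.001 Th), not only the closest one.

## Scoring

The MSforID-style match probability is implemented as

    MP = 100 · (2·n_m / (n_s + n_r)) · sqrt((I_m,s / I_s) · (I_m,r / I_r)),

a Dice factor on matched peak counts times the geometric mean of
matched-intensity fractions. It satisfies the published contract of the
score family — range 0–100, 0 with no matching fragments, 100 at
identity, monotone in spectral overlap — without claiming to be the
proprietary MSforID formula, whose exact form is not public. AMP is the
plain arithmetic mean of MP over a compound's reference spectra, with no
renormalisation across candidates: renormalising would make AMP depend
on library composition and break the fixed acceptance threshold.
Ranking is fully deterministic (AMP desc, dot product desc, name).

Fragment matching is greedy one-to-one by ascending |mass error| (ties:
larger intensity product). On generic data this equals the exhaustive
max-cardinality minimum-total-error assignment (verified by brute force
on ≤6-peak instances); adversarial peak clusters inside the match window
could in principle differ, but at 0.01 Th windows and centroided data
this is not observed.

The dot product is the cosine over aligned intensity vectors; unmatched
peaks contribute to the norms only. It is cross-checked in the test
suite against an independent implementation (matchms `CosineGreedy`).

## Retention-time model

OLS of glucuronide RT on aglycone RT, computed from the closed-form
normal equations (the direction follows the use case: predicting the
conjugate's RT from the known aglycone). R² = 1 − SS_res/SS_tot;
residual SD uses n − 2 degrees of freedom; the mean shift is the mean of
(glucuronide − aglycone). Fits require n ≥ 3 and non-degenerate
predictor variance. The ±3·SD consistency band is a convention exposed
as a parameter, since the underlying study used RT qualitatively.

## Synthetic data

`make_aglycone_library` draws per compound a precursor on a 0.05 Th grid
(aglycone window chosen so the conjugate stays inside the 75–1000 Th
scan range), 5–12 fragment peaks on the same grid strictly below the
precursor, plus a surviving molecular-ion peak *at* the precursor m/z.
That molecular-ion peak is a deliberate design choice: the conjugate's
neutral-loss fragment falls exactly at the aglycone precursor, and
without a reference counterpart the noiseless deconjugated spectrum
could never reproduce the reference exactly. One or two reference
spectra per compound carry collision-energy tags (20/40 eV); scoring is
CE-agnostic but the tags propagate into reports.

`make_glucuronide_dataset` shifts the precursor up by 176.0321, keeps a
subset of the aglycone fragments (keep probability 0.9) with log-normal
intensity noise (CV 0.2), jitters all m/z by N(0, 0.0002 Th), adds the
NL fragment, a GlucA fragment for half the compounds, and — for a
configurable fraction — 1–2 high-intensity interference peaks absent
from the reference. Decoys are aglycone-only spectra. The 0.05 Th grid
is what makes the zero-false-positive property constructible: both loss
masses are ≥ 0.007 Th away from any multiple of 0.05, so no grid peak
can fall inside a ±0.001 Th screening window by accident — only the
deliberately placed fragments can. `FixtureConfig.noiseless()` switches
off every stochastic distortion for exact-recovery checks.

The generator emulates structure, not instrument physics: no isotope
patterns, chromatographic peak shapes, in-source fragmentation, profile
data or realistic intensity statistics. Passing tests therefore
demonstrate the correctness of the screening/deconjugation/scoring logic
under the stated assumptions, not performance on real instrument data,
where deviating fragmentation, chimeric spectra and calibration drift
dominate.

RT defaults (slope 0.95, intercept −0.8 min, residual SD 0.1 min over a
1–14 min gradient) encode a realistic reversed-phase shift of roughly
−1 min for the conjugate.

## Numerical choices and degenerate inputs

- Loss deltas are computed from elemental monoisotopic masses at full
  precision; printed four-decimal values are rounded displays (the
  ±0.001 window leaves no room for rounded constants).
- Duplicate peaks within 1e-4 Th are merged (summed intensity,
  intensity-weighted mean m/z) at construction, preventing
  double-matching.
- Base-peak normalisation to 100 is idempotent; empty spectra are
  errors at normalisation, `None` (not an error) in screening, and a
  reported `DeconjugationError` when truncation empties a spectrum.
- Retention time is minutes internally; MGF I/O converts RTINSECONDS.
- Problem sizes in tests and the acceptance script (50-compound
  libraries, 25/25 glucuronide/decoy splits, 40 RT pairs, 1000-spectrum
  property sweeps) are chosen so each suite completes in seconds while
  keeping the binomial/OLS error bars well inside the asserted
  tolerances.

## Known limitations

- Di-glucuronides are out of scope: a single deconjugation pass cannot
  strip two moieties, and no iterative mode is offered.
- Negative ionization mode is untested.
- The MSforID-inspired MP is not numerically comparable to published
  AMP values from the proprietary implementation; only its contract is.
- MS1 feature detection, EIC screening and fragmentation-tree
  elucidation are deliberately outside the package.
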