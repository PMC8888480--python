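# aglycon — in silico deconjugation of glucuronide MS/MS spectra

Phase-II metabolism attaches glucuronic acid to drugs, steroids and other
xenobiotics, so in urine or in vitro incubations a compound often appears
only as its glucuronide — for which almost no reference MS/MS spectra
exist. Under collision-induced dissociation, however, a glucuronide
predominantly ejects the neutral anhydroglucuronic acid moiety
(C₆H₈O₆, 176.0321 Da), leaving fragment ions that largely mirror those of
the unconjugated parent compound (the *aglycone*). `aglycon` exploits this
to annotate glucuronides in non-targeted, data-dependent LC-HRMS datasets
using ordinary aglycone spectral libraries. It is aimed at metabolomics,
forensic and exposomics groups doing suspect/non-target screening in
positive ionization mode.

## Method

For every MS/MS spectrum with precursor m/z *P* (assumed [M+H]⁺):

1. **Neutral-loss screen.** Flag the spectrum if a fragment lies at
   *P* − 176.0321 within ±0.001 Th (Gluc-NL). A loss of intact glucuronic
   acid, C₆H₁₀O₇ = 194.0426 Da (GlucA-NL), is annotated as well.
2. **In silico deconjugation.** Reassign the precursor to the predicted
   aglycone m/z *P* − Δ, truncate fragments above it, and remove the
   GlucA fragment if present (it has no counterpart in the aglycone
   spectrum). The result is an aglycone *pseudo-spectrum*.
3. **Library search.** Compare the pseudo-spectrum against all library
   compounds within ±0.01 Th of the predicted aglycone mass, after an
   intensity cut-off factor of 0.01. Matching fragments (±0.01 Th,
   greedy one-to-one, smallest mass error first) feed two scores:

   - a per-reference-spectrum match probability
     `MP = 100 · (2·n_m / (n_s + n_r)) · √((I_m,s/I_s)(I_m,r/I_r))`
     (MSforID-inspired; n = peak counts, I = intensity sums, subscript m
     = matched), averaged over a compound's reference spectra into the
     **AMP** (0–100); an annotation is accepted when AMP > 5.0;
   - the familiar cosine **dot product** (0–1) over aligned intensity
     vectors.
4. **Retention-time filter.** Glucuronides elute in a tight linear
   relationship with their aglycones (≈1 min earlier on reversed phase).
   `rt_glucuronide = slope · rt_aglycone + intercept` is fitted by OLS
   and annotations outside ±3 residual SD are flagged as inconsistent.

A seeded synthetic-data module generates aglycone libraries and derived
glucuronide/decoy datasets with this exact structure, so the entire
workflow is testable without instrument data.

## Worked example

```bash
aglycon simulate --out demo --seed 42 --noiseless
# wrote 50 library compounds, 50 spectra, 50 RT pairs to demo
aglycon pipeline demo/dataset.mgf --library demo/library.msp \
    --rt-pairs demo/rt_pairs.tsv --out-dir demo/run
# flagged=25 searched=25 accepted=25 -> demo/run/report.tsv
aglycon rtfit demo/rt_pairs.tsv --out demo/model.txt
# slope=0.9500 intercept=-0.8000 R2=1.0000 mean_shift=-1.1721 min residual_sd=0.0000 n=50
```

The simulated study contains 25 glucuronides and 25 aglycone-only decoys.
`flagged=25` means every glucuronide — and no decoy — carried the
Gluc-NL; each report row then shows its best library match, e.g.

```
source_id              parent_precursor_mz  deconjugated_precursor_mz  best_match    amp    dot_product  rt_flag     accepted
sim:gluc:compound_001  434.0821             258.05                     compound_001  100.0  1.0          consistent  True
```

AMP 100 and dot product 1.0 are what a noiseless conjugate of a library
compound should score; the RT flag confirms the observed retention time
matches the fitted aglycone→glucuronide model (here slope 0.95,
intercept −0.80 min, i.e. a mean shift of about −1.2 min across the
gradient).

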