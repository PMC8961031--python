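# neuromode

EEG spatio-frequency mode discovery for selecting transcranial
alternating-current stimulation (tACS) parameters.

Non-invasive stimulation can modulate working memory, but only if the
stimulation frequency and scalp target actually match the brain activity
that tracks performance. `neuromode` implements the analysis side of that
problem for repeated verbal n-back sessions: given multichannel task EEG and
behavioural tables, it identifies the oscillation frequency and channels
whose activity best separates low- from high-performing subjects, and emits
a stimulation recommendation backed by three independent evidence strands.
It is aimed at cognitive-neuroscience groups prototyping
electrophysiology-guided stimulation protocols, and ships a synthetic cohort
generator with planted ground truth so every stage is testable without human
data.

## What it computes

1. **Preprocessing** — zero-phase FIR band-pass (1–48 Hz), epoching
   (−1.0..+1.5 s), baseline correction (−0.5..0 s), average reference,
   ±100 µV amplitude rejection, correct-trial selection.
2. **Performance grouping** — target-trial accuracy (target-ACC) and
   correct-target reaction time; 2 SD outlier exclusion; median split of
   summed block-1 scores into LP (label 0) and HP (label 1) groups.
3. **Filter-bank CSP with mutual-information ranking** — per band
   q ∈ {θ, α, β}, spatial filters W_q jointly diagonalise the class
   covariances; projected trials Z_{i,q} = W_q E_{i,q} yield normalised
   log-variance features

       X_p = log( var(Z_p) / Σ_{p'} var(Z_{p'}) ),   p = 1..2m,  m = 2,

   ranked by the mutual information I(X; L) = H(X) − H(X|L) (bits) with the
   binary capacity label; the top modes come with scalp patterns (columns
   of W⁻¹) for topographic display.
4. **Attention-based spectral graph network** — channels as vertices, a
   graph-attention layer that re-estimates the adjacency
   (A' = sym(αA), α row-softmaxed attention), spectral convolutions
   y = U g_θ(Λ) Uᵀ x on the Laplacian L = D − A' = UΛUᵀ, mean pooling and a
   sigmoid head; trained by full-batch momentum gradient descent with fully
   analytic gradients (numpy, including the eigendecomposition backward
   pass). Yields a held-out accuracy and the top-15 edges of the learned
   adjacency.
5. **Per-frequency MI** — single-trial wavelet power at 4, 5, 6, 7, 8 Hz
   (newtimef-style cycles (3, 0.5), Hanning taper, padratio 8) on candidate
   channels, versus the capacity label.
6. **Recommendation** — stimulation frequency = argmax of the per-frequency
   MI; target channels = dominant pattern weights of the top CSP mode;
   concordance across the three strands reported, never silently fused.

## Worked example

Generate a synthetic cohort with a planted 8 Hz prefrontal mode (the
generator's defaults: 2×2 subjects, 50 trials each, source at Fp1/Fp2 with
a 3× group power ratio at in-band SNR 1), then run the full analysis:

```bash
neuromode simulate --out demo/bundle --seed 5 --subjects-per-group 2 --trials 50
printf 'labels:\n  source: simulation\n' > demo/cfg.yaml
neuromode recommend --bundle demo/bundle --config demo/cfg.yaml --out demo/evidence --seed 5
```

which prints

```
recommended stimulation frequency : 8 Hz
recommended target channels       : Fp1, Fp2
confidence                        : normal
evidence concordance:
  fbcsp_top_band_contains_frequency: True
  fbcsp_top_band: alpha
  gcnn_top_edge: Fp1-Fp2
  gcnn_top_edge_touches_recommended_channels: True
```

The evidence tables land in `demo/evidence/`. The per-frequency MI table
(`per_frequency_mi.tsv`) shows the planted frequency winning at both
planted channels — 0.56 bits at Fp1 and 0.35 bits at Fp2 for 8 Hz, against
≤ 0.09 bits everywhere at 4–6 Hz (7 Hz rides at 0.54/0.30 bits because a
four-cycle wavelet at 7 Hz still passes two-thirds of an 8 Hz tone's
power). The top CSP mode (`top_modes.tsv`) is component 3 of the α band
(8–13 Hz, containing the planted 8 Hz) at 0.52 bits, and the network's
top-ranked edge (`edge_ranking.tsv`) is Fp1–Fp2 with normalised weight 1.0
— the planted coupling. `provenance.txt` records the config hash and seed
that reproduce the run.

The same stages are importable as a library (`neuromode.preprocess`,
`neuromode.fbcsp`, `neuromode.gcnn`, `neuromode.timefreq`,
`neuromode.behavior`, `neuromode.pipeline`, `neuromode.simulate`); see
`docs/methods.md` for the model details, parameter defaults and the
generator's scope.

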