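# pacfield

Phase–amplitude coupling (PAC) analysis of paired local field potential
(LFP) recordings during open-field exploration.

Cross-frequency coupling — the phase of a slow rhythm in one brain region
modulating the amplitude of a fast rhythm in another — is a candidate
mechanism for inter-areal communication, and its weakening is a candidate
electrophysiological marker of depression-like states. `pacfield` implements
the full analysis chain used to quantify theta→high-gamma coupling between
the medial prefrontal cortex (mPFC, phase provider) and the basolateral
amygdala (BLA, amplitude provider) in rats exploring an open field:

* **preprocessing** — zero-phase Butterworth band-pass (acquisition band
  0.3–120 Hz), 50 Hz powerline notch, polynomial baseline removal, and
  extraction of the canonical bands (delta 1–4, theta 4–12, beta 12–30,
  low gamma 30–70, high gamma 70–120 Hz);
* **coupling estimation** — the entropy-based Modulation Index. With the
  instantaneous phase φ_fp(t) and amplitude envelope A_fA(t) from the
  Hilbert analytic signal, the phase axis is split into N = 18 bins of 20°,
  the mean amplitude per bin is normalised to a distribution
  P(i) = ⟨A_fA⟩_i / Σ_k ⟨A_fA⟩_k, and

      MI = (log N − H(P)) / log N,   H(P) = −Σ_i P(i) log P(i),

  so MI = 0 for uniform P (no coupling) and MI = 1 for a Dirac-like P;
* **comodulograms** — MI over a grid of (phase, amplitude) band pairs;
* **behavioural segmentation** — open-field zone geometry (100 cm arena,
  concentric 60 cm central zone), detection of exploration trials
  (peripheral→central entries with ≥ 4 s prior peripheral residence; trials
  with < 4 s central dwell are excluded), trial-aligned MI time courses
  around the entry reference point (RP), and summary metrics (distance,
  entries, centre time, speed);
* **group statistics** — independent t-tests from raw samples or from
  published mean ± SEM summaries, balanced two-way and mixed-design ANOVA
  with Bonferroni post hoc contrasts, Pearson correlation;
* **a synthetic-data generator** — two-region LFP pairs with a ground-truth
  coupling depth χ ∈ [0, 1] (multiplicative amplitude modulation of a fast
  carrier by a slow driver) plus open-field trajectories with a scripted
  number of central-zone visits, so every stage is testable without
  recordings.

The package is aimed at systems-neuroscience analysts who need a tested,
reproducible PAC pipeline, and at methodologists who want a ground-truth
test bed for entropy-based coupling estimators.

## Worked example

```python
from pacfield import PhaseAmplitudeCoupling, SynthConfig, gen_coupled_lfp

# 8 s synthetic session: 8 Hz driver fully modulating an 80 Hz carrier
cfg = SynthConfig(chi=1.0, noise_sd=5.0, duration=8.0, seed=42)
mpfc, bla = gen_coupled_lfp(cfg)

res = PhaseAmplitudeCoupling(mpfc, bla).fit()
print(res.summary())
```

```
Phase-Amplitude Coupling (entropy-based Modulation Index)
=========================================================
phase band   : theta [4, 12] Hz (mPFC)
amp band     : high_gamma [70, 120] Hz (BLA)
phase bins   : 18
samples used : 12000
entropy H(P) : 2.699577 nats (max 2.890372)
MI           : 0.0660106
preferred phase: 10.0 deg
```

The entropy falls short of its maximum log 18 ≈ 2.890 because the
high-gamma envelope concentrates near the driver's amplitude maximum
(phase ≈ 0°), giving MI ≈ 0.066. The same session generated with `chi=0`
yields MI ≈ 2.4 × 10⁻⁶: no coupling beyond estimator noise. 12 000 of the
16 000 samples are used; the first and last second are excluded as filter
edge margins.

An end-to-end two-group study (simulate → preprocess → trials → PAC →
stats) runs from the shell:

```sh
pacfield run --out run_dir --seed 7
```

which writes per-trial zone MI tables, behaviour summaries, group t-test
and group × zone ANOVA results, MI time courses, and a manifest with
content hashes for reproducibility.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and known limitations.
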