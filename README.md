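# scclfp

Analysis of acute deep-brain-stimulation (DBS) effects on local field
potentials (LFPs) recorded from the DBS lead itself, for the
subcallosal cingulate (SCC) target used in treatment-resistant
depression.  Given multi-channel intraoperative recordings, artifact
annotations and stimulation-cycle metadata, the package quantifies how
band-limited spectral power in the minute *after* a 3-minute
stimulation cycle differs from the minute *before*, and tests those
changes across a patient cohort with exact nonparametric statistics.
It is aimed at electrophysiologists and methods researchers who want a
tested, reusable implementation of this peri-stimulation analysis —
plus a synthetic-cohort generator with known ground truth to validate
every stage.

## The measure

For each stimulation cycle, the bipolar (differential) signal flanking
the stimulated contact is bandpass filtered (1–50 Hz, zero phase),
decimated to 128 Hz, pruned of annotated artifacts (samples discarded,
not blanked), and cut into the 1-minute pre and post epochs.  Each
epoch is decomposed with a complex-Morlet CWT on 200 frequencies over
1–50 Hz.  Per frequency f, the acute effect is the relative change of
median CWT magnitude,

    rc(f) = ( median v_POST(f) − median v_PRE(f) ) / median v_PRE(f),

bootstrapped over time points to a 95% percentile CI; the CI midpoints
are averaged within δ (1–4 Hz), θ (4–8), α (8–15), β (15–30) and
γ (30–50) to give five band-limited change values per cycle (−0.5
means the post median is half the pre median).  Group inference uses
exact Wilcoxon tests (signed-rank by default, with full enumeration of
the permutation null at these sample sizes), Hedges' g, and Bonferroni
correction over the 5 bands (0.05/5 = 0.01).  Clinical response is a
≥50% drop in HDRS-17 at 6 months.

See `docs/methods.md` for the full model, parameter defaults, and
design rationale.

## Worked example

Generate a ground-truth synthetic cycle in which stimulation halves
the theta amplitude, run the full measurement chain, and recover the
effect:

```python
import scclfp as s

spec = s.SyntheticCycleSpec(
    post_multipliers={"delta": 1, "theta": 0.5, "alpha": 1, "beta": 1, "gamma": 1},
    seed=2,
)
syn  = s.synthesize_cycle(spec)                       # 8-ch, 5-min cycle
rec  = s.preprocess_recording(syn.recording)          # 1-50 Hz, 128 Hz
diff = s.derive_differential(rec, "L2", syn.artifacts)  # L1 - L3
pair = s.extract_epoch_pair(diff, syn.cycle)          # 1-min pre/post
res  = s.analyze_cycle(pair, s.SpectralConfig(n_boot=500, seed=1))
for band, value in res.band_change.as_dict().items():
    print(f"{band:>6}: {value:+.3f}")
```

Output:

```
 delta: +0.003
 theta: -0.444
 alpha: -0.031
  beta: +0.001
 gamma: +0.000
```

The injected theta multiplier 0.5 is recovered as a band change of
≈ −0.44 (truth −0.5, slightly diluted by background noise and band
leakage); the unperturbed bands stay near 0.

A whole cohort, from the shell:

```bash
scclfp synthesize data/ --seed 1          # 14 patients, EDF+ + sidecars
scclfp describe data/                     # 896 epochs (14 x 8 x 4 x 2)
scclfp run data/ out/ --n-boot 500        # band_changes.tsv, test_table.tsv,
                                          # clinical_summary.json, report.json
```

`examples/` contains short narrative scripts, one per capability
(EDF round-tripping, preprocessing, the bootstrap spectral measure,
exact statistics, clinical summaries, and the full pipeline).

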