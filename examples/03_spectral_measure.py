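"""The bootstrapped relative-change spectral measure on ground truth.

Synthesizes one stimulation cycle whose theta amplitude is halved
after stimulation, then recovers the effect as a band-limited change.
"""

import scclfp as s

spec = s.SyntheticCycleSpec(
    post_multipliers={"delta": 1, "theta": 0.5, "alpha": 1, "beta": 1, "gamma": 1},
    seed=2,
)
syn = s.synthesize_cycle(spec)
rec = s.preprocess_recording(syn.recording)
diff = s.derive_differential(rec, "L2", syn.artifacts)
pair = s.extract_epoch_pair(diff, syn.cycle)
res = s.analyze_cycle(pair, s.SpectralConfig(n_boot=500, seed=1))

print("band   change   truth")
for band, value in res.band_change.as_dict().items():
    print(f"{band:>5}  {value:+.3f}   {syn.truth['amplitude'][band]:+.2f}")
# A value of -0.5 means the post-stimulation median CWT magnitude is
# half the pre-stimulation one.  The theta estimate is slightly diluted
# toward zero by background noise; unperturbed bands sit near 0.
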