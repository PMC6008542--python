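"""Signal conditioning: filter, decimate, prune, difference, epoch.

A 10 Hz rhythm plus slow drift and an injected artifact transit the
whole conditioning chain; the printout shows what each stage did.
"""

import numpy as np

import scclfp as s

fs = 1024.0
t = np.arange(400 * int(fs)) / fs
base = 8 * np.sin(2 * np.pi * 10 * t) + 60 * np.sin(2 * np.pi * 0.05 * t)
samples = np.vstack([base + np.random.default_rng(i).normal(0, 2, len(t))
                     for i in range(8)])
samples[0, int(70 * fs): int(71 * fs)] += 200.0  # 1 s artifact on L1
rec = s.LfpRecording("demo", ["L1", "L2", "L3", "L4", "R1", "R2", "R3", "R4"],
                     fs, samples)

clean = s.preprocess_recording(rec)            # 1-50 Hz zero phase, 128 Hz
found = s.detect_artifacts(rec.samples[0], fs, channel="L1")
print(f"decimated: {rec.rate_hz:.0f} Hz -> {clean.rate_hz:.0f} Hz "
      f"({clean.samples.shape[1]} samples for {clean.duration_s:.0f} s)")
print(f"detector found {len(found)} artifact(s): "
      + ", ".join(f"[{a.start_s:.2f}, {a.end_s:.2f}) s on {a.channel}" for a in found))

diff = s.derive_differential(clean, "L2", found)
cycle = s.CycleMetadata("demo", "L2", "L", "effective", 100.0, 280.0)
pair = s.extract_epoch_pair(diff, cycle)
print(f"differential: {diff.minuend} - {diff.subtrahend} around L2")
print(f"pre epoch: {len(pair.pre)} samples retained "
      f"(lost fraction {pair.lost_fraction_pre:.3f} to the artifact)")
print(f"post epoch: {len(pair.post)} samples retained "
      f"(lost fraction {pair.lost_fraction_post:.3f})")
# The artifact at 70-71 s falls inside the pre window [40, 100) and on a
# flanking contact (L1), so those 128 samples are discarded, not blanked.
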