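"""Simulate one experience-sampling EEG session and inspect its structure.

Builds a SART session (12 blocks x 135 trials, 54 thought probes 7-24 trials
apart), draws a latent mind-wandering/on-task state sequence, and renders
stimulus-locked epochs for the six trials preceding each probe.
"""

import numpy as np

from mweeg import synth

gen = synth.GenParams(mw_rate=0.4)
epochs, probes, design = synth.simulate_session("SART", gen, seed=1,
                                                epochs_for="labeled")

gaps = np.diff(np.concatenate([[-1], design.probe_positions]))
print(f"session: {design.n_trials} trials in {design.n_blocks} blocks, "
      f"{design.n_probes} probes (gaps {gaps.min()}-{gaps.max()} trials)")
print(f"epochs rendered: {epochs.n_trials} trials x {len(epochs.channels)} "
      f"channels x {epochs.n_samples} samples "
      f"({epochs.time_ms[0]:.0f}..{epochs.time_ms[-1]:.0f} ms at {epochs.fs:.0f} Hz)")

mw_probes = sum(p.response in (3, 5) for p in probes)
excluded = sum(p.response in (4, 6) for p in probes)
print(f"probe reports: {mw_probes} mind-wandering, "
      f"{design.n_probes - mw_probes - excluded} on-task, {excluded} excluded")
print("-> each kept probe labels its six preceding trials; the excluded "
      "reports (external distraction / blank) label nothing")
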