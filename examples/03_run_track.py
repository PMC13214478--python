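"""Run one adaptive SRT track against a virtual listener.

The staircase starts the first sentence at 0 dB SNR (escalating in 5 dB
steps until it is repeated completely correctly), then moves down after
correct and up after incorrect responses with 5 / 2 / 1 dB steps across
the three phases.  The SRT is the mean nominal SNR of the phase-2 and
phase-3 presentations.
"""

import numpy as np
import pandas as pd

import srtkit as sk

rng_list = np.random.default_rng(0)
midpoints = rng_list.normal(-4.8, 1.6, 20)
reference = midpoints.mean()
sentences = pd.DataFrame(
    {
        "sentence_id": np.arange(1, 21),
        "midpoint_db": midpoints,
        "slope_pct_per_db": 18.5,
        "offset_db": midpoints - reference,
    }
)

listener = sk.VirtualListener(listener_id=1, srt_shift_db=0.0)
rng = np.random.default_rng(np.random.SeedSequence([3, 1]))
track = sk.simulate_track(sentences, listener, rng)
srt, se = sk.compute_srt(track)

log = track.to_frame()
print(log[["index", "sentence_id", "phase", "nominal_snr_db",
           "k_correct", "correct"]].to_string(index=False))
print()
print(f"SRT = {srt:.2f} dB SNR (SE {se:.2f} dB), "
      f"{len(track.scored(phases=(2, 3)))} phase-2/3 presentations")
print(f"listener's true 50% point: {reference:.2f} dB SNR")
print()
print("The SRT estimates the SNR at which the listener repeats half the")
print("keywords correctly; it should sit near the true 50% point above.")
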