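"""Localize place-restricted sensory damage from DP-gram changes.

Two-tone stimuli (f2/f1 = 1.25, L1 = L2 = 60 dB SPL) evoke 2f1-f2
distortion products measurable as ear-canal DPOAEs and as eCochG-DPs at
the round-window and vertex electrodes.  Damage confined to the 4-kHz
cochlear place (intense-tone exposure) carves a notch into the DP-gram
centered where 2f1-f2 meets the damaged place.
"""

import numpy as np

from ecochg import preset, dp_sweep, dp_change, localize_notch
from ecochg.spectral import AnalysisError

model, healthy = preset("healthy")
_, notch = preset("notch_4khz")

pre = dp_sweep(model, healthy, seed=11)
post = dp_sweep(model, notch, seed=12)
profile = dp_change(pre, post)

print("f2 (Hz)   2f1-f2 (Hz)   change RW (dB)   change remote (dB)")
for f2, fdp, rw, rem in zip(profile.f2, profile.f_dp,
                            profile.change_db["rw"],
                            profile.change_db["remote"]):
    print(f"{f2:7.0f}   {fdp:9.0f}   {rw:+14.1f}   {rem:+16.1f}")

for ch in ("rw", "remote", "ecp"):
    try:
        loc = localize_notch(profile, ch)
        print(f"{ch:6s}: notch at 2f1-f2 = {loc.center_dp_hz:.0f} Hz "
              f"({np.log2(loc.center_dp_hz / 4000):+.2f} oct re 4 kHz), "
              f"depth {loc.depth_db:.1f} dB, width {loc.width_oct:.2f} oct")
    except AnalysisError as exc:
        print(f"{ch:6s}: {exc}")
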