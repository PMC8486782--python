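"""Classify sensory vs neural hearing loss from low-frequency I/O curves.

A healthy low-frequency I/O curve has a shallow (compressive, neural)
segment below ~60 dB SPL and a steep (1 dB/dB, sensory) segment above.
Fitting the magnitude-sum of those two components before and after damage
separates neural loss (compressive gain drops, high levels untouched)
from sensory loss (whole curve shifts down, shallow tail more prominent).
"""

import numpy as np
from dataclasses import replace

from ecochg import preset, io_curve, io_slopes, fit_two_component, classify_loss

model, _ = preset("healthy")
quiet = replace(model, ecp_noise_pa=0.0, rw_noise_v=0.0, remote_noise_v=0.0)
levels = np.arange(30.0, 91.0, 10.0)

fits = {}
for name in ("healthy", "ka", "broadband_trauma"):
    _, damage = preset(name)
    curve = io_curve(quiet, damage, 1000.0, levels)
    mid, slopes = io_slopes(curve)
    fits[name] = fit_two_component(curve)
    print(f"{name}: slopes (dB/dB) at {mid.astype(int).tolist()} dB SPL = "
          f"{np.round(slopes, 2).tolist()}")
    f = fits[name]
    print(f"  fit: sensory gain {f.g_sensory:7.1f} dB, neural gain "
          f"{f.g_neural:7.1f} dB, exponent {f.c_neural:.2f}, "
          f"breakpoint {f.breakpoint_db_spl:6.1f} dB SPL"
          + (" (extrapolated)" if f.extrapolated else ""))

for name in ("ka", "broadband_trauma"):
    cl = classify_loss(fits["healthy"], fits[name])
    print(f"{name} vs healthy -> {cl.label}  "
          f"(sensory loss {cl.delta_g_sensory:+.1f} dB, "
          f"neural loss {cl.delta_g_neural:+.1f} dB)")
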