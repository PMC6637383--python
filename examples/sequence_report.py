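"""Build the three diffusion encodings and report their characteristics.

The b-value measures diffusion weighting; the protocol targets
450 s/mm^2 for PGSE and STEAM with two scanner axes driven at G_max.
The motion-compensated spin echo additionally nulls the first and
second gradient moments, making it insensitive to constant velocity
and acceleration (its residuals should print as ~1e-10 or smaller).
"""

import numpy as np

from myowalk import build_waveform, bvalue, moments, table1_spec

for kind in ("PGSE", "M2SE", "STEAM"):
    spec = table1_spec(kind, 40)
    wave = build_waveform(spec)
    b, bmat = bvalue(wave)
    m = moments(wave)
    scale = np.max(np.abs(wave.g)) * wave.total_time ** np.arange(1, 4)
    rel = [np.linalg.norm(m[k]) / scale[k] for k in range(3)]
    print(f"{kind:6s} G={spec.g_max:6.2f} mT/m  TE={spec.te:6.2f} ms  "
          f"T={wave.total_time:8.2f} ms  b={b:6.1f} s/mm^2  "
          f"|m0|,|m1|,|m2| rel = {rel[0]:.1e}, {rel[1]:.1e}, {rel[2]:.1e}")
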