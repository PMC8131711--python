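"""Build a calibrated stimulus and verify the contrast parameterization.

A synthetic 'photograph' is standardized, smoothed, edge-windowed, rescaled
to [-1, 1] and mapped to display intensities I(c) = b (I_scaled c + 1)
around the background b = 127.  The displayed contrast c = (Imax - Imin)/2b
is exactly recoverable from the pixels.  A phase-scrambled counterpart keeps
the amplitude spectrum (category-specific low-level features) but destroys
the object.
"""

import numpy as np

from liminal import stimgen

rng = np.random.default_rng(0)

raw = stimgen.synthetic_photo("house", size=300, rng=rng)
for c in (0.1, 0.5, 1.0):
    stim = stimgen.make_stimulus(raw, c)
    print(
        f"requested contrast {c:4.2f}: pixel range "
        f"[{stim.pixels.min():6.1f}, {stim.pixels.max():6.1f}], "
        f"measured contrast {stimgen.measure_contrast(stim.pixels):.4f}"
    )

scrambled = stimgen.make_stimulus(raw, 0.5, scramble=True, rng=rng)
print(
    "\nscrambled stimulus: measured contrast "
    f"{stimgen.measure_contrast(scrambled.pixels):.4f} "
    "(same contrast as its real counterpart by construction)"
)
# the round-trip numbers above show Eq. I(c)=b(I_scaled c+1) and its inverse
# agree to machine precision; the scrambled image is display-matched.
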