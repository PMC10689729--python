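"""Build the three binary blocks of an LMFD descriptor by hand.

Takes a single 5x5 patch, computes the symbolic (centre-vs-surround),
mean (window-mean) and centroid (intensity-centroid) blocks, and shows
how they concatenate into the 90-bit descriptor.
"""

import numpy as np

from lmfd import (DescriptorParams, centroid_descriptor, combine, decompose,
                  mean_descriptor, reconstruct, symbolic_descriptor)

# the sign/magnitude split of a difference vector round-trips exactly
d = np.array([-70, -133, 23, 11, -48, -125, 121, 78,
              32, -31, -113, 108, -57, -80, 69, 12])
s, m = decompose(d)
print("sign vector     :", s.tolist())
print("magnitude vector:", m.tolist())
print("round trip exact:", bool((reconstruct(s, m) == d).all()))

rng = np.random.default_rng(0)
patch = rng.integers(0, 256, (5, 5)).astype(np.uint8)
print("\npatch:\n", patch)

S = symbolic_descriptor(patch, kz=1)     # 9 windows x 8 comparison bits
M = mean_descriptor(patch, kz=1)         # 9 window-mean bits
C = centroid_descriptor(patch, kz=1, image_mean=128.0)  # 9 centroid bits
print("\nsymbolic block (72 bits):", S.astype(int))
print("mean block      (9 bits):", M.astype(int))
print("centroid block  (9 bits):", C.astype(int))

bits = combine(S, M, C, order="MSC")
params = DescriptorParams()              # r=3, kz=1, ps=5, MSC
print(f"\ncombined MSC descriptor: {bits.size} bits "
      f"(= bit_width {params.bit_width}), popcount {int(bits.sum())}")
# The popcount is order-independent; only the bit positions move between
# the six combination orders.
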