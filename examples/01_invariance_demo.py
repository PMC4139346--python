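"""Gray-level invariance: one subject, five simulated scanners.

Renders the same phantom subject under five different scanner transforms
(gamma + gain) and shows that raw intensities diverge wildly while the
LBP-TOP code maps are bit-identical.

Run:  python examples/01_invariance_demo.py
"""

import numpy as np

from lbpbrain import PhantomCohortSpec, lbp_top, make_subject

spec = PhantomCohortSpec(noise_sigma=0.0, seed=0)  # noise off: exact demo
scanners = [(0.5, 0.3), (0.8, 1.0), (1.0, 2.0), (1.4, 0.6), (2.0, 3.5)]

reference = None
print(f"{'gamma':>6} {'gain':>6} {'GM mean intensity':>18} {'codes identical':>16}")
for gamma, gain in scanners:
    vol, labels = make_subject(spec, +1, subject_seed=42, gamma=gamma, gain=gain)
    gm_mean = vol.data[labels == 2].mean()
    maps = lbp_top(vol.data)
    if reference is None:
        reference = maps
        same = True
    else:
        same = all(np.array_equal(a, b)
                   for a, b in zip(reference.planes, maps.planes))
    print(f"{gamma:>6.2f} {gain:>6.2f} {gm_mean:>18.4f} {str(same):>16}")

print("\nRaw gray-matter intensities differ by an order of magnitude "
      "across scanners, yet every LBP-TOP code map is bit-identical: the "
      "codes depend only on intensity orderings, which every (strictly "
      "increasing) scanner transform preserves.")
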