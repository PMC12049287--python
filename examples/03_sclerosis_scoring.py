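"""Sclerosis scoring on synthetic distal-slice images.

The cut surface is modelled as two Gaussian grey populations (spongious
bone around 120, sclerotic bone around 280, noise sd 15). The score puts
the cut-off at the upper third of the in-mask grey range, after checking
that the slice actually shows two populations.
"""

import numpy as np

from resectfit import make_sclerosis_slice, score_slice

print("true%   recovered%   threshold")
for i, fraction in enumerate([0.0, 0.1, 0.2, 0.3]):
    grey, mask, true_f = make_sclerosis_slice(fraction, seed=40 + i)
    result = score_slice(grey, mask)
    print(f"{100 * true_f:5.1f}   {result.percentage:9.1f}   "
          f"{result.threshold:9.1f}")

# affine grey rescaling (e.g. a different scanner calibration) does not
# change the score: the rule is range-relative
grey, mask, true_f = make_sclerosis_slice(0.2, seed=44)
a = score_slice(grey, mask).percentage
b = score_slice(grey * 3.0 + 500.0, mask).percentage
print(f"\naffine invariance: {a:.2f}% == {b:.2f}% -> {np.isclose(a, b)}")
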