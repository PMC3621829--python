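"""Screen autofocus probe strips with the three-criterion validity filter.

A focus point is only usable if its probe image shows in-focus cellular
material.  Each strip passes through a size filter (an object at least
as large as a small nucleus, 200 px), an edge filter (Canny, high
threshold 0.07, sigma 1.41: blurred strips have no edges), and a color
filter (at least 10 object pixels in one of the four stain HSV classes:
dust is achromatic and fails).
"""

from collections import Counter

import cytofocus as cf
from cytofocus.focus_filters import FocusPointImage, classify_focus_point

strips = cf.make_validation_strips(40, seed=7)

outcomes = Counter()
for img, truth in strips:
    verdict = classify_focus_point(FocusPointImage(img))
    outcomes[(truth, verdict.valid)] += 1

tp = outcomes[(True, True)]
tn = outcomes[(False, False)]
fp = outcomes[(False, True)]
fn = outcomes[(True, False)]
print(f"strips: {len(strips)} (half valid by construction)")
print(f"agree on valid:   {tp}")
print(f"agree on invalid: {tn}")
print(f"disagreements:    {fp + fn}")
print(f"accuracy: {100 * (tp + tn) / len(strips):.1f}%")
print("Valid means all three filters passed; blank, dust-focused and "
      "defocused strips fail at least one.")
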