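"""Categorization is blind to monotone transforms of the logits.

Applies increasing maps (signed square, cube, exp, affine) to random logit
vectors and counts Top-1/Top-3 agreement with the originals: always 100%.
A decreasing control map breaks agreement, showing the check is not
vacuous.
"""

import numpy as np

from repnonuniq import apply_transform, categorization_agreement

rng = np.random.default_rng(0)
X = rng.normal(size=(5000, 10)) * 3

for fname in ("signed_square", "cube", "exp", "affine"):
    Y = apply_transform(fname, X)
    a1 = np.mean([categorization_agreement(x, y, 1) for x, y in zip(X, Y)])
    a3 = np.mean([categorization_agreement(x, y, 3) for x, y in zip(X, Y)])
    print(f"f={fname:13s} top-1 agreement {a1:.1%}, top-3 agreement {a3:.1%}")

neg = np.mean([categorization_agreement(x, -x, 1) for x in X])
print(f"control f(x)=-x   top-1 agreement {neg:.1%}")
# 100% for every increasing f: a softmax classifier's behavior cannot
# distinguish logit vectors related by a monotone map, which is what
# makes the penultimate representation non-unique.
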