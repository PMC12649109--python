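"""Worked example of the composite training objective.

A 16-pixel image with 4 positive pixels and a uniform 0.5 prediction is
small enough to evaluate every term by hand: soft counts TP=2, FP=6,
FN=2 give Tversky 1 - 2/5.2, BCE is ln 2, and the weighted combinations
follow exactly.
"""

import numpy as np

from clinsegnet.losses import (bce_loss, histo_loss, total_loss, tversky_loss)

target = np.zeros((1, 1, 4, 4))
target.flat[:4] = 1.0
pred = np.full((1, 1, 4, 4), 0.5)

print(f"BCE       : {bce_loss(pred, target).item():.4f}   (= ln 2)")
print(f"Tversky   : {tversky_loss(pred, target).item():.4f}   "
      "(= 1 - 2/(2 + 0.3*6 + 0.7*2))")
print(f"HistoLoss : {histo_loss(pred, target).item():.4f}   "
      "(= 0.3*BCE + 0.7*Tversky)")
total, comps = total_loss(pred, pred, target)
print(f"Total     : {total.item():.4f}   (= HistoLoss + 0.4 * edge BCE)")
print(f"components: { {k: round(v, 4) for k, v in comps.items()} }")
# The 0.7 false-negative weight is what tilts optimisation toward recall:
# a missed lesion pixel costs more than a false alarm of the same size.
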