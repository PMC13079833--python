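"""Dice and Hausdorff evaluation of label maps, including edge conventions.

Shows the per-class decomposition, the not-applicable convention for empty
masks, and the 95th-percentile Hausdorff variant.
"""

import numpy as np

from duoseg.metrics import dice_coefficient, evaluate_case, hausdorff_distance

a = np.zeros((32, 32), bool)
a[8:16, 8:16] = True
b = np.roll(a, 3, axis=1)  # same square, shifted 3 px

print("Dice of 3-px-shifted squares     :", round(dice_coefficient(a, b), 4))
print("Hausdorff (max)                  :", hausdorff_distance(a, b))
print("Hausdorff (95th percentile)      :", round(hausdorff_distance(a, b, 95), 3))

gt = np.zeros((32, 32), dtype=int)
gt[4:10, 4:10] = 1
gt[20:26, 20:26] = 2
pred = gt.copy()
pred[20:26, 20:26] = 0  # class 2 entirely missed
cm = evaluate_case(pred, gt, num_classes=4)
print("\nper-class Dice      :", np.round(cm.dice, 3))
print("per-class Hausdorff :", cm.hausdorff)
print("mean foreground Dice:", round(cm.mean_dice, 3))
# Class 3 appears in neither map: it is excluded from the mean (nan above),
# not counted as 0. Class 2's Hausdorff is undefined (empty prediction) and
# likewise excluded, while its Dice of 0 does count.
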