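"""Capacity accounting: parameters and analytic forward cost of the network.

Parameter counts are exact sums of weight-tensor sizes; the MAC count is
accumulated analytically inside the conv/matmul primitives during one
profiling forward pass (one fused multiply-add = one operation).
"""

from duoseg.model import build_model
from duoseg.summary import model_summary

tiny = build_model(encoder_variant="tiny", num_classes=4, seed=0)
print("== tiny variant (desk-scale testing) at 64x64 ==")
print(model_summary(tiny, input_size=64))

full = build_model(encoder_variant="b2", num_classes=7, seed=0)
print("\n== full model (b2 encoder, 7 classes) at 256x256 ==")
print(model_summary(full, input_size=256))
# The encoder dominates the parameter budget; the decoders dominate nothing
# in parameters but contribute a large share of the MACs because they work
# at strides 4-8 rather than 16-32.
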