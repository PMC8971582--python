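"""Segment the synthetic glioma-like phantom and score it against ground truth.

Builds the 128x128 core+annulus phantom (bright core 9, enhancing ring 6,
background 1 on the (0, 10) scale), runs the BEC-kernel SVM pipeline at the
reference operating point (T, mu) = (6, 3), and prints precision, recall and
F-measure.  On the noiseless phantom recovery is exact; with pixel noise
sd 0.3 the F-measure stays above 0.95.
"""

from becseg import KernelParams, evaluate_masks, segment
from becseg.synthdata import PHANTOM_PRESETS, make_phantom

params = KernelParams(T=6.0, mu=3.0)

for name in ("default", "noisy"):
    image, truth = make_phantom(PHANTOM_PRESETS[name])
    result = segment(image, params)
    rep = evaluate_masks(result.mask, truth)
    print(f"{name:8s} phantom: P={rep.precision:.4f} R={rep.recall:.4f} "
          f"F={rep.f_measure:.4f}  "
          f"({int(result.mask.sum())} px predicted tumor, "
          f"{int(truth.sum())} px true)")

print("\nP is the purity of the predicted tumor region, R the fraction of the")
print("true tumor retrieved, and F their harmonic mean 2PR/(P+R).")
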