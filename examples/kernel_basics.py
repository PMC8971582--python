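"""Evaluate the BEC kernel and its Gaussian baseline at a few arguments.

The BEC kernel 1/(exp(a / (1.38 T)) - 1) is the Bose-Einstein occupation
number of the shifted pixel distance a = ||x1 - x2 - mu||.  For T > 0 it
decays monotonically from a capped singularity at a = 0; for T < 0 every
off-singularity value is <= -1.
"""

import numpy as np

from becseg import GaussianParams, KernelParams, bec_kernel_value, gaussian_kernel_value

bec = KernelParams(T=1.0, mu=0.0)
print("BEC kernel, T=1, mu=0:")
for a in (0.0, 0.5, 1.38, 5.0, 20.0):
    print(f"  a={a:5.2f}  ->  {bec_kernel_value(a, bec):.6g}")
print("  (a=0 hits the singularity exp(0)-1=0 and is capped at 1e6;")
print("   a=1.38 gives exactly 1/(e-1) = 0.581977...)")

cold = KernelParams(T=-1.0)
print("\nNegative temperature, T=-1: values lie at or below -1")
for a in (0.5, 1.38, 5.0):
    print(f"  a={a:5.2f}  ->  {bec_kernel_value(a, cold):.6f}")

gauss = GaussianParams(sigma=0.125)
print("\nGaussian baseline, sigma=0.125 (exp(-a^2 / 2 sigma^2)):")
for a in (0.0, 0.125, 0.5):
    print(f"  a={a:5.3f}  ->  {gaussian_kernel_value(a, gauss):.6f}")

# only the product kb_scale * T matters
v1 = bec_kernel_value(2.0, KernelParams(T=3.0, kb_scale=1.38))
v2 = bec_kernel_value(2.0, KernelParams(T=6.0, kb_scale=0.69))
print(f"\nScale law: (T=3, kb=1.38) -> {v1:.12f}; (T=6, kb=0.69) -> {v2:.12f}")
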