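"""Sweep the kernel hyperparameters (T, mu) on a noisy phantom.

Runs the full pipeline at every cell of a T x mu grid (same RNG seed per
cell, so cells differ only through the kernel), tabulates P/R/F, and selects
the max-F cell with a deterministic tie cascade.
"""

from becseg import SegmenterConfig, SweepGrid, best_params, run_sweep
from becseg.sweep import mu_symmetry_gap
from becseg.synthdata import PHANTOM_PRESETS, make_phantom

image, truth = make_phantom(PHANTOM_PRESETS["small-noisy"])
grid = SweepGrid(T_values=(-6, -2, 1, 2, 6), mu_values=(0, 1, 3, 6))
config = SegmenterConfig(max_train_pixels=600)

table = run_sweep(image, truth, grid, config)

print(f"{'T':>4} {'mu':>4} {'P':>8} {'R':>8} {'F':>8}")
for cell in table.cells:
    r = cell.report
    print(f"{cell.T:4g} {cell.mu:4g} {r.precision:8.4f} {r.recall:8.4f} "
          f"{r.f_measure:8.4f}")

t, mu = best_params(table)
print(f"\nbest cell: T={t:g}, mu={mu:g} (max F; ties -> higher P, smaller |T|,"
      f" smaller |mu|)")
print(f"mu sign-symmetry diagnostic max|F(mu)-F(-mu)|: "
      f"{mu_symmetry_gap(table):.4f}")
print("\nCells with mu=0 collapse: the literal argument |x1-x2-mu| then peaks")
print("at identical intensities only, and the capped similarity spikes of the")
print("Gram dominate; a moderate positive mu separates core, ring and")
print("background differences.")
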