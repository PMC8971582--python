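"""Grid sweep of the kernel hyperparameters (T, mu) with per-cell P/R/F.

Each grid cell re-runs the full segmentation pipeline with the same RNG seed,
so cells differ only through the kernel parameters.  "Best" is the max-F cell
with an explicit, order-independent tie cascade: higher precision, then
smaller |T|, then smaller |mu|, then canonical grid order (T-major).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from becseg.kernel import KernelParams
from becseg.metrics import MetricsReport, evaluate_masks, round_display
from becseg.segment import SegmenterConfig, segment

__all__ = [
    "SweepGrid",
    "SweepCell",
    "SweepTable",
    "run_sweep",
    "best_params",
    "export_table",
    "load_table",
    "mu_symmetry_gap",
]


def _default_T():
    return tuple(t for t in range(-10, 11) if t != 0)


def _default_mu():
    return tuple(range(-10, 11))


@dataclass(frozen=True)
class SweepGrid:
    """T x mu grid; T = 0 is rejected (the kernel is undefined there).

    Defaults cover the integer grid -10..10 on both axes (T without 0); pass
    ``include_mu_endpoint=True`` to ``with_mu_endpoint`` helpers or extend
    ``mu_values`` with 6.7, the upper end of the suggested chemical-potential
    range.
    """

    T_values: tuple[float, ...] = field(default_factory=_default_T)
    mu_values: tuple[float, ...] = field(default_factory=_default_mu)

    def __post_init__(self) -> None:
        if not self.T_values or not self.mu_values:
            raise ValueError("grid axes must be nonempty")
        if any(t == 0 for t in self.T_values):
            raise ValueError("T = 0 is not a valid grid point (kernel undefined)")

    def cells(self):
        """Canonical iteration order: T-major, mu-minor, with flat index."""
        k = 0
        for t in self.T_values:
            for m in self.mu_values:
                yield k, t, m
                k += 1


@dataclass
class SweepCell:
    T: float
    mu: float
    grid_index: int
    report: MetricsReport | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.report is not None


@dataclass
class SweepTable:
    cells: list[SweepCell]
    grid: SweepGrid
    config: SegmenterConfig


def run_sweep(
    image,
    truth_mask,
    grid: SweepGrid,
    config: SegmenterConfig = SegmenterConfig(),
    params_template: KernelParams | None = None,
) -> SweepTable:
    """Segment and evaluate at every (T, mu); failed cells are recorded, not fatal."""
    truth = np.asarray(truth_mask)
    if truth.shape != np.asarray(image).shape:
        raise ValueError("truth mask and image shapes differ")
    template = params_template if params_template is not None else KernelParams(T=1.0)
    cells = []
    for k, t, m in grid.cells():
        cell = SweepCell(T=t, mu=m, grid_index=k)
        try:
            params = replace(template, T=t, mu=m)
            result = segment(image, params, config)
            cell.report = evaluate_masks(result.mask, truth)
        except (ValueError, ArithmeticError) as exc:
            cell.error = str(exc)
        cells.append(cell)
    return SweepTable(cells=cells, grid=grid, config=config)


def best_params(table: SweepTable) -> tuple[float, float]:
    """Max-F cell under the tie cascade; independent of cell list order."""
    ok = [c for c in table.cells if c.ok]
    if not ok:
        raise ValueError("all sweep cells failed; nothing to select")
    best = min(
        ok,
        key=lambda c: (
            -c.report.f_measure,
            -c.report.precision,
            abs(c.T),
            abs(c.mu),
            c.grid_index,
        ),
    )
    return best.T, best.mu


def _frame(table: SweepTable) -> pd.DataFrame:
    rows = []
    for c in sorted(table.cells, key=lambda c: c.grid_index):
        if c.ok:
            p, r, f = c.report.precision, c.report.recall, c.report.f_measure
        else:
            p = r = f = np.nan
        rows.append({
            "T": c.T, "mu": c.mu,
            "P": np.nan if np.isnan(p) else round_display(p),
            "R": np.nan if np.isnan(r) else round_display(r),
            "F": np.nan if np.isnan(f) else round_display(f),
            "P_full": p, "R_full": r, "F_full": f,
            "error": c.error or "",
        })
    return pd.DataFrame(rows)


def export_table(table: SweepTable, path) -> None:
    """One CSV row per cell: display columns at 4 decimals plus full-precision
    companions so the unrounded values reload losslessly."""
    _frame(table).to_csv(path, index=False, float_format="%.17g")


def load_table(path) -> pd.DataFrame:
    """Reload an exported sweep table (full-precision columns intact)."""
    return pd.read_csv(path)


def mu_symmetry_gap(table: SweepTable) -> float:
    """Diagnostic: max |F(T, mu) - F(T, -mu)| over cells with both signs present.

    The positive/negative chemical-potential symmetry is an empirical
    observation, not an identity, so it is reported rather than asserted.
    """
    by_key = {(c.T, c.mu): c.report.f_measure for c in table.cells if c.ok}
    gaps = [
        abs(f - by_key[(t, -m)])
        for (t, m), f in by_key.items()
        if m > 0 and (t, -m) in by_key
    ]
    return max(gaps, default=0.0)
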