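"""Tabular I/O: protocol tables and result tables.

Protocol tables are delimited text files with a time column (minutes) and a
power column (watts).  They are turned into either a piecewise-constant
interpolant (the default; matches stepped exercise bouts, with the value
jumping at each tabulated time) or a cubic spline.  Evaluation outside the
tabulated domain clamps to the boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ProtocolTable", "load_protocol_table", "write_results"]


@dataclass
class ProtocolTable:
    """Callable interpolant over a (time, power) table."""

    times: np.ndarray
    powers: np.ndarray
    mode: str = "step"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if self.mode not in ("step", "spline"):
            raise ValueError("mode must be 'step' or 'spline'")
        if len(self.times) == 0:
            raise ValueError("protocol table is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time column must be strictly increasing")
        if self.mode == "spline" and len(self.times) >= 2:
            from scipy.interpolate import CubicSpline

            self._spline = CubicSpline(self.times, self.powers)
        else:
            self._spline = None

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def __call__(self, t: float) -> float:
        t = float(np.clip(t, self.times[0], self.times[-1]))
        if self._spline is not None:
            return float(self._spline(t))
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.powers[max(i, 0)])


def load_protocol_table(path, mode: str = "step", time_col: str = "time",
                        power_col: str = "power") -> ProtocolTable:
    """Read a delimited (CSV/TSV) protocol table into an interpolant.

    Raises on a missing time/power column or a non-monotone time column.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (time_col, power_col):
        if col not in df.columns:
            raise ValueError(
                f"protocol table lacks column {col!r}; has {list(df.columns)}"
            )
    return ProtocolTable(df[time_col].to_numpy(), df[power_col].to_numpy(), mode)


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table (time plus one column per observable) as CSV."""
    df.to_csv(path, index=False)
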