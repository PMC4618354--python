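"""Binned pulse profiles: the experimental observable.

A transport experiment ends with the stem cut into short segments (classically
2 mm) and the label in each segment counted. A :class:`PulseProfile` is one
such binned amount-vs-position profile at one transport time. Profiles
round-trip through a simple delimited-text format (columns ``time_s``,
``position_mm``, ``amount``) shared by the simulator, the synthetic-data
generator and the fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PulseProfile", "read_profiles", "write_profiles"]


@dataclass
class PulseProfile:
    """Amounts of auxin per segment bin along the stem at one time point."""

    positions_mm: np.ndarray  # bin midpoints, mm from the apical end
    amounts: np.ndarray
    time_hr: float = 0.0
    bin_width_mm: float = 2.0

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.positions_mm.shape != self.amounts.shape:
            raise ValueError("positions and amounts must have the same shape")
        if self.bin_width_mm <= 0:
            raise ValueError("bin width must be > 0")

    def __len__(self) -> int:
        return self.positions_mm.size

    @property
    def total(self) -> float:
        return float(self.amounts.sum())

    def moments(self) -> tuple[float, float]:
        """Amount-weighted (mean, variance) over bin midpoints, in mm / mm^2."""
        total = self.total
        if total <= 0:
            raise ValueError("profile has zero total amount")
        w = self.amounts / total
        mean = float(np.dot(w, self.positions_mm))
        var = float(np.dot(w, (self.positions_mm - mean) ** 2))
        return mean, var

    def scaled(self, factor: float) -> "PulseProfile":
        return PulseProfile(
            self.positions_mm.copy(),
            self.amounts * factor,
            time_hr=self.time_hr,
            bin_width_mm=self.bin_width_mm,
        )


def write_profiles(path, profiles: list[PulseProfile]) -> None:
    """Write profiles as TSV with columns time_s, position_mm, amount."""
    frames = []
    for prof in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": prof.time_hr * 3600.0,
                    "position_mm": prof.positions_mm,
                    "amount": prof.amounts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[PulseProfile]:
    """Read profiles from delimited text (TSV/CSV/whitespace).

    Requires ``position_mm`` and ``amount`` columns; an absent ``time_s``
    column means a single profile at time zero.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "position_mm" not in df.columns or "amount" not in df.columns:
        raise ValueError("profile file needs 'position_mm' and 'amount' columns")
    if "time_s" not in df.columns:
        df = df.assign(time_s=0.0)
    out = []
    for t, grp in df.groupby("time_s", sort=True):
        pos = grp["position_mm"].to_numpy(dtype=float)
        width = float(np.median(np.diff(np.sort(pos)))) if pos.size > 1 else 2.0
        out.append(
            PulseProfile(
                positions_mm=pos,
                amounts=grp["amount"].to_numpy(dtype=float),
                time_hr=float(t) / 3600.0,
                bin_width_mm=width,
            )
        )
    return out
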