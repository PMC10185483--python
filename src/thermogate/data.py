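"""Containers and CSV I/O for open-probability count data.

A gating dataset is a set of per-temperature Bernoulli-trial summaries: at
each temperature (and optionally each holding voltage) the channel was
observed ``n_trials`` times and found open ``n_open`` times. This is the
natural patch-clamp observable behind an empirical P_open(T) curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin

__all__ = ["PopenDataset", "InsufficientDataError"]

#: CSV schema: exactly one temperature column is permitted.
_TEMP_COLUMNS = ("temperature_K", "temperature_C")


class InsufficientDataError(ValueError):
    """Fewer distinct temperatures than the fit requires."""


@dataclass(frozen=True)
class PopenDataset:
    """Per-temperature open/trial counts, the unit of inference.

    Attributes
    ----------
    T : ndarray
        Temperatures in kelvin, one per record.
    n_trials, n_open : ndarray of int
        Trial and open counts per record, 0 <= n_open <= n_trials.
    V : ndarray or None
        Optional holding voltage per record, volts.
    label : str
        Free-form provenance label.
    """

    T: np.ndarray
    n_trials: np.ndarray
    n_open: np.ndarray
    V: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        n_trials = np.asarray(self.n_trials, dtype=int)
        n_open = np.asarray(self.n_open, dtype=int)
        if not (T.shape == n_trials.shape == n_open.shape) or T.ndim != 1:
            raise ValueError("T, n_trials and n_open must be 1-d arrays of equal length")
        if np.any(T <= 0):
            raise ValueError("all temperatures must be positive (kelvin)")
        if np.any(n_trials < 1):
            raise ValueError("n_trials must be >= 1 in every record")
        if np.any(n_open < 0) or np.any(n_open > n_trials):
            raise ValueError("n_open must satisfy 0 <= n_open <= n_trials in every record")
        if self.V is not None:
            V = np.asarray(self.V, dtype=float)
            if V.shape != T.shape:
                raise ValueError("V must match the length of T")
            object.__setattr__(self, "V", V)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "n_trials", n_trials)
        object.__setattr__(self, "n_open", n_open)

    def __len__(self) -> int:
        return self.T.size

    @property
    def proportions(self) -> np.ndarray:
        """Observed open proportions n_open / n_trials."""
        return self.n_open / self.n_trials

    @property
    def n_distinct_temperatures(self) -> int:
        return np.unique(self.T).size

    def require_fittable(self, min_temperatures: int = 3) -> None:
        """Raise :class:`InsufficientDataError` if too few distinct temperatures."""
        if self.n_distinct_temperatures < min_temperatures:
            raise InsufficientDataError(
                f"fitting requires at least {min_temperatures} distinct temperatures, "
                f"got {self.n_distinct_temperatures}"
            )

    def sorted_by_temperature(self) -> "PopenDataset":
        order = np.argsort(self.T, kind="stable")
        return PopenDataset(
            T=self.T[order],
            n_trials=self.n_trials[order],
            n_open=self.n_open[order],
            V=None if self.V is None else self.V[order],
            label=self.label,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"temperature_K": self.T, "n_trials": self.n_trials, "n_open": self.n_open}
        )
        if self.V is not None:
            frame["voltage_mV"] = self.V * 1000.0
        return frame

    def to_csv(self, path: str | Path) -> None:
        """Write the dataset in the package's CSV schema (temperatures in K)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "PopenDataset":
        """Read a dataset from CSV.

        The header must contain ``n_trials``, ``n_open`` and exactly one of
        ``temperature_K`` / ``temperature_C`` (Celsius is converted to kelvin
        on input); ``voltage_mV`` is optional.
        """
        frame = pd.read_csv(path)
        present = [c for c in _TEMP_COLUMNS if c in frame.columns]
        if len(present) != 1:
            raise ValueError(
                f"{path}: exactly one temperature column of {_TEMP_COLUMNS} is required, "
                f"found {present or 'none'}"
            )
        missing = {"n_trials", "n_open"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        temp_col = present[0]
        T = frame[temp_col].to_numpy(dtype=float)
        if temp_col == "temperature_C":
            T = celsius_to_kelvin(T)
        V = None
        if "voltage_mV" in frame.columns:
            V = frame["voltage_mV"].to_numpy(dtype=float) / 1000.0
        return cls(
            T=T,
            n_trials=frame["n_trials"].to_numpy(dtype=int),
            n_open=frame["n_open"].to_numpy(dtype=int),
            V=V,
            label=Path(path).stem if label is None else label,
        )
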