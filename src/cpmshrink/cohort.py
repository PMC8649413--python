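"""Tabular cohort container: predictor matrix plus binary outcome.

A :class:`Cohort` is the universal input unit of the package — every
estimation strategy, performance metric and validation routine consumes
one.  Cohorts round-trip to headered CSV (columns ``x1..xP, y``) so that
development data can be exchanged with other software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Cohort"]


@dataclass
class Cohort:
    """Predictor matrix ``X`` (n x P) with binary outcome vector ``y``.

    Parameters
    ----------
    X
        Real-valued predictor matrix, one row per observation, columns in
        fixed predictor order 1..P.  No missing values are permitted.
    y
        Binary outcome vector in {0, 1}.
    true_lp
        Optional linear predictor under a known generating model
        (``beta0 + X @ beta``); carried through splits for diagnostics.
    """

    X: np.ndarray
    y: np.ndarray
    true_lp: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary in {0, 1}")
        self.y = self.y.astype(float)
        if self.true_lp is not None:
            self.true_lp = np.asarray(self.true_lp, dtype=float)
            if self.true_lp.shape[0] != self.n:
                raise ValueError("true_lp length does not match number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    @property
    def prevalence(self) -> float:
        """Observed outcome proportion mean(y)."""
        return float(self.y.mean())

    def subset(self, idx: np.ndarray) -> "Cohort":
        """Row subset by integer index, preserving ``true_lp`` if present."""
        return Cohort(
            X=self.X[idx],
            y=self.y[idx],
            true_lp=None if self.true_lp is None else self.true_lp[idx],
        )

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{p + 1}": self.X[:, p] for p in range(self.P)}
        cols["y"] = self.y.astype(int)
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        """Write as headered CSV with columns ``x1..xP, y``."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        df = pd.read_csv(path)
        if "y" not in df.columns:
            raise ValueError("cohort CSV must contain a 'y' column")
        xcols = [c for c in df.columns if c.startswith("x")]
        xcols.sort(key=lambda c: int(c[1:]))
        return cls(X=df[xcols].to_numpy(dtype=float), y=df["y"].to_numpy())
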