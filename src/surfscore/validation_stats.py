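"""Small downstream quantitative procedures: Pearson correlation with a
t-based p-value, caliper tumor-volume computation, and percent-of-control
normalization of viability readouts."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from surfscore.errors import ValidationError


@dataclass
class DensitometrySeries:
    """Paired densitometry readouts (arbitrary units) for correlation."""

    labels: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x/y: need equal-length 1-D vectors")
        if len(self.labels) != self.x.size:
            raise ValidationError("labels: one label per observation")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("x/y: values must be finite")


@dataclass
class TumorMeasurement:
    """One caliper reading; L and W auto-ordered so L >= W."""

    L: float
    W: float

    def __post_init__(self) -> None:
        if self.L < 0 or self.W < 0:
            raise ValidationError("L/W: caliper readings must be non-negative")
        if self.W > self.L:
            self.L, self.W = self.W, self.L

    @property
    def V(self) -> float:
        return tumor_volume(self.L, self.W)


def pearson_with_p(series: DensitometrySeries) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p from the exact t transform
    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom."""
    x, y = series.x, series.y
    n = x.size
    if n < 3:
        raise ValidationError("x/y: need n >= 3 for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("x/y: correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def tumor_volume(L: float, W: float) -> float:
    """V = L * W^2 / 2 in mm^3, with (L, W) reordered so L >= W."""
    if L < 0 or W < 0:
        raise ValidationError("L/W: caliper readings must be non-negative")
    if W > L:
        L, W = W, L
    return L * W * W / 2.0


def percent_of_control(values: np.ndarray, control_mean: float) -> np.ndarray:
    """100 * value / control_mean per element."""
    if not control_mean > 0:
        raise ValidationError("control_mean: must be > 0")
    return 100.0 * np.asarray(values, dtype=float) / control_mean


# ---------------------------------------------------------------------------
# TSV conveniences
# ---------------------------------------------------------------------------

def read_densitometry_tsv(path: str | Path) -> DensitometrySeries:
    """Two data columns (x, y) with an optional leading label column."""
    frame = pd.read_csv(path, sep="\t")
    numeric = frame.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise ValidationError(f"{path}: need two numeric columns")
    labels = (
        frame.iloc[:, 0].astype(str).tolist()
        if frame.shape[1] > numeric.shape[1]
        else [str(i) for i in range(len(frame))]
    )
    return DensitometrySeries(
        labels=labels,
        x=numeric.iloc[:, 0].to_numpy(),
        y=numeric.iloc[:, 1].to_numpy(),
    )


def append_volume_column(path: str | Path, out_path: str | Path) -> pd.DataFrame:
    """Read an `L<TAB>W` measurement TSV and append a volume column."""
    frame = pd.read_csv(path, sep="\t")
    if not {"L", "W"} <= set(frame.columns):
        raise ValidationError(f"{path}: expected columns L and W")
    frame["V"] = [tumor_volume(l, w) for l, w in zip(frame["L"], frame["W"])]
    frame.to_csv(out_path, sep="\t", index=False)
    return frame
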