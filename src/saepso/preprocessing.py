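"""Shared feature preprocessing: min-max scaling and median imputation.

Scaling statistics are always fitted on training rows only and applied
frozen to held-out rows, which are then clipped back into [0, 1]; constant
features map to 0.5 so sigmoid reconstruction targets stay interior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DataError

__all__ = ["MinMaxScaler", "median_impute"]


@dataclass
class MinMaxScaler:
    """Per-feature affine map onto [0, 1] fitted on training rows."""

    mins: np.ndarray | None = None
    spans: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "MinMaxScaler":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self.mins = np.nanmin(x, axis=0)
        self.spans = np.nanmax(x, axis=0) - self.mins
        return self

    def transform(self, x: np.ndarray, clip: bool = True) -> np.ndarray:
        if self.mins is None or self.spans is None:
            raise RuntimeError("scaler must be fitted before transform")
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty_like(x)
        constant = self.spans == 0
        safe = np.where(constant, 1.0, self.spans)
        out = (x - self.mins) / safe
        out[:, constant] = 0.5
        if clip:
            np.clip(out, 0.0, 1.0, out=out)
        return out

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def median_impute(
    x: np.ndarray, train_mask: np.ndarray | None = None
) -> np.ndarray:
    """Replace NaN entries with the per-feature median.

    Medians are computed on ``train_mask`` rows when given (avoiding test-set
    leakage) and on all rows otherwise.  A column with no observed value in
    the reference rows raises :class:`DataError`.
    """
    x = np.array(np.atleast_2d(np.asarray(x, dtype=float)))
    ref = x if train_mask is None else x[train_mask]
    all_nan = np.all(np.isnan(ref), axis=0)
    if np.any(all_nan):
        cols = np.flatnonzero(all_nan).tolist()
        raise DataError(f"column(s) {cols} contain no observed values")
    with np.errstate(all="ignore"):
        medians = np.nanmedian(ref, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = medians[nan_c]
    return x
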