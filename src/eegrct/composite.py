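"""Post hoc mid-to-high-frequency summary index over alpha/beta/gamma power.

A summary-index (Anderson/Kling-style) data reduction: average the z-scores
of the three mid-to-high absolute band powers over the analytic sample
(``zmean``, default), or simply sum the raw powers (``rawsum``).  The index
is analyzed by :func:`eegrct.itt.fit_itt` like any single band, trading the
biological interpretation of individual bands for one aggregate test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MID_HIGH_BANDS: tuple[str, ...] = ("alpha", "beta", "gamma")
METHODS: tuple[str, ...] = ("zmean", "rawsum")


def build_index(
    band_powers: pd.DataFrame,
    method: str = "zmean",
    columns: tuple[str, ...] = tuple(f"abs_{b}" for b in MID_HIGH_BANDS),
) -> pd.Series:
    """Per-child mid-to-high-frequency index from absolute band powers.

    ``zmean``: mean of the three band powers z-scored over the supplied
    sample (sample mean 0 by construction; invariant to rescaling any
    component).  ``rawsum``: plain sum of the three absolute powers (µV²).
    """
    missing = [c for c in columns if c not in band_powers.columns]
    if missing:
        raise ValueError(f"band power columns missing: {missing}")
    X = band_powers[list(columns)].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("band powers contain missing values")
    if method == "zmean":
        z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        values = z.mean(axis=1)
    elif method == "rawsum":
        values = X.sum(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return pd.Series(values, index=band_powers.index, name=f"midhigh_index_{method}")
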