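"""Display surfaces: ITT table, standardized-spectra curves, topographic data.

Everything is emitted as plain data tables; figures (if any) are rendered
from these tables so every displayed number stays recomputable from
persisted intermediates.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .config import CHANNEL_COORDS, DEFAULT_BANDS, BandDefinition
from .itt import ITTEstimate
from .spectral import StandardizedSpectra

#: Temporal reference channels are displayed from neighbor interpolation.
_TEMPORAL_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "T7": ("F7", "C3", "P7"),
    "T8": ("F8", "C4", "P8"),
}

#: Canonical row order of the treatment-effect table.
TABLE2_OUTCOMES: tuple[str, ...] = (
    "abs_alpha", "abs_beta", "abs_gamma", "abs_theta",
    "rel_alpha", "rel_beta", "rel_gamma", "rel_theta",
)


def make_table2(
    estimates: Mapping[str, ITTEstimate],
    adjusted_p: Mapping[str, float],
    data: pd.DataFrame,
    outcomes: Sequence[str] = TABLE2_OUTCOMES,
) -> pd.DataFrame:
    """Numeric treatment-effect table, one row per band outcome.

    ``data`` is the analytic sample with an ``arm`` column and one column
    per outcome; group means/SDs are recomputed from it directly.  Raises if
    any requested outcome lacks an estimate, an adjusted p, or a data
    column.
    """
    rows = []
    for out in outcomes:
        if out not in estimates:
            raise ValueError(f"no ITT estimate for outcome {out!r}")
        if out not in adjusted_p:
            raise ValueError(f"no adjusted p-value for outcome {out!r}")
        if out not in data.columns:
            raise ValueError(f"outcome column {out!r} missing from data")
        est = estimates[out]
        lo = data.loc[data["arm"] == "low", out]
        hi = data.loc[data["arm"] == "high", out]
        rows.append(
            {
                "outcome": out,
                "low_mean": lo.mean(),
                "low_sd": lo.std(ddof=1),
                "high_mean": hi.mean(),
                "high_sd": hi.std(ddof=1),
                "coef_fe": est.coef_unadjusted,
                "se_fe": est.se_unadjusted,
                "coef_adj": est.coef_adjusted,
                "se_adj": est.se_adjusted,
                "effect_size": est.effect_size,
                "p_unadjusted": est.p_unadjusted,
                "p_wy": adjusted_p[out],
                "n": est.n,
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


def format_table2(table: pd.DataFrame) -> pd.DataFrame:
    """Display layout: mean (SD) and coef (SE) strings, rounded as printed."""

    def ms(m: float, s: float) -> str:
        return f"{m:.3f} ({s:.3f})"

    out = pd.DataFrame(
        {
            "low_mean_sd": [ms(r.low_mean, r.low_sd) for r in table.itertuples()],
            "high_mean_sd": [ms(r.high_mean, r.high_sd) for r in table.itertuples()],
            "ols_site_fe": [ms(r.coef_fe, r.se_fe) for r in table.itertuples()],
            "ols_site_fe_covariates": [ms(r.coef_adj, r.se_adj) for r in table.itertuples()],
            "effect_size": [f"{r.effect_size:.2f}" for r in table.itertuples()],
            "p_unadjusted": [f"{r.p_unadjusted:.2f}" for r in table.itertuples()],
            "p_westfall_young": [f"{r.p_wy:.2f}" for r in table.itertuples()],
            "n": table["n"].to_numpy(),
        },
        index=table.index,
    )
    out.insert(0, "outcome", table.index)
    return out.reset_index(drop=True)


def fig1_data(
    std: StandardizedSpectra,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """48-row table of group-mean z per bin plus the difference curve.

    Columns: ``bin_hz``, ``z_low``, ``z_high``, ``difference`` (high − low),
    ``band`` (which band the bin belongs to).
    """
    bins = [int(c.split("_")[1]) for c in std.group_mean.columns]
    band_of = {}
    for b in bands:
        for hz in b.bins:
            band_of[hz] = b.name
    return pd.DataFrame(
        {
            "bin_hz": bins,
            "z_low": std.group_mean.loc["low"].to_numpy(),
            "z_high": std.group_mean.loc["high"].to_numpy(),
            "difference": std.difference.to_numpy(),
            "band": [band_of.get(hz, "") for hz in bins],
        }
    )


def topomap_data(
    channel_power: pd.DataFrame,
    arms: pd.DataFrame,
    interpolate_temporal: bool = True,
) -> pd.DataFrame:
    """Per-channel per-band mean power by arm, with 10–20 map coordinates.

    ``channel_power`` is long format (``id``, ``channel``, ``band``,
    ``power``); ``arms`` maps ``id`` → ``arm``.  The temporal reference
    channels carry no scalp signal of their own after re-referencing, so
    their displayed value is interpolated from the surrounding electrodes
    and flagged ``interpolated=True``.
    """
    unknown = set(channel_power["channel"]) - set(CHANNEL_COORDS)
    if unknown:
        raise ValueError(f"unknown montage label(s): {sorted(unknown)}")
    merged = channel_power.merge(arms[["id", "arm"]], on="id")
    agg = (
        merged.groupby(["channel", "band", "arm"], as_index=False)["power"]
        .mean()
        .rename(columns={"power": "mean_power"})
    )
    agg["interpolated"] = False
    if interpolate_temporal:
        for temporal, neighbors in _TEMPORAL_NEIGHBORS.items():
            for (band, arm), grp in agg.groupby(["band", "arm"]):
                neigh = grp[grp["channel"].isin(neighbors)]["mean_power"]
                sel = (
                    (agg["channel"] == temporal)
                    & (agg["band"] == band)
                    & (agg["arm"] == arm)
                )
                if sel.any() and len(neigh):
                    agg.loc[sel, "mean_power"] = neigh.mean()
                    agg.loc[sel, "interpolated"] = True
    agg["x"] = agg["channel"].map(lambda c: CHANNEL_COORDS[c][0])
    agg["y"] = agg["channel"].map(lambda c: CHANNEL_COORDS[c][1])
    return agg
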