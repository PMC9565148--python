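"""Mode-choice utilities and the mode-choice logsum (MCLS) impedance.

The MCLS is a continuous, multimodal generalisation of travel time: each
(zone, resource) pair gets the log of summed exponentiated utilities of
driving, riding transit, and walking,

    MCLS_ij = log( exp(V_auto) + exp(V_transit) + exp(V_walk) ),

with the sum running over the modes that are actually available for the
pair.  Because utilities are nonpositive and decline with time, MCLS is a
(negative) utility-denominated impedance: less negative means better
multimodal access.  When driving is the only realistic option, MCLS
collapses to ``b_time * t_auto`` exactly, which is why the estimated MCLS
coefficient in a destination-choice model is near-proportional (by
``1/|b_time|``) to the car-time coefficient on auto-dominated data.

The default coefficients are fixed, transferred values typical of regional
travel demand models; they are configuration, not estimated quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import logsumexp

from .region import SkimSet

__all__ = ["ModeCoefficients", "mode_utilities", "mcls", "impedance_matrix"]


@dataclass(frozen=True)
class ModeCoefficients:
    """Fixed mode-choice utility coefficients.

    Parameters
    ----------
    b_time : utility per minute of in-vehicle (or walking) time.
    asc_transit, asc_walk : alternative-specific constants.
    b_wait : utility per minute of transit wait + transfer time.
    b_access : utility per minute of transit access/egress walking.
    b_dist_short, b_dist_long : utility per mile of walk distance below /
        at-or-above ``dist_threshold``.
    dist_threshold : walk-distance breakpoint in miles.
    dialect : ``"literal"`` applies the distance coefficient selected by the
        threshold to the *full* distance (a discontinuity at the
        threshold); ``"marginal"`` applies them piecewise-continuously,
        ``b_dist_short*min(d,T) + b_dist_long*max(d-T,0)``.
    """

    b_time: float = -0.028
    asc_transit: float = -4.0
    b_wait: float = -0.056
    b_access: float = -0.372
    asc_walk: float = -5.0
    b_dist_short: float = -1.12
    b_dist_long: float = -5.58
    dist_threshold: float = 1.5
    dialect: Literal["literal", "marginal"] = "literal"

    def __post_init__(self) -> None:
        for name in ("b_time", "b_wait", "b_access", "b_dist_short", "b_dist_long"):
            if getattr(self, name) > 0:
                raise ValueError(f"slope coefficient {name} must be <= 0")
        if self.dist_threshold <= 0:
            raise ValueError("dist_threshold must be positive")
        if self.dialect not in ("literal", "marginal"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


def _walk_dist_term(d: np.ndarray, c: ModeCoefficients) -> np.ndarray:
    if c.dialect == "literal":
        return np.where(d < c.dist_threshold, c.b_dist_short * d, c.b_dist_long * d)
    return c.b_dist_short * np.minimum(d, c.dist_threshold) + c.b_dist_long * np.maximum(
        d - c.dist_threshold, 0.0
    )


def _utility_arrays(df, c: ModeCoefficients) -> np.ndarray:
    """(n, 3) array of mode utilities (auto, transit, walk); NaN = unavailable."""
    for col in ("t_auto", "t_transit_iv", "wt", "at", "t_walk"):
        avail = {
            "t_auto": "avail_auto", "t_walk": "avail_walk",
        }.get(col, "avail_transit")
        vals = df[col].to_numpy(dtype=float)
        if np.any((vals < 0) & df[avail].to_numpy()):
            raise ValueError(f"negative {col} for an available mode")
    v_auto = c.b_time * df["t_auto"].to_numpy(dtype=float)
    v_transit = (
        c.asc_transit
        + c.b_time * df["t_transit_iv"].to_numpy(dtype=float)
        + c.b_wait * df["wt"].to_numpy(dtype=float)
        + c.b_access * df["at"].to_numpy(dtype=float)
    )
    d = df["d_walk"].to_numpy(dtype=float)
    v_walk = c.asc_walk + c.b_time * df["t_walk"].to_numpy(dtype=float) + _walk_dist_term(d, c)
    V = np.column_stack([v_auto, v_transit, v_walk])
    avail = df[["avail_auto", "avail_transit", "avail_walk"]].to_numpy(dtype=bool)
    V[~avail] = np.nan
    return V


def mode_utilities(pair, coeffs: ModeCoefficients | None = None) -> dict[str, float]:
    """Per-mode utilities for one skim row; unavailable modes are omitted.

    ``pair`` is a Series/mapping with the skim component and availability
    fields (as returned by :meth:`SkimSet.lookup`).
    """
    import pandas as pd

    coeffs = coeffs or ModeCoefficients()
    df = pd.DataFrame([dict(pair)])
    V = _utility_arrays(df, coeffs)[0]
    return {
        mode: float(V[k])
        for k, mode in enumerate(("auto", "transit", "walk"))
        if np.isfinite(V[k])
    }


class UnreachableError(ValueError):
    """No mode is available for the pair; the alternative must be excluded."""


def mcls(pair, coeffs: ModeCoefficients | None = None) -> float:
    """Mode-choice logsum for one pair over its available modes.

    Overflow-safe (max-shift); raises :class:`UnreachableError` when no mode
    is available.  Always ``>=`` the best single-mode utility.
    """
    V = mode_utilities(pair, coeffs)
    if not V:
        raise UnreachableError("no travel mode available for this pair")
    return float(logsumexp(list(V.values())))


def impedance_matrix(
    skims: SkimSet,
    coeffs: ModeCoefficients | None = None,
    kind: Literal["mcls", "t_auto", "t_walk"] = "mcls",
    zone_ids=None,
    resource_ids=None,
) -> np.ndarray:
    """Dense (zone, resource) impedance matrix; NaN marks unreachable pairs.

    ``kind="t_auto"`` / ``"t_walk"`` pass raw minutes through (the "Car"
    style impedance); ``"mcls"`` computes the multimodal logsum.
    """
    coeffs = coeffs or ModeCoefficients()
    df = skims.df
    zi = np.unique(df["zone_id"]) if zone_ids is None else np.asarray(zone_ids)
    ri = np.unique(df["resource_id"]) if resource_ids is None else np.asarray(resource_ids)
    if kind in ("t_auto", "t_walk"):
        return skims.matrix(zi, ri, kind)
    if kind != "mcls":
        raise ValueError(f"unknown impedance kind {kind!r}")
    V = _utility_arrays(df, coeffs)
    with np.errstate(invalid="ignore"):
        vals = logsumexp(np.where(np.isnan(V), -np.inf, V), axis=1)
    vals[~np.isfinite(vals)] = np.nan  # all-unavailable pairs
    import pandas as pd

    wide = (
        pd.DataFrame({"zone_id": df["zone_id"], "resource_id": df["resource_id"], "v": vals})
        .pivot(index="zone_id", columns="resource_id", values="v")
        .reindex(index=pd.Index(zi), columns=pd.Index(ri))
    )
    return wide.to_numpy(dtype=float)
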