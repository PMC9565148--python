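"""Per-zone accessibility surfaces: logsum, buffer/cumulative, gravity.

The utility-based (logsum) measure applies an estimated destination-choice
model to the *full* resource inventory of a type:

    A_i = log sum_j exp( beta * t_ij + X_j @ gamma ),

summed over every reachable resource j (sampling of alternatives was an
estimation device only).  The arbitrary constant is fixed at zero, so
values are relative — only differences between zones are meaningful — and
all outputs are labelled accordingly.  For comparison the module also
provides the traditional buffer (binary within-threshold) and cumulative
opportunity measures, and a generic gravity measure with exponential or
power decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .choicedata import ModelSpec
from .impedance import ModeCoefficients, impedance_matrix
from .region import Resources, SkimSet, Zones

__all__ = [
    "AccessSurface",
    "logsum_access",
    "buffer_access",
    "gravity_access",
    "nearest_time",
    "compare_surfaces",
    "SurfaceComparison",
]

_MODE_COL = {"auto": "t_auto", "walk": "t_walk"}


@dataclass
class AccessSurface:
    """One accessibility value per zone under a named measure.

    ``values`` is indexed by zone_id.  NaN marks a zone with no reachable
    resource (excluded from means).  ``metadata`` records the measure's
    provenance (model, threshold, decay); logsum surfaces carry
    ``relative=True`` because the level is arbitrary.
    """

    measure: Literal["logsum", "buffer", "cumulative", "gravity", "nearest_time"]
    rtype: str
    values: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.rename("value")
        self.values.index.name = "zone_id"
        v = self.values.dropna()
        if self.measure == "buffer" and not v.isin([0, 1]).all():
            raise ValueError("buffer surface values must be binary")
        if self.measure == "cumulative" and ((v < 0) | (v != v.round())).any():
            raise ValueError("cumulative surface values must be nonnegative integers")

    def mean(self, zones: Zones | None = None, weighted: bool = False) -> float:
        """Regional mean over zones with a finite value; optionally
        household-weighted."""
        v = self.values.dropna()
        if not weighted:
            return float(v.mean())
        if zones is None:
            raise ValueError("household weighting requires the zone table")
        hh = zones.df.set_index("zone_id")["households"].reindex(v.index)
        return float(np.average(v, weights=hh))

    def standardized(self, zones: Zones | None = None, weighted: bool = False) -> "AccessSurface":
        """Subtract the regional mean (needed for 'below regional mean'
        classifications); only meaningful for relative measures."""
        mu = self.mean(zones, weighted)
        meta = dict(self.metadata, standardized=True, regional_mean=mu, weighted=weighted)
        return AccessSurface(self.measure, self.rtype, self.values - mu, meta)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.reset_index()
        out.insert(1, "measure", self.measure)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, rtype: str, metadata: dict | None = None) -> "AccessSurface":
        df = pd.read_csv(path)
        measure = df["measure"].iloc[0]
        return cls(measure, rtype, df.set_index("zone_id")["value"], metadata or {})

    def to_geojson(self, path: str | Path, zones: Zones) -> None:
        """Choropleth-ready point export joined to zone centroids."""
        zdf = zones.df.set_index("zone_id")
        feats = []
        for zid, val in self.values.items():
            row = zdf.loc[zid]
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                "properties": {
                    "zone_id": zid,
                    "measure": self.measure,
                    "value": None if pd.isna(val) else float(val),
                },
            })
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def _utility_matrix(
    params: Mapping[str, float],
    spec: ModelSpec,
    zones: Zones,
    resources: Resources,
    skims: SkimSet,
    coeffs: ModeCoefficients,
) -> np.ndarray:
    """(n_zones, n_resources) systematic utilities; NaN where unreachable."""
    zi = zones.ids.to_numpy()
    ri = resources.ids.to_numpy()
    imp = impedance_matrix(skims, coeffs, spec.impedance_kind, zi, ri)
    V = params[spec.impedance_kind] * imp
    attrs = resources.df.set_index("resource_id")
    for name, transform in spec.attribute_terms:
        vals = attrs[name].astype(float).reindex(ri).to_numpy()
        col = name
        if transform == "log":
            col, vals = f"log_{name}", np.log(vals)
        V = V + params[col] * vals[None, :]
    return V


def logsum_access(
    model,
    zones: Zones,
    resources: Resources,
    skims: SkimSet,
    coeffs: ModeCoefficients | None = None,
    spec: ModelSpec | None = None,
) -> AccessSurface:
    """Utility-based accessibility from a fitted destination-choice model.

    ``model`` is a :class:`~accesslogit.mnl.DestinationChoiceResults` (or a
    mapping of coefficient name to value, with ``spec`` given).  The sum
    runs over every reachable resource of the spec's rtype; a zone with no
    reachable resource gets NaN.
    """
    coeffs = coeffs or ModeCoefficients()
    if hasattr(model, "params"):
        params = model.params.to_dict()
        spec = spec or model.model.spec
    else:
        params = dict(model)
    if spec is None:
        raise ValueError("a ModelSpec is required when passing raw coefficients")
    V = _utility_matrix(params, spec, zones, resources, skims, coeffs)
    with np.errstate(invalid="ignore"):
        vals = logsumexp(np.where(np.isnan(V), -np.inf, V), axis=1)
    vals = np.where(np.isfinite(vals), vals, np.nan)
    n_unreach = int(np.isnan(vals).sum())
    return AccessSurface(
        "logsum",
        spec.rtype,
        pd.Series(vals, index=zones.ids.to_numpy()),
        {
            "impedance_kind": spec.impedance_kind,
            "relative": True,
            "note": "relative measure: only differences between zones are meaningful",
            "n_unreachable_zones": n_unreach,
        },
    )


def buffer_access(
    zones: Zones,
    resources: Resources,
    skims: SkimSet,
    mode: Literal["auto", "walk"],
    t_star: float,
    cumulative: bool = False,
) -> AccessSurface:
    """Threshold measure: 1 iff any resource lies within ``t_star`` minutes
    by ``mode`` (closed inequality, t <= t*); with ``cumulative=True``, the
    count of such resources."""
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    col = _MODE_COL.get(mode)
    if col is None:
        raise ValueError(f"mode must be one of {sorted(_MODE_COL)}, got {mode!r}")
    t = skims.matrix(zones.ids, resources.ids, col)
    within = (t <= t_star) & np.isfinite(t)
    vals = within.sum(axis=1).astype(float) if cumulative else within.any(axis=1).astype(float)
    return AccessSurface(
        "cumulative" if cumulative else "buffer",
        resources.rtype,
        pd.Series(vals, index=zones.ids.to_numpy()),
        {"mode": mode, "t_star": t_star},
    )


def gravity_access(
    zones: Zones,
    resources: Resources,
    skims: SkimSet,
    beta: float,
    size_attr: str | None = None,
    decay: Literal["exponential", "power"] = "exponential",
    mode: Literal["auto", "walk"] = "auto",
) -> AccessSurface:
    """Gravity measure: ``A_i = sum_j S_j * f(t_ij, beta)`` with
    ``f = exp(-beta t)`` (exponential) or ``t**-beta`` (power, t floored at
    one minute).  ``S_j = 1`` when no size attribute is named."""
    if beta <= 0:
        raise ValueError("decay parameter beta must be positive")
    t = skims.matrix(zones.ids, resources.ids, _MODE_COL[mode])
    if size_attr is None:
        S = np.ones(len(resources))
    else:
        S = resources.df[size_attr].astype(float).to_numpy()
        if (S <= 0).any():
            raise ValueError(f"size attribute {size_attr!r} must be positive")
    if decay == "exponential":
        f = np.exp(-beta * t)
    elif decay == "power":
        f = np.maximum(t, 1.0) ** (-beta)
    else:
        raise ValueError(f"unknown decay {decay!r}")
    f = np.where(np.isfinite(t), f, 0.0)
    vals = f @ S
    return AccessSurface(
        "gravity",
        resources.rtype,
        pd.Series(vals, index=zones.ids.to_numpy()),
        {"decay": decay, "beta": beta, "size_attr": size_attr, "mode": mode},
    )


def nearest_time(
    zones: Zones, resources: Resources, skims: SkimSet, mode: Literal["auto", "walk"]
) -> AccessSurface:
    """Minutes to the nearest reachable resource by ``mode`` (NaN if none)."""
    t = skims.matrix(zones.ids, resources.ids, _MODE_COL[mode])
    finite = np.isfinite(t)
    vals = np.min(np.where(finite, t, np.inf), axis=1)
    vals = np.where(finite.any(axis=1), vals, np.nan)
    return AccessSurface(
        "nearest_time", resources.rtype,
        pd.Series(vals, index=zones.ids.to_numpy()), {"mode": mode},
    )


@dataclass
class SurfaceComparison:
    """Zone-by-zone alignment of a buffer and a logsum surface.

    ``per_zone`` columns: nearest-resource travel time, binary buffer flag,
    logsum value.  ``band_summary`` shows the dispersion of the logsum
    within travel-time bands — nonzero within-band variance is exactly what
    the binary buffer cannot express.
    """

    per_zone: pd.DataFrame
    rtype: str
    mode: str
    t_star: float

    def band_summary(self, band_width: float = 2.0) -> pd.DataFrame:
        df = self.per_zone.dropna(subset=["nearest_time", "logsum"]).copy()
        df["band"] = (df["nearest_time"] // band_width) * band_width
        g = df.groupby("band")["logsum"]
        out = g.agg(n="size", mean="mean", std="std", min="min", max="max")
        out["straddles_threshold"] = [
            b <= self.t_star < b + band_width for b in out.index
        ]
        return out

    def plot(self, ax=None):
        """Scatter of logsum access against nearest travel time, with the
        buffer threshold marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.per_zone
        ax.scatter(df["nearest_time"], df["logsum"], s=12, alpha=0.7)
        ax.axvline(self.t_star, ls="--", color="grey")
        ax.set_xlabel(f"nearest {self.rtype} travel time ({self.mode} min)")
        ax.set_ylabel("accessibility logsum (relative)")
        return ax


def compare_surfaces(
    buffer: AccessSurface, logsum: AccessSurface, skims: SkimSet,
    zones: Zones, resources: Resources,
) -> SurfaceComparison:
    """Align a buffer and a logsum surface for the same zones and rtype."""
    if len(resources) == 0:
        raise ValueError("empty resource set")
    if buffer.rtype != logsum.rtype:
        raise ValueError("surfaces describe different resource types")
    if not buffer.values.index.equals(logsum.values.index):
        raise ValueError("surfaces cover different zone sets")
    mode = buffer.metadata.get("mode", "auto")
    nt = nearest_time(zones, resources, skims, mode)
    per_zone = pd.DataFrame({
        "nearest_time": nt.values,
        "buffer": buffer.values,
        "logsum": logsum.values,
    })
    return SurfaceComparison(per_zone, buffer.rtype, mode, buffer.metadata.get("t_star", np.nan))
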