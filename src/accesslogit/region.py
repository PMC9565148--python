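"""Domain tables for a study region: zones, resources, travel-cost skims, visit flows.

All four tables are thin, validated wrappers around :class:`pandas.DataFrame`
with CSV (and, for the geometric tables, GeoJSON) readers and writers.
Coordinates are planar (projected) units throughout; no CRS handling is done
here because travel costs arrive as pre-computed skims and coordinates only
feed the synthetic skim generator and map exports.

Conventions
-----------
* A missing skim component means the mode is *unavailable* for that pair,
  never that it is free.  Zero cost would dominate any logsum downstream.
* Every (zone, resource) lookup is total: a pair absent from the skim table
  is reported as fully unavailable rather than silently defaulted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "RTYPES",
    "RESOURCE_SCHEMAS",
    "Zones",
    "Resources",
    "SkimSet",
    "FlowTable",
    "read_zones",
    "read_resources",
    "read_skims",
    "write_skims",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """Values violate a table invariant (duplicates, negative counts, ...)."""


RTYPES = ("park", "grocery", "library")

#: Closed attribute schemas per resource type.  ``size`` columns must be
#: strictly positive (they are log-transformed in model specifications),
#: ``bool`` columns are coerced from {0,1,true,false}, ``count`` columns are
#: nonnegative integers.
RESOURCE_SCHEMAS: Mapping[str, Mapping[str, str]] = {
    "park": {
        "acres": "size",
        "playground": "bool",
        "volleyball": "bool",
        "basketball": "bool",
        "tennis": "bool",
    },
    "grocery": {
        "n_registers": "count",
        "n_selfcheckout": "count",
        "convenience": "bool",
        "other_nonstandard": "bool",
        "pharmacy": "bool",
        "ethnic_market": "bool",
        "other_merchandise": "bool",
    },
    "library": {
        "sqft": "size",
        "offers_classes": "bool",
        "genealogy": "bool",
    },
}

_SKIM_TIME_COLS = ["t_auto", "t_transit_iv", "wt", "at", "t_walk", "d_walk"]
_SKIM_AVAIL_COLS = ["avail_auto", "avail_transit", "avail_walk"]

_BOOL_MAP = {
    "0": False, "1": True, "true": True, "false": False,
    "True": True, "False": False, 0: False, 1: True,
    True: True, False: False, 0.0: False, 1.0: True,
}


def _coerce_bool(series: pd.Series, col: str) -> pd.Series:
    try:
        return series.map(lambda v: _BOOL_MAP[v]).astype(bool)
    except KeyError as exc:
        raise SchemaError(
            f"column {col!r} must contain booleans (0/1/true/false); got {exc.args[0]!r}"
        ) from None


def _require(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {missing}")


# ---------------------------------------------------------------------------
# Zones
# ---------------------------------------------------------------------------

@dataclass
class Zones:
    """Origin neighbourhoods.

    ``df`` columns: ``zone_id`` (unique), ``x``, ``y`` (planar centroid),
    ``households`` (>= 0), ``frac_low_income`` (in [0, 1], share of
    households under $35k/yr).  Additional demographic columns are carried
    through untouched.
    """

    df: pd.DataFrame

    REQUIRED = ("zone_id", "x", "y", "households", "frac_low_income")

    def __post_init__(self) -> None:
        _require(self.df, self.REQUIRED, "zones")
        df = self.df
        if df["zone_id"].duplicated().any():
            dups = df.loc[df["zone_id"].duplicated(), "zone_id"].tolist()
            raise ValidationError(f"duplicate zone_id(s): {dups}")
        if (df["households"] < 0).any():
            raise ValidationError("households must be nonnegative")
        f = df["frac_low_income"]
        if ((f < 0) | (f > 1)).any():
            raise ValidationError("frac_low_income must lie in [0, 1]")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df["zone_id"]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_zones(path: str | Path, fmt: str | None = None) -> Zones:
    """Read a zone table from CSV or GeoJSON.

    For GeoJSON, centroid coordinates are taken from ``x``/``y`` properties
    when present, otherwise computed as the geometric centroid of the
    feature geometry.
    """
    path = Path(path)
    fmt = fmt or ("geojson" if path.suffix.lower() in {".geojson", ".json"} else "csv")
    if fmt == "csv":
        return Zones(pd.read_csv(path))
    if fmt == "geojson":
        from shapely.geometry import shape

        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj["features"]:
            props = dict(feat.get("properties") or {})
            if "x" not in props or "y" not in props:
                cent = shape(feat["geometry"]).centroid
                props["x"], props["y"] = cent.x, cent.y
            rows.append(props)
        return Zones(pd.DataFrame(rows))
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------

@dataclass
class Resources:
    """Destinations of one resource type with the closed attribute schema.

    ``df`` columns: ``resource_id`` (unique), ``x``, ``y``, plus every
    attribute named in ``RESOURCE_SCHEMAS[rtype]``.  Unknown extra columns
    are carried through untouched but are not usable in model
    specifications unless declared in the schema.
    """

    df: pd.DataFrame
    rtype: str

    def __post_init__(self) -> None:
        if self.rtype not in RESOURCE_SCHEMAS:
            raise ValueError(f"rtype must be one of {RTYPES}, got {self.rtype!r}")
        schema = RESOURCE_SCHEMAS[self.rtype]
        _require(self.df, ("resource_id", "x", "y", *schema), f"{self.rtype} resources")
        df = self.df.copy()
        if df["resource_id"].duplicated().any():
            raise ValidationError("duplicate resource_id(s)")
        for col, kind in schema.items():
            if kind == "bool":
                df[col] = _coerce_bool(df[col], col)
            elif kind == "size":
                if (df[col] <= 0).any() or df[col].isna().any():
                    raise ValidationError(
                        f"{self.rtype} {col!r} must be strictly positive "
                        "(it is log-transformed in model specifications)"
                    )
            elif kind == "count":
                if (df[col] < 0).any() or df[col].isna().any():
                    raise ValidationError(f"{col!r} must be a nonnegative count")
                df[col] = df[col].astype(int)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df["resource_id"]

    @property
    def schema(self) -> Mapping[str, str]:
        return RESOURCE_SCHEMAS[self.rtype]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_resources(path: str | Path, rtype: str, fmt: str | None = None) -> Resources:
    """Read a resource table (CSV, or GeoJSON point features) for one rtype."""
    path = Path(path)
    fmt = fmt or ("geojson" if path.suffix.lower() in {".geojson", ".json"} else "csv")
    if fmt == "csv":
        return Resources(pd.read_csv(path), rtype)
    if fmt == "geojson":
        from shapely.geometry import shape

        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj["features"]:
            props = dict(feat.get("properties") or {})
            if "x" not in props or "y" not in props:
                cent = shape(feat["geometry"]).centroid
                props["x"], props["y"] = cent.x, cent.y
            rows.append(props)
        return Resources(pd.DataFrame(rows), rtype)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Skims
# ---------------------------------------------------------------------------

@dataclass
class SkimSet:
    """Per-mode travel-cost components for (zone, resource) pairs.

    ``df`` columns: ``zone_id``, ``resource_id``, the six cost components
    (``t_auto``, ``t_transit_iv``, ``wt``, ``at`` in minutes, ``t_walk``
    minutes, ``d_walk`` miles) and the three availability flags.  A NaN cost
    component implies the mode is unavailable; availability flags are
    derived from completeness when absent from the input.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require(self.df, ("zone_id", "resource_id"), "skims")
        df = self.df.copy()
        for col in _SKIM_TIME_COLS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
        # Derive availability from component completeness where not given.
        derived = {
            "avail_auto": df["t_auto"].notna(),
            "avail_transit": df[["t_transit_iv", "wt", "at"]].notna().all(axis=1),
            "avail_walk": df[["t_walk", "d_walk"]].notna().all(axis=1),
        }
        for col, fallback in derived.items():
            if col in df.columns:
                given = df[col].astype(object).where(df[col].notna(), False)
                df[col] = _coerce_bool(given, col) & fallback
            else:
                df[col] = fallback
        # canonical form: components of unavailable modes are blank, so a
        # write->read round trip is the identity
        df.loc[~df["avail_auto"], "t_auto"] = np.nan
        df.loc[~df["avail_transit"], ["t_transit_iv", "wt", "at"]] = np.nan
        df.loc[~df["avail_walk"], ["t_walk", "d_walk"]] = np.nan
        for col in _SKIM_TIME_COLS:
            avail = {
                "t_auto": "avail_auto", "t_transit_iv": "avail_transit",
                "wt": "avail_transit", "at": "avail_transit",
                "t_walk": "avail_walk", "d_walk": "avail_walk",
            }[col]
            bad = df[avail] & (df[col] < 0)
            if bad.any():
                raise ValidationError(f"negative {col} for available mode")
        if df.duplicated(["zone_id", "resource_id"]).any():
            raise ValidationError("duplicate (zone_id, resource_id) pair in skims")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate_ids(self, zones: Zones, resources: Resources) -> None:
        """Raise if any pair references an unknown zone or resource id."""
        bad_z = set(self.df["zone_id"]) - set(zones.ids)
        bad_r = set(self.df["resource_id"]) - set(resources.ids)
        if bad_z or bad_r:
            raise ValidationError(
                f"skims reference unknown ids: zones {sorted(bad_z)!r}, "
                f"resources {sorted(bad_r)!r}"
            )

    def lookup(self, zone_id, resource_id) -> pd.Series:
        """Total lookup: returns the component row, or an all-unavailable row
        when the pair is absent from the table."""
        m = (self.df["zone_id"] == zone_id) & (self.df["resource_id"] == resource_id)
        if not m.any():
            row = pd.Series(
                {c: np.nan for c in _SKIM_TIME_COLS}
                | {c: False for c in _SKIM_AVAIL_COLS}
            )
            row["zone_id"], row["resource_id"] = zone_id, resource_id
            return row
        return self.df.loc[m].iloc[0]

    def matrix(self, zone_ids: Iterable, resource_ids: Iterable, col: str) -> np.ndarray:
        """Dense (n_zones, n_resources) array of one component; NaN where the
        pair is absent or the component unavailable."""
        zi = pd.Index(zone_ids)
        ri = pd.Index(resource_ids)
        avail_col = {
            "t_auto": "avail_auto", "t_transit_iv": "avail_transit",
            "wt": "avail_transit", "at": "avail_transit",
            "t_walk": "avail_walk", "d_walk": "avail_walk",
        }.get(col)
        vals = self.df[col].where(self.df[avail_col]) if avail_col else self.df[col]
        wide = (
            pd.DataFrame({
                "zone_id": self.df["zone_id"],
                "resource_id": self.df["resource_id"],
                "v": vals,
            })
            .pivot(index="zone_id", columns="resource_id", values="v")
            .reindex(index=zi, columns=ri)
        )
        return wide.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        write_skims(self, path)


def read_skims(path: str | Path) -> SkimSet:
    """Read a long skim CSV; blank cost fields encode mode unavailability."""
    return SkimSet(pd.read_csv(path))


def write_skims(skims: SkimSet, path: str | Path) -> None:
    """Write the long skim CSV; unavailable components are written blank so
    that a read→write→read round trip is the identity."""
    df = skims.df.copy()
    df.loc[~df["avail_auto"], "t_auto"] = np.nan
    df.loc[~df["avail_transit"], ["t_transit_iv", "wt", "at"]] = np.nan
    df.loc[~df["avail_walk"], ["t_walk", "d_walk"]] = np.nan
    cols = ["zone_id", "resource_id", *_SKIM_TIME_COLS, *_SKIM_AVAIL_COLS]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Flows
# ---------------------------------------------------------------------------

@dataclass
class FlowTable:
    """Aggregated device-trip counts between zones and resources.

    ``df`` columns: ``zone_id``, ``resource_id``, ``count`` (nonnegative int).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require(self.df, ("zone_id", "resource_id", "count"), "flows")
        df = self.df.copy()
        if (df["count"] < 0).any():
            raise ValidationError("flow counts must be nonnegative")
        df["count"] = df["count"].astype(int)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total(self) -> int:
        return int(self.df["count"].sum())

    def validate_ids(self, zones: Zones, resources: Resources) -> None:
        bad_z = set(self.df["zone_id"]) - set(zones.ids)
        bad_r = set(self.df["resource_id"]) - set(resources.ids)
        if bad_z or bad_r:
            raise ValidationError(
                f"flows reference unknown ids: zones {sorted(bad_z)!r}, "
                f"resources {sorted(bad_r)!r}"
            )

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_flows(path: str | Path) -> FlowTable:
    return FlowTable(pd.read_csv(path))
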