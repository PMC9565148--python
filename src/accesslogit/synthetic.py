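"""Synthetic study region: zones, resources, skims, and visit flows.

The generator emulates the data environment of a mid-size suburban county
organised around a single dense north–south corridor ("spine"): zones sit
on a jittered grid, resources cluster toward the spine, and a transit line
runs along it.  Travel costs are derived from straight-line distance with
a circuity factor rather than a road network.  Visit flows are drawn from
a *known* multinomial-logit destination-choice model over the full
resource inventory, so the whole estimation pipeline can be validated by
parameter recovery against the generating coefficients.

Default scale is a desk-size region — 50 zones, 30 parks, 12 grocery
stores, 8 libraries, 10,000 trips per resource type — with demographic and
attribute distributions chosen to resemble published block-group summary
statistics for such a county (median ~500 households/zone, mean low-income
share ~0.16, park sizes lognormal around a few acres, and so on).

One global seed expands to per-stage child seeds by fixed offsets, so each
stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from .choicedata import ModelSpec
from .impedance import ModeCoefficients, impedance_matrix
from .region import RTYPES, FlowTable, Resources, SkimSet, Zones

__all__ = [
    "RegionConfig",
    "default_truth",
    "gen_region",
    "gen_skims",
    "gen_flows",
    "SyntheticRegion",
    "generate",
    "simulate",
]

KM_PER_MILE = 1.609344

#: Generating ("ground truth") coefficients per resource type, car-time
#: impedance.  These mirror the preference structure of estimated
#: destination-choice models for parks, grocery stores, and libraries in a
#: suburban U.S. county: impedance ~ -0.27..-0.31 per minute, strong draw
#: of size (log acres / log sqft / registers) and of playgrounds, mild
#: penalties for niche amenities.
_TRUTH_COEF: dict[str, dict[str, float]] = {
    "park": {
        "t_auto": -0.267, "log_acres": 1.307, "playground": 4.467,
        "volleyball": -0.555, "basketball": -0.508, "tennis": -0.881,
    },
    "grocery": {
        "t_auto": -0.270, "convenience": -1.343, "other_nonstandard": -1.418,
        "pharmacy": 0.330, "ethnic_market": -0.887, "other_merchandise": 0.909,
        "n_registers": 0.087, "n_selfcheckout": 0.020,
    },
    "library": {
        "t_auto": -0.313, "offers_classes": -0.819, "genealogy": -0.867,
        "log_sqft": 1.219,
    },
}


def default_truth(rtype: str) -> tuple[ModelSpec, dict[str, float]]:
    """The generating specification and coefficients for one rtype."""
    spec = ModelSpec.default(rtype, impedance_kind="t_auto")
    return spec, dict(_TRUTH_COEF[rtype])


@dataclass
class RegionConfig:
    """Knobs of the synthetic region.

    Distances are km, speeds km/h, times minutes.  ``extent`` is the
    (width, height) of the rectangle; the transit spine is the vertical
    line ``x = spine_x`` served within ``corridor_width`` on either side.
    """

    n_zones: int = 50
    n_resources: Mapping[str, int] = field(
        default_factory=lambda: {"park": 30, "grocery": 12, "library": 8}
    )
    extent: tuple[float, float] = (20.0, 40.0)
    spine_x: float = 10.0
    corridor_width: float = 3.0
    # households per zone ~ lognormal; median exp(mu)
    hh_mu: float = np.log(500.0)
    hh_sigma: float = 0.8
    # low-income share: logistic decline with distance from the spine
    low_income_intercept: float = -1.0
    low_income_slope: float = -0.25
    low_income_noise: float = 0.5
    # resource placement: Laplace spread around the spine
    resource_spread: float = 4.0
    # attribute distributions
    park_acres_mu: float = 1.5
    park_acres_sigma: float = 1.2
    amenity_p: Mapping[str, float] = field(default_factory=lambda: {
        "playground": 0.6, "volleyball": 0.2, "basketball": 0.3, "tennis": 0.25,
        "convenience": 0.2, "other_nonstandard": 0.1, "pharmacy": 0.4,
        "ethnic_market": 0.1, "other_merchandise": 0.3,
        "offers_classes": 0.7, "genealogy": 0.4,
    })
    grocery_registers_lam: float = 6.0
    grocery_selfcheckout_lam: float = 3.0
    library_sqft_mu: float = 9.6
    library_sqft_sigma: float = 0.7
    # skims
    circuity: float = 1.3
    auto_speed: float = 40.0
    terminal_time: float = 2.0
    walk_speed: float = 4.8
    transit_speed: float = 25.0
    headway: float = 15.0
    stop_access_time: float = 2.0
    walk_limit_km: float = 10.0
    total_limit_min: float = 120.0
    # flows: the observed device-trip volume aggregated into the flow table
    # is much larger than the estimation sample drawn from it, as with
    # commercial location-based-services data; estimating on a sample the
    # same size as the underlying volume would understate standard errors.
    n_device_trips: int = 200_000
    n_trips: int = 10_000
    n_alt: int = 10
    seed: int = 0

    # fixed child-seed offsets per stage
    SEED_REGION = 11
    SEED_FLOWS = 13

    def __post_init__(self) -> None:
        if self.n_zones < 1 or any(n < 1 for n in self.n_resources.values()):
            raise ValueError("counts must be at least 1")
        if self.auto_speed <= 0 or self.walk_speed <= 0 or self.transit_speed <= 0:
            raise ValueError("speeds must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _grid_positions(n: int, extent: tuple[float, float], rng) -> np.ndarray:
    w, h = extent
    nx = max(1, round(np.sqrt(n * w / h)))
    ny = int(np.ceil(n / nx))
    if w / nx < 0.5 or h / ny < 0.5:
        raise ValueError(f"extent {extent} too small for {n} zones (cells under 0.5 km)")
    cx, cy = w / nx, h / ny
    cells = [(i, j) for j in range(ny) for i in range(nx)][:n]
    jitter = rng.uniform(0.15, 0.85, size=(n, 2))
    return np.array([[(i + jx) * cx, (j + jy) * cy] for (i, j), (jx, jy) in zip(cells, jitter)])


def gen_region(config: RegionConfig) -> tuple[Zones, dict[str, Resources]]:
    """Zones on a jittered grid plus resources clustered toward the spine."""
    rng = np.random.default_rng(config.seed + config.SEED_REGION)
    w, h = config.extent
    pos = _grid_positions(config.n_zones, config.extent, rng)
    dist_spine = np.abs(pos[:, 0] - config.spine_x)
    households = np.maximum(
        1, np.round(rng.lognormal(config.hh_mu, config.hh_sigma, config.n_zones))
    ).astype(int)
    frac_low = expit(
        config.low_income_intercept
        + config.low_income_slope * dist_spine
        + rng.normal(0, config.low_income_noise, config.n_zones)
    )
    zones = Zones(pd.DataFrame({
        "zone_id": [f"z{i:03d}" for i in range(config.n_zones)],
        "x": pos[:, 0],
        "y": pos[:, 1],
        "households": households,
        "frac_low_income": np.clip(frac_low, 0.0, 1.0),
    }))

    resources: dict[str, Resources] = {}
    for rtype in RTYPES:
        n = config.n_resources.get(rtype, 0)
        if n == 0:
            continue
        x = np.clip(config.spine_x + rng.laplace(0, config.resource_spread, n), 0.0, w)
        y = rng.uniform(0, h, n)
        df = pd.DataFrame({
            "resource_id": [f"{rtype[0]}{i:03d}" for i in range(n)],
            "x": x,
            "y": y,
        })
        if rtype == "park":
            df["acres"] = rng.lognormal(config.park_acres_mu, config.park_acres_sigma, n)
        elif rtype == "grocery":
            df["n_registers"] = 1 + rng.poisson(config.grocery_registers_lam, n)
            df["n_selfcheckout"] = rng.poisson(config.grocery_selfcheckout_lam, n)
        elif rtype == "library":
            df["sqft"] = rng.lognormal(config.library_sqft_mu, config.library_sqft_sigma, n)
        from .region import RESOURCE_SCHEMAS

        for col, kind in RESOURCE_SCHEMAS[rtype].items():
            if kind == "bool":
                df[col] = rng.random(n) < config.amenity_p[col]
        resources[rtype] = Resources(df, rtype)
    return zones, resources


def gen_skims(zones: Zones, resources: Resources, config: RegionConfig) -> SkimSet:
    """Distance-derived travel costs for every (zone, resource) pair.

    Auto times come from circuity-inflated straight-line distance plus a
    terminal time; walking is available within the 10 km walk limit;
    transit exists only when both endpoints sit in the spine corridor,
    with wait = half the headway and access/egress walked to the spine.
    """
    zpos = zones.df[["x", "y"]].to_numpy()
    rpos = resources.df[["x", "y"]].to_numpy()
    dx = zpos[:, 0][:, None] - rpos[:, 0][None, :]
    dy = zpos[:, 1][:, None] - rpos[:, 1][None, :]
    d_km = np.hypot(dx, dy) * config.circuity

    t_auto = d_km / config.auto_speed * 60.0 + config.terminal_time
    avail_auto = t_auto <= config.total_limit_min

    t_walk = d_km / config.walk_speed * 60.0
    d_walk = d_km / KM_PER_MILE
    avail_walk = (d_km <= config.walk_limit_km) & (t_walk <= config.total_limit_min)

    z_off = np.abs(zpos[:, 0] - config.spine_x)
    r_off = np.abs(rpos[:, 0] - config.spine_x)
    in_corridor = (z_off[:, None] <= config.corridor_width) & (r_off[None, :] <= config.corridor_width)
    at = (z_off[:, None] + r_off[None, :]) / config.walk_speed * 60.0 + config.stop_access_time
    t_iv = np.abs(dy) / config.transit_speed * 60.0 + 1.0
    wt = np.full_like(t_iv, config.headway / 2.0)
    access_km = z_off[:, None] + r_off[None, :]
    total_transit = t_iv + wt + at
    avail_transit = (
        in_corridor & (access_km <= config.walk_limit_km) & (total_transit <= config.total_limit_min)
    )

    nz, nr = len(zones), len(resources)
    df = pd.DataFrame({
        "zone_id": np.repeat(zones.ids.to_numpy(), nr),
        "resource_id": np.tile(resources.ids.to_numpy(), nz),
        "t_auto": np.where(avail_auto, t_auto, np.nan).ravel(),
        "t_transit_iv": np.where(avail_transit, t_iv, np.nan).ravel(),
        "wt": np.where(avail_transit, wt, np.nan).ravel(),
        "at": np.where(avail_transit, at, np.nan).ravel(),
        "t_walk": np.where(avail_walk, t_walk, np.nan).ravel(),
        "d_walk": np.where(avail_walk, d_walk, np.nan).ravel(),
    })
    return SkimSet(df)


def gen_flows(
    zones: Zones,
    resources: Resources,
    skims: SkimSet,
    truth: dict[str, float],
    coeffs: ModeCoefficients | None = None,
    n_trips: int = 10_000,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> FlowTable:
    """Draw visit flows from the generating choice model.

    Each trip picks an origin zone proportional to households, then a
    destination from the full-choice-set MNL probabilities at the true
    coefficients; trips aggregate to (zone, resource) counts.
    """
    from .accessibility import _utility_matrix

    spec = spec or ModelSpec.default(resources.rtype, impedance_kind="t_auto")
    coeffs = coeffs or ModeCoefficients()
    V = _utility_matrix(truth, spec, zones, resources, skims, coeffs)
    V = np.where(np.isnan(V), -np.inf, V)
    P = softmax(V, axis=1)

    rng = np.random.default_rng(seed)
    hh = zones.df["households"].to_numpy(dtype=float)
    origin_counts = rng.multinomial(n_trips, hh / hh.sum())
    counts = np.zeros((len(zones), len(resources)), dtype=int)
    for z, c in enumerate(origin_counts):
        if c:
            counts[z] = rng.multinomial(c, P[z])
    zi, ri = np.nonzero(counts)
    return FlowTable(pd.DataFrame({
        "zone_id": zones.ids.to_numpy()[zi],
        "resource_id": resources.ids.to_numpy()[ri],
        "count": counts[zi, ri],
    }))


@dataclass
class SyntheticRegion:
    """A fully generated study region with known generating coefficients."""

    config: RegionConfig
    zones: Zones
    resources: dict[str, Resources]
    skims: dict[str, SkimSet]
    flows: dict[str, FlowTable]
    truth: dict[str, dict[str, float]]
    specs: dict[str, ModelSpec]


def generate(config: RegionConfig | None = None, coeffs: ModeCoefficients | None = None) -> SyntheticRegion:
    """End-to-end generation of zones, resources, skims, and flows."""
    config = config or RegionConfig()
    zones, resources = gen_region(config)
    skims, flows, truth, specs = {}, {}, {}, {}
    for k, (rtype, res) in enumerate(resources.items()):
        spec, coef = default_truth(rtype)
        sk = gen_skims(zones, res, config)
        flows[rtype] = gen_flows(
            zones, res, sk, coef, coeffs,
            n_trips=config.n_device_trips,
            seed=config.seed + config.SEED_FLOWS + k, spec=spec,
        )
        skims[rtype], truth[rtype], specs[rtype] = sk, coef, spec
    return SyntheticRegion(config, zones, resources, skims, flows, truth, specs)


def simulate(config: RegionConfig | None = None, out_dir: str | Path = ".") -> SyntheticRegion:
    """Generate a region and write the standard CSVs plus a truth file."""
    region = generate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region.zones.to_csv(out / "zones.csv")
    for rtype, res in region.resources.items():
        res.to_csv(out / f"{rtype}_resources.csv")
        region.skims[rtype].to_csv(out / f"{rtype}_skims.csv")
        region.flows[rtype].to_csv(out / f"{rtype}_flows.csv")
    truth_payload = {
        rtype: {
            "impedance_kind": region.specs[rtype].impedance_kind,
            "coef": region.truth[rtype],
        }
        for rtype in region.truth
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=2))
    return region
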