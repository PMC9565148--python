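"""Assemble destination-choice estimation datasets from visit flows.

The observed data are aggregate origin–destination visit counts (for
instance from location-based-services devices).  Estimation works on
simulated "trips": each trip is a (zone, chosen resource) pair drawn with
probability proportional to the flow count, paired with a fresh random
sample of non-chosen alternatives drawn uniformly without replacement from
the remaining resources.  Uniform sampling of alternatives keeps the
multinomial-logit estimator consistent without correction terms, at some
cost in efficiency.

Observations containing any unreachable pair or missing covariate are
dropped whole — never thinned alternative-by-alternative — so every
retained observation keeps the same choice-set size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .impedance import ModeCoefficients, impedance_matrix
from .region import RESOURCE_SCHEMAS, FlowTable, Resources, SkimSet

__all__ = [
    "ModelSpec",
    "ChoiceDataset",
    "sample_trips",
    "sample_alternatives",
    "attach_covariates",
    "build_dataset",
]

logger = logging.getLogger(__name__)

Transform = Literal["identity", "log"]

#: Default "full" specification per resource type: the relevant impedance
#: plus every attribute in the schema, with sizes log-transformed.
DEFAULT_ATTRIBUTE_TERMS: dict[str, list[tuple[str, Transform]]] = {
    "park": [
        ("acres", "log"), ("playground", "identity"), ("volleyball", "identity"),
        ("basketball", "identity"), ("tennis", "identity"),
    ],
    "grocery": [
        ("convenience", "identity"), ("other_nonstandard", "identity"),
        ("pharmacy", "identity"), ("ethnic_market", "identity"),
        ("other_merchandise", "identity"), ("n_registers", "identity"),
        ("n_selfcheckout", "identity"),
    ],
    "library": [
        ("offers_classes", "identity"), ("genealogy", "identity"), ("sqft", "log"),
    ],
}


@dataclass(frozen=True)
class ModelSpec:
    """Columns of a destination-choice utility: one impedance term plus
    declared attribute transforms.

    ``impedance_kind="t_auto"`` gives the car-time model; ``"mcls"`` uses the
    multimodal mode-choice logsum.  ``attribute_terms`` is an ordered list
    of ``(attribute, transform)`` with transform in {identity, log}; log is
    only valid on strictly positive attributes.
    """

    rtype: str
    impedance_kind: Literal["mcls", "t_auto"] = "t_auto"
    attribute_terms: tuple[tuple[str, Transform], ...] = ()

    def __post_init__(self) -> None:
        schema = RESOURCE_SCHEMAS.get(self.rtype)
        if schema is None:
            raise ValueError(f"unknown rtype {self.rtype!r}")
        if self.impedance_kind not in ("mcls", "t_auto"):
            raise ValueError(f"unknown impedance kind {self.impedance_kind!r}")
        for name, transform in self.attribute_terms:
            if name not in schema:
                raise ValueError(
                    f"attribute {name!r} is not in the {self.rtype} schema "
                    f"({sorted(schema)})"
                )
            if transform not in ("identity", "log"):
                raise ValueError(f"unknown transform {transform!r}")
            if transform == "log" and schema[name] != "size":
                raise ValueError(f"log transform requires a positive size attribute, not {name!r}")

    @classmethod
    def default(cls, rtype: str, impedance_kind: str = "t_auto") -> "ModelSpec":
        """The full specification (impedance + all attributes) for an rtype."""
        return cls(rtype, impedance_kind, tuple(DEFAULT_ATTRIBUTE_TERMS[rtype]))

    @property
    def covariate_names(self) -> list[str]:
        names = [self.impedance_kind]
        for name, transform in self.attribute_terms:
            names.append(f"log_{name}" if transform == "log" else name)
        return names


@dataclass
class ChoiceDataset:
    """Long-format estimation data: one row per alternative, grouped by
    observation, with exactly one chosen row per observation.

    ``df`` columns: ``obs_id``, ``zone_id``, ``resource_id``, ``chosen``
    plus one column per covariate in ``spec.covariate_names``.
    """

    df: pd.DataFrame
    spec: ModelSpec
    n_dropped: int = 0
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        chosen_per_obs = self.df.groupby("obs_id")["chosen"].sum()
        if not (chosen_per_obs == 1).all():
            raise ValueError("each observation must have exactly one chosen alternative")
        if self.df.duplicated(["obs_id", "resource_id"]).any():
            raise ValueError("duplicate resource within an observation")
        if not np.isfinite(self.df[self.spec.covariate_names].to_numpy(float)).all():
            raise ValueError("non-finite covariates in retained observations")

    @property
    def n_obs(self) -> int:
        return self.df["obs_id"].nunique()

    @property
    def n_alt_per_obs(self) -> int:
        """Choice-set size (constant across observations by construction)."""
        sizes = self.df.groupby("obs_id").size()
        return int(sizes.iloc[0]) if (sizes == sizes.iloc[0]).all() else int(sizes.mode().iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, spec: ModelSpec) -> "ChoiceDataset":
        df = pd.read_csv(path)
        df["chosen"] = df["chosen"].astype(bool)
        return cls(df, spec)


def sample_trips(flows: FlowTable, n_trips: int, seed: int) -> pd.DataFrame:
    """Draw ``n_trips`` (zone, chosen resource) pairs i.i.d. with probability
    proportional to flow counts.  Returns obs_id / zone_id / resource_id."""
    counts = flows.df["count"].to_numpy(dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot sample trips from an all-zero flow table")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(flows.df), size=n_trips, p=counts / total)
    picked = flows.df.iloc[idx]
    return pd.DataFrame({
        "obs_id": np.arange(n_trips),
        "zone_id": picked["zone_id"].to_numpy(),
        "resource_id": picked["resource_id"].to_numpy(),
    })


def sample_alternatives(
    trips: pd.DataFrame,
    resources: Resources,
    n_alt: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair each trip with ``n_alt`` distinct non-chosen resources drawn
    uniformly without replacement, independently per observation.

    If fewer than ``n_alt`` other resources exist, all of them are used.
    Returns the long frame (obs_id, zone_id, resource_id, chosen) with the
    chosen alternative included once per observation.
    """
    res_ids = resources.ids.to_numpy()
    n_res = len(res_ids)
    if n_res < 2:
        raise ValueError("need at least two resources to form a choice contrast")
    k = min(n_alt, n_res - 1)
    rng = np.random.default_rng(seed)
    id_to_pos = {rid: p for p, rid in enumerate(res_ids)}
    chosen_pos = trips["resource_id"].map(id_to_pos).to_numpy()
    # One uniform key per (obs, resource); the chosen column is forced to the
    # bottom so the k smallest keys are a uniform sample of the others.
    keys = rng.random((len(trips), n_res))
    keys[np.arange(len(trips)), chosen_pos] = np.inf
    samp = np.argpartition(keys, k - 1, axis=1)[:, :k]

    n_rows = k + 1
    obs = np.repeat(trips["obs_id"].to_numpy(), n_rows)
    zones = np.repeat(trips["zone_id"].to_numpy(), n_rows)
    alt_pos = np.column_stack([chosen_pos, samp]).ravel()
    chosen = np.tile(np.arange(n_rows) == 0, len(trips))
    return pd.DataFrame({
        "obs_id": obs,
        "zone_id": zones,
        "resource_id": res_ids[alt_pos],
        "chosen": chosen,
    })


def attach_covariates(
    long: pd.DataFrame,
    skims: SkimSet,
    resources: Resources,
    spec: ModelSpec,
    coeffs: ModeCoefficients | None = None,
) -> ChoiceDataset:
    """Join the impedance and attribute covariates onto a sampled long frame.

    Observations with any unreachable pair or non-finite covariate are
    dropped whole; the drop count is logged and recorded on the dataset.
    """
    coeffs = coeffs or ModeCoefficients()
    df = long.copy()

    zone_ids = np.unique(df["zone_id"])
    res_ids = resources.ids.to_numpy()
    imp = impedance_matrix(skims, coeffs, spec.impedance_kind, zone_ids, res_ids)
    z_pos = pd.Series(np.arange(len(zone_ids)), index=zone_ids)
    r_pos = pd.Series(np.arange(len(res_ids)), index=res_ids)
    df[spec.impedance_kind] = imp[
        z_pos[df["zone_id"]].to_numpy(), r_pos[df["resource_id"]].to_numpy()
    ]

    attrs = resources.df.set_index("resource_id")
    for name, transform in spec.attribute_terms:
        vals = attrs[name].astype(float)
        col = name
        if transform == "log":
            col = f"log_{name}"
            vals = np.log(vals)
        df[col] = vals.reindex(df["resource_id"]).to_numpy()

    cov = df[spec.covariate_names].to_numpy(dtype=float)
    bad_obs = df.loc[~np.isfinite(cov).all(axis=1), "obs_id"].unique()
    n_dropped = len(bad_obs)
    if n_dropped:
        logger.info(
            "dropped %d of %d observations with unreachable pairs or missing covariates",
            n_dropped, df["obs_id"].nunique(),
        )
        df = df[~df["obs_id"].isin(bad_obs)]
    if df.empty:
        raise ValueError("all observations dropped: no reachable choice sets")
    return ChoiceDataset(df.reset_index(drop=True), spec, n_dropped=n_dropped)


def build_dataset(
    flows: FlowTable,
    resources: Resources,
    skims: SkimSet,
    spec: ModelSpec,
    n_trips: int = 10_000,
    n_alt: int = 10,
    seed: int = 0,
    coeffs: ModeCoefficients | None = None,
) -> ChoiceDataset:
    """Full pipeline: sample trips, sample alternatives, attach covariates.

    Child seeds are derived from ``seed`` by fixed offsets so each stage is
    independently reproducible.
    """
    trip_seed, alt_seed = seed + 101, seed + 202
    trips = sample_trips(flows, n_trips, trip_seed)
    long = sample_alternatives(trips, resources, n_alt=n_alt, seed=alt_seed)
    ds = attach_covariates(long, skims, resources, spec, coeffs)
    ds.seeds = {"seed": seed, "trips": trip_seed, "alternatives": alt_seed}
    return ds
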