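"""Household-weighted equity accounting of low-access zones.

Two definitions of "low access" are cross-tabulated:

* outside every resource buffer — no park within a walkable threshold, no
  grocery or library within a drivable one; and
* below the regional mean utility-based (logsum) access to *all* resource
  types at once (strict inequality).

Counts are sums of zone households over flagged zones; low-income counts
attribute each zone's households fractionally by its low-income share
(block-group aggregates admit nothing finer) and are rounded half-even
once, at table level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .accessibility import AccessSurface
from .region import RTYPES, Zones

__all__ = ["EquityTable", "classify_zones", "equity_summary"]


def classify_zones(
    buffer_surfaces: Mapping[str, AccessSurface],
    logsum_surfaces: Mapping[str, AccessSurface],
    zones: Zones,
    weighted_mean: bool = False,
) -> pd.DataFrame:
    """Flag each zone on both low-access definitions.

    Returns a frame indexed by zone_id with boolean columns
    ``outside_all_buffers`` (buffer flag 0 for *every* rtype) and
    ``below_mean_all_logsum`` (logsum strictly below the regional mean for
    *every* rtype).  The regional mean is unweighted by default;
    ``weighted_mean=True`` weights it by households.
    """
    missing = [r for r in RTYPES if r not in buffer_surfaces or r not in logsum_surfaces]
    if missing:
        raise ValueError(f"missing surfaces for rtype(s): {missing}")
    idx = pd.Index(zones.ids.to_numpy(), name="zone_id")
    outside = pd.Series(True, index=idx)
    below = pd.Series(True, index=idx)
    for rtype in RTYPES:
        buf = buffer_surfaces[rtype].values.reindex(idx)
        ls = logsum_surfaces[rtype].values.reindex(idx)
        mu = logsum_surfaces[rtype].mean(zones, weighted=weighted_mean)
        outside &= buf == 0
        below &= ls < mu  # strict: "beneath the regional mean"
    return pd.DataFrame({"outside_all_buffers": outside, "below_mean_all_logsum": below})


@dataclass
class EquityTable:
    """Household counts by low-access classification.

    Every overlap count is bounded by each of its marginals, and every
    low-income count by its total.
    """

    hh_outside_buffers: int
    low_income_outside_buffers: int
    hh_below_mean_logsum: int
    low_income_below_mean_logsum: int
    hh_both: int
    low_income_both: int

    def __post_init__(self) -> None:
        assert self.hh_both <= min(self.hh_outside_buffers, self.hh_below_mean_logsum)
        assert self.low_income_outside_buffers <= self.hh_outside_buffers
        assert self.low_income_below_mean_logsum <= self.hh_below_mean_logsum
        assert self.low_income_both <= self.hh_both

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "households": [
                    self.hh_outside_buffers,
                    self.hh_below_mean_logsum,
                    self.hh_both,
                ],
                "low_income_households": [
                    self.low_income_outside_buffers,
                    self.low_income_below_mean_logsum,
                    self.low_income_both,
                ],
            },
            index=pd.Index(
                ["outside_all_buffers", "below_mean_all_logsum", "both"],
                name="classification",
            ),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def narrative(self) -> str:
        """Formatted text block summarising the cross-tabulation."""
        return (
            f"{self.hh_outside_buffers} households live in zones outside all "
            f"resource buffers ({self.low_income_outside_buffers} low-income).\n"
            f"{self.hh_below_mean_logsum} households live in zones beneath the "
            f"regional mean utility-based access to all resources "
            f"({self.low_income_below_mean_logsum} low-income).\n"
            f"{self.hh_both} households are in both low-access groups "
            f"({self.low_income_both} low-income)."
        )


def equity_summary(flags: pd.DataFrame, zones: Zones) -> EquityTable:
    """Aggregate classification flags into household counts.

    Total counts sum zone households; low-income counts sum
    households × frac_low_income per zone and round half-even at the end.
    """
    zdf = zones.df.set_index("zone_id").reindex(flags.index)
    hh = zdf["households"].to_numpy(dtype=float)
    low = hh * zdf["frac_low_income"].to_numpy(dtype=float)

    out = flags["outside_all_buffers"].to_numpy(dtype=bool)
    bel = flags["below_mean_all_logsum"].to_numpy(dtype=bool)
    both = out & bel

    def count(mask, w):
        return int(np.round(w[mask].sum()))

    return EquityTable(
        hh_outside_buffers=count(out, hh),
        low_income_outside_buffers=count(out, low),
        hh_below_mean_logsum=count(bel, hh),
        low_income_below_mean_logsum=count(bel, low),
        hh_both=count(both, hh),
        low_income_both=count(both, low),
    )
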