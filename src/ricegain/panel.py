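"""Elite core panel selection.

The founder set for recurrent selection is chosen from the breeding-value
table by a deterministic rule pipeline: (1) keep lines whose breeding-value
reliability clears a floor; (2) keep the top fraction ranked by breeding
value (ties broken by reliability, then id); (3) greedily prune pairs more
related than a coefficient-of-parentage ceiling, dropping the lower-BV
member; (4) apply a seed-availability / IP mask.  Stage counts are reported
so the selection cascade can be audited.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("ricegain")


@dataclass
class SelectionConfig:
    reliability_min: float = 0.4
    top_fraction: float = 0.10
    cop_max: float = 0.5  # with cop_max = 1 the relatedness stage is a no-op
    availability_column: str = "available"

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if not (0 <= self.reliability_min < 1):
            raise ValueError("reliability_min must be in [0, 1)")


@dataclass
class PanelReport:
    selected: list[str]
    counts: dict[str, int]  # candidates / post_reliability / post_top / post_cop / post_availability
    summary: dict[str, float] = field(default_factory=dict)


def select_elite_panel(
    bvs: pd.DataFrame,
    cop: Callable[[str, str], float] | Mapping[tuple[str, str], float] | None,
    cfg: SelectionConfig = SelectionConfig(),
    availability: Optional[pd.Series] = None,
) -> PanelReport:
    """Apply the four-stage elite-panel rule pipeline.

    ``cop`` is a pairwise coefficient-of-parentage accessor (callable or
    mapping keyed by id pairs); it may be None when ``cfg.cop_max >= 1``.
    ``availability`` is a boolean Series indexed by line id; lines absent
    from it are treated as available.  The result is deterministic and
    independent of the input row order.
    """
    df = bvs.loc[bvs["bv_yield"].notna()].copy()
    n0 = len(df)

    # stage 1: reliability floor
    df = df.loc[df["reliability"] >= cfg.reliability_min]
    n1 = len(df)
    if n1 == 0:
        warnings.warn("no lines pass the reliability floor; empty panel", stacklevel=2)
        return PanelReport(
            selected=[],
            counts={
                "candidates": n0, "post_reliability": 0, "post_top_fraction": 0,
                "post_relatedness": 0, "post_availability": 0,
            },
        )

    # stage 2: top fraction by BV, ties by reliability then id
    k = math.ceil(cfg.top_fraction * n1)
    df = df.sort_values(
        ["bv_yield", "reliability", "line_id"], ascending=[False, False, True]
    ).head(k)
    n2 = len(df)

    # stage 3: greedy relatedness pruning (drop the lower-BV member of any
    # pair with CoP above the ceiling; iterate from the top down)
    if cfg.cop_max < 1 and cop is not None:
        get = cop.__getitem__ if isinstance(cop, Mapping) else cop
        def pair_cop(a: str, b: str) -> float:
            if isinstance(cop, Mapping):
                return cop.get((a, b), cop.get((b, a), 0.0))  # type: ignore[union-attr]
            return float(get(a, b))
        kept: list[str] = []
        for line in df["line_id"]:
            if all(pair_cop(line, other) <= cfg.cop_max for other in kept):
                kept.append(line)
        df = df.loc[df["line_id"].isin(kept)]
    n3 = len(df)

    # stage 4: availability mask
    if availability is not None:
        avail = df["line_id"].map(availability).fillna(True).astype(bool)
        df = df.loc[avail.to_numpy()]
    n4 = len(df)

    counts = {
        "candidates": n0,
        "post_reliability": n1,
        "post_top_fraction": n2,
        "post_relatedness": n3,
        "post_availability": n4,
    }
    summary = {}
    if n4:
        summary = {
            "bv_min": float(df["bv_yield"].min()),
            "bv_max": float(df["bv_yield"].max()),
            "bv_mean": float(df["bv_yield"].mean()),
            "eqg_mean": float(df["eqg"].mean()) if "eqg" in df.columns else np.nan,
        }
    logger.info("elite panel selection cascade: %s", counts)
    return PanelReport(selected=sorted(df["line_id"].tolist()), counts=counts,
                       summary=summary)
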