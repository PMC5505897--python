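"""Persistence of diet-induced expression changes after the diet switch.

A gene is *persistent* when it is significantly altered in DR vs. AL and
remains significantly altered, in the same direction, in DR-AL vs. AL (both
comparisons against the same ad-libitum reference). Genes that change only
after the switch back to AL are "new" changes and are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Set

import numpy as np

from .diffexp import DEGTable

__all__ = ["PersistenceSummary", "classify_persistence", "intersect_tissues"]


@dataclass(frozen=True)
class PersistenceSummary:
    """Gene sets and counts for one tissue's DR / DR-AL comparison pair."""

    up_dr: frozenset
    down_dr: frozenset
    up_dral: frozenset
    down_dral: frozenset
    persist_up: frozenset
    persist_down: frozenset
    new_up: frozenset
    new_down: frozenset
    lenient: bool = False

    @property
    def n_up_dr(self) -> int:
        return len(self.up_dr)

    @property
    def n_down_dr(self) -> int:
        return len(self.down_dr)

    @property
    def n_up_dral(self) -> int:
        return len(self.up_dral)

    @property
    def n_down_dral(self) -> int:
        return len(self.down_dral)

    @property
    def n_persist_up(self) -> int:
        return len(self.persist_up)

    @property
    def n_persist_down(self) -> int:
        return len(self.persist_down)

    @property
    def pct_persist_up(self) -> float:
        """100 * persistent-up / up-in-DR; NaN when nothing was up in DR."""
        return 100.0 * self.n_persist_up / self.n_up_dr if self.n_up_dr else float("nan")

    @property
    def pct_persist_down(self) -> float:
        return 100.0 * self.n_persist_down / self.n_down_dr if self.n_down_dr else float("nan")

    @property
    def persistent(self) -> frozenset:
        return self.persist_up | self.persist_down

    def to_dict(self) -> dict:
        d = {
            "n_up_DR": self.n_up_dr,
            "n_down_DR": self.n_down_dr,
            "n_up_DRAL": self.n_up_dral,
            "n_down_DRAL": self.n_down_dral,
            "n_persist_up": self.n_persist_up,
            "n_persist_down": self.n_persist_down,
            "pct_persist_up": None if np.isnan(self.pct_persist_up) else self.pct_persist_up,
            "pct_persist_down": None if np.isnan(self.pct_persist_down) else self.pct_persist_down,
            "lenient": self.lenient,
        }
        for name in ("up_dr", "down_dr", "up_dral", "down_dral",
                     "persist_up", "persist_down", "new_up", "new_down"):
            d[f"genes_{name}"] = sorted(getattr(self, name))
        return d


def classify_persistence(
    deg_dr: DEGTable,
    deg_dral: DEGTable,
    lenient: bool = False,
) -> PersistenceSummary:
    """Classify DR-induced changes as persistent or transient after a switch.

    Both tables must cover the same gene universe and share the reference
    library (AL). Strict mode (default) requires significance in BOTH
    comparisons in the same direction. Lenient mode requires significance in
    DR only, plus a same-sign fold change in DR-AL.
    """
    if set(deg_dr.table.index) != set(deg_dral.table.index):
        raise ValueError("gene universes of the two DEG tables differ")
    if deg_dr.ref != deg_dral.ref:
        raise ValueError("the two comparisons must share the same reference")

    up_dr = frozenset(deg_dr.significant_genes("up"))
    down_dr = frozenset(deg_dr.significant_genes("down"))
    up_dral = frozenset(deg_dral.significant_genes("up"))
    down_dral = frozenset(deg_dral.significant_genes("down"))

    if lenient:
        fc = deg_dral.table["fold_change"]
        same_up = frozenset(fc.index[fc >= 1.0].tolist())
        same_down = frozenset(fc.index[fc <= -1.0].tolist())
        persist_up = up_dr & same_up
        persist_down = down_dr & same_down
    else:
        persist_up = up_dr & up_dral
        persist_down = down_dr & down_dral

    return PersistenceSummary(
        up_dr=up_dr,
        down_dr=down_dr,
        up_dral=up_dral,
        down_dral=down_dral,
        persist_up=persist_up,
        persist_down=persist_down,
        new_up=up_dral - up_dr,
        new_down=down_dral - down_dr,
        lenient=lenient,
    )


def intersect_tissues(persistent_sets: Mapping[str, Set]) -> dict:
    """Intersect named persistent-gene sets across tissues.

    Returns a report with the full intersection and every pairwise
    intersection (set semantics). Requires at least two named sets.
    """
    if len(persistent_sets) < 2:
        raise ValueError("need at least 2 tissue gene sets to intersect")
    names = list(persistent_sets)
    sets = {k: set(v) for k, v in persistent_sets.items()}
    common = set.intersection(*sets.values())
    pairwise = {}
    for a, b in combinations(names, 2):
        inter = sets[a] & sets[b]
        pairwise[f"{a}&{b}"] = {"n": len(inter), "genes": sorted(inter)}
    return {
        "tissues": names,
        "set_sizes": {k: len(v) for k, v in sets.items()},
        "common": {"n": len(common), "genes": sorted(common)},
        "pairwise": pairwise,
    }
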