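"""Shared statistical primitives.

One-way ANOVA, Tukey's HSD, the Benjamini-Hochberg step-up, and
comparative-Ct (2^-ddCt) relative quantification for qPCR plates.

ANOVA and Tukey delegate to scipy; BH delegates to statsmodels. The thin
wrappers exist to pin down behaviour at degenerate inputs (constant groups)
that the underlying routines leave as NaN, and to present group data as the
labelled mappings the rest of the package uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QpcrPlate",
    "RelExpression",
    "anova_oneway",
    "bh_adjust",
    "ddct",
    "tukey_hsd",
]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, where p_(1) <= ...
    <= p_(m) are the sorted raw p-values. Returned in the input order.

    Raises ``ValueError`` for p outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_arrays(groups) -> list[np.ndarray]:
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for a in arrays:
        if a.size < 1:
            raise ValueError("every group needs at least one observation")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite observation")
    n_total = sum(a.size for a in arrays)
    if n_total - len(arrays) < 1:
        raise ValueError("no residual degrees of freedom")
    return arrays


def anova_oneway(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA.

    ``groups`` is a mapping label -> sample vector, or a plain sequence of
    vectors. Returns ``(F, p)``.

    Degenerate conventions: zero between-group variance gives F = 0, p = 1
    even when the within-group variance is also zero; a nonzero between-group
    spread over constant groups gives F = inf, p = 0.
    """
    arrays = _group_arrays(groups)
    grand = np.concatenate(arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if np.isclose(ss_between, 0.0, atol=1e-30):
        return 0.0, 1.0
    if np.isclose(ss_within, 0.0, atol=1e-30):
        return float("inf"), 0.0
    f, p = scipy.stats.f_oneway(*arrays)
    return float(f), float(p)


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey's honestly-significant-difference test for all group pairs.

    Uses the studentized-range distribution on the pooled within-group
    variance (scipy's ``tukey_hsd``). Returns a DataFrame with one row per
    unordered pair: columns ``group1, group2, mean_diff, p_adj``.

    Constant input convention: when the pooled within-group variance is zero,
    pairs with equal means get p_adj = 1 and unequal means p_adj = 0.
    """
    labels = list(groups.keys())
    arrays = _group_arrays(groups)
    means = [a.mean() for a in arrays]
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    rows = []
    if np.isclose(ss_within, 0.0, atol=1e-30):
        for i, j in combinations(range(len(labels)), 2):
            diff = means[j] - means[i]
            rows.append((labels[i], labels[j], diff,
                         1.0 if np.isclose(diff, 0.0) else 0.0))
    else:
        res = scipy.stats.tukey_hsd(*arrays)
        for i, j in combinations(range(len(labels)), 2):
            rows.append((labels[i], labels[j], means[j] - means[i],
                         float(res.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p_adj"])


@dataclass(frozen=True)
class QpcrPlate:
    """Technical-replicate Ct values for a target and an endogenous control.

    ``data`` is long-format with columns ``sample, group, gene, replicate,
    ct``; every sample must carry at least one replicate of both genes, and
    all Ct values must be finite.
    """

    data: pd.DataFrame
    target_gene: str
    control_gene: str

    def __post_init__(self) -> None:
        required = {"sample", "group", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.data["ct"].to_numpy(dtype=float))):
            raise ValueError("non-finite Ct value on plate")
        genes = set(self.data["gene"])
        for gene, role in ((self.target_gene, "target"),
                           (self.control_gene, "control")):
            if gene not in genes:
                raise ValueError(f"{role} gene {gene!r} absent from plate")
        per_sample = self.data.groupby("sample")["gene"].agg(set)
        for sample, present in per_sample.items():
            if self.control_gene not in present:
                raise ValueError(f"sample {sample!r} has no control-gene wells")
            if self.target_gene not in present:
                raise ValueError(f"sample {sample!r} has no target-gene wells")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class RelExpression:
    """Per-sample comparative-Ct relative expression.

    ``table`` columns: sample, group, target_ct, control_ct, dct, ddct, rq.
    ``rq = 2^(-ddCt)`` is fold expression relative to the calibrator-group
    mean; the calibrator group's ddCt values average to zero by construction,
    so its rq values have geometric mean 1.
    """

    table: pd.DataFrame
    calibrator_group: str = "AL"
    calibrator_mean_dct: float = field(default=np.nan)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def ddct(plate: QpcrPlate, calibrator_group: str = "AL") -> RelExpression:
    """2^-ddCt relative expression against an endogenous control.

    Technical replicates are averaged arithmetically on the Ct scale. Per
    sample, dCt = mean target Ct - mean control Ct; ddCt subtracts the mean
    dCt of the calibrator group; rq = 2^(-ddCt).
    """
    if calibrator_group not in set(plate.data["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} not on plate")
    mean_ct = (
        plate.data.groupby(["sample", "group", "gene"])["ct"]
        .mean()
        .unstack("gene")
        .reset_index()
    )
    out = pd.DataFrame({
        "sample": mean_ct["sample"],
        "group": mean_ct["group"],
        "target_ct": mean_ct[plate.target_gene],
        "control_ct": mean_ct[plate.control_gene],
    })
    out["dct"] = out["target_ct"] - out["control_ct"]
    cal_mean = float(out.loc[out["group"] == calibrator_group, "dct"].mean())
    out["ddct"] = out["dct"] - cal_mean
    out["rq"] = np.exp2(-out["ddct"])
    # keep plate sample order
    order = {s: i for i, s in enumerate(plate.samples)}
    out = out.sort_values("sample", key=lambda s: s.map(order),
                          ignore_index=True)
    return RelExpression(out, calibrator_group, cal_mean)
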