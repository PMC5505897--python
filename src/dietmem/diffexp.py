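"""Differential expression between pooled, unreplicated RNA-seq libraries.

With one pooled library per diet group there are no biological replicates,
so ordinary dispersion-based tests do not apply. Counts are treated as
Poisson, normalized by each library's total mapped reads, and compared with
a Z-test after a square-root variance-stabilizing transform: for
X ~ Poisson(lam), sqrt(X) has variance ~= 1/4 independent of lam, so

    z = ( sqrt(x1/N1) - sqrt(x2/N2) ) / ( 0.5 * sqrt(1/N1 + 1/N2) )

is approximately standard normal under the null of equal rates. The
denominator is the delta-method standard error of the transformed rate
difference. Genes are declared differentially expressed when the
Benjamini-Hochberg q-value clears alpha AND the signed fold change clears a
magnitude threshold (default 1.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .stats import bh_adjust

__all__ = [
    "CountTable",
    "DEGTable",
    "call_degs",
    "fold_change",
    "normalize_rates",
    "sqrt_z_test",
]


@dataclass(frozen=True)
class CountTable:
    """Gene-by-library raw counts plus per-library total mapped reads.

    ``total_mapped_reads`` are sequencing-run totals and may exceed the
    column sums (reads mapping outside annotated genes still count toward
    the total).
    """

    counts: pd.DataFrame
    total_mapped_reads: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.total_mapped_reads.index):
            raise ValueError("count columns and totals index must match")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        totals = self.total_mapped_reads.to_numpy(dtype=float)
        if not np.all(totals > 0):
            raise ValueError("total mapped reads must be positive")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def to_tsv(self, counts_path, totals_path) -> None:
        """Write counts as TSV (gene column first) and totals as JSON."""
        import json

        self.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        with open(totals_path, "w") as fh:
            json.dump({k: int(v) for k, v in self.total_mapped_reads.items()},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_tsv(cls, counts_path, totals_path) -> "CountTable":
        import json

        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        with open(totals_path) as fh:
            totals = json.load(fh)
        return cls(counts, pd.Series(totals, dtype=float)[counts.columns])


@dataclass(frozen=True)
class DEGTable:
    """Per-gene differential-expression calls for one pairwise comparison.

    ``table`` columns: gene (index), rate_ref, rate_other (reads per million
    mapped), fold_change (signed, |fc| >= 1), z, p, q, direction
    (up/down/none), significant, tested. Genes with zero counts in both
    libraries are kept with tested=False and are not part of the BH family.
    """

    table: pd.DataFrame
    ref: str
    other: str
    alpha: float
    fc_threshold: float

    def significant_genes(self, direction: str | None = None) -> set[str]:
        t = self.table
        mask = t["significant"]
        if direction is not None:
            mask = mask & (t["direction"] == direction)
        return set(t.index[mask])

    def to_tsv(self, path) -> None:
        out = self.table.rename(columns={"rate_ref": f"rate_{self.ref}",
                                         "rate_other": f"rate_{self.other}"})
        out.rename_axis("gene").to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, alpha: float = 0.05,
                 fc_threshold: float = 1.25) -> "DEGTable":
        """Load a DEG table written by :meth:`to_tsv`.

        The reference and other library labels are recovered from the two
        ``rate_<label>`` column names (reference first).
        """
        df = pd.read_csv(path, sep="\t", index_col="gene")
        rate_cols = [c for c in df.columns if c.startswith("rate_")]
        if len(rate_cols) != 2:
            raise ValueError("expected exactly two rate_<library> columns")
        ref, other = (c[len("rate_"):] for c in rate_cols)
        df = df.rename(columns={rate_cols[0]: "rate_ref",
                                rate_cols[1]: "rate_other"})
        df["significant"] = df["significant"].astype(bool)
        df["tested"] = df["tested"].astype(bool)
        return cls(df, ref=ref, other=other, alpha=alpha,
                   fc_threshold=fc_threshold)


def normalize_rates(table: CountTable, per_million: bool = False) -> pd.DataFrame:
    """Per-gene, per-library expression rates: count / total mapped reads.

    With ``per_million`` the rate is scaled to reads per million mapped reads
    for readability; all downstream statistics use the raw rate.
    """
    totals = table.total_mapped_reads.to_numpy(dtype=float)
    rates = table.counts.to_numpy(dtype=float) / totals
    if per_million:
        rates = rates * 1e6
    return pd.DataFrame(rates, index=table.counts.index,
                        columns=table.counts.columns)


def sqrt_z_test(x1, n1, x2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Square-root-transformed Poisson Z-test between two libraries.

    ``x1, x2`` are counts (scalars or arrays) and ``n1, n2`` the library
    totals. Returns ``(z, p)`` with p the two-sided standard-normal tail
    probability. z is finite for all valid inputs, including zero counts.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("counts must be non-negative")
    if not (np.all(np.asarray(n1) > 0) and np.all(np.asarray(n2) > 0)):
        raise ValueError("library totals must be positive")
    se = 0.5 * np.sqrt(1.0 / n1 + 1.0 / n2)
    z = (np.sqrt(x1 / n1) - np.sqrt(x2 / n2)) / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return z, p


def fold_change(x1, n1, x2, n2, pseudocount: float = 0.5):
    """Signed rate ratio of library 2 over library 1.

    r = rate2 / rate1 reported as +r when r >= 1 and -1/r otherwise, so the
    magnitude is always >= 1 and the sign gives the direction. The
    pseudocount is added to BOTH counts, but only where a zero count would
    make the ratio zero or undefined. Cells where both counts and the
    pseudocount are zero come back NaN (not computable).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    needs_pc = (x1 == 0) | (x2 == 0)
    a1 = np.where(needs_pc, x1 + pseudocount, x1)
    a2 = np.where(needs_pc, x2 + pseudocount, x2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a2 / n2) / (a1 / n1)
        signed = np.where(r >= 1.0, r, -1.0 / r)
    signed = np.where((a1 == 0) & (a2 == 0), np.nan, signed)
    if signed.ndim == 0:
        return float(signed)
    return signed


def call_degs(
    table: CountTable,
    comparison: tuple[str, str],
    alpha: float = 0.05,
    fc_threshold: float = 1.25,
    pseudocount: float = 0.5,
) -> DEGTable:
    """Call differentially expressed genes between two pooled libraries.

    ``comparison = (reference, other)``; fold change and direction are
    other-vs-reference. The BH family is the set of genes with a nonzero
    count in at least one of the two libraries. Significance requires
    q < alpha and |fold change| >= fc_threshold.
    """
    ref, other = comparison
    for lib in (ref, other):
        if lib not in table.libraries:
            raise ValueError(f"library {lib!r} not in count table")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")

    x1 = table.counts[ref].to_numpy(dtype=float)
    x2 = table.counts[other].to_numpy(dtype=float)
    n1 = float(table.total_mapped_reads[ref])
    n2 = float(table.total_mapped_reads[other])

    tested = (x1 > 0) | (x2 > 0)
    z, p = sqrt_z_test(x1, n1, x2, n2)
    fc = fold_change(x1, n1, x2, n2, pseudocount)

    q = np.full(len(x1), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    with np.errstate(invalid="ignore"):
        direction = np.where(fc >= 1.0, "up", "down")
    direction = np.asarray(direction, dtype=object)
    abs_fc = np.abs(fc)
    significant = tested & (q < alpha) & (abs_fc >= fc_threshold)
    significant = np.where(np.isnan(fc), False, significant).astype(bool)
    direction[~significant] = "none"

    rates = normalize_rates(table, per_million=True)
    out = pd.DataFrame(
        {
            "rate_ref": rates[ref],
            "rate_other": rates[other],
            "fold_change": fc,
            "z": z,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": significant,
            "tested": tested,
        },
        index=table.counts.index,
    )
    return DEGTable(out, ref=ref, other=other, alpha=alpha,
                    fc_threshold=fc_threshold)
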