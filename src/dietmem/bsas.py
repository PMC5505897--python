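"""Bisulfite amplicon sequencing (BSAS) methylation quantitation.

Reads from a bisulfite-converted, PCR-amplified locus are placed on the
amplicon reference by ungapped comparison in *bisulfite space*: at reference
positions that hold a cytosine, both C (methylated, protected) and T
(converted) read bases match; everywhere else the read must match the
reference literally. At each annotated cytosine, C calls count as methylated
and T calls as unmethylated; percent methylation is per-site, per-sample.

Group statistics follow the amplicon-sequencing convention for small animal
cohorts: one-way ANOVA with Tukey's HSD on the per-sample *total* (mean
across sites of one context) and one-way ANOVA with a Benjamini-Hochberg
correction across the individual sites, CG and CH contexts adjusted as
separate families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec
from .stats import anova_oneway, bh_adjust, tukey_hsd

__all__ = [
    "MethCallMatrix",
    "SiteStatResult",
    "TotalMethResult",
    "call_sites",
    "place_read",
    "test_sites",
    "test_total",
    "total_methylation",
]

_BASE2CODE = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 255, dtype=np.uint8)
    for base, code in _BASE2CODE.items():
        out[arr == ord(base)] = code
    return out


def place_read(read: str, spec: AmpliconSpec, max_mm: float = 0.1
               ) -> tuple[int, int] | None:
    """Place one read on the amplicon by ungapped bisulfite-space matching.

    Tries every offset where the read fits; a position mismatches when the
    read base differs from the reference base, except at reference cytosines
    where both C and T are accepted. Returns ``(offset, n_mismatches)`` for
    the best (fewest-mismatch, then leftmost) offset whose mismatch fraction
    is <= ``max_mm``, or None when the read fails everywhere.
    """
    lr = len(read)
    if lr == 0 or lr > len(spec.sequence):
        return None
    ref = _encode(spec.sequence)
    r = _encode(read)
    is_c = ref == _BASE2CODE["C"]
    n_off = len(spec.sequence) - lr + 1
    # windows over the reference: (n_off, lr) strided views
    ref_w = np.lib.stride_tricks.sliding_window_view(ref, lr)
    isc_w = np.lib.stride_tricks.sliding_window_view(is_c, lr)
    literal = ref_w != r
    bis_ok = isc_w & ((r == _BASE2CODE["C"]) | (r == _BASE2CODE["T"]))
    mm = (literal & ~bis_ok).sum(axis=1)
    best = int(np.argmin(mm))  # argmin takes the smallest index on ties
    if mm[best] / lr > max_mm:
        return None
    return best, int(mm[best])


@dataclass(frozen=True)
class MethCallMatrix:
    """Per sample x site methylation calls.

    ``n_meth``, ``n_unmeth``, ``n_other`` are DataFrames (samples x site
    offsets); ``pct`` is 100 * n_meth / (n_meth + n_unmeth), NaN where no
    informative call covers the site. ``n_rejected`` counts reads per sample
    that failed placement.
    """

    spec: AmpliconSpec
    n_meth: pd.DataFrame
    n_unmeth: pd.DataFrame
    n_other: pd.DataFrame
    n_rejected: pd.Series
    min_coverage: int = 1000

    @property
    def samples(self) -> list[str]:
        return list(self.n_meth.index)

    @property
    def coverage(self) -> pd.DataFrame:
        """Informative (C or T) calls per sample per site."""
        return self.n_meth + self.n_unmeth

    @property
    def pct(self) -> pd.DataFrame:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.n_meth / cov.where(cov > 0)

    def covered_offsets(self) -> list[int]:
        """Sites whose coverage clears ``min_coverage`` in every sample."""
        cov = self.coverage
        ok = (cov >= self.min_coverage).all(axis=0)
        return [int(c) for c in cov.columns[ok]]

    def context_offsets(self, context: str, covered_only: bool = True) -> list[int]:
        if context not in ("CG", "CH"):
            raise ValueError("context must be 'CG' or 'CH'")
        wanted = {s.offset for s in self.spec.sites if s.context == context}
        pool = self.covered_offsets() if covered_only else [int(c) for c in self.n_meth.columns]
        return [o for o in pool if o in wanted]

    def to_tsv(self, path) -> None:
        ctx = {s.offset: s.context for s in self.spec.sites}
        pct = self.pct
        rows = []
        for off in pct.columns:
            row = {"offset": int(off), "context": ctx[int(off)]}
            for sample in pct.index:
                row[f"pct_{sample}"] = pct.loc[sample, off]
                row[f"cov_{sample}"] = int(self.coverage.loc[sample, off])
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                                  float_format="%.4f")


def call_sites(
    reads_by_sample: Mapping[str, Iterable[str]],
    spec: AmpliconSpec,
    min_coverage: int = 1000,
    max_mm: float = 0.1,
) -> MethCallMatrix:
    """Place reads and tally methylated/unmethylated calls at every site.

    At each annotated cytosine covered by a placed read, a C base call counts
    as methylated, T as unmethylated, and any other base is tallied
    separately and ignored by the percentage. ``min_coverage`` (default 1000,
    the depth the assay is designed for) is recorded on the matrix and
    governs which sites enter downstream group statistics.
    """
    offsets = np.array([s.offset for s in spec.sites], dtype=int)
    samples = list(reads_by_sample)
    shape = (len(samples), offsets.size)
    n_meth = np.zeros(shape, dtype=int)
    n_unmeth = np.zeros(shape, dtype=int)
    n_other = np.zeros(shape, dtype=int)
    n_rej = np.zeros(len(samples), dtype=int)

    code_c, code_t = _BASE2CODE["C"], _BASE2CODE["T"]
    for si, sample in enumerate(samples):
        placed: dict[tuple[int, int], list[np.ndarray]] = {}
        for read in reads_by_sample[sample]:
            hit = place_read(read, spec, max_mm=max_mm)
            if hit is None:
                n_rej[si] += 1
                continue
            off, _ = hit
            placed.setdefault((off, len(read)), []).append(_encode(read))
        for (off, lr), rows in placed.items():
            mat = np.vstack(rows)
            in_win = (offsets >= off) & (offsets < off + lr)
            cols = offsets[in_win] - off
            calls = mat[:, cols]  # (reads, sites-in-window)
            n_meth[si, in_win] += (calls == code_c).sum(axis=0)
            n_unmeth[si, in_win] += (calls == code_t).sum(axis=0)
            n_other[si, in_win] += ((calls != code_c) & (calls != code_t)).sum(axis=0)

    if not samples or (n_meth.sum() + n_unmeth.sum() + n_other.sum()) == 0:
        import warnings

        warnings.warn("no reads were placed; methylation matrix is empty",
                      stacklevel=2)

    cols = pd.Index(offsets, name="offset")
    idx = pd.Index(samples, name="sample")
    return MethCallMatrix(
        spec=spec,
        n_meth=pd.DataFrame(n_meth, index=idx, columns=cols),
        n_unmeth=pd.DataFrame(n_unmeth, index=idx, columns=cols),
        n_other=pd.DataFrame(n_other, index=idx, columns=cols),
        n_rejected=pd.Series(n_rej, index=idx),
        min_coverage=min_coverage,
    )


def total_methylation(
    matrix: MethCallMatrix,
    context: str,
    weighting: str = "site-mean",
) -> pd.Series:
    """Per-sample total methylation over the sites of one context.

    ``site-mean`` (default) is the unweighted mean of per-site percentages —
    invariant to coverage imbalance between sites. ``read-weighted`` pools
    the raw calls first (100 * sum meth / sum informative); the two coincide
    when coverage is equal at every site. Only sites clearing the matrix's
    ``min_coverage`` in all samples contribute.
    """
    offs = matrix.context_offsets(context)
    if not offs:
        raise ValueError(f"no covered {context} sites")
    if weighting == "site-mean":
        return matrix.pct[offs].mean(axis=1)
    if weighting == "read-weighted":
        meth = matrix.n_meth[offs].sum(axis=1)
        info = matrix.coverage[offs].sum(axis=1)
        return 100.0 * meth / info.where(info > 0)
    raise ValueError("weighting must be 'site-mean' or 'read-weighted'")


@dataclass(frozen=True)
class TotalMethResult:
    """Group comparison of per-sample total methylation for one context."""

    context: str
    totals: Mapping[str, np.ndarray]
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    percent_decrease: Mapping[str, float]
    reference: str = "AL"

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "group_means": {g: float(np.mean(v)) for g, v in self.totals.items()},
            "anova_F": self.anova_f,
            "anova_p": self.anova_p,
            "tukey": self.tukey.to_dict(orient="records"),
            "percent_decrease_vs_" + self.reference: dict(self.percent_decrease),
        }


def test_total(
    totals_by_group: Mapping[str, Sequence[float]],
    context: str = "CG",
    reference: str = "AL",
) -> TotalMethResult:
    """ANOVA + Tukey HSD on per-sample total methylation across diet groups.

    Also reports the percent decrease of every non-reference group relative
    to the reference mean: 100 * (mean_ref - mean_g) / mean_ref.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in totals_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    f, p = anova_oneway(groups)
    tk = tukey_hsd(groups)
    decrease: dict[str, float] = {}
    if reference in groups:
        ref_mean = float(groups[reference].mean())
        for g, v in groups.items():
            if g != reference and ref_mean != 0:
                decrease[g] = 100.0 * (ref_mean - float(v.mean())) / ref_mean
    return TotalMethResult(context=context, totals=groups, anova_f=f,
                           anova_p=p, tukey=tk, percent_decrease=decrease,
                           reference=reference)


@dataclass(frozen=True)
class SiteStatResult:
    """Per-site group comparison with BH adjustment within each context.

    ``table`` columns: offset, context, mean_<group>..., f, p, q,
    significant. CG and CH sites form separate BH families.
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def flagged_offsets(self, context: str | None = None) -> list[int]:
        t = self.table
        mask = t["significant"]
        if context is not None:
            mask = mask & (t["context"] == context)
        return [int(o) for o in t.loc[mask, "offset"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def test_sites(
    matrix_by_group: Mapping[str, MethCallMatrix],
    alpha: float = 0.05,
) -> SiteStatResult:
    """Per-site one-way ANOVA across diet groups with BH per context family.

    Each group's matrix holds that group's samples over the same amplicon.
    A site enters the test only when it clears ``min_coverage`` in every
    sample of every group; CG and CH q-values are adjusted separately.
    """
    if len(matrix_by_group) < 2:
        raise ValueError("need at least 2 groups")
    matrices = list(matrix_by_group.values())
    spec = matrices[0].spec
    if any(m.spec.sequence != spec.sequence for m in matrices):
        raise ValueError("matrices cover different amplicons")

    covered = set(matrices[0].covered_offsets())
    for m in matrices[1:]:
        covered &= set(m.covered_offsets())
    ctx = {s.offset: s.context for s in spec.sites}

    rows = []
    for off in sorted(covered):
        vals = {g: m.pct[off].to_numpy(dtype=float)
                for g, m in matrix_by_group.items()}
        f, p = anova_oneway(vals)
        row = {"offset": off, "context": ctx[off], "f": f, "p": p}
        for g, v in vals.items():
            row[f"mean_{g}"] = float(np.mean(v))
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(columns=["offset", "context", "f", "p", "q",
                                      "significant"])
        return SiteStatResult(table, alpha=alpha)

    table["q"] = np.nan
    for context in ("CG", "CH"):
        mask = table["context"] == context
        if mask.any():
            table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return SiteStatResult(table.reset_index(drop=True), alpha=alpha)
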