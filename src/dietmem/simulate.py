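"""Synthetic data with known ground truth for the three-diet study design.

Emulates (i) pooled RNA-seq count tables for AL / DR / DR-AL groups with a
configurable fraction of persistent vs. transient fold-change effects,
(ii) deep bisulfite amplicon read sets over references with planted CG
layouts (e.g. 3 CG in 397 bp, 5 CG in 342 bp, 22 CG in 560 bp),
(iii) qPCR Ct plates with technical replicates.

Counts are Poisson — the same distributional assumption the pooled Z-test
makes — so the generator doubles as a calibration bench for that test.
Bisulfite conversion inefficiency is modeled as unconverted unmethylated
cytosines (the standard failure mode: they read as C and inflate apparent
methylation). All randomness flows from explicit per-scenario seeds; there
is no global state, and identical scenarios give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec, annotate_cytosines
from .diffexp import CountTable
from .stats import QpcrPlate

__all__ = [
    "ExpressionScenario",
    "ExpressionTruth",
    "MethylationScenario",
    "QpcrScenario",
    "make_amplicon",
    "simulate_bisulfite_reads",
    "simulate_counts",
    "simulate_qpcr",
    "uniform_site_methylation",
    "write_fastq",
]

GROUPS = ("AL", "DR", "DR-AL")

STATUSES = ("null", "up_persistent", "up_transient",
            "down_persistent", "down_transient")


# ---------------------------------------------------------------- expression

@dataclass(frozen=True)
class ExpressionScenario:
    """Pooled three-group RNA-seq design with planted fold-change effects.

    ``baseline_mean`` is the expected read count per gene in the AL library
    at its stated size; other libraries scale by their total mapped reads.
    ``frac_persistent`` is the fraction of affected genes whose DR effect is
    retained in DR-AL (the rest revert to baseline after the switch).
    """

    n_genes: int = 10_000
    groups: tuple[str, ...] = GROUPS
    library_size_per_group: tuple[int, ...] = (30_000_000,) * 3
    baseline_mean: float = 100.0
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_fold: float = 2.0
    frac_persistent: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.groups) != 3:
            raise ValueError("expected three ordered groups (baseline, "
                             "restricted, switched)")
        if len(self.groups) != len(self.library_size_per_group):
            raise ValueError("one library size per group")
        if any(n <= 0 for n in self.library_size_per_group):
            raise ValueError("library sizes must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        for name in ("frac_up", "frac_down", "frac_persistent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if self.effect_fold < 1.0:
            raise ValueError("effect_fold must be >= 1")


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth for a simulated count table.

    ``table``: per gene, the status label and the true rate multiplier in
    every group. The status fully determines the multipliers: persistent
    effects apply in DR and DR-AL, transient effects in DR only, and the AL
    multiplier is always 1.
    """

    table: pd.DataFrame
    scenario: ExpressionScenario

    def genes_with_status(self, status: str) -> set[str]:
        if status not in STATUSES:
            raise ValueError(f"unknown status {status!r}")
        t = self.table
        return set(t.index[t["status"] == status])

    @property
    def persistent_fraction_up(self) -> float:
        n_up = len(self.genes_with_status("up_persistent")) \
            + len(self.genes_with_status("up_transient"))
        if n_up == 0:
            return float("nan")
        return len(self.genes_with_status("up_persistent")) / n_up

    def to_json(self, path) -> None:
        payload = {
            "scenario": asdict(self.scenario),
            "genes": {
                g: {"status": row["status"],
                    "multipliers": {grp: row[f"mult_{grp}"]
                                    for grp in self.scenario.groups}}
                for g, row in self.table.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_counts(scenario: ExpressionScenario
                    ) -> tuple[CountTable, ExpressionTruth]:
    """Draw a pooled Poisson count table with planted DE effects.

    Exactly ``round(frac_up * n_genes)`` genes go up and
    ``round(frac_down * n_genes)`` down by ``effect_fold`` in DR; of each
    affected set, ``round(frac_persistent * n)`` keep the effect in DR-AL.
    Counts are independent Poisson draws with mean
    ``baseline_mean * multiplier * library_size / reference_size`` where the
    reference is the first (AL) library.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(sc.n_genes)], name="gene")

    n_up = round(sc.frac_up * sc.n_genes)
    n_down = round(sc.frac_down * sc.n_genes)
    n_up_pers = round(sc.frac_persistent * n_up)
    n_down_pers = round(sc.frac_persistent * n_down)

    status = np.array(["null"] * sc.n_genes, dtype=object)
    order = rng.permutation(sc.n_genes)
    up_idx, down_idx = order[:n_up], order[n_up:n_up + n_down]
    status[up_idx[:n_up_pers]] = "up_persistent"
    status[up_idx[n_up_pers:]] = "up_transient"
    status[down_idx[:n_down_pers]] = "down_persistent"
    status[down_idx[n_down_pers:]] = "down_transient"

    f = sc.effect_fold
    mult_for = {
        "null": {g: 1.0 for g in sc.groups},
        "up_persistent": {"AL": 1.0, "DR": f, "DR-AL": f},
        "up_transient": {"AL": 1.0, "DR": f, "DR-AL": 1.0},
        "down_persistent": {"AL": 1.0, "DR": 1 / f, "DR-AL": 1 / f},
        "down_transient": {"AL": 1.0, "DR": 1 / f, "DR-AL": 1.0},
    }
    # non-canonical group labels: first group is baseline, the second gets
    # the DR-style effect, the third the persistence behaviour
    alias = dict(zip(sc.groups, GROUPS))

    mult = np.ones((sc.n_genes, len(sc.groups)))
    for j, grp in enumerate(sc.groups):
        canon = alias[grp]
        mult[:, j] = [mult_for[s][canon] for s in status]

    n_ref = sc.library_size_per_group[0]
    lam = (sc.baseline_mean * mult
           * (np.asarray(sc.library_size_per_group, dtype=float) / n_ref))
    counts = rng.poisson(lam)

    table = CountTable(
        counts=pd.DataFrame(counts, index=genes, columns=list(sc.groups)),
        total_mapped_reads=pd.Series(sc.library_size_per_group,
                                     index=list(sc.groups), dtype=float),
    )
    truth_df = pd.DataFrame({"status": status}, index=genes)
    for j, grp in enumerate(sc.groups):
        truth_df[f"mult_{grp}"] = mult[:, j]
    return table, ExpressionTruth(truth_df, sc)


# ---------------------------------------------------------------- methylation

def make_amplicon(length: int, cg_positions: Sequence[int], seed: int = 0,
                  name: str = "amplicon",
                  annotations: Mapping[str, tuple[int, int]] | None = None
                  ) -> AmpliconSpec:
    """Random amplicon reference with CG dinucleotides planted exactly
    where requested and nowhere else.

    ``cg_positions`` are 0-based offsets of the C of each CG; they must lie
    in [0, length-2] and be at least 2 apart. Every other cytosine in the
    emitted sequence is in CH context by construction (no G ever follows a
    non-planted C, and the final base is never C).
    """
    positions = sorted(set(int(p) for p in cg_positions))
    if len(positions) != len(cg_positions):
        raise ValueError("duplicate CG positions")
    if any(p < 0 or p > length - 2 for p in positions):
        raise ValueError("CG positions must lie in [0, length-2]")
    if any(b - a < 2 for a, b in zip(positions, positions[1:])):
        raise ValueError("CG positions overlap")

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq = []
    for i in range(length):
        prev_c = bool(seq) and seq[-1] == "C"
        pool = "ACT" if prev_c else bases          # never a G after a C
        if i == length - 1:
            pool = pool.replace("C", "") or "AT"   # no trailing C
        seq.append(pool[rng.integers(len(pool))])
    for p in positions:
        seq[p], seq[p + 1] = "C", "G"
    return AmpliconSpec.from_sequence(name, "".join(seq),
                                      annotations=annotations)


def uniform_site_methylation(spec: AmpliconSpec, cg_level: float,
                             ch_level: float) -> tuple[float, ...]:
    """Per-site methylation vector with one level per context."""
    return tuple(cg_level if s.context == "CG" else ch_level
                 for s in spec.sites)


@dataclass(frozen=True)
class MethylationScenario:
    """Bisulfite amplicon read simulation over a fixed site-truth table.

    ``group_site_methylation`` maps each diet group to one true methylation
    fraction per annotated site, in site order. Depth defaults to 2000 reads
    per sample — comfortably above the >1000x the assay is designed for.
    """

    amplicon: AmpliconSpec
    group_site_methylation: Mapping[str, Sequence[float]]
    depth: int = 2000
    conversion_efficiency: float = 1.0
    base_error_rate: float = 0.0
    n_samples_per_group: int = 5
    seed: int = 0
    quality_char: str = "I"  # constant Phred+33 quality for emitted FASTQ

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be positive")
        for name in ("conversion_efficiency", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        n_sites = len(self.amplicon.sites)
        for grp, fracs in self.group_site_methylation.items():
            if len(fracs) != n_sites:
                raise ValueError(
                    f"group {grp!r}: need one methylation value per site "
                    f"({n_sites}), got {len(fracs)}")
            if any(not 0.0 <= f <= 1.0 for f in fracs):
                raise ValueError(f"group {grp!r}: fractions outside [0, 1]")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {65: 0, 67: 1, 71: 2, 84: 3}


def _simulate_sample_reads(spec: AmpliconSpec, site_fracs: np.ndarray,
                           depth: int, conv_eff: float, err: float,
                           rng: np.random.Generator) -> list[str]:
    ref = np.frombuffer(spec.sequence.encode("ascii"), dtype=np.uint8)
    idx = np.array([_B2I[b] for b in ref], dtype=np.uint8)
    reads = np.tile(idx, (depth, 1))
    offs = np.array([s.offset for s in spec.sites], dtype=int)
    if offs.size:
        meth = rng.random((depth, offs.size)) < site_fracs
        converted = rng.random((depth, offs.size)) < conv_eff
        to_t = ~meth & converted
        block = reads[:, offs]
        block[to_t] = 3  # T
        reads[:, offs] = block
    if err > 0:
        mask = rng.random(reads.shape) < err
        shift = rng.integers(1, 4, size=int(mask.sum()))
        reads[mask] = (reads[mask] + shift) % 4
    chars = _BASES[reads]
    return [bytes(row).decode("ascii") for row in chars]


def simulate_bisulfite_reads(scenario: MethylationScenario
                             ) -> tuple[dict[str, list[str]], dict]:
    """Simulate full-length top-strand bisulfite reads per sample.

    Each read methylates every annotated cytosine independently with its
    site's group probability; unmethylated cytosines convert C->T with
    probability ``conversion_efficiency`` (incomplete conversion leaves a C
    that is indistinguishable from methylation); uniform base-call errors are
    applied last. Returns ``(reads_by_sample, truth)`` where sample names are
    ``<group>_s<k>`` and the truth sidecar records the programmed per-site
    fractions and simulation parameters.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    reads_by_sample: dict[str, list[str]] = {}
    for group in sc.group_site_methylation:
        fracs = np.asarray(sc.group_site_methylation[group], dtype=float)
        for k in range(sc.n_samples_per_group):
            sample = f"{group}_s{k + 1}"
            reads_by_sample[sample] = _simulate_sample_reads(
                sc.amplicon, fracs, sc.depth, sc.conversion_efficiency,
                sc.base_error_rate, rng)
    truth = {
        "amplicon": sc.amplicon.name,
        "sites": [{"offset": s.offset, "context": s.context}
                  for s in sc.amplicon.sites],
        "group_site_methylation": {g: list(map(float, v))
                                   for g, v in sc.group_site_methylation.items()},
        "depth": sc.depth,
        "conversion_efficiency": sc.conversion_efficiency,
        "base_error_rate": sc.base_error_rate,
        "n_samples_per_group": sc.n_samples_per_group,
        "seed": sc.seed,
        "samples_by_group": {
            g: [f"{g}_s{k + 1}" for k in range(sc.n_samples_per_group)]
            for g in sc.group_site_methylation
        },
    }
    return reads_by_sample, truth


def write_fastq(reads: Sequence[str], path, sample: str = "sample",
                quality_char: str = "I") -> None:
    """Write reads as 4-line FASTQ with a constant Phred+33 quality."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{sample}_read{i + 1}\n{read}\n+\n"
                     f"{quality_char * len(read)}\n")


def read_fastq(path) -> list[str]:
    """Read sequences from a FASTQ file."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------- qPCR

@dataclass(frozen=True)
class QpcrScenario:
    """Comparative-Ct plate design with per-group true log2 offsets.

    ``group_log2_offset`` maps each group to its true log2 expression change
    relative to the calibrator; a +1 offset lowers the target Ct by one cycle
    and doubles the recovered relative expression. Three technical
    replicates per well, the standard plate layout.
    """

    group_log2_offset: Mapping[str, float]
    n_samples_per_group: int = 5
    target_ct_mean: float = 26.0
    control_ct_mean: float = 18.0
    n_replicates: int = 3
    ct_noise_sd: float = 0.1
    target_gene: str = "target"
    control_gene: str = "Actb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one technical replicate")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be positive")


def simulate_qpcr(scenario: QpcrScenario) -> QpcrPlate:
    """Simulate a qPCR plate from a comparative-Ct scenario.

    Target Ct replicates are ``target_ct_mean - group offset + N(0, sd)``
    (more template -> earlier threshold crossing -> lower Ct); control
    replicates are ``control_ct_mean + N(0, sd)``, independent per well.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    rows = []
    for group, offset in sc.group_log2_offset.items():
        for k in range(sc.n_samples_per_group):
            sample = f"{group}_s{k + 1}"
            for gene, mean in ((sc.target_gene, sc.target_ct_mean - offset),
                               (sc.control_gene, sc.control_ct_mean)):
                cts = mean + rng.normal(0.0, sc.ct_noise_sd, sc.n_replicates) \
                    if sc.ct_noise_sd > 0 else np.full(sc.n_replicates, mean)
                for r, ct in enumerate(cts):
                    rows.append((sample, group, gene, r + 1, float(ct)))
    data = pd.DataFrame(rows, columns=["sample", "group", "gene",
                                       "replicate", "ct"])
    return QpcrPlate(data, target_gene=sc.target_gene,
                     control_gene=sc.control_gene)
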