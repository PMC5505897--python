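"""Amplicon references with per-cytosine context annotation.

An :class:`AmpliconSpec` carries the untreated top-strand reference of a
bisulfite PCR amplicon together with the ordered list of its cytosines, each
tagged CG (next base is G) or CH (next base is A, C, or T). The annotation
covers every cytosine in the sequence; downstream methylation calls are made
site-by-site against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["AmpliconSpec", "CytosineSite", "annotate_cytosines", "convert_reference"]

_VALID = set("ACGT")


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine in amplicon-local, 0-based coordinates."""

    offset: int
    context: str  # "CG" or "CH"


def annotate_cytosines(sequence: str) -> tuple[CytosineSite, ...]:
    """Scan a sequence and annotate every C as a CG or CH site.

    A cytosine is CG iff the next base is G; a cytosine at the final
    position has no following base and counts as CH.
    """
    sites = []
    n = len(sequence)
    for i, base in enumerate(sequence):
        if base == "C":
            ctx = "CG" if i + 1 < n and sequence[i + 1] == "G" else "CH"
            sites.append(CytosineSite(i, ctx))
    return tuple(sites)


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference sequence of a bisulfite amplicon with annotated cytosines.

    ``annotations`` optionally names sub-intervals of interest (0-based,
    half-open), e.g. a transcription-factor consensus motif span.
    """

    name: str
    sequence: str
    sites: tuple[CytosineSite, ...]
    annotations: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"non-ACGT characters in reference: {sorted(bad)}")
        if self.sites != annotate_cytosines(self.sequence):
            raise ValueError("site list does not match the reference's cytosines")
        for label, (start, end) in self.annotations.items():
            if not 0 <= start < end <= len(self.sequence):
                raise ValueError(f"annotation {label!r} outside the amplicon")

    @classmethod
    def from_sequence(cls, name: str, sequence: str,
                      annotations: Mapping[str, tuple[int, int]] | None = None
                      ) -> "AmpliconSpec":
        """Build a spec by auto-annotating the cytosines of ``sequence``."""
        sequence = sequence.upper()
        return cls(name, sequence, annotate_cytosines(sequence),
                   dict(annotations or {}))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cg_offsets(self) -> tuple[int, ...]:
        return tuple(s.offset for s in self.sites if s.context == "CG")

    @property
    def ch_offsets(self) -> tuple[int, ...]:
        return tuple(s.offset for s in self.sites if s.context == "CH")

    def to_fasta(self, path) -> None:
        record = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([record], path, "fasta")

    def sites_to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "length": len(self.sequence),
            "sites": [{"offset": s.offset, "context": s.context}
                      for s in self.sites],
            "annotations": {k: list(v) for k, v in self.annotations.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_fasta(cls, fasta_path,
                   annotations: Mapping[str, tuple[int, int]] | None = None
                   ) -> "AmpliconSpec":
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
        return cls.from_sequence(record.id, str(record.seq), annotations)


def convert_reference(spec: AmpliconSpec) -> tuple[str, tuple[int, ...]]:
    """Fully bisulfite-convert the top strand of the reference.

    Every C becomes T (the converted, unmethylated expectation). Returns the
    converted sequence and the original cytosine offsets, which map converted
    coordinates back to the annotated sites (positions are unchanged by the
    substitution).
    """
    converted = spec.sequence.replace("C", "T")
    return converted, tuple(s.offset for s in spec.sites)
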