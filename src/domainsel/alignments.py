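"""Sequence containers, file readers/writers, and the read-support consensus caller.

Coordinates follow the biologist-facing convention in configs and reports
(1-based, inclusive) and the arithmetic convention internally (0-based,
half-open).  Characters other than ``A C G T -`` are stored as ``N``; both
``-`` and ``N`` are treated as missing by the downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN-")
#: characters treated as missing data in every downstream statistic
MISSING = frozenset("N-")


class AlignmentError(ValueError):
    """Raised when sequences do not form a valid alignment."""


class RegionMapError(ValueError):
    """Raised when a region map is malformed (overlap, descending order, ...)."""


@dataclass(frozen=True)
class CodonAlignment:
    """An aligned set of protein-coding nucleotide sequences.

    Parameters
    ----------
    records
        ``(id, sequence)`` pairs over the alphabet ``{A,C,G,T,-,N}``; all
        sequences must have equal length and unique ids.
    frame_offset
        0-based column index of the first complete codon position relative to
        the exon reading frame (normally 0).
    outgroup_id
        Optional id of the record used as outgroup for polarized statistics.
        The outgroup is excluded from all ingroup summaries.
    """

    records: tuple[tuple[str, str], ...]
    frame_offset: int = 0
    outgroup_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "records", tuple((str(i), str(s)) for i, s in self.records))
        if not self.records:
            raise AlignmentError("alignment contains no records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            bad = sorted({i for i, s in self.records})
            raise AlignmentError(f"sequences have unequal lengths: {bad}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        for i, s in self.records:
            extra = set(s) - NUCLEOTIDE_ALPHABET
            if extra:
                raise AlignmentError(f"record {i!r} contains illegal characters {sorted(extra)}")
        if self.outgroup_id is not None and self.outgroup_id not in set(ids):
            raise AlignmentError(f"outgroup id {self.outgroup_id!r} not among records")
        if not 0 <= self.frame_offset < 3:
            raise AlignmentError("frame_offset must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.records)

    @property
    def has_partial_codon(self) -> bool:
        """True when the frame leaves a trailing partial codon."""
        return (self.length - self.frame_offset) % 3 != 0

    def sequence(self, rec_id: str) -> str:
        for i, s in self.records:
            if i == rec_id:
                return s
        raise KeyError(rec_id)

    def ingroup(self) -> tuple[tuple[str, str], ...]:
        """Records excluding the outgroup (all records when no outgroup is set)."""
        return tuple((i, s) for i, s in self.records if i != self.outgroup_id)

    def slice(self, start: int, end: int) -> "CodonAlignment":
        """Columns ``start..end`` (1-based, inclusive) of every record.

        The slice's ``frame_offset`` is set so that codon phase relative to
        the parent exon frame is preserved.
        """
        if not (1 <= start <= end <= self.length):
            raise IndexError(f"region {start}..{end} outside alignment of length {self.length}")
        s0 = start - 1
        new_offset = (self.frame_offset - s0) % 3
        return CodonAlignment(
            records=tuple((i, s[s0:end]) for i, s in self.records),
            frame_offset=new_offset,
            outgroup_id=self.outgroup_id,
        )


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise RegionMapError(f"invalid region {self.name!r}: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionMap:
    """Named, ordered, non-overlapping subintervals of an exon."""

    gene: str
    regions: tuple[Region, ...]

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        prev_end = 0
        for r in self.regions:
            if r.start <= prev_end:
                raise RegionMapError(
                    f"region {r.name!r} ({r.start}..{r.end}) overlaps or is out of order"
                )
            prev_end = r.end
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise RegionMapError("duplicate region names")

    @property
    def lengths(self) -> dict[str, int]:
        return {r.name: r.length for r in self.regions}

    def __iter__(self):
        return iter(self.regions)


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant call with its read-support fraction."""

    position: int  # 1-based on the reference
    ref_base: str
    alt_base: str
    support_fraction: float

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt identical at position {self.position}")
        if not 0.0 <= self.support_fraction <= 1.0:
            raise ValueError(f"support fraction {self.support_fraction} outside [0, 1]")


def read_fasta_alignment(
    path: str | Path, frame_offset: int = 0, outgroup_id: str | None = None
) -> CodonAlignment:
    """Read an aligned FASTA file into a :class:`CodonAlignment`.

    Sequences are uppercased; characters outside ``{A,C,G,T,-,N}`` are mapped
    to ``N`` with a logged warning.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in NUCLEOTIDE_ALPHABET else "N" for c in seq)
        if cleaned != seq:
            bad = sorted(set(seq) - NUCLEOTIDE_ALPHABET)
            logger.warning("record %r: mapped characters %s to N", rec.id, bad)
        records.append((rec.id, cleaned))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return CodonAlignment(tuple(records), frame_offset=frame_offset, outgroup_id=outgroup_id)


def write_fasta_alignment(alignment: CodonAlignment, path: str | Path, wrap: int = 70) -> None:
    """Write the alignment as FASTA wrapped at ``wrap`` columns."""
    seqrecs = [SeqRecord(Seq(s), id=i, description="") for i, s in alignment.records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecs)


def read_region_map(path: str | Path) -> RegionMap:
    """Read a region map from YAML (``gene:`` plus ``regions: [{name, start, end}]``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "gene" not in doc or "regions" not in doc:
        raise RegionMapError(f"{path}: expected keys 'gene' and 'regions'")
    regions = tuple(
        Region(name=str(r["name"]), start=int(r["start"]), end=int(r["end"]))
        for r in doc["regions"]
    )
    rm = RegionMap(gene=str(doc["gene"]), regions=regions)
    logger.info("region map %s: %s", rm.gene, rm.lengths)
    return rm


def write_region_map(region_map: RegionMap, path: str | Path) -> None:
    doc = {
        "gene": region_map.gene,
        "regions": [{"name": r.name, "start": r.start, "end": r.end} for r in region_map],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read variants from a TSV with header ``position ref alt support_fraction``."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "ref", "alt", "support_fraction"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        VariantRecord(int(r.position), str(r.ref), str(r.alt), float(r.support_fraction))
        for r in df.itertuples()
    ]


def hapmap_consensus(reference: str, variants: list[VariantRecord]) -> str:
    """Apply majority-read variant calls to a reference sequence.

    A variant replaces the reference base only when its read-support fraction
    is strictly greater than 0.5; ties keep the reference.
    """
    seq = list(reference)
    for v in variants:
        if not 1 <= v.position <= len(reference):
            raise ValueError(f"variant position {v.position} outside reference")
        if seq[v.position - 1] != v.ref_base:
            raise ValueError(
                f"reference mismatch at {v.position}: expected {v.ref_base}, "
                f"found {seq[v.position - 1]}"
            )
        if v.support_fraction > 0.5:
            seq[v.position - 1] = v.alt_base
    return "".join(seq)
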