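"""Genomes, annotations and strand-specific 5'-end coverage.

This module owns the core containers of the pipeline: the genome, the
feature annotation with a strand-aware interval index, per-sample
nucleotide-resolution 5'-end coverage vectors, and the position x sample
count matrix that feeds the differential test.

All internal coordinates are 0-based half-open on the forward genomic
strand.  GFF3 (1-based inclusive) and SAM (1-based POS) conversions happen
only at the file boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .errors import (
    CoordinateError,
    InputError,
    ParseError,
    UnknownChromosomeError,
)

STRANDS = ("+", "-")
FEATURE_TYPES = ("gene", "CDS", "five_prime_UTR", "three_prime_UTR", "sRNA")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Ordered collection of named chromosome sequences (A/C/G/T/N)."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ParseError("duplicate chromosome id in genome")
        for cid, seq in self.records:
            if len(seq) == 0:
                raise ParseError(f"empty sequence for chromosome {cid!r}")
        self._seqs = {cid: seq for cid, seq in self.records}

    @property
    def chrom_ids(self) -> list[str]:
        return [cid for cid, _ in self.records]

    def sequence(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise UnknownChromosomeError(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence [start, end); reverse-complemented for the - strand."""
        seq = self.sequence(chrom)
        if start < 0 or end > len(seq) or start >= end:
            raise CoordinateError(
                f"window [{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Raises :class:`ParseError` on duplicate headers or empty records.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA header {rec.id!r}", path=str(path))
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ParseError("no FASTA records found", path=str(path))
    return Genome(records)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.records
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """A stranded genomic feature in 0-based half-open coordinates."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    ftype: str
    feature_id: str
    parent_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise InputError(f"bad strand {self.strand!r} for {self.feature_id}")
        if self.ftype not in FEATURE_TYPES:
            raise InputError(f"bad feature type {self.ftype!r} for {self.feature_id}")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"bad interval [{self.start}, {self.end}) for {self.feature_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def five_prime_pos(self) -> int:
        """Genomic position of the feature's 5'-most nucleotide."""
        return self.start if self.strand == "+" else self.end - 1


class AnnotationSet:
    """Feature list with a per-(chrom, strand) interval index."""

    def __init__(self, features: Sequence[Feature], genome: Genome | None = None):
        self.features: list[Feature] = list(features)
        if genome is not None:
            for f in self.features:
                if f.end > genome.length(f.chrom):
                    raise CoordinateError(
                        f"feature {f.feature_id} ends at {f.end}, beyond "
                        f"{f.chrom} (length {genome.length(f.chrom)})"
                    )
        self._index: dict[tuple[str, str], IntervalTree] = {}
        for f in self.features:
            key = (f.chrom, f.strand)
            self._index.setdefault(key, IntervalTree()).addi(f.start, f.end, f)

    def __len__(self) -> int:
        return len(self.features)

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[Feature]:
        """Features overlapping [start, end); both strands when strand is None."""
        strands = STRANDS if strand is None else (strand,)
        hits: list[Feature] = []
        for s in strands:
            tree = self._index.get((chrom, s))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(start, end))
        hits.sort(key=lambda f: (f.chrom, f.start, f.end, f.strand, f.feature_id))
        return hits

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    def by_gene(self) -> dict[str, list[Feature]]:
        """Group non-gene features by their parent gene id."""
        out: dict[str, list[Feature]] = {}
        for f in self.features:
            gid = f.feature_id if f.ftype == "gene" else f.parent_gene_id
            if gid is not None:
                out.setdefault(gid, []).append(f)
        return out


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        key, _, val = item.partition("=")
        attrs[key.strip()] = val.strip()
    return attrs


def read_annotation(path: str | Path, genome: Genome) -> AnnotationSet:
    """Read GFF3 into an :class:`AnnotationSet`.

    Coordinates are converted from GFF3 1-based inclusive to 0-based
    half-open.  Only the feature types used by the pipeline are kept
    (gene, CDS, five_prime_UTR, three_prime_UTR, sRNA); other types are
    ignored.  Features outside the genome bounds raise
    :class:`CoordinateError`; unknown chromosomes raise
    :class:`UnknownChromosomeError`.
    """
    features: list[Feature] = []
    known = set(genome.chrom_ids)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}",
                    path=str(path),
                    line=lineno,
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype not in FEATURE_TYPES:
                continue
            if chrom not in known:
                raise UnknownChromosomeError(
                    f"unknown chromosome {chrom!r} at {path}:{lineno}"
                )
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    "non-integer coordinates", path=str(path), line=lineno
                ) from None
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"bad GFF3 interval {start1}..{end1}", path=str(path), line=lineno
                )
            if end1 > genome.length(chrom):
                raise CoordinateError(
                    f"feature ends at {end1}, beyond {chrom} "
                    f"(length {genome.length(chrom)}) at {path}:{lineno}"
                )
            attrs = _parse_gff_attributes(attr_s)
            fid = attrs.get("ID", f"{ftype}:{chrom}:{start1}-{end1}({strand})")
            parent = attrs.get("Parent")
            features.append(
                Feature(
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    ftype=ftype,
                    feature_id=fid,
                    parent_gene_id=parent,
                )
            )
    return AnnotationSet(features, genome=genome)


def write_annotation(annotation: AnnotationSet, path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation.features:
            attrs = f"ID={f.feature_id}"
            if f.parent_gene_id is not None:
                attrs += f";Parent={f.parent_gene_id}"
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "tiercall",
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library: strain x temperature x replicate."""

    sample_id: str
    strain: str  # "WT" or "TS"
    temperature: int  # 30 or 44 (degrees C)
    replicate: int

    def __post_init__(self) -> None:
        if self.strain not in ("WT", "TS"):
            raise InputError(f"strain must be WT or TS, got {self.strain!r}")
        if self.temperature not in (30, 44):
            raise InputError(f"temperature must be 30 or 44, got {self.temperature}")


def read_design(path: str | Path) -> list[SampleDesign]:
    design: list[SampleDesign] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            design.append(
                SampleDesign(
                    sample_id=row["sample_id"],
                    strain=row["strain"],
                    temperature=int(row["temperature"]),
                    replicate=int(row["replicate"]),
                )
            )
    keys = [(d.strain, d.temperature, d.replicate) for d in design]
    if len(set(keys)) != len(keys):
        raise ParseError("duplicate (strain, temperature, replicate) in design", path=str(path))
    return design


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstrain\ttemperature\treplicate\n")
        for d in design:
            fh.write(f"{d.sample_id}\t{d.strain}\t{d.temperature}\t{d.replicate}\n")


def select_samples(
    design: Sequence[SampleDesign], strain: str | None = None, temperature: int | None = None
) -> list[str]:
    """Sample ids matching the given strain/temperature, in design order."""
    return [
        d.sample_id
        for d in design
        if (strain is None or d.strain == strain)
        and (temperature is None or d.temperature == temperature)
    ]


# ---------------------------------------------------------------------------
# 5'-end coverage
# ---------------------------------------------------------------------------


@dataclass
class FivePrimeCoverage:
    """Per-(chrom, strand) vectors of counted read 5' ends for one sample.

    ``arrays[(chrom, strand)][p]`` is the number of counted reads whose
    5'-most aligned base maps to position ``p`` of ``chrom`` on ``strand``.
    """

    sample_id: str
    arrays: dict[tuple[str, str], np.ndarray]
    n_counted: int = 0

    @classmethod
    def zeros(cls, sample_id: str, genome: Genome) -> "FivePrimeCoverage":
        arrays = {
            (cid, s): np.zeros(genome.length(cid), dtype=np.int64)
            for cid in genome.chrom_ids
            for s in STRANDS
        }
        return cls(sample_id=sample_id, arrays=arrays, n_counted=0)

    def total(self) -> int:
        return int(sum(int(a.sum()) for a in self.arrays.values()))

    def nonzero(self) -> pd.Series:
        """Nonzero counts as a Series indexed by (chrom, pos0, strand)."""
        chroms: list[str] = []
        positions: list[np.ndarray] = []
        strands: list[str] = []
        counts: list[np.ndarray] = []
        for (chrom, strand), arr in sorted(self.arrays.items()):
            nz = np.nonzero(arr)[0]
            if nz.size:
                chroms.extend([chrom] * nz.size)
                strands.extend([strand] * nz.size)
                positions.append(nz)
                counts.append(arr[nz])
        if not positions:
            idx = pd.MultiIndex.from_arrays(
                [[], [], []], names=["chrom", "pos0", "strand"]
            )
            return pd.Series([], index=idx, dtype=np.int64, name=self.sample_id)
        idx = pd.MultiIndex.from_arrays(
            [chroms, np.concatenate(positions), strands],
            names=["chrom", "pos0", "strand"],
        )
        return pd.Series(np.concatenate(counts), index=idx, name=self.sample_id)


def _cigar_softclip_lengths(read: pysam.AlignedSegment) -> tuple[int, int]:
    """(leading, trailing) soft-clipped lengths in reference-left order."""
    cig = read.cigartuples or []
    lead = cig[0][1] if cig and cig[0][0] == 4 else 0
    trail = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    return lead, trail


def five_prime_coverage(
    alignments: str | Path | pysam.AlignmentFile,
    genome: Genome,
    sample_id: str | None = None,
    min_mapq: int = 0,
    count_soft_clipped_start: bool = False,
) -> FivePrimeCoverage:
    """Count read 5' ends from single-end alignments.

    For a forward-strand alignment the counted position is the leftmost
    aligned base; for a reverse-strand alignment the rightmost aligned base
    (POS + reference span - 1).  Secondary, supplementary and unmapped
    records and reads below ``min_mapq`` are skipped.  With
    ``count_soft_clipped_start`` the counted position is shifted outwards by
    the length of the 5'-terminal soft clip.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    if sample_id is None:
        sample_id = "sample"
    cov = FivePrimeCoverage.zeros(sample_id, genome)
    n = 0
    try:
        for read in alignments.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            if chrom not in set(genome.chrom_ids):
                raise UnknownChromosomeError(
                    f"alignment references unknown chromosome {chrom!r}"
                )
            lead, trail = _cigar_softclip_lengths(read)
            if read.is_reverse:
                pos = read.reference_end - 1  # rightmost aligned base
                if count_soft_clipped_start:
                    pos += trail
                strand = "-"
            else:
                pos = read.reference_start
                if count_soft_clipped_start:
                    pos -= lead
                strand = "+"
            length = genome.length(chrom)
            if not (0 <= pos < length):
                raise CoordinateError(
                    f"counted position {pos} outside {chrom} (length {length})"
                )
            cov.arrays[(chrom, strand)][pos] += 1
            n += 1
    finally:
        if own:
            alignments.close()
    cov.n_counted = n
    return cov


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def read_count_table(
    path: str | Path, genome: Genome, sample_id: str | None = None
) -> FivePrimeCoverage:
    """Read a per-position 5'-end count TSV (chrom, pos0, strand, count)."""
    if sample_id is None:
        sample_id = Path(path).stem
    cov = FivePrimeCoverage.zeros(sample_id, genome)
    seen: set[tuple[str, int, str]] = set()
    total = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"expected 4 columns, got {len(fields)}", path=str(path), line=lineno
                )
            chrom, pos_s, strand, count_s = fields
            if strand not in STRANDS:
                raise ParseError(f"bad strand {strand!r}", path=str(path), line=lineno)
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError:
                raise ParseError("non-integer field", path=str(path), line=lineno) from None
            if count < 0:
                raise ParseError(f"negative count {count}", path=str(path), line=lineno)
            key = (chrom, pos, strand)
            if key in seen:
                raise ParseError(
                    f"duplicate row for {key}", path=str(path), line=lineno
                )
            seen.add(key)
            if chrom not in set(genome.chrom_ids):
                raise UnknownChromosomeError(
                    f"unknown chromosome {chrom!r} at {path}:{lineno}"
                )
            if not (0 <= pos < genome.length(chrom)):
                raise CoordinateError(
                    f"position {pos} outside {chrom} at {path}:{lineno}"
                )
            cov.arrays[(chrom, strand)][pos] = count
            total += count
    cov.n_counted = total
    return cov


def write_count_table(cov: FivePrimeCoverage, path: str | Path) -> None:
    """Write nonzero positions as TSV, sorted within (chrom, strand)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos0\tstrand\tcount\n")
        for (chrom, strand), arr in sorted(cov.arrays.items()):
            nz = np.nonzero(arr)[0]
            for p in nz:
                fh.write(f"{chrom}\t{p}\t{strand}\t{arr[p]}\n")


def write_bedgraph(cov: FivePrimeCoverage, strand: str, path: str | Path) -> None:
    """One-strand bedGraph of 5'-end counts for genome-browser inspection."""
    with open(path, "w") as fh:
        for (chrom, s), arr in sorted(cov.arrays.items()):
            if s != strand:
                continue
            nz = np.nonzero(arr)[0]
            for p in nz:
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{arr[p]}\n")


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


def build_count_matrix(
    coverages: Iterable[FivePrimeCoverage] | Mapping[str, FivePrimeCoverage],
    design: Sequence[SampleDesign],
) -> pd.DataFrame:
    """Assemble the position x sample count matrix.

    Rows are the union of positions with a nonzero count in at least one
    sample, indexed by (chrom, pos0, strand) and sorted; columns follow the
    design order.  Every design row must have a matching coverage.
    """
    if isinstance(coverages, Mapping):
        by_id = dict(coverages)
    else:
        by_id = {c.sample_id: c for c in coverages}
    missing = [d.sample_id for d in design if d.sample_id not in by_id]
    if missing:
        raise InputError(f"no coverage provided for samples: {missing}")
    cols = [by_id[d.sample_id].nonzero() for d in design]
    mat = pd.concat(cols, axis=1)
    mat = mat.fillna(0).astype(np.int64).sort_index()
    mat.columns = [d.sample_id for d in design]
    return mat
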