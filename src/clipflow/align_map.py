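"""Unique-best ungapped read mapping and stranded coverage tracks.

The mapper is an internal seed-and-extend aligner adequate for desk-scale
genomes.  The external aligner's MAPQ multimapper cut is rendered as a hard
uniqueness rule: a read whose best ungapped score is achieved at two or
more locations is *ambiguous* and excluded downstream; ties are never
broken.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np

from ._kmer import KmerIndex, hamming_scan, seq_array
from .io_formats import DNA_ALPHABET, Genome, ReadRecord, revcomp

__all__ = [
    "MapStatus",
    "AlignmentRecord",
    "MapResult",
    "map_read",
    "map_reads",
    "build_coverage",
    "write_alignments_bed",
]


class MapStatus(Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped end-to-end alignment in plus-strand coordinates."""

    read_id: str
    replicon: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    unique: bool = True
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("alignment interval is empty")


@dataclass(frozen=True)
class MapResult:
    status: MapStatus
    alignment: Optional[AlignmentRecord] = None


def _candidate_locations(
    index: KmerIndex, query: str, max_mismatches: int
) -> set[tuple[str, int]]:
    """Candidate alignment start positions for ``query`` on the plus strand.

    When the read is long enough that any alignment with <= max_mismatches
    must contain an exact run of >= k bases (pigeonhole: the mismatches cut
    the read into max_mismatches+1 runs), looking up every read k-mer is
    guaranteed complete.  Shorter reads fall back to a brute-force scan.
    """
    k = index.k
    m = len(query)
    guaranteed = (m - max_mismatches) // (max_mismatches + 1) >= k
    candidates: set[tuple[str, int]] = set()
    if guaranteed:
        for i in range(m - k + 1):
            for replicon, pos in index.lookup(query[i : i + k]):
                start = pos - i
                if 0 <= start <= len(index.genome[replicon]) - m:
                    candidates.add((replicon, start))
    else:
        qarr = seq_array(query)
        for replicon, garr in index.arrays.items():
            counts = hamming_scan(garr, qarr)
            for start in np.flatnonzero(counts <= max_mismatches):
                candidates.add((replicon, int(start)))
    return candidates


def map_read(
    genome: Genome,
    seq: str,
    max_mismatches: int = 2,
    index: Optional[KmerIndex] = None,
    read_id: str = "",
    multiplicity: int = 1,
) -> MapResult:
    """Map one read end-to-end (ungapped) against both strands.

    Returns the single best-scoring location; two or more locations tying
    at the best score yield :attr:`MapStatus.AMBIGUOUS`.  Minus-strand hits
    are reported in plus coordinates with strand ``-``.
    """
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"read contains non-DNA characters: {sorted(bad)}")
    if index is None:
        index = KmerIndex(genome)
    if len(seq) < index.k:
        return MapResult(MapStatus.UNMAPPED)

    hits: list[tuple[int, str, int, str]] = []  # (mismatches, replicon, start, strand)
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        qarr = seq_array(query)
        for replicon, start in _candidate_locations(index, query, max_mismatches):
            garr = index.arrays[replicon]
            nmm = int(np.count_nonzero(garr[start : start + len(query)] != qarr))
            if nmm <= max_mismatches:
                hits.append((nmm, replicon, start, strand))
    if not hits:
        return MapResult(MapStatus.UNMAPPED)
    best = min(h[0] for h in hits)
    best_hits = sorted(set(h for h in hits if h[0] == best))
    if len(best_hits) > 1:
        return MapResult(MapStatus.AMBIGUOUS)
    nmm, replicon, start, strand = best_hits[0]
    return MapResult(
        MapStatus.UNIQUE,
        AlignmentRecord(
            read_id=read_id,
            replicon=replicon,
            start=start,
            end=start + len(seq),
            strand=strand,
            n_mismatches=nmm,
            unique=True,
            multiplicity=multiplicity,
        ),
    )


def map_reads(
    genome: Genome,
    reads: Iterable[ReadRecord],
    max_mismatches: int = 2,
    index: Optional[KmerIndex] = None,
) -> tuple[list[AlignmentRecord], list[ReadRecord], list[ReadRecord]]:
    """Map a library; returns (unique alignments, unmapped, ambiguous)."""
    if index is None:
        index = KmerIndex(genome)
    aligned: list[AlignmentRecord] = []
    unmapped: list[ReadRecord] = []
    ambiguous: list[ReadRecord] = []
    for read in reads:
        result = map_read(
            genome,
            read.seq,
            max_mismatches=max_mismatches,
            index=index,
            read_id=read.id,
            multiplicity=read.multiplicity,
        )
        if result.status is MapStatus.UNIQUE:
            aligned.append(result.alignment)
        elif result.status is MapStatus.AMBIGUOUS:
            ambiguous.append(read)
        else:
            unmapped.append(read)
    return aligned, unmapped, ambiguous


def build_coverage(
    alignments: Iterable[AlignmentRecord],
    genome: Genome,
    use_multiplicity: bool = False,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-strand, per-replicon base coverage from unique alignments.

    Returns ``{strand: {replicon: vector}}``.  Each alignment increments
    every covered base by 1, or by its multiplicity when
    ``use_multiplicity`` is set.
    """
    cov = {
        strand: {name: np.zeros(length, dtype=np.int64) for name, length in genome.lengths.items()}
        for strand in ("+", "-")
    }
    for aln in alignments:
        weight = aln.multiplicity if use_multiplicity else 1
        cov[aln.strand][aln.replicon][aln.start : aln.end] += weight
    return cov


def write_alignments_bed(alignments: Iterable[AlignmentRecord], path) -> None:
    """BED6 export; the score column carries the collapse multiplicity."""
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(
                f"{aln.replicon}\t{aln.start}\t{aln.end}\t{aln.read_id}"
                f"\t{aln.multiplicity}\t{aln.strand}\n"
            )
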