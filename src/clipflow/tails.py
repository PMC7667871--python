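"""Non-templated 3' attachment (RNA tail) detection and composition
profiling.

A tail read consists of a 5' section that maps perfectly to the genome
followed by a suffix that does not.  The anchor must start at the read's
first base, match at a unique genomic location, and is extended maximally
along the template; the minimal remaining non-templated suffix is the
tail.  Maximal extension systematically shortens reported tails whenever
the genome continues with the same base the tail starts with — a known
convention, applied identically by the synthetic generator's truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._kmer import KmerIndex
from .io_formats import Genome, ReadRecord, revcomp

__all__ = [
    "TailRecord",
    "TailCompositionProfile",
    "detect_tail",
    "detect_tails",
    "profile_tails",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class TailRecord:
    """A read's genomic anchor plus its non-templated 3' suffix."""

    read_id: str
    replicon: str
    anchor_start: int
    anchor_end: int
    strand: str
    tail: str

    def __post_init__(self) -> None:
        if not self.tail:
            raise ValueError("tail must be at least 1 nt")


@dataclass
class TailCompositionProfile:
    """Per-position and overall base composition of a tail set.

    ``position_counts`` has shape (max_len, 4) with columns A/C/G/T;
    position k (1-based row k-1) aggregates base k of every tail of length
    >= k.  Counts are monotone non-increasing along positions.
    """

    max_len: int
    position_counts: np.ndarray
    length_histogram: np.ndarray  # index = tail length (0 unused)
    n_tails: int

    @property
    def n_per_position(self) -> np.ndarray:
        return self.position_counts.sum(axis=1)

    def position_fractions(self) -> np.ndarray:
        n = self.n_per_position[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.position_counts / n, np.nan)

    def overall_fractions(self) -> dict[str, float]:
        total = self.position_counts.sum()
        if total == 0:
            return {}
        sums = self.position_counts.sum(axis=0)
        return {base: sums[i] / total for i, base in enumerate(BASES)}

    def to_frame(self) -> pd.DataFrame:
        frac = self.position_fractions()
        rows = []
        for k in range(self.max_len):
            row = {"position": k + 1, "n": int(self.n_per_position[k])}
            for i, base in enumerate(BASES):
                row[f"count_{base}"] = int(self.position_counts[k, i])
                row[f"frac_{base}"] = frac[k, i]
            rows.append(row)
        return pd.DataFrame(rows)


def _anchor_sites(
    read_seq: str, index: KmerIndex, min_anchor: int
) -> list[tuple[str, int, str]]:
    """Candidate genomic sites where the read's 5' prefix of length
    ``min_anchor`` matches exactly.

    Returned as (replicon, site, strand) where ``site`` is the plus-strand
    coordinate of the anchor's 5'-most templated base on "+", or the
    plus-strand coordinate one past the anchor's start base on "-" (the
    anchor then runs leftward).
    """
    prefix = read_seq[:min_anchor]
    sites = []
    for replicon, pos in index.occurrences(prefix):
        sites.append((replicon, pos, "+"))
    for replicon, pos in index.occurrences(revcomp(prefix)):
        sites.append((replicon, pos + min_anchor, "-"))
    return sites


def detect_tail(
    read: ReadRecord | str,
    genome: Genome,
    min_anchor: int = 20,
    index: Optional[KmerIndex] = None,
) -> Optional[TailRecord]:
    """Detect a non-templated 3' suffix on one unmapped, non-junction read.

    Returns ``None`` when the 5' anchor is shorter than ``min_anchor``,
    matches at zero or multiple genomic locations (ambiguity rule), when
    the read matches the template to its end (no suffix), or when the
    suffix contains ``N``.
    """
    if index is None:
        index = KmerIndex(genome)
    seq = read.seq if isinstance(read, ReadRecord) else read
    read_id = read.id if isinstance(read, ReadRecord) else ""
    if len(seq) <= min_anchor:
        return None
    sites = _anchor_sites(seq, index, min_anchor)
    if len(sites) != 1:
        return None
    replicon, site, strand = sites[0]
    template = genome[replicon]
    if strand == "+":
        k = min_anchor
        while k < len(seq) and site + k < len(template) and seq[k] == template[site + k]:
            k += 1
        anchor_start, anchor_end = site, site + k
    else:
        k = min_anchor
        while (
            k < len(seq)
            and site - k - 1 >= 0
            and seq[k] == _COMPLEMENT[template[site - k - 1]]
        ):
            k += 1
        anchor_start, anchor_end = site - k, site
    tail = seq[k:]
    if not tail or "N" in tail:
        return None
    return TailRecord(
        read_id=read_id,
        replicon=replicon,
        anchor_start=anchor_start,
        anchor_end=anchor_end,
        strand=strand,
        tail=tail,
    )


def detect_tails(
    reads: Iterable[ReadRecord],
    genome: Genome,
    min_anchor: int = 20,
    exclude_ids: Optional[set[str]] = None,
    index: Optional[KmerIndex] = None,
) -> list[TailRecord]:
    """Tail detection over a library, skipping junction reads by id."""
    if index is None:
        index = KmerIndex(genome)
    exclude = exclude_ids or set()
    out = []
    for read in reads:
        if read.id in exclude:
            continue
        rec = detect_tail(read, genome, min_anchor=min_anchor, index=index)
        if rec is not None:
            out.append(rec)
    return out


def profile_tails(
    tails: Sequence[TailRecord | str], max_len: int = 40
) -> TailCompositionProfile:
    """Aggregate per-position and overall base composition.

    Position k counts base k of every tail with length >= k, for
    k <= ``max_len``; longer tails are truncated at ``max_len``.
    """
    counts = np.zeros((max_len, 4), dtype=np.int64)
    max_hist = max_len + 1
    lengths = []
    base_col = {b: i for i, b in enumerate(BASES)}
    for item in tails:
        tail = item.tail if isinstance(item, TailRecord) else item
        lengths.append(len(tail))
        for k, base in enumerate(tail[:max_len]):
            counts[k, base_col[base]] += 1
    hist = np.bincount(
        np.minimum(lengths, max_hist - 1) if lengths else [], minlength=max_hist
    )
    return TailCompositionProfile(
        max_len=max_len,
        position_counts=counts,
        length_histogram=hist,
        n_tails=len(lengths),
    )
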