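"""Read preprocessing: first-base trim, two-step quality filter, PCR
duplicate collapsing, 3' adapter clipping and experimental-barcode
demultiplexing.

The stage order is fixed (and deliberately reproduces the published chain,
including collapsing *before* adapter clipping):

    trim first base -> quality (5, 95) -> quality (20, 90)
    -> collapse identical -> clip adapter -> demultiplex / trim barcodes

Reads start with a 9-nt composite barcode: 3 random + 4 experimental +
2 random nucleotides.  After the first-base trim, 8 barcode nucleotides
remain (2 random + 4 experimental + 2 random).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import ReadRecord, ValidationError

__all__ = [
    "DEFAULT_ADAPTER",
    "BarcodeScheme",
    "PreprocessStats",
    "trim_first_base",
    "quality_filter",
    "collapse_identical",
    "clip_adapter",
    "demultiplex",
    "run_preprocess",
]

DEFAULT_ADAPTER = "TGAGATCGGA"

#: (min_quality, min_percent) pairs applied in order.
DEFAULT_QUALITY_STEPS = ((5, 95), (20, 90))


@dataclass(frozen=True)
class BarcodeScheme:
    """Composite barcode layout and the library -> experimental 4-mer table."""

    table: Mapping[str, str]
    n_random_5p: int = 3
    n_experimental: int = 4
    n_random_3p: int = 2

    def __post_init__(self) -> None:
        barcodes = list(self.table.values())
        if len(set(barcodes)) != len(barcodes):
            raise ValidationError("experimental barcodes must be unique")
        for lib, bc in self.table.items():
            if len(bc) != self.n_experimental:
                raise ValidationError(
                    f"library {lib!r}: barcode {bc!r} is not "
                    f"{self.n_experimental} nt"
                )
            if set(bc) - set("ACGT"):
                raise ValidationError(f"library {lib!r}: barcode {bc!r} is not DNA")

    @property
    def total_length(self) -> int:
        return self.n_random_5p + self.n_experimental + self.n_random_3p

    def library_for(self, barcode: str) -> Optional[str]:
        for lib, bc in self.table.items():
            if bc == barcode:
                return lib
        return None


@dataclass
class PreprocessStats:
    """Per-stage read accounting; input = survivors + removals per stage."""

    input: int = 0
    removed_short_first_trim: int = 0
    removed_by_quality: int = 0
    collapsed_duplicates: int = 0  # reads absorbed into representatives
    adapter_clipped: int = 0
    discarded_short_insert: int = 0
    discarded_no_barcode: int = 0
    demultiplexed: dict = field(default_factory=dict)  # library -> read count

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.input),
            ("removed_short_first_trim", self.removed_short_first_trim),
            ("removed_by_quality", self.removed_by_quality),
            ("collapsed_duplicates", self.collapsed_duplicates),
            ("adapter_clipped", self.adapter_clipped),
            ("discarded_short_insert", self.discarded_short_insert),
            ("discarded_no_barcode", self.discarded_no_barcode),
        ] + [(f"library:{lib}", n) for lib, n in sorted(self.demultiplexed.items())]
        return pd.DataFrame(rows, columns=["stage", "count"])


def trim_first_base(
    reads: Iterable[ReadRecord], stats: Optional[PreprocessStats] = None
) -> list[ReadRecord]:
    """Drop the first (low-quality) base of every read; reads shorter than
    2 nt are discarded and counted."""
    out = []
    for read in reads:
        if len(read) < 2:
            if stats is not None:
                stats.removed_short_first_trim += 1
            continue
        out.append(read.trimmed(1))
    return out


def quality_filter(
    reads: Iterable[ReadRecord],
    min_q: int,
    min_pct: float,
    stats: Optional[PreprocessStats] = None,
) -> list[ReadRecord]:
    """Keep a read iff >= ``min_pct`` percent of its bases have quality
    >= ``min_q`` (inclusive on both comparisons)."""
    if min_q < 0 or not (0 < min_pct <= 100):
        raise ValueError("min_q must be >= 0 and 0 < min_pct <= 100")
    out = []
    for read in reads:
        phred = read.phred()
        pct = 100.0 * (phred >= min_q).sum() / len(phred)
        if pct >= min_pct:
            out.append(read)
        elif stats is not None:
            stats.removed_by_quality += 1
    return out


def collapse_identical(
    reads: Iterable[ReadRecord], stats: Optional[PreprocessStats] = None
) -> list[ReadRecord]:
    """Merge byte-identical sequences into one record with multiplicity.

    Applied *before* adapter clipping and barcode removal, so the random
    barcode keeps biological duplicates apart while PCR copies (identical
    over the full read, barcode included) collapse.  The first read of each
    sequence is the representative; its qualities are kept.
    """
    by_seq: "OrderedDict[str, ReadRecord]" = OrderedDict()
    for read in reads:
        kept = by_seq.get(read.seq)
        if kept is None:
            by_seq[read.seq] = ReadRecord(
                id=read.id, seq=read.seq, qual=read.qual, multiplicity=read.multiplicity
            )
        else:
            kept.multiplicity += read.multiplicity
            if stats is not None:
                stats.collapsed_duplicates += 1
    return list(by_seq.values())


def clip_adapter(
    read: ReadRecord,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 5,
    stats: Optional[PreprocessStats] = None,
) -> ReadRecord:
    """Clip the 3' adapter: truncate at the leftmost full occurrence, or at
    a 3'-terminal prefix of the adapter of length >= ``min_overlap``
    (longest such prefix wins).  Returns the read unchanged when no match
    is found; length-0 results are legal here and discarded downstream."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    pos = read.seq.find(adapter)
    if pos < 0:
        for k in range(min(len(adapter) - 1, len(read)), min_overlap - 1, -1):
            if read.seq.endswith(adapter[:k]):
                pos = len(read) - k
                break
    if pos < 0:
        return read
    if stats is not None:
        stats.adapter_clipped += 1
    return read.trimmed(0, pos)


def demultiplex(
    reads: Iterable[ReadRecord],
    scheme: BarcodeScheme,
    min_insert: int = 1,
    stats: Optional[PreprocessStats] = None,
) -> dict[str, list[ReadRecord]]:
    """Assign reads to libraries by exact experimental-barcode match.

    Expects reads that already lost their first base, so the remaining
    barcode is 2 random + 4 experimental + 2 random nt.  The leading 2 nt
    are dropped, the next 4 matched exactly against the table, then 6 nt
    (experimental + trailing random) are removed.  Unmatched reads land in
    the ``"unassigned"`` bin; reads too short to carry a barcode plus
    ``min_insert`` insert bases are discarded and counted.
    """
    lead = scheme.n_random_5p - 1  # first random base was already trimmed
    bc_len = scheme.n_experimental
    tail = scheme.n_random_3p
    needed = lead + bc_len + tail + min_insert
    bins: dict[str, list[ReadRecord]] = {lib: [] for lib in scheme.table}
    bins["unassigned"] = []
    for read in reads:
        if len(read) < needed:
            if stats is not None:
                stats.discarded_short_insert += 1
            continue
        barcode = read.seq[lead : lead + bc_len]
        library = scheme.library_for(barcode)
        insert = read.trimmed(lead + bc_len + tail)
        if library is None:
            bins["unassigned"].append(insert)
            if stats is not None:
                stats.discarded_no_barcode += 1
        else:
            insert.library = library
            bins[library].append(insert)
            if stats is not None:
                stats.demultiplexed[library] = stats.demultiplexed.get(library, 0) + 1
    return bins


def run_preprocess(
    reads: Sequence[ReadRecord],
    scheme: BarcodeScheme,
    adapter: str = DEFAULT_ADAPTER,
    quality_steps: Sequence[tuple[int, float]] = DEFAULT_QUALITY_STEPS,
    min_overlap: int = 5,
    min_insert: int = 1,
) -> tuple[dict[str, list[ReadRecord]], PreprocessStats]:
    """The full fixed-order preprocessing chain for one raw FASTQ."""
    stats = PreprocessStats(input=len(reads))
    out = trim_first_base(reads, stats)
    for min_q, min_pct in quality_steps:
        out = quality_filter(out, min_q, min_pct, stats)
    out = collapse_identical(out, stats)
    out = [clip_adapter(r, adapter, min_overlap, stats) for r in out]
    bins = demultiplex(out, scheme, min_insert=min_insert, stats=stats)
    return bins, stats
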