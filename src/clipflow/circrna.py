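"""Circular-RNA junction detection from unmapped reads.

A read sequenced across a circularization joint contains two adjacent
fragments that align to the genome in *permuted* order: the read-5'
fragment lies genomically downstream of the read-3' fragment.  Detection
is a two-pass exact-fragment search: a primary fragment of >= 20 nt, then
a secondary fragment of >= 12 nt in the remaining flank, restricted to the
primary's strand, within 4000 nt, and required to be single-positional.

Minus-strand reads are handled by orienting the query: the analysis runs
on the reverse complement against the plus-strand genome, which leaves
junction coordinates unchanged and flips only the reported strand.  All
``qstart``/``qend`` fields therefore refer to the *oriented* query (the
read itself on "+", its reverse complement on "-").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from ._kmer import KmerIndex
from .io_formats import Genome, ReadRecord, revcomp

__all__ = [
    "FragmentHit",
    "JunctionCall",
    "CircCandidate",
    "find_primary_fragment",
    "find_secondary_fragment",
    "call_junction",
    "detect_junction",
    "detect_junctions",
    "junction_supports",
    "aggregate_candidates",
]


@dataclass(frozen=True)
class FragmentHit:
    """An ungapped exact fragment match of the oriented query."""

    qstart: int
    qend: int
    replicon: str
    sstart: int
    send: int
    strand: str
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.qend - self.qstart != self.send - self.sstart:
            raise ValueError("fragment is not ungapped")

    def __len__(self) -> int:
        return self.qend - self.qstart


@dataclass(frozen=True)
class JunctionCall:
    """One read's evidence for a circle ``[circ_start, circ_end)``.

    ``circ_start`` is the acceptor (0-based), ``circ_end`` the donor
    (exclusive); coordinates are canonical (joint shifted maximally toward
    lower genome coordinates across identical bases).
    """

    replicon: str
    strand: str
    circ_start: int
    circ_end: int
    read_id: str

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.replicon, self.strand, self.circ_start, self.circ_end)


@dataclass
class CircCandidate:
    replicon: str
    strand: str
    circ_start: int
    circ_end: int
    counts: dict[str, int]  # per-library supporting reads
    passed: bool = False


def _maximal_matches(
    query: str, index: KmerIndex, min_len: int
) -> list[tuple[int, int, str, int]]:
    """All maximal exact matches (qstart, qend, replicon, sstart) of the
    query against the plus-strand genome, length >= min_len."""
    k = index.k
    found: dict[tuple[str, int, int], tuple[int, int, str, int]] = {}
    covered: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for i in range(len(query) - k + 1):
        for replicon, pos in index.lookup(query[i : i + k]):
            diag = (replicon, pos - i)
            runs = covered.setdefault(diag, [])
            if any(qs <= i < qe for qs, qe in runs):
                continue
            qs, qe = index.extend_match(replicon, pos, query, i)
            runs.append((qs, qe))
            if qe - qs >= min_len:
                sstart = (pos - i) + qs
                found[(replicon, diag[1], qs)] = (qs, qe, replicon, sstart)
    return list(found.values())


def find_primary_fragment(
    read: str,
    genome: Genome,
    min_len: int = 20,
    min_flank: int = 12,
    index: Optional[KmerIndex] = None,
) -> Optional[FragmentHit]:
    """Longest exact fragment of the read on either strand.

    Best = longest, ties broken by lowest genome coordinate, then plus
    strand.  Returns ``None`` when no fragment reaches ``min_len`` or when
    neither query flank of the best fragment is at least ``min_flank`` nt
    (no room for a secondary fragment).
    """
    if index is None:
        index = KmerIndex(genome)
    hits: list[tuple[int, str, int, str, int, int]] = []
    for strand in ("+", "-"):
        query = read if strand == "+" else revcomp(read)
        for qs, qe, replicon, sstart in _maximal_matches(query, index, min_len):
            hits.append((-(qe - qs), replicon, sstart, strand, qs, qe))
    if not hits:
        return None
    neglen, replicon, sstart, strand, qs, qe = min(
        hits, key=lambda h: (h[0], h[1], h[2], 0 if h[3] == "+" else 1)
    )
    qlen = len(read)
    if qs < min_flank and qlen - qe < min_flank:
        return None  # fully matching or no usable unaligned flank
    return FragmentHit(qs, qe, replicon, sstart, sstart + (qe - qs), strand)


def find_secondary_fragment(
    flank_seq: str,
    genome: Genome,
    strand: str,
    anchor: FragmentHit,
    min_seed: int = 12,
    max_span: int = 4000,
    anchored_end: str = "start",
    index: Optional[KmerIndex] = None,
) -> Optional[FragmentHit]:
    """Exact match of an unaligned flank, adjacent to the joint.

    ``anchored_end`` is ``"start"`` when the flank is the query's 3' flank
    (the match must begin at the flank's first base) and ``"end"`` for the
    5' flank (the match must end at the flank's last base).  The search is
    restricted to the anchor's replicon/strand orientation (the query is
    already oriented).  More than one genomic location matching the seed is
    rejected (single-positional rule), as is a fragment farther than
    ``max_span`` from the anchor (nearest-edge distance).
    """
    if len(flank_seq) < min_seed:
        return None
    if index is None:
        index = KmerIndex(genome)
    seed = flank_seq[:min_seed] if anchored_end == "start" else flank_seq[-min_seed:]
    occurrences = index.occurrences(seed)
    occurrences = [(rep, pos) for rep, pos in occurrences if rep == anchor.replicon]
    if len(occurrences) != 1:
        return None
    replicon, pos = occurrences[0]
    seq = genome[replicon]
    if anchored_end == "start":
        length = min_seed
        while length < len(flank_seq) and pos + length < len(seq) and flank_seq[length] == seq[pos + length]:
            length += 1
        sstart, send = pos, pos + length
        fstart = 0
    else:
        length = min_seed
        while (
            length < len(flank_seq)
            and pos - (length - min_seed) > 0
            and flank_seq[-(length + 1)] == seq[pos - (length - min_seed) - 1]
        ):
            length += 1
        send = pos + min_seed
        sstart = send - length
        fstart = len(flank_seq) - length
    # nearest-edge distance between the two fragments
    if send <= anchor.sstart:
        distance = anchor.sstart - send
    elif sstart >= anchor.send:
        distance = sstart - anchor.send
    else:
        distance = 0
    if distance > max_span:
        return None
    return FragmentHit(fstart, fstart + length, replicon, sstart, send, strand)


def call_junction(
    frag_read5: FragmentHit,
    frag_read3: FragmentHit,
    genome: Genome,
    read_id: str = "",
    max_span: int = 4000,
) -> Optional[JunctionCall]:
    """Combine the query-5' and query-3' fragments into a junction.

    In oriented-query space a junction exists iff the query-5' fragment
    lies genomically strictly downstream of the query-3' fragment
    (permuted order).  ``circ_start`` is the genomic start of the query-3'
    fragment, ``circ_end`` the genomic end of the query-5' fragment.
    Coordinates are canonicalized by shifting the joint maximally toward
    lower genome coordinates across identical bases.
    """
    if frag_read5.replicon != frag_read3.replicon or frag_read5.strand != frag_read3.strand:
        return None
    if frag_read5.sstart <= frag_read3.sstart:
        return None  # colinear, not permuted
    circ_start, circ_end = frag_read3.sstart, frag_read5.send
    if not circ_start < circ_end:
        return None
    if circ_end - circ_start > max_span:
        return None
    seq = genome[frag_read5.replicon]
    while circ_start > 0 and seq[circ_start - 1] == seq[circ_end - 1]:
        circ_start -= 1
        circ_end -= 1
    return JunctionCall(
        replicon=frag_read5.replicon,
        strand=frag_read5.strand,
        circ_start=circ_start,
        circ_end=circ_end,
        read_id=read_id,
    )


def detect_junction(
    read: ReadRecord | str,
    genome: Genome,
    min_primary: int = 20,
    min_seed: int = 12,
    max_span: int = 4000,
    index: Optional[KmerIndex] = None,
) -> Optional[JunctionCall]:
    """Run the two-pass procedure on one unmapped read."""
    if index is None:
        index = KmerIndex(genome)
    seq = read.seq if isinstance(read, ReadRecord) else read
    read_id = read.id if isinstance(read, ReadRecord) else ""
    primary = find_primary_fragment(seq, genome, min_len=min_primary, min_flank=min_seed, index=index)
    if primary is None:
        return None
    query = seq if primary.strand == "+" else revcomp(seq)
    calls = []
    # unaligned 3' flank: primary is the query-5' fragment
    flank3 = query[primary.qend :]
    if len(flank3) >= min_seed:
        secondary = find_secondary_fragment(
            flank3, genome, primary.strand, primary,
            min_seed=min_seed, max_span=max_span, anchored_end="start", index=index,
        )
        if secondary is not None:
            call = call_junction(primary, secondary, genome, read_id, max_span=max_span)
            if call is not None:
                calls.append(call)
    # unaligned 5' flank: primary is the query-3' fragment
    flank5 = query[: primary.qstart]
    if len(flank5) >= min_seed:
        secondary = find_secondary_fragment(
            flank5, genome, primary.strand, primary,
            min_seed=min_seed, max_span=max_span, anchored_end="end", index=index,
        )
        if secondary is not None:
            call = call_junction(secondary, primary, genome, read_id, max_span=max_span)
            if call is not None:
                calls.append(call)
    if not calls:
        return None
    if len(calls) == 2 and calls[0].key != calls[1].key:
        return None  # both flank orders succeed with different joints: ambiguous
    return calls[0]


def detect_junctions(
    reads: Iterable[ReadRecord],
    genome: Genome,
    min_primary: int = 20,
    min_seed: int = 12,
    max_span: int = 4000,
    index: Optional[KmerIndex] = None,
) -> list[JunctionCall]:
    if index is None:
        index = KmerIndex(genome)
    calls = []
    for read in reads:
        call = detect_junction(
            read, genome, min_primary=min_primary, min_seed=min_seed,
            max_span=max_span, index=index,
        )
        if call is not None:
            calls.append(call)
    return calls


def junction_supports(call: JunctionCall, read_seq: str, genome: Genome) -> bool:
    """Soundness check: the read is a contiguous substring of the
    circularized sequence read across the joint."""
    circ = genome[call.replicon][call.circ_start : call.circ_end]
    query = read_seq if call.strand == "+" else revcomp(read_seq)
    return query in circ + circ


def aggregate_candidates(
    calls_per_library: Mapping[str, Sequence[JunctionCall]],
    eligible_libraries: Sequence[str],
    min_reads: int = 10,
    min_libraries: int = 3,
) -> list[CircCandidate]:
    """Group identical junction keys and apply the abundance filter.

    A candidate passes with >= ``min_reads`` supporting reads in at least
    ``min_libraries`` of the eligible (non-control) libraries; counts in
    other libraries are reported but never qualify.
    """
    eligible = set(eligible_libraries)
    counts: dict[tuple, dict[str, int]] = {}
    for library, calls in calls_per_library.items():
        for call in calls:
            per_lib = counts.setdefault(call.key, {lib: 0 for lib in calls_per_library})
            per_lib[library] += 1
    candidates = []
    for key in sorted(counts):
        replicon, strand, circ_start, circ_end = key
        per_lib = counts[key]
        n_qualifying = sum(
            1 for lib, n in per_lib.items() if lib in eligible and n >= min_reads
        )
        candidates.append(
            CircCandidate(
                replicon=replicon,
                strand=strand,
                circ_start=circ_start,
                circ_end=circ_end,
                counts=per_lib,
                passed=n_qualifying >= min_libraries,
            )
        )
    return candidates
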