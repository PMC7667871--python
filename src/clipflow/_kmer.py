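"""Shared exact-match machinery: k-mer index and byte-array helpers.

Used by the mapper, the junction caller and the tail detector.  Genomes in
this pipeline are desk scale (tens of kb to a few Mb), so a plain hash
index over plus-strand k-mers is sufficient; queries handle the minus
strand by reverse-complementing themselves.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .io_formats import Genome


def seq_array(seq: str) -> np.ndarray:
    """DNA string as a uint8 byte array (for vectorized comparisons)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class KmerIndex:
    """Hash index of every plus-strand k-mer of a genome."""

    def __init__(self, genome: Genome, k: int = 12):
        if k < 4:
            raise ValueError("k-mer size must be >= 4")
        self.genome = genome
        self.k = k
        self.arrays: dict[str, np.ndarray] = {
            name: seq_array(seq) for name, seq in genome.replicons.items()
        }
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.replicons.items():
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((name, pos))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def occurrences(self, pattern: str) -> list[tuple[str, int]]:
        """All plus-strand occurrences of ``pattern`` (len >= k), found by
        seeding on the first k bases and verifying the remainder."""
        if len(pattern) < self.k:
            raise ValueError(f"pattern shorter than k={self.k}")
        hits = []
        pat = seq_array(pattern)
        for replicon, pos in self.lookup(pattern[: self.k]):
            arr = self.arrays[replicon]
            if pos + len(pat) <= arr.size and np.array_equal(arr[pos : pos + len(pat)], pat):
                hits.append((replicon, pos))
        return hits

    def extend_match(self, replicon: str, gpos: int, query: str, qpos: int) -> tuple[int, int]:
        """Maximal exact extension of a match anchored at query[qpos] ==
        genome[gpos]; returns (qstart, qend) of the maximal run around qpos
        such that query[qstart:qend] == genome[gpos-(qpos-qstart):...]."""
        seq = self.genome[replicon]
        glen = len(seq)
        qs, gs = qpos, gpos
        while qs > 0 and gs > 0 and query[qs - 1] == seq[gs - 1]:
            qs -= 1
            gs -= 1
        qe, ge = qpos, gpos
        while qe < len(query) and ge < glen and query[qe] == seq[ge]:
            qe += 1
            ge += 1
        return qs, qe


def hamming_scan(genome_arr: np.ndarray, query_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every ungapped offset of the
    genome array; vector of length ``len(genome) - len(query) + 1``."""
    n, m = genome_arr.size, query_arr.size
    if m > n:
        return np.zeros(0, dtype=np.int32)
    counts = np.zeros(n - m + 1, dtype=np.int32)
    for i in range(m):
        counts += genome_arr[i : n - m + 1 + i] != query_arr[i]
    return counts
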