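"""TPM normalization, iCLIP/RNA-Seq coverage ratios, 2-fold enrichment
calls at candidate loci, and genome nucleotide-content statistics.

Quantiles use linear interpolation (numpy's default, R type-7) so that the
reported quartiles are reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneRecord, Genome, Interval, ValidationError

__all__ = [
    "GeneCountTable",
    "ContentRecord",
    "RatioSummary",
    "EnrichmentCall",
    "tpm_normalize",
    "igr_complement",
    "coverage_ratio",
    "call_enrichment",
    "cds_content",
    "content_summary",
    "find_igr_polyA",
    "per_million",
]


@dataclass
class GeneCountTable:
    """Raw counts, lengths and TPM values per gene (TPM sums to 1e6)."""

    table: pd.DataFrame  # columns: gene_id, count, length, tpm


@dataclass(frozen=True)
class ContentRecord:
    """Per-CDS coding-strand composition statistics."""

    gene_id: str
    a_fraction: float
    ag_fraction: float
    longest_a_run: int


@dataclass
class RatioSummary:
    """Per-position iCLIP/RNA-Seq ratio summary for a region class."""

    region_class: str
    median: float
    q1: float
    q3: float
    n_positions: int
    n_zero_rnaseq: int
    ratios: Optional[np.ndarray] = None


@dataclass
class EnrichmentCall:
    locus: Interval
    folds: dict[str, float]  # per-sample iCLIP/RNA-Seq peak fold (inf if RNA-Seq 0)
    verdict: bool
    rule: Optional[str] = None  # "fold" | "zero_rnaseq"


def tpm_normalize(
    counts: Mapping[str, float], lengths: Mapping[str, float]
) -> GeneCountTable:
    """TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6."""
    gene_ids = list(counts)
    c = np.array([counts[g] for g in gene_ids], dtype=float)
    l = np.array([lengths[g] for g in gene_ids], dtype=float)
    if np.any(l <= 0):
        raise ValidationError("gene lengths must be positive")
    if not np.any(c > 0):
        raise ValidationError("all-zero count table cannot be TPM normalized")
    rate = c / l
    tpm = rate / rate.sum() * 1e6
    return GeneCountTable(
        pd.DataFrame({"gene_id": gene_ids, "count": c, "length": l, "tpm": tpm})
    )


def igr_complement(genes: Sequence[GeneRecord], genome: Genome) -> list[Interval]:
    """Strand-blind complement of the union of gene intervals per replicon."""
    igrs: list[Interval] = []
    by_replicon: dict[str, list[tuple[int, int]]] = {}
    for gene in genes:
        by_replicon.setdefault(gene.replicon, []).append((gene.start, gene.end))
    for replicon, length in genome.lengths.items():
        intervals = sorted(by_replicon.get(replicon, []))
        merged: list[list[int]] = []
        for start, end in intervals:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        prev = 0
        for start, end in merged:
            if start > prev:
                igrs.append(Interval(replicon, prev, start))
            prev = max(prev, end)
        if prev < length:
            igrs.append(Interval(replicon, prev, length))
    return igrs


def per_million(track: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Scale a coverage track so its genome-wide sum is one million."""
    total = sum(float(np.sum(v)) for v in track.values())
    if total == 0:
        return {name: np.asarray(v, dtype=float) for name, v in track.items()}
    return {name: np.asarray(v, dtype=float) * 1e6 / total for name, v in track.items()}


def coverage_ratio(
    iclip_cov: Mapping[str, np.ndarray],
    rnaseq_cov: Mapping[str, np.ndarray],
    regions: Sequence[Interval],
    region_class: str = "CDS",
    normalize: bool = True,
    keep_ratios: bool = False,
) -> RatioSummary:
    """Per-position iCLIP/RNA-Seq ratio over positions with RNA-Seq
    coverage > 0 inside ``regions``; zero-RNA-Seq positions are counted
    separately.  Summary quartiles use linear interpolation."""
    if normalize:
        iclip_cov = per_million(iclip_cov)
        rnaseq_cov = per_million(rnaseq_cov)
    ratio_chunks = []
    n_zero = 0
    n_positions = 0
    for region in regions:
        ic = np.asarray(iclip_cov[region.replicon][region.start : region.end], dtype=float)
        rs = np.asarray(rnaseq_cov[region.replicon][region.start : region.end], dtype=float)
        n_positions += len(ic)
        covered = rs > 0
        n_zero += int((~covered).sum())
        if covered.any():
            ratio_chunks.append(ic[covered] / rs[covered])
    if ratio_chunks:
        ratios = np.concatenate(ratio_chunks)
        q1, median, q3 = np.percentile(ratios, [25, 50, 75])
    else:
        ratios = np.zeros(0)
        q1 = median = q3 = float("nan")
    return RatioSummary(
        region_class=region_class,
        median=float(median),
        q1=float(q1),
        q3=float(q3),
        n_positions=n_positions,
        n_zero_rnaseq=n_zero,
        ratios=ratios if keep_ratios else None,
    )


def call_enrichment(
    iclip_samples: Mapping[str, Mapping[str, np.ndarray]],
    rnaseq: Mapping[str, np.ndarray],
    locus: Interval,
    fold: float = 2.0,
    min_peak: float = 5.0,
    normalize: bool = True,
) -> EnrichmentCall:
    """Peak-based enrichment at a locus.

    Per sample the peak (maximum per-base coverage over the locus) is
    compared between iCLIP and RNA-Seq.  Rule A fires when
    iCLIP/RNA-Seq >= ``fold``; rule B when the iCLIP peak is at least
    ``min_peak`` while the RNA-Seq peak is zero.  The verdict is true when
    any sample fires either rule.
    """
    if normalize:
        iclip_samples = {name: per_million(track) for name, track in iclip_samples.items()}
        rnaseq = per_million(rnaseq)
    rs_peak = float(np.max(rnaseq[locus.replicon][locus.start : locus.end]))
    folds: dict[str, float] = {}
    verdict = False
    rule = None
    for name, track in iclip_samples.items():
        ic_peak = float(np.max(track[locus.replicon][locus.start : locus.end]))
        if rs_peak > 0:
            f = ic_peak / rs_peak
            folds[name] = f
            if f >= fold:
                verdict = True
                rule = rule or "fold"
        else:
            folds[name] = float("inf") if ic_peak > 0 else 0.0
            if ic_peak >= min_peak:
                verdict = True
                rule = rule or "zero_rnaseq"
    return EnrichmentCall(locus=locus, folds=folds, verdict=verdict, rule=rule)


_A_RUN = re.compile(r"A+")


def cds_content(cds_sequences: Mapping[str, str]) -> list[ContentRecord]:
    """A fraction, A+G fraction and longest poly(A) run per coding-strand
    sequence; empty sequences are excluded."""
    records = []
    for gene_id, seq in cds_sequences.items():
        if not seq:
            continue
        seq = seq.upper()
        n = len(seq)
        n_a = seq.count("A")
        n_g = seq.count("G")
        runs = _A_RUN.findall(seq)
        records.append(
            ContentRecord(
                gene_id=gene_id,
                a_fraction=n_a / n,
                ag_fraction=(n_a + n_g) / n,
                longest_a_run=max((len(r) for r in runs), default=0),
            )
        )
    return records


def content_summary(records: Sequence[ContentRecord]) -> dict:
    """Distribution summaries over per-CDS content records."""
    if not records:
        return {"n_cds": 0}
    a = np.array([r.a_fraction for r in records])
    runs = np.array([r.longest_a_run for r in records])
    amin, amax = int(np.argmin(a)), int(np.argmax(a))
    run_q1, run_med, run_q3 = np.percentile(runs, [25, 50, 75])
    return {
        "n_cds": len(records),
        "a_fraction_min": float(a.min()),
        "a_fraction_min_gene": records[amin].gene_id,
        "a_fraction_max": float(a.max()),
        "a_fraction_max_gene": records[amax].gene_id,
        "a_fraction_median": float(np.median(a)),
        "longest_run_median": float(run_med),
        "longest_run_q1": float(run_q1),
        "longest_run_q3": float(run_q3),
        "n_runs_above_7": int((runs > 7).sum()),
    }


def find_igr_polyA(
    igrs: Sequence[Interval],
    genome: Genome,
    top_n: int = 20,
    min_run: int = 1,
) -> list[tuple[Interval, int]]:
    """Maximal poly(A) runs inside IGRs, both strands.

    Plus-strand poly(A) appears as an ``A`` run, minus-strand poly(A) as a
    plus-strand ``T`` run; runs are truncated at IGR edges and ranked by
    length (descending), ties by coordinate.  Returns (interval, length)
    with the interval's strand marking the poly(A) strand.
    """
    hits: list[tuple[Interval, int]] = []
    for igr in igrs:
        seq = genome[igr.replicon][igr.start : igr.end]
        for base, strand in (("A", "+"), ("T", "-")):
            for match in re.finditer(f"{base}+", seq):
                length = match.end() - match.start()
                if length >= min_run:
                    hits.append(
                        (
                            Interval(
                                igr.replicon,
                                igr.start + match.start(),
                                igr.start + match.end(),
                                strand,
                            ),
                            length,
                        )
                    )
    hits.sort(key=lambda h: (-h[1], h[0].replicon, h[0].start, h[0].strand))
    return hits[:top_n]
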