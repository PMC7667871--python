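"""Synthetic genome, annotation and library generator with planted truth.

Every downstream stage is tested against libraries produced here: iCLIP
truncation reads starting one nt 3' of a planted crosslink, composite
5' barcodes with PCR duplication, junction-spanning reads from planted
circles, reads ending in A-rich non-templated tails, and RNA-Seq reads
drawn from per-gene abundances.  A ground-truth manifest plus per-read
truth tables are the generator's contract with the tests.

Determinism: all sampling goes through one ``numpy`` generator seeded from
the manifest, so a fixed seed yields byte-identical FASTQ and truth tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneRecord, Genome, ReadRecord, ValidationError
from .preprocess import DEFAULT_ADAPTER

__all__ = [
    "DEFAULT_BARCODES",
    "FULL_LINKER",
    "PlantedCircle",
    "TailModel",
    "GroundTruthManifest",
    "SimulatedLibrary",
    "build_genome",
    "build_annotation",
    "simulate_iclip_library",
    "simulate_rnaseq_library",
    "sample_crosslinks",
    "canonicalize_circle",
]

#: Library -> experimental 4-mer (the published six-library layout).
DEFAULT_BARCODES = {
    "target_1": "GGTT",
    "target_2": "TGGC",
    "target_3": "GGTC",
    "target_4": "CGGA",
    "control_1": "GGCA",
    "control_2": "CCGG",
}

#: Full 3' linker DNA; reads sequence into this, the clipper matches its
#: first 10 nt.
FULL_LINKER = "TGAGATCGGAAGAGCGGTTCAG"

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def canonicalize_circle(genome: Genome, replicon: str, circ_start: int, circ_end: int) -> tuple[int, int]:
    """Shift a circle's joint maximally toward lower genome coordinates
    across identical bases — the same canonical form the junction caller
    emits, so planted and recovered coordinates compare exactly."""
    seq = genome[replicon]
    while circ_start > 0 and seq[circ_start - 1] == seq[circ_end - 1]:
        circ_start -= 1
        circ_end -= 1
    return circ_start, circ_end


@dataclass(frozen=True)
class PlantedCircle:
    replicon: str
    circ_start: int
    circ_end: int
    strand: str
    n_junction_reads: Mapping[str, int]  # library -> molecules
    circle_id: str = ""


@dataclass
class TailModel:
    """Per-position base probabilities and a truncated-geometric length law.

    ``base_probs`` is either a single (4,) vector used at every position or
    a (max_len, 4) matrix (columns A, C, G, T).  Lengths are geometric with
    the given mean, truncated at ``max_len``.
    """

    base_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.73, 0.09, 0.09, 0.09])
    )
    length_mean: float = 4.0
    max_len: int = 40

    def __post_init__(self) -> None:
        self.base_probs = np.atleast_2d(np.asarray(self.base_probs, dtype=float))
        if self.base_probs.shape[1] != 4 or self.base_probs.shape[0] > self.max_len:
            raise ValidationError("tail base_probs must be (<=max_len, 4)")
        if not np.allclose(self.base_probs.sum(axis=1), 1.0):
            raise ValidationError("tail base probabilities must sum to 1 per position")

    def probs_at(self, position: int) -> np.ndarray:
        row = min(position, self.base_probs.shape[0] - 1)
        return self.base_probs[row]

    def sample(self, rng: np.random.Generator) -> str:
        length = min(int(rng.geometric(1.0 / self.length_mean)), self.max_len)
        return "".join(
            "ACGT"[rng.choice(4, p=self.probs_at(k))] for k in range(length)
        )


@dataclass
class GroundTruthManifest:
    """Planted observables and generator knobs; validated on construction."""

    seed: int = 0
    planted_circles: list[PlantedCircle] = field(default_factory=list)
    tail_model: TailModel = field(default_factory=TailModel)
    tail_fraction: float = 0.0
    decile_weights: np.ndarray = field(default_factory=lambda: np.ones(10))
    hotspot_offset: Optional[int] = None  # transcript-space offset from gene start
    hotspot_weight: float = 0.0
    duplication_rate: float = 0.0
    barcode_table: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    rnaseq_abundance: Optional[Mapping[str, float]] = None  # gene_id -> weight
    gene_weights: Optional[Mapping[str, float]] = None  # crosslink gene sampling

    def __post_init__(self) -> None:
        self.decile_weights = np.asarray(self.decile_weights, dtype=float)
        if self.decile_weights.shape != (10,) or np.any(self.decile_weights < 0):
            raise ValidationError("decile_weights must be 10 non-negative numbers")
        barcodes = list(self.barcode_table.values())
        if len(set(barcodes)) != len(barcodes):
            raise ValidationError("barcodes must be unique")
        if any(len(b) != 4 for b in barcodes):
            raise ValidationError("barcodes must be 4 nt")
        if not (0.0 <= self.tail_fraction <= 1.0):
            raise ValidationError("tail_fraction must be in [0, 1]")
        if not (0.0 <= self.hotspot_weight <= 1.0):
            raise ValidationError("hotspot_weight must be in [0, 1]")

    def validate_against(self, genome: Genome) -> None:
        for circle in self.planted_circles:
            if circle.replicon not in genome:
                raise ValidationError(f"circle on unknown replicon {circle.replicon!r}")
            if not (0 <= circle.circ_start < circle.circ_end <= genome.lengths[circle.replicon]):
                raise ValidationError(f"circle {circle.circle_id!r} outside replicon")

    def canonical_circles(self, genome: Genome) -> list[PlantedCircle]:
        out = []
        for c in self.planted_circles:
            cs, ce = canonicalize_circle(genome, c.replicon, c.circ_start, c.circ_end)
            out.append(PlantedCircle(c.replicon, cs, ce, c.strand, c.n_junction_reads, c.circle_id))
        return out


@dataclass
class SimulatedLibrary:
    library: str
    records: list[ReadRecord]
    truth: pd.DataFrame  # one row per read

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate read ids in simulated library")
        if set(ids) != set(self.truth["read_id"]):
            raise ValidationError("truth table does not cover the read set exactly")

    @property
    def n_molecules(self) -> int:
        return self.truth["molecule_id"].nunique()


# ---------------------------------------------------------------------------
# Genome / annotation
# ---------------------------------------------------------------------------


def build_genome(
    seed: int, n_replicons: int = 1, length: int = 50_000, gc: float = 0.5
) -> Genome:
    """Random genome with i.i.d. bases at the requested GC content."""
    if length < 5_000:
        raise ValidationError("replicon length must be >= 5000")
    if not (0.0 < gc < 1.0):
        raise ValidationError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    replicons = {}
    for i in range(n_replicons):
        draws = rng.choice(BASES, size=length, p=p)
        replicons[f"chr{i + 1}"] = draws.tobytes().decode("ascii")
    return Genome(replicons)


def _biotype_counts(n_genes: int, biotype_mix: Mapping[str, float]) -> dict[str, int]:
    """Deterministic rounding: each non-coding biotype gets
    floor(fraction * n); protein_coding absorbs the remainder."""
    counts = {}
    assigned = 0
    for biotype in sorted(biotype_mix):
        if biotype == "protein_coding":
            continue
        counts[biotype] = int(biotype_mix[biotype] * n_genes)
        assigned += counts[biotype]
    counts["protein_coding"] = n_genes - assigned
    if counts["protein_coding"] < 0:
        raise ValidationError("biotype fractions exceed 1")
    return counts


def build_annotation(
    genome: Genome,
    seed: int,
    n_genes: int = 20,
    biotype_mix: Optional[Mapping[str, float]] = None,
    operon_fraction: float = 0.0,
    gene_length_range: tuple[int, int] = (300, 1200),
    min_gap: int = 80,
    include_convergent_pair: bool = True,
) -> list[GeneRecord]:
    """Pack non-overlapping genes onto the genome.

    Gene lengths are multiples of 10 and >= 100 (so deciles are exact and
    >= 10 nt).  One designed convergent pair with overlapping 3' ends is
    planted when requested; ``operon_fraction`` of the genes are grouped
    into adjacent same-strand operons of 2-3 genes.
    """
    if biotype_mix is None:
        biotype_mix = {"protein_coding": 0.8, "tRNA": 0.1, "rRNA": 0.1}
    rng = np.random.default_rng(seed)
    counts = _biotype_counts(n_genes, biotype_mix)
    biotypes = [b for b, n in sorted(counts.items()) for _ in range(n)]
    rng.shuffle(biotypes)

    lo, hi = gene_length_range
    lengths = [max(100, int(rng.integers(lo, hi + 1)) // 10 * 10) for _ in range(n_genes)]
    replicon = next(iter(genome.replicons))
    glen = genome.lengths[replicon]
    # leave margin at the replicon edges so boundary windows fit
    margin = 200
    needed = sum(lengths) + min_gap * (n_genes - 1) + 2 * margin
    if needed > glen:
        raise ValidationError(
            f"cannot pack {n_genes} genes ({needed} nt needed) into {glen} nt"
        )
    slack = glen - needed
    gaps = rng.multinomial(slack, np.ones(n_genes) / n_genes)

    genes: list[GeneRecord] = []
    pos = margin
    convergent_at = n_genes // 2 if include_convergent_pair and n_genes >= 2 else -1
    for i in range(n_genes):
        pos += int(gaps[i])
        start = pos
        end = start + lengths[i]
        if i == convergent_at:
            strand = "+"
        elif i == convergent_at + 1 and convergent_at >= 0:
            strand = "-"
            overlap = 30
            start = genes[-1].end - overlap  # 3'-ends overlap
            end = start + lengths[i]
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        if end + margin > glen:
            raise ValidationError("gene packing overflowed the replicon")
        genes.append(
            GeneRecord(
                replicon=replicon,
                start=start,
                end=end,
                strand=strand,
                biotype=biotypes[i],
                gene_id=f"g{i + 1:04d}",
            )
        )
        pos = end + min_gap

    if operon_fraction > 0:
        n_operon_genes = int(operon_fraction * n_genes)
        i = 0
        op = 0
        assigned = 0
        while assigned < n_operon_genes and i < n_genes - 1:
            size = int(rng.integers(2, 4))
            group = genes[i : i + size]
            if len({g.strand for g in group}) == 1 and len(group) >= 2:
                op += 1
                for j, g in enumerate(group):
                    genes[i + j] = GeneRecord(
                        g.replicon, g.start, g.end, g.strand, g.biotype,
                        g.gene_id, operon_id=f"op{op:03d}",
                    )
                assigned += len(group)
                i += size
            else:
                i += 1
    return genes


# ---------------------------------------------------------------------------
# iCLIP library
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def _sample_crosslink(
    rng: np.random.Generator,
    genes: Sequence[GeneRecord],
    manifest: GroundTruthManifest,
    gene_probs: np.ndarray,
) -> tuple[GeneRecord, int]:
    """Crosslink position (plus-strand coordinate, on the gene's strand)."""
    gene = genes[int(rng.choice(len(genes), p=gene_probs))]
    if manifest.hotspot_offset is not None and rng.random() < manifest.hotspot_weight:
        off = manifest.hotspot_offset  # transcript-space, negative = upstream
        delta = off if off < 0 else off - 1  # skip-zero offset -> 0-based delta
        if gene.strand == "+":
            return gene, gene.start + delta
        return gene, (gene.end - 1) - delta
    w = manifest.decile_weights
    decile = int(rng.choice(10, p=w / w.sum()))
    length = len(gene)
    lo, hi = (decile * length) // 10, ((decile + 1) * length) // 10
    i = int(rng.integers(lo, hi))
    return gene, gene.start + i if gene.strand == "+" else gene.end - 1 - i


def simulate_iclip_library(
    genome: Genome,
    annotation: Sequence[GeneRecord],
    truth: GroundTruthManifest,
    library: str,
    n_molecules: int,
    seed: int,
    read_length: int = 75,
    insert_range: tuple[int, int] = (30, 60),
    anchor_range: tuple[int, int] = (25, 45),
    error_rate: float = 0.0,
    quality_char: str = "I",
    adapter: str = DEFAULT_ADAPTER,
) -> SimulatedLibrary:
    """One iCLIP library with planted crosslink, junction and tail reads.

    Each molecule is a 9-nt composite barcode (3 random + 4 experimental +
    2 random) followed by the insert, then the 3' linker when the insert is
    shorter than the read.  Truncation convention: the insert starts one nt
    3' of the crosslink on the transcript strand.  PCR emits
    ``1 + Poisson(duplication_rate)`` identical copies per molecule.

    Molecules whose barcode+insert happens to contain the adapter decamer
    are resampled, so adapter clipping can never truncate a planted insert
    (the decamer appears in a random sequence at rate ~1e-6/nt).
    """
    if library not in truth.barcode_table:
        raise ValidationError(f"library {library!r} missing from barcode table")
    truth.validate_against(genome)
    rng = np.random.default_rng((truth.seed, seed, zlib.crc32(library.encode())))
    barcode4 = truth.barcode_table[library]
    gene_list = list(annotation)
    if truth.gene_weights is None:
        gene_probs = np.ones(len(gene_list)) / len(gene_list)
    else:
        w = np.array([truth.gene_weights.get(g.gene_id, 0.0) for g in gene_list])
        gene_probs = w / w.sum()

    circles = truth.canonical_circles(genome)
    n_junction = sum(c.n_junction_reads.get(library, 0) for c in circles)
    if n_junction > n_molecules:
        raise ValidationError("more junction reads requested than molecules")

    rows = []
    records = []

    def emit(molecule_id, insert, kind, replicon, strand, crosslink, circle_id, tail,
             anchor_start, anchor_end):
        for _ in range(20):
            barcode = _random_bases(rng, 3) + barcode4 + _random_bases(rng, 2)
            if adapter not in barcode + insert:
                break
        else:
            raise ValidationError("could not avoid adapter motif in read")
        space = read_length - len(barcode) - len(insert)
        if space <= 0:
            insert = insert[: read_length - len(barcode)]
            read_seq = barcode + insert
        elif space < 5:
            read_seq = barcode + insert  # too little room for a clippable adapter
        else:
            read_seq = (barcode + insert + FULL_LINKER)[:read_length]
            pad = read_length - len(read_seq)
            if pad > 0:
                read_seq += _random_bases(rng, pad)
        if error_rate > 0:
            arr = np.frombuffer(read_seq.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(arr.size) < error_rate)
            for h in hits:
                arr[h] = rng.choice(BASES[BASES != arr[h]])
            read_seq = arr.tobytes().decode("ascii")
        n_copies = 1 + int(rng.poisson(truth.duplication_rate))
        for copy in range(n_copies):
            read_id = f"{library}:m{molecule_id:06d}/d{copy}"
            records.append(
                ReadRecord(id=read_id, seq=read_seq, qual=quality_char * len(read_seq))
            )
            rows.append(
                dict(
                    read_id=read_id,
                    molecule_id=f"{library}:m{molecule_id:06d}",
                    library=library,
                    kind=kind,
                    replicon=replicon,
                    strand=strand,
                    crosslink=crosslink,
                    circle_id=circle_id,
                    tail=tail,
                    anchor_start=anchor_start,
                    anchor_end=anchor_end,
                    insert=insert,
                    read_seq=read_seq,
                )
            )

    mol = 0
    for circle in circles:
        circ_t = genome.fetch(circle.replicon, circle.circ_start, circle.circ_end, circle.strand)
        for _ in range(circle.n_junction_reads.get(library, 0)):
            total = int(rng.integers(max(insert_range[0], 40), insert_range[1] + 1))
            total = min(total, 2 * len(circ_t))
            a = int(rng.integers(22, total - 14))  # query-5' part; leaves >= 15 for the rest
            insert = circ_t[-a:] + circ_t[: total - a]
            emit(mol, insert, "junction", circle.replicon, circle.strand, -1,
                 circle.circle_id, "", -1, -1)
            mol += 1

    for _ in range(n_molecules - n_junction):
        is_tail = rng.random() < truth.tail_fraction
        for _ in range(50):
            gene, crosslink = _sample_crosslink(rng, gene_list, truth, gene_probs)
            length = int(
                rng.integers(*anchor_range) if is_tail else rng.integers(*insert_range)
            )
            replicon_len = genome.lengths[gene.replicon]
            if gene.strand == "+":
                if crosslink + 1 + length <= replicon_len and crosslink >= 0:
                    anchor_start, anchor_end = crosslink + 1, crosslink + 1 + length
                    break
            else:
                if crosslink - length >= 0 and crosslink < replicon_len:
                    anchor_start, anchor_end = crosslink - length, crosslink
                    break
        else:
            raise ValidationError("could not place a molecule inside the replicon")
        anchor_seq = genome.fetch(gene.replicon, anchor_start, anchor_end, gene.strand)
        if is_tail:
            tail = truth.tail_model.sample(rng)
            while not tail:
                tail = truth.tail_model.sample(rng)
            insert = anchor_seq + tail
            emit(mol, insert, "tail", gene.replicon, gene.strand, crosslink, "",
                 tail, anchor_start, anchor_end)
        else:
            emit(mol, anchor_seq, "crosslink", gene.replicon, gene.strand, crosslink,
                 "", "", anchor_start, anchor_end)
        mol += 1

    truth_df = pd.DataFrame(rows)
    return SimulatedLibrary(library=library, records=records, truth=truth_df)


def sample_crosslinks(
    genome: Genome,
    annotation: Sequence[GeneRecord],
    truth: GroundTruthManifest,
    n: int,
    seed: int,
) -> list[tuple[str, int, str]]:
    """Draw ``n`` crosslink sites from the manifest's placement model
    without synthesizing reads — the fast path for profiling tests.

    Returns (replicon, position, strand) triples drawn exactly as
    :func:`simulate_iclip_library` places its crosslink molecules.
    """
    rng = np.random.default_rng((truth.seed, seed, 777))
    genes = list(annotation)
    if truth.gene_weights is None:
        gene_probs = np.ones(len(genes)) / len(genes)
    else:
        w = np.array([truth.gene_weights.get(g.gene_id, 0.0) for g in genes])
        gene_probs = w / w.sum()
    sites = []
    for _ in range(n):
        gene, pos = _sample_crosslink(rng, genes, truth, gene_probs)
        if 0 <= pos < genome.lengths[gene.replicon]:
            sites.append((gene.replicon, pos, gene.strand))
    return sites


def simulate_rnaseq_library(
    genome: Genome,
    annotation: Sequence[GeneRecord],
    truth: GroundTruthManifest,
    n_reads: int,
    seed: int,
    read_length: int = 50,
    quality_char: str = "I",
) -> SimulatedLibrary:
    """RNA-Seq reads drawn uniformly within genes, genes weighted by
    ``rnaseq_abundance``; no barcodes, no adapters."""
    rng = np.random.default_rng((truth.seed, seed, 987654321))
    genes = [g for g in annotation if len(g) >= read_length]
    if truth.rnaseq_abundance is None:
        probs = np.ones(len(genes)) / len(genes)
    else:
        w = np.array([truth.rnaseq_abundance.get(g.gene_id, 0.0) for g in genes])
        probs = w / w.sum()
    rows = []
    records = []
    for i in range(n_reads):
        gene = genes[int(rng.choice(len(genes), p=probs))]
        start = int(rng.integers(gene.start, gene.end - read_length + 1))
        seq = genome.fetch(gene.replicon, start, start + read_length, gene.strand)
        read_id = f"rnaseq:r{i:07d}"
        records.append(ReadRecord(id=read_id, seq=seq, qual=quality_char * read_length))
        rows.append(
            dict(
                read_id=read_id,
                molecule_id=read_id,
                library="rnaseq",
                kind="rnaseq",
                replicon=gene.replicon,
                strand=gene.strand,
                crosslink=-1,
                circle_id="",
                tail="",
                anchor_start=start,
                anchor_end=start + read_length,
                insert=seq,
                read_seq=seq,
                gene_id=gene.gene_id,
            )
        )
    truth_df = pd.DataFrame(
        rows,
        columns=[
            "read_id", "molecule_id", "library", "kind", "replicon", "strand",
            "crosslink", "circle_id", "tail", "anchor_start", "anchor_end",
            "insert", "read_seq", "gene_id",
        ],
    )
    return SimulatedLibrary(library="rnaseq", records=records, truth=truth_df)
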