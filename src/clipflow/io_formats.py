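"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based, half-open intervals expressed on the
plus strand.  Conversion to and from external conventions (GFF3's 1-based
inclusive coordinates, bedGraph runs) happens only in this module so that
no other stage ever performs an off-by-one adjustment.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "ValidationError",
    "BIOTYPES",
    "Genome",
    "GeneRecord",
    "Interval",
    "ReadRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_fastq",
    "write_fastq",
    "write_bedgraph",
    "read_bedgraph",
    "read_operon_table",
    "write_operon_table",
    "revcomp",
]

DNA_ALPHABET = frozenset("ACGTN")

#: Closed biotype vocabulary; anything else collapses to "other".
BIOTYPES = ("protein_coding", "rRNA", "tRNA", "other")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input that violates a pipeline invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return reverse_complement(seq)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Genome:
    """Named replicon sequences; the single coordinate authority.

    Sequences are upper-case DNA (``A/C/G/T/N``), never empty, with unique
    names.  ``U`` has already been converted to ``T`` by the readers.
    """

    replicons: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValidationError("genome must contain at least one replicon")
        for name, seq in self.replicons.items():
            if not seq:
                raise ValidationError(f"replicon {name!r} is empty")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"replicon {name!r} contains non-DNA characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.replicons.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.replicons

    def __getitem__(self, name: str) -> str:
        return self.replicons[name]

    def fetch(self, replicon: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; minus strand returns the reverse
        complement (still a 5'->3' string)."""
        seq = self.replicons[replicon]
        if not (0 <= start < end <= len(seq)):
            raise ValidationError(
                f"interval [{start}, {end}) outside replicon {replicon!r} "
                f"of length {len(seq)}"
            )
        frag = seq[start:end]
        return revcomp(frag) if strand == "-" else frag


@dataclass(frozen=True)
class Interval:
    """Plain 0-based half-open interval, optionally stranded."""

    replicon: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in (None, "+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene/CDS on a replicon.

    ``start``/``end`` are 0-based half-open; ``biotype`` is drawn from
    :data:`BIOTYPES`.
    """

    replicon: str
    start: int
    end: int
    strand: str
    biotype: str
    gene_id: str
    operon_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"gene {self.gene_id!r}: biotype {self.biotype!r} not in {BIOTYPES}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.replicon, self.start, self.end, self.strand)


@dataclass
class ReadRecord:
    """A sequencing read (Phred+33 qualities), with collapse multiplicity."""

    id: str
    seq: str
    qual: str
    multiplicity: int = 1
    library: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def phred(self) -> np.ndarray:
        """Quality scores as an integer array."""
        return np.frombuffer(self.qual.encode("ascii"), dtype=np.uint8) - 33

    def trimmed(self, start: int, end: Optional[int] = None) -> "ReadRecord":
        return replace(self, seq=self.seq[start:end], qual=self.qual[start:end])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: os.PathLike | str) -> Genome:
    """Parse a FASTA file into a :class:`Genome`.

    Sequences are upper-cased and ``U`` is converted to ``T``.  Duplicate
    headers are rejected.
    """
    replicons: dict[str, str] = {}
    name: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    replicons[name] = "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                if name in replicons:
                    raise FormatError(
                        f"{path}: duplicate FASTA header {name!r} at line {lineno}"
                    )
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line.upper().replace("U", "T"))
    if name is None:
        raise FormatError(f"{path}: no FASTA records found")
    replicons[name] = "".join(chunks)
    try:
        return Genome(replicons)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(genome: Genome | Mapping[str, str], path: os.PathLike | str, width: int = 70) -> None:
    replicons = genome.replicons if isinstance(genome, Genome) else genome
    with open(path, "w") as fh:
        for name, seq in replicons.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}


def _coerce_biotype(value: Optional[str]) -> str:
    return _BIOTYPE_ALIASES.get(value or "", "other")


def read_gff3(
    path: os.PathLike | str,
    genome: Genome,
    feature_types: Sequence[str] = ("gene",),
    biotype_key: str = "gene_biotype",
    biotype_fallback_key: str = "biotype",
    id_keys: Sequence[str] = ("ID", "locus_tag", "gene_id"),
) -> list[GeneRecord]:
    """Read gene records from a GFF3 file.

    GFF3's 1-based inclusive coordinates become 0-based half-open.  The
    biotype is read from ``biotype_key`` (RefSeq dialect), falling back to
    ``biotype_fallback_key`` (Ensembl dialect); unknown values map to
    ``"other"``.  Rows on replicons absent from ``genome`` and rows whose
    interval exceeds the replicon are rejected.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    wanted = set(feature_types)
    records: list[GeneRecord] = []
    seen_ids: set[str] = set()
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in wanted:
            continue
        if feat.seqid not in genome:
            raise ValidationError(
                f"{path}: feature on unknown replicon {feat.seqid!r}"
            )
        start = feat.start - 1  # GFF3 1-based inclusive -> 0-based half-open
        end = feat.end
        if end < feat.start:
            raise ValidationError(f"{path}: feature with end < start: {feat.id}")
        if end > genome.lengths[feat.seqid]:
            raise ValidationError(
                f"{path}: feature {feat.id} extends past replicon {feat.seqid!r}"
            )
        if feat.strand not in ("+", "-"):
            raise ValidationError(f"{path}: feature {feat.id} lacks a strand")
        biotype = None
        for key in (biotype_key, biotype_fallback_key):
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        gene_id = None
        for key in id_keys:
            if key in feat.attributes:
                gene_id = feat.attributes[key][0]
                break
        if gene_id is None:
            gene_id = feat.id
        if gene_id in seen_ids:
            # RefSeq GFFs repeat IDs on multi-row features; make unique.
            n = 2
            while f"{gene_id}_{n}" in seen_ids:
                n += 1
            gene_id = f"{gene_id}_{n}"
        seen_ids.add(gene_id)
        operon = feat.attributes["operon_id"][0] if "operon_id" in feat.attributes else None
        records.append(
            GeneRecord(
                replicon=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand,
                biotype=_coerce_biotype(biotype),
                gene_id=gene_id,
                operon_id=operon,
            )
        )
    return records


def write_gff3(
    genes: Iterable[GeneRecord],
    path: os.PathLike | str,
    feature_type: str = "gene",
    source: str = "clipflow",
) -> None:
    """Write gene records as GFF3 (coordinates converted back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}", f"gene_biotype={g.biotype}"]
            if g.operon_id is not None:
                attrs.append(f"operon_id={g.operon_id}")
            fh.write(
                "\t".join(
                    [
                        g.replicon,
                        source,
                        feature_type,
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)
# ---------------------------------------------------------------------------


def read_fastq(path: os.PathLike | str) -> list[ReadRecord]:
    records: list[ReadRecord] = []
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: read {title!r} has mismatched seq/qual lengths"
                    )
                records.append(ReadRecord(id=title.split()[0], seq=seq.upper(), qual=qual))
        except ValueError as exc:  # biopython signals malformed records this way
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[ReadRecord], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(
    track: Mapping[str, np.ndarray],
    path: os.PathLike | str,
    name: Optional[str] = None,
) -> None:
    """Write per-base count vectors as bedGraph.

    Zero runs are omitted and adjacent equal values are merged into a
    single 0-based half-open run.
    """
    with open(path, "w") as fh:
        if name is not None:
            fh.write(f'track type=bedGraph name="{name}"\n')
        for replicon in track:
            values = np.asarray(track[replicon])
            if values.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    v_out = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{replicon}\t{s}\t{e}\t{v_out}\n")


def read_bedgraph(
    path: os.PathLike | str, genome: Genome, dtype=np.float64
) -> dict[str, np.ndarray]:
    """Read a bedGraph back into dense per-base vectors (zeros elsewhere)."""
    track = {name: np.zeros(length, dtype=dtype) for name, length in genome.lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            replicon, start, end, value = parts
            if replicon not in track:
                raise ValidationError(f"{path}:{lineno}: unknown replicon {replicon!r}")
            s, e = int(start), int(end)
            if not (0 <= s < e <= track[replicon].size):
                raise ValidationError(f"{path}:{lineno}: interval outside replicon")
            track[replicon][s:e] = float(value)
    return track


# ---------------------------------------------------------------------------
# Operon table (TSV: gene_id <tab> operon_id)
# ---------------------------------------------------------------------------


def read_operon_table(path: os.PathLike | str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "operon_id"}.issubset(df.columns):
        raise FormatError(f"{path}: operon table needs columns gene_id, operon_id")
    return dict(zip(df["gene_id"], df["operon_id"]))


def write_operon_table(operons: Mapping[str, str], path: os.PathLike | str) -> None:
    pd.DataFrame(
        {"gene_id": list(operons.keys()), "operon_id": list(operons.values())}
    ).to_csv(path, sep="\t", index=False)
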