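"""Readers/writers and coordinate conventions for the survey pipeline.

All genomic coordinates in this package are 1-based and inclusive on both
ends, matching GFF3. BED input (0-based, half-open) is converted on read.
Strand is stored but ignored by every distance computation downstream: the
tandem/segmental rules operate on positions only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("tps_survey")

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | set("BJXZUO*")
DNA_ALPHABET = set("ACGT") | set("RYSWKMBDHVN")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, empty sequences, bad columns)."""


class CoordinateError(ValueError):
    """Violation of the 1-based inclusive coordinate contract."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"empty sequence for id {self.id!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        bad = set(self.residues.upper()) - allowed - {"-"}
        if bad:
            raise FormatError(
                f"{self.id}: residues outside {self.alphabet} alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    rank: int = 0
    coding_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise CoordinateError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.coding_length > self.end - self.start + 1:
            raise CoordinateError(f"{self.gene_id}: coding_length exceeds gene span")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GenomeAnnotation:
    species: str
    genome_size: int
    chromosomes: dict[str, list[GeneModel]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        max_end = 0
        for chrom, genes in self.chromosomes.items():
            for g in genes:
                if g.gene_id in seen:
                    raise FormatError(f"duplicate gene_id {g.gene_id!r}")
                seen.add(g.gene_id)
                max_end = max(max_end, g.end)
        if self.genome_size < max_end:
            raise CoordinateError("genome_size smaller than the last gene end")

    def gene(self, gene_id: str) -> GeneModel:
        for genes in self.chromosomes.values():
            for g in genes:
                if g.gene_id == gene_id:
                    return g
        raise KeyError(gene_id)

    def all_genes(self) -> list[GeneModel]:
        return [g for genes in self.chromosomes.values() for g in genes]


@dataclass(frozen=True)
class FeatureInterval:
    chrom: str
    start: int
    end: int
    feature_type: str

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise CoordinateError(f"invalid interval [{self.start}, {self.end}]")


def span_length(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive interval.

    The convention is anchored on the maize worked example: an
    LTR-retrotransposon printed as chr10:73,878,251–73,885,160 spans 6,910 bp.
    """
    if start < 1 or end < 1:
        raise CoordinateError("coordinates must be positive (1-based)")
    if start > end:
        raise CoordinateError(f"start {start} > end {end}")
    return end - start + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords; residues are uppercased on read."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper(), desc, alphabet=alphabet)
        )
    logger.info("read %d %s records from %s", len(records), alphabet, path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def read_gff_genes(
    path: str | Path, species: str = "", genome_size: int | None = None
) -> GenomeAnnotation:
    """Read gene features from GFF3; ranks assigned by start order per chromosome.

    Rank ties (identical starts) are broken by gene_id lexicographic order.
    """
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str}
    )
    df = df[df["type"] == "gene"]
    chromosomes: dict[str, list[GeneModel]] = {}
    seen: set[str] = set()
    for chrom, sub in df.groupby("seqid", sort=True):
        rows = sorted(
            sub.itertuples(index=False),
            key=lambda r: (int(r.start), _gff_attr(r.attributes, "ID") or ""),
        )
        genes = []
        for rank, r in enumerate(rows, start=1):
            gid = _gff_attr(r.attributes, "ID")
            if gid is None:
                raise FormatError(f"gene without ID attribute on {chrom}")
            if gid in seen:
                raise FormatError(f"duplicate gene id {gid!r}")
            seen.add(gid)
            clen_s = _gff_attr(r.attributes, "coding_length")
            genes.append(
                GeneModel(
                    gene_id=gid, chrom=str(chrom), start=int(r.start), end=int(r.end),
                    strand=str(r.strand), rank=rank,
                    coding_length=int(clen_s) if clen_s else 0,
                )
            )
        chromosomes[str(chrom)] = genes
    if genome_size is None:
        genome_size = max((g.end for c in chromosomes.values() for g in c), default=0)
    ann = GenomeAnnotation(species=species, genome_size=genome_size, chromosomes=chromosomes)
    logger.info("read %d genes on %d chromosomes from %s",
                len(ann.all_genes()), len(chromosomes), path)
    return ann


def write_gff_genes(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chromosomes):
            for g in annotation.chromosomes[chrom]:
                attrs = f"ID={g.gene_id}"
                if g.coding_length:
                    attrs += f";coding_length={g.coding_length}"
                fh.write(
                    f"{chrom}\ttps_survey\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED elements (0-based half-open on disk -> 1-based inclusive in memory)
# ---------------------------------------------------------------------------

def read_bed_elements(path: str | Path) -> list[FeatureInterval]:
    feats: list[FeatureInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "element"
            feats.append(FeatureInterval(chrom, start0 + 1, end0, name))
    return feats


def write_bed_elements(elements: Iterable[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.feature_type}\n")


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix; first column is the gene id index."""
    return pd.read_csv(str(path), sep="\t", index_col=0)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    """Design table with columns sample, tissue, replicate (sample as index)."""
    df = pd.read_csv(str(path), sep="\t")
    required = {"sample", "tissue", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(f"design table needs columns {sorted(required)}")
    return df.set_index("sample")
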