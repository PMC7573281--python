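"""Readers/writers for the formats the pipeline touches: VCF, GFF3, FASTA, TSV.

Coordinate convention: every position held in memory is 1-based inclusive,
matching the VCF and GFF3 source formats.  Conversions to half-open systems
(e.g. the BED block track) are localized to the writers that need them.

Only ``CHROM``, ``POS``, ``REF``, ``ALT`` and the ``GT`` field carry meaning
downstream; everything else in a VCF is ignored on read and emitted as ``.``
on write.  Genotypes are stored as tuples of allele indices (``0`` = REF,
``k`` = k-th ALT) or ``None`` when the call is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Genotype = tuple[int, ...] | None

__all__ = [
    "Genotype",
    "GenomeSequence",
    "VariantRecord",
    "TranscriptModel",
    "GeneModel",
    "CountMatrix",
    "VcfParseError",
    "Gff3ParseError",
    "CountsError",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_gff3_genes",
    "write_gff3",
    "read_counts",
    "write_counts",
    "is_hom",
    "is_het",
]


class VcfParseError(ValueError):
    pass


class Gff3ParseError(ValueError):
    pass


class CountsError(ValueError):
    pass


@dataclass
class GenomeSequence:
    """One reference contig: id plus uppercase DNA."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive subsequence."""
        if start < 1 or end > self.length:
            raise IndexError(
                f"[{start},{end}] outside contig {self.contig_id} (length {self.length})"
            )
        return self.sequence[start - 1 : end]


@dataclass
class VariantRecord:
    """A variant site with per-sample genotype codes.

    ``pos`` is the 1-based position of the first REF base.  ``evidence``
    accumulates support tags (``DNA``, ``RNA_skin``, ``RNA_liver``) as the
    record flows through the filtering chain.
    """

    contig_id: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: dict[str, Genotype]
    source: str = ""
    evidence: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValueError("ref_allele must be nonempty")
        for alt in self.alt_alleles:
            if alt == self.ref_allele:
                raise ValueError(f"alt equals ref at {self.contig_id}:{self.pos}")
        n_alleles = 1 + len(self.alt_alleles)
        for sample, gt in self.genotypes.items():
            if gt is not None and any(a >= n_alleles or a < 0 for a in gt):
                raise ValueError(
                    f"genotype {gt} for {sample} indexes a nonexistent allele "
                    f"at {self.contig_id}:{self.pos}"
                )

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.contig_id, self.pos, self.ref_allele, tuple(sorted(self.alt_alleles)))

    def allele(self, index: int) -> str:
        return self.ref_allele if index == 0 else self.alt_alleles[index - 1]

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)


def is_hom(gt: Genotype) -> bool:
    return gt is not None and len(set(gt)) == 1


def is_het(gt: Genotype) -> bool:
    return gt is not None and len(set(gt)) > 1


@dataclass
class TranscriptModel:
    """Stranded exon/CDS structure of one transcript.

    ``exons`` are (start, end) pairs and ``cds_segments`` are
    (start, end, phase) triples, all 1-based inclusive and sorted by genomic
    position regardless of strand.
    """

    transcript_id: str
    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        last_end = 0
        for s, e in self.exons:
            if s <= last_end:
                raise ValueError(f"overlapping/unsorted exons in {self.transcript_id}")
            last_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)


@dataclass
class GeneModel:
    gene_id: str
    contig_id: str
    strand: str
    gene_start: int
    gene_end: int
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(f"gene_start > gene_end for {self.gene_id}")

    def overlaps(self, contig_id: str, pos: int) -> bool:
        return contig_id == self.contig_id and self.gene_start <= pos <= self.gene_end


@dataclass
class CountMatrix:
    """Gene-by-sample read counts plus a strain label per sample."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: "pd.DataFrame"
    strain_of: dict[str, str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, strain_of: Mapping[str, str]) -> "CountMatrix":
        if (frame.to_numpy() < 0).any():
            raise CountsError("negative counts are not allowed")
        missing = [s for s in frame.columns if s not in strain_of]
        if missing:
            raise CountsError(f"samples missing from metadata: {', '.join(missing)}")
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            counts=frame,
            strain_of={s: strain_of[s] for s in frame.columns},
        )

    def samples_of(self, strain: str) -> list[str]:
        return [s for s in self.sample_ids if self.strain_of[s] == strain]

    @property
    def strains(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            if self.strain_of[s] not in seen:
                seen.append(self.strain_of[s])
        return seen


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, GenomeSequence]:
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig id {rec.id}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    return genome


def write_fasta(genome: Mapping[str, GenomeSequence], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.contig_id, description="") for g in genome.values()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF v4.x into `VariantRecord`s.

    Multiallelic sites are retained as single records; samples follow the
    header order.  Rows without a GT field raise ``VcfParseError``.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vf.header.samples)
    records: list[VariantRecord] = []
    line_no = _header_line_count(path)
    try:
        for rec in vf:
            line_no += 1
            if samples and "GT" not in rec.format:
                raise VcfParseError(f"{path} line {line_no}: no GT field")
            genotypes: dict[str, Genotype] = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    genotypes[s] = None
                else:
                    genotypes[s] = tuple(a for a in gt if a is not None)
            records.append(
                VariantRecord(
                    contig_id=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts or ()),
                    genotypes=genotypes,
                )
            )
    except VcfParseError:
        raise
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path} line {line_no + 1}: {exc}") from exc
    return records


def _header_line_count(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            n += 1
            if line.startswith("#CHROM"):
                return n
    return n


def _gt_string(gt: Genotype) -> str:
    if gt is None:
        return "./."
    return "/".join(str(a) for a in gt)


def write_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write GT-only VCF v4.2.

    ``contigs`` maps contig id to length; when supplied, every record must
    lie on a known contig (and ``##contig`` header lines are emitted).
    """
    records = list(records)
    if contigs is not None:
        for r in records:
            if r.contig_id not in contigs:
                raise ValueError(f"record on unknown contig {r.contig_id}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for cid, length in contigs.items():
                fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols += ["FORMAT", *samples]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            unknown = set(r.genotypes) - set(samples)
            if unknown:
                raise ValueError(f"record samples not in sample list: {sorted(unknown)}")
            alt = ",".join(r.alt_alleles) if r.alt_alleles else "."
            row = [r.contig_id, str(r.pos), ".", r.ref_allele, alt, ".", "PASS", "."]
            if samples:
                row.append("GT")
                row += [_gt_string(r.genotypes.get(s)) for s in samples]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features linked by ID/Parent into `GeneModel`s."""
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise Gff3ParseError(f"cannot parse GFF3 {path}: {exc}") from exc

    known_tx = {f.id for f in db.features_of_type("mRNA")}
    known_genes = {f.id for f in db.features_of_type("gene")}
    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            if not parents or not any(p in known_tx for p in parents):
                raise Gff3ParseError(f"orphan {ftype} feature {f.id!r}: Parent unresolvable")
    for f in db.features_of_type("mRNA"):
        parents = f.attributes.get("Parent", [])
        if not parents or not any(p in known_genes for p in parents):
            raise Gff3ParseError(f"orphan mRNA {f.id!r}: Parent unresolvable")

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            exons = [(c.start, c.end) for c in db.children(t, featuretype="exon", order_by="start")]
            cds = [
                (c.start, c.end, int(c.frame) if c.frame != "." else 0)
                for c in db.children(t, featuretype="CDS", order_by="start")
            ]
            transcripts.append(
                TranscriptModel(
                    transcript_id=t.id,
                    gene_id=g.id,
                    contig_id=g.seqid,
                    strand=t.strand,
                    exons=exons,
                    cds_segments=cds,
                )
            )
        genes.append(
            GeneModel(
                gene_id=g.id,
                contig_id=g.seqid,
                strand=g.strand,
                gene_start=g.start,
                gene_end=g.end,
                transcripts=transcripts,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tsibstrain\tgene\t{g.gene_start}\t{g.gene_end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                t_start = min(s for s, _ in t.exons)
                t_end = max(e for _, e in t.exons)
                fh.write(
                    f"{g.contig_id}\tsibstrain\tmRNA\t{t_start}\t{t_end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.contig_id}\tsibstrain\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                for i, (s, e, phase) in enumerate(t.cds_segments, 1):
                    fh.write(
                        f"{g.contig_id}\tsibstrain\tCDS\t{s}\t{e}\t.\t{t.strand}\t{phase}\t"
                        f"ID={t.transcript_id}.cds;Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Count matrices


def read_counts(path, metadata_path) -> CountMatrix:
    """Read a gene x sample TSV plus a sample->strain metadata TSV."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    for col in frame.columns:
        values = frame[col]
        if not all(float(v).is_integer() for v in values):
            bad = next(v for v in values if not float(v).is_integer())
            raise CountsError(f"non-integer count {bad!r} in sample {col}")
    frame = frame.astype(int)
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"sample_id", "strain"} <= set(meta.columns):
        raise CountsError("metadata must have columns sample_id and strain")
    strain_of = dict(zip(meta["sample_id"].astype(str), meta["strain"].astype(str)))
    return CountMatrix.from_frame(frame, strain_of)


def write_counts(matrix: CountMatrix, counts_path, metadata_path=None) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        pd.DataFrame(
            {"sample_id": matrix.sample_ids, "strain": [matrix.strain_of[s] for s in matrix.sample_ids]}
        ).to_csv(metadata_path, sep="\t", index=False)
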