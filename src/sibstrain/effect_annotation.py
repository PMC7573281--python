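"""Transcript-aware classification of variant effects on coding sequences.

A deliberately compact annotator covering the effect vocabulary used for
protein-level interpretation: synonymous / missense / start_lost /
stop_gained / stop_lost for SNVs; frameshift and conservative vs disruptive
in-frame insertions/deletions for indels (conservative = the edited span
aligns with codon boundaries, the common annotator convention); intergenic,
intron, splice_region (2 bp of intron flanking an exon) and UTR for
non-coding contexts.  One effect is produced per (variant, transcript)
pair; a gene-level rollup picks the most severe.

Indels are expected in left-normalized VCF representation (shared anchor
base first).  Variants whose edited span crosses a CDS/exon boundary are
conservatively classified as splice_region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .io_formats import GeneModel, GenomeSequence, TranscriptModel, VariantRecord

__all__ = [
    "EFFECT_SEVERITY",
    "PROTEIN_ALTERING",
    "CodingEffect",
    "spliced_cds",
    "classify_snv",
    "classify_indel",
    "classify_context",
    "annotate_variant",
    "annotate_all",
    "rollup_coding_genes",
    "coding_tallies",
]

# most severe first
EFFECT_SEVERITY = [
    "frameshift",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "inframe_insertion_disruptive",
    "inframe_deletion_disruptive",
    "inframe_insertion_conservative",
    "inframe_deletion_conservative",
    "missense",
    "splice_region",
    "synonymous",
    "utr",
    "intron",
    "intergenic",
]
_RANK = {e: i for i, e in enumerate(EFFECT_SEVERITY)}

PROTEIN_ALTERING = frozenset(
    [
        "frameshift",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "inframe_insertion_disruptive",
        "inframe_deletion_disruptive",
        "inframe_insertion_conservative",
        "inframe_deletion_conservative",
        "missense",
        "splice_region",
    ]
)


@dataclass
class CodingEffect:
    """Effect of one variant on one transcript."""

    variant: VariantRecord
    gene_id: str
    transcript_id: str
    effect: str
    codon_change: str = ""
    aa_change: str = ""
    cds_pos: int = 0

    def __post_init__(self) -> None:
        if self.effect not in _RANK:
            raise ValueError(f"unknown effect class {self.effect!r}")


def worst_effect(effects: Iterable[str]) -> str:
    return min(effects, key=lambda e: _RANK[e])


def spliced_cds(tx: TranscriptModel, genome: Mapping[str, GenomeSequence]) -> str:
    """CDS in translation order (reverse-complemented on the minus strand)."""
    contig = genome[tx.contig_id]
    parts = [contig.slice(s, e) for s, e, _ in tx.cds_segments]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_coordinate(tx: TranscriptModel, pos: int) -> int | None:
    """1-based position within the spliced CDS, or None if outside the CDS."""
    segments = tx.cds_segments if tx.strand == "+" else tx.cds_segments[::-1]
    offset = 0
    for s, e, _ in segments:
        if s <= pos <= e:
            return offset + (pos - s + 1 if tx.strand == "+" else e - pos + 1)
        offset += e - s + 1
    return None


def _segment_of(tx: TranscriptModel, pos: int) -> tuple[int, int] | None:
    for s, e, _ in tx.cds_segments:
        if s <= pos <= e:
            return (s, e)
    return None


def _check_ref(v: VariantRecord, genome: Mapping[str, GenomeSequence]) -> None:
    contig = genome[v.contig_id]
    observed = contig.slice(v.pos, v.pos + len(v.ref_allele) - 1)
    if observed != v.ref_allele:
        raise ValueError(
            f"REF mismatch at {v.contig_id}:{v.pos}: {v.ref_allele!r} vs genome {observed!r}"
        )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(cds: str) -> str:
    usable = cds[: len(cds) - len(cds) % 3]
    return str(Seq(usable).translate())


def _codon_change_string(codon_ref: str, codon_alt: str, within: int) -> str:
    def fmt(codon: str) -> str:
        return "".join(b.upper() if i == within else b.lower() for i, b in enumerate(codon))

    return f"{fmt(codon_ref)}/{fmt(codon_alt)}"


def classify_snv(
    v: VariantRecord,
    tx: TranscriptModel,
    genome: Mapping[str, GenomeSequence],
    alt_index: int = 1,
) -> CodingEffect:
    """Classify a CDS-overlapping SNV by translating the affected codon."""
    _check_ref(v, genome)
    alt = v.allele(alt_index)
    if len(v.ref_allele) != 1 or len(alt) != 1:
        raise ValueError("classify_snv requires a single-nucleotide variant")
    p = _cds_coordinate(tx, v.pos)
    if p is None:
        raise ValueError(f"variant {v.contig_id}:{v.pos} does not overlap the CDS of {tx.transcript_id}")
    cds = spliced_cds(tx, genome)
    ref_base = v.ref_allele if tx.strand == "+" else _revcomp(v.ref_allele)
    alt_base = alt if tx.strand == "+" else _revcomp(alt)
    if cds[p - 1] != ref_base:
        raise ValueError(f"CDS/ref inconsistency at cds position {p} of {tx.transcript_id}")
    codon_idx = (p - 1) // 3
    within = (p - 1) % 3
    codon_ref = cds[codon_idx * 3 : codon_idx * 3 + 3]
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())

    if codon_idx == 0 and codon_alt != "ATG":
        effect = "start_lost"
    elif aa_ref == "*" and aa_alt != "*":
        effect = "stop_lost"
    elif aa_alt == "*" and aa_ref != "*":
        effect = "stop_gained"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    else:
        effect = "missense"
    return CodingEffect(
        variant=v,
        gene_id=tx.gene_id,
        transcript_id=tx.transcript_id,
        effect=effect,
        codon_change=_codon_change_string(codon_ref, codon_alt, within),
        aa_change=f"{aa_ref}{codon_idx + 1}{aa_alt}",
        cds_pos=p,
    )


def classify_indel(
    v: VariantRecord,
    tx: TranscriptModel,
    genome: Mapping[str, GenomeSequence],
    alt_index: int = 1,
) -> CodingEffect:
    """Classify a CDS-overlapping indel (left-normalized, anchored form).

    Net length change not divisible by three is a frameshift.  In-frame
    events are conservative when the edited span aligns with codon
    boundaries and disruptive otherwise; an in-frame event introducing a
    premature stop is promoted to stop_gained.
    """
    _check_ref(v, genome)
    alt = v.allele(alt_index)
    net = len(alt) - len(v.ref_allele)
    if net == 0:
        raise ValueError("classify_indel requires a length-changing variant")
    cds = spliced_cds(tx, genome)
    n = len(cds)

    if net % 3 != 0:
        p = _cds_coordinate(tx, v.pos)
        return CodingEffect(
            variant=v, gene_id=tx.gene_id, transcript_id=tx.transcript_id,
            effect="frameshift", cds_pos=p or 0,
        )

    is_deletion = len(v.ref_allele) > len(alt)
    if is_deletion:
        # deleted genomic span is pos+1 .. pos+len(ref)-1
        del_positions = range(v.pos + 1, v.pos + len(v.ref_allele))
        cds_coords = sorted(
            c for c in (_cds_coordinate(tx, p) for p in del_positions) if c is not None
        )
        d1, d2 = cds_coords[0], cds_coords[-1]
        conservative = (d1 - 1) % 3 == 0 and d2 % 3 == 0
        mutated = cds[: d1 - 1] + cds[d2:]
        effect = "inframe_deletion_conservative" if conservative else "inframe_deletion_disruptive"
        cds_pos = d1
    else:
        inserted = alt[len(v.ref_allele):]
        # anchored insertion sits between genomic pos and pos+1
        if tx.strand == "+":
            t = _cds_coordinate(tx, v.pos)
            coding_insert = inserted
        else:
            t = _cds_coordinate(tx, v.pos + 1)
            coding_insert = _revcomp(inserted)
        if t is None:
            t = 0
        conservative = t % 3 == 0
        mutated = cds[:t] + coding_insert + cds[t:]
        effect = "inframe_insertion_conservative" if conservative else "inframe_insertion_disruptive"
        cds_pos = t + 1

    prot_ref = _translate(cds)
    prot_alt = _translate(mutated)
    if "*" in prot_alt[:-1] and "*" not in prot_ref[:-1]:
        effect = "stop_gained"
    return CodingEffect(
        variant=v, gene_id=tx.gene_id, transcript_id=tx.transcript_id,
        effect=effect, cds_pos=cds_pos,
    )


def classify_context(v: VariantRecord, genes: Sequence[GeneModel]) -> str:
    """Locate a variant relative to gene models: intergenic / intron /
    splice_region / utr (exonic but outside the CDS)."""
    overlapping = [g for g in genes if g.overlaps(v.contig_id, v.pos)]
    if not overlapping:
        return "intergenic"
    classes = []
    for gene in overlapping:
        for tx in gene.transcripts:
            in_exon = any(s <= v.pos <= e for s, e in tx.exons)
            if in_exon:
                # exonic: context-level classification reports utr (CDS hits
                # are routed to the coding classifiers by annotate_variant)
                classes.append("utr")
            else:
                near_boundary = any(
                    0 < v.pos - e <= 2 or 0 < s - v.pos <= 2 for s, e in tx.exons
                )
                classes.append("splice_region" if near_boundary else "intron")
        if not gene.transcripts:
            classes.append("intron")
    return worst_effect(classes)


def _edited_span(v: VariantRecord, alt: str) -> tuple[int, int]:
    """Genomic positions whose bases are changed/deleted, or the anchor pair
    for a pure insertion."""
    if len(v.ref_allele) == 1 and len(alt) == 1:
        return (v.pos, v.pos)
    if len(v.ref_allele) > 1:
        return (v.pos + 1, v.pos + len(v.ref_allele) - 1)
    return (v.pos, v.pos + 1)  # insertion anchor


def annotate_variant(
    v: VariantRecord,
    genes: Sequence[GeneModel],
    genome: Mapping[str, GenomeSequence],
    alt_index: int = 1,
) -> list[CodingEffect]:
    """Annotate one (biallelic) variant against every overlapping transcript.

    Returns one `CodingEffect` per (variant, transcript) pair, or a single
    context-level record when the variant touches no transcript CDS.
    """
    alt = v.allele(alt_index)
    span = _edited_span(v, alt)
    results: list[CodingEffect] = []
    for gene in genes:
        if gene.contig_id != v.contig_id:
            continue
        if not (gene.gene_start <= span[1] and span[0] <= gene.gene_end):
            continue
        for tx in gene.transcripts:
            seg_first = _segment_of(tx, span[0])
            seg_last = _segment_of(tx, span[1])
            is_insertion = len(alt) > len(v.ref_allele) and len(v.ref_allele) == 1
            if is_insertion:
                anchored_inside = seg_first is not None and seg_first == seg_last
                if anchored_inside:
                    results.append(classify_indel(v, tx, genome, alt_index))
                elif seg_first is not None or seg_last is not None:
                    results.append(
                        CodingEffect(v, gene.gene_id, tx.transcript_id, "splice_region")
                    )
                else:
                    results.append(
                        CodingEffect(v, gene.gene_id, tx.transcript_id, classify_context(v, [gene]))
                    )
                continue
            if seg_first is not None and seg_first == seg_last:
                if v.is_snv:
                    results.append(classify_snv(v, tx, genome, alt_index))
                else:
                    results.append(classify_indel(v, tx, genome, alt_index))
            elif seg_first is not None or seg_last is not None:
                # edited span crosses a CDS segment boundary
                results.append(
                    CodingEffect(v, gene.gene_id, tx.transcript_id, "splice_region")
                )
            else:
                results.append(
                    CodingEffect(v, gene.gene_id, tx.transcript_id, classify_context(v, [gene]))
                )
    if not results:
        results.append(CodingEffect(v, "", "", "intergenic"))
    return results


def annotate_all(
    variants: Iterable[VariantRecord],
    genes: Sequence[GeneModel],
    genome: Mapping[str, GenomeSequence],
) -> list[CodingEffect]:
    effects: list[CodingEffect] = []
    for v in variants:
        for alt_index in range(1, len(v.alt_alleles) + 1):
            effects.extend(annotate_variant(v, genes, genome, alt_index))
    return effects


def rollup_coding_genes(
    effects: Iterable[CodingEffect],
) -> tuple[set[str], dict[str, str]]:
    """Genes carrying at least one protein-altering effect, with each gene's
    most severe effect class."""
    worst: dict[str, str] = {}
    for eff in effects:
        if eff.effect not in PROTEIN_ALTERING or not eff.gene_id:
            continue
        cur = worst.get(eff.gene_id)
        if cur is None or _RANK[eff.effect] < _RANK[cur]:
            worst[eff.gene_id] = eff.effect
    return set(worst), worst


def coding_tallies(effects: Iterable[CodingEffect]) -> dict[str, int]:
    """Protein-altering counts both per distinct variant and per
    variant-transcript pair, plus the distinct gene count."""
    effects = [e for e in effects if e.effect in PROTEIN_ALTERING and e.gene_id]
    variants = {e.variant.key for e in effects}
    genes = {e.gene_id for e in effects}
    return {
        "n_protein_altering_variants": len(variants),
        "n_protein_altering_effects": len(effects),
        "n_genes": len(genes),
    }
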