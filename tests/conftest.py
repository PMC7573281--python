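import numpy as np
import pytest

from sibstrain.io_formats import GeneModel, GenomeSequence, TranscriptModel, VariantRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_toy_gene(
    coding: str,
    strand: str = "+",
    splits: tuple[int, ...] = (),
    intron_len: int = 20,
    pad: int = 30,
    gene_id: str = "g1",
    contig_id: str = "chr1",
    pad_base: str = "G",
):
    """A single-gene genome from a coding sequence.

    ``splits`` are spliced-CDS offsets where introns are inserted.  Returns
    (genome dict, GeneModel); the spliced CDS of the gene equals ``coding``.
    """
    payload = coding if strand == "+" else revcomp(coding)
    pieces = []
    prev = 0
    for cut in sorted(splits):
        pieces.append(payload[prev:cut])
        prev = cut
    pieces.append(payload[prev:])

    seq = pad_base * pad
    segments = []
    pos = pad + 1
    for i, piece in enumerate(pieces):
        if i > 0:
            seq += pad_base * intron_len
            pos += intron_len
        segments.append((pos, pos + len(piece) - 1))
        seq += piece
        pos += len(piece)
    seq += pad_base * pad

    order = segments if strand == "+" else segments[::-1]
    phases = []
    cum = 0
    for s, e in order:
        phases.append((3 - cum % 3) % 3)
        cum += e - s + 1
    phase_of = dict(zip(order, phases))
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        contig_id=contig_id,
        strand=strand,
        exons=segments,
        cds_segments=[(s, e, phase_of[(s, e)]) for s, e in segments],
    )
    gene = GeneModel(
        gene_id=gene_id,
        contig_id=contig_id,
        strand=strand,
        gene_start=segments[0][0],
        gene_end=segments[-1][1],
        transcripts=[tx],
    )
    return {contig_id: GenomeSequence(contig_id, seq)}, gene


def make_record(contig="chr1", pos=100, ref="A", alts=("G",), genotypes=None):
    return VariantRecord(
        contig_id=contig,
        pos=pos,
        ref_allele=ref,
        alt_alleles=tuple(alts),
        genotypes=genotypes or {},
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_sim():
    """One shared desk-scale simulation (deep inbreeding, zero-error calls)."""
    from sibstrain.synthetic_data import SimConfig, run_simulation

    cfg = SimConfig(
        seed=11,
        generations=60,
        caller_fn_rates=(0.0, 0.0),
        genotype_error_rate=0.0,
    )
    return run_simulation(cfg)
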