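"""Forward simulation of two sibling-founded, full-sib-inbred lines.

The history being emulated: a single wild-caught heterozygous pair produces
a brood; two disjoint sibling pairs from that brood found two lines (JpA and
JpB), which are then propagated by brother-sister mating for on the order of
a hundred generations.  Ancestral heterozygous sites fix independently in
each line, producing inter-strain fixed differences arranged in
recombination-bounded chromosomal blocks.  On top of the genetic truth the
module emulates the measurement layer: two DNA variant callers with
independent miss/error profiles, RNA-derived callsets restricted to exonic
sites of expressed genes, and negative-binomial expression counts with a
planted fraction of differentially expressed genes, some forced to lie
within a cis window of a fixed variant.

Under the "ancestral" founder phase (the default), both founders are
heterozygous at every polymorphic site and each carries one chromosome from
each of two diverged ancestral lineages, so whether a segment is fixed
different between the lines is purely a function of descent: fixation
status can only switch at a recorded crossover breakpoint, which is what
gives the variant blocks their sharp recombination-defined edges.  The
"random" phase scrambles the alternate allele across haplotypes per site,
breaking that alignment while preserving per-site heterozygosity dynamics.

Expected heterozygosity under repeated full-sib mating follows the classic
second-order recurrence H_t = 1/2 H_{t-1} + 1/4 H_{t-2}; the simulator's
decay is validated against a numerical evaluation of that recurrence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    CountMatrix,
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    VariantRecord,
    write_counts,
    write_fasta,
    write_gff3,
    write_vcf,
)
from .variant_consensus import CallSet, left_normalize

__all__ = [
    "SimConfig",
    "SiteTable",
    "Diplotype",
    "Pedigree",
    "SimResult",
    "make_founder_genome",
    "seed_ancestral_variation",
    "meiosis",
    "breed_sib_lines",
    "emulate_callsets",
    "simulate_expression",
    "run_simulation",
    "expected_heterozygosity",
    "genotype_matrix",
    "truth_fixed_differences",
]

STRAIN_A = "JpA"
STRAIN_B = "JpB"

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NONSTOP = [c for c in _CODONS if c not in _STOPS]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Free parameters of the simulation.

    Defaults are desk-scale for genome size and gene count but follow the
    study design for the breeding and sampling structure: ~110 generations
    of brother-sister mating, 4 DNA samples per strain, skin RNA cohorts of
    25 (JpA) and 30 (JpB) and liver cohorts of 6 and 4.
    """

    n_contigs: int = 3
    contig_length: int = 200_000
    n_genes: int = 45
    exons_per_gene: tuple[int, int] = (2, 5)
    founder_het_rate: float = 1e-3
    indel_fraction: float = 0.1
    max_indel_len: int = 6
    crossovers_per_meiosis: float = 1.0
    generations: int = 110
    pre_separation_generations: int = 0
    brood_size: int = 6
    n_dna_samples_per_strain: int = 4
    n_rna_skin: tuple[int, int] = (25, 30)
    n_rna_liver: tuple[int, int] = (6, 4)
    genotype_error_rate: float = 0.0
    caller_fn_rates: tuple[float, float] = (0.05, 0.05)
    nb_mean_range: tuple[float, float] = (20.0, 500.0)
    nb_dispersion: float = 0.1
    library_factor_range: tuple[float, float] = (0.75, 1.25)
    rna_expression_floor: float = 10.0
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    cis_de_fraction: float = 0.25
    cis_window: int = 3000
    founder_phase: str = "ancestral"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "founder_het_rate",
            "indel_fraction",
            "genotype_error_rate",
            "de_fraction",
            "cis_de_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for r in self.caller_fn_rates:
            if not 0 <= r <= 1:
                raise ValueError(f"caller_fn_rates must be in [0,1], got {r}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.brood_size < 4:
            raise ValueError("brood_size must be >= 4 (two sibling pairs found the lines)")
        if self.founder_phase not in ("ancestral", "random"):
            raise ValueError("founder_phase must be 'ancestral' or 'random'")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)


@dataclass
class SiteTable:
    """Polymorphic sites on one contig: position, ref and alt allele."""

    contig_id: str
    positions: np.ndarray  # 1-based, sorted ascending
    refs: list[str]
    alts: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class Diplotype:
    """Two haplotypes over a contig's polymorphic sites (0 = ref, 1 = alt)."""

    contig_id: str
    positions: np.ndarray
    hap0: np.ndarray
    hap1: np.ndarray

    def __post_init__(self) -> None:
        if len(self.hap0) != len(self.positions) or len(self.hap1) != len(self.positions):
            raise ValueError("haplotypes must cover the same site set")

    def haps(self) -> tuple[np.ndarray, np.ndarray]:
        return self.hap0, self.hap1


Individual = dict[str, Diplotype]  # contig_id -> Diplotype


@dataclass
class PedigreeEvent:
    line: str
    generation: int
    offspring_id: str
    parent_id: str
    contig_id: str
    breakpoints: tuple[int, ...]


@dataclass
class Pedigree:
    """Record of every gamete's crossover breakpoints along both lineages."""

    events: list[PedigreeEvent] = field(default_factory=list)

    def add(self, line, generation, offspring_id, parent_id, contig_id, breakpoints) -> None:
        bps = tuple(int(b) for b in breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        self.events.append(
            PedigreeEvent(line, generation, offspring_id, parent_id, contig_id, bps)
        )

    def breakpoints_on(self, contig_id: str) -> np.ndarray:
        bps = sorted(
            {b for ev in self.events if ev.contig_id == contig_id for b in ev.breakpoints}
        )
        return np.array(bps, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line": [e.line for e in self.events],
                "generation": [e.generation for e in self.events],
                "offspring_id": [e.offspring_id for e in self.events],
                "parent_id": [e.parent_id for e in self.events],
                "contig_id": [e.contig_id for e in self.events],
                "breakpoints": [",".join(map(str, e.breakpoints)) for e in self.events],
            }
        )


# ---------------------------------------------------------------------------
# Genome and gene construction


def make_founder_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, GenomeSequence], list[GeneModel]]:
    """Random contigs with non-overlapping multi-exon protein-coding genes.

    Every CDS starts with ATG, ends in a stop codon, contains no internal
    stop and has spliced length divisible by three, so the effect annotator
    can be exercised on fully valid gene models.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    contig_ids = [f"chr{i + 1}" for i in range(config.n_contigs)]
    sequences = {
        cid: rng.choice(_BASES, size=config.contig_length) for cid in contig_ids
    }

    genes: list[GeneModel] = []
    cursor = {cid: int(rng.integers(200, 2000)) for cid in contig_ids}
    contig_cycle = 0
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        n_codons = int(rng.integers(60, 200))
        cds_len = 3 * n_codons
        # split the spliced CDS into n_exons pieces of >= 3 bp
        cuts = np.sort(rng.choice(np.arange(1, cds_len // 3), size=n_exons - 1, replace=False)) * 3 if n_exons > 1 else np.array([], dtype=int)
        piece_lens = np.diff(np.concatenate(([0], cuts, [cds_len])))
        intron_lens = rng.integers(60, 1500, size=n_exons - 1)
        span = int(piece_lens.sum() + intron_lens.sum())

        placed = False
        for _ in range(config.n_contigs):
            cid = contig_ids[contig_cycle % config.n_contigs]
            start = cursor[cid]
            if start + span < config.contig_length - 500:
                placed = True
                break
            contig_cycle += 1
        if not placed:
            raise ValueError(
                f"cannot place gene {gi + 1} of {config.n_genes} without overlap; "
                "lower n_genes or raise contig_length"
            )

        strand = "+" if rng.random() < 0.5 else "-"
        coding = "ATG" + "".join(rng.choice(_NONSTOP, size=n_codons - 2)) + str(
            rng.choice(np.array(_STOPS))
        )
        genomic_payload = coding if strand == "+" else _revcomp(coding)

        segments: list[tuple[int, int]] = []
        pos = start
        offset = 0
        for k, plen in enumerate(piece_lens):
            seg = (pos, pos + int(plen) - 1)
            segments.append(seg)
            sequences[cid][seg[0] - 1 : seg[1]] = list(
                genomic_payload[offset : offset + int(plen)]
            )
            offset += int(plen)
            if k < n_exons - 1:
                pos = seg[1] + 1 + int(intron_lens[k])
        gene_start, gene_end = segments[0][0], segments[-1][1]
        cursor[cid] = gene_end + int(rng.integers(500, 4000))
        contig_cycle += 1

        # phase = bases to skip to reach the next codon start, in translation order
        order = segments if strand == "+" else segments[::-1]
        phases_in_order = []
        cum = 0
        for s, e in order:
            phases_in_order.append((3 - cum % 3) % 3)
            cum += e - s + 1
        phase_of = dict(zip(order, phases_in_order))
        cds_segments = [(s, e, phase_of[(s, e)]) for s, e in segments]

        gene_id = f"gene{gi + 1:04d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig_id=cid,
                strand=strand,
                gene_start=gene_start,
                gene_end=gene_end,
                transcripts=[
                    TranscriptModel(
                        transcript_id=f"{gene_id}.t1",
                        gene_id=gene_id,
                        contig_id=cid,
                        strand=strand,
                        exons=segments,
                        cds_segments=cds_segments,
                    )
                ],
            )
        )

    genome = {cid: GenomeSequence(cid, "".join(seq)) for cid, seq in sequences.items()}
    return genome, genes


# ---------------------------------------------------------------------------
# Ancestral variation and founders


def seed_ancestral_variation(
    genome: Mapping[str, GenomeSequence],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, SiteTable], tuple[Individual, Individual]]:
    """Plant heterozygous ancestral sites and build the founder pair.

    Site count per contig is Binomial(contig_length, founder_het_rate);
    a configured fraction are short indels (<= max_indel_len bp), the rest
    SNVs.  All sites are stored left-normalized against the genome.  Both
    founders are heterozygous at every site; under the "ancestral" phase,
    haplotype 0 carries ref and haplotype 1 carries alt for every founder
    (the founders behave like F1s of two diverged ancestral lineages),
    while the "random" phase scrambles which haplotype carries alt per
    founder per site.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sites: dict[str, SiteTable] = {}
    for cid, contig in genome.items():
        n = rng.binomial(contig.length, config.founder_het_rate)
        margin = config.max_indel_len + 2
        lo, hi = margin, contig.length - margin
        n = min(n, max(hi - lo, 0))
        positions = np.sort(rng.choice(np.arange(lo, hi), size=n, replace=False))
        seen: dict[int, tuple[int, str, str]] = {}
        for pos in positions:
            pos = int(pos)
            ref_base = contig.slice(pos, pos)
            if rng.random() >= config.indel_fraction:
                ref = ref_base
                alt = str(rng.choice(_BASES[_BASES != ref_base]))
            else:
                length = int(rng.integers(1, config.max_indel_len + 1))
                if rng.random() < 0.5:  # deletion
                    ref = contig.slice(pos, pos + length)
                    alt = ref_base
                else:  # insertion
                    ref = ref_base
                    alt = ref_base + "".join(rng.choice(_BASES, size=length))
            norm = left_normalize(VariantRecord(cid, pos, ref, (alt,), {}), genome)
            # first site normalizing to a position wins; duplicates dropped
            seen.setdefault(norm.pos, (norm.pos, norm.ref_allele, norm.alt_alleles[0]))
        ordered = sorted(seen.values())
        sites[cid] = SiteTable(
            contig_id=cid,
            positions=np.array([p for p, _, _ in ordered], dtype=int),
            refs=[r for _, r, _ in ordered],
            alts=[a for _, _, a in ordered],
        )

    def founder() -> Individual:
        ind: Individual = {}
        for cid, tab in sites.items():
            n = tab.n_sites
            if config.founder_phase == "ancestral":
                hap0 = np.zeros(n, dtype=np.int8)
                hap1 = np.ones(n, dtype=np.int8)
            else:
                flip = rng.integers(0, 2, size=n).astype(np.int8)
                hap0 = flip
                hap1 = 1 - flip
            ind[cid] = Diplotype(cid, tab.positions, hap0, hap1)
        return ind

    return sites, (founder(), founder())


# ---------------------------------------------------------------------------
# Meiosis and breeding


def meiosis(
    parent: Diplotype,
    contig_length: int,
    crossovers_per_meiosis: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a diplotype: Poisson crossover count, uniform
    breakpoints, no interference.

    Returns (haplotype alleles, breakpoint positions).  A site at position p
    takes the phase active on the segment containing p; phase flips occur
    immediately after each breakpoint.
    """
    k = rng.poisson(crossovers_per_meiosis)
    breakpoints = np.unique(rng.integers(1, contig_length, size=k)) if k else np.array([], dtype=int)
    start_phase = int(rng.integers(0, 2))
    seg_index = np.searchsorted(breakpoints, parent.positions, side="left")
    phase = (start_phase + seg_index) % 2
    haps = np.stack(parent.haps())
    gamete = haps[phase, np.arange(len(parent.positions))]
    return gamete.astype(np.int8), breakpoints


def _offspring(
    mother: Individual,
    father: Individual,
    config: SimConfig,
    rng: np.random.Generator,
    pedigree: Pedigree | None,
    line: str,
    generation: int,
    offspring_id: str,
    mother_id: str,
    father_id: str,
) -> Individual:
    child: Individual = {}
    for cid in mother:
        egg, bp_m = meiosis(mother[cid], config.contig_length, config.crossovers_per_meiosis, rng)
        sperm, bp_f = meiosis(father[cid], config.contig_length, config.crossovers_per_meiosis, rng)
        if pedigree is not None:
            pedigree.add(line, generation, offspring_id, mother_id, cid, bp_m)
            pedigree.add(line, generation, offspring_id, father_id, cid, bp_f)
        child[cid] = Diplotype(cid, mother[cid].positions, egg, sperm)
    return child


@dataclass
class SibLines:
    """Final-generation sample genotypes for both strains, plus the pedigree."""

    samples: dict[str, dict[str, Individual]]  # strain -> sample_id -> Individual
    pedigree: Pedigree
    sample_roles: dict[str, str]  # sample_id -> {dna, skin, liver}

    def sample_ids(self, strain: str, role: str | None = None) -> list[str]:
        ids = list(self.samples[strain])
        if role is None:
            return ids
        return [s for s in ids if self.sample_roles[s] == role]


def breed_sib_lines(
    founders: tuple[Individual, Individual],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SibLines:
    """Propagate two lines from two sibling pairs of the founder brood.

    ``generations = 0`` samples the founder brood itself (heterozygosity at
    the founder-cross expectation); ``generations = g`` samples the
    offspring of the pair reached after g rounds of brother-sister mating.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pedigree = Pedigree()
    mother, father = founders

    def brood(pair, line, generation, n, prefix) -> list[tuple[str, Individual]]:
        m, f = pair
        out = []
        for i in range(n):
            oid = f"{prefix}_g{generation}_{i + 1}"
            out.append(
                (
                    oid,
                    _offspring(
                        m[1], f[1], config, rng, pedigree, line, generation,
                        oid, m[0], f[0],
                    ),
                )
            )
        return out

    pair0 = (("founder_F", mother), ("founder_M", father))
    # optional flock-mating phase before the lines were separated
    for g in range(config.pre_separation_generations):
        kids = brood(pair0, "flock", -config.pre_separation_generations + g, config.brood_size, "flock")
        idx = rng.choice(len(kids), size=2, replace=False)
        pair0 = (kids[idx[0]], kids[idx[1]])

    f1 = brood(pair0, "founding", 0, max(config.brood_size, 4), "f1")
    idx = rng.choice(len(f1), size=4, replace=False)
    pairs = {STRAIN_A: (f1[idx[0]], f1[idx[1]]), STRAIN_B: (f1[idx[2]], f1[idx[3]])}

    final_pairs: dict[str, tuple] = {}
    for strain in (STRAIN_A, STRAIN_B):
        pair = pairs[strain] if config.generations > 0 else pair0
        for g in range(1, config.generations):
            kids = brood(pair, strain, g, config.brood_size, strain)
            idx = rng.choice(len(kids), size=2, replace=False)
            pair = (kids[idx[0]], kids[idx[1]])
        final_pairs[strain] = pair

    samples: dict[str, dict[str, Individual]] = {STRAIN_A: {}, STRAIN_B: {}}
    roles: dict[str, str] = {}
    n_skin = dict(zip((STRAIN_A, STRAIN_B), config.n_rna_skin))
    n_liver = dict(zip((STRAIN_A, STRAIN_B), config.n_rna_liver))
    for strain in (STRAIN_A, STRAIN_B):
        pair = final_pairs[strain]
        plan = (
            [("dna", i) for i in range(config.n_dna_samples_per_strain)]
            + [("skin", i) for i in range(n_skin[strain])]
            + [("liver", i) for i in range(n_liver[strain])]
        )
        for role, i in plan:
            sid = f"{strain}_{role}{i + 1}"
            samples[strain][sid] = _offspring(
                pair[0][1], pair[1][1], config, rng, pedigree, strain,
                config.generations, sid, pair[0][0], pair[1][0],
            )
            roles[sid] = role
    return SibLines(samples=samples, pedigree=pedigree, sample_roles=roles)


def expected_heterozygosity(generations: int) -> float:
    """Numerical evaluation of the full-sib recurrence H_t = 1/2 H_{t-1} + 1/4 H_{t-2}.

    Index 0 is the founder brood (H = 1/2 when both founders are
    heterozygous); index 1 (offspring of a sibling pair from that brood) is
    also 1/2, after which the recurrence decays geometrically with ratio
    (1 + sqrt(5))/4 ~ 0.809.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    h = [0.5, 0.5]
    for _ in range(2, generations + 1):
        h.append(0.5 * h[-1] + 0.25 * h[-2])
    return h[generations]


# ---------------------------------------------------------------------------
# Genotype matrices and truth


def genotype_matrix(
    lines: SibLines, contig_id: str, sample_ids: Sequence[str]
) -> np.ndarray:
    """(n_samples, n_sites) alt-allele dosage matrix (0/1/2)."""
    rows = []
    all_samples = {**lines.samples[STRAIN_A], **lines.samples[STRAIN_B]}
    for sid in sample_ids:
        d = all_samples[sid][contig_id]
        rows.append(d.hap0.astype(int) + d.hap1.astype(int))
    return np.array(rows, dtype=int)


def truth_fixed_differences(
    lines: SibLines, sites: Mapping[str, SiteTable]
) -> dict[str, np.ndarray]:
    """Boolean mask per contig: all strain-A samples homozygous for one
    allele and all strain-B samples homozygous for the other."""
    out: dict[str, np.ndarray] = {}
    for cid, tab in sites.items():
        masks = {}
        for strain in (STRAIN_A, STRAIN_B):
            ids = lines.sample_ids(strain)
            g = genotype_matrix(lines, cid, ids)
            masks[strain] = {
                "ref": (g == 0).all(axis=0),
                "alt": (g == 2).all(axis=0),
            }
        out[cid] = (masks[STRAIN_A]["ref"] & masks[STRAIN_B]["alt"]) | (
            masks[STRAIN_A]["alt"] & masks[STRAIN_B]["ref"]
        )
    return out


# ---------------------------------------------------------------------------
# Measurement layer


def _dosage_to_gt(code: int) -> tuple[int, int]:
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(code)]


def _records_for(
    sites: Mapping[str, SiteTable],
    lines: SibLines,
    sample_ids: Sequence[str],
    rng: np.random.Generator,
    fn_rate: float,
    error_rate: float,
    source: str,
    site_mask: Mapping[str, np.ndarray] | None = None,
) -> CallSet:
    records = []
    for cid, tab in sites.items():
        if tab.n_sites == 0:
            continue
        keep = rng.random(tab.n_sites) >= fn_rate
        if site_mask is not None:
            keep &= site_mask[cid]
        g = genotype_matrix(lines, cid, sample_ids)
        if error_rate > 0:
            err = rng.random(g.shape) < error_rate
            shift = rng.integers(1, 3, size=g.shape)
            g = np.where(err, (g + shift) % 3, g)
        for j in np.flatnonzero(keep):
            genotypes = {
                sid: _dosage_to_gt(g[i, j]) for i, sid in enumerate(sample_ids)
            }
            records.append(
                VariantRecord(
                    contig_id=cid,
                    pos=int(tab.positions[j]),
                    ref_allele=tab.refs[j],
                    alt_alleles=(tab.alts[j],),
                    genotypes=genotypes,
                    source=source,
                )
            )
    return CallSet(records=records, sample_ids=list(sample_ids), source=source)


def _exonic_mask(
    sites: Mapping[str, SiteTable], genes: Sequence[GeneModel], expressed: set[str]
) -> dict[str, np.ndarray]:
    mask = {cid: np.zeros(tab.n_sites, dtype=bool) for cid, tab in sites.items()}
    for gene in genes:
        if gene.gene_id not in expressed:
            continue
        tab = sites.get(gene.contig_id)
        if tab is None:
            continue
        for tx in gene.transcripts:
            for s, e in tx.exons:
                mask[gene.contig_id] |= (tab.positions >= s) & (tab.positions <= e)
    return mask


def emulate_callsets(
    sites: Mapping[str, SiteTable],
    lines: SibLines,
    genes: Sequence[GeneModel],
    expressed_genes: Mapping[str, set[str]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CallSet, CallSet, dict[str, CallSet]]:
    """Emulate two DNA callers and per-tissue RNA callsets.

    Each DNA caller misses a true site independently with its false-negative
    rate and corrupts individual genotype calls at ``genotype_error_rate``.
    RNA callsets only contain sites inside exons of genes expressed above
    the floor in that tissue, genotyped on that tissue's RNA samples.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dna_samples = lines.sample_ids(STRAIN_A, "dna") + lines.sample_ids(STRAIN_B, "dna")
    caller1 = _records_for(
        sites, lines, dna_samples, rng, config.caller_fn_rates[0],
        config.genotype_error_rate, "DNA_caller1",
    )
    caller2 = _records_for(
        sites, lines, dna_samples, rng, config.caller_fn_rates[1],
        config.genotype_error_rate, "DNA_caller2",
    )
    rna: dict[str, CallSet] = {}
    for tissue in ("skin", "liver"):
        rna_samples = lines.sample_ids(STRAIN_A, tissue) + lines.sample_ids(STRAIN_B, tissue)
        if not rna_samples:
            continue
        mask = _exonic_mask(sites, genes, expressed_genes.get(tissue, set()))
        rna[tissue] = _records_for(
            sites, lines, rna_samples, rng, 0.0, config.genotype_error_rate,
            f"RNA_{tissue}", site_mask=mask,
        )
    return caller1, caller2, rna


def simulate_expression(
    genes: Sequence[GeneModel],
    fixed_positions: Mapping[str, np.ndarray],
    lines: SibLines,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """NB-distributed skin and liver counts with a planted DEG fraction.

    Gene baseline means are log-uniform on ``nb_mean_range``; a fraction
    ``de_fraction`` of genes get their strain-B skin mean multiplied by
    2**(+/- de_log2fc).  A fraction ``cis_de_fraction`` of planted DEGs are
    chosen among genes with a true fixed variant within ``cis_window`` bp of
    the gene span, so cis-proximity linkage has signal to recover.  Liver
    counts share the baseline means with no planted effect.  Returns the two
    count matrices plus the planted-truth table.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(genes)
    lo, hi = config.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))

    has_cis = np.zeros(n_genes, dtype=bool)
    for i, g in enumerate(genes):
        pos = fixed_positions.get(g.contig_id)
        if pos is None or len(pos) == 0:
            continue
        has_cis[i] = (
            (pos >= g.gene_start - config.cis_window) & (pos <= g.gene_end + config.cis_window)
        ).any()

    n_de = int(round(config.de_fraction * n_genes))
    cis_target = int(round(config.cis_de_fraction * n_de))
    cis_pool = np.flatnonzero(has_cis)
    other_pool = np.flatnonzero(~has_cis)
    n_cis = min(cis_target, len(cis_pool), n_de)
    chosen_cis = rng.choice(cis_pool, size=n_cis, replace=False) if n_cis else np.array([], dtype=int)
    remaining = np.setdiff1d(np.arange(n_genes), chosen_cis)
    n_rest = min(n_de - n_cis, len(remaining))
    chosen_rest = rng.choice(remaining, size=n_rest, replace=False) if n_rest else np.array([], dtype=int)
    de_idx = np.sort(np.concatenate([chosen_cis, chosen_rest]).astype(int))
    sign = np.zeros(n_genes)
    sign[de_idx] = rng.choice([-1.0, 1.0], size=len(de_idx))

    phi = config.nb_dispersion

    def draw(sample_ids: Sequence[str], strain_of: dict[str, str], de: bool) -> pd.DataFrame:
        cols = {}
        for sid in sample_ids:
            factor = rng.uniform(*config.library_factor_range)
            mu = base_mean.copy()
            if de and strain_of[sid] == STRAIN_B:
                mu = mu * np.power(2.0, sign * config.de_log2fc)
            mu = mu * factor
            n_param = 1.0 / phi
            p_param = n_param / (n_param + mu)
            cols[sid] = rng.negative_binomial(n_param, p_param)
        return pd.DataFrame(cols, index=gene_ids)

    matrices = {}
    for tissue, de in (("skin", True), ("liver", False)):
        ids = lines.sample_ids(STRAIN_A, tissue) + lines.sample_ids(STRAIN_B, tissue)
        strain_of = {s: (STRAIN_A if s.startswith(STRAIN_A) else STRAIN_B) for s in ids}
        if ids:
            matrices[tissue] = CountMatrix.from_frame(draw(ids, strain_of, de), strain_of)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": sign != 0,
            "planted_log2fc": sign * config.de_log2fc,
            "cis_linked": [i in set(chosen_cis.tolist()) for i in range(n_genes)],
            "has_cis_variant": has_cis,
        }
    )
    return matrices.get("skin"), matrices.get("liver"), truth


# ---------------------------------------------------------------------------
# Driver


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, GenomeSequence]
    genes: list[GeneModel]
    sites: dict[str, SiteTable]
    lines: SibLines
    caller1: CallSet
    caller2: CallSet
    rna: dict[str, CallSet]
    counts_skin: CountMatrix
    counts_liver: CountMatrix | None
    truth_degs: pd.DataFrame
    truth_fixed: dict[str, np.ndarray]

    def truth_fixed_records(self) -> list[VariantRecord]:
        recs = []
        for cid, tab in self.sites.items():
            mask = self.truth_fixed[cid]
            for j in np.flatnonzero(mask):
                recs.append(
                    VariantRecord(cid, int(tab.positions[j]), tab.refs[j], (tab.alts[j],), {})
                )
        return recs


def run_simulation(config: SimConfig, out_dir=None) -> SimResult:
    """Run the whole generator; optionally write every artifact to ``out_dir``.

    All randomness flows from ``config.seed``; the same seed reproduces
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genome, genes = make_founder_genome(config, rng)
    sites, founders = seed_ancestral_variation(genome, config, rng)
    lines = breed_sib_lines(founders, config, rng)
    truth_fixed = truth_fixed_differences(lines, sites)
    fixed_positions = {
        cid: sites[cid].positions[mask] for cid, mask in truth_fixed.items()
    }
    counts_skin, counts_liver, truth_degs = simulate_expression(
        genes, fixed_positions, lines, config, rng
    )
    expressed = {}
    for tissue, cm in (("skin", counts_skin), ("liver", counts_liver)):
        if cm is not None:
            row_means = cm.counts.mean(axis=1)
            expressed[tissue] = set(row_means.index[row_means >= config.rna_expression_floor])
    caller1, caller2, rna = emulate_callsets(sites, lines, genes, expressed, config, rng)

    result = SimResult(
        config=config,
        genome=genome,
        genes=genes,
        sites=sites,
        lines=lines,
        caller1=caller1,
        caller2=caller2,
        rna=rna,
        counts_skin=counts_skin,
        counts_liver=counts_liver,
        truth_degs=truth_degs,
        truth_fixed=truth_fixed,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(res: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = {cid: g.length for cid, g in res.genome.items()}
    write_fasta(res.genome, out_dir / "genome.fa")
    write_gff3(res.genes, out_dir / "genes.gff3")
    write_vcf(res.truth_fixed_records(), [], out_dir / "truth_variants.vcf", contigs)
    for name, cs in (("caller1", res.caller1), ("caller2", res.caller2)):
        write_vcf(cs.records, cs.sample_ids, out_dir / f"{name}.vcf", contigs)
    for tissue, cs in res.rna.items():
        write_vcf(cs.records, cs.sample_ids, out_dir / f"rna_{tissue}.vcf", contigs)
    rows = []
    for strain in (STRAIN_A, STRAIN_B):
        for sid in res.lines.sample_ids(strain):
            rows.append({"sample_id": sid, "strain": strain, "role": res.lines.sample_roles[sid]})
    pd.DataFrame(rows).to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    if res.counts_skin is not None:
        write_counts(res.counts_skin, out_dir / "counts_skin.tsv")
    if res.counts_liver is not None:
        write_counts(res.counts_liver, out_dir / "counts_liver.tsv")
    res.truth_degs.to_csv(out_dir / "truth_degs.tsv", sep="\t", index=False)
    res.lines.pedigree.to_frame().to_csv(out_dir / "pedigree.tsv", sep="\t", index=False)
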