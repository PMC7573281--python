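"""Fixed inter-strain variant detection.

The filtering chain mirrors the comparative design for two inbred lines:
variants are left-normalized so records from different callers are
comparable, only sites reported by both callers are kept, a site is a fixed
difference when at least 75% of one strain's samples are homozygous for one
allele and at least 75% of the other strain's samples are homozygous for a
different allele, and finally every fixed difference must be corroborated by
an RNA-derived callset (allele-level support in the strain carrying the
non-reference allele).

Multiallelic records are decomposed to biallelic ones before the
two-allele fixed-difference rule is applied; genotypes involving a different
alternate allele are treated as missing in the decomposed record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomeSequence, VariantRecord, is_hom

__all__ = [
    "CallSet",
    "FixedDifference",
    "left_normalize",
    "decompose_multiallelic",
    "intersect_callsets",
    "fixed_differences",
    "require_rna_support",
]


@dataclass
class CallSet:
    """An ordered collection of variant records from one caller/tissue."""

    records: list[VariantRecord]
    sample_ids: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.contig_id, r.pos))

    def keys(self) -> set[tuple]:
        return {r.key for r in self.records}


@dataclass
class FixedDifference:
    """A site fixed for different alleles in the two strains."""

    variant: VariantRecord
    strain_a_allele: str
    strain_b_allele: str
    frac_a_hom: float
    frac_b_hom: float
    rna_supported: bool = False

    def __post_init__(self) -> None:
        if self.strain_a_allele == self.strain_b_allele:
            raise ValueError("strain alleles must differ")

    @property
    def key(self) -> tuple:
        return self.variant.key


def left_normalize(v: VariantRecord, genome: Mapping[str, GenomeSequence]) -> VariantRecord:
    """Left-align and parsimony-trim a variant against the reference.

    Implements the standard normalization loop: right-trim shared trailing
    bases (extending left with reference sequence whenever an allele would
    empty), then left-trim shared leading bases.  SNVs pass through
    unchanged; the operation is idempotent.
    """
    contig = genome[v.contig_id]
    if contig.slice(v.pos, v.pos + len(v.ref_allele) - 1) != v.ref_allele:
        raise ValueError(
            f"REF mismatch at {v.contig_id}:{v.pos}: VCF says {v.ref_allele!r}, "
            f"genome says {contig.slice(v.pos, v.pos + len(v.ref_allele) - 1)!r}"
        )
    alleles = [v.ref_allele, *v.alt_alleles]
    pos = v.pos
    while True:
        # right-trim a shared trailing base (an emptied allele triggers a
        # left extension with reference sequence on the next pass)
        if (
            all(len(a) >= 1 for a in alleles)
            and not all(len(a) == 1 for a in alleles)
            and len({a[-1] for a in alleles}) == 1
        ):
            alleles = [a[:-1] for a in alleles]
            continue
        if any(len(a) == 0 for a in alleles):
            if pos == 1:
                raise ValueError(f"cannot left-extend past contig start at {v.contig_id}:1")
            pos -= 1
            base = contig.slice(pos, pos)
            alleles = [base + a for a in alleles]
            continue
        break
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return VariantRecord(
        contig_id=v.contig_id,
        pos=pos,
        ref_allele=alleles[0],
        alt_alleles=tuple(alleles[1:]),
        genotypes=dict(v.genotypes),
        source=v.source,
        evidence=set(v.evidence),
    )


def decompose_multiallelic(
    records: Iterable[VariantRecord],
    genome: Mapping[str, GenomeSequence] | None = None,
) -> list[VariantRecord]:
    """Split multiallelic records into biallelic ones.

    In each decomposed record, genotypes referring to a different alternate
    allele become missing (the two-allele fixed-difference rule is only
    well-defined on biallelic records).  When a genome is supplied, each
    decomposed record is re-normalized, since per-allele trimming can shift
    the position.
    """
    out: list[VariantRecord] = []
    for rec in records:
        if len(rec.alt_alleles) <= 1:
            out.append(rec)
            continue
        for k, alt in enumerate(rec.alt_alleles, start=1):
            genotypes = {}
            for s, gt in rec.genotypes.items():
                if gt is None or any(a not in (0, k) for a in gt):
                    genotypes[s] = None
                else:
                    genotypes[s] = tuple(1 if a == k else 0 for a in gt)
            sub = VariantRecord(
                contig_id=rec.contig_id,
                pos=rec.pos,
                ref_allele=rec.ref_allele,
                alt_alleles=(alt,),
                genotypes=genotypes,
                source=rec.source,
                evidence=set(rec.evidence),
            )
            out.append(left_normalize(sub, genome) if genome is not None else sub)
    return out


def _warn_if_unnormalized(records: Iterable[VariantRecord]) -> None:
    for r in records:
        alleles = [r.ref_allele, *r.alt_alleles]
        if len(alleles) > 1 and all(len(a) > 1 for a in alleles) and len({a[-1] for a in alleles}) == 1:
            warnings.warn(
                f"record {r.contig_id}:{r.pos} shares a redundant allele suffix; "
                "input looks unnormalized",
                stacklevel=3,
            )


def intersect_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Keep sites reported identically (contig, pos, ref, alt set) by both callers.

    Genotypes come from callset ``a`` (the primary); record order is
    preserved.
    """
    _warn_if_unnormalized(a.records)
    _warn_if_unnormalized(b.records)
    b_keys = b.keys()
    kept = [r for r in a.records if r.key in b_keys]
    return CallSet(records=kept, sample_ids=list(a.sample_ids), source=a.source)


def _hom_fraction(genotypes: Sequence, allele_index: int) -> float:
    called = [g for g in genotypes if g is not None]
    if not called:
        return 0.0
    hom = sum(1 for g in called if is_hom(g) and g[0] == allele_index)
    return hom / len(called)


def fixed_differences(
    calls: CallSet,
    strain_a_samples: Sequence[str],
    strain_b_samples: Sequence[str],
    threshold: float = 0.75,
    genome: Mapping[str, GenomeSequence] | None = None,
    min_called: int = 2,
) -> list[FixedDifference]:
    """Apply the >= ``threshold`` homozygosity rule between the two strains.

    A site qualifies when some allele x is homozygous in at least
    ``threshold`` of strain-A samples and a different allele y is homozygous
    in at least ``threshold`` of strain-B samples.  Fractions use genotyped
    (non-missing) samples as the denominator; sites with fewer than
    ``min_called`` genotyped samples in either strain are skipped.
    """
    if not strain_a_samples or not strain_b_samples:
        raise ValueError("both strain sample lists must be nonempty")
    if not 0.5 < threshold <= 1:
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    known = set(calls.sample_ids)
    for s in [*strain_a_samples, *strain_b_samples]:
        if s not in known:
            raise ValueError(f"sample {s!r} not present in callset")

    out: list[FixedDifference] = []
    for rec in decompose_multiallelic(calls.records, genome):
        gts_a = [rec.genotypes.get(s) for s in strain_a_samples]
        gts_b = [rec.genotypes.get(s) for s in strain_b_samples]
        if sum(g is not None for g in gts_a) < min_called:
            continue
        if sum(g is not None for g in gts_b) < min_called:
            continue
        # threshold > 0.5 means at most one allele can qualify per strain
        best = None
        for x in (0, 1):
            frac_a = _hom_fraction(gts_a, x)
            if frac_a < threshold:
                continue
            for y in (0, 1):
                if y == x:
                    continue
                frac_b = _hom_fraction(gts_b, y)
                if frac_b >= threshold:
                    best = (x, y, frac_a, frac_b)
        if best is not None:
            x, y, frac_a, frac_b = best
            out.append(
                FixedDifference(
                    variant=rec,
                    strain_a_allele=rec.allele(x),
                    strain_b_allele=rec.allele(y),
                    frac_a_hom=frac_a,
                    frac_b_hom=frac_b,
                )
            )
    return out


def require_rna_support(
    fixed: Sequence[FixedDifference],
    rna: Sequence[CallSet],
    strain_a_samples: Sequence[str] | None = None,
    strain_b_samples: Sequence[str] | None = None,
) -> list[FixedDifference]:
    """Keep fixed differences corroborated by an RNA callset.

    Support means: some RNA callset contains a record with the same
    (contig, pos, ref, alt) whose genotypes show the non-reference allele in
    a sample of the strain that carries it.  When the per-strain RNA sample
    lists are not given, any sample carrying the allele counts.
    """
    rna_index: dict[tuple, list[VariantRecord]] = {}
    for cs in rna:
        for rec in decompose_multiallelic(cs.records):
            rna_index.setdefault(rec.key, []).append(rec)

    kept: list[FixedDifference] = []
    for fd in fixed:
        ref = fd.variant.ref_allele
        if fd.strain_a_allele != ref:
            carrier_samples = strain_a_samples
        else:
            carrier_samples = strain_b_samples
        supported = False
        for rec in rna_index.get(fd.key, []):
            for s, gt in rec.genotypes.items():
                if gt is None or 1 not in gt:
                    continue
                if carrier_samples is None or s in carrier_samples:
                    supported = True
                    break
            if supported:
                break
        if supported:
            kept.append(
                FixedDifference(
                    variant=fd.variant,
                    strain_a_allele=fd.strain_a_allele,
                    strain_b_allele=fd.strain_b_allele,
                    frac_a_hom=fd.frac_a_hom,
                    frac_b_hom=fd.frac_b_hom,
                    rna_supported=True,
                )
            )
    return kept
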