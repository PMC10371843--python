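"""Mutation block detection across a patient cohort (MuSSD).

Somatic SNVs from many patients are chained into mutation clusters (adjacent
SNVs closer than ``max_adjacent_gap``), clusters are merged into mutation
blocks (inter-cluster distance below ``max_block_gap``), and each block is
tested for mutational enrichment with an exact binomial test against a
cohort-wide background rate per bp per patient, Bonferroni-corrected over
candidate blocks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

from scipy import stats

from .io import GenomicIntervals

logger = logging.getLogger(__name__)

_DNA = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class PatientVariant:
    """A single-nucleotide somatic variant of one patient (0-based pos)."""

    patient_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.ref_base not in _DNA or self.alt_base not in _DNA:
            raise ValueError(f"not an SNV: {self.ref_base}>{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")


@dataclass
class MutationCluster:
    """A chain of nearby SNVs shared by at least ``min_patients`` patients."""

    chrom: str
    start: int  # 0-based inclusive of first variant
    end: int    # 0-based half-open past last variant
    variants: list[PatientVariant]

    @property
    def patients(self) -> set[str]:
        return {v.patient_id for v in self.variants}


@dataclass
class MutationBlock:
    """A merged group of mutation clusters with cohort-level significance."""

    block_id: str
    chrom: str
    start: int
    end: int
    clusters: list[MutationCluster]
    variants: list[PatientVariant]
    p_value: float | None = None
    p_adjusted: float | None = None

    @property
    def patients(self) -> set[str]:
        return {v.patient_id for v in self.variants}

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _block_id(k: int, chrom: str, start: int, end: int) -> str:
    # id coordinates are 1-based inclusive: [start+1, end] for half-open [start, end)
    return f"block_{k}_{chrom}_{start + 1}_{end}"


@dataclass
class VariantLoadStats:
    n_records: int = 0
    n_kept: int = 0
    n_non_snv: int = 0
    n_ref_mismatch: int = 0


def load_patient_variants(
    vcf_paths,
    genome: dict[str, str] | None = None,
) -> tuple[list[PatientVariant], VariantLoadStats]:
    """Load SNVs from per-patient VCFs (patient id = filename stem) or one
    multi-sample VCF (variants assigned to samples carrying a non-ref GT).

    Non-SNV records are skipped and counted; 1-based VCF POS becomes 0-based;
    multi-allelic records are split per ALT.  When a genome is supplied,
    records whose REF disagrees with it are skipped with a warning.
    """
    import pysam

    if isinstance(vcf_paths, (str, Path)):
        vcf_paths = [vcf_paths]
    variants: list[PatientVariant] = []
    stats_ = VariantLoadStats()
    seen: set[tuple] = set()
    for path in vcf_paths:
        path = Path(path)
        stem = path.name.split(".")[0]
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            for rec in vf:
                stats_.n_records += 1
                pos0 = rec.pos - 1
                ref = (rec.ref or "").upper()
                alts = [a.upper() for a in (rec.alts or ())]
                if ref not in _DNA:
                    stats_.n_non_snv += 1
                    continue
                snv_alts = [a for a in alts if a in _DNA and a != ref]
                if not snv_alts:
                    stats_.n_non_snv += 1
                    continue
                if len(snv_alts) < len(alts):
                    stats_.n_non_snv += 1  # count the dropped non-SNV allele(s)
                if genome is not None:
                    gseq = genome.get(rec.chrom, "")
                    if pos0 >= len(gseq) or gseq[pos0] != ref:
                        stats_.n_ref_mismatch += 1
                        logger.warning(
                            "REF mismatch at %s:%d in %s; record skipped",
                            rec.chrom, rec.pos, path.name,
                        )
                        continue
                if samples:
                    carriers = []
                    for s in samples:
                        gt = rec.samples[s].get("GT")
                        if gt and any(a not in (None, 0) for a in gt):
                            carriers.append(s)
                else:
                    carriers = [stem]
                for alt in snv_alts:
                    for patient in carriers:
                        key = (patient, rec.chrom, pos0, alt)
                        if key in seen:
                            continue
                        seen.add(key)
                        variants.append(
                            PatientVariant(patient, rec.chrom, pos0, ref, alt)
                        )
                        stats_.n_kept += 1
    return variants, stats_


def _dedup_sort(variants) -> dict[str, list[PatientVariant]]:
    """Per-chromosome position-sorted variants, deduplicating same
    patient+position records (multiple patients at one position all count)."""
    seen = set()
    per_chrom: dict[str, list[PatientVariant]] = {}
    for v in variants:
        key = (v.patient_id, v.chrom, v.pos)
        if key in seen:
            continue
        seen.add(key)
        per_chrom.setdefault(v.chrom, []).append(v)
    for chrom in per_chrom:
        per_chrom[chrom].sort(key=lambda v: v.pos)
    return per_chrom


def find_mutation_clusters(
    variants,
    max_adjacent_gap: int = 30,
    min_snvs: int = 2,
    min_patients: int = 2,
) -> list[MutationCluster]:
    """Chain sorted variants whose adjacent position gaps are < max_adjacent_gap,
    keeping chains with enough SNVs from enough distinct patients."""
    clusters: list[MutationCluster] = []
    per_chrom = _dedup_sort(variants)
    for chrom in sorted(per_chrom):
        vs = per_chrom[chrom]
        chain: list[PatientVariant] = []
        for v in vs:
            if chain and v.pos - chain[-1].pos >= max_adjacent_gap:
                clusters.extend(
                    _finalize_cluster(chrom, chain, min_snvs, min_patients)
                )
                chain = []
            chain.append(v)
        clusters.extend(_finalize_cluster(chrom, chain, min_snvs, min_patients))
    return clusters


def _finalize_cluster(chrom, chain, min_snvs, min_patients):
    if len(chain) >= min_snvs and len({v.patient_id for v in chain}) >= min_patients:
        return [
            MutationCluster(
                chrom=chrom,
                start=chain[0].pos,
                end=chain[-1].pos + 1,
                variants=list(chain),
            )
        ]
    return []


def merge_clusters_into_blocks(
    clusters,
    max_block_gap: int = 500,
    min_block_snvs: int = 3,
    min_block_patients: int = 3,
) -> list[MutationBlock]:
    """Merge per-chromosome cluster chains separated by < max_block_gap into
    blocks, applying block-level SNV/patient thresholds.

    Cohort-scale runs use the 3-SNV / 3-patient thresholds; genome-wide scans
    may relax both to 2.
    """
    per_chrom: dict[str, list[MutationCluster]] = {}
    for c in clusters:
        per_chrom.setdefault(c.chrom, []).append(c)
    blocks: list[MutationBlock] = []
    k = 0
    for chrom in sorted(per_chrom):
        cs = sorted(per_chrom[chrom], key=lambda c: c.start)
        chain: list[MutationCluster] = []
        for c in cs:
            if chain and c.start - chain[-1].end >= max_block_gap:
                k = _finalize_block(chain, blocks, k, min_block_snvs, min_block_patients)
                chain = []
            chain.append(c)
        k = _finalize_block(chain, blocks, k, min_block_snvs, min_block_patients)
    return blocks


def _finalize_block(chain, blocks, k, min_snvs, min_patients):
    if not chain:
        return k
    variants = [v for c in chain for v in c.variants]
    patients = {v.patient_id for v in variants}
    if len(variants) >= min_snvs and len(patients) >= min_patients:
        k += 1
        start, end = chain[0].start, chain[-1].end
        blocks.append(
            MutationBlock(
                block_id=_block_id(k, chain[0].chrom, start, end),
                chrom=chain[0].chrom,
                start=start,
                end=end,
                clusters=list(chain),
                variants=variants,
            )
        )
    return k


def test_block_significance(
    block: MutationBlock,
    n_patients: int,
    background_rate: float,
    n_candidate_blocks: int = 1,
) -> tuple[float, float]:
    """Exact binomial upper tail for observing >= k SNVs in the block.

    k = SNVs in the block, n = span_bp * n_patients trials, p = cohort
    background mutation rate per bp per patient.  Bonferroni over the
    candidate blocks.  Sets p_value/p_adjusted on the block and returns them.
    """
    if not (0 < background_rate < 1):
        raise ValueError(f"background_rate must be in (0,1), got {background_rate}")
    if block.span_bp < 1:
        raise ValueError("block span must be >= 1 bp")
    if background_rate > 0.01:
        warnings.warn(
            f"implausibly high background rate {background_rate}; "
            "binomial enrichment test may be meaningless"
        )
    k = len(block.variants)
    n = block.span_bp * n_patients
    p = float(stats.binom.sf(k - 1, n, background_rate)) if k > 0 else 1.0
    p_adj = min(1.0, p * n_candidate_blocks)
    block.p_value = p
    block.p_adjusted = p_adj
    return p, p_adj


def cohort_background_rate(variants, region_length_bp: int, n_patients: int) -> float:
    """Cohort-wide per-bp per-patient SNV rate over the analyzed regions."""
    if region_length_bp <= 0 or n_patients <= 0:
        raise ValueError("region length and patient count must be positive")
    return len(list(variants)) / (region_length_bp * n_patients)


def restrict_to_regions(items, regions: GenomicIntervals, flank: int = 0):
    """Keep variants whose position falls in a region, or blocks overlapping a
    region by >= 1 bp.  ``flank`` widens each region on both sides first."""
    if flank:
        regions = regions.flanked(flank)
    out = []
    for item in items:
        if isinstance(item, PatientVariant):
            if regions.contains_point(item.chrom, item.pos):
                out.append(item)
        else:
            if regions.overlaps(item.chrom, item.start, item.end):
                out.append(item)
    return out


def write_block_table(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "block_id\tchrom\tstart0\tend0\tn_snvs\tn_patients\tpatients\t"
            "p_value\tp_adjusted\n"
        )
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.chrom}\t{b.start}\t{b.end}\t{len(b.variants)}\t"
                f"{len(b.patients)}\t{','.join(sorted(b.patients))}\t"
                f"{'' if b.p_value is None else f'{b.p_value:.6g}'}\t"
                f"{'' if b.p_adjusted is None else f'{b.p_adjusted:.6g}'}\n"
            )
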