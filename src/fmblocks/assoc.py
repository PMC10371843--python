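"""Mutation block to gene association and chromatin-state enrichment.

Blocks are annotated to four gene-anchored region categories (gene body, TSS
window, TES window, distal 5'), filtered by requiring a DMR overlap or a
differentially expressed target gene, gated by shared TAD membership, and
finally selected by a permutation enrichment test of each gene's blocks
against the seven-state chromatin segmentation: a gene's associations are
kept when its blocks are enriched (expected p < alpha) in TSS or enhancer
states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .diffexpr import GeneRegions
from .io import GenomicIntervals
from .mussd import MutationBlock

CHROMATIN_STATES = ("TSS", "PF", "E", "WE", "CTCF", "R", "T")


@dataclass
class ChromatinStateSet:
    """Seven-state chromatin segmentation (TSS, PF, E, WE, CTCF, R, T)."""

    intervals: GenomicIntervals

    def __post_init__(self):
        labels = {label for _, _, _, label in self.intervals}
        bad = labels - set(CHROMATIN_STATES)
        if bad:
            raise ValueError(
                f"unknown chromatin state labels {sorted(bad)}; "
                f"expected {CHROMATIN_STATES}"
            )

    @classmethod
    def from_bed(cls, path) -> "ChromatinStateSet":
        return cls(intervals=GenomicIntervals.from_bed(path))

    def block_overlaps(self, block: MutationBlock, state: str) -> bool:
        return any(
            label == state
            for _, _, label in self.intervals.overlapping(
                block.chrom, block.start, block.end
            )
        )


@dataclass
class BlockGeneAssociation:
    """One (block, gene, region category) association with its filter flags."""

    block_id: str
    gene: str
    region_category: str  # gene_body | TSS | TES | distal5p
    tad_id: str | None = None
    overlaps_dmr: bool = False
    gene_is_deg: bool = False
    selected: bool = False


@dataclass
class EnrichmentResult:
    """Chromatin-state permutation enrichment for one gene's blocks."""

    gene: str
    actual_fraction: dict[str, float]
    expected_p: dict[str, float]
    n_perm: int
    seed: int


ASSOC_CATEGORIES = ("gene_body", "TSS", "TES", "distal5p")


def annotate_blocks_to_genes(
    blocks: list[MutationBlock],
    gene_regions: dict[str, GeneRegions],
) -> list[BlockGeneAssociation]:
    """One association per (block, gene, category) with >= 1 bp overlap.

    ``gene_regions`` must come from the four-category association scheme.
    """
    out: list[BlockGeneAssociation] = []
    for block in blocks:
        for gene, regions in gene_regions.items():
            if regions.chrom != block.chrom:
                continue
            for cat in ASSOC_CATEGORIES:
                window = regions.windows.get(cat)
                if window is None:
                    continue
                s, e = window
                if block.start < e and s < block.end:
                    out.append(
                        BlockGeneAssociation(
                            block_id=block.block_id, gene=gene, region_category=cat
                        )
                    )
    return out


def filter_associations(
    assocs: list[BlockGeneAssociation],
    blocks_by_id: dict[str, MutationBlock],
    gene_regions: dict[str, GeneRegions],
    dmrs: GenomicIntervals,
    degs: set[str],
    tads: GenomicIntervals,
) -> list[BlockGeneAssociation]:
    """Keep associations with (DMR overlap OR DEG gene) AND a shared TAD.

    The TAD gate requires the block midpoint and the gene TSS to fall inside
    the same TAD interval; the gene TSS is the transcription-direction start
    of the stored TSS/gene-body windows.
    """
    out: list[BlockGeneAssociation] = []
    for a in assocs:
        block = blocks_by_id[a.block_id]
        a.overlaps_dmr = dmrs.overlaps(block.chrom, block.start, block.end)
        a.gene_is_deg = a.gene in degs
        if not (a.overlaps_dmr or a.gene_is_deg):
            continue
        regions = gene_regions[a.gene]
        tss = _gene_tss(regions)
        block_tads = tads.at(block.chrom, block.midpoint)
        tss_tads = tads.at(regions.chrom, tss)
        if not block_tads or not tss_tads:
            continue
        shared = {t[:2] for t in block_tads} & {t[:2] for t in tss_tads}
        if not shared:
            continue
        s, e = sorted(shared)[0]
        first = next(
            (t for t in block_tads if t[:2] == (s, e)), None
        )
        a.tad_id = (
            str(first[2]) if first and first[2] is not None else f"{block.chrom}:{s}-{e}"
        )
        out.append(a)
    return out


def _gene_tss(regions: GeneRegions) -> int:
    lo, hi = regions.windows.get("gene_body", next(iter(regions.windows.values())))
    return hi - 1 if regions.strand == "-" else lo


def chromatin_enrichment_test(
    gene_blocks: list[MutationBlock],
    all_blocks: list[MutationBlock],
    states: ChromatinStateSet,
    n_perm: int = 10000,
    seed: int = 0,
    gene: str = "",
    exhaustive: bool = False,
) -> EnrichmentResult:
    """Permutation enrichment of a gene's M blocks in each chromatin state.

    actual[s] = fraction of the gene's blocks overlapping state s.  Each
    permutation draws M blocks without replacement from the pool (all blocks
    minus the gene's); the expected p is the fraction of draws whose state
    fraction is strictly greater than the actual one (ties do not count), so
    it may legitimately be 0.  ``exhaustive`` enumerates every possible draw
    instead of sampling.
    """
    M = len(gene_blocks)
    if M == 0:
        raise ValueError("gene has no blocks to test")
    gene_ids = {b.block_id for b in gene_blocks}
    pool = [b for b in all_blocks if b.block_id not in gene_ids]
    if len(pool) < M:
        raise ValueError(
            f"insufficient pool: {len(pool)} blocks left after excluding the "
            f"gene's {M}"
        )
    def block_labels(b: MutationBlock) -> set:
        return {
            label
            for _, _, label in states.intervals.overlapping(b.chrom, b.start, b.end)
        }

    pool_labels = [block_labels(b) for b in pool]
    gene_labels = [block_labels(b) for b in gene_blocks]
    flags = {
        s: np.array([s in ls for ls in pool_labels], dtype=float)
        for s in CHROMATIN_STATES
    }
    actual = {
        s: float(np.mean([s in ls for ls in gene_labels])) for s in CHROMATIN_STATES
    }
    if exhaustive:
        combos = list(itertools.combinations(range(len(pool)), M))
        idx = np.array(combos)
        n_draws = len(combos)
    else:
        rng = np.random.default_rng(seed)
        # uniform draws without replacement, vectorized over permutations
        keys = rng.random((n_perm, len(pool)))
        idx = np.argpartition(keys, M - 1, axis=1)[:, :M]
        n_draws = n_perm
    expected_p = {}
    for s in CHROMATIN_STATES:
        fracs = flags[s][idx].mean(axis=1)
        expected_p[s] = float((fracs > actual[s]).sum() / n_draws)
    return EnrichmentResult(
        gene=gene,
        actual_fraction=actual,
        expected_p=expected_p,
        n_perm=n_draws,
        seed=seed,
    )


def select_functional_associations(
    assocs: list[BlockGeneAssociation],
    enrichments: dict[str, EnrichmentResult],
    alpha: float = 0.05,
    states_of_interest: tuple[str, ...] = ("TSS", "E"),
    require_presence: bool = True,
) -> list[BlockGeneAssociation]:
    """Keep every association of a gene enriched (expected p < alpha) in any
    state of interest (TSS or enhancer by default).

    With ``require_presence`` (default) a state only counts when at least one
    of the gene's blocks actually overlaps it; this guards against the
    degenerate expected_p = 0 that the exceedance formula produces when a
    state is absent from both the gene's blocks and the sampling pool.
    """
    def state_hit(enr: EnrichmentResult, s: str) -> bool:
        if enr.expected_p.get(s, 1.0) >= alpha:
            return False
        return not require_presence or enr.actual_fraction.get(s, 0.0) > 0

    selected_genes = {
        gene
        for gene, enr in enrichments.items()
        if any(state_hit(enr, s) for s in states_of_interest)
    }
    out = []
    for a in assocs:
        if a.gene in selected_genes:
            a.selected = True
            out.append(a)
    return out


def write_association_table(
    assocs: list[BlockGeneAssociation],
    enrichments: dict[str, EnrichmentResult],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "block_id\tgene\tcategory\ttad_id\toverlaps_dmr\tgene_is_deg\t"
            "expected_p_TSS\texpected_p_E\tselected\n"
        )
        for a in assocs:
            enr = enrichments.get(a.gene)
            p_tss = "" if enr is None else f"{enr.expected_p['TSS']:.6g}"
            p_e = "" if enr is None else f"{enr.expected_p['E']:.6g}"
            fh.write(
                f"{a.block_id}\t{a.gene}\t{a.region_category}\t{a.tad_id or ''}\t"
                f"{int(a.overlaps_dmr)}\t{int(a.gene_is_deg)}\t{p_tss}\t{p_e}\t"
                f"{int(a.selected)}\n"
            )
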