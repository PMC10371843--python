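"""End-to-end orchestration of the mutation-block analysis.

Stages: differential expression -> scan-region derivation -> mutation
cluster/block detection -> binomial block significance -> PWM set selection
(all PWMs, clustered pseudo-TFs, or the two-level scheme) -> mutation
signature and background blocks -> per-TF delta_dbA rank-sum tests ->
per-patient heatmaps -> optional block-gene association with chromatin-state
enrichment.  Fully deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import affinity, assoc, clustering, diffexpr, mussd
from . import io as fio
from .pwm import ChemicalPotentialGrid, ShuffleSpec, pwm_to_energy, read_pwms

logger = logging.getLogger(__name__)

MODES = ("PWMs_full", "C1_full", "C1fC2_N")


def derive_seed(master: int, *salts: int) -> int:
    """A reproducible child seed below 2**31 for one work item."""
    h = np.uint64(master % (2**31))
    for s in salts:
        h = (h * np.uint64(1000003) + np.uint64(s + 1)) % np.uint64(2**31 - 1)
    return int(h)


@dataclass
class RunConfig:
    """All paths and stage parameters of one orchestrated run.

    Defaults mirror the cohort analysis settings: cluster gap < 30 bp, block
    gap < 500 bp, 3 SNVs / 3 patients per block, block Bonferroni 0.001, TF
    Bonferroni 0.05, DEG alpha 0.05, chemical potentials -8..-20, RPKM
    filter 0.03.
    """

    # paths
    genome: str = ""
    vcfs: list[str] = field(default_factory=list)
    expression: str = ""
    groups: str = ""
    annotation: str = ""
    pwms: str = ""
    tf_expression: str | None = None
    dmr: str | None = None
    tad: str | None = None
    states: str | None = None
    predefined_regions: str | None = None
    outdir: str = "fmblocks_out"
    # mode
    mode: str = "PWMs_full"
    top_n_clusters: int = 5
    # stage parameters
    seed: int = 0
    deg_method: str = "t"
    deg_alpha: float = 0.05
    scan_scope: str = "deg_promoters"  # deg_promoters | predefined | genome
    promoter_scheme: str = "promoter1k"
    region_flank: int = 0
    max_adjacent_gap: int = 30
    max_block_gap: int = 500
    min_cluster_snvs: int = 2
    min_cluster_patients: int = 2
    min_block_snvs: int = 3
    min_block_patients: int = 3
    block_alpha: float = 0.001
    mu_grid: list[float] | None = None
    kmer: int = 3
    n_background_blocks: int = 1000
    shuffle_count: int = 10
    mu_aggregate: str = "max"
    sample_mode: str = "aggregate"
    tf_alpha: float = 0.05
    min_fg: int = 3
    rpkm_threshold: float = 0.03
    heatmap_p_cutoff: float = 0.01
    n_perm: int = 10000
    enrichment_alpha: float = 0.05
    top_n_score: int = 20
    cluster_preference: float | None = None
    associate: bool = True

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "C1fC2_N" and self.top_n_clusters < 1:
            raise ValueError("C1fC2_N requires top_n_clusters >= 1")
        if self.scan_scope not in ("deg_promoters", "predefined", "genome"):
            raise ValueError(f"unknown scan_scope {self.scan_scope!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("genome", "expression", "groups", "annotation", "pwms"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} missing: {p}")
        for v in self.vcfs:
            if not Path(v).exists():
                raise FileNotFoundError(f"VCF missing: {v}")


@dataclass
class RunSummary:
    """Per-stage counts of one pipeline run."""

    n_variants: int = 0
    n_degs: int = 0
    n_clusters: int = 0
    n_blocks: int = 0
    n_significant_blocks: int = 0
    n_pwm_clusters: int = 0
    n_tfs_tested: int = 0
    n_significant_tfs: int = 0
    n_associations: int = 0
    n_filtered_associations: int = 0
    n_selected_associations: int = 0
    n_selected_genes: int = 0
    seed: int = 0
    mode: str = ""


@dataclass
class PipelineResult:
    summary: RunSummary
    blocks: list = field(default_factory=list)
    significant_blocks: list = field(default_factory=list)
    degs: set = field(default_factory=set)
    tf_tests: dict = field(default_factory=dict)       # block_id -> [TfBlockTest]
    significant_tfs: dict = field(default_factory=dict)  # block_id -> set of TF names
    heatmaps: dict = field(default_factory=dict)
    clusters: list = field(default_factory=list)
    associations: list = field(default_factory=list)
    selected: list = field(default_factory=list)
    enrichments: dict = field(default_factory=dict)


def _scan_regions(config, annotation, deg_set, chrom_lengths):
    if config.scan_scope == "predefined":
        if not config.predefined_regions:
            raise ValueError("scan_scope 'predefined' needs predefined_regions")
        regions = fio.GenomicIntervals.from_bed(config.predefined_regions)
        if config.region_flank:
            regions = regions.flanked(config.region_flank)
        return regions
    if config.scan_scope == "genome":
        return fio.GenomicIntervals.from_tuples(
            (c, 0, n) for c, n in chrom_lengths.items()
        )
    gene_regions = diffexpr.derive_regions(
        annotation, config.promoter_scheme, chrom_lengths
    )
    return fio.GenomicIntervals.from_tuples(
        (gene_regions[g].chrom, *gene_regions[g].windows["promoter"])
        for g in deg_set
        if g in gene_regions and "promoter" in gene_regions[g].windows
    )


def _region_length(regions) -> int:
    return sum(e - s for _, s, e, _ in regions)


def _test_blocks_on_pwms(
    config, blocks, variants, genome, models, grid, signature, bg_regions
):
    """Foreground/background delta_dbA tests for every block against a PWM set."""
    import zlib

    shuffles = ShuffleSpec(count=config.shuffle_count, seed=derive_seed(config.seed, 7))
    tests, samples_by_block = {}, {}
    for block in blocks:
        bi = zlib.crc32(block.block_id.encode()) % 100000
        carriers: dict[str, list] = {}
        for v in block.variants:
            carriers.setdefault(v.patient_id, []).append(v)
        n_mut = max(1, round(np.mean([len(vs) for vs in carriers.values()])))
        bg_blocks = affinity.generate_background_blocks(
            bg_regions,
            block.span_bp,
            config.n_background_blocks,
            n_mut,
            signature,
            genome,
            seed=derive_seed(config.seed, 11, bi),
        )
        samples = affinity.compute_delta_dba_samples(
            block, carriers, genome, models, grid, bg_blocks,
            shuffles=shuffles, mu_aggregate=config.mu_aggregate,
        )
        tests[block.block_id] = affinity.test_tf_block_significance(
            samples,
            alpha=config.tf_alpha,
            sample_mode=config.sample_mode,
            min_n=config.min_fg,
        )
        samples_by_block[block.block_id] = samples
    return tests, samples_by_block


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full analysis described by ``config``."""
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    genome = fio.read_genome(config.genome)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    annotation = fio.read_annotation(config.annotation)
    pwms = read_pwms(config.pwms)
    matrix, groups = fio.read_expression(config.expression, config.groups)
    tf_expression = None
    if config.tf_expression:
        tf_expression = {}
        with open(config.tf_expression) as fh:
            for line in fh:
                tf, rpkm = line.rstrip("\n").split("\t")
                tf_expression[tf] = float(rpkm)

    summary = RunSummary(seed=config.seed, mode=config.mode)
    result = PipelineResult(summary=summary)

    # --- stage 1: differential expression --------------------------------
    degs = diffexpr.call_degs(
        matrix, groups, method=config.deg_method, alpha=config.deg_alpha
    )
    deg_set = set(degs.index[degs["is_deg"]])
    result.degs = deg_set
    summary.n_degs = len(deg_set)
    if write_outputs:
        diffexpr.write_deg_table(degs, outdir / "degs.tsv")

    # --- stage 2: scan regions and variants ------------------------------
    regions = _scan_regions(config, annotation, deg_set, chrom_lengths)
    variants, vstats = mussd.load_patient_variants(config.vcfs, genome=genome)
    summary.n_variants = vstats.n_kept
    n_patients = len(config.vcfs) or len({v.patient_id for v in variants})
    scan_variants = (
        variants
        if config.scan_scope == "genome"
        else mussd.restrict_to_regions(variants, regions)
    )

    # --- stage 3: MuSSD ---------------------------------------------------
    clusters = mussd.find_mutation_clusters(
        scan_variants,
        max_adjacent_gap=config.max_adjacent_gap,
        min_snvs=config.min_cluster_snvs,
        min_patients=config.min_cluster_patients,
    )
    blocks = mussd.merge_clusters_into_blocks(
        clusters,
        max_block_gap=config.max_block_gap,
        min_block_snvs=config.min_block_snvs,
        min_block_patients=config.min_block_patients,
    )
    summary.n_clusters = len(clusters)
    summary.n_blocks = len(blocks)
    result.blocks = blocks

    region_length = _region_length(regions) or sum(chrom_lengths.values())
    if scan_variants and blocks:
        rate = mussd.cohort_background_rate(scan_variants, region_length, n_patients)
        for b in blocks:
            mussd.test_block_significance(
                b, n_patients, rate, n_candidate_blocks=len(blocks)
            )
    significant = [
        b for b in blocks if b.p_adjusted is not None and b.p_adjusted < config.block_alpha
    ]
    summary.n_significant_blocks = len(significant)
    result.significant_blocks = significant
    if write_outputs:
        mussd.write_block_table(blocks, outdir / "blocks.tsv")

    if not significant:
        if write_outputs:
            _write_summary(summary, outdir)
        return result

    # --- stage 4: PWM set per mode ----------------------------------------
    grid = ChemicalPotentialGrid(
        values=np.array(config.mu_grid, dtype=float)
        if config.mu_grid
        else ChemicalPotentialGrid().values
    )
    signature = affinity.derive_mutation_signature(variants, genome, k=config.kmer)
    bg_regions = regions
    all_models = [pwm_to_energy(p) for p in pwms]
    by_name = {p.name: p for p in pwms}

    pwm_clusters: list = []
    if config.mode in ("C1_full", "C1fC2_N"):
        pwm_clusters = clustering.cluster_library(
            pwms,
            params=clustering.ClusterParams(
                preference=config.cluster_preference,
                seed=derive_seed(config.seed, 3),
            ),
        )
        summary.n_pwm_clusters = len(pwm_clusters)
        result.clusters = pwm_clusters
        c1_models = [pwm_to_energy(c.representative) for c in pwm_clusters]
        tests, samples_by_block = _test_blocks_on_pwms(
            config, significant, variants, genome, c1_models, grid, signature, bg_regions
        )
        if config.mode == "C1fC2_N":
            # expand the top-N pseudo-TFs per block and re-test on members
            level2_tests = {}
            samples2 = {}
            for block in significant:
                ranking = [
                    t.tf for t in affinity.rank_tf_tests(tests[block.block_id])
                ]
                members = clustering.select_top_clusters(
                    ranking, config.top_n_clusters, pwm_clusters
                )
                member_models = [pwm_to_energy(by_name[m]) for m in sorted(members)]
                t2, s2 = _test_blocks_on_pwms(
                    config, [block], variants, genome, member_models, grid,
                    signature, bg_regions,
                )
                level2_tests.update(t2)
                samples2.update(s2)
            tests, samples_by_block = level2_tests, samples2
    else:
        tests, samples_by_block = _test_blocks_on_pwms(
            config, significant, variants, genome, all_models, grid, signature, bg_regions
        )

    result.tf_tests = tests
    cluster_members = {
        c.representative.name: set(c.members)
        for c in pwm_clusters
        if c.representative is not None
    }
    n_sig_tfs = 0
    for block_id, block_tests in tests.items():
        sig = set()
        for t in block_tests:
            if t.p_adjusted < config.tf_alpha:
                sig.add(t.tf)
        # pseudo-TF hits stand for all of their member PWMs
        expanded = set()
        for tf in sig:
            expanded |= cluster_members.get(tf, {tf})
        result.significant_tfs[block_id] = expanded
        n_sig_tfs += len(sig)
    summary.n_tfs_tested = sum(len(ts) for ts in tests.values())
    summary.n_significant_tfs = n_sig_tfs
    if write_outputs:
        affinity.write_tf_test_table(
            [t for ts in tests.values() for t in ts], outdir / "tf_tests.tsv"
        )

    # --- stage 5: heatmaps -------------------------------------------------
    for block_id, samples in samples_by_block.items():
        p_values = {t.tf: t.p_value for t in tests[block_id]}
        hm = affinity.build_patient_heatmap(
            samples,
            tf_expression=tf_expression,
            rpkm_threshold=config.rpkm_threshold,
            tf_p_values=p_values,
            p_cutoff=config.heatmap_p_cutoff,
        )
        result.heatmaps[block_id] = hm
        if write_outputs:
            affinity.write_heatmap(hm, outdir / f"heatmap_{block_id}.tsv")

    # --- stage 6: block-gene association -----------------------------------
    if config.associate and config.tad and config.states:
        gene_regions = diffexpr.derive_regions(annotation, "assoc4", chrom_lengths)
        assocs = assoc.annotate_blocks_to_genes(significant, gene_regions)
        summary.n_associations = len(assocs)
        blocks_by_id = {b.block_id: b for b in significant}
        dmrs = (
            fio.GenomicIntervals.from_bed(config.dmr)
            if config.dmr
            else fio.GenomicIntervals()
        )
        tads = fio.GenomicIntervals.from_bed(config.tad)
        states = assoc.ChromatinStateSet.from_bed(config.states)
        filtered = assoc.filter_associations(
            assocs, blocks_by_id, gene_regions, dmrs, deg_set, tads
        )
        summary.n_filtered_associations = len(filtered)
        gene_blocks: dict[str, list] = {}
        for a in filtered:
            gene_blocks.setdefault(a.gene, [])
            if blocks_by_id[a.block_id] not in gene_blocks[a.gene]:
                gene_blocks[a.gene].append(blocks_by_id[a.block_id])
        enrichments = {}
        for gi, (gene, gblocks) in enumerate(sorted(gene_blocks.items())):
            try:
                enrichments[gene] = assoc.chromatin_enrichment_test(
                    gblocks, significant, states,
                    n_perm=config.n_perm,
                    seed=derive_seed(config.seed, 13, gi),
                    gene=gene,
                )
            except ValueError as exc:
                logger.warning("enrichment skipped for %s: %s", gene, exc)
        selected = assoc.select_functional_associations(
            filtered, enrichments, alpha=config.enrichment_alpha
        )
        result.associations = filtered
        result.selected = selected
        result.enrichments = enrichments
        summary.n_selected_associations = len(selected)
        summary.n_selected_genes = len({a.gene for a in selected})
        if write_outputs:
            assoc.write_association_table(
                filtered, enrichments, outdir / "associations.tsv"
            )

    if write_outputs:
        _write_summary(summary, outdir)
    return result


def _write_summary(summary: RunSummary, outdir: Path) -> None:
    import json

    with open(outdir / "summary.json", "w") as fh:
        json.dump(asdict(summary), fh, indent=1, sort_keys=True)
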