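"""Deterministic synthetic cohort generator with planted ground truth.

A scenario bundles a random genome, a spaced gene annotation, an informative
PWM library, per-patient somatic SNVs, a tumor/normal expression matrix and
DMR/TAD/chromatin-state tracks.  Ground truth is planted so every pipeline
stage has a known answer:

* ``n_planted_blocks`` target genes carry a promoter mutation block — three
  consensus occurrences of one planted TF motif whose maximum-information
  base is mutated to the minimum-probability base (the strongest possible
  binding-loss signal) by each of ``patients_per_block`` patients, arranged
  so the SNVs satisfy the cluster (<30 bp) and block (<500 bp) chaining
  rules with 9 SNVs from 3 patients;
* target genes are differentially expressed (mean shift in tumor samples)
  and their planted blocks sit inside a DMR, a TSS chromatin state and the
  same TAD as the gene's TSS;
* ``n_decoy_blocks`` clustered-but-nonfunctional blocks are planted in
  intergenic repressed (R-state) chromatin with random alternate alleles;
* background SNVs are scattered uniformly per patient with uniform alternate
  bases, so the derived mutation signature is approximately flat.

Everything is reproducible from the config seed, and the written files
(FASTA, VCF, TSV, BED, JSON) round-trip through the package's own readers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .assoc import ChromatinStateSet
from .io import GenomicIntervals
from .mussd import PatientVariant
from .pwm import BASES, PositionWeightMatrix, read_pwms, write_pwms

_SITE_OFFSETS = (0, 22, 170)  # motif start offsets within a planted block


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int
    n_patients: int = 14
    n_normals: int = 8
    genome_length: int = 200_000
    chrom: str = "chr1"
    n_genes: int = 24
    gene_length: int = 2000
    n_pwms: int = 8
    motif_length: int = 9
    motif_dominance: float = 0.85
    n_planted_blocks: int = 3
    n_decoy_blocks: int = 4
    patients_per_block: int = 3
    background_rate: float = 2e-6  # per bp per patient
    effect_size: float = 2.0       # tumor mean shift for planted DEGs
    expression_sd: float = 1.0

    def __post_init__(self):
        for name in (
            "n_patients", "n_normals", "genome_length", "n_genes",
            "gene_length", "n_pwms", "motif_length", "patients_per_block",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_blocks < 0 or self.n_decoy_blocks < 0:
            raise ValueError("block counts must be non-negative")
        if not (0 <= self.background_rate < 1):
            raise ValueError("background_rate must be in [0, 1)")
        spacing = self.genome_length // (self.n_genes + 1)
        if spacing < 2 * self.gene_length + 2500:
            raise ValueError(
                "genome too small for the requested gene count: increase "
                "genome_length or reduce n_genes"
            )


@dataclass
class ScenarioBundle:
    """A complete synthetic cohort plus its planted-truth manifest."""

    config: ScenarioConfig
    genome: dict[str, str]
    annotation: pd.DataFrame
    pwms: list[PositionWeightMatrix]
    variants: list[PatientVariant]
    patient_ids: list[str]
    expression: pd.DataFrame
    groups: pd.Series
    tf_expression: dict[str, float]
    dmrs: GenomicIntervals
    tads: GenomicIntervals
    states: ChromatinStateSet
    truth: dict = field(default_factory=dict)


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Build a fully reproducible synthetic cohort from the config seed."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom
    L = config.genome_length
    codes = _random_genome(rng, L)

    # --- genes: evenly spaced TSSs, alternating strands -------------------
    spacing = L // (config.n_genes + 1)
    genes = []
    for i in range(config.n_genes):
        gene = f"gene_{i:03d}"
        tss = spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start, end = tss, tss + config.gene_length
        else:
            start, end = tss - config.gene_length + 1, tss + 1
        genes.append((chrom, start, end, gene, 0, strand))
    annotation = pd.DataFrame(
        genes, columns=["chrom", "start", "end", "gene", "score", "strand"]
    )
    plus = annotation["strand"] == "+"
    annotation["tss"] = annotation["end"] - 1
    annotation.loc[plus, "tss"] = annotation.loc[plus, "start"]
    annotation["tes"] = annotation["start"]
    annotation.loc[plus, "tes"] = annotation.loc[plus, "end"] - 1
    annotation = annotation.set_index("gene", drop=False)

    # --- PWM library: informative random motifs ---------------------------
    pwms = []
    for j in range(config.n_pwms):
        cons = rng.integers(0, 4, size=config.motif_length)
        probs = np.full((config.motif_length, 4), (1 - config.motif_dominance) / 3)
        probs[np.arange(config.motif_length), cons] = config.motif_dominance
        # vary one flank column so max-information columns differ from flanks
        probs[0] = 0.25 + (probs[0] - 0.25) * 0.4
        pwms.append(PositionWeightMatrix(name=f"TF_{j:02d}", probs=probs,
                                         dbd_family=f"family_{j % 3}"))

    patient_ids = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    normal_ids = [f"N{i + 1:02d}" for i in range(config.n_normals)]
    variants: list[PatientVariant] = []
    truth_blocks = []
    dmr_tuples = []
    state_tuples = []

    # --- planted functional blocks in target-gene promoters ---------------
    target_genes = [f"gene_{(i * config.n_genes // max(config.n_planted_blocks, 1)):03d}"
                    for i in range(config.n_planted_blocks)]
    for b, gene in enumerate(target_genes):
        tss = int(annotation.loc[gene, "tss"])
        tf = pwms[b % config.n_pwms]
        cons_codes = np.array([BASES.index(c) for c in tf.consensus])
        # strongest-signal disruption column: maximum information content
        info = (2 + (tf.probs * np.log2(tf.probs)).sum(axis=1))
        j_star = int(np.argmax(info))
        alt_code = int(np.argmin(tf.probs[j_star]))
        block_anchor = tss - 320
        positions = []
        carriers = [patient_ids[(b * config.patients_per_block + i) % config.n_patients]
                    for i in range(config.patients_per_block)]
        for off in _SITE_OFFSETS:
            site = block_anchor + off
            codes[site : site + config.motif_length] = cons_codes
            positions.append(site + j_star)
        for p in carriers:
            for pos in positions:
                variants.append(
                    PatientVariant(p, chrom, pos, BASES[cons_codes[j_star]],
                                   BASES[alt_code])
                )
        span = (positions[0], positions[-1] + 1)
        truth_blocks.append(
            {
                "block_id": f"block_{b + 1}_{chrom}_{span[0] + 1}_{span[1]}",
                "chrom": chrom,
                "start": span[0],
                "end": span[1],
                "gene": gene,
                "tf": tf.name,
                "patients": carriers,
                "positions": positions,
            }
        )
        dmr_tuples.append((chrom, span[0] - 50, span[1] + 50, f"dmr_{b}"))
        state_tuples.append((chrom, tss - 1000, tss + 1001, "TSS"))
        state_tuples.append((chrom, tss + 1200, tss + 2200, "E"))

    # --- decoy blocks: clustered but non-functional, repressed chromatin --
    decoy_blocks = []
    decoy_anchors_used = 0
    gi = 0
    target_set = set(target_genes)
    while decoy_anchors_used < config.n_decoy_blocks and gi < config.n_genes - 1:
        gene = f"gene_{gi:03d}"
        # the decoy block sits at the TAD boundary downstream of gene gi and
        # falls into gene gi+1's TAD; neither may be a planted target gene
        if gene in target_set or f"gene_{gi + 1:03d}" in target_set:
            gi += 1
            continue
        tss = int(annotation.loc[gene, "tss"])
        anchor = tss + spacing // 2  # intergenic midpoint, outside promoters
        carriers = [patient_ids[(decoy_anchors_used + i + 5) % config.n_patients]
                    for i in range(config.patients_per_block)]
        positions = [anchor + off for off in _SITE_OFFSETS]
        for p in carriers:
            for pos in positions:
                ref = BASES[codes[pos]]
                alt = BASES[(codes[pos] + int(rng.integers(1, 4))) % 4]
                variants.append(PatientVariant(p, chrom, pos, ref, alt))
        decoy_blocks.append(
            {"chrom": chrom, "start": positions[0], "end": positions[-1] + 1}
        )
        state_tuples.append((chrom, positions[0] - 50, positions[-1] + 51, "R"))
        decoy_anchors_used += 1
        gi += 2

    # --- background SNVs: uniform positions, uniform alternates -----------
    if config.background_rate > 0:
        for p in patient_ids:
            n_bg = rng.binomial(L, config.background_rate)
            for pos in sorted(int(x) for x in rng.integers(0, L, size=n_bg)):
                ref = BASES[codes[pos]]
                alt = BASES[(codes[pos] + int(rng.integers(1, 4))) % 4]
                variants.append(PatientVariant(p, chrom, pos, ref, alt))

    genome = {chrom: "".join(BASES[c] for c in codes)}
    # planted variants must match the final genome
    variants = [
        v if genome[v.chrom][v.pos] == v.ref_base
        else PatientVariant(v.patient_id, v.chrom, v.pos,
                            genome[v.chrom][v.pos], v.alt_base)
        for v in variants
    ]
    variants = [v for v in variants if v.ref_base != v.alt_base]

    # --- expression: planted DEGs shifted in tumors ------------------------
    deg_genes = list(target_genes)
    base = rng.uniform(3, 8, size=config.n_genes)
    tumor = rng.normal(
        base[:, None], config.expression_sd, size=(config.n_genes, config.n_patients)
    )
    normal = rng.normal(
        base[:, None], config.expression_sd, size=(config.n_genes, config.n_normals)
    )
    for gene in deg_genes:
        i = annotation.index.get_loc(gene)
        tumor[i] += config.effect_size
    values = np.clip(np.concatenate([tumor, normal], axis=1), 0.01, None)
    expression = pd.DataFrame(
        values, index=annotation.index, columns=patient_ids + normal_ids
    )
    groups = pd.Series(
        ["tumor"] * config.n_patients + ["normal"] * config.n_normals,
        index=patient_ids + normal_ids,
        name="group",
    )
    tf_expression = {p.name: 1.0 for p in pwms}

    # --- tracks -------------------------------------------------------------
    tads = GenomicIntervals.from_tuples(
        (chrom, max(0, int(annotation.loc[g, "tss"]) - spacing // 2),
         min(L, int(annotation.loc[g, "tss"]) + spacing // 2), f"tad_{i}")
        for i, g in enumerate(annotation.index)
    )
    # ensure all seven states occur at least once
    state_tuples.append((chrom, 5, 55, "PF"))
    state_tuples.append((chrom, 60, 110, "WE"))
    state_tuples.append((chrom, 115, 165, "CTCF"))
    state_tuples.append((chrom, 170, 400, "T"))
    if not any(s[3] == "R" for s in state_tuples):
        state_tuples.append((chrom, 405, 450, "R"))
    if not any(s[3] == "TSS" for s in state_tuples):
        state_tuples.append((chrom, 455, 500, "TSS"))
    if not any(s[3] == "E" for s in state_tuples):
        state_tuples.append((chrom, 505, 550, "E"))
    states = ChromatinStateSet(
        intervals=GenomicIntervals.from_tuples(sorted(state_tuples))
    )
    dmrs = GenomicIntervals.from_tuples(sorted(dmr_tuples))

    truth = {
        "planted_blocks": truth_blocks,
        "decoy_blocks": decoy_blocks,
        "planted_degs": deg_genes,
        "fmb_gene_pairs": [
            {"block_id": tb["block_id"], "chrom": tb["chrom"],
             "start": tb["start"], "end": tb["end"], "gene": tb["gene"]}
            for tb in truth_blocks
        ],
    }
    return ScenarioBundle(
        config=config,
        genome=genome,
        annotation=annotation,
        pwms=pwms,
        variants=sorted(variants, key=lambda v: (v.patient_id, v.chrom, v.pos)),
        patient_ids=patient_ids,
        expression=expression,
        groups=groups,
        tf_expression=tf_expression,
        dmrs=dmrs,
        tads=tads,
        states=states,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "{contigs}"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_scenario(bundle: ScenarioBundle, directory) -> dict[str, str]:
    """Write every component as plain-text files; returns the file manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    fio.write_genome(bundle.genome, d / "genome.fa")
    manifest["genome"] = "genome.fa"

    vcf_dir = d / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    contigs = "".join(
        f"##contig=<ID={c},length={len(s)}>\n" for c, s in bundle.genome.items()
    )
    by_patient: dict[str, list[PatientVariant]] = {p: [] for p in bundle.patient_ids}
    for v in bundle.variants:
        by_patient.setdefault(v.patient_id, []).append(v)
    vcf_files = []
    for patient in bundle.patient_ids:
        path = vcf_dir / f"{patient}.vcf"
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER.format(contigs=contigs))
            for v in sorted(by_patient[patient], key=lambda v: (v.chrom, v.pos)):
                fh.write(
                    f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_base}\t{v.alt_base}\t"
                    f".\tPASS\t.\n"
                )
        vcf_files.append(str(path.relative_to(d)))
    manifest["vcfs"] = ",".join(vcf_files)

    bundle.annotation[["chrom", "start", "end", "gene", "score", "strand"]].to_csv(
        d / "annotation.tsv", sep="\t", header=False, index=False
    )
    manifest["annotation"] = "annotation.tsv"

    bundle.expression.to_csv(d / "expression.tsv", sep="\t", index_label="gene")
    bundle.groups.to_csv(d / "groups.tsv", sep="\t", header=False)
    manifest["expression"] = "expression.tsv"
    manifest["groups"] = "groups.tsv"

    write_pwms(bundle.pwms, d / "pwms.txt")
    manifest["pwms"] = "pwms.txt"
    with open(d / "tf_expression.tsv", "w") as fh:
        for tf, rpkm in sorted(bundle.tf_expression.items()):
            fh.write(f"{tf}\t{rpkm}\n")
    manifest["tf_expression"] = "tf_expression.tsv"

    bundle.dmrs.to_bed(d / "dmr.bed")
    bundle.tads.to_bed(d / "tad.bed")
    bundle.states.intervals.to_bed(d / "states.bed")
    manifest.update(dmr="dmr.bed", tad="tad.bed", states="states.bed")

    with open(d / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    with open(d / "config.json", "w") as fh:
        json.dump(asdict(bundle.config), fh, indent=1, sort_keys=True)
    manifest["truth"] = "truth.json"
    manifest["config"] = "config.json"
    return manifest


def read_scenario(directory) -> ScenarioBundle:
    """Read a written scenario back with the package's own readers."""
    from .mussd import load_patient_variants

    d = Path(directory)
    with open(d / "config.json") as fh:
        config = ScenarioConfig(**json.load(fh))
    genome = fio.read_genome(d / "genome.fa")
    annotation = fio.read_annotation(d / "annotation.tsv")
    pwms = read_pwms(d / "pwms.txt")
    vcfs = sorted((d / "vcf").glob("*.vcf"))
    variants, _ = load_patient_variants(vcfs, genome=genome)
    expression, groups = fio.read_expression(d / "expression.tsv", d / "groups.tsv")
    tf_expression = {}
    with open(d / "tf_expression.tsv") as fh:
        for line in fh:
            tf, rpkm = line.rstrip("\n").split("\t")
            tf_expression[tf] = float(rpkm)
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    return ScenarioBundle(
        config=config,
        genome=genome,
        annotation=annotation,
        pwms=pwms,
        variants=sorted(variants, key=lambda v: (v.patient_id, v.chrom, v.pos)),
        patient_ids=[p.name.split(".")[0] for p in vcfs],
        expression=expression,
        groups=groups,
        tf_expression=tf_expression,
        dmrs=GenomicIntervals.from_bed(d / "dmr.bed"),
        tads=GenomicIntervals.from_bed(d / "tad.bed"),
        states=ChromatinStateSet.from_bed(d / "states.bed"),
        truth=truth,
    )
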