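"""Foreground/background TF binding-affinity change testing.

For each detected mutation block, every patient's SNVs are applied jointly to
the reference block sequence and per-TF delta_dbA values are computed over a
chemical-potential grid (the foreground).  Background blocks of the same
length are drawn from the scanned regions and mutated under the cohort's
k-mer mutation signature; their delta_dbA values form the per-TF background.
A two-sided Wilcoxon rank-sum (Mann-Whitney) test per TF, Bonferroni-
corrected over the TFs tested, flags TFs whose binding is significantly
gained or lost in the patients relative to signature-matched randomness.

The module also provides the per-patient heatmap matrices (signed empirical
log-probabilities), the per-SNV mutation score used to separate functional
from random regulatory variants, and the ROC/rank-accuracy evaluation
harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicIntervals
from .mussd import MutationBlock, PatientVariant
from .pwm import (
    ChemicalPotentialGrid,
    EnergyModel,
    ShuffleSpec,
    delta_dba_pairs_batch,
    encode_sequence,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# mutation signature
# ---------------------------------------------------------------------------

@dataclass
class MutationSignature:
    """k-mer context -> alternate-base mutation probabilities.

    ``table`` maps (context, alt) to a probability; for each populated
    context the alt probabilities sum to 1.  Contexts never observed fall
    back to a uniform draw over the three non-reference bases.
    """

    k: int = 3
    table: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.k % 2 != 1:
            raise ValueError("context size k must be odd")

    def contexts(self) -> set[str]:
        return {ctx for ctx, _ in self.table}

    def sample_alt(self, context: str, rng: np.random.Generator) -> str:
        center = context[self.k // 2]
        alts = [b for b in _BASES if b != center]
        probs = [self.table.get((context, a), 0.0) for a in alts]
        total = sum(probs)
        if total <= 0:
            return alts[rng.integers(len(alts))]
        return rng.choice(alts, p=np.array(probs) / total)


def derive_mutation_signature(
    variants: list[PatientVariant],
    genome: dict[str, str],
    k: int = 3,
    collapse_reverse_complement: bool = False,
) -> MutationSignature:
    """Tally cohort SNVs into a (context -> alt) probability table.

    Contexts containing N are skipped (and counted in the log).  By default
    strand collapsing is off: a context and its reverse complement are kept
    as distinct entries.
    """
    from .pwm import reverse_complement

    if k % 2 != 1:
        raise ValueError("context size k must be odd")
    flank = k // 2
    counts: dict[tuple[str, str], int] = {}
    n_skipped = 0
    for v in variants:
        seq = genome[v.chrom]
        if v.pos < flank or v.pos + flank >= len(seq):
            n_skipped += 1
            continue
        ctx = seq[v.pos - flank : v.pos + flank + 1]
        alt = v.alt_base
        if any(b not in _BASES for b in ctx):
            n_skipped += 1
            continue
        if collapse_reverse_complement and ctx[flank] in "GT":
            ctx = reverse_complement(ctx)
            alt = reverse_complement(alt)
        counts[(ctx, alt)] = counts.get((ctx, alt), 0) + 1
    if n_skipped:
        logger.info("mutation signature: %d variants skipped (N/edge context)", n_skipped)
    ctx_totals: dict[str, int] = {}
    for (ctx, _), c in counts.items():
        ctx_totals[ctx] = ctx_totals.get(ctx, 0) + c
    table = {key: c / ctx_totals[key[0]] for key, c in counts.items()}
    return MutationSignature(k=k, table=table)


# ---------------------------------------------------------------------------
# background blocks
# ---------------------------------------------------------------------------

@dataclass
class BackgroundBlock:
    """A random same-length block with signature-drawn synthetic mutations."""

    chrom: str
    start: int
    end: int
    variants: list[tuple[int, str, str]]  # (pos, ref, alt)
    seed: int | None = None


def generate_background_blocks(
    regions: GenomicIntervals,
    block_length: int,
    n_blocks: int,
    n_mut_per_block: int,
    signature: MutationSignature,
    genome: dict[str, str],
    seed: int = 0,
) -> list[BackgroundBlock]:
    """Sample background blocks uniformly over all valid placements.

    Block starts are drawn uniformly over every position (in every region)
    where a full-length block fits; within each block ``n_mut_per_block``
    distinct positions are mutated, the alternate base drawn from the
    mutation signature conditioned on the reference context.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    placements = []  # (chrom, region_start, n_starts)
    for chrom, start, end, _ in regions:
        n_starts = (end - start) - block_length + 1
        if n_starts > 0:
            placements.append((chrom, start, n_starts))
    if not placements:
        raise ValueError(
            f"no region can fit a background block of length {block_length}"
        )
    weights = np.array([n for _, _, n in placements], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    flank = signature.k // 2
    blocks: list[BackgroundBlock] = []
    for _ in range(n_blocks):
        i = rng.choice(len(placements), p=weights)
        chrom, rstart, n_starts = placements[i]
        bstart = rstart + int(rng.integers(n_starts))
        bend = bstart + block_length
        seq = genome[chrom]
        candidates = [
            p for p in range(bstart, bend)
            if seq[p] in _BASES
            and p >= flank
            and p + flank < len(seq)
        ]
        n_mut = min(n_mut_per_block, len(candidates))
        positions = sorted(
            int(p) for p in rng.choice(candidates, size=n_mut, replace=False)
        )
        muts = []
        for p in positions:
            ctx = seq[p - flank : p + flank + 1]
            alt = str(signature.sample_alt(ctx, rng))
            muts.append((p, seq[p], alt))
        blocks.append(BackgroundBlock(chrom, bstart, bend, muts, seed=seed))
    return blocks


# ---------------------------------------------------------------------------
# delta-dbA sample computation
# ---------------------------------------------------------------------------

def apply_variants(seq: str, offset: int, variants) -> str:
    """Apply (pos, ref, alt) or PatientVariant records to a sequence slice."""
    out = list(seq)
    for v in variants:
        if isinstance(v, PatientVariant):
            pos, ref, alt = v.pos, v.ref_base, v.alt_base
        else:
            pos, ref, alt = v
        i = pos - offset
        if not (0 <= i < len(out)):
            raise ValueError(f"variant position {pos} outside block [{offset}, {offset + len(out)})")
        if out[i] != ref:
            raise ValueError(
                f"reference mismatch at {pos}: block has {out[i]}, variant says {ref}"
            )
        out[i] = alt
    return "".join(out)


@dataclass
class DeltaDbaSamples:
    """Per-TF foreground and background delta_dbA samples for one block."""

    block_id: str
    patients: list[str]
    mus: np.ndarray
    fg: dict[str, np.ndarray]       # tf -> (n_patients, n_mu)
    bg: dict[str, np.ndarray]       # tf -> (n_background, n_mu)
    fg_agg: dict[str, np.ndarray]   # tf -> (n_patients,) signed max-magnitude
    bg_agg: dict[str, np.ndarray]   # tf -> (n_background,)
    zero_patients: list[str] = field(default_factory=list)


def _signed_max_magnitude(values: np.ndarray) -> np.ndarray:
    """Signed value of maximal magnitude along the last axis."""
    idx = np.argmax(np.abs(values), axis=-1)
    return np.take_along_axis(values, idx[..., None], axis=-1)[..., 0]


def aggregate_over_mu(values: np.ndarray, how: str = "max") -> np.ndarray:
    if how == "max":
        return _signed_max_magnitude(values)
    if how == "mean":
        return values.mean(axis=-1)
    raise ValueError(f"unknown mu aggregation {how!r}")


def compute_delta_dba_samples(
    block: MutationBlock,
    patient_variants: dict[str, list[PatientVariant]],
    genome: dict[str, str],
    models: list[EnergyModel],
    grid: ChemicalPotentialGrid,
    background_blocks: list[BackgroundBlock],
    shuffles: ShuffleSpec | None = None,
    mu_aggregate: str = "max",
) -> DeltaDbaSamples:
    """Compute per-TF foreground and background delta_dbA sample sets.

    Each patient's SNVs inside the block are applied jointly to the reference
    block sequence; each background block's synthetic variants are applied to
    its own reference slice.  Patients with no variants in the block
    contribute exact zeros (kept, flagged in ``zero_patients``).
    """
    if not models:
        raise ValueError("no PWMs supplied")
    shuffles = shuffles or ShuffleSpec()
    ref_seq = genome[block.chrom][block.start : block.end]
    patients = sorted(patient_variants)
    zero_patients = [p for p in patients if not patient_variants[p]]
    fg_muts = [
        apply_variants(ref_seq, block.start, patient_variants[p]) for p in patients
    ]
    bg_refs = [genome[b.chrom][b.start : b.end] for b in background_blocks]
    bg_muts = [
        apply_variants(r, b.start, b.variants)
        for r, b in zip(bg_refs, background_blocks)
    ]
    n_fg, n_bg = len(fg_muts), len(bg_muts)
    ref_codes = encode_sequence(ref_seq)
    refs = np.concatenate(
        [
            np.tile(ref_codes, (n_fg, 1)) if n_fg else np.empty((0, len(ref_codes)), np.int8),
            np.array([encode_sequence(s) for s in bg_refs], dtype=np.int8).reshape(n_bg, -1),
        ]
    )
    muts = np.concatenate(
        [
            np.array([encode_sequence(s) for s in fg_muts], dtype=np.int8).reshape(n_fg, -1),
            np.array([encode_sequence(s) for s in bg_muts], dtype=np.int8).reshape(n_bg, -1),
        ]
    )
    fg, bg, fg_agg, bg_agg = {}, {}, {}, {}
    for model in models:
        vals = delta_dba_pairs_batch(refs, muts, model, grid.values, background=shuffles)
        fg[model.name] = vals[:n_fg]
        bg[model.name] = vals[n_fg:]
        fg_agg[model.name] = aggregate_over_mu(vals[:n_fg], mu_aggregate)
        bg_agg[model.name] = aggregate_over_mu(vals[n_fg:], mu_aggregate)
    return DeltaDbaSamples(
        block_id=block.block_id,
        patients=patients,
        mus=grid.values,
        fg=fg,
        bg=bg,
        fg_agg=fg_agg,
        bg_agg=bg_agg,
        zero_patients=zero_patients,
    )


# ---------------------------------------------------------------------------
# per-TF significance test
# ---------------------------------------------------------------------------

@dataclass
class TfBlockTest:
    """Per-TF foreground-vs-background rank-sum result for one block.

    ``effect_size`` is the median |aggregate delta_dbA| over the foreground
    samples; it breaks p-value ties (complete separation floors the rank-sum
    p at the same value for every fully separated TF) when ranking TFs.
    """

    tf: str
    block_id: str
    direction: str  # 'gain' or 'loss'
    p_value: float
    p_adjusted: float
    n_fg: int
    n_bg: int
    effect_size: float = 0.0


def rank_tf_tests(tests: list["TfBlockTest"]) -> list["TfBlockTest"]:
    """TF tests ranked by significance, ties broken by impact (|delta_dbA|)."""
    return sorted(tests, key=lambda t: (t.p_value, -t.effect_size, t.tf))


def rank_sum_p(fg: np.ndarray, bg: np.ndarray) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact null distribution when n + m <= 20 and there are no ties; normal
    approximation with tie correction otherwise.  Identical constant samples
    in both groups give p = 1.
    """
    fg = np.asarray(fg, dtype=float).ravel()
    bg = np.asarray(bg, dtype=float).ravel()
    pooled = np.concatenate([fg, bg])
    if np.all(pooled == pooled[0]):
        return 1.0
    n, m = fg.size, bg.size
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n + m <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(fg, bg, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))


def test_tf_block_significance(
    samples: DeltaDbaSamples,
    alpha: float = 0.05,
    n_tests: int | None = None,
    sample_mode: str = "aggregate",
    min_n: int = 3,
) -> list[TfBlockTest]:
    """Rank-sum test per TF between foreground and background delta_dbA.

    ``sample_mode='aggregate'`` (default) uses one signed max-magnitude value
    per patient and per background block, keeping the samples exchangeable
    under the null; ``'pooled'`` uses all per-mu values as samples.
    Bonferroni correction is over the TFs tested in this run.
    """
    if sample_mode not in ("aggregate", "pooled"):
        raise ValueError(f"unknown sample_mode {sample_mode!r}")
    tfs = sorted(samples.fg)
    n_tests = n_tests if n_tests is not None else len(tfs)
    out: list[TfBlockTest] = []
    for tf in tfs:
        if sample_mode == "aggregate":
            fg, bg = samples.fg_agg[tf], samples.bg_agg[tf]
        else:
            fg, bg = samples.fg[tf].ravel(), samples.bg[tf].ravel()
        if fg.size < min_n or bg.size < min_n:
            logger.warning(
                "TF %s on %s: %d fg / %d bg samples < %d; test skipped",
                tf, samples.block_id, fg.size, bg.size, min_n,
            )
            continue
        p = rank_sum_p(fg, bg)
        med_display = float(np.median(-samples.fg_agg[tf]))
        direction = "gain" if med_display > 0 else "loss"
        out.append(
            TfBlockTest(
                tf=tf,
                block_id=samples.block_id,
                direction=direction,
                p_value=p,
                p_adjusted=min(1.0, p * n_tests),
                n_fg=fg.size,
                n_bg=bg.size,
                effect_size=float(np.median(np.abs(samples.fg_agg[tf]))),
            )
        )
    return out


def write_tf_test_table(tests: list[TfBlockTest], path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tblock_id\tdirection\tp_value\tp_adjusted\tn_fg\tn_bg\n")
        for t in sorted(tests, key=lambda t: (t.block_id, t.p_value)):
            fh.write(
                f"{t.tf}\t{t.block_id}\t{t.direction}\t{t.p_value:.6g}\t"
                f"{t.p_adjusted:.6g}\t{t.n_fg}\t{t.n_bg}\n"
            )


# ---------------------------------------------------------------------------
# per-patient heatmap
# ---------------------------------------------------------------------------

@dataclass
class PatientHeatmap:
    """TF x patient matrix of signed empirical log-probabilities.

    Cell = sign(display_change) * (-log10 p_emp) where p_emp is the add-one
    smoothed probability that random (background) mutations affect the TF at
    least as strongly as the patient's mutations.
    """

    block_id: str
    matrix: pd.DataFrame  # rows TF, columns patient


def build_patient_heatmap(
    samples: DeltaDbaSamples,
    tf_expression: dict[str, float] | None = None,
    rpkm_threshold: float = 0.03,
    tf_p_values: dict[str, float] | None = None,
    p_cutoff: float | None = 0.01,
) -> PatientHeatmap:
    """Per-patient signed -log10 empirical probability matrix for one block.

    p_emp(TF, patient) = (1 + #{|background agg| >= |patient agg|}) / (B + 1).
    Rows are limited to TFs passing the expression (RPKM) filter and, when
    per-TF p-values are given, a significance cutoff.
    """
    from .diffexpr import filter_low_expression_tfs

    tfs = sorted(samples.fg_agg)
    if tf_expression is not None:
        tfs = filter_low_expression_tfs(tf_expression, tfs, rpkm_threshold)
    if tf_p_values is not None and p_cutoff is not None:
        tfs = [tf for tf in tfs if tf_p_values.get(tf, 1.0) < p_cutoff]
    patients = samples.patients
    mat = np.zeros((len(tfs), len(patients)))
    for i, tf in enumerate(tfs):
        bg = np.abs(samples.bg_agg[tf])
        B = bg.size
        if B < 1:
            raise ValueError("heatmap needs at least one background aggregate per TF")
        for j, _ in enumerate(patients):
            agg = samples.fg_agg[tf][j]
            p_emp = (1 + int((bg >= abs(agg)).sum())) / (B + 1)
            mat[i, j] = np.sign(-agg) * (-np.log10(p_emp))
    return PatientHeatmap(
        block_id=samples.block_id,
        matrix=pd.DataFrame(mat, index=tfs, columns=patients),
    )


def write_heatmap(heatmap: PatientHeatmap, path, png_path=None) -> None:
    heatmap.matrix.to_csv(path, sep="\t", index_label="tf")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.4 * heatmap.matrix.shape[1], 1 + 0.3 * heatmap.matrix.shape[0])
        )
        vmax = max(1.0, np.abs(heatmap.matrix.values).max())
        im = ax.imshow(heatmap.matrix.values, cmap="coolwarm", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(heatmap.matrix.shape[1]))
        ax.set_xticklabels(heatmap.matrix.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(heatmap.matrix.shape[0]))
        ax.set_yticklabels(heatmap.matrix.index, fontsize=6)
        ax.set_title(heatmap.block_id, fontsize=8)
        fig.colorbar(im, ax=ax, label="signed -log10 p_emp")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# single-variant mutation score and evaluation harness
# ---------------------------------------------------------------------------

def score_variant(
    variant: PatientVariant,
    genome: dict[str, str],
    models: list[EnergyModel],
    grid: ChemicalPotentialGrid | None = None,
    top_n: int = 20,
    shuffles: ShuffleSpec | None = None,
    per_direction: bool = False,
) -> float:
    """Per-SNV mutation score: mean |aggregate delta_dbA| of the top-ranked TFs.

    For each TF the ref/mut pair around the variant (motif-length flanks each
    side) is scored and aggregated over the mu grid; TFs are ranked by
    absolute aggregate and the top ``top_n`` absolute values are averaged.
    With ``per_direction`` the union of the top ``top_n`` gains and top
    ``top_n`` losses is averaged instead.
    """
    grid = grid or ChemicalPotentialGrid()
    shuffles = shuffles if shuffles is not None else ShuffleSpec(count=0)
    seq = genome[variant.chrom]
    aggs = []
    for model in models:
        L = len(model)
        lo, hi = variant.pos - (L - 1), variant.pos + L
        if lo < 0 or hi > len(seq):
            raise ValueError(
                f"variant {variant.chrom}:{variant.pos} too close to the "
                f"chromosome end for PWM {model.name!r} (length {L})"
            )
        ref = seq[lo:hi]
        i = variant.pos - lo
        if ref[i] != variant.ref_base:
            raise ValueError(
                f"reference mismatch at {variant.chrom}:{variant.pos}"
            )
        mut = ref[:i] + variant.alt_base + ref[i + 1 :]
        vals = delta_dba_pairs_batch(
            encode_sequence(ref)[None, :],
            encode_sequence(mut)[None, :],
            model,
            grid.values,
            background=shuffles,
        )[0]
        aggs.append(float(_signed_max_magnitude(vals[None, :])[0]))
    aggs = np.array(aggs)
    if per_direction:
        desc = np.argsort(-aggs, kind="stable")
        asc = np.argsort(aggs, kind="stable")
        top = {i for i in desc[:top_n] if aggs[i] > 0}
        top |= {i for i in asc[:top_n] if aggs[i] < 0}
        chosen = np.abs(aggs[sorted(top)]) if top else np.abs(aggs)
    else:
        chosen = np.sort(np.abs(aggs))[::-1][: min(top_n, aggs.size)]
    return float(chosen.mean())


def rank_tfs_for_variant(
    variant: PatientVariant,
    genome: dict[str, str],
    models: list[EnergyModel],
    grid: ChemicalPotentialGrid | None = None,
    shuffles: ShuffleSpec | None = None,
) -> list[str]:
    """TF names ranked by decreasing |aggregate delta_dbA| for one variant."""
    grid = grid or ChemicalPotentialGrid()
    shuffles = shuffles if shuffles is not None else ShuffleSpec(count=0)
    seq = genome[variant.chrom]
    scored = []
    for model in models:
        L = len(model)
        lo, hi = variant.pos - (L - 1), variant.pos + L
        if lo < 0 or hi > len(seq):
            raise ValueError(
                f"variant {variant.chrom}:{variant.pos} too close to the "
                f"chromosome end for PWM {model.name!r}"
            )
        ref = seq[lo:hi]
        i = variant.pos - lo
        mut = ref[:i] + variant.alt_base + ref[i + 1 :]
        vals = delta_dba_pairs_batch(
            encode_sequence(ref)[None, :],
            encode_sequence(mut)[None, :],
            model,
            grid.values,
            background=shuffles,
        )[0]
        scored.append((model.name, abs(float(_signed_max_magnitude(vals[None, :])[0]))))
    scored.sort(key=lambda x: (-x[1], x[0]))
    return [name for name, _ in scored]


def evaluate_roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC (Mann-Whitney U / (n_pos * n_neg), ties half-credit)."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cumulative_rank_accuracy(
    ranked_lists: dict[str, list],
    truth: dict[str, set],
    N_values,
) -> dict[int, float]:
    """Fraction of variants whose verified TF appears at rank <= N.

    Entries in a ranked list may be TF names or iterables of member names
    (pseudo-TF clusters); a cluster counts as a hit if the verified TF is a
    member.
    """
    out = {}
    variants = sorted(truth)
    for N in N_values:
        hits = 0
        for var in variants:
            true_tfs = truth[var]
            for entry in ranked_lists.get(var, [])[:N]:
                members = {entry} if isinstance(entry, str) else set(entry)
                if members & true_tfs:
                    hits += 1
                    break
        out[int(N)] = hits / len(variants) if variants else 0.0
    return out
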