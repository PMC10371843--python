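"""Clustering of PWMs into representative pseudo-TFs.

PWMs are grouped by DNA-binding-domain (DBD) family, pairwise similarity is
the mean per-column Pearson correlation at the best ungapped offset over both
orientations, and affinity propagation partitions each family.  Each cluster
gets a representative "pseudo-TF" motif — the trimmed column-wise average of
its members aligned to the exemplar — which can stand in for the whole
cluster in the affinity tests (the clustered level C1).  The two-level scheme
(C1fC2_N) runs the pseudo-TFs first and expands the top-N clusters back to
their member PWMs for a second pass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pwm import PositionWeightMatrix

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class SimilarityRecord:
    """Best ungapped alignment between two PWMs.

    ``offset`` is the column shift of b relative to a (b's column 0 aligns
    with a's column ``offset``); ``orientation`` records whether b was
    reverse-complemented.  Score is symmetric and 1 for identical PWMs; -1 is
    a sentinel for pairs with no admissible overlap.
    """

    pwm_a: str
    pwm_b: str
    score: float
    offset: int
    orientation: str  # 'forward' | 'reverse-complement'


@dataclass
class PwmCluster:
    """One affinity-propagation cluster of PWMs with its pseudo-TF."""

    cluster_id: str
    family: str
    members: list[str]
    exemplar: str
    representative: PositionWeightMatrix | None = None
    alignments: dict[str, SimilarityRecord] = field(default_factory=dict)


def assign_dbd(pwm: PositionWeightMatrix, table: dict[str, str]) -> str:
    """Family for a PWM: its own label, then the lookup table, else UNCLASSIFIED."""
    if pwm.dbd_family:
        return pwm.dbd_family
    return table.get(pwm.name, UNCLASSIFIED)


def _safe_column_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 4-vectors; constant columns handled:
    both constant -> 1, one constant -> 0."""
    sx, sy = x.std(), y.std()
    if sx == 0 and sy == 0:
        return 1.0
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def pwm_similarity(
    a: PositionWeightMatrix, b: PositionWeightMatrix, min_overlap: int = 4
) -> SimilarityRecord:
    """Best mean per-column Pearson correlation over ungapped offsets and both
    orientations of b, requiring at least ``min_overlap`` overlapping columns.

    If no offset achieves the overlap, the score is the -1 sentinel.
    """
    if min_overlap < 2:
        raise ValueError("min_overlap must be >= 2")
    pa = a.probs
    best: tuple[float, int, str] | None = None
    for orientation, pb in (
        ("forward", b.probs),
        ("reverse-complement", b.probs[::-1, ::-1]),
    ):
        La, Lb = pa.shape[0], pb.shape[0]
        for offset in range(-(Lb - min_overlap), La - min_overlap + 1):
            a_lo, a_hi = max(0, offset), min(La, offset + Lb)
            if a_hi - a_lo < min_overlap:
                continue
            cols_a = pa[a_lo:a_hi]
            cols_b = pb[a_lo - offset : a_hi - offset]
            score = float(
                np.mean([_safe_column_corr(x, y) for x, y in zip(cols_a, cols_b)])
            )
            if best is None or score > best[0]:
                best = (score, offset, orientation)
    if best is None:
        warnings.warn(
            f"PWMs {a.name!r} and {b.name!r} share no offset with "
            f">= {min_overlap} overlapping columns"
        )
        return SimilarityRecord(a.name, b.name, -1.0, 0, "forward")
    return SimilarityRecord(a.name, b.name, best[0], best[1], best[2])


@dataclass
class ClusterParams:
    preference: float | None = None  # None -> median pairwise similarity
    damping: float = 0.9
    max_iter: int = 1000
    seed: int = 0
    min_overlap: int = 4
    exact_below: int = 11  # families smaller than this are solved exactly


def _exact_affinity_labels(S: np.ndarray, preference: float) -> np.ndarray:
    """Exact maximization of the affinity-propagation objective.

    AP message passing approximately maximizes
    sum_exemplars preference + sum_non-exemplars max_e S(i, e);
    for small families every exemplar subset can be enumerated, which is
    deterministic and immune to the oscillation AP suffers on tied
    similarities.  Ties prefer more clusters, then the lexicographically
    smallest exemplar set.
    """
    import itertools

    n = S.shape[0]
    best = None
    for k in range(1, n + 1):
        for exemplars in itertools.combinations(range(n), k):
            ex = np.array(exemplars)
            score = preference * k + sum(
                S[i, ex].max() for i in range(n) if i not in exemplars
            )
            key = (score, k, tuple(-e for e in exemplars))
            if best is None or key > best[0]:
                best = (key, ex)
    ex = best[1]
    labels = np.empty(n, dtype=int)
    for rank, e in enumerate(ex):
        labels[e] = rank
    for i in range(n):
        if i not in ex:
            labels[i] = int(np.argmax(S[i, ex]))
    return labels, np.asarray(ex)


def cluster_family(
    pwms: list[PositionWeightMatrix],
    family: str = UNCLASSIFIED,
    params: ClusterParams | None = None,
) -> list[PwmCluster]:
    """Affinity propagation over the pairwise similarity matrix of one family.

    Deterministic given the seed and input order; non-convergence falls back
    to all-singleton clusters with a warning.
    """
    from sklearn.cluster import AffinityPropagation
    from sklearn.exceptions import ConvergenceWarning

    params = params or ClusterParams()
    if not pwms:
        raise ValueError("cluster_family needs at least one PWM")
    n = len(pwms)
    names = [p.name for p in pwms]
    if n == 1:
        rec = SimilarityRecord(names[0], names[0], 1.0, 0, "forward")
        return [
            PwmCluster(
                cluster_id=f"{family}_1",
                family=family,
                members=names,
                exemplar=names[0],
                alignments={names[0]: rec},
            )
        ]
    sims = {}
    S = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rec = pwm_similarity(pwms[i], pwms[j], params.min_overlap)
            S[i, j] = S[j, i] = rec.score
            sims[(i, j)] = rec
    preference = (
        params.preference
        if params.preference is not None
        else float(np.median(S[np.triu_indices(n, 1)]))
    )
    if n < params.exact_below:
        labels, centers = _exact_affinity_labels(S, preference)
    else:
        ap = AffinityPropagation(
            affinity="precomputed",
            damping=params.damping,
            max_iter=params.max_iter,
            preference=preference,
            random_state=params.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = ap.fit_predict(S)
        if (labels < 0).any():
            warnings.warn(
                f"affinity propagation did not converge for family {family!r}; "
                "falling back to singleton clusters"
            )
            labels = np.arange(n)
            centers = np.arange(n)
        else:
            centers = ap.cluster_centers_indices_
    clusters: list[PwmCluster] = []
    for k, label in enumerate(sorted(set(labels))):
        idx = [i for i in range(n) if labels[i] == label]
        ex = centers[label] if len(centers) > label and labels[centers[label]] == label else idx[0]
        alignments = {}
        for i in idx:
            if i == ex:
                alignments[names[i]] = SimilarityRecord(
                    names[ex], names[i], 1.0, 0, "forward"
                )
            else:
                lo, hi = min(ex, i), max(ex, i)
                rec = sims[(lo, hi)]
                if lo != ex:  # stored as (i, ex); flip to exemplar-relative
                    rec = _flip_record(rec, pwms[lo], pwms[hi])
                alignments[names[i]] = rec
        clusters.append(
            PwmCluster(
                cluster_id=f"{family}_{k + 1}",
                family=family,
                members=[names[i] for i in idx],
                exemplar=names[ex],
                alignments=alignments,
            )
        )
    return clusters


def _flip_record(
    rec: SimilarityRecord, a: PositionWeightMatrix, b: PositionWeightMatrix
) -> SimilarityRecord:
    """Re-express a similarity record with the roles of a and b swapped."""
    La, Lb = len(a), len(b)
    if rec.orientation == "forward":
        offset = -rec.offset
    else:
        # b was reverse-complemented and placed at rec.offset on a; seen from
        # b's frame, a sits reverse-complemented at this offset:
        offset = Lb - (rec.offset + La)
    return SimilarityRecord(rec.pwm_b, rec.pwm_a, rec.score, offset, rec.orientation)


def build_representative(
    cluster: PwmCluster,
    member_pwms: dict[str, PositionWeightMatrix],
    name: str | None = None,
) -> PositionWeightMatrix:
    """Trimmed column-average pseudo-TF of a cluster.

    Members are aligned to the exemplar at their stored offset/orientation;
    columns covered by at least ceil(m/2) members are averaged and the result
    renormalized.
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    ex = member_pwms[cluster.exemplar]
    lo = 0
    hi = len(ex)
    placed: list[tuple[int, np.ndarray]] = []
    for m in cluster.members:
        rec = cluster.alignments[m]
        probs = member_pwms[m].probs
        if rec.orientation == "reverse-complement":
            probs = probs[::-1, ::-1]
        placed.append((rec.offset, probs))
        lo = min(lo, rec.offset)
        hi = max(hi, rec.offset + probs.shape[0])
    width = hi - lo
    total = np.zeros((width, 4))
    cover = np.zeros(width, dtype=int)
    for offset, probs in placed:
        s = offset - lo
        total[s : s + probs.shape[0]] += probs
        cover[s : s + probs.shape[0]] += 1
    need = int(np.ceil(len(cluster.members) / 2))
    keep = cover >= need
    avg = total[keep] / cover[keep, None]
    rep = PositionWeightMatrix(
        name=name or f"pseudo_{cluster.family}_{cluster.cluster_id.rsplit('_', 1)[-1]}",
        probs=avg / avg.sum(axis=1, keepdims=True),
        dbd_family=cluster.family,
    )
    cluster.representative = rep
    return rep


def cluster_library(
    pwms: list[PositionWeightMatrix],
    dbd_table: dict[str, str] | None = None,
    params: ClusterParams | None = None,
) -> list[PwmCluster]:
    """Cluster a whole PWM library family by family (UNCLASSIFIED included),
    building a representative pseudo-TF for every cluster."""
    dbd_table = dbd_table or {}
    by_family: dict[str, list[PositionWeightMatrix]] = {}
    for p in pwms:
        by_family.setdefault(assign_dbd(p, dbd_table), []).append(p)
    lookup = {p.name: p for p in pwms}
    clusters: list[PwmCluster] = []
    for family in sorted(by_family):
        fam_clusters = cluster_family(by_family[family], family, params)
        for c in fam_clusters:
            build_representative(c, lookup)
        clusters.extend(fam_clusters)
    return clusters


def select_top_clusters(
    c1_ranking: list[str], N: int, clusters: list[PwmCluster]
) -> set[str]:
    """Union of member PWM names of the first min(N, #clusters) pseudo-TFs in
    ranking order.  Ranking entries may be cluster ids or pseudo-TF names."""
    if N < 0:
        raise ValueError("N must be >= 0")
    by_id: dict[str, PwmCluster] = {}
    for c in clusters:
        by_id[c.cluster_id] = c
        if c.representative is not None:
            by_id[c.representative.name] = c
    out: set[str] = set()
    for cid in c1_ranking[: min(N, len(clusters))]:
        if cid not in by_id:
            raise KeyError(f"unknown pseudo-TF or cluster id {cid!r}")
        out.update(by_id[cid].members)
    return out


def write_cluster_table(clusters: list[PwmCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tfamily\texemplar\tmember\toffset\torientation\n")
        for c in clusters:
            for m in c.members:
                rec = c.alignments[m]
                fh.write(
                    f"{c.cluster_id}\t{c.family}\t{c.exemplar}\t{m}\t"
                    f"{rec.offset}\t{rec.orientation}\n"
                )
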