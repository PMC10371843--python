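"""Biophysical model of protein-DNA binding.

A transcription factor's sequence preference is given as a position weight
matrix (PWM) of per-position base probabilities.  The PWM is converted into a
position-specific affinity matrix (PSAM): additive mismatch energies relative
to the per-column consensus base, with the consensus window at total energy
zero.  The probability that a TF occupies a length-L window S is given by the
Fermi-Dirac form

    P(S) = 1 / (1 + exp((E(S) - mu) / kT))

where ``mu`` is the chemical potential (effective protein concentration) and
``kT`` the thermal energy scale.  Sequence occupancy sums P over all windows
(both strands by default).  The differential binding affinity (dbA) of a
sequence is its log-occupancy minus the mean log-occupancy of
mononucleotide-shuffled copies; the shifted differential binding affinity of
a variant is

    delta_dbA = dbA(reference) - dbA(mutated)

evaluated over a grid of chemical potentials.  A positive delta_dbA means
binding was lost due to the mutation; user-facing outputs also carry
``display_change = -delta_dbA`` so that positive means binding gained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> base code lookup; A=0 C=1 G=2 T=3, anything else (incl. N) = -1
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, N/other=-1)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """A TF motif as per-position base probabilities (columns ordered A,C,G,T).

    A pseudocount is added to every entry at construction and columns are
    renormalized, so ``probs`` is always strictly positive with unit column
    sums.
    """

    name: str
    probs: np.ndarray
    dbd_family: str | None = None
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"PWM {self.name!r}: probs must be L x 4, got {p.shape}")
        if p.shape[0] < 2:
            raise ValueError(f"PWM {self.name!r}: needs at least 2 positions")
        if not np.isfinite(p).all():
            raise ValueError(f"PWM {self.name!r}: non-finite probabilities")
        if (p < 0).any():
            raise ValueError(f"PWM {self.name!r}: negative probabilities")
        if self.pseudocount <= 0:
            raise ValueError(f"PWM {self.name!r}: pseudocount must be positive")
        # idempotent regularization: a matrix that is already strictly
        # positive with unit column sums (e.g. read back from disk) is kept
        # as-is so write/read round-trips are exact up to float formatting
        already = (p.min() >= self.pseudocount / 2) and np.allclose(
            p.sum(axis=1), 1.0, atol=1e-6
        )
        if not already:
            p = p + self.pseudocount
            p = p / p.sum(axis=1, keepdims=True)
        self.probs = p

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            name=self.name,
            probs=self.probs[::-1, ::-1],
            dbd_family=self.dbd_family,
            pseudocount=self.pseudocount,
        )

    def information_content(self) -> float:
        """Total information content in bits (2 - column entropy, summed)."""
        p = self.probs
        return float((2 + (p * np.log2(p)).sum(axis=1)).sum())


@dataclass
class EnergyModel:
    """PSAM mismatch energies derived from a PWM.

    ``energies[i, b] = -kT * ln(p[i, b] / max_b p[i, b])`` so the per-column
    consensus base sits at energy 0 and all energies are non-negative and
    finite (the PWM pseudocount guarantees finiteness).
    """

    source: PositionWeightMatrix
    energies: np.ndarray
    kT: float = 1.0

    @property
    def name(self) -> str:
        return self.source.name

    def __len__(self) -> int:
        return self.energies.shape[0]

    @property
    def rc_energies(self) -> np.ndarray:
        """Energy matrix for scanning the reverse-complement strand."""
        return self.energies[::-1, ::-1]


def pwm_to_energy(pwm: PositionWeightMatrix, kT: float = 1.0) -> EnergyModel:
    """Convert a PWM into its additive mismatch-energy (PSAM) form."""
    if not (kT > 0) or not math.isfinite(kT):
        raise ValueError(f"kT must be a positive finite scalar, got {kT}")
    p = pwm.probs
    e = -kT * np.log(p / p.max(axis=1, keepdims=True))
    return EnergyModel(source=pwm, energies=e, kT=kT)


@dataclass
class ChemicalPotentialGrid:
    """Ordered grid of chemical potentials over which binding is evaluated."""

    values: np.ndarray = field(default_factory=lambda: np.arange(-8.0, -21.0, -1.0))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("chemical potential grid must be a non-empty 1-D array")
        d = np.diff(v)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("chemical potential grid must be strictly monotone")
        self.values = v

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def alternate_range(cls) -> "ChemicalPotentialGrid":
        """The admissible 0..23 range used when no concentration estimate exists."""
        return cls(values=np.arange(0.0, 24.0))


def binding_probability(E_total, mu, kT: float = 1.0):
    """Fermi-Dirac occupation probability 1 / (1 + exp((E - mu)/kT)).

    Numerically stable for arbitrarily large |E - mu| / kT; accepts scalars
    or broadcastable arrays.
    """
    if not (kT > 0):
        raise ValueError(f"kT must be positive, got {kT}")
    x = (np.asarray(mu, dtype=float) - np.asarray(E_total, dtype=float)) / kT
    out = expit(x)
    if np.ndim(out) == 0:
        return float(out)
    return out


def _window_energies(codes: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Total window energies for every length-L window of each row of codes.

    codes: (S, n) int8 with -1 for N.  Windows containing N get +inf energy,
    which makes their Fermi-Dirac occupancy exactly 0 (i.e. they are skipped).
    Returns (S, n - L + 1) float.
    """
    L = energies.shape[0]
    win = sliding_window_view(codes, L, axis=-1)  # (S, W, L)
    bad = (win < 0).any(axis=-1)
    e = energies[np.arange(L), np.clip(win, 0, 3)].sum(axis=-1)
    if bad.any():
        e = np.where(bad, np.inf, e)
    return e


def occupancy_batch(
    codes: np.ndarray,
    model: EnergyModel,
    mus: np.ndarray,
    both_strands: bool = True,
) -> np.ndarray:
    """Occupancy of each sequence (rows of codes) at each chemical potential.

    Returns (S, M) for codes (S, n) and mus (M,).
    """
    codes = np.atleast_2d(codes)
    L = len(model)
    if codes.shape[1] < L:
        raise ValueError(
            f"sequence length {codes.shape[1]} shorter than PWM "
            f"{model.name!r} of length {L}"
        )
    mus = np.asarray(mus, dtype=float)
    e_fwd = _window_energies(codes, model.energies)  # (S, W)
    x = (mus[None, None, :] - e_fwd[:, :, None]) / model.kT
    occ = expit(x).sum(axis=1)
    if both_strands:
        e_rev = _window_energies(codes, model.rc_energies)
        x = (mus[None, None, :] - e_rev[:, :, None]) / model.kT
        occ = occ + expit(x).sum(axis=1)
    return occ


def sequence_occupancy(
    seq: str,
    model: EnergyModel,
    mu,
    both_strands: bool = True,
):
    """Summed Fermi-Dirac binding probability over all motif windows of seq.

    With ``both_strands`` the reverse-complement strand windows are added
    (scanned as the reverse-complemented energy matrix).  Windows containing
    N contribute zero.  Scalar mu gives a scalar; an array of mus gives an
    array.
    """
    codes = encode_sequence(seq)
    scalar = np.ndim(mu) == 0
    mus = np.atleast_1d(np.asarray(mu, dtype=float))
    occ = occupancy_batch(codes[None, :], model, mus, both_strands=both_strands)[0]
    return float(occ[0]) if scalar else occ


@dataclass
class ShuffleSpec:
    """Mononucleotide-shuffle background specification for dbA.

    ``count`` shuffled copies are produced from ``seed``; with ``count == 0``
    dbA reduces to the pure log-occupancy.
    """

    count: int = 10
    seed: int = 0
    kind: str = "mononucleotide"

    def permutations(self, n: int) -> list[np.ndarray]:
        if self.kind != "mononucleotide":
            raise ValueError(f"unsupported shuffle kind {self.kind!r}")
        rng = np.random.default_rng(self.seed)
        return [rng.permutation(n) for _ in range(self.count)]


def _log_occupancy_with_shuffles(
    codes_rows: np.ndarray,
    perms: list[np.ndarray],
    model: EnergyModel,
    mus: np.ndarray,
    both_strands: bool,
) -> np.ndarray:
    """dbA rows = ln occ(row) - mean_b ln occ(perm_b(row)); returns (S, M)."""
    S, n = codes_rows.shape
    rows = [codes_rows]
    for p in perms:
        rows.append(codes_rows[:, p])
    stacked = np.concatenate(rows, axis=0)
    occ = occupancy_batch(stacked, model, mus, both_strands=both_strands)
    logocc = np.log(occ)
    base = logocc[:S]
    if not perms:
        return base
    shuf = logocc[S:].reshape(len(perms), S, -1)
    return base - shuf.mean(axis=0)


def dba(
    seq: str,
    model: EnergyModel,
    mu,
    background: ShuffleSpec | None = None,
    both_strands: bool = True,
):
    """Differential binding affinity of seq at chemical potential(s) mu.

    dbA = ln occupancy(seq) - mean_b ln occupancy(shuffle_b(seq)); with an
    empty background (count 0) it is the plain log-occupancy.  Deterministic
    given the background seed.
    """
    background = background or ShuffleSpec()
    codes = encode_sequence(seq)
    scalar = np.ndim(mu) == 0
    mus = np.atleast_1d(np.asarray(mu, dtype=float))
    perms = background.permutations(len(codes))
    out = _log_occupancy_with_shuffles(
        codes[None, :], perms, model, mus, both_strands
    )[0]
    return float(out[0]) if scalar else out


@dataclass
class DeltaDbaProfile:
    """Per-chemical-potential delta_dbA of one TF for one subject.

    ``aggregate`` is the signed value of maximal magnitude across the grid;
    ``display_change = -aggregate`` so a positive display value means the
    mutation gained binding.
    """

    tf: str
    subject: str
    mus: np.ndarray
    values: np.ndarray

    @property
    def per_mu(self) -> dict[float, float]:
        return {float(m): float(v) for m, v in zip(self.mus, self.values)}

    @property
    def aggregate(self) -> float:
        idx = int(np.argmax(np.abs(self.values)))
        return float(self.values[idx])

    @property
    def display_change(self) -> float:
        return -self.aggregate


def delta_dba_pairs_batch(
    refs: np.ndarray,
    muts: np.ndarray,
    model: EnergyModel,
    mus: np.ndarray,
    background: ShuffleSpec | None = None,
    both_strands: bool = True,
) -> np.ndarray:
    """delta_dbA for S (ref, mut) same-length pairs; returns (S, M).

    The same shuffle permutations are applied to every ref and its mut so the
    background term cancels exactly when ref == mut.
    """
    background = background or ShuffleSpec()
    refs = np.atleast_2d(refs)
    muts = np.atleast_2d(muts)
    if refs.shape != muts.shape:
        raise ValueError(
            f"ref/mut shape mismatch: {refs.shape} vs {muts.shape}"
        )
    mus = np.asarray(mus, dtype=float)
    perms = background.permutations(refs.shape[1])
    dba_ref = _log_occupancy_with_shuffles(refs, perms, model, mus, both_strands)
    dba_mut = _log_occupancy_with_shuffles(muts, perms, model, mus, both_strands)
    return dba_ref - dba_mut


def delta_dba(
    ref_seq: str,
    mut_seq: str,
    model: EnergyModel,
    grid: ChemicalPotentialGrid | None = None,
    background: ShuffleSpec | None = None,
    both_strands: bool = True,
    subject: str = "",
) -> DeltaDbaProfile:
    """Shifted differential binding affinity dbA(ref) - dbA(mut) over a mu grid."""
    if len(ref_seq) != len(mut_seq):
        raise ValueError(
            f"ref/mut length mismatch: {len(ref_seq)} vs {len(mut_seq)}"
        )
    grid = grid or ChemicalPotentialGrid()
    vals = delta_dba_pairs_batch(
        encode_sequence(ref_seq)[None, :],
        encode_sequence(mut_seq)[None, :],
        model,
        grid.values,
        background=background,
        both_strands=both_strands,
    )[0]
    return DeltaDbaProfile(tf=model.name, subject=subject, mus=grid.values, values=vals)


# ---------------------------------------------------------------------------
# PWM file format: header line ">NAME<TAB>DBD_FAMILY" (family optional),
# then L rows of 4 whitespace-separated probabilities (A C G T order).
# '#' comment lines are ignored.  Round-trips up to %.6g formatting.
# ---------------------------------------------------------------------------

def read_pwms(path) -> list[PositionWeightMatrix]:
    pwms: list[PositionWeightMatrix] = []
    name = None
    family = None
    rows: list[list[float]] = []

    def flush():
        if name is not None:
            if not rows:
                raise ValueError(f"PWM {name!r} has no probability rows")
            pwms.append(
                PositionWeightMatrix(name=name, probs=np.array(rows), dbd_family=family)
            )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                name = parts[0].strip()
                family = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
                rows = []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(
                        f"PWM row must have 4 values (A C G T), got {len(vals)}: {line!r}"
                    )
                rows.append(vals)
        flush()
    return pwms


def write_pwms(pwms: Iterable[PositionWeightMatrix], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            if pwm.dbd_family:
                fh.write(f">{pwm.name}\t{pwm.dbd_family}\n")
            else:
                fh.write(f">{pwm.name}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
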