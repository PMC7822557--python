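"""Binding-energy landscapes for nucleosomes, PWM factors, and poly(A/T) tracts.

Every binding species on the DNA lattice is summarised by a per-start energy
track ``E(i)`` in units of k_B*T: the energy of placing the factor's footprint
with its left edge at (0-based) start ``i``.  Disallowed starts carry
``NO_BIND`` (= +inf), which contributes zero Boltzmann weight downstream.

All tracks are normalised so that the mean of ``exp(-E)`` over bindable
(finite) starts equals 1.  The additive constant removed by the normalisation
is degenerate with the factor's concentration parameter, so this convention
costs nothing and keeps concentrations of different factors on comparable
scales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger("nuclattice")

#: Energy assigned to starts where a factor cannot bind (zero Boltzmann weight).
NO_BIND = np.inf

#: Nucleosome footprint on DNA, bp.
NUCLEOSOME_FOOTPRINT = 147

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)  # 4 encodes N / anything else
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A chromosome: an identifier plus an uppercase ACGTN string."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.name!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """Residues as int8 codes: A=0, C=1, G=2, T=3, other=4."""
        return _CODE[np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)]

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.name, self.residues.translate(_COMPLEMENT)[::-1])


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position base probabilities of a binding motif.

    ``weights[j, a]`` is the probability of base ``a`` (A,C,G,T order) at motif
    position ``j``.  ``threshold`` is a log-odds score cutoff (versus a uniform
    background); windows scoring below it are treated as non-binding.  When
    ``threshold`` is None a default of ``DEFAULT_THRESHOLD_FRACTION`` times the
    maximum achievable log-odds score is used at scan time.
    """

    name: str
    weights: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError(f"PWM {self.name!r}: weights must be (l, 4), l >= 1")
        if np.any(w < 0):
            raise ValueError(f"PWM {self.name!r}: negative weight")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: rows must sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    def max_log_odds(self) -> float:
        """Best achievable log-odds score against a uniform background."""
        with np.errstate(divide="ignore"):
            lw = np.log(self.weights)
        return float(np.sum(lw.max(axis=1)) + self.width * np.log(4.0))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.name, self.weights[::-1, ::-1].copy(), self.threshold
        )


#: Default PWM score cutoff, as a fraction of the maximum achievable log-odds.
DEFAULT_THRESHOLD_FRACTION = 0.6


@dataclass
class EnergyTrack:
    """Per-start binding energies (k_B*T) of one factor along one chromosome.

    ``energies[i]`` is the energy of the footprint starting at 0-based
    position ``i``; valid starts are ``0 .. L - footprint``.  ``NO_BIND``
    (+inf) marks disallowed starts.
    """

    name: str
    footprint: int
    energies: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        if self.energies.ndim != 1 or self.energies.size < 1:
            raise ValueError("energies must be a non-empty 1-D array")
        if np.any(np.isnan(self.energies)) or np.any(self.energies == -np.inf):
            raise ValueError("energies must be finite or NO_BIND (+inf)")

    @property
    def L(self) -> int:
        """Length of the chromosome the track was built on."""
        return self.energies.size + self.footprint - 1

    @property
    def n_starts(self) -> int:
        return self.energies.size

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.energies)

    def copy(self) -> "EnergyTrack":
        return EnergyTrack(self.name, self.footprint, self.energies.copy())


def _window_scores(code: np.ndarray, log_w: np.ndarray) -> np.ndarray:
    """Sum of ``log_w[j, base]`` over each window; -inf where a window hits a
    zero-probability base or an N."""
    l = log_w.shape[0]
    n = code.size - l + 1
    # column 4 (N) is -inf so N-containing windows fail automatically
    lw5 = np.hstack([log_w, np.full((l, 1), -np.inf)])
    scores = np.zeros(n)
    for j in range(l):
        scores += lw5[j, code[j : j + n]]
    return scores


def scan_pwm(
    seq: SequenceRecord,
    pwm: PositionWeightMatrix,
    *,
    both_strands: bool = True,
    threshold: float | None = None,
) -> EnergyTrack:
    """Scan a PWM along a chromosome and return the raw (unnormalised) energy
    track ``E0(i) = -sum_j log w(j, base_{i+j})``.

    A start is bindable only where the window's log-odds score (vs uniform
    background) passes the cutoff on at least one scanned strand; with
    ``both_strands`` the lower energy (better-scoring orientation) is kept.
    Windows containing N, or a zero-probability base, are ``NO_BIND``.
    """
    L = len(seq)
    l = pwm.width
    if l > L:
        raise ValueError(f"PWM {pwm.name!r} wider ({l}) than sequence ({L})")
    if threshold is None:
        threshold = pwm.threshold
    if threshold is None:
        threshold = DEFAULT_THRESHOLD_FRACTION * pwm.max_log_odds()

    code = seq.encoded()
    with np.errstate(divide="ignore"):
        log_w = np.log(pwm.weights)
    bg = l * np.log(4.0)

    loglik = _window_scores(code, log_w)  # sum log w, forward strand
    passing = (loglik + bg) >= threshold
    energy = np.where(passing, -loglik, NO_BIND)

    if both_strands:
        log_w_rc = log_w[::-1, ::-1]
        loglik_rc = _window_scores(code, log_w_rc)
        passing_rc = (loglik_rc + bg) >= threshold
        energy_rc = np.where(passing_rc, -loglik_rc, NO_BIND)
        energy = np.minimum(energy, energy_rc)

    return EnergyTrack(pwm.name, l, energy)


def normalize_energy(raw: EnergyTrack) -> EnergyTrack:
    """Shift a track so that ``mean(exp(-E))`` over finite starts equals 1.

    The shift is ``E_T = log(mean_finite exp(-E0))``; NO_BIND starts are
    preserved and excluded from the mean.
    """
    finite = raw.finite_mask()
    n = int(finite.sum())
    if n == 0:
        raise ValueError(f"factor {raw.name!r} has no bindable start")
    e_t = float(logsumexp(-raw.energies[finite]) - np.log(n))
    energies = raw.energies + e_t  # inf + c = inf
    return EnergyTrack(raw.name, raw.footprint, energies)


def build_polyA_factors(
    seq: SequenceRecord, lengths: list[int] | tuple[int, ...] = (5, 6, 7, 8, 9)
) -> list[EnergyTrack]:
    """One binding species per tract length ``k``: bindable exactly at pure
    homopolymer A_k or T_k windows (mixed A/T windows do not qualify), zero
    energy there, NO_BIND elsewhere; normalised.

    These species stand in for RSC recruitment to poly(A/T) tracts.  Lengths
    with no occurrence in the sequence are dropped with a warning.
    """
    L = len(seq)
    code = seq.encoded()
    is_a = (code == 0).astype(np.int64)
    is_t = (code == 3).astype(np.int64)
    ca = np.concatenate([[0], np.cumsum(is_a)])
    ct = np.concatenate([[0], np.cumsum(is_t)])
    tracks: list[EnergyTrack] = []
    for k in lengths:
        if not 1 <= k <= L:
            raise ValueError(f"poly(A/T) length {k} outside [1, {L}]")
        n = L - k + 1
        sum_a = ca[k : k + n] - ca[:n]
        sum_t = ct[k : k + n] - ct[:n]
        bindable = (sum_a == k) | (sum_t == k)
        if not bindable.any():
            msg = f"no poly(A/T) tract of length {k} in {seq.name!r}; factor dropped"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        energies = np.where(bindable, 0.0, NO_BIND)
        tracks.append(normalize_energy(EnergyTrack(f"PolyA{k}", k, energies)))
    return tracks


def load_nucleosome_energy(
    values: np.ndarray,
    *,
    kind: str = "probability",
    footprint: int = NUCLEOSOME_FOOTPRINT,
    name: str = "nucleosome",
    per_start: bool = False,
) -> EnergyTrack:
    """Build the nucleosome energy track from a precomputed per-position
    track of binding probabilities (``kind='probability'``, ``E0 = -log P``)
    or of energies (``kind='energy'``, pass-through), then normalise.

    ``values`` is a per-bp track over the chromosome unless ``per_start``;
    in the per-bp case only the first ``L - footprint + 1`` entries are valid
    nucleosome starts.  Non-positive probabilities become NO_BIND.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("track must be 1-D")
    if not per_start:
        if values.size < footprint:
            raise ValueError(
                f"track length {values.size} shorter than footprint {footprint}"
            )
        values = values[: values.size - footprint + 1]
    if kind == "probability":
        with np.errstate(divide="ignore", invalid="ignore"):
            e0 = np.where(values > 0, -np.log(np.maximum(values, 1e-300)), NO_BIND)
    elif kind == "energy":
        e0 = values.copy()
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return normalize_energy(EnergyTrack(name, footprint, e0))


def constant_nucleosome_track(
    L: int, footprint: int = NUCLEOSOME_FOOTPRINT, name: str = "nucleosome"
) -> EnergyTrack:
    """Sequence-independent surrogate: a flat (zero) nucleosome energy track.

    This is the no-sequence-preference control; with it, nucleosome
    positioning is driven purely by entropy and competition with factors.
    """
    if L < footprint:
        raise ValueError(f"L={L} shorter than footprint {footprint}")
    return EnergyTrack(name, footprint, np.zeros(L - footprint + 1))


__all__ = [
    "NO_BIND",
    "NUCLEOSOME_FOOTPRINT",
    "DEFAULT_THRESHOLD_FRACTION",
    "SequenceRecord",
    "PositionWeightMatrix",
    "EnergyTrack",
    "scan_pwm",
    "normalize_energy",
    "build_polyA_factors",
    "load_nucleosome_energy",
    "constant_nucleosome_track",
]
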