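"""Exact equilibrium of the 1-D hard-core lattice gas of nucleosomes and TFs.

DNA is a lattice of L sites (1 bp each).  Each binding species t occupies a
contiguous footprint of l_t sites; footprints may not overlap.  A configuration
n has weight g_n = prod over placed particles of c_t * exp(-gamma_t * E_t(i)),
where c_t is the species' concentration, gamma_t its binding specificity and
E_t(i) its per-start binding energy.  The partition function Z = sum_n g_n and
all marginals are computed exactly with forward/backward recursions over
prefix/suffix partition functions:

    F(i) = F(i-1) + sum_t F(i - l_t) * w_t(i - l_t),   F(0) = 1
    B(i) = B(i+1) + sum_t B(i + l_t) * w_t(i),         B(L) = 1

(0-based starts; w_t(s) = c_t * exp(-gamma_t * E_t(s)), zero at NO_BIND).
The probability that a particle of species t starts at s is

    P_t(s) = F(s) * w_t(s) * B(s + l_t) / Z,

and the occupancy of species t at base pair p sums P_t over the l_t starts
whose footprint covers p.  Everything runs in the log domain: genome-scale Z
overflows any fixed-precision float.

A brute-force configuration enumerator (`enumerate_configurations`) serves as
an independent exact oracle on tiny systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .energy import EnergyTrack

#: Round-off tolerance absorbed when clipping occupancies into [0, 1];
#: larger violations raise.
_CLIP_TOL = 1e-8


@dataclass
class FactorSpec:
    """A binding species: an energy track plus its (c, gamma) scaling."""

    track: EnergyTrack
    c: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c) and self.c >= 0):
            raise ValueError(f"{self.name}: concentration must be finite and >= 0")
        if not (np.isfinite(self.gamma) and self.gamma >= 0):
            raise ValueError(f"{self.name}: specificity must be finite and >= 0")

    @property
    def name(self) -> str:
        return self.track.name

    @property
    def footprint(self) -> int:
        return self.track.footprint

    def log_weights(self, L: int) -> np.ndarray:
        """log w(s) = log c - gamma * E(s), padded with -inf to length L."""
        out = np.full(L, -np.inf)
        if self.c == 0:
            return out
        n = self.track.n_starts
        with np.errstate(invalid="ignore"):
            lw = np.log(self.c) - self.gamma * self.track.energies
        # gamma * inf would give nan at gamma=0; NO_BIND must stay -inf
        lw[~self.track.finite_mask()] = -np.inf
        out[:n] = lw
        return out

    def copy(self) -> "FactorSpec":
        return FactorSpec(self.track.copy(), self.c, self.gamma)


@dataclass
class LatticeSystem:
    """One chromosome's lattice: length L and the competing species."""

    L: int
    factors: list[FactorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        for f in self.factors:
            if f.track.L != self.L:
                raise ValueError(
                    f"factor {f.name!r} track built for L={f.track.L}, system L={self.L}"
                )

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def without(self, name: str) -> "LatticeSystem":
        """A system with the named factor removed entirely."""
        return LatticeSystem(self.L, [f.copy() for f in self.factors if f.name != name])

    def copy(self) -> "LatticeSystem":
        return LatticeSystem(self.L, [f.copy() for f in self.factors])


@dataclass
class PartitionVector:
    """Log-domain prefix (forward) or suffix (backward) partition functions."""

    direction: str
    log_values: np.ndarray
    log_Z: float


@dataclass
class OccupancyProfile:
    """Per-bp occupancy O(p) in [0, 1] and per-start probabilities P(s)."""

    name: str
    occupancy: np.ndarray
    start_probabilities: np.ndarray


@njit(cache=False)
def _logaddexp(a: float, b: float) -> float:
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    if a < b:
        a, b = b, a
    return a + np.log1p(np.exp(b - a))


@njit(cache=False)
def _forward_kernel(L: int, lens: np.ndarray, logw: np.ndarray) -> np.ndarray:
    logF = np.zeros(L + 1)
    T = lens.shape[0]
    for i in range(1, L + 1):
        acc = logF[i - 1]
        for t in range(T):
            l = lens[t]
            if i >= l:
                lw = logw[t, i - l]
                if lw > -np.inf:
                    acc = _logaddexp(acc, logF[i - l] + lw)
        logF[i] = acc
    return logF


@njit(cache=False)
def _backward_kernel(L: int, lens: np.ndarray, logw: np.ndarray) -> np.ndarray:
    logB = np.zeros(L + 1)
    T = lens.shape[0]
    for s in range(L - 1, -1, -1):
        acc = logB[s + 1]
        for t in range(T):
            l = lens[t]
            if s + l <= L:
                lw = logw[t, s]
                if lw > -np.inf:
                    acc = _logaddexp(acc, logB[s + l] + lw)
        logB[s] = acc
    return logB


def _weight_matrix(sys: LatticeSystem) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([f.footprint for f in sys.factors], dtype=np.int64)
    if len(sys.factors) == 0:
        return lens, np.full((0, sys.L), -np.inf)
    logw = np.stack([f.log_weights(sys.L) for f in sys.factors])
    return lens, logw


def forward_partition(sys: LatticeSystem) -> PartitionVector:
    """Prefix partition functions F(0..L); F(i) covers lattice sites < i."""
    lens, logw = _weight_matrix(sys)
    logF = _forward_kernel(sys.L, lens, logw)
    return PartitionVector("forward", logF, float(logF[-1]))


def backward_partition(sys: LatticeSystem) -> PartitionVector:
    """Suffix partition functions B(0..L); B(s) covers lattice sites >= s.

    B(0) equals the forward total F(L) (both are Z), a required identity
    checked by `solve`.
    """
    lens, logw = _weight_matrix(sys)
    logB = _backward_kernel(sys.L, lens, logw)
    return PartitionVector("backward", logB, float(logB[0]))


def start_probabilities(
    sys: LatticeSystem,
    factor: FactorSpec,
    fwd: PartitionVector,
    bwd: PartitionVector,
) -> np.ndarray:
    """P_t(s) for all s in 0..L-1 (zero beyond the last valid start)."""
    L = sys.L
    logw = factor.log_weights(L)
    l = factor.footprint
    logP = np.full(L, -np.inf)
    n = max(L - l + 1, 0)
    if n > 0:
        logP[:n] = (
            fwd.log_values[:n] + logw[:n] + bwd.log_values[l : l + n] - fwd.log_Z
        )
    return np.exp(logP)


def _occupancy_from_starts(P: np.ndarray, l: int) -> np.ndarray:
    L = P.size
    c = np.concatenate([[0.0], np.cumsum(P)])
    p = np.arange(L)
    lo = np.maximum(p - l + 1, 0)
    return c[p + 1] - c[lo]


def solve(sys: LatticeSystem) -> dict[str, OccupancyProfile]:
    """Full equilibrium solve: one OccupancyProfile per species.

    Verifies the forward/backward identity and hard-core feasibility
    (total occupancy <= 1 everywhere, up to round-off).
    """
    fwd = forward_partition(sys)
    bwd = backward_partition(sys)
    if not np.isclose(fwd.log_Z, bwd.log_Z, rtol=1e-9, atol=1e-9):
        raise FloatingPointError(
            f"forward/backward partition mismatch: {fwd.log_Z} vs {bwd.log_Z}"
        )
    profiles: dict[str, OccupancyProfile] = {}
    total = np.zeros(sys.L)
    for f in sys.factors:
        P = start_probabilities(sys, f, fwd, bwd)
        O = _occupancy_from_starts(P, f.footprint)
        if O.min() < -_CLIP_TOL or O.max() > 1 + _CLIP_TOL:
            raise FloatingPointError(
                f"occupancy of {f.name!r} outside [0,1] beyond round-off: "
                f"[{O.min()}, {O.max()}]"
            )
        O = np.clip(O, 0.0, 1.0)
        total += O
        profiles[f.name] = OccupancyProfile(f.name, O, P)
    if total.size and total.max() > 1 + _CLIP_TOL:
        raise FloatingPointError(
            f"total occupancy {total.max()} exceeds 1 beyond round-off"
        )
    return profiles


def occupancy(sys: LatticeSystem, name: str) -> OccupancyProfile:
    """Occupancy of a single named species (convenience wrapper over solve)."""
    return solve(sys)[name]


def log_partition(sys: LatticeSystem) -> float:
    return forward_partition(sys).log_Z


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


@dataclass
class Enumeration:
    """Exhaustive ensemble of a tiny system: every configuration listed."""

    Z: float
    states: list[tuple[tuple[int, int], ...]]  # ((factor_index, start), ...)
    weights: list[float]
    start_probabilities: dict[str, np.ndarray]
    occupancy: dict[str, np.ndarray]


def enumerate_configurations(
    sys: LatticeSystem, max_L: int = 30, max_states: int = 1_000_000
) -> Enumeration:
    """Enumerate every non-overlapping placement configuration explicitly.

    Independent of the recursion code path; intended as an exact oracle for
    small systems only (L <= `max_L`).
    """
    if sys.L > max_L:
        raise ValueError(f"L={sys.L} too large for enumeration (max {max_L})")
    L = sys.L
    specs = [
        (ti, f.footprint, np.exp(f.log_weights(L)))
        for ti, f in enumerate(sys.factors)
    ]
    states: list[tuple[tuple[int, int], ...]] = []
    weights: list[float] = []

    def recurse(pos: int, placed: tuple, weight: float) -> None:
        if len(states) > max_states:
            raise ValueError("state space too large for enumeration")
        if pos >= L:
            states.append(placed)
            weights.append(weight)
            return
        # site `pos` left empty
        recurse(pos + 1, placed, weight)
        for ti, l, w in specs:
            if pos + l <= L and w[pos] > 0:
                recurse(pos + l, placed + ((ti, pos),), weight * w[pos])

    recurse(0, (), 1.0)
    Z = float(sum(weights))
    sp = {f.name: np.zeros(L) for f in sys.factors}
    occ = {f.name: np.zeros(L) for f in sys.factors}
    for state, w in zip(states, weights):
        for ti, s in state:
            f = sys.factors[ti]
            sp[f.name][s] += w / Z
            occ[f.name][s : s + f.footprint] += w / Z
    return Enumeration(Z, states, weights, sp, occ)


__all__ = [
    "FactorSpec",
    "LatticeSystem",
    "PartitionVector",
    "OccupancyProfile",
    "forward_partition",
    "backward_partition",
    "start_probabilities",
    "solve",
    "occupancy",
    "log_partition",
    "Enumeration",
    "enumerate_configurations",
]
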