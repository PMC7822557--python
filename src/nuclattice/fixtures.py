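"""Synthetic genomes, energy landscapes, and reference tracks for testing.

Everything the pipeline consumes can be generated here deterministically from
a seed: random background sequence with planted motif instances and poly(A/T)
tracts, a smooth surrogate nucleosome energy landscape, and reference
occupancy tracks either forward-simulated from a known-truth lattice system
(plus additive Gaussian noise, clipped to [0, 1]) or drawn by hand as smooth
dips in a flat background whose geometry satisfies or violates the NDR rules
on demand.  The hand-drawn mode emulates the shape of a modified reference
map (near-saturating background, sharply depleted NDRs); it does not emulate
MNase digestion bias or read-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .energy import (
    EnergyTrack,
    NUCLEOSOME_FOOTPRINT,
    PositionWeightMatrix,
    SequenceRecord,
    build_polyA_factors,
    constant_nucleosome_track,
    normalize_energy,
    scan_pwm,
)
from .lattice import FactorSpec, LatticeSystem, solve
from .ndr import NDR, ReferenceTrack, annotate_ndrs


@dataclass
class PlantedDip:
    """A hand-drawn smooth occupancy dip: flat bottom with cosine ramps."""

    center: int
    bottom: float = 0.30
    half_width: int = 80
    flank: int = 40


@dataclass
class FixtureSpec:
    """Recipe for a synthetic study genome.

    Defaults describe a small yeast-like setting: a few chromosomes of tens
    of kb at 38% GC, occupancy background at 0.85 with dips reaching 0.30.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 20_000, "chrII": 20_000, "chrIII": 20_000}
    )
    gc: float = 0.38
    motif_plants: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    polyA_plants: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    dips: dict[str, list[PlantedDip]] = field(default_factory=dict)
    baseline: float = 0.85
    noise_sd: float = 0.0
    seed: int = 0
    allow_overlap: bool = False


def consensus_pwm(
    name: str, consensus: str, certainty: float = 0.9, threshold: float | None = None
) -> PositionWeightMatrix:
    """A PWM putting `certainty` on each consensus base, the remainder split
    evenly over the other three."""
    idx = {b: i for i, b in enumerate("ACGT")}
    w = np.full((len(consensus), 4), (1 - certainty) / 3)
    for j, b in enumerate(consensus.upper()):
        w[j, idx[b]] = certainty
    return PositionWeightMatrix(name, w, threshold)


def generate_genome(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], dict[str, list[tuple[int, int, str]]]]:
    """i.i.d. background at the requested GC fraction with planted features
    overwritten at recorded coordinates.  Returns the records and a map of
    chrom -> [(start, end, label)] for every plant."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    records, annots = [], {}
    for chrom, L in spec.chrom_lengths.items():
        seq = np.array(list("ACGT"))[rng.choice(4, size=L, p=p)]
        placed: list[tuple[int, int, str]] = []

        def plant(pos: int, text: str, label: str) -> None:
            if pos < 0 or pos + len(text) > L:
                raise ValueError(f"plant {label!r} outside {chrom} bounds")
            if not spec.allow_overlap:
                for a, b, other in placed:
                    if pos < b and pos + len(text) > a:
                        raise ValueError(
                            f"plant {label!r} overlaps {other!r} on {chrom}"
                        )
            seq[pos : pos + len(text)] = list(text)
            placed.append((pos, pos + len(text), label))

        for pos, consensus in spec.motif_plants.get(chrom, []):
            plant(pos, consensus.upper(), f"motif:{consensus}")
        for pos, k, base in spec.polyA_plants.get(chrom, []):
            plant(pos, base.upper() * k, f"poly{base.upper()}{k}")
        records.append(SequenceRecord(chrom, "".join(seq)))
        annots[chrom] = placed
    return records, annots


def surrogate_nucleosome_energy(
    L: int,
    rng: np.random.Generator,
    *,
    amplitude: float = 1.0,
    smooth_bp: float = 50.0,
    footprint: int = NUCLEOSOME_FOOTPRINT,
    name: str = "nucleosome",
) -> EnergyTrack:
    """A smooth random stand-in for a sequence-dependent nucleosome energy
    landscape (synthetic; no dinucleotide model behind it): Gaussian-filtered
    white noise, scaled to the requested SD, then normalised."""
    if L < footprint:
        raise ValueError(f"L={L} shorter than footprint {footprint}")
    n = L - footprint + 1
    raw = gaussian_filter1d(rng.normal(size=n), smooth_bp, mode="reflect")
    sd = raw.std()
    if sd > 0:
        raw = raw * (amplitude / sd)
    return normalize_energy(EnergyTrack(name, footprint, raw))


def assemble_system(
    seq: SequenceRecord,
    nucleosome_track: EnergyTrack | None = None,
    pwms: list[PositionWeightMatrix] = (),
    polyA_lengths: tuple[int, ...] = (),
    params: dict[str, tuple[float, float]] | None = None,
    both_strands: bool = True,
) -> LatticeSystem:
    """Build a LatticeSystem for one chromosome: scan + normalise each PWM,
    add poly(A/T) species, and attach (c, gamma) per factor name from
    `params` (default (1, 1))."""
    params = params or {}
    L = len(seq)
    if nucleosome_track is None:
        nucleosome_track = constant_nucleosome_track(L)
    tracks = [nucleosome_track]
    for pwm in pwms:
        tracks.append(normalize_energy(scan_pwm(seq, pwm, both_strands=both_strands)))
    if polyA_lengths:
        tracks.extend(build_polyA_factors(seq, polyA_lengths))
    factors = []
    for t in tracks:
        c, gamma = params.get(t.name, (1.0, 1.0))
        factors.append(FactorSpec(t, c, gamma))
    return LatticeSystem(L, factors)


def dip_profile(
    L: int,
    dips: list[PlantedDip],
    baseline: float = 0.85,
) -> np.ndarray:
    """Flat background with smooth flat-bottomed dips (cosine ramps).  Where
    dips overlap the deeper value wins."""
    y = np.full(L, baseline)
    x = np.arange(L)
    for d in dips:
        prof = np.full(L, baseline)
        inner = np.abs(x - d.center) <= d.half_width
        prof[inner] = d.bottom
        for side in (-1, 1):
            a = d.center + side * d.half_width
            ramp = (x - a) * side
            on = (ramp > 0) & (ramp <= d.flank)
            t = ramp[on] / d.flank
            prof[on] = d.bottom + (baseline - d.bottom) * (1 - np.cos(np.pi * t)) / 2
        y = np.minimum(y, prof)
    return y


def generate_reference(
    spec: FixtureSpec,
    truth_sys: dict[str, LatticeSystem] | None = None,
    rng: np.random.Generator | None = None,
    nucleosome: str = "nucleosome",
) -> tuple[dict[str, ReferenceTrack], dict[str, list[NDR]]]:
    """Reference occupancy per chromosome plus truth NDR intervals.

    With `truth_sys` the reference is the forward-simulated nucleosome
    occupancy plus seeded Gaussian noise (clipped to [0, 1]) and the truth
    NDRs are annotated on the noiseless profile; otherwise hand-drawn dips
    from `spec.dips` on a flat baseline, with truth NDRs at the planted
    bottoms.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    refs: dict[str, ReferenceTrack] = {}
    truth: dict[str, list[NDR]] = {}
    for chrom, L in spec.chrom_lengths.items():
        if truth_sys is not None:
            clean = solve(truth_sys[chrom])[nucleosome].occupancy
            truth[chrom] = annotate_ndrs(clean) if L >= 147 else []
        else:
            dips = spec.dips.get(chrom, [])
            clean = dip_profile(L, dips, spec.baseline)
            truth[chrom] = [
                NDR(
                    d.center - d.half_width,
                    d.center + d.half_width + 1,
                    float(d.center),
                    2 * d.half_width + 1,
                )
                for d in dips
            ]
        y = clean
        if spec.noise_sd > 0:
            y = np.clip(y + rng.normal(0, spec.noise_sd, L), 0.0, 1.0)
        refs[chrom] = ReferenceTrack(y)
    return refs, truth


__all__ = [
    "PlantedDip",
    "FixtureSpec",
    "consensus_pwm",
    "generate_genome",
    "surrogate_nucleosome_energy",
    "assemble_system",
    "dip_profile",
    "generate_reference",
]
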