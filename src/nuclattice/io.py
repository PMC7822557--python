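"""Readers and writers for the standard formats the pipeline speaks.

FASTA via Biopython; PWMs in JASPAR PFM or MEME-minimal dialects via
Bio.motifs (count matrices become frequencies with a configurable
pseudocount); per-bp tracks as plain-text bedGraph or fixed-step wig; NDRs
and clusters as BED (0-based half-open, length and center in extra columns);
fitted parameters as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .cooperativity import SiteCluster
from .energy import PositionWeightMatrix, SequenceRecord
from .ndr import NDR

DEFAULT_PSEUDOCOUNT = 0.01


# --- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [BioSeqRecord(Seq(r.residues), id=r.name, description="") for r in records],
        str(path),
        "fasta",
    )


# --- PWMs -------------------------------------------------------------------


def _motif_to_pwm(motif, pseudocount: float) -> PositionWeightMatrix:
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float).T  # (l, 4)
    freq = counts + pseudocount
    freq /= freq.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(motif.name or motif.base_id or "motif", freq)


def read_pwms(
    path: str | Path,
    fmt: str = "jaspar",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PositionWeightMatrix]:
    """Read PWMs from a JASPAR PFM file (`fmt='jaspar'`) or a MEME minimal
    motif file (`fmt='minimal'`)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
    pwms = [_motif_to_pwm(m, pseudocount) for m in parsed]
    if not pwms:
        raise ValueError(f"no motifs in {path}")
    return pwms


def write_pwms_jaspar(pwms: list[PositionWeightMatrix], path: str | Path) -> None:
    """Write probability matrices in JASPAR PFM layout (values are
    frequencies, not counts)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for bi, b in enumerate("ACGT"):
                row = " ".join(f"{v:.6f}" for v in p.weights[:, bi])
                fh.write(f"{b} [ {row} ]\n")


# --- per-bp tracks ----------------------------------------------------------


def write_bedgraph(
    tracks: dict[str, np.ndarray], path: str | Path, precision: int = 6
) -> None:
    """Run-length-compressed bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, y in tracks.items():
            y = np.asarray(y, dtype=float)
            vals = np.round(y, precision)
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [y.size]])
            for a, b in zip(starts, ends):
                fh.write(f"{chrom}\t{a}\t{b}\t{vals[a]:.{precision}g}\n")


def read_bedgraph(
    path: str | Path,
    lengths: dict[str, int] | None = None,
    fill: float = 0.0,
) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome arrays.  Without `lengths` the
    array extends to the last covered position; uncovered gaps take `fill`."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, a, b, v = line.split()[:4]
            intervals.setdefault(chrom, []).append((int(a), int(b), float(v)))
    out = {}
    for chrom, ivs in intervals.items():
        L = lengths[chrom] if lengths else max(b for _, b, _ in ivs)
        y = np.full(L, fill)
        for a, b, v in ivs:
            y[a : min(b, L)] = v
        out[chrom] = y
    return out


def read_wig(
    path: str | Path, lengths: dict[str, int] | None = None, fill: float = 0.0
) -> dict[str, np.ndarray]:
    """Fixed-step wig reader (1-based starts, as the format defines)."""
    data: dict[str, list[tuple[int, int, list[float]]]] = {}
    chrom, start, step, vals = None, None, None, []
    def flush():
        if chrom is not None and vals:
            data.setdefault(chrom, []).append((start, step, list(vals)))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                flush()
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv["start"])
                step = int(kv.get("step", 1))
                vals = []
            else:
                vals.append(float(line))
    flush()
    out = {}
    for ch, blocks in data.items():
        need = max(s - 1 + st * len(v) for s, st, v in blocks)
        L = lengths[ch] if lengths else need
        y = np.full(L, fill)
        for s, st, v in blocks:
            pos = s - 1 + st * np.arange(len(v))
            keep = pos < L
            y[pos[keep]] = np.asarray(v)[keep]
        out[ch] = y
    return out


# --- intervals --------------------------------------------------------------


def write_ndr_bed(ndrs: dict[str, list[NDR]], path: str | Path) -> None:
    """BED with name, then length and center as extra columns."""
    with open(path, "w") as fh:
        i = 0
        for chrom, lst in ndrs.items():
            for n in lst:
                i += 1
                fh.write(
                    f"{chrom}\t{n.start}\t{n.end}\tNDR{i}\t{n.length}\t{n.center:.1f}\n"
                )


def read_ndr_bed(path: str | Path) -> dict[str, list[NDR]]:
    out: dict[str, list[NDR]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            chrom, a, b = parts[0], int(parts[1]), int(parts[2])
            length = int(parts[4]) if len(parts) > 4 else b - a
            center = float(parts[5]) if len(parts) > 5 else (a + b - 1) / 2
            out.setdefault(chrom, []).append(NDR(a, b, center, length))
    return out


def write_clusters_bed(
    clusters: dict[str, list[SiteCluster]], path: str | Path
) -> None:
    """Clusters as BED blocks: one line per cluster, member motifs as blocks."""
    with open(path, "w") as fh:
        i = 0
        for chrom, lst in clusters.items():
            for cl in lst:
                i += 1
                sizes = ",".join(str(s.length) for s in cl.sites)
                starts = ",".join(str(s.start - cl.start) for s in cl.sites)
                fh.write(
                    f"{chrom}\t{cl.start}\t{cl.end}\tcluster{i}\t{cl.count}\t."
                    f"\t{cl.start}\t{cl.end}\t0\t{cl.count}\t{sizes}\t{starts}\n"
                )


# --- parameters and reports -------------------------------------------------


def write_params_tsv(params: dict[str, float], path: str | Path) -> None:
    """Flat factor/parameter/value TSV ('<factor>.<kind>' keys split out)."""
    with open(path, "w") as fh:
        fh.write("factor\tparameter\tvalue\n")
        for key in sorted(params):
            name, kind = key.rsplit(".", 1)
            fh.write(f"{name}\t{kind}\t{params[key]:.10g}\n")


def read_params_tsv(path: str | Path) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            name, kind, value = line.rstrip("\n").split("\t")
            out[f"{name}.{kind}"] = float(value)
    return out


def write_report_tsv(report: dict, path: str | Path) -> None:
    """Flat metric/value TSV of an evaluation report's scalar fields."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, val in report.items():
            if isinstance(val, (int, float, np.floating, np.integer)):
                fh.write(f"{key}\t{val:.10g}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pwms",
    "write_pwms_jaspar",
    "write_bedgraph",
    "read_bedgraph",
    "read_wig",
    "write_ndr_bed",
    "read_ndr_bed",
    "write_clusters_bed",
    "write_params_tsv",
    "read_params_tsv",
    "write_report_tsv",
    "write_json",
]
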