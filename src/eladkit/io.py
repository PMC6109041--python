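"""Readers and writers for the plain-text interchange formats.

Every file uses 0-based half-open coordinates.  The dense Hi-C matrix
format is whitespace-delimited text with a JSON sidecar (``<path>.json``)
recording chromosome, resolution, and bin count.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Gene, GenomeModel
from .hic import ContactMatrix
from .signal import PeakSet, SignalTrack

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_matrix",
    "write_matrix",
    "read_expression",
    "write_expression",
    "write_peaks_bed",
    "write_fasta",
    "read_genes_bed",
]


def read_bed(path):
    """Parse BED3/4/6 into a list of (chrom, start, end[, name[, score, strand]])."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{ln}: end ≤ start")
            rec = [chrom, start, end]
            if len(parts) >= 4:
                rec.append(parts[3])
            if len(parts) >= 6:
                rec.extend([float(parts[4]), parts[5]])
                if parts[5] not in ("+", "-", "."):
                    raise ValueError(f"{path}:{ln}: bad strand {parts[5]!r}")
            records.append(tuple(rec))
    return records


def write_bed(path, records):
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(_fmt(v) for v in rec) + "\n")


def _fmt(v):
    if isinstance(v, float):
        return f"{v:g}"
    return str(v)


def read_genes_bed(path, chromosomes) -> GenomeModel:
    """Build a GenomeModel from a BED6 gene file plus chromosome sizes."""
    genes = []
    for rec in read_bed(path):
        if len(rec) < 6:
            raise ValueError("gene BED must have 6 columns (name, score, strand)")
        chrom, start, end, name, _, strand = rec[:6]
        tss = start if strand == "+" else end - 1
        genes.append(Gene(name, chrom, start, end, strand, tss))
    return GenomeModel(list(chromosomes), genes)


def write_peaks_bed(path, peaks: PeakSet):
    """Peaks as BED6; score column is min(1000, 10·score) MACS-style."""
    rows = []
    for i, p in enumerate(peaks.peaks):
        rows.append((p.chrom, p.start, p.end, f"{peaks.condition}_peak_{i}",
                     min(1000.0, 10.0 * p.score), "."))
    write_bed(path, rows)


def write_bedgraph(path, track: SignalTrack, chrom_lengths: dict[str, int] | None = None):
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom, vec in track.data.items():
            limit = chrom_lengths.get(chrom) if chrom_lengths else None
            for i, v in enumerate(vec):
                end = (i + 1) * bs
                if limit:
                    end = min(end, limit)
                fh.write(f"{chrom}\t{i * bs}\t{end}\t{_fmt(float(v))}\n")


def read_bedgraph(path, bin_size: int) -> SignalTrack:
    """Fixed-step bedGraph → SignalTrack; the declared bin size must match
    record spacing (last record of a chromosome may be truncated)."""
    data: dict[str, list] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            s, e, v = int(s), int(e), float(v)
            vec = data.setdefault(chrom, [])
            if s != len(vec) * bin_size:
                raise ValueError(f"{path}:{ln}: bin grid inconsistent with bin_size {bin_size}")
            if e - s > bin_size:
                raise ValueError(f"{path}:{ln}: record wider than bin_size")
            vec.append(v)
    return SignalTrack(bin_size, {c: np.asarray(v) for c, v in data.items()})


def write_matrix(path, m: ContactMatrix):
    path = Path(path)
    np.savetxt(path, m.matrix, fmt="%.8g")
    sidecar = {"chrom": m.chrom, "resolution": m.resolution,
               "n_bins": m.n_bins, "balanced": m.balanced}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_matrix(path, symmetry_tol: float = 1e-8) -> ContactMatrix:
    """Dense matrix + JSON sidecar.  Small asymmetries are symmetrized
    with a warning; large ones are an error."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape != (meta["n_bins"], meta["n_bins"]):
        raise ValueError("matrix shape disagrees with sidecar n_bins")
    scale = max(np.abs(mat).max(), 1.0)
    asym = np.abs(mat - mat.T).max() / scale
    if asym > 0:
        if asym <= max(symmetry_tol, 1e-8):
            warnings.warn("slightly asymmetric matrix: symmetrizing")
            mat = (mat + mat.T) / 2
        else:
            raise ValueError(f"matrix asymmetric (relative error {asym:.3g})")
    return ContactMatrix(meta["chrom"], meta["resolution"], mat,
                         balanced=bool(meta.get("balanced", False)))


def write_expression(path, expr: pd.DataFrame):
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path, genome: GenomeModel | None = None) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (expr < 0).any().any():
        raise ValueError("negative FPKM values")
    if genome is not None:
        known = {g.id for g in genome.genes}
        unknown = sorted(set(expr.index) - known)
        if unknown:
            raise ValueError(f"expression table contains unknown genes: {unknown[:5]}")
        missing = sorted(known - set(expr.index))
        if missing:
            raise ValueError(f"expression table missing genes: {missing[:5]}")
    return expr


def write_fasta(path, sequences: dict[str, str], width: int = 70):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
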