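"""Readers and writers for the pipeline's tabular interchange formats.

All formats are plain text: genotypes as a strain x SNP TSV with a
``#chrom``/``#pos`` header block, abundance as a sample x taxon TSV with a
two-row taxonomy header (OTU id, family), tracking profiles as per-mouse
CSV (t_s, area_fraction, x_mm, y_mm), gene models as BED-like four-column
files, human GWAS gene lists as one symbol per line, and ground truth /
run reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TrackingProfile
from .genassoc import GenotypeMatrix

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_abundance",
    "read_abundance",
    "write_profile",
    "read_profile",
    "write_genes_bed",
    "read_genes_bed",
    "write_gene_list",
    "read_gene_list",
    "write_json",
    "read_json",
]


def write_genotypes(G: GenotypeMatrix, path) -> None:
    path = Path(path)
    chars = G.allele_chars()
    with path.open("w") as fh:
        fh.write("#chrom\t" + "\t".join(map(str, G.chrom)) + "\n")
        fh.write("#pos\t" + "\t".join(map(str, G.pos)) + "\n")
        fh.write("strain\t" + "\t".join(map(str, G.snp_ids)) + "\n")
        for i, s in enumerate(G.strains):
            fh.write(s + "\t" + "\t".join(chars[i]) + "\n")


def read_genotypes(path) -> GenotypeMatrix:
    path = Path(path)
    with path.open() as fh:
        chrom_line = fh.readline().rstrip("\n").split("\t")
        pos_line = fh.readline().rstrip("\n").split("\t")
        if chrom_line[0] != "#chrom" or pos_line[0] != "#pos":
            raise ValueError(f"{path}: expected #chrom/#pos header block")
        header = fh.readline().rstrip("\n").split("\t")
        snp_ids = np.array(header[1:])
        strains, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            strains.append(parts[0])
            rows.append(parts[1:])
    alleles = GenotypeMatrix.codes_from_chars(np.array(rows))
    return GenotypeMatrix(
        alleles=alleles,
        strains=strains,
        snp_ids=snp_ids,
        chrom=np.array(chrom_line[1:]),
        pos=np.array(pos_line[1:], dtype=np.int64),
    )


def write_abundance(table: pd.DataFrame, taxonomy: pd.Series, path) -> None:
    path = Path(path)
    fams = taxonomy.reindex(table.columns)
    with path.open("w") as fh:
        fh.write("otu\t" + "\t".join(map(str, table.columns)) + "\n")
        fh.write("family\t" + "\t".join(map(str, fams)) + "\n")
        for sid, row in table.iterrows():
            fh.write(str(sid) + "\t" + "\t".join(f"{v:.10g}" for v in row.to_numpy()) + "\n")


def read_abundance(path) -> tuple[pd.DataFrame, pd.Series]:
    path = Path(path)
    with path.open() as fh:
        otus = fh.readline().rstrip("\n").split("\t")[1:]
        fams = fh.readline().rstrip("\n").split("\t")[1:]
        samples, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            samples.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    table = pd.DataFrame(rows, index=samples, columns=otus)
    taxonomy = pd.Series(fams, index=otus, name="family")
    return table, taxonomy


def write_profile(profile: TrackingProfile, path) -> None:
    df = pd.DataFrame(
        {
            "t_s": profile.t,
            "area_fraction": profile.area_fraction,
            "x_mm": profile.x,
            "y_mm": profile.y,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_profile(path, frame_rate: float | None = None, mouse_id: str = "") -> TrackingProfile:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    if frame_rate is None:
        if t.size < 2:
            raise ValueError("cannot infer frame rate from a single frame")
        frame_rate = (t.size - 1) / (t[-1] - t[0])
    # rebuild the exact uniform grid: written time stamps are rounded
    t = np.arange(t.size) / frame_rate
    return TrackingProfile(
        t=t,
        area_fraction=df["area_fraction"].to_numpy(dtype=float),
        x=df["x_mm"].to_numpy(dtype=float),
        y=df["y_mm"].to_numpy(dtype=float),
        frame_rate=float(frame_rate),
        mouse_id=mouse_id,
    )


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """Write gene models as BED4 (0-based half-open, name in column 4)."""
    out = genes.copy()
    out["bed_start"] = out["start"] - 1  # internal 1-based inclusive -> BED
    out[["chrom", "bed_start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path, zero_based: bool = True) -> pd.DataFrame:
    """Load BED-like gene models to internal 1-based inclusive intervals.

    With ``zero_based`` (standard BED), start is incremented by one; the
    (exclusive) BED end already equals the 1-based inclusive end.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    if zero_based:
        df["start"] = df["start"] + 1
    bad = df["start"] > df["end"]
    if bad.any():
        raise ValueError(f"malformed gene interval: {df.loc[bad, 'name'].iloc[0]}")
    return df[["name", "chrom", "start", "end"]]


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
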