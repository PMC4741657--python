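"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular interchange is TSV.  Panel regions are BED (0-based, half-open)
with the region name encoding ``gene:exon``; genomic sites in count tables
are 1-based.  Gene sets are GMT.  Everything round-trips through pandas.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

#: Required columns of a site-count table.  ``ref`` / ``alt`` allele columns
#: are optional and preserved when present.
SITE_COLUMNS = ["chrom", "pos", "ref_count", "alt_count", "sample_id", "role"]

#: Columns of an exon-depth table.
EXON_DEPTH_COLUMNS = ["gene", "exon", "chrom", "start", "end", "mean_depth", "sample_id"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a panel BED file into a region table.

    The BED ``name`` field is expected to be ``gene:exon`` (exon index
    integer); a bare gene name is accepted and given exon index 0.
    Returns a DataFrame with columns chrom, start, end, gene, exon.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    split = df["name"].str.split(":", n=1, expand=True)
    df["gene"] = split[0]
    df["exon"] = pd.to_numeric(split[1], errors="coerce").fillna(0).astype(int)
    return df[["chrom", "start", "end", "gene", "exon"]]


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    out = regions.copy()
    out["name"] = out["gene"].astype(str) + ":" + out["exon"].astype(str)
    out[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def read_site_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str, "role": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site-count table {path} lacks columns: {missing}")
    return df


def write_site_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_exon_depths(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "sample_id": str})
    missing = [c for c in ("gene", "exon", "mean_depth", "sample_id") if c not in df.columns]
    if missing:
        raise ValueError(f"exon-depth table {path} lacks columns: {missing}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene name)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated genes in expression matrix: {dupes}")
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def bundled_path(name: str) -> Path:
    """Path to a data file bundled with the package (``her2seq/data``)."""
    return Path(importlib.resources.files("her2seq") / "data" / name)
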