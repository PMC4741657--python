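"""Low-frequency variant calling from tumour/normal site-level read counts.

A *site count* is the pileup at one genomic position: ``a`` reads supporting
the alternate allele and ``r`` supporting the reference, so the variant
allele fraction (VAF) is ``a / (a + r)``.  Calling is a one-sided exact
binomial test of the alternate count against a per-base sequencing error
rate, which is transparent and well calibrated at the 0.2-2% allele
fractions and 1,000-25,000x depths a hybrid-capture panel produces.
Germline events are removed with the patient's matched blood sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ERROR_RATE = 1e-3
DEFAULT_MIN_ALT = 5
DEFAULT_ALPHA = 1e-6
DEFAULT_NORMAL_VAF_MAX = 0.01
DEFAULT_NORMAL_ALT_MAX = 3


@dataclass(frozen=True)
class CoverageSummary:
    """Depth QC over a set of sites: mean depth and the fraction of sites
    covered at or above a threshold (default 100x)."""

    mean_depth: float
    frac_ge_threshold: float
    threshold: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_ge_threshold <= 1.0:
            raise ValueError("frac_ge_threshold must lie in [0, 1]")


def compute_vaf(a, r):
    """Variant allele fraction a/(a+r).

    Accepts scalars or arrays.  Multiplying by 100 gives the percentage
    form.  Raises on an uncovered site (a + r == 0).
    """
    a = np.asarray(a, dtype=float)
    r = np.asarray(r, dtype=float)
    depth = a + r
    if np.any(depth <= 0):
        raise ValueError("uncovered site: a + r must be positive")
    out = a / depth
    return out.item() if out.ndim == 0 else out


def call_variants(
    counts: pd.DataFrame,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_alt: int = DEFAULT_MIN_ALT,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Call candidate variants from a tumour site-count table.

    A site is a candidate iff ``alt_count >= min_alt`` and the upper
    binomial tail ``P[X >= a | n = a + r, p = error_rate]`` is below
    ``alpha``.  Returns the candidate rows with ``vaf``, ``depth``,
    ``p_value`` and ``status='candidate'`` attached.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    if min_alt < 1:
        raise ValueError("min_alt must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    a = counts["alt_count"].to_numpy()
    d = a + counts["ref_count"].to_numpy()
    covered = d > 0
    # sf(a-1) is the inclusive upper tail P[X >= a]
    pvals = np.ones(len(counts))
    pvals[covered] = stats.binom.sf(a[covered] - 1, d[covered], error_rate)
    keep = covered & (a >= min_alt) & (pvals < alpha)

    calls = counts.loc[keep].copy()
    calls["depth"] = d[keep]
    calls["vaf"] = a[keep] / d[keep]
    calls["p_value"] = pvals[keep]
    calls["status"] = "candidate"
    return calls.reset_index(drop=True)


def filter_germline(
    tumour_calls: pd.DataFrame,
    normal_counts: pd.DataFrame,
    normal_vaf_max: float = DEFAULT_NORMAL_VAF_MAX,
    normal_alt_max: int = DEFAULT_NORMAL_ALT_MAX,
) -> pd.DataFrame:
    """Flag germline events using the matched normal sample.

    A call is ``germline_filtered`` iff its matched-normal VAF is at or
    above ``normal_vaf_max`` AND the normal alternate count is at or above
    ``normal_alt_max`` (both thresholds inclusive); surviving calls are
    marked ``somatic``.  Tumour and normal are paired by ``sample_id``;
    a tumour sample without any normal rows raises a ValueError naming it.
    Sites absent from the normal table are treated as having zero normal
    coverage (somatic).
    """
    normals = normal_counts[normal_counts["role"] == "normal"]
    out = tumour_calls.copy()
    if out.empty:
        out["status"] = pd.Series(dtype=str)
        return out

    normal_samples = set(normals["sample_id"].unique())
    for sid in out["sample_id"].unique():
        if sid not in normal_samples:
            raise ValueError(f"no matched normal counts for sample {sid!r}")

    ndepth = normals["alt_count"] + normals["ref_count"]
    nvaf = np.where(ndepth > 0, normals["alt_count"] / ndepth.where(ndepth > 0, 1), 0.0)
    lookup = normals[["sample_id", "chrom", "pos", "alt_count"]].copy()
    lookup["normal_vaf"] = nvaf
    lookup = lookup.rename(columns={"alt_count": "normal_alt"})

    merged = out.merge(lookup, on=["sample_id", "chrom", "pos"], how="left")
    merged["normal_alt"] = merged["normal_alt"].fillna(0).astype(int)
    merged["normal_vaf"] = merged["normal_vaf"].fillna(0.0)
    germline = (merged["normal_vaf"] >= normal_vaf_max) & (
        merged["normal_alt"] >= normal_alt_max
    )
    merged["status"] = np.where(germline, "germline_filtered", "somatic")
    return merged


def coverage_qc(depths, threshold: int = 100) -> CoverageSummary:
    """Mean depth and fraction of sites at/above ``threshold``."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("coverage_qc requires a non-empty depth list")
    return CoverageSummary(
        mean_depth=float(depths.mean()),
        frac_ge_threshold=float((depths >= threshold).mean()),
        threshold=threshold,
    )


def write_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls as a minimal VCF 4.2 with VAF/DP/PV INFO tags.

    Positions are 1-based.  Calls with status ``germline_filtered`` get
    FILTER ``germline``; everything else is PASS.  ``ref``/``alt`` allele
    columns are used when present, otherwise placeholder ``N``/``<ALT>``.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">',
        '##INFO=<ID=PV,Number=1,Type=Float,Description="Binomial tail p-value">',
        '##FILTER=<ID=germline,Description="Present in matched normal">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for _, row in calls.iterrows():
        ref = row.get("ref", "N") or "N"
        alt = row.get("alt", "<ALT>") or "<ALT>"
        filt = "germline" if row.get("status") == "germline_filtered" else "PASS"
        info = f"VAF={row['vaf']:.6g};DP={int(row['depth'])};PV={row['p_value']:.6g}"
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
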