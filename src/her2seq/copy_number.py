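"""Depth-ratio copy-number estimation against a panel of normals.

Per-exon mean depths are normalized within each sample by its total
on-target depth (removing library-size effects), a per-exon reference is
taken as the median across the normal samples, and tumour/reference ratios
are re-centred by their panel-wide median so that the diploid background
sits at ratio 1 even when a highly amplified gene inflates the tumour's
total depth.  The gene-level amplification value is reported on a
copy-number scale, A = 2 x median(exon ratios), so a diploid gene reads 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_AMP_THRESHOLD = 3.0


@dataclass(frozen=True)
class AmplificationResult:
    gene: str
    exon_ratios: list = field(repr=False)
    amplification_value: float = 0.0
    amplified: bool = False


def _normalize_by_total(depths: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's exon depths by its total on-target depth."""
    out = depths.copy()
    totals = out.groupby("sample_id")["mean_depth"].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, "sample_id"].unique().tolist()
        raise ValueError(f"samples with zero total on-target depth: {bad}")
    out["norm_depth"] = out["mean_depth"] / totals
    return out


def build_normal_reference(normal_depths: pd.DataFrame) -> pd.Series:
    """Per-exon expected (normalized) depth from a panel of normals.

    Each normal is first normalized by its total on-target depth; the
    reference is the per-exon median across normals.  Requires at least
    three normal samples and at least one covered normal per exon.
    """
    n_samples = normal_depths["sample_id"].nunique()
    if n_samples < 3:
        raise ValueError(f"panel of normals needs >= 3 samples, got {n_samples}")
    norm = _normalize_by_total(normal_depths)
    wide = norm.pivot_table(
        index=["gene", "exon"], columns="sample_id", values="norm_depth"
    )
    reference = wide.median(axis=1)
    dead = reference.index[(wide.fillna(0) == 0).all(axis=1)].tolist()
    if dead:
        raise ValueError(f"exons with zero depth in all normals: {dead}")
    reference.name = "ref_depth"
    return reference


def exon_ratios(
    tumour_depths: pd.DataFrame,
    reference: pd.Series,
    recenter: bool = True,
) -> pd.DataFrame:
    """Tumour/reference depth ratio per exon.

    The tumour is normalized by its own total on-target depth, divided by
    the reference, and (by default) re-centred by the median of per-gene
    median ratios.  Re-centring pins the copy-neutral background at ratio
    1; without it a strong amplification drags every other exon's ratio
    below 1 because it inflates the tumour's total depth.  The centre is
    taken over genes rather than exons because amplification is a
    gene-level event: a heavily amplified multi-exon gene can contribute
    a large fraction of panel *exons* while still being one of few
    affected *genes*.  Assumes most panel genes are copy-neutral.
    """
    norm = _normalize_by_total(tumour_depths)
    norm = norm.set_index(["gene", "exon"])
    missing = reference.index.difference(norm.index)
    if len(missing):
        raise ValueError(f"tumour lacks depth for panel exons: {list(missing)[:5]}")
    ref = reference.reindex(norm.index)
    if ref.isna().any() or (ref <= 0).any():
        bad = norm.index[ref.isna() | (ref <= 0)].tolist()
        raise ValueError(f"reference depth missing or zero for exons: {bad[:5]}")
    ratios = norm["norm_depth"] / ref
    if recenter:
        centre = ratios.groupby(level="gene").median().median()
        if centre <= 0:
            raise ValueError("cannot re-centre: median gene ratio is zero")
        ratios = ratios / centre
    out = norm.reset_index()[["gene", "exon"]]
    out["ratio"] = ratios.to_numpy()
    return out


def gene_amplification_value(ratios, summary: str = "median") -> float:
    """Gene amplification value A = 2 x median(exon ratios).

    ``summary='mean'`` is available for panels where single-exon dropout
    is not a concern; the default median is robust to it.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("gene_amplification_value requires >= 1 exon ratio")
    if summary == "median":
        centre = float(np.median(ratios))
    elif summary == "mean":
        centre = float(np.mean(ratios))
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return 2.0 * centre


def call_amplification(amplification_value: float, threshold: float = DEFAULT_AMP_THRESHOLD) -> bool:
    """Amplified iff A >= threshold (inclusive). Diploid is A = 2."""
    if amplification_value < 0:
        raise ValueError("amplification value must be >= 0")
    return bool(amplification_value >= threshold)


def amplification_table(
    tumour_depths: pd.DataFrame,
    reference: pd.Series,
    threshold: float = DEFAULT_AMP_THRESHOLD,
    summary: str = "median",
) -> pd.DataFrame:
    """Per-gene amplification values and calls for one tumour sample."""
    ratios = exon_ratios(tumour_depths, reference)
    rows = []
    for gene, grp in ratios.groupby("gene", sort=True):
        a = gene_amplification_value(grp["ratio"], summary=summary)
        rows.append(
            {
                "gene": gene,
                "n_exons": len(grp),
                "amplification_value": a,
                "amplified": call_amplification(a, threshold),
            }
        )
    return pd.DataFrame(rows)


def exon_depths_from_sites(site_counts: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Mean per-exon depth from a site-count table and a panel region table.

    Sites are 1-based; panel intervals are 0-based half-open, so position
    ``p`` falls in ``[start, end)`` iff ``start < p <= end``.
    """
    sc = site_counts.copy()
    sc["depth"] = sc["alt_count"] + sc["ref_count"]
    rows = []
    for _, region in panel.iterrows():
        mask = (
            (sc["chrom"] == region["chrom"])
            & (sc["pos"] > region["start"])
            & (sc["pos"] <= region["end"])
        )
        sub = sc.loc[mask]
        for sid, grp in sub.groupby("sample_id"):
            rows.append(
                {
                    "gene": region["gene"],
                    "exon": region["exon"],
                    "chrom": region["chrom"],
                    "start": region["start"],
                    "end": region["end"],
                    "mean_depth": grp["depth"].mean(),
                    "sample_id": sid,
                }
            )
    return pd.DataFrame(rows)
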