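"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three data modalities the pipeline consumes:

* ``simulate_panel`` -- tumour/matched-normal site-count tables over a
  capture panel.  Per-exon depth is negative-binomial (overdispersed, as
  capture panels are) around ``depth_mean``, scaled by copy-number/2 in
  the tumour; alternate counts are binomial with spiked variant allele
  fractions, a per-base error rate at background sites, and ~0.5 VAF
  germline heterozygous sites present in both members of a pair.
* ``simulate_dpcr_chip`` -- Poisson loading of a ~20,000-well digital-PCR
  chip at given mutant (FAM) and wild-type (VIC) concentrations.
* ``simulate_expression`` -- normal-reference and tumour expression
  matrices where the HER2 gene tracks copy number linearly, pathway genes
  are shifted down in mutated samples (with an extra shift on a
  designated GRB2-like gene), and an optional location-scale batch effect
  distorts the tumour batch.

Every generator takes one explicit seed and touches no global state, so
identical arguments reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from her2seq.dpcr import DEFAULT_PARTITION_VOLUME_NL, DpcrChipResult

DEFAULT_DEPTH_MEAN = 941.3  # study-scale mean panel coverage
# NB2 overdispersion of per-exon depth (var = m + a*m^2): a = 0.02 gives a
# ~14% depth CV at panel-scale coverage, typical of normalized
# hybrid-capture exon depths and well above Poisson noise.
DEFAULT_DISPERSION = 0.02
DEFAULT_ERROR_RATE = 1e-3
DEFAULT_GERMLINE_HET_PER_KB = 1.0


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset (parameter-recovery key)."""

    variants: list = field(default_factory=list)  # [(site, true VAF fraction)]
    copy_events: list = field(default_factory=list)  # [(gene, true copy number)]
    dpcr_truth: tuple | None = None  # (mutant copies/ul, wild-type copies/ul)
    expression_effects: dict = field(default_factory=dict)  # gene -> SD shift
    seed: int | None = None

    def __post_init__(self) -> None:
        for site, vaf in self.variants:
            if not 0.0 < vaf < 1.0:
                raise ValueError(f"true VAF must lie in (0, 1): {site} -> {vaf}")
        for gene, cn in self.copy_events:
            if cn <= 0:
                raise ValueError(f"true copy number must be positive: {gene} -> {cn}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variants": [[list(site), vaf] for site, vaf in self.variants],
            "copy_events": [[gene, cn] for gene, cn in self.copy_events],
            "dpcr_truth": list(self.dpcr_truth) if self.dpcr_truth else None,
            "expression_effects": self.expression_effects,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            variants=[(tuple(site), vaf) for site, vaf in payload["variants"]],
            copy_events=[(gene, cn) for gene, cn in payload["copy_events"]],
            dpcr_truth=tuple(payload["dpcr_truth"]) if payload["dpcr_truth"] else None,
            expression_effects=payload["expression_effects"],
            seed=payload["seed"],
        )


def make_panel(
    n_genes: int = 20,
    exons_per_gene: int = 8,
    exon_length: int = 120,
    gap: int = 500,
    chrom: str = "chr17",
    gene_names: list[str] | None = None,
    exons_per_gene_map: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Lay out a synthetic capture panel as a BED-style region table.

    Genes are tiled along one chromosome with ``exon_length``-bp exons
    separated by ``gap`` bp.  ``exons_per_gene_map`` overrides the exon
    count for named genes (large genes carry many more exons than small
    ones, which matters for copy-number precision).
    """
    if gene_names is None:
        gene_names = [f"GENE{i:03d}" for i in range(n_genes)]
    rows = []
    cursor = 10_000
    for gene in gene_names:
        n_ex = (exons_per_gene_map or {}).get(gene, exons_per_gene)
        for exon in range(n_ex):
            rows.append(
                {
                    "chrom": chrom,
                    "start": cursor,
                    "end": cursor + exon_length,
                    "gene": gene,
                    "exon": exon,
                }
            )
            cursor += exon_length + gap
    return pd.DataFrame(rows)


def _draw_depths(rng, mean, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial depths with var = m + dispersion * m^2.

    ``dispersion=0`` degenerates to a fixed depth of round(mean), which
    gives exactly binomial alternate counts for oracle cross-checks.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if dispersion == 0:
        return np.maximum(np.rint(mean).astype(int), 0)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_panel(
    regions: pd.DataFrame,
    pairs: int = 1,
    spikes: list[tuple[tuple, float]] | None = None,
    copy_events: list[tuple[str, float]] | None = None,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    error_rate: float = DEFAULT_ERROR_RATE,
    dispersion: float = DEFAULT_DISPERSION,
    germline_het_per_kb: float = DEFAULT_GERMLINE_HET_PER_KB,
    site_spacing: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate tumour/matched-normal site counts over a capture panel.

    ``spikes`` is a list of ``((chrom, pos), vaf)`` somatic variants
    present in the tumour only; ``copy_events`` scales tumour depth of the
    named genes by copy-number/2.  Sites are placed every ``site_spacing``
    bp within each region (1-based positions).  Germline heterozygous
    sites (about ``germline_het_per_kb`` per kb of panel) appear at ~0.5
    VAF in both members of each pair.

    Returns (tumour counts, normal counts, truth); alt + ref always equals
    the drawn depth at every site.
    """
    if regions.empty:
        raise ValueError("panel regions must be non-empty")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    spikes = list(spikes or [])
    copy_events = list(copy_events or [])
    for site, vaf in spikes:
        if vaf <= error_rate:
            raise ValueError(
                f"spiked VAF {vaf} at {site} is not above the error rate "
                f"{error_rate}: undetectable by construction"
            )

    rng = np.random.default_rng(seed)
    cn_by_gene = dict(copy_events)

    # enumerate sites (1-based) per exon
    site_rows = []
    for _, reg in regions.iterrows():
        positions = np.arange(reg["start"] + 1, reg["end"] + 1, site_spacing)
        cn = cn_by_gene.get(reg["gene"], 2.0)
        for pos in positions:
            site_rows.append((reg["chrom"], int(pos), cn))
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "copy_number"])
    sites = sites.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    n_sites = len(sites)

    spike_map = {tuple(site): vaf for site, vaf in spikes}
    spike_vaf = np.array(
        [spike_map.get((c, p), 0.0) for c, p in zip(sites["chrom"], sites["pos"])]
    )
    panel_bp = int((regions["end"] - regions["start"]).sum())
    n_het = int(round(panel_bp / 1000.0 * germline_het_per_kb))

    tumour_frames, normal_frames = [], []
    truth_variants = [(site, vaf) for site, vaf in spikes]
    for pair_idx in range(pairs):
        het_idx = (
            rng.choice(n_sites, size=min(n_het, n_sites), replace=False)
            if n_het > 0
            else np.array([], dtype=int)
        )
        is_het = np.zeros(n_sites, dtype=bool)
        is_het[het_idx] = True

        for role in ("tumour", "normal"):
            mean = depth_mean * (sites["copy_number"] / 2.0 if role == "tumour" else 1.0)
            depth = _draw_depths(rng, mean, dispersion, n_sites)
            p_alt = np.full(n_sites, error_rate)
            if role == "tumour":
                spiked = spike_vaf > 0
                p_alt[spiked] = spike_vaf[spiked] + (1 - spike_vaf[spiked]) * error_rate
            p_alt[is_het] = 0.5
            alt = rng.binomial(depth, p_alt)
            frame = pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "pos": sites["pos"],
                    "ref_count": depth - alt,
                    "alt_count": alt,
                    "sample_id": f"P{pair_idx:03d}",
                    "role": role,
                }
            )
            (tumour_frames if role == "tumour" else normal_frames).append(frame)

    truth = SimTruth(
        variants=truth_variants,
        copy_events=copy_events,
        seed=seed,
    )
    return (
        pd.concat(tumour_frames, ignore_index=True),
        pd.concat(normal_frames, ignore_index=True),
        truth,
    )


def simulate_exon_depths(
    regions: pd.DataFrame,
    sample_ids: list[str],
    role: str = "normal",
    copy_events: list[tuple[str, float]] | None = None,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-exon mean depths directly (no site-level detail).

    Tumour samples (``role='tumour'``) scale the named genes' expected
    depth by copy-number/2; normals ignore ``copy_events``.  This is the
    fast path for exercising the copy-number stage.
    """
    if regions.empty:
        raise ValueError("panel regions must be non-empty")
    rng = np.random.default_rng(seed)
    cn_by_gene = dict(copy_events or [])
    frames = []
    for sid in sample_ids:
        if role == "tumour":
            mean = depth_mean * regions["gene"].map(
                lambda g: cn_by_gene.get(g, 2.0) / 2.0
            )
        else:
            mean = np.full(len(regions), depth_mean)
        depth = _draw_depths(rng, mean, dispersion, len(regions))
        frame = regions[["gene", "exon", "chrom", "start", "end"]].copy()
        frame["mean_depth"] = depth.astype(float)
        frame["sample_id"] = sid
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_dpcr_chip(
    mutant_conc: float,
    wildtype_conc: float,
    n_partitions: int = 20_000,
    partition_volume_nl: float = DEFAULT_PARTITION_VOLUME_NL,
    dilution: float = 1.0,
    seed: int = 0,
) -> tuple[DpcrChipResult, SimTruth]:
    """Simulate one dual-dye digital-PCR chip.

    Concentrations are copies/ul of the loaded (already diluted) reaction.
    Each dye's positive-partition count is Binomial(n, 1 - exp(-lambda))
    with lambda = conc x partition volume (in ul) / dilution, i.e. the
    Poisson probability that a well holds at least one template molecule.
    """
    if mutant_conc < 0 or wildtype_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if n_partitions <= 0:
        raise ValueError("n_partitions must be positive")
    if partition_volume_nl <= 0:
        raise ValueError("partition volume must be positive")
    rng = np.random.default_rng(seed)
    v_ul = partition_volume_nl * 1e-3
    lam_fam = mutant_conc * v_ul / dilution
    lam_vic = wildtype_conc * v_ul / dilution
    k_fam = int(rng.binomial(n_partitions, -np.expm1(-lam_fam)))
    k_vic = int(rng.binomial(n_partitions, -np.expm1(-lam_vic)))
    chip = DpcrChipResult(
        n_partitions=n_partitions,
        k_fam=k_fam,
        k_vic=k_vic,
        partition_volume_nl=partition_volume_nl,
        dilution=dilution,
    )
    truth = SimTruth(dpcr_truth=(mutant_conc, wildtype_conc), seed=seed)
    return chip, truth


def simulate_expression(
    geneset: list[str],
    n_normals: int = 61,
    n_wild: int = 7,
    n_mutated: int = 4,
    pathway_effect: float = -0.5,
    grb2_extra: float = -1.5,
    batch_shift: tuple[float, float] = (0.0, 1.0),
    copy_numbers: np.ndarray | None = None,
    noise_sd: float = 0.5,
    her2_gene: str = "ERBB2",
    her2_slope: float = 0.5,
    grb2_gene: str | None = None,
    n_background_genes: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate normal-reference and tumour expression matrices.

    Shifts are signed and in units of each gene's normal-tissue SD:
    mutated samples add ``pathway_effect`` to every gene-set gene and
    ``pathway_effect + grb2_extra`` to the designated GRB2-like gene
    (the first gene of the set unless ``grb2_gene`` names one).  The HER2
    gene's expression is ``baseline + her2_slope x copy number + noise``.
    ``batch_shift=(loc, scale)`` maps every tumour value x to
    ``loc + scale * x``; the default group sizes (4 mutated vs 7 wild
    among 11 amplified tumours, 61 normals) mirror the study design.

    Returns ``(tumour expr, sample annotations, normal expr, truth)``.
    """
    if min(n_normals, n_wild, n_mutated) < 1:
        raise ValueError("all group sizes must be >= 1")
    if n_normals < 2:
        raise ValueError("need >= 2 normals to estimate a reference SD")
    if not all(np.isfinite([pathway_effect, grb2_extra, *batch_shift])):
        raise ValueError("effects and batch shift must be finite")
    geneset = list(geneset)
    if not geneset:
        raise ValueError("geneset must be non-empty")
    grb2_gene = grb2_gene or geneset[0]
    if grb2_gene not in geneset:
        raise ValueError(f"designated GRB2-like gene {grb2_gene!r} not in gene set")

    rng = np.random.default_rng(seed)
    background = [f"BG{i:04d}" for i in range(n_background_genes)]
    genes = list(dict.fromkeys([*geneset, her2_gene, *background]))
    n_genes = len(genes)
    mu = rng.uniform(5.0, 12.0, n_genes)
    sigma = rng.uniform(0.5, 2.0, n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    normal_ids = [f"N{i:03d}" for i in range(n_normals)]
    normals = mu[:, None] + sigma[:, None] * rng.standard_normal((n_genes, n_normals))
    normals_df = pd.DataFrame(normals, index=genes, columns=normal_ids)

    n_tumour = n_wild + n_mutated
    tumour_ids = [f"T{i:03d}" for i in range(n_tumour)]
    mutated_mask = np.array([i < n_mutated for i in range(n_tumour)])
    if copy_numbers is None:
        copy_numbers = rng.uniform(3.0, 30.0, n_tumour)
    copy_numbers = np.asarray(copy_numbers, dtype=float)
    if copy_numbers.shape != (n_tumour,):
        raise ValueError("copy_numbers must have one value per tumour sample")

    expr = mu[:, None] + noise_sd * sigma[:, None] * rng.standard_normal(
        (n_genes, n_tumour)
    )
    hi = gene_idx[her2_gene]
    expr[hi, :] = (
        mu[hi]
        + her2_slope * copy_numbers
        + noise_sd * sigma[hi] * rng.standard_normal(n_tumour)
    )
    effects = {g: pathway_effect for g in geneset}
    effects[grb2_gene] = pathway_effect + grb2_extra
    for g, shift in effects.items():
        gi = gene_idx[g]
        expr[gi, mutated_mask] += shift * sigma[gi]

    loc, scale = batch_shift
    expr = loc + scale * expr
    expr_df = pd.DataFrame(expr, index=genes, columns=tumour_ids)
    annot = pd.DataFrame(
        {
            "sample_id": tumour_ids,
            "batch": "tumour",
            "group": np.where(mutated_mask, "mutated", "wild"),
            "copy_number": copy_numbers,
            "her2_mutant": mutated_mask,
        }
    ).set_index("sample_id")
    truth = SimTruth(expression_effects=effects, seed=seed)
    return expr_df, annot, normals_df, truth
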