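"""End-to-end parameter-recovery experiments.

Each function simulates data with the :mod:`her2seq.simdata` generators,
runs the corresponding analysis stage and measures how well the known
ground truth is recovered.  They back both the validation test suite and
the reproduction script, so the experiment definitions live in one place.
All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from her2seq import copy_number as cnv
from her2seq import pathway, simdata, variants
from her2seq.dpcr import DEFAULT_PARTITION_VOLUME_NL


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def caller_operating_characteristics(
    seed: int,
    n_null_sites: int = 120_000,
    null_depth: float = 1000.0,
    spike_depth: float = 5000.0,
    n_spiked: int = 500,
    spike_vaf: float = 0.01,
    error_rate: float = 1e-3,
    min_alt: int = 5,
    alpha: float = 1e-6,
) -> dict:
    """False-positive rate on null sites and power on spiked sites.

    The null panel carries no variants, so every call is a false positive;
    the binomial test is calibrated when the called fraction is consistent
    with ``alpha``.  Power is measured at fixed depth (zero depth
    dispersion) so the exact binomial oracle predicts it in closed form:
    detection happens iff the alternate count reaches the smallest value
    that clears both the ``min_alt`` floor and the tail-probability cut.
    """
    s_null, s_spike = _child_seeds(seed, 2)

    # enough 100-bp exons to reach the requested number of null sites
    n_exons = int(np.ceil(n_null_sites / 100))
    null_panel = simdata.make_panel(
        n_genes=max(1, n_exons // 20), exons_per_gene=20, exon_length=100
    )
    tumour, _, _ = simdata.simulate_panel(
        null_panel,
        depth_mean=null_depth,
        error_rate=error_rate,
        germline_het_per_kb=0.0,
        seed=s_null,
    )
    tumour = tumour.iloc[:n_null_sites]
    null_calls = variants.call_variants(
        tumour, error_rate=error_rate, min_alt=min_alt, alpha=alpha
    )
    fp_fraction = len(null_calls) / len(tumour)

    spike_panel = simdata.make_panel(
        n_genes=1, exons_per_gene=max(1, n_spiked // 100), exon_length=100
    )
    positions = [
        ("chr17", int(r["start"]) + 1 + i)
        for _, r in spike_panel.iterrows()
        for i in range(100)
    ][:n_spiked]
    spiked_tumour, _, _ = simdata.simulate_panel(
        spike_panel,
        spikes=[(p, spike_vaf) for p in positions],
        depth_mean=spike_depth,
        error_rate=error_rate,
        dispersion=0.0,  # fixed depth -> exact binomial oracle applies
        germline_het_per_kb=0.0,
        seed=s_spike,
    )
    spike_calls = variants.call_variants(
        spiked_tumour, error_rate=error_rate, min_alt=min_alt, alpha=alpha
    )
    power = len(spike_calls) / n_spiked

    # closed-form oracle at the fixed depth
    depth = int(round(spike_depth))
    a_star = min_alt
    while stats.binom.sf(a_star - 1, depth, error_rate) >= alpha:
        a_star += 1
    p_eff = spike_vaf + (1 - spike_vaf) * error_rate
    oracle_power = float(stats.binom.sf(a_star - 1, depth, p_eff))

    return {
        "n_null_sites": len(tumour),
        "false_positives": len(null_calls),
        "fp_fraction": fp_fraction,
        "n_spiked": n_spiked,
        "power": power,
        "oracle_power": oracle_power,
        "detection_threshold": a_star,
    }


def cnv_recovery(
    seed: int,
    copy_numbers: tuple[float, ...] = (3.99, 5.39, 14.53, 30.13),
    n_replicates: int = 100,
    depth_mean: float = 1000.0,
    n_normals: int = 20,
    tolerance: float = 0.15,
) -> dict:
    """Recovery of gene-level amplification values from simulated panels.

    For each true copy number, ``n_replicates`` tumours are simulated on a
    panel whose amplified gene has 27 exons (ERBB2-sized) over a 20-gene
    diploid background, each against a fresh 20-normal reference.  Reports
    the fraction of replicates whose estimate lands within ``tolerance``
    of truth, and the median background (diploid) amplification value.
    """
    panel = simdata.make_panel(
        n_genes=21,
        exons_per_gene=8,
        gene_names=["ERBB2"] + [f"BG{i:02d}" for i in range(20)],
        exons_per_gene_map={"ERBB2": 27},
    )
    normal_ids = [f"N{i}" for i in range(n_normals)]
    seeds = _child_seeds(seed, 2 * n_replicates * len(copy_numbers))
    seed_iter = iter(seeds)

    recovery = {}
    diploid_values = []
    for cn_true in copy_numbers:
        estimates = []
        for _ in range(n_replicates):
            normals = simdata.simulate_exon_depths(
                panel, normal_ids, depth_mean=depth_mean, seed=next(seed_iter)
            )
            tumour = simdata.simulate_exon_depths(
                panel,
                ["T"],
                role="tumour",
                copy_events=[("ERBB2", cn_true)],
                depth_mean=depth_mean,
                seed=next(seed_iter),
            )
            reference = cnv.build_normal_reference(normals)
            table = cnv.amplification_table(tumour, reference).set_index("gene")
            estimates.append(float(table.loc["ERBB2", "amplification_value"]))
            diploid_values.append(
                float(table.drop("ERBB2")["amplification_value"].median())
            )
        estimates = np.asarray(estimates)
        recovery[cn_true] = {
            "estimates_mean": float(estimates.mean()),
            "fraction_within_tol": float(
                (np.abs(estimates / cn_true - 1) <= tolerance).mean()
            ),
            "n": n_replicates,
        }
    return {
        "recovery": recovery,
        "diploid_median_A": float(np.median(diploid_values)),
        "tolerance": tolerance,
    }


def dpcr_lambda_recovery(
    seed: int,
    lambdas: tuple[float, ...] = (0.005, 0.05, 0.5),
    n_chips: int = 500,
    n_partitions: int = 20_000,
) -> dict:
    """Mean Poisson-estimator error over simulated chips at several loads.

    For each true mean copies/partition, simulates ``n_chips`` chips and
    reports the mean estimated lambda with its standard error, so callers
    can check ``|mean - truth| < 3 SE``.
    """
    seeds = _child_seeds(seed, len(lambdas))
    out = {}
    for lam, s in zip(lambdas, seeds):
        conc = lam / (DEFAULT_PARTITION_VOLUME_NL * 1e-3)
        chip_seeds = _child_seeds(s, n_chips)
        estimates = []
        for cs in chip_seeds:
            chip, _ = simdata.simulate_dpcr_chip(
                0.0, conc, n_partitions=n_partitions, seed=cs
            )
            chip.estimate()
            estimates.append(chip.lambda_vic)
        estimates = np.asarray(estimates)
        out[lam] = {
            "mean_estimate": float(estimates.mean()),
            "se": float(estimates.std(ddof=1) / np.sqrt(n_chips)),
            "n": n_chips,
        }
    return out


def pathway_effect_recovery(
    seed: int,
    geneset: list[str],
    n_seeds: int = 100,
    pathway_effect: float = -0.5,
    grb2_extra: float = -1.5,
) -> dict:
    """Recovery of a simulated pathway down-shift at the study design.

    Runs ``n_seeds`` replicates of the default 4-mutated-vs-7-wild design.
    Part one sets the GRB2 extra shift to zero so the expected
    mutated-minus-wild score difference equals ``pathway_effect`` exactly;
    part two uses the full defaults and asks how often the designated
    GRB2-like gene ranks most down-regulated.  Copy number is held fixed
    across the cohort: the HER2 gene belongs to the scored set and its
    expression tracks copy number, so per-sample copy-number variation
    would inject variance that has nothing to do with the expression
    effect under test.
    """
    seeds = _child_seeds(seed, n_seeds)
    fixed_cn = np.full(11, 12.0)  # one amplified level for all 11 tumours
    diffs = []
    grb2_first = 0
    for s in seeds:
        # uniform-effect replicate: score difference estimates pathway_effect
        expr, annot, normals, _ = simdata.simulate_expression(
            geneset, pathway_effect=pathway_effect, grb2_extra=0.0,
            batch_shift=(0.0, 1.0), copy_numbers=fixed_cn, seed=s,
        )
        z = pathway.standardize_to_normals(expr, normals)
        scores = pathway.pathway_score(z, geneset)
        res = pathway.compare_groups(
            scores["score"], annot["group"], groups=("mutated", "wild")
        )
        diffs.append(res["mean_difference"])

        # full-design replicate: designated gene should rank first
        expr2, annot2, normals2, _ = simdata.simulate_expression(
            geneset, pathway_effect=pathway_effect, grb2_extra=grb2_extra,
            batch_shift=(0.0, 1.0), copy_numbers=fixed_cn, seed=s + 1,
        )
        z2 = pathway.standardize_to_normals(expr2, normals2)
        ranking = pathway.rank_pathway_genes(z2, annot2["group"], geneset)
        grb2_first += ranking.iloc[0]["gene"] == geneset[0]

    return {
        "true_effect": pathway_effect,
        "mean_recovered_difference": float(np.mean(diffs)),
        "grb2_first_fraction": grb2_first / n_seeds,
        "n_seeds": n_seeds,
    }


def ranksum_enumeration_agreement(seed: int, n_datasets: int = 10) -> dict:
    """Exact rank-sum vs exhaustive 330-arrangement enumeration (4 vs 7).

    Generates random 4-vs-7 splits and compares the p-value reported by
    :func:`her2seq.pathway.compare_groups` with the full permutation
    enumeration; reports the largest absolute discrepancy (0 when exact).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_datasets):
        a = rng.normal(0.0, 1.0, 4)
        b = rng.normal(0.4, 1.0, 7)
        scores = pd.Series(np.concatenate([a, b]))
        labels = pd.Series(["a"] * 4 + ["b"] * 7)
        res = pathway.compare_groups(scores, labels, groups=("a", "b"))
        enum_p = pathway.exact_ranksum_p(a, b)
        max_diff = max(max_diff, abs(res["ranksum_p"] - enum_p))
    return {"max_abs_p_difference": max_diff, "n_datasets": n_datasets}
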