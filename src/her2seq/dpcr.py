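"""Poisson quantification of digital-PCR chips.

A chip partitions the reaction into ~20,000 wells; template molecules land
in wells as a Poisson process, so the mean copies per well is
``lambda = -ln(1 - k/n)`` where ``k`` of ``n`` wells are positive for a
dye.  FAM-labelled probes detect the mutant allele and VIC the wild type;
the mutant-allele percentage is reported as 100 x FAM/VIC concentration,
matching how dPCR instruments summarize rare-allele assays.  Chips may be
supplied either as partition counts or as instrument-reported copies/ul;
both paths yield the same mutant quantification record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Nominal well volume of a 20K-well chip, in nanolitres.
DEFAULT_PARTITION_VOLUME_NL = 0.809
DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_SIMILARITY_BAND = (0.5, 2.0)


@dataclass
class DpcrChipResult:
    """One assay's chip: partition counts and/or per-dye concentrations."""

    n_partitions: int
    k_fam: int | None = None
    k_vic: int | None = None
    partition_volume_nl: float = DEFAULT_PARTITION_VOLUME_NL
    dilution: float = 1.0
    c_fam: float | None = None
    c_vic: float | None = None
    lambda_fam: float | None = None
    lambda_vic: float | None = None

    def estimate(self) -> "DpcrChipResult":
        """Fill per-dye lambda and copies/ul from partition counts.

        Pre-supplied concentrations (the instrument path) are kept as-is.
        """
        if self.k_fam is not None:
            self.lambda_fam = poisson_lambda(self.k_fam, self.n_partitions)
            if self.c_fam is None:
                self.c_fam = concentration(
                    self.lambda_fam, self.partition_volume_nl, self.dilution
                )
        if self.k_vic is not None:
            self.lambda_vic = poisson_lambda(self.k_vic, self.n_partitions)
            if self.c_vic is None:
                self.c_vic = concentration(
                    self.lambda_vic, self.partition_volume_nl, self.dilution
                )
        return self


@dataclass(frozen=True)
class MutantQuant:
    mutant_pct: float
    control_pct: float
    fold_over_control: float
    positive: bool


def poisson_lambda(k, n) -> float:
    """Mean copies per partition from k positive wells of n.

    lambda = -ln(1 - k/n); undefined on a saturated chip (k = n).
    Accepts scalars or arrays.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n")
    if np.any(k == n):
        raise ValueError("saturated chip (k = n): lambda is undefined")
    out = -np.log1p(-(k / n))
    return out.item() if out.ndim == 0 else out


def concentration(lam, partition_volume_nl: float, dilution: float = 1.0):
    """Copies/ul from mean copies per partition.

    c = lambda / (v_p in ul) x dilution, with v_p given in nL.
    """
    if partition_volume_nl <= 0:
        raise ValueError("partition volume must be positive")
    if dilution <= 0:
        raise ValueError("dilution factor must be positive")
    lam = np.asarray(lam, dtype=float)
    out = lam / (partition_volume_nl * 1e-3) * dilution
    return out.item() if out.ndim == 0 else out


def mutant_percentage(c_fam: float, c_vic: float, convention: str = "fam_over_vic") -> float:
    """Mutant-allele percentage from per-dye concentrations.

    Default is 100 x FAM/VIC; ``convention='fam_over_total'`` gives
    100 x FAM/(FAM+VIC) for comparison with VAF-style fractions.
    """
    if c_vic <= 0:
        raise ValueError("VIC (wild-type) concentration must be positive")
    if c_fam < 0:
        raise ValueError("FAM concentration must be >= 0")
    if convention == "fam_over_vic":
        return 100.0 * c_fam / c_vic
    if convention == "fam_over_total":
        return 100.0 * c_fam / (c_fam + c_vic)
    raise ValueError(f"unknown convention {convention!r}")


def classify_positive(
    sample_pct: float,
    control_pct: float,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> MutantQuant:
    """Call a sample mutant-positive against its negative control.

    Positive iff sample percentage >= fold_threshold x control percentage
    (inclusive).  The negative control sets the assay's background signal.
    """
    if sample_pct < 0 or control_pct < 0:
        raise ValueError("percentages must be >= 0")
    fold = math.inf if control_pct == 0 and sample_pct > 0 else (
        0.0 if control_pct == 0 else sample_pct / control_pct
    )
    return MutantQuant(
        mutant_pct=sample_pct,
        control_pct=control_pct,
        fold_over_control=fold,
        positive=bool(sample_pct >= fold_threshold * control_pct),
    )


def vaf_concordance(
    ngs_vaf_pct: pd.Series,
    dpcr_pct: pd.Series,
    band: tuple[float, float] = DEFAULT_SIMILARITY_BAND,
) -> tuple[pd.DataFrame, float]:
    """Compare dPCR mutant percentages to NGS VAF percentages.

    Both inputs are indexed by sample id (percent scale).  Returns a
    per-pair table with the dPCR/NGS ratio and a ``similar`` flag (ratio
    within ``band``), plus the Spearman rank correlation across pairs
    (NaN for a single pair, where rank correlation is undefined).
    """
    ngs = pd.Series(ngs_vaf_pct, dtype=float)
    dp = pd.Series(dpcr_pct, dtype=float)
    unmatched = ngs.index.symmetric_difference(dp.index)
    if len(unmatched):
        raise ValueError(f"unmatched sample ids: {unmatched.tolist()}")
    if len(ngs) < 1:
        raise ValueError("need at least one pair")
    dp = dp.reindex(ngs.index)
    ratio = dp / ngs
    table = pd.DataFrame(
        {
            "ngs_vaf_pct": ngs,
            "dpcr_pct": dp,
            "ratio": ratio,
            "similar": (ratio >= band[0]) & (ratio <= band[1]),
        }
    )
    if len(ngs) >= 2 and ngs.nunique() > 1 and dp.nunique() > 1:
        rho = float(stats.spearmanr(ngs, dp).statistic)
    else:
        rho = 1.0 if len(ngs) >= 2 and (ngs.rank() == dp.rank()).all() else float("nan")
    return table, rho
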