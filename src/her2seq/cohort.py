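"""Clinicopathological cohort summaries and mutation-table parsing.

Consumes two tables: a clinical table (one row per patient with ER/PR/HER2
status, grades, stage, prior chemotherapy regimens and biopsy site) and a
gene-status table (one row per sample carrying the ERBB2 mutation string
with its parenthetical allele fraction, the amplification annotation and
per-sample expression scores).  Produces the standard cohort summaries:
receptor-subtype counts, median/range statistics, mutation frequency and
the amplification-by-mutation cross-tabulation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

# "p.P420fs (0.22)" or "S413L (0.01)" -> change + parenthetical percent
_MUTATION_RE = re.compile(r"^\s*(?P<change>[^()]+?)\s*\(\s*(?P<pct>[\d.]+)\s*\)\s*$")
# "Amp. (14.53)" -> amplification value; "None" -> not amplified
_AMP_RE = re.compile(r"^\s*Amp\.?\s*\(\s*(?P<value>[\d.]+)\s*\)\s*$", re.IGNORECASE)


@dataclass(frozen=True)
class CohortRecord:
    """One patient's clinicopathological row."""

    patient_id: str
    age: int
    menopausal_status: str
    er: int
    pr: int
    her2: int
    stage: str
    prior_regimens: int
    biopsy_site: str
    histologic_grade: str | None = None
    nuclear_grade: str | None = None
    her2_mutation: tuple[str, float] | None = None  # (protein change, VAF fraction)
    amplification_value: float | None = None

    def __post_init__(self) -> None:
        for name in ("er", "pr", "her2"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0/1 for patient {self.patient_id}")
        if self.prior_regimens < 0:
            raise ValueError(f"negative prior_regimens for patient {self.patient_id}")
        if self.her2_mutation is not None and not 0 <= self.her2_mutation[1] <= 1:
            raise ValueError(f"VAF outside [0, 1] for patient {self.patient_id}")


def parse_mutation(text) -> tuple[str, float] | None:
    """Parse an ERBB2 mutation cell like ``"S413L (0.01)"``.

    Returns (protein change, VAF as a fraction) or None for an empty
    cell.  The parenthetical is a fraction rounded to two decimals
    (cross-checkable against a deep-sequencing VAF% column: 1.6919%
    prints as 0.02); it is stored unchanged.
    """
    if text is None or (isinstance(text, float) and pd.isna(text)) or str(text).strip() in ("", "NA", "N/A"):
        return None
    m = _MUTATION_RE.match(str(text))
    if not m:
        raise ValueError(f"unparseable mutation annotation: {text!r}")
    return m.group("change").strip(), float(m.group("pct"))


def parse_amplification(text) -> float | None:
    """Parse an amplification cell: ``"Amp. (14.53)"`` -> 14.53, ``"None"`` -> None."""
    if text is None or (isinstance(text, float) and pd.isna(text)) or str(text).strip() in ("", "NA", "N/A"):
        return None
    s = str(text).strip()
    if s.lower() == "none":
        return None
    m = _AMP_RE.match(s)
    if not m:
        raise ValueError(f"unparseable amplification annotation: {text!r}")
    return float(m.group("value"))


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "stage": str})
    required = ["patient_id", "er", "pr", "her2", "prior_regimens"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} lacks columns: {missing}")
    return df


def read_gene_status_table(path: str | Path) -> pd.DataFrame:
    """Read the per-sample gene-status table and derive typed columns.

    Adds ``mutation_change`` / ``mutation_vaf`` (parsed from
    ``erbb2_mutation``), a boolean ``mutated`` and a boolean ``amplified``
    with its numeric ``amplification_value``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    parsed = df["erbb2_mutation"].map(parse_mutation)
    df["mutation_change"] = [p[0] if p else None for p in parsed]
    df["mutation_vaf"] = [p[1] if p else None for p in parsed]
    if "mutated" in df.columns:
        df["mutated"] = df["mutated"].astype(str).str.strip().str.lower().eq("yes")
    else:
        df["mutated"] = [p is not None for p in parsed]
    amp = pd.to_numeric(df["erbb2_copy_status"].map(parse_amplification))
    df["amplified"] = amp.notna()
    if "amplification_value" in df.columns:
        df["amplification_value"] = pd.to_numeric(df["amplification_value"], errors="coerce")
    else:
        # a non-amplified gene sits at the diploid value 2
        df["amplification_value"] = amp.fillna(2.0)
    return df


def subtype_counts(records: pd.DataFrame) -> dict:
    """Receptor-subtype counts over the cohort.

    HR-positive means ER and/or PR positive; triple-negative means
    ER = PR = HER2 = 0.  Categories may overlap (an HR+/HER2+ patient is
    counted in both), so the counts need not partition the cohort.
    """
    for col in ("er", "pr", "her2"):
        if records[col].isna().any():
            bad = records.loc[records[col].isna(), "patient_id"].tolist()
            raise ValueError(f"missing {col} status for patients: {bad}")
    er = records["er"].astype(int)
    pr = records["pr"].astype(int)
    her2 = records["her2"].astype(int)
    return {
        "hr_positive": int(((er == 1) | (pr == 1)).sum()),
        "her2_positive": int((her2 == 1).sum()),
        "triple_negative": int(((er == 0) & (pr == 0) & (her2 == 0)).sum()),
        "total": int(len(records)),
    }


def summarize_numeric(values) -> dict:
    """Median (even-n convention: mean of the central pair) plus min/max."""
    s = pd.Series(values).dropna().astype(float)
    if s.empty:
        raise ValueError("summarize_numeric requires non-empty values")
    return {"median": float(s.median()), "min": float(s.min()), "max": float(s.max())}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (report convention for percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def mutation_frequency(records: pd.DataFrame, flag_column: str = "her2_mutated") -> float:
    """Percent of patients carrying a mutation, to one decimal (half-up)."""
    if len(records) == 0:
        raise ValueError("mutation_frequency requires a non-empty cohort")
    if records[flag_column].isna().any():
        bad_idx = records.index[records[flag_column].isna()].tolist()
        raise ValueError(f"missing mutation flag for records: {bad_idx}")
    frac = records[flag_column].astype(bool).mean()
    return round_half_up(100.0 * frac, 1)


def mutation_amplification_crosstab(records: pd.DataFrame) -> dict:
    """2x2 counts of amplification status by mutation status."""
    for col in ("amplified", "mutated"):
        if col not in records.columns or records[col].isna().any():
            raise ValueError(f"missing {col} flags in gene-status records")
    amp = records["amplified"].astype(bool)
    mut = records["mutated"].astype(bool)
    counts = {
        "amplified_mutated": int((amp & mut).sum()),
        "amplified_wild": int((amp & ~mut).sum()),
        "non_amplified_mutated": int((~amp & mut).sum()),
        "non_amplified_wild": int((~amp & ~mut).sum()),
    }
    assert sum(counts.values()) == len(records)
    return counts


def merge_mutation_flags(
    clinical: pd.DataFrame, gene_status: pd.DataFrame
) -> pd.DataFrame:
    """Attach a ``her2_mutated`` flag to the clinical table.

    Patients absent from the gene-status table are wild type; the flag is
    therefore defined for every patient.
    """
    flags = gene_status.set_index("sample_id")["mutated"]
    out = clinical.copy()
    mapped = out["patient_id"].map(flags)
    out["her2_mutated"] = mapped.where(mapped.notna(), False).astype(bool)
    return out


def cohort_report(clinical: pd.DataFrame, gene_status: pd.DataFrame) -> dict:
    """Full cohort summary: subtypes, numeric medians, mutation statistics."""
    merged = merge_mutation_flags(clinical, gene_status)
    scores_present = gene_status["amplified"] & gene_status["her2_3_pathway"].notna()
    report = {
        "subtypes": subtype_counts(clinical),
        "age": summarize_numeric(clinical["age"]),
        "prior_regimens": summarize_numeric(clinical["prior_regimens"]),
        "her2_mutation_frequency_pct": mutation_frequency(merged),
        "n_her2_mutated": int(merged["her2_mutated"].sum()),
        "amplification_mutation_crosstab": mutation_amplification_crosstab(gene_status),
        "amplified_with_pathway_scores": int(scores_present.sum()),
    }
    return report


def report_markdown(report: dict) -> str:
    """Render a cohort report as a short Markdown summary."""
    sub = report["subtypes"]
    ct = report["amplification_mutation_crosstab"]
    lines = [
        "# Cohort summary",
        "",
        f"- Patients: {sub['total']}",
        f"- HR-positive (ER and/or PR): {sub['hr_positive']}",
        f"- HER2-positive: {sub['her2_positive']}",
        f"- Triple-negative: {sub['triple_negative']}",
        f"- Age: median {report['age']['median']:g} "
        f"(range {report['age']['min']:g}-{report['age']['max']:g})",
        f"- Prior chemotherapy regimens: median {report['prior_regimens']['median']:g} "
        f"(range {report['prior_regimens']['min']:g}-{report['prior_regimens']['max']:g})",
        f"- HER2 mutation frequency: {report['n_her2_mutated']} patients "
        f"({report['her2_mutation_frequency_pct']}%)",
        "",
        "## Amplification x mutation",
        "",
        f"- amplified & mutated: {ct['amplified_mutated']}",
        f"- amplified & wild type: {ct['amplified_wild']}",
        f"- non-amplified & mutated: {ct['non_amplified_mutated']}",
        f"- non-amplified & wild type: {ct['non_amplified_wild']}",
        f"- amplified samples with pathway scores: "
        f"{report['amplified_with_pathway_scores']}",
        "",
    ]
    return "\n".join(lines)


def write_report(report: dict, out_prefix: str | Path) -> None:
    prefix = Path(out_prefix)
    prefix.with_suffix(".json").write_text(json.dumps(report, indent=2) + "\n")
    prefix.with_suffix(".md").write_text(report_markdown(report))
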