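import pandas as pd
import pytest

from her2seq import cohort, io as hio


@pytest.fixture(scope="session")
def clinical_table() -> pd.DataFrame:
    """Bundled 36-patient clinicopathological table."""
    return cohort.read_clinical_table(hio.bundled_path("cohort_clinical.tsv"))


@pytest.fixture(scope="session")
def gene_status_table() -> pd.DataFrame:
    """Bundled per-sample ERBB2 mutation/amplification/score table."""
    return cohort.read_gene_status_table(hio.bundled_path("her2_gene_status.tsv"))


@pytest.fixture(scope="session")
def dpcr_table() -> pd.DataFrame:
    """Bundled digital-PCR validation table (five mutated samples)."""
    return pd.read_csv(hio.bundled_path("dpcr_validation.tsv"), sep="\t",
                       dtype={"sample_id": str})


@pytest.fixture(scope="session")
def pathway_geneset() -> list[str]:
    """Bundled ERBB2/ERBB3 signalling gene set (GRB2 listed first)."""
    gmt = hio.read_gmt(hio.bundled_path("her2_pathway.gmt"))
    return gmt["PID_ERBB2_ERBB3"]
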