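import numpy as np
import pandas as pd
import pytest

from pleioscan import datasets
from pleioscan.ld import HaplotypePanel
from pleioscan.summary_stats import SnpAssociation


@pytest.fixture(scope="session")
def table1_frame():
    return datasets.load_table1()


@pytest.fixture(scope="session")
def table1_records():
    """(RA records, SZ records) of the packaged 18-SNP reference table."""
    return datasets.table1_associations()


@pytest.fixture(scope="session")
def table1_models():
    return datasets.table1_gene_models()


def make_panel(columns: dict[str, list[int]], chrom: str = "1",
               spacing: int = 1000) -> HaplotypePanel:
    """Panel from explicit per-SNP haplotype columns (test helper)."""
    snp_ids = list(columns)
    mat = np.array([columns[s] for s in snp_ids], dtype=np.uint8).T
    variants = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": [1000 + i * spacing for i in range(len(snp_ids))],
            "ref": "A",
            "alt": "G",
        }
    )
    return HaplotypePanel(variants=variants, haplotypes=mat)


def assoc(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", odds=1.2,
          p=1e-10, trait="A") -> SnpAssociation:
    return SnpAssociation(snp_id=snp_id, chrom=chrom, pos=pos,
                          effect_allele=ea, other_allele=oa,
                          odds_ratio=odds, p_value=p, trait=trait)
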