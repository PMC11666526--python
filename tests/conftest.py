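from pathlib import Path

import pytest

from neoprio.cohort_model import SomaticVariant, VariantClass, VariantType

REPO_ROOT = Path(__file__).resolve().parent.parent
FIXTURES = REPO_ROOT / "fixtures"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture(scope="session")
def table2_path(fixtures_dir: Path) -> Path:
    return fixtures_dir / "table2_pairs.tsv"


def make_snv(
    sample="P1.1",
    gene="GENE0001",
    pos=10,
    ref="C",
    alt="T",
    vclass=VariantClass.MISSENSE,
) -> SomaticVariant:
    return SomaticVariant(
        sample_id=sample,
        gene=gene,
        chrom=gene,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        variant_class=vclass,
        variant_type=VariantType.SNV,
    )
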