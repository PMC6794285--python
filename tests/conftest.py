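import pytest

from dnmenrich.datasets import load_candidate_genes, load_tanc2_cohorts, load_tanc2_variants
from dnmenrich.variants import DeNovoVariant, Effect, Inheritance


def mkvar(
    individual_id,
    gene="G1",
    effect=Effect.STOPGAIN,
    inheritance=Inheritance.DE_NOVO,
    **kw,
):
    """Shorthand variant factory for tests."""
    kw.setdefault("nt_change", f"c.{abs(hash((individual_id, gene))) % 9999}A>T")
    return DeNovoVariant(
        individual_id=individual_id, gene=gene, effect=effect, inheritance=inheritance, **kw
    )


@pytest.fixture(scope="session")
def tanc2_variants():
    return load_tanc2_variants()


@pytest.fixture(scope="session")
def tanc2_cohorts():
    return load_tanc2_cohorts()


@pytest.fixture(scope="session")
def candidate_genes():
    return load_candidate_genes()
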