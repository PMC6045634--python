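import numpy as np
import pytest

from codonclusters import (
    CodonUsageTable,
    backtranslate,
    random_usage_table,
    standard_code,
)
from codonclusters.simulate import AA_ALPHABET, random_protein


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def random_table(code):
    """Factory: a random complete usage table for a given seed/skew."""

    def make(seed=0, skew=1.5, organism_id="synthetic"):
        return random_usage_table(seed, skew=skew, organism_id=organism_id, code=code)

    return make


@pytest.fixture
def random_cds(code):
    """Factory: a random valid CDS of n codons, codons sampled per a table."""

    def make(seed=0, n_codons=60, table=None, mode="frequency_sampled"):
        rng = np.random.default_rng(seed)
        table = table or random_usage_table(seed + 1, skew=1.5, code=code)
        protein = random_protein(rng, n_codons)
        return backtranslate(protein, table, mode=mode, seed=rng)

    return make


def max_codon_gene(table, protein):
    """Gene using each family's most frequent codon at every position."""
    return backtranslate(protein, table, mode="max_codon")


def min_codon_gene(table, protein):
    """Gene using each family's rarest codon at every position."""
    code = table.code
    out = []
    for aa in protein:
        fam = code.families[aa]
        out.append(min(fam, key=lambda c: (table.freq[c], c)))
    return "".join(out)
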