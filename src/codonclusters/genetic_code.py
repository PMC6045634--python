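"""Genetic-code structure: codon -> amino acid and synonymous families.

Codons are DNA strings over {A, C, G, T}; RNA input is normalised with
U -> T everywhere in the package.  The default code is the standard
(NCBI translation table 1) code; any Biopython table id, or an explicit
codon -> amino-acid mapping, may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from .errors import AlphabetError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: All 64 codons in lexicographic order; index i encodes bases of codon i.
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(ALL_CODONS)}

STOP_SYMBOL = "*"


def normalize_codon(codon: str) -> str:
    """Uppercase and U->T normalise a codon string."""
    return codon.upper().replace("U", "T")


def encode_cds(cds: str) -> np.ndarray:
    """Encode a DNA string (length divisible by 3) as codon indices 0..63."""
    seq = normalize_codon(cds)
    bad = set(seq) - set(BASES)
    if bad:
        raise AlphabetError(
            f"non-ACGT character(s) {sorted(bad)} in sequence"
        )
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.empty(arr.shape, dtype=np.int64)
    for base, val in _BASE_INDEX.items():
        idx[arr == ord(base)] = val
    return idx[0::3] * 16 + idx[1::3] * 4 + idx[2::3]


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with its synonymous-family structure.

    Parameters
    ----------
    codon_to_aa
        Mapping of all 64 codons to one-letter amino acids, with stop
        codons mapped to ``"*"``.
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        mapping = {normalize_codon(c): aa for c, aa in self.codon_to_aa.items()}
        if set(mapping) != set(ALL_CODONS):
            missing = sorted(set(ALL_CODONS) - set(mapping))
            raise ValueError(f"genetic code must define all 64 codons; missing {missing}")
        fams: dict[str, list[str]] = {}
        stops = []
        for codon in ALL_CODONS:  # lexicographic order within families
            aa = mapping[codon]
            if aa == STOP_SYMBOL:
                stops.append(codon)
            else:
                fams.setdefault(aa, []).append(codon)
        object.__setattr__(self, "codon_to_aa", mapping)
        object.__setattr__(self, "families", {aa: tuple(cs) for aa, cs in fams.items()})
        object.__setattr__(self, "stop_codons", tuple(stops))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP_SYMBOL)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.families)

    def family_of(self, codon: str) -> tuple[str, ...]:
        """Synonymous codons of ``codon``'s amino acid (stop codons: empty)."""
        aa = self.codon_to_aa[normalize_codon(codon)]
        return () if aa == STOP_SYMBOL else self.families[aa]

    # --- integer-encoded views used by the vectorised profile path ---

    @property
    def aa_of_codon_index(self) -> np.ndarray:
        """Array of length 64: one-letter amino acid (or '*') per codon index."""
        return np.array([self.codon_to_aa[c] for c in ALL_CODONS])

    @property
    def is_stop(self) -> np.ndarray:
        return self.aa_of_codon_index == STOP_SYMBOL

    def translate_indices(self, codon_indices: np.ndarray) -> str:
        return "".join(self.aa_of_codon_index[codon_indices])


@lru_cache(maxsize=None)
def standard_code(table_id: int = 1) -> GeneticCode:
    """The genetic code for a Biopython/NCBI translation table id (default 1)."""
    table = _BioCodonTable.unambiguous_dna_by_id[table_id]
    mapping = {c: aa for c, aa in table.forward_table.items() if "U" not in c}
    for stop in table.stop_codons:
        mapping[stop] = STOP_SYMBOL
    return GeneticCode(mapping)
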