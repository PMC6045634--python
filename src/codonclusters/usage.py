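"""Codon usage tables: construction from ORF pools, file I/O, family statistics
and relative adaptiveness.

Frequencies follow the Kazusa convention of occurrences per thousand codons.
All downstream %MinMax metrics are invariant to this scale, and CAI uses
within-family ratios, so the unit choice is cosmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    AlphabetError,
    DegenerateFamilyError,
    FrameError,
    TableCompletenessError,
    TableFormatError,
)
from .genetic_code import (
    ALL_CODONS,
    CODON_INDEX,
    GeneticCode,
    encode_cds,
    normalize_codon,
    standard_code,
)

__all__ = [
    "CodonUsageTable",
    "FamilyStats",
    "build_usage_from_orfs",
    "read_usage_table",
    "write_usage_table",
    "family_stats",
    "relative_adaptiveness",
]


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon frequency table for one organism.

    ``freq`` maps every sense codon (and optionally stop codons) to its
    frequency in occurrences per thousand codons.  ``counts`` carries raw
    codon counts when the table was built from an ORF pool.
    """

    organism_id: str
    freq: Mapping[str, float]
    counts: Mapping[str, int] | None = None
    source_n_orfs: int | None = None
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        freq = {normalize_codon(c): float(v) for c, v in self.freq.items()}
        missing = [c for c in self.code.sense_codons if c not in freq]
        if missing:
            raise TableCompletenessError(
                f"usage table '{self.organism_id}' missing sense codons: {missing}"
            )
        negative = [c for c, v in freq.items() if v < 0]
        if negative:
            raise TableFormatError(f"negative frequencies for codons: {negative}")
        object.__setattr__(self, "freq", freq)
        if self.counts is not None:
            # counts are auxiliary (pseudocounts, provenance); published
            # tables often round freq independently, so no cross-check here
            counts = {normalize_codon(c): int(v) for c, v in self.counts.items()}
            object.__setattr__(self, "counts", counts)

    @property
    def freq_array(self) -> np.ndarray:
        """Length-64 array of per-thousand frequencies indexed by codon index
        (stop codons and untabulated codons are 0)."""
        arr = np.zeros(64)
        for c, v in self.freq.items():
            arr[CODON_INDEX[c]] = v
        return arr

    def scaled(self, k: float) -> "CodonUsageTable":
        """The same table with every frequency multiplied by ``k`` (> 0)."""
        return CodonUsageTable(
            organism_id=self.organism_id,
            freq={c: v * k for c, v in self.freq.items()},
            code=self.code,
        )


@dataclass(frozen=True)
class FamilyStats:
    """Per-amino-acid max / min / unweighted mean frequency over each
    synonymous family; precomputation for the %MinMax window statistic."""

    f_max: Mapping[str, float]
    f_min: Mapping[str, float]
    f_avg: Mapping[str, float]
    code: GeneticCode

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(fmax, fmin, favg), each length 64 indexed by codon index; stop
        codon entries are NaN."""
        fmax = np.full(64, np.nan)
        fmin = np.full(64, np.nan)
        favg = np.full(64, np.nan)
        for aa, fam in self.code.families.items():
            for c in fam:
                i = CODON_INDEX[c]
                fmax[i] = self.f_max[aa]
                fmin[i] = self.f_min[aa]
                favg[i] = self.f_avg[aa]
        return fmax, fmin, favg


def build_usage_from_orfs(
    orfs: Iterable[str] | Mapping[str, str],
    code: GeneticCode | None = None,
    organism_id: str = "custom",
    skip_ambiguous: bool = False,
) -> CodonUsageTable:
    """Tabulate pooled codon usage over a collection of ORFs.

    Emulates the Kazusa Countcodon tabulation: codons are counted over all
    records and frequencies reported per thousand codons.  Stop codons are
    counted too (they appear in ``counts``/``freq`` but are ignored by all
    metrics).

    Parameters
    ----------
    orfs
        DNA coding sequences, or a mapping record-id -> sequence (ids are
        used in error messages).
    skip_ambiguous
        If true, codons containing non-ACGT characters are skipped instead
        of raising :class:`AlphabetError`.
    """
    code = code or standard_code()
    items = orfs.items() if isinstance(orfs, Mapping) else (
        (f"orf_{i + 1}", s) for i, s in enumerate(orfs)
    )
    counts = np.zeros(64, dtype=np.int64)
    n_orfs = 0
    for rec_id, orf in items:
        n_orfs += 1
        seq = normalize_codon(orf)
        if len(seq) % 3 != 0:
            raise FrameError(f"record '{rec_id}': length {len(seq)} not divisible by 3")
        if set(seq) - set("ACGT"):
            if not skip_ambiguous:
                raise AlphabetError(
                    f"record '{rec_id}': non-ACGT character(s) "
                    f"{sorted(set(seq) - set('ACGT'))}"
                )
            kept = [seq[i : i + 3] for i in range(0, len(seq), 3)
                    if not set(seq[i : i + 3]) - set("ACGT")]
            seq = "".join(kept)
            if not seq:
                continue
        counts += np.bincount(encode_cds(seq), minlength=64)
    total = int(counts.sum())
    if total == 0:
        raise FrameError("ORF pool contains no codons")
    freq = {c: 1000.0 * counts[i] / total for i, c in enumerate(ALL_CODONS)}
    return CodonUsageTable(
        organism_id=organism_id,
        freq=freq,
        counts={c: int(counts[i]) for i, c in enumerate(ALL_CODONS)},
        source_n_orfs=n_orfs,
        code=code,
    )


# "UUU 17.6 (  1234)" style blocks, U or T accepted
_KAZUSA_TOKEN = re.compile(
    r"([ACGTU]{3})\s+([0-9]+(?:\.[0-9]+)?)(?:\s*\(\s*([0-9]+)\s*\))?"
)


def read_usage_table(
    path,
    format: str = "tsv",
    organism_id: str | None = None,
    code: GeneticCode | None = None,
) -> CodonUsageTable:
    """Read a codon usage table.

    ``format="tsv"``: two or three tab-separated columns
    (codon, per-thousand frequency[, count]); '#' lines and an optional
    ``codon<TAB>per_thousand`` header are skipped.
    ``format="kazusa"``: free-text Kazusa/Countcodon blocks of
    ``CODON freq (count)`` tokens; U is normalised to T.
    """
    code = code or standard_code()
    with open(path) as fh:
        text = fh.read()
    freq: dict[str, float] = {}
    counts: dict[str, int] = {}
    have_counts = False

    def _add(codon: str, f: float, n: int | None) -> None:
        nonlocal have_counts
        codon = normalize_codon(codon)
        if codon in freq:
            raise TableFormatError(f"duplicate codon {codon} in {path}")
        freq[codon] = f
        if n is not None:
            counts[codon] = n
            have_counts = True

    if format == "tsv":
        for line_no, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "codon":  # header
                continue
            if len(fields) not in (2, 3):
                raise TableFormatError(f"{path}:{line_no}: expected 2-3 columns")
            _add(fields[0], float(fields[1]),
                 int(fields[2]) if len(fields) == 3 else None)
    elif format == "kazusa":
        for m in _KAZUSA_TOKEN.finditer(text):
            codon, f, n = m.groups()
            _add(codon, float(f), int(n) if n is not None else None)
    else:
        raise ValueError(f"unknown usage-table format {format!r}")

    missing = [c for c in code.sense_codons if c not in freq]
    if missing:
        raise TableCompletenessError(
            f"usage table {path} missing sense codons: {missing}"
        )
    name = organism_id if organism_id is not None else str(path)
    return CodonUsageTable(
        organism_id=name,
        freq=freq,
        counts=counts if have_counts else None,
        code=code,
    )


def write_usage_table(table: CodonUsageTable, path) -> None:
    """Write a table in the TSV dialect (round-trips with read_usage_table)."""
    with open(path, "w") as fh:
        cols = "codon\tper_thousand"
        if table.counts is not None:
            cols += "\tcount"
        fh.write(f"# organism: {table.organism_id}\n{cols}\n")
        for codon in ALL_CODONS:
            if codon not in table.freq:
                continue
            row = f"{codon}\t{table.freq[codon]:.17g}"
            if table.counts is not None:
                row += f"\t{table.counts.get(codon, 0)}"
            fh.write(row + "\n")


def family_stats(table: CodonUsageTable, code: GeneticCode | None = None) -> FamilyStats:
    """Max, min and unweighted mean frequency per synonymous family."""
    code = code or table.code
    f_max, f_min, f_avg = {}, {}, {}
    for aa, fam in code.families.items():
        vals = [table.freq[c] for c in fam]
        f_max[aa] = max(vals)
        f_min[aa] = min(vals)
        f_avg[aa] = sum(vals) / len(vals)
    return FamilyStats(f_max=f_max, f_min=f_min, f_avg=f_avg, code=code)


def relative_adaptiveness(table: CodonUsageTable) -> dict[str, float]:
    """Relative adaptiveness w (Sharp & Li): each codon's frequency divided
    by its most frequent synonym's frequency.

    Zero-frequency codons receive a pseudocount substitute to keep ln(w)
    finite in CAI: w = 0.5 / (family's maximum raw count) when counts are
    available, else w = 1e-3.  A family whose frequencies are all zero has
    no defined w and raises :class:`DegenerateFamilyError`.
    """
    code = table.code
    w: dict[str, float] = {}
    for aa, fam in code.families.items():
        fmax = max(table.freq[c] for c in fam)
        if fmax == 0:
            raise DegenerateFamilyError(
                f"family {aa} ({'/'.join(fam)}) has all-zero frequencies"
            )
        for c in fam:
            if table.freq[c] > 0:
                w[c] = table.freq[c] / fmax
            elif table.counts is not None:
                cmax = max(table.counts.get(x, 0) for x in fam)
                w[c] = 0.5 / cmax if cmax > 0 else 1e-3
            else:
                w[c] = 1e-3
    return w
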