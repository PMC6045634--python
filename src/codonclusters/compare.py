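"""Host-vs-target comparison metrics for a single gene.

Two genes' worth of information go into each comparison: the same CDS is
profiled under the expression host's codon usage table and under the source
organism's table.  Delta %MinMax is the mean absolute difference of the two
profiles (how far apart the landscapes sit); the %MinMax correlation is the
Pearson correlation of their window values (whether the landscapes have the
same shape, regardless of offset).  CAI and GC content round out the
per-gene covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DomainError
from .minmax import MinMaxProfile
from .stats import CorrelationResult, pearson_with_p
from .usage import CodonUsageTable, relative_adaptiveness
from .minmax import prepare_cds

__all__ = [
    "ProfileComparison",
    "delta_minmax",
    "minmax_correlation",
    "compare_profiles",
    "cai",
    "gc_content",
]


@dataclass(frozen=True)
class ProfileComparison:
    """Delta %MinMax and %MinMax correlation for one host/target table pair."""

    orf_id: str
    host_organism: str
    target_organism: str
    delta_minmax: float
    minmax_correlation: CorrelationResult
    n_windows: int
    per_class: Mapping[str, CorrelationResult] | None = None


def delta_minmax(p_host: MinMaxProfile, p_target: MinMaxProfile) -> float:
    """Mean absolute difference between two aligned %MinMax profiles,
    (1/n) * sum |x_i - y_i| in percentage points."""
    p_host.require_aligned(p_target)
    return float(np.mean(np.abs(p_host.values - p_target.values)))


def minmax_correlation(p_host: MinMaxProfile, p_target: MinMaxProfile) -> CorrelationResult:
    """Pearson correlation between two aligned profiles' window values,
    with the host-table profile as x and the target-table profile as y.

    A constant profile (e.g. an all-most-frequent-codon recoded gene) has
    zero variance: the result is flagged undefined rather than silently NaN.
    """
    p_host.require_aligned(p_target)
    return pearson_with_p(p_host.values, p_target.values)


def compare_profiles(p_host: MinMaxProfile, p_target: MinMaxProfile) -> ProfileComparison:
    return ProfileComparison(
        orf_id=p_host.orf_id,
        host_organism=p_host.organism_id,
        target_organism=p_target.organism_id,
        delta_minmax=delta_minmax(p_host, p_target),
        minmax_correlation=minmax_correlation(p_host, p_target),
        n_windows=p_host.n_windows,
    )


def cai(
    cds: str,
    reference_table: CodonUsageTable,
    orf_id: str = "?",
    trim_5prime: int = 0,
) -> float:
    """Codon adaptation index: the geometric mean of relative adaptiveness
    values w over all L sense codons, exp((1/L) * sum ln w).

    All codons are included, singleton families (Met, Trp, w = 1) among
    them.  The reference table should describe highly expressed genes of
    the host; any complete table is accepted.
    """
    code = reference_table.code
    idx = prepare_cds(cds, code, orf_id=orf_id, trim_5prime=trim_5prime)
    w = relative_adaptiveness(reference_table)
    w_arr = np.zeros(64)
    from .genetic_code import CODON_INDEX

    for codon, val in w.items():
        w_arr[CODON_INDEX[codon]] = val
    vals = w_arr[idx]
    if np.any(vals <= 0):
        raise DomainError(f"record '{orf_id}': zero-adaptiveness codon without pseudocount")
    return float(math.exp(np.mean(np.log(vals))))


def gc_content(cds: str) -> float:
    """Fraction of G + C bases in a non-empty ACGT (or ACGU) string."""
    seq = cds.upper().replace("U", "T")
    if not seq:
        raise DomainError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        from .errors import AlphabetError

        raise AlphabetError(f"non-ACGT character(s) {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)
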