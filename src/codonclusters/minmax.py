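"""%MinMax sliding-window codon-cluster profiles.

For a window of W consecutive codons let

    A   = mean actual usage frequency of the window's codons,
    Max = mean over the window of each codon family's most frequent synonym,
    Min = mean of each family's rarest synonym,
    Avg = mean of each family's unweighted-average synonym frequency.

The window scores ``100 * (A - Avg) / (Max - Avg)`` when A >= Avg (a cluster
of commoner-than-average codons, up to +100) and
``-100 * (Avg - A) / (Avg - Min)`` otherwise (a rare-codon cluster, down to
-100).  A window made entirely of single-codon families has
A = Max = Min = Avg and is scored 0, the unique continuous completion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    PrematureStopError,
    ProfileAlignmentError,
    SequenceTooShortError,
)
from .genetic_code import GeneticCode, encode_cds
from .usage import CodonUsageTable, family_stats

__all__ = ["MinMaxProfile", "compute_minmax_profile", "prepare_cds"]

DEFAULT_WINDOW = 18  # codons; Rare Codon Calculator default


@dataclass(frozen=True)
class MinMaxProfile:
    """Ordered per-window %MinMax values for one CDS under one usage table."""

    orf_id: str
    organism_id: str
    window_size: int
    values: np.ndarray
    window_start: np.ndarray  # 0-based codon index of each window's first codon
    trim_5prime: int = 0      # codons removed from the 5' end before profiling

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "window_start", np.asarray(self.window_start, dtype=np.int64)
        )

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def aligned_with(self, other: "MinMaxProfile") -> bool:
        return (
            self.window_size == other.window_size
            and self.n_windows == other.n_windows
            and bool(np.array_equal(self.window_start, other.window_start))
            and self.trim_5prime == other.trim_5prime
        )

    def require_aligned(self, other: "MinMaxProfile") -> None:
        if not self.aligned_with(other):
            raise ProfileAlignmentError(
                f"profiles '{self.orf_id}'/{self.organism_id} and "
                f"'{other.orf_id}'/{other.organism_id} do not share windows "
                f"(n={self.n_windows} vs {other.n_windows}, "
                f"W={self.window_size} vs {other.window_size}, "
                f"trim={self.trim_5prime} vs {other.trim_5prime})"
            )


def prepare_cds(
    cds: str,
    code: GeneticCode,
    orf_id: str = "?",
    trim_5prime: int = 0,
) -> np.ndarray:
    """Validate a CDS and return its sense codons as indices 0..63.

    A trailing stop codon is silently stripped; an internal stop raises
    :class:`PrematureStopError`.  ``trim_5prime`` drops that many leading
    codons (e.g. a His6/TEV tag) after validation.
    """
    if len(cds) % 3 != 0:
        from .errors import FrameError

        raise FrameError(f"record '{orf_id}': length {len(cds)} not divisible by 3")
    idx = encode_cds(cds)
    if len(idx) == 0:
        raise SequenceTooShortError(f"record '{orf_id}': empty sequence")
    stop_mask = code.is_stop[idx]
    if stop_mask[-1]:
        idx = idx[:-1]
        stop_mask = stop_mask[:-1]
    if stop_mask.any():
        pos = int(np.nonzero(stop_mask)[0][0])
        raise PrematureStopError(
            f"record '{orf_id}': internal stop codon at codon {pos}"
        )
    if trim_5prime:
        idx = idx[trim_5prime:]
    return idx


def _sliding_mean(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(x)))
    return (c[w:] - c[:-w]) / w


def compute_minmax_profile(
    cds: str,
    table: CodonUsageTable,
    window_size: int = DEFAULT_WINDOW,
    orf_id: str = "?",
    trim_5prime: int = 0,
) -> MinMaxProfile:
    """Compute the %MinMax profile of a CDS under a codon usage table.

    Windows advance one codon at a time; a CDS of L sense codons yields
    L - W + 1 values, each in [-100, 100].  The profile is invariant to
    rescaling the table's frequencies.
    """
    code = table.code
    idx = prepare_cds(cds, code, orf_id=orf_id, trim_5prime=trim_5prime)
    L = len(idx)
    if L < window_size:
        raise SequenceTooShortError(
            f"record '{orf_id}': {L} sense codons < window size {window_size}"
        )
    fmax, fmin, favg = family_stats(table, code).arrays()
    freq = table.freq_array

    A = _sliding_mean(freq[idx], window_size)
    Max = _sliding_mean(fmax[idx], window_size)
    Min = _sliding_mean(fmin[idx], window_size)
    Avg = _sliding_mean(favg[idx], window_size)

    up = A >= Avg
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = 100.0 * (A - Avg) / (Max - Avg)
        neg = -100.0 * (Avg - A) / (Avg - Min)
    values = np.where(up, pos, neg)
    # degenerate windows (all singleton families): A = Avg = Max = Min -> 0
    values = np.where(np.isfinite(values), values, 0.0)
    values = np.clip(values, -100.0, 100.0)  # guard float round-off at the rails

    return MinMaxProfile(
        orf_id=orf_id,
        organism_id=table.organism_id,
        window_size=window_size,
        values=values,
        window_start=np.arange(L - window_size + 1, dtype=np.int64),
        trim_5prime=trim_5prime,
    )
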