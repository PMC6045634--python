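"""Secondary-structure stratification of %MinMax windows.

Three-state annotations (H = alpha-helix, E = beta-sheet, C = coil, the
latter covering everything that is neither helix nor sheet, disorder
included) are aligned residue-per-codon with a CDS.  Each sliding window is
assigned one class — by default the class of its centre residue — and the
%MinMax correlation is recomputed within each class.  A dataset-level
analysis of one class should include only proteins with more than 5% of
their residues in that class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import AnnotationFormatError, AnnotationPairingError
from .minmax import MinMaxProfile
from .stats import CorrelationResult, pearson_with_p

__all__ = [
    "SS_CLASSES",
    "SSAnnotation",
    "parse_ss_annotation",
    "parse_ss_annotations",
    "assign_window_classes",
    "stratified_minmax_correlation",
    "ss_content_filter",
]

SS_CLASSES = ("H", "E", "C")
# characters accepted on input; '-', '.', ' ' and explicit 'C' all mean coil
_NORMALISE = {"H": "H", "E": "E", "C": "C", "-": "C", ".": "C", " ": "C", "B": "E"}


@dataclass(frozen=True)
class SSAnnotation:
    """Per-residue 3-state secondary structure string for one protein."""

    orf_id: str
    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set(SS_CLASSES)
        if bad:
            raise AnnotationFormatError(
                f"record '{self.orf_id}': invalid state(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.states)

    def class_fractions(self) -> dict[str, float]:
        """Residue-level fraction of each class (basis of the 5% filter)."""
        n = len(self.states)
        return {c: self.states.count(c) / n for c in SS_CLASSES}


def _normalise_states(raw: str, orf_id: str) -> str:
    out = []
    for pos, ch in enumerate(raw):
        ch = ch.upper()
        if ch not in _NORMALISE:
            raise AnnotationFormatError(
                f"record '{orf_id}': unknown state {ch!r} at position {pos}"
            )
        out.append(_NORMALISE[ch])
    return "".join(out)


def parse_ss_annotations(path, format: str = "fasta-like") -> list[SSAnnotation]:
    """Parse secondary-structure annotations.

    ``fasta-like``: records ``>orf_id`` followed by H/E/C lines ('-', '.'
    and blanks normalise to C).  ``jpred-jnet``: a JPred .jnet concise file;
    the ``jnetpred`` line carries the comma-separated final prediction and
    the record takes the file's stem as its id unless a ``>`` header
    precedes it.
    """
    anns: list[SSAnnotation] = []
    if format == "fasta-like":
        with open(path) as fh:
            rec_id, chunks = None, []
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if rec_id is not None:
                        anns.append(
                            SSAnnotation(rec_id, _normalise_states("".join(chunks), rec_id))
                        )
                    rec_id, chunks = line[1:].split()[0], []
                elif line.strip():
                    chunks.append(line.strip())
            if rec_id is not None:
                anns.append(SSAnnotation(rec_id, _normalise_states("".join(chunks), rec_id)))
    elif format == "jpred-jnet":
        import os

        stem = os.path.splitext(os.path.basename(str(path)))[0]
        with open(path) as fh:
            for line in fh:
                if line.lower().startswith("jnetpred:"):
                    payload = line.split(":", 1)[1].strip().rstrip(",")
                    states = "".join(tok.strip() for tok in payload.split(",") if tok.strip())
                    anns.append(SSAnnotation(stem, _normalise_states(states, stem)))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not anns:
        raise AnnotationFormatError(f"no annotation records found in {path}")
    return anns


def parse_ss_annotation(path, format: str = "fasta-like") -> SSAnnotation:
    """Parse a single-record annotation file (first record if several)."""
    return parse_ss_annotations(path, format=format)[0]


def assign_window_classes(
    ann: SSAnnotation,
    window_size: int,
    rule: str = "center",
    window_start: Sequence[int] | None = None,
) -> np.ndarray:
    """Assign each sliding window one secondary-structure class.

    ``center`` (default): the class of the residue at
    window_start + floor(W/2).  ``majority``: the modal class over the
    window's residues, ties broken H > E > C.
    """
    L = len(ann.states)
    if L < window_size:
        raise AnnotationPairingError(
            f"record '{ann.orf_id}': {L} residues < window size {window_size}"
        )
    starts = (
        np.arange(L - window_size + 1)
        if window_start is None
        else np.asarray(window_start, dtype=np.int64)
    )
    states = np.frombuffer(ann.states.encode(), dtype=np.uint8)
    if rule == "center":
        centers = starts + window_size // 2
        return np.array([chr(s) for s in states[centers]])
    if rule == "majority":
        out = []
        for s in starts:
            window = ann.states[s : s + window_size]
            counts = {c: window.count(c) for c in SS_CLASSES}
            best = max(counts.values())
            # H > E > C tie-break follows SS_CLASSES order
            out.append(next(c for c in SS_CLASSES if counts[c] == best))
        return np.array(out)
    raise ValueError(f"unknown assignment rule {rule!r}")


def stratified_minmax_correlation(
    p_host: MinMaxProfile,
    p_target: MinMaxProfile,
    ann: SSAnnotation,
    rule: str = "center",
    min_windows: int = 3,
) -> dict[str, CorrelationResult]:
    """Per-class %MinMax correlation between two aligned profiles.

    The annotation must have one state per sense codon of the profiled CDS
    (after any 5' trim).  Classes with fewer than ``min_windows`` windows,
    or zero variance within the class, are reported undefined.
    """
    p_host.require_aligned(p_target)
    expected_len = p_host.n_windows + p_host.window_size - 1
    if len(ann.states) != expected_len:
        raise AnnotationPairingError(
            f"record '{ann.orf_id}': annotation length {len(ann.states)} != "
            f"{expected_len} profiled codons"
        )
    classes = assign_window_classes(
        ann, p_host.window_size, rule=rule, window_start=p_host.window_start
    )
    out: dict[str, CorrelationResult] = {}
    for c in SS_CLASSES:
        mask = classes == c
        n = int(mask.sum())
        if n < min_windows:
            out[c] = CorrelationResult.undefined(n)
        else:
            out[c] = pearson_with_p(p_host.values[mask], p_target.values[mask])
    return out


def ss_content_filter(
    rows: "object",
    ss_class: str,
    threshold: float = 0.05,
    fraction_columns: Mapping[str, str] | None = None,
):
    """Keep dataset rows whose residue-level content of ``ss_class`` is
    strictly greater than ``threshold`` (default 5%).

    ``rows`` is a pandas DataFrame; the class-fraction column is
    ``frac_<class>`` unless remapped via ``fraction_columns``.
    """
    if ss_class not in SS_CLASSES:
        raise ValueError(f"unknown secondary-structure class {ss_class!r}")
    col = (fraction_columns or {}).get(ss_class, f"frac_{ss_class}")
    return rows[rows[col] > threshold]
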