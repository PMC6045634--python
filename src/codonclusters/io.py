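"""File I/O: FASTA, tabular inputs (band intensities, discrete 0-5 screen
scores, external predictor scores), dataset manifests and report headers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from . import __version__
from .errors import ManifestError
from .genetic_code import GeneticCode, standard_code
from .minmax import prepare_cds


def read_fasta(path) -> dict[str, str]:
    """Ordered record-id -> sequence mapping; duplicate ids are an error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ManifestError(f"duplicate record id '{rec.id}' in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records.items():
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def translate(cds: str, code: GeneticCode | None = None, orf_id: str = "?") -> str:
    """Translate a CDS (trailing stop dropped; internal stop is an error)."""
    code = code or standard_code()
    idx = prepare_cds(cds, code, orf_id=orf_id)
    return code.translate_indices(idx)


def read_intensity_tsv(path) -> pd.DataFrame:
    """Band-intensity table: orf_id, temperature, I_sf, I_if
    [, I_ladder, I_target]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"orf_id", "I_sf", "I_if"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_spine_tsv(path) -> pd.DataFrame:
    """Discrete 0-5 screen scores: orf_id, expression_scores,
    solubility_scores (semicolon-separated integers)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"orf_id", "expression_scores", "solubility_scores"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_predictions_tsv(path) -> pd.DataFrame:
    """External predictor scores: orf_id, tool, score (0-1)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"orf_id", "tool", "score"} - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def file_checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class DatasetManifest:
    """Paths and flags of one batch run, loaded from a manifest JSON."""

    base_dir: Path
    cds_fasta: Path
    host_table: Path
    target_table: Path
    ss_annotations: Path | None = None
    intensity_tsv: Path | None = None
    spine_tsv: Path | None = None
    cai_table: Path | None = None
    window_size: int = 18
    trim_5prime: int = 0
    ss_rule: str = "center"
    band: str = "prediction"
    soluble_threshold: float = 0.30
    seed: int | None = None

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh)
        base = path.parent
        kwargs: dict = {"base_dir": base}
        path_keys = (
            "cds_fasta",
            "host_table",
            "target_table",
            "ss_annotations",
            "intensity_tsv",
            "spine_tsv",
            "cai_table",
        )
        for key in path_keys:
            if raw.get(key) is not None:
                kwargs[key] = base / raw[key]
        for key in (
            "window_size",
            "trim_5prime",
            "ss_rule",
            "band",
            "soluble_threshold",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        missing = [k for k in ("cds_fasta", "host_table", "target_table") if k not in kwargs]
        if missing:
            raise ManifestError(f"{path}: missing required key(s) {missing}")
        absent = [
            str(p)
            for p in (
                kwargs.get(k) for k in path_keys if kwargs.get(k) is not None
            )
            if not Path(p).exists()
        ]
        if absent:
            raise ManifestError(f"{path}: referenced file(s) not found: {absent}")
        return cls(**kwargs)

    def checksums(self) -> dict[str, str]:
        out = {}
        for name in (
            "cds_fasta",
            "host_table",
            "target_table",
            "ss_annotations",
            "intensity_tsv",
            "spine_tsv",
            "cai_table",
        ):
            p = getattr(self, name)
            if p is not None:
                out[name] = file_checksum(p)
        return out


def report_header(flags: Mapping[str, object], checksums: Mapping[str, str] | None = None) -> str:
    """'#'-prefixed header block recording version, flags and input
    checksums; prepended to every report TSV."""
    lines = [f"# codonclusters {__version__}"]
    for key, val in flags.items():
        lines.append(f"# {key}: {val}")
    for name, digest in (checksums or {}).items():
        lines.append(f"# md5 {name}: {digest}")
    return "\n".join(lines) + "\n"


def write_report(df: pd.DataFrame, path, flags: Mapping[str, object],
                 checksums: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(report_header(flags, checksums))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
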