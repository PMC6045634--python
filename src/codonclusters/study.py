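"""Dataset-level analysis as a model/results pair.

:class:`CodonUsageStudy` bundles a screen's data — coding sequences, host
and target codon usage tables, optional secondary-structure annotations,
and per-gene outcome measurements (solubility fraction, total expression) —
and computes per-gene codon-usage features.  ``fit()`` runs the dataset-level
statistical analysis: each feature is correlated with each outcome by
Pearson's method after a single-pass regression-band outlier screen, and the
secondary-structure-stratified correlations are restricted to proteins with
more than 5% content of the class under analysis.  The returned
:class:`StudyResults` carries both tables and renders a summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .compare import cai as _cai
from .compare import delta_minmax, gc_content, minmax_correlation
from .errors import ManifestError
from .io import (
    DatasetManifest,
    read_fasta,
    read_intensity_tsv,
    read_spine_tsv,
)
from .minmax import compute_minmax_profile
from .stats import (
    classify_soluble,
    pearson_with_p,
    regression_outlier_filter,
    solubility_fraction,
    spine_average,
)
from .structure import (
    SS_CLASSES,
    SSAnnotation,
    parse_ss_annotations,
    stratified_minmax_correlation,
)
from .usage import CodonUsageTable, read_usage_table

__all__ = ["CodonUsageStudy", "StudyResults", "run_batch"]

#: features entering the dataset-level correlation analysis
BASE_FEATURES = ("cai", "gc", "delta_minmax", "minmax_correlation")
OUTCOMES = ("solubility", "expression")


@dataclass
class StudyResults:
    """Fitted study: per-gene feature table and dataset-level correlations."""

    model: "CodonUsageStudy"
    per_orf: pd.DataFrame
    correlations: pd.DataFrame

    def summary(self) -> str:
        m = self.model
        lines = [
            "Codon usage cluster study",
            "=" * 64,
            f"Genes:              {len(self.per_orf)}",
            f"Host table:         {m.host_table.organism_id}",
            f"Target table:       {m.target_table.organism_id}",
            f"Window size:        {m.window_size} codons",
            f"SS assignment rule: {m.ss_rule}",
            f"Outlier screen:     residual > {m.outlier_multiple} x 95% "
            f"{m.band} band half-width",
            "",
            "Dataset-level Pearson correlations (feature vs outcome)",
            "-" * 64,
        ]
        show = self.correlations.copy()
        for col, fmt in (("r", "{:+.3f}"), ("p", "{:.3g}")):
            show[col] = [
                fmt.format(v) if np.isfinite(v) else "undef" for v in show[col]
            ]
        lines.append(show.to_string(index=False))
        return "\n".join(lines)


class CodonUsageStudy:
    """Model object for a host-vs-target codon-usage-cluster screen.

    Parameters
    ----------
    cds
        Mapping orf_id -> coding sequence (sense strand, frame 0).
    host_table, target_table
        Complete codon usage tables for the expression host and the source
        organism of the genes.
    outcomes
        DataFrame with ``orf_id`` and any of ``solubility`` (fraction in
        [0, 1] or averaged 0-5 score) and ``expression`` columns.
    ss
        Optional mapping orf_id -> :class:`SSAnnotation`; enables the
        stratified analysis.
    cai_table
        Reference table for CAI (defaults to the host table; ideally a
        highly-expressed-genes table).
    """

    def __init__(
        self,
        cds: Mapping[str, str],
        host_table: CodonUsageTable,
        target_table: CodonUsageTable,
        outcomes: pd.DataFrame,
        ss: Mapping[str, SSAnnotation] | None = None,
        cai_table: CodonUsageTable | None = None,
        window_size: int = 18,
        trim_5prime: int = 0,
        ss_rule: str = "center",
        soluble_threshold: float = 0.30,
    ) -> None:
        self.cds = dict(cds)
        self.host_table = host_table
        self.target_table = target_table
        self.outcomes = outcomes.copy()
        self.ss = dict(ss) if ss else None
        self.cai_table = cai_table or host_table
        self.window_size = window_size
        self.trim_5prime = trim_5prime
        self.ss_rule = ss_rule
        self.soluble_threshold = soluble_threshold
        # set by fit()
        self.outlier_multiple = 3.0
        self.band = "prediction"
        self._validate_cross_references()

    def _validate_cross_references(self) -> None:
        problems = []
        ids = set(self.cds)
        if "orf_id" not in self.outcomes.columns:
            raise ManifestError("outcomes table lacks an orf_id column")
        for orf_id in self.outcomes["orf_id"]:
            if orf_id not in ids:
                problems.append(f"outcome row '{orf_id}' has no CDS")
        if self.ss is not None:
            for orf_id in ids:
                if orf_id not in self.ss:
                    problems.append(f"CDS '{orf_id}' has no SS annotation")
        if problems:
            raise ManifestError(
                "manifest cross-reference failures: " + "; ".join(sorted(problems))
            )

    @classmethod
    def from_manifest(cls, path) -> "CodonUsageStudy":
        """Build a study from a manifest JSON (paths relative to it)."""
        man = DatasetManifest.load(path)
        cds = read_fasta(man.cds_fasta)
        host = read_usage_table(man.host_table, organism_id="host")
        target = read_usage_table(man.target_table, organism_id="target")
        cai_table = (
            read_usage_table(man.cai_table, organism_id="cai_reference")
            if man.cai_table
            else None
        )
        ss = None
        if man.ss_annotations:
            ss = {a.orf_id: a for a in parse_ss_annotations(man.ss_annotations)}
        if man.intensity_tsv:
            raw = read_intensity_tsv(man.intensity_tsv)
            outcomes = pd.DataFrame({"orf_id": raw["orf_id"]})
            outcomes["solubility"] = [
                solubility_fraction(sf, if_)
                for sf, if_ in zip(raw["I_sf"], raw["I_if"])
            ]
            if {"I_ladder", "I_target"} <= set(raw.columns):
                outcomes["expression"] = raw["I_target"] / raw["I_ladder"]
        elif man.spine_tsv:
            raw = read_spine_tsv(man.spine_tsv)
            outcomes = pd.DataFrame({"orf_id": raw["orf_id"]})
            outcomes["solubility"] = [
                spine_average([int(s) for s in row.split(";")])
                for row in raw["solubility_scores"]
            ]
            outcomes["expression"] = [
                spine_average([int(s) for s in row.split(";")])
                for row in raw["expression_scores"]
            ]
        else:
            raise ManifestError(
                f"{path}: need either intensity_tsv or spine_tsv for outcomes"
            )
        study = cls(
            cds=cds,
            host_table=host,
            target_table=target,
            outcomes=outcomes,
            ss=ss,
            cai_table=cai_table,
            window_size=man.window_size,
            trim_5prime=man.trim_5prime,
            ss_rule=man.ss_rule,
            soluble_threshold=man.soluble_threshold,
        )
        study.band = man.band
        return study

    # ------------------------------------------------------------------

    def per_orf_features(self) -> pd.DataFrame:
        """Per-gene feature table (deterministic; no statistics yet)."""
        rows = []
        for orf_id, seq in self.cds.items():
            p_host = compute_minmax_profile(
                seq,
                self.host_table,
                self.window_size,
                orf_id=orf_id,
                trim_5prime=self.trim_5prime,
            )
            p_target = compute_minmax_profile(
                seq,
                self.target_table,
                self.window_size,
                orf_id=orf_id,
                trim_5prime=self.trim_5prime,
            )
            corr = minmax_correlation(p_host, p_target)
            row = {
                "orf_id": orf_id,
                "n_windows": p_host.n_windows,
                "delta_minmax": delta_minmax(p_host, p_target),
                "minmax_correlation": corr.r if corr.defined else np.nan,
                "minmax_correlation_p": corr.p_two_tailed if corr.defined else np.nan,
                "minmax_correlation_defined": corr.defined,
                "cai": _cai(
                    seq, self.cai_table, orf_id=orf_id, trim_5prime=self.trim_5prime
                ),
                "gc": gc_content(seq),
            }
            if self.ss is not None:
                ann = self.ss[orf_id]
                states = ann.states[self.trim_5prime :] if self.trim_5prime else ann.states
                ann_used = SSAnnotation(orf_id, states)
                per_class = stratified_minmax_correlation(
                    p_host, p_target, ann_used, rule=self.ss_rule
                )
                fracs = ann_used.class_fractions()
                for c in SS_CLASSES:
                    res = per_class[c]
                    row[f"minmax_correlation_{c}"] = res.r if res.defined else np.nan
                    row[f"n_windows_{c}"] = res.n
                    row[f"frac_{c}"] = fracs[c]
            rows.append(row)
        return pd.DataFrame(rows)

    def fit(
        self,
        outlier_filter: bool = True,
        outlier_multiple: float = 3.0,
        band: str | None = None,
        ss_min_fraction: float = 0.05,
        alpha: float = 0.05,
    ) -> StudyResults:
        """Run the dataset-level correlation analysis.

        For every feature x outcome pair: optionally exclude genes whose
        point lies further than ``outlier_multiple`` times the 95%
        regression-band half-width from the OLS fit (single pass), then
        compute Pearson r with a two-tailed p.  Stratified features first
        drop proteins with at most ``ss_min_fraction`` residue content of
        the class.
        """
        self.outlier_multiple = outlier_multiple
        if band is not None:
            self.band = band
        features = self.per_orf_features()
        table = features.merge(self.outcomes, on="orf_id", how="left")
        if "solubility" in table.columns:
            sol = table["solubility"]
            if sol.notna().all() and sol.between(0, 1).all():
                table["soluble_class"] = [
                    classify_soluble(v, self.soluble_threshold) for v in sol
                ]

        feature_cols = list(BASE_FEATURES)
        if self.ss is not None:
            feature_cols += [f"minmax_correlation_{c}" for c in SS_CLASSES]

        recs = []
        for outcome in OUTCOMES:
            if outcome not in table.columns:
                continue
            for feat in feature_cols:
                sub = table[["orf_id", feat, outcome]].dropna()
                cls = feat.rsplit("_", 1)[-1]
                if cls in SS_CLASSES and f"frac_{cls}" in table.columns:
                    keep = table.loc[sub.index, f"frac_{cls}"] > ss_min_fraction
                    sub = sub[keep]
                x = sub[feat].to_numpy(dtype=float)
                y = sub[outcome].to_numpy(dtype=float)
                n_excluded = 0
                if outlier_filter and len(x) >= 4 and np.ptp(x) > 0:
                    res = regression_outlier_filter(
                        x, y, multiple=outlier_multiple, band=self.band, alpha=alpha
                    )
                    n_excluded = res.n_excluded
                    x, y = x[res.kept], y[res.kept]
                corr = pearson_with_p(x, y)
                recs.append(
                    {
                        "feature": feat,
                        "outcome": outcome,
                        "r": corr.r,
                        "p": corr.p_two_tailed,
                        "n": corr.n,
                        "n_excluded": n_excluded,
                        "defined": corr.defined,
                    }
                )
        correlations = pd.DataFrame(
            recs, columns=["feature", "outcome", "r", "p", "n", "n_excluded", "defined"]
        )
        return StudyResults(model=self, per_orf=table, correlations=correlations)


def run_batch(manifest_path, out_dir=None) -> StudyResults:
    """Load a manifest, fit the study, optionally write the report TSVs."""
    from pathlib import Path

    from .io import write_report

    man = DatasetManifest.load(manifest_path)
    study = CodonUsageStudy.from_manifest(manifest_path)
    results = study.fit(band=man.band)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flags = {
            "window_size": study.window_size,
            "trim_5prime": study.trim_5prime,
            "ss_rule": study.ss_rule,
            "band": study.band,
            "soluble_threshold": study.soluble_threshold,
            "seed": man.seed,
        }
        sums = man.checksums()
        write_report(results.per_orf, out / "per_orf_metrics.tsv", flags, sums)
        write_report(results.correlations, out / "dataset_correlations.tsv", flags, sums)
    return results
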