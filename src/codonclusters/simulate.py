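"""Synthetic study generator.

Emulates the inputs of a small heterologous-expression screen: two
organisms' codon usage tables, coding sequences produced under controllable
codon-choice regimes, per-residue secondary-structure strings, and
densitometric expression/solubility values carrying planted linear effects
of the codon-cluster comparison metrics.  Everything is driven by a single
integer seed; the same seed yields a byte-identical bundle.

The planted outcome model is deliberately the simplest structure matching
the sign pattern such screens report: solubility increases linearly with
the %MinMax correlation between host- and native-table profiles, total
expression decreases linearly with delta %MinMax, both with Gaussian noise.
Coefficients are configuration, not claims about nature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import cai, delta_minmax, minmax_correlation
from .errors import AlphabetError
from .genetic_code import ALL_CODONS, GeneticCode, standard_code
from .minmax import compute_minmax_profile
from .structure import SS_CLASSES, SSAnnotation
from .usage import CodonUsageTable, write_usage_table

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "random_usage_table",
    "random_protein",
    "backtranslate",
    "harmonize",
    "random_ss_string",
    "simulate_study",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

RECODING_MODES = ("harmonized", "max_codon", "uniform_random", "frequency_sampled")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic screen.

    Defaults mirror a 30-target screen with proteins of 80-500 residues.
    The noise scales are set so the planted associations have strengths
    comparable to what a real screen of this size can exhibit (dataset-level
    Pearson r around 0.6-0.8 in magnitude).
    """

    seed: int = 0
    n_orfs: int = 30
    length_range: tuple[int, int] = (80, 500)  # protein residues
    host_skew: float = 1.5
    target_skew: float = 1.5
    recoding_mode: str = "frequency_sampled"
    window_size: int = 18
    # planted model: solubility = a + b * minmax_correlation + N(0, sigma_sol)
    a: float = 0.50
    b: float = 0.60
    sigma_sol: float = 0.08
    # planted model: expression = c - d * delta_minmax + N(0, sigma_expr)
    c: float = 2.0
    d: float = 0.015
    sigma_expr: float = 0.20
    # H / E / C residue composition of the synthetic structure strings
    ss_composition: tuple[float, float, float] = (0.38, 0.17, 0.45)
    mean_segment_length: int = 6

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid length range")
        if self.recoding_mode not in RECODING_MODES:
            raise ValueError(f"unknown recoding mode {self.recoding_mode!r}")
        if self.sigma_sol < 0 or self.sigma_expr < 0:
            raise ValueError("noise scales must be non-negative")


def random_usage_table(
    seed: int | np.random.Generator,
    skew: float = 1.5,
    organism_id: str = "synthetic",
    code: GeneticCode | None = None,
) -> CodonUsageTable:
    """A random complete codon usage table.

    ``skew`` controls within-family concentration: 0 makes every family's
    codons exactly equally frequent (so every %MinMax profile is
    identically 0), large values make one codon dominate each family.
    Amino-acid totals are Dirichlet-distributed; sense frequencies sum
    to 1000.
    """
    if skew < 0:
        raise ValueError("skew must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code = code or standard_code()
    fams = code.families
    aa_totals = rng.dirichlet(np.full(len(fams), 5.0))
    freq: dict[str, float] = {}
    for (aa, fam), total in zip(fams.items(), aa_totals):
        z = rng.standard_normal(len(fam))
        wt = np.exp(skew * z)
        wt /= wt.sum()
        for codonm, w in zip(fam, wt):
            freq[codonm] = 1000.0 * total * w
    for stop in code.stop_codons:
        freq[stop] = 0.0
    return CodonUsageTable(organism_id=organism_id, freq=freq, code=code)


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Uniform-random protein over the 20 standard amino acids."""
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _family_ranked(table: CodonUsageTable, fam: tuple[str, ...]) -> list[str]:
    # most frequent first; ties broken by lexicographic codon order
    return sorted(fam, key=lambda c: (-table.freq[c], c))


def backtranslate(
    protein: str,
    table: CodonUsageTable,
    mode: str = "frequency_sampled",
    seed: int | np.random.Generator | None = None,
    reference_cds: str | None = None,
    reference_table: CodonUsageTable | None = None,
) -> str:
    """Back-translate a protein into a CDS under a codon-choice regime.

    Modes
    -----
    ``max_codon``
        Each residue gets its family's most frequent codon ("one amino
        acid - one codon" optimisation).
    ``frequency_sampled``
        Codons drawn per within-family frequencies (emulates a native gene
        of the table's organism).
    ``uniform_random``
        Uniform within family.
    ``harmonized``
        Rank-matching against a reference CDS: each position takes the
        codon whose within-family frequency rank under ``table`` equals the
        reference codon's rank under ``reference_table``.
    """
    code = table.code
    for aa in set(protein):
        if aa not in code.families:
            raise AlphabetError(f"unknown amino-acid residue {aa!r}")
    if mode == "harmonized":
        if reference_cds is None or reference_table is None:
            raise ValueError("harmonized mode needs reference_cds and reference_table")
        return harmonize(reference_cds, reference_table, table)
    if mode == "max_codon":
        best = {aa: _family_ranked(table, fam)[0] for aa, fam in code.families.items()}
        return "".join(best[aa] for aa in protein)
    if mode == "uniform_random" or mode == "frequency_sampled":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        residues = np.array(list(protein))
        out = np.empty(len(protein), dtype=object)
        # grouped per amino acid (vectorised draws); deterministic given rng
        for aa in sorted(set(protein)):
            fam = code.families[aa]
            if mode == "uniform_random":
                p = np.full(len(fam), 1.0 / len(fam))
            else:
                f = np.array([table.freq[c] for c in fam])
                p = f / f.sum() if f.sum() > 0 else np.full(len(fam), 1.0 / len(fam))
            pos = np.nonzero(residues == aa)[0]
            draws = rng.choice(len(fam), size=len(pos), p=p)
            out[pos] = np.array(fam, dtype=object)[draws]
        return "".join(out)
    raise ValueError(f"unknown recoding mode {mode!r}")


def harmonize(
    reference_cds: str,
    source_table: CodonUsageTable,
    host_table: CodonUsageTable,
) -> str:
    """Rank-matched codon harmonization.

    For each reference codon, find its within-family frequency rank under
    the source organism's table and emit the host-table codon of the same
    rank; the recoded gene reproduces the reference's local
    common-vs-rare pattern in the host."""
    from .minmax import prepare_cds

    code = source_table.code
    idx = prepare_cds(reference_cds, code, orf_id="harmonize-reference")
    src_rank: dict[str, int] = {}
    host_by_rank: dict[str, list[str]] = {}
    for aa, fam in code.families.items():
        for r, c in enumerate(_family_ranked(source_table, fam)):
            src_rank[c] = r
        host_by_rank[aa] = _family_ranked(host_table, fam)
    out = []
    for i in idx:
        codon = ALL_CODONS[i]
        aa = code.codon_to_aa[codon]
        out.append(host_by_rank[aa][src_rank[codon]])
    return "".join(out)


def random_ss_string(
    rng: np.random.Generator,
    length: int,
    composition: tuple[float, float, float] = (0.38, 0.17, 0.45),
    mean_segment_length: int = 6,
) -> str:
    """Segmented H/E/C string: segment classes drawn per the H/E/C
    composition, segment lengths geometric.  Emulates the run structure of
    real secondary-structure predictions; long-range consistency (paired
    strands and the like) is not modelled."""
    p = np.asarray(composition, dtype=float)
    p = p / p.sum()
    chunks: list[str] = []
    n = 0
    while n < length:
        cls = SS_CLASSES[rng.choice(3, p=p)]
        seg = 1 + rng.geometric(1.0 / mean_segment_length)
        chunks.append(cls * min(seg, length - n))
        n += seg
    return "".join(chunks)[:length]


@dataclass
class StudyBundle:
    """In-memory synthetic screen: every input the pipeline consumes plus
    the planted truth."""

    config: SimulationConfig
    host_table: CodonUsageTable
    target_table: CodonUsageTable
    cds: dict[str, str]
    ss: dict[str, SSAnnotation]
    intensities: pd.DataFrame  # orf_id, temperature, I_sf, I_if, I_ladder, I_target
    truth: pd.DataFrame        # per-ORF planted values and measured metrics

    def write(self, out_dir) -> dict:
        """Write the bundle as plain-text files and return the manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "cds.fasta"
        with open(fasta, "w") as fh:
            for orf_id, seq in self.cds.items():
                fh.write(f">{orf_id}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        host_path = out / "host_usage.tsv"
        target_path = out / "target_usage.tsv"
        write_usage_table(self.host_table, host_path)
        write_usage_table(self.target_table, target_path)
        ss_path = out / "ss.fasta"
        with open(ss_path, "w") as fh:
            for orf_id, ann in self.ss.items():
                fh.write(f">{orf_id}\n{ann.states}\n")
        intens_path = out / "intensities.tsv"
        self.intensities.to_csv(intens_path, sep="\t", index=False)
        truth_path = out / "planted_truth.json"
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "config": asdict(self.config),
                    "per_orf": self.truth.to_dict(orient="records"),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        manifest = {
            "cds_fasta": fasta.name,
            "host_table": host_path.name,
            "target_table": target_path.name,
            "ss_annotations": ss_path.name,
            "intensity_tsv": intens_path.name,
            "window_size": self.config.window_size,
            "seed": self.config.seed,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest


def simulate_study(cfg: SimulationConfig) -> StudyBundle:
    """Generate a full synthetic screen under ``cfg``.

    The genes are "native" to the target organism (codons sampled, by
    default, from the target table's within-family frequencies); host and
    target profiles are computed and the planted linear models turn the
    comparison metrics into band intensities and expression ratios.
    """
    root = np.random.SeedSequence(cfg.seed)
    s_host, s_target, s_genes, s_ss, s_noise = root.spawn(5)
    host = random_usage_table(
        np.random.default_rng(s_host), skew=cfg.host_skew, organism_id="host"
    )
    target = random_usage_table(
        np.random.default_rng(s_target), skew=cfg.target_skew, organism_id="target"
    )
    rng_genes = np.random.default_rng(s_genes)
    rng_ss = np.random.default_rng(s_ss)
    rng_noise = np.random.default_rng(s_noise)

    lo, hi = cfg.length_range
    cds: dict[str, str] = {}
    ss: dict[str, SSAnnotation] = {}
    rows = []
    for k in range(cfg.n_orfs):
        orf_id = f"orf_{k + 1:03d}"
        length = int(rng_genes.integers(lo, hi + 1))
        protein = random_protein(rng_genes, length)
        seq = backtranslate(protein, target, mode=cfg.recoding_mode, seed=rng_genes)
        cds[orf_id] = seq
        ss[orf_id] = SSAnnotation(
            orf_id,
            random_ss_string(
                rng_ss, length, cfg.ss_composition, cfg.mean_segment_length
            ),
        )
        p_host = compute_minmax_profile(seq, host, cfg.window_size, orf_id=orf_id)
        p_target = compute_minmax_profile(seq, target, cfg.window_size, orf_id=orf_id)
        r = minmax_correlation(p_host, p_target)
        dmm = delta_minmax(p_host, p_target)
        sol = cfg.a + cfg.b * r.r + rng_noise.normal(0.0, cfg.sigma_sol)
        sol = float(np.clip(sol, 0.0, 1.0))
        expr = cfg.c - cfg.d * dmm + rng_noise.normal(0.0, cfg.sigma_expr)
        expr = float(max(expr, 0.01))
        rows.append(
            {
                "orf_id": orf_id,
                "length_codons": length,
                "minmax_correlation": r.r,
                "delta_minmax": dmm,
                "cai_host": cai(seq, host, orf_id=orf_id),
                "planted_solubility": sol,
                "planted_expression": expr,
            }
        )
    truth = pd.DataFrame(rows)

    ladder = 1000.0
    intensities = pd.DataFrame(
        {
            "orf_id": truth["orf_id"],
            "temperature": "20C",
            "I_sf": np.round(1000.0 * truth["planted_solubility"], 3),
            "I_if": np.round(1000.0 * (1.0 - truth["planted_solubility"]), 3),
            "I_ladder": ladder,
            "I_target": np.round(ladder * truth["planted_expression"], 3),
        }
    )
    return StudyBundle(
        config=cfg,
        host_table=host,
        target_table=target,
        cds=cds,
        ss=ss,
        intensities=intensities,
        truth=truth,
    )
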