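"""Synthetic-data generator: tables, back-translation regimes, study bundles."""

import json

import numpy as np
import pandas as pd
import pytest

from codonclusters import (
    SimulationConfig,
    backtranslate,
    cai,
    compute_minmax_profile,
    harmonize,
    minmax_correlation,
    random_usage_table,
    simulate_study,
    translate,
)
from codonclusters.errors import AlphabetError
from codonclusters.simulate import random_protein, random_ss_string


class TestRandomUsageTable:
    def test_deterministic(self):
        t1 = random_usage_table(7, skew=1.5)
        t2 = random_usage_table(7, skew=1.5)
        assert t1.freq == t2.freq

    def test_sums_to_1000(self):
        t = random_usage_table(1, skew=2.0)
        assert sum(t.freq.values()) == pytest.approx(1000.0, abs=1e-9)

    def test_zero_skew_uniform_within_family(self, code, random_cds):
        t = random_usage_table(3, skew=0.0)
        for aa, fam in code.families.items():
            vals = {round(t.freq[c], 12) for c in fam}
            assert len(vals) == 1
        prof = compute_minmax_profile(random_cds(seed=5, n_codons=50), t, 18)
        assert np.allclose(prof.values, 0.0)

    def test_large_skew_concentrates_and_max_codon_cai_near_one(self, rng):
        t = random_usage_table(4, skew=8.0)
        gene = backtranslate(random_protein(rng, 60), t, mode="max_codon")
        assert cai(gene, t) == pytest.approx(1.0)
        # dominant codon takes nearly all of a typical multi-codon family
        dominance = [
            max(t.freq[c] for c in fam) / sum(t.freq[c] for c in fam)
            for fam in t.code.families.values()
            if len(fam) >= 4
        ]
        assert np.median(dominance) > 0.9


class TestBacktranslate:
    @pytest.mark.parametrize("mode", ["max_codon", "uniform_random", "frequency_sampled"])
    def test_round_trip_translation(self, rng, mode):
        protein = random_protein(rng, 80)
        t = random_usage_table(11, skew=1.5)
        gene = backtranslate(protein, t, mode=mode, seed=1)
        assert translate(gene) == protein

    def test_max_codon_flat_plus_100(self, rng):
        t = random_usage_table(12, skew=2.0)
        gene = backtranslate(random_protein(rng, 50), t, mode="max_codon")
        prof = compute_minmax_profile(gene, t, 18)
        assert np.allclose(prof.values, 100.0)

    def test_unknown_residue(self):
        t = random_usage_table(1)
        with pytest.raises(AlphabetError):
            backtranslate("MKX", t, mode="max_codon")

    def test_harmonized_round_trip(self, rng):
        src = random_usage_table(21, skew=2.0, organism_id="src")
        host = random_usage_table(22, skew=2.0, organism_id="host")
        protein = random_protein(rng, 60)
        native = backtranslate(protein, src, mode="frequency_sampled", seed=5)
        recoded = harmonize(native, src, host)
        assert translate(recoded) == protein

    def test_harmonized_rank_preservation(self, code):
        """The recoded codon's within-family rank under the host table
        equals the native codon's rank under the source table."""
        src = random_usage_table(23, skew=2.0)
        host = random_usage_table(24, skew=2.0)
        native = backtranslate(random_protein(np.random.default_rng(0), 40),
                               src, mode="frequency_sampled", seed=9)
        recoded = harmonize(native, src, host)

        def rank(codon, table):
            fam = code.family_of(codon)
            ordered = sorted(fam, key=lambda c: (-table.freq[c], c))
            return ordered.index(codon)

        for i in range(0, len(native), 3):
            assert rank(native[i : i + 3], src) == rank(recoded[i : i + 3], host)

    def test_recoding_regimes_order_profile_conservation(self):
        """Rank-matched harmonization preserves the native %MinMax
        landscape best, codon re-sampling less, and one-amino-acid-one-codon
        optimisation destroys it (flat profile, undefined correlation) while
        maximising CAI — the expression/solubility trade-off direction."""
        rng = np.random.default_rng(31)
        src = random_usage_table(31, skew=2.0, organism_id="src")
        host = random_usage_table(32, skew=2.0, organism_id="host")
        r_harm, r_freq = [], []
        for k in range(20):
            protein = random_protein(rng, 120)
            native = backtranslate(protein, src, mode="frequency_sampled", seed=rng)
            p_native = compute_minmax_profile(native, src, 18)
            recoded = harmonize(native, src, host)
            r_harm.append(
                minmax_correlation(compute_minmax_profile(recoded, host, 18), p_native).r
            )
            resampled = backtranslate(protein, host, mode="frequency_sampled", seed=rng)
            r_freq.append(
                minmax_correlation(compute_minmax_profile(resampled, host, 18), p_native).r
            )
        assert np.median(r_harm) > np.median(r_freq)
        assert np.median(r_harm) > 0.5
        # max-codon recoding: flat +100 profile, correlation undefined, CAI 1
        protein = random_protein(rng, 120)
        opt = backtranslate(protein, host, mode="max_codon")
        p_opt = compute_minmax_profile(opt, host, 18)
        native = backtranslate(protein, src, mode="frequency_sampled", seed=rng)
        res = minmax_correlation(p_opt, compute_minmax_profile(native, src, 18))
        assert not res.defined
        assert cai(opt, host) == pytest.approx(1.0)


class TestRandomSS:
    def test_alphabet_and_length(self, rng):
        s = random_ss_string(rng, 137)
        assert len(s) == 137 and set(s) <= set("HEC")

    def test_composition_roughly_respected(self):
        rng = np.random.default_rng(0)
        s = "".join(random_ss_string(rng, 1000) for _ in range(20))
        frac_c = s.count("C") / len(s)
        assert 0.35 <= frac_c <= 0.55  # target 45%


class TestSimulateStudy:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = SimulationConfig(seed=99, n_orfs=6, length_range=(80, 120))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(cfg).write(d1)
        simulate_study(cfg).write(d2)
        for name in [p.name for p in d1.iterdir()]:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_bundle_passes_upstream_validators(self, tmp_path):
        from codonclusters import CodonUsageStudy

        cfg = SimulationConfig(seed=5, n_orfs=5, length_range=(80, 150))
        bundle = simulate_study(cfg)
        bundle.write(tmp_path / "bundle")
        study = CodonUsageStudy.from_manifest(tmp_path / "bundle" / "manifest.json")
        res = study.fit()
        assert len(res.per_orf) == 5
        assert res.per_orf["minmax_correlation"].notna().all()

    def test_lengths_within_configured_range(self):
        cfg = SimulationConfig(seed=2, n_orfs=8, length_range=(80, 500))
        bundle = simulate_study(cfg)
        assert bundle.truth["length_codons"].between(80, 500).all()
        for orf_id, seq in bundle.cds.items():
            assert len(seq) % 3 == 0
            assert len(bundle.ss[orf_id].states) == len(seq) // 3

    def test_planted_truth_sidecar(self, tmp_path):
        cfg = SimulationConfig(seed=8, n_orfs=4, length_range=(80, 100))
        simulate_study(cfg).write(tmp_path)
        with open(tmp_path / "planted_truth.json") as fh:
            truth = json.load(fh)
        assert truth["config"]["b"] == cfg.b
        assert len(truth["per_orf"]) == 4

    def test_planted_slope_recovered_within_2_se(self):
        """Regressing simulated solubility on the computed %MinMax
        correlation recovers the planted slope b (pooled replicates)."""
        import statsmodels.api as sm

        xs, ys = [], []
        for seed in range(12):  # 12 x 30 genes keeps the test brisk
            bundle = simulate_study(SimulationConfig(seed=seed))
            t = bundle.truth
            clipped = (t["planted_solubility"] <= 0) | (t["planted_solubility"] >= 1)
            xs.append(t.loc[~clipped, "minmax_correlation"])
            ys.append(t.loc[~clipped, "planted_solubility"])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        b_hat, se = fit.params[1], fit.bse[1]
        assert abs(b_hat - SimulationConfig.b) <= 2 * se
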