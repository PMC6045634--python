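"""Codon usage tables: construction, I/O, family statistics, adaptiveness."""

import numpy as np
import pytest

import oracles
from codonclusters import (
    CodonUsageTable,
    build_usage_from_orfs,
    family_stats,
    read_usage_table,
    relative_adaptiveness,
    write_usage_table,
)
from codonclusters.errors import (
    AlphabetError,
    DegenerateFamilyError,
    FrameError,
    TableCompletenessError,
    TableFormatError,
)
from codonclusters.genetic_code import ALL_CODONS, encode_cds, standard_code


class TestGeneticCode:
    def test_structure(self, code):
        assert len(code.codon_to_aa) == 64
        assert len(code.sense_codons) == 61
        assert len(code.stop_codons) == 3
        assert sum(len(f) for f in code.families.values()) == 61
        # every sense codon in exactly one family
        seen = [c for fam in code.families.values() for c in fam]
        assert sorted(seen) == sorted(code.sense_codons)

    def test_singleton_families(self, code):
        assert code.families["M"] == ("ATG",)
        assert code.families["W"] == ("TGG",)

    def test_encode_decode(self, code):
        idx = encode_cds("ATGAAATGG")
        assert [ALL_CODONS[i] for i in idx] == ["ATG", "AAA", "TGG"]

    def test_u_normalisation(self, code):
        assert (encode_cds("AUG") == encode_cds("ATG")).all()


class TestBuildUsage:
    def test_single_codon_pool(self, code):
        t = build_usage_from_orfs(["ATGATG"], code)
        assert t.freq["ATG"] == 1000.0
        assert all(v == 0 for c, v in t.freq.items() if c != "ATG")

    def test_quarter_three_quarters(self, code):
        t = build_usage_from_orfs(["ATGTGG", "TGGTGG"], code)
        assert t.freq["ATG"] == pytest.approx(250.0)
        assert t.freq["TGG"] == pytest.approx(750.0)

    def test_matches_brute_force_tally(self, code, random_cds):
        orfs = [random_cds(seed=s, n_codons=30) for s in range(50)]
        t = build_usage_from_orfs(orfs, code)
        expected = oracles.per_thousand(oracles.tally_codons(orfs))
        for codon in ALL_CODONS:
            assert t.freq[codon] == pytest.approx(expected.get(codon, 0.0), abs=1e-12)

    def test_order_and_concatenation_invariance(self, code, random_cds):
        orfs = [random_cds(seed=s, n_codons=20) for s in range(6)]
        t1 = build_usage_from_orfs(orfs, code)
        t2 = build_usage_from_orfs(list(reversed(orfs)), code)
        t3 = build_usage_from_orfs(["".join(orfs)], code)
        assert t1.freq == t2.freq == t3.freq

    def test_freq_sums_to_1000(self, code, random_cds):
        t = build_usage_from_orfs([random_cds(seed=3, n_codons=100)], code)
        assert sum(t.freq.values()) == pytest.approx(1000.0, abs=1e-6)

    def test_frame_error_names_record(self, code):
        with pytest.raises(FrameError, match="orf_2"):
            build_usage_from_orfs(["ATGTGG", "ATGA"], code)

    def test_alphabet_error_and_skip_option(self, code):
        with pytest.raises(AlphabetError):
            build_usage_from_orfs(["ATGNNN"], code)
        t = build_usage_from_orfs(["ATGNNNTGG"], code, skip_ambiguous=True)
        assert t.freq["ATG"] == pytest.approx(500.0)
        assert t.freq["TGG"] == pytest.approx(500.0)


class TestTableIO:
    def test_tsv_round_trip(self, tmp_path, random_table):
        t = random_table(seed=11)
        path = tmp_path / "t.tsv"
        write_usage_table(t, path)
        back = read_usage_table(path, organism_id=t.organism_id)
        for codon, v in t.freq.items():
            assert back.freq[codon] == pytest.approx(v, abs=1e-9)

    def test_counts_round_trip(self, tmp_path, code, random_cds):
        t = build_usage_from_orfs([random_cds(seed=5, n_codons=80)], code)
        path = tmp_path / "t.tsv"
        write_usage_table(t, path)
        back = read_usage_table(path)
        assert back.counts == t.counts

    def test_kazusa_token(self, tmp_path, code):
        lines = " ".join(
            f"{c.replace('T', 'U')} 16.4 ( 100)"
            for c in code.sense_codons
            if c != "TTT"
        )
        # override one token to the documented example
        path = tmp_path / "k.txt"
        path.write_text("UUU 17.6 (1234)\n" + lines)
        t = read_usage_table(path, format="kazusa")
        assert t.freq["TTT"] == pytest.approx(17.6)
        assert t.counts["TTT"] == 1234

    def test_missing_codon_reported(self, tmp_path, code):
        rows = ["codon\tper_thousand"] + [
            f"{c}\t10.0" for c in code.sense_codons if c != "GCA"
        ]
        path = tmp_path / "short.tsv"
        path.write_text("\n".join(rows))
        with pytest.raises(TableCompletenessError, match="GCA"):
            read_usage_table(path)

    def test_duplicate_codon(self, tmp_path, code):
        rows = ["codon\tper_thousand"] + [f"{c}\t10.0" for c in code.sense_codons]
        rows.append("ATG\t5.0")
        path = tmp_path / "dup.tsv"
        path.write_text("\n".join(rows))
        with pytest.raises(TableFormatError, match="duplicate"):
            read_usage_table(path)


class TestFamilyStats:
    def test_two_element_family(self, code):
        freq = {c: 10.0 for c in code.sense_codons}
        freq["GAA"], freq["GAG"] = 30.0, 10.0
        t = CodonUsageTable("x", freq, code=code)
        fs = family_stats(t)
        assert (fs.f_max["E"], fs.f_min["E"], fs.f_avg["E"]) == (30.0, 10.0, 20.0)

    def test_singleton_family(self, code):
        freq = {c: 10.0 for c in code.sense_codons}
        freq["ATG"] = 25.0
        fs = family_stats(CodonUsageTable("x", freq, code=code))
        assert fs.f_max["M"] == fs.f_min["M"] == fs.f_avg["M"] == 25.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_scan(self, code, random_table, seed):
        t = random_table(seed=seed)
        fs = family_stats(t)
        for aa, (mx, mn, av) in oracles.family_scan(t.freq, code.families).items():
            assert fs.f_max[aa] == pytest.approx(mx, rel=1e-12)
            assert fs.f_min[aa] == pytest.approx(mn, rel=1e-12)
            assert fs.f_avg[aa] == pytest.approx(av, rel=1e-12)

    def test_scaling(self, code, random_table):
        t = random_table(seed=2)
        fs, fs3 = family_stats(t), family_stats(t.scaled(3.0))
        for aa in code.families:
            assert fs3.f_max[aa] == pytest.approx(3 * fs.f_max[aa])
            assert fs3.f_min[aa] == pytest.approx(3 * fs.f_min[aa])
            assert fs3.f_avg[aa] == pytest.approx(3 * fs.f_avg[aa])


class TestRelativeAdaptiveness:
    def test_ratio_to_family_max(self, code):
        freq = {c: 10.0 for c in code.sense_codons}
        freq["GAA"], freq["GAG"] = 30.0, 10.0
        w = relative_adaptiveness(CodonUsageTable("x", freq, code=code))
        assert w["GAA"] == pytest.approx(1.0)
        assert w["GAG"] == pytest.approx(1 / 3)
        assert w["ATG"] == pytest.approx(1.0)  # singleton

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive(self, code, random_table, seed):
        t = random_table(seed=seed)
        w = relative_adaptiveness(t)
        expected = oracles.naive_w(t.freq, code.families)
        for codon in code.sense_codons:
            assert w[codon] == pytest.approx(expected[codon], rel=1e-12)

    def test_one_max_per_family(self, code, random_table):
        w = relative_adaptiveness(random_table(seed=9))
        for aa, fam in code.families.items():
            assert sum(1 for c in fam if w[c] == 1.0) >= 1

    def test_zero_frequency_pseudocount(self, code):
        freq = {c: 10.0 for c in code.sense_codons}
        freq["GAG"] = 0.0
        w = relative_adaptiveness(CodonUsageTable("x", freq, code=code))
        assert w["GAG"] == pytest.approx(1e-3)
        counts = {c: 7 for c in code.sense_codons}
        counts["GAG"] = 0
        total = sum(counts.values())
        freq2 = {c: 1000.0 * n / total for c, n in counts.items()}
        w2 = relative_adaptiveness(CodonUsageTable("x", freq2, counts=counts, code=code))
        assert w2["GAG"] == pytest.approx(0.5 / 7)

    def test_degenerate_family_error(self, code):
        freq = {c: 10.0 for c in code.sense_codons}
        freq["GAA"] = freq["GAG"] = 0.0
        with pytest.raises(DegenerateFamilyError):
            relative_adaptiveness(CodonUsageTable("x", freq, code=code))
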