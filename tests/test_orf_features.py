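"""ORF detection and the coding-potential feature family."""

import numpy as np
import pytest

from lncloc import orf_features as O
from lncloc.errors import DegenerateInputError
from lncloc.seq_io import LabeledDataset, NucleotideSequence, RNA_ALPHABET


def seq(residues: str, sid: str = "s") -> NucleotideSequence:
    return NucleotideSequence(sid, residues)


def exhaustive_longest_orf(residues: str):
    """Oracle: enumerate every AUG and its first in-frame stop directly."""
    best = (0, -1, -1)
    m = len(residues)
    for start in range(m - 2):
        if residues[start:start + 3] != "AUG":
            continue
        for stop in range(start + 3, m - 2, 3):
            if residues[stop:stop + 3] in O.STOP_CODONS:
                length = stop + 3 - start
                if length > best[0] or (length == best[0] and start < best[1]):
                    best = (length, start, stop + 3)
                break
    return best


class TestFindLongestOrf:
    def test_whole_sequence_orf(self):
        orf = O.find_longest_orf(seq("AUGAAAUAA"))
        assert (orf.start, orf.length, orf.found) == (0, 9, True)

    def test_internal_orf_with_offset_frame(self):
        orf = O.find_longest_orf(seq("AAAUGAAAUAAAA"))
        assert (orf.start, orf.end, orf.length) == (2, 11, 9)

    def test_no_start_codon(self):
        orf = O.find_longest_orf(seq("CCCCCC"))
        assert not orf.found and orf.length == 0

    def test_stop_codon_is_required_in_frame(self):
        # AUG then UAA out of frame only: no complete ORF
        orf = O.find_longest_orf(seq("AUGAAUAA"))
        assert not orf.found

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        residues = "".join(rng.choice(list(RNA_ALPHABET), size=300))
        orf = O.find_longest_orf(seq(residues))
        length, start, end = exhaustive_longest_orf(residues)
        assert orf.length == length
        if length:
            assert (orf.start, orf.end) == (start, end)
            assert residues[orf.start:orf.start + 3] == "AUG"
            assert residues[orf.end - 3:orf.end] in O.STOP_CODONS
            assert orf.length % 3 == 0


class TestCoverage:
    def test_full_coverage(self):
        s = seq("AUGAAAUAA")
        assert O.orf_coverage(s, O.find_longest_orf(s)) == 1.0

    def test_partial_coverage(self):
        s = seq("AAAUGAAAUAAAA")
        assert O.orf_coverage(s, O.find_longest_orf(s)) == pytest.approx(9 / 13)

    def test_no_orf_gives_zero(self):
        s = seq("CCCCCC")
        assert O.orf_coverage(s, O.find_longest_orf(s)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_coverages_partition_sequence(self, seed):
        rng = np.random.default_rng(seed)
        residues = "".join(rng.choice(list(RNA_ALPHABET), size=240))
        s = seq(residues)
        orf = O.find_longest_orf(s)
        if not orf.found:
            return
        cov5, cov3, *_ = O.utr_features(s, orf)
        assert cov5 + O.orf_coverage(s, orf) + cov3 == pytest.approx(1.0)


class TestEdpOrf:
    def test_two_amino_acid_orf(self):
        s = seq("AUGAAAUAA")  # codes M, K; stop excluded
        e = O.edp_orf(s, O.find_longest_orf(s))
        assert e.shape == (20,)
        assert e[O.AA20.index("M")] == pytest.approx(0.5)
        assert e[O.AA20.index("K")] == pytest.approx(0.5)
        assert e.sum() == pytest.approx(1.0)

    def test_single_codon_orf_is_degenerate(self):
        s = seq("AUGAUGAUGUAA")  # M M M -> zero entropy
        with pytest.warns(UserWarning, match="uniform"):
            e = O.edp_orf(s, O.find_longest_orf(s))
        np.testing.assert_allclose(e, 1 / 20)

    def test_no_orf_gives_zero_vector(self):
        s = seq("CCCCCCCCC")
        assert not O.edp_orf(s, O.find_longest_orf(s)).any()


def make_dataset(mapping: dict[str, list[str]]) -> LabeledDataset:
    seqs, labels = [], {}
    i = 0
    for cls, residues_list in mapping.items():
        for residues in residues_list:
            sid = f"{cls}{i}"
            seqs.append(NucleotideSequence(sid, residues))
            labels[sid] = cls
            i += 1
    return LabeledDataset(seqs, labels)


class TestHexamerTables:
    def test_inframe_enumeration_single_orf(self):
        ds = make_dataset({
            "cytoplasm": ["AUGAAAAAAUAA"],  # coding hexamers: AUGAAA, AAAAAA
            "nucleus": ["AUGCCCCCCUAA"],
        })
        tables = O.build_hexamer_tables(ds)
        f = tables.inframe_freq["cytoplasm"]
        from lncloc.kmer_features import kmer_index

        top = np.argsort(f)[::-1][:2]
        assert set(top) == {kmer_index("AUGAAA"), kmer_index("AAAAAA")}
        # equal shares (~0.5 each before pseudocounting), everything else tiny
        assert f[top[0]] == pytest.approx(f[top[1]])
        assert f.sum() == pytest.approx(1.0)
        assert f[top[0]] > 0.3 > 100 * np.sort(f)[-3]

    def test_all_entries_positive(self):
        ds = make_dataset({
            "cytoplasm": ["AUGAAAAAAUAA"], "nucleus": ["AUGCCCCCCUAA"],
        })
        tables = O.build_hexamer_tables(ds)
        for table in (*tables.inframe_freq.values(), *tables.background_freq.values(),
                      *tables.seq_freq.values()):
            assert (table > 0).all()

    def test_identical_corpora_give_equal_tables(self):
        residues = "AUGAAACCCGGGUAA"
        ds = make_dataset({"cytoplasm": [residues], "nucleus": [residues]})
        tables = O.build_hexamer_tables(ds)
        np.testing.assert_allclose(
            tables.inframe_freq["cytoplasm"], tables.inframe_freq["nucleus"]
        )
        np.testing.assert_allclose(
            tables.inframe_freq["cytoplasm"], tables.background_freq["cytoplasm"]
        )

    def test_class_without_orfs_falls_back_to_uniform(self):
        ds = make_dataset({
            "cytoplasm": ["AUGAAACCCUAA"], "nucleus": ["CCCCCCCCCCCC"],
        })
        with pytest.warns(UserWarning, match="uniform"):
            tables = O.build_hexamer_tables(ds)
        np.testing.assert_allclose(tables.inframe_freq["nucleus"], 1 / 4096)


class TestHexamerBias:
    def _tables(self):
        ds = make_dataset({
            "cytoplasm": ["AUGAAAAAAUAA"], "nucleus": ["AUGCCCCCCUAA"],
        })
        return O.build_hexamer_tables(ds)

    def test_identical_tables_give_zero(self):
        tables = self._tables()
        tables.background_freq["cytoplasm"] = tables.inframe_freq["cytoplasm"]
        s = seq("AUGAAAAAAUAA")
        assert O.hexamer_bias(s, O.find_longest_orf(s), tables, "cytoplasm") == 0.0

    def test_doubled_ratio_gives_log2(self):
        tables = self._tables()
        tables.inframe_freq["cytoplasm"] = 2.0 * tables.background_freq["cytoplasm"]
        s = seq("AUGAAAAAAUAA")
        mu = O.hexamer_bias(s, O.find_longest_orf(s), tables, "cytoplasm")
        assert mu == pytest.approx(np.log(2))

    def test_antisymmetric_under_table_swap(self):
        tables = self._tables()
        s = seq("AUGAAAAAAUAA")
        orf = O.find_longest_orf(s)
        mu = O.hexamer_bias(s, orf, tables, "cytoplasm")
        tables.inframe_freq["cytoplasm"], tables.background_freq["cytoplasm"] = (
            tables.background_freq["cytoplasm"], tables.inframe_freq["cytoplasm"],
        )
        assert O.hexamer_bias(s, orf, tables, "cytoplasm") == pytest.approx(-mu)

    def test_matches_window_loop_oracle(self):
        rng = np.random.default_rng(4)
        tables = self._tables()
        residues = "AUG" + "".join(rng.choice(list(RNA_ALPHABET), size=60)) + "UAA"
        s = seq(residues)
        orf = O.OrfAnnotation(0, len(residues), True)
        fj = tables.inframe_freq["cytoplasm"]
        fbg = tables.background_freq["cytoplasm"]
        from lncloc.kmer_features import kmer_index

        vals = []
        for i in range(orf.start, orf.end - 3 - 5, 3):
            vals.append(np.log(fj[kmer_index(residues[i:i + 6])]
                               / fbg[kmer_index(residues[i:i + 6])]))
        assert O.hexamer_bias(s, orf, tables, "cytoplasm") == pytest.approx(np.mean(vals))


class TestHexamerLogDistances:
    def test_zero_distance_to_own_profile(self):
        residues = "AUGAAACCCGGGUAAACGUACGUGCAUGCUA"
        ds = make_dataset({"cytoplasm": [residues], "nucleus": ["ACGU" * 10]})
        tables = O.build_hexamer_tables(ds)
        d_cyto, _, _ = O.hexamer_log_distances(seq(residues), tables)
        assert d_cyto == pytest.approx(0.0, abs=1e-12)

    def test_identical_profiles_give_unit_ratio(self):
        residues = "ACGUACGUACGUGCAUGCAUCCAA"
        ds = make_dataset({"cytoplasm": [residues], "nucleus": [residues]})
        tables = O.build_hexamer_tables(ds)
        d_cyto, d_nuc, ratio = O.hexamer_log_distances(seq("GCAUGCAUACGU"), tables)
        assert d_cyto == pytest.approx(d_nuc)
        assert ratio == pytest.approx(1.0)

    def test_matches_window_loop_oracle(self):
        rng = np.random.default_rng(9)
        pool = ["".join(rng.choice(list(RNA_ALPHABET), size=80)) for _ in range(4)]
        ds = make_dataset({"cytoplasm": pool[:2], "nucleus": pool[2:]})
        tables = O.build_hexamer_tables(ds)
        residues = "".join(rng.choice(list(RNA_ALPHABET), size=70))
        n = len(residues) - 5
        from collections import Counter
        from lncloc.kmer_features import kmer_index

        counts = Counter(residues[i:i + 6] for i in range(n))
        expect = sum(
            np.log(((c + 1 / 4096) / (n + 1)) / tables.seq_freq["cytoplasm"][kmer_index(w)])
            for w, c in counts.items()
        ) / n
        d_cyto, _, _ = O.hexamer_log_distances(seq(residues), tables)
        assert d_cyto == pytest.approx(expect)

    def test_short_sequence_rejected(self):
        ds = make_dataset({"cytoplasm": ["ACGU" * 10], "nucleus": ["GCAU" * 10]})
        tables = O.build_hexamer_tables(ds)
        with pytest.raises(DegenerateInputError):
            O.hexamer_log_distances(seq("ACGU"), tables)


class TestUtrFeatures:
    def test_flanking_coverages(self):
        s = seq("AAAUGAAAUAAAA")
        cov5, cov3, gc5, gc3, gc_all = O.utr_features(s, O.find_longest_orf(s))
        assert cov5 == pytest.approx(2 / 13)
        assert cov3 == pytest.approx(2 / 13)
        assert (gc5, gc3, gc_all) == (0.0, 0.0, 0.0)

    def test_orf_covering_whole_sequence(self):
        s = seq("AUGAAAUAA")
        assert O.utr_features(s, O.find_longest_orf(s))[:2] == (0.0, 0.0)

    def test_gc_of_flanks(self):
        s = seq("GCAUGAAAUAA")  # 5'UTR is "GC"
        cov5, _, gc5, gc3, gc_all = O.utr_features(s, O.find_longest_orf(s))
        assert gc5 == 1.0 and gc3 == 0.0 and gc_all == 1.0

    def test_no_orf_zeroes_everything(self):
        s = seq("CCCCCC")
        assert O.utr_features(s, O.find_longest_orf(s)) == (0.0,) * 5


class TestFickett:
    def test_hand_counted_acg(self):
        v = O.fickett_vector(seq("ACG"))
        assert v[0] == pytest.approx(1.0)  # A: phases (1, 0, 0)
        assert v[4] == pytest.approx(100 / 3)

    def test_homopolymer(self):
        v = O.fickett_vector(seq("AAAAAA"))
        assert v[0] == pytest.approx(2 / 3)  # A1=A2=A3=2 -> 2/(2+1)
        assert v[4] == pytest.approx(100.0)

    def test_dimension_and_percentage_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            residues = "".join(rng.choice(list(RNA_ALPHABET), size=101))
            v = O.fickett_vector(seq(residues))
            assert v.shape == (8,)
            assert v[4:].sum() == pytest.approx(100.0, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            O.fickett_vector(seq("AC"))
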