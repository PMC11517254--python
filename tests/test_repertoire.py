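import gzip
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoprior.errors import (
    DegenerateInputError,
    EmptyInputError,
    FormatError,
    ValidationError,
)
from neoprior.repertoire import (
    Clonotype,
    ClonotypeTable,
    clonality,
    clonotype_sharing,
    filter_by_count,
    rarefaction_curve,
    read_airr_table,
    segment_usage,
    shannon_entropy,
)


class TestClonotype:
    def test_rejects_empty_cdr3(self):
        with pytest.raises(ValidationError):
            Clonotype("", "TRBV1", "TRBJ1", 1)

    def test_rejects_stop_codon(self):
        with pytest.raises(ValidationError):
            Clonotype("CAS*L", "TRBV1", "TRBJ1", 1)

    def test_rejects_zero_count(self):
        with pytest.raises(ValidationError):
            Clonotype("CASSL", "TRBV1", "TRBJ1", 0)

    def test_table_rejects_duplicate_keys(self):
        with pytest.raises(ValidationError):
            ClonotypeTable(
                "s",
                [
                    Clonotype("CASSL", "TRBV1", "TRBJ1", 1),
                    Clonotype("CASSL", "TRBV1", "TRBJ1", 2),
                ],
            )

    def test_frequencies_sum_to_one(self, small_table):
        assert small_table.frequencies.sum() == pytest.approx(1.0, abs=1e-9)


class TestReadAirrTable:
    def test_identity_read(self, airr_tsv):
        path = airr_tsv(
            [
                ("CASSL", "TRBV1", "TRBJ1", 2),
                ("CASSQ", "TRBV1", "TRBJ2", 3),
                ("CASSR", "TRBV2", "TRBJ1", 1),
            ]
        )
        table = read_airr_table(path)
        assert len(table) == 3
        assert table.total_reads == 6

    def test_merge_rule(self, airr_tsv):
        path = airr_tsv(
            [("CASSL", "TRBV1", "TRBJ1", 2), ("CASSL", "TRBV1", "TRBJ1", 3)]
        )
        table = read_airr_table(path)
        assert len(table) == 1
        assert table.clonotypes[0].count == 5

    def test_empty_cdr3_skipped(self, airr_tsv):
        path = airr_tsv([("", "TRBV1", "TRBJ1", 2), ("CASSL", "TRBV1", "TRBJ1", 1)])
        table = read_airr_table(path)
        assert len(table) == 1
        assert table.n_skipped == 1

    def test_missing_column_names_it(self, airr_tsv):
        path = airr_tsv([("CASSL", "TRBV1", 1)], header=["junction_aa", "v_call", "duplicate_count"])
        with pytest.raises(FormatError, match="j_call"):
            read_airr_table(path)

    def test_empty_after_filter(self, airr_tsv):
        path = airr_tsv([("", "TRBV1", "TRBJ1", 1)])
        with pytest.raises(EmptyInputError):
            read_airr_table(path)

    def test_gzip_transparent(self, airr_tsv, tmp_path):
        plain = airr_tsv([("CASSL", "TRBV1", "TRBJ1", 2)])
        gz = tmp_path / "sample.tsv.gz"
        gz.write_bytes(gzip.compress(plain.read_bytes()))
        assert len(read_airr_table(gz)) == 1

    def test_generic_dialect(self, airr_tsv):
        path = airr_tsv(
            [("CASSL", "TRBV1", "TRBJ1", 2)],
            header=["aaSeqCDR3", "bestV", "bestJ", "cloneCount"],
        )
        table = read_airr_table(
            path,
            dialect="generic-tsv",
            column_map={
                "aaSeqCDR3": "cdr3_aa",
                "bestV": "v_call",
                "bestJ": "j_call",
                "cloneCount": "count",
            },
        )
        assert table.clonotypes[0].count == 2


class TestFilterByCount:
    def _table(self, counts):
        return ClonotypeTable(
            "s",
            [Clonotype(f"CASS{'AG'[i % 2] * (i + 1)}", "TRBV1", "TRBJ1", c)
             for i, c in enumerate(counts)],
        )

    def test_threshold(self):
        table = filter_by_count(self._table([1, 2, 5]), 2)
        assert sorted(c.count for c in table.clonotypes) == [2, 5]

    def test_identity(self):
        table = self._table([1, 2, 5])
        assert len(filter_by_count(table, 1)) == 3

    def test_renormalized_frequencies(self):
        table = filter_by_count(self._table([3, 4]), 2)
        assert sorted(table.frequencies) == pytest.approx([3 / 7, 4 / 7])

    def test_all_removed(self):
        with pytest.raises(EmptyInputError):
            filter_by_count(self._table([1, 1]), 5)


class TestShannonClonality:
    def test_uniform(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(math.log(4), abs=1e-9)

    def test_single_clone(self):
        assert shannon_entropy([1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_derived_value(self):
        assert shannon_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.039721, abs=1e-6)

    def test_invalid_probs(self):
        with pytest.raises(ValidationError):
            shannon_entropy([0.5, 0.5, 0.0])
        with pytest.raises(ValidationError):
            shannon_entropy([0.6, 0.6])

    def test_clonality_uniform_zero(self):
        assert clonality([0.25] * 4) == pytest.approx(0.0, abs=1e-12)

    def test_clonality_derived(self):
        # exact value 0.0536054; the commonly quoted 0.053604 is a rounding
        assert clonality([0.5, 0.25, 0.25]) == pytest.approx(0.053604, abs=5e-6)
        exact = 1 - 1.5 * math.log(2) / math.log(3)
        assert clonality([0.5, 0.25, 0.25]) == pytest.approx(exact, abs=1e-12)
        assert clonality([0.97, 0.01, 0.01, 0.01]) == pytest.approx(0.879, abs=1e-3)

    def test_clonality_undefined_single(self):
        with pytest.raises(DegenerateInputError):
            clonality([1.0])

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_shannon_bound_and_oracle(self, weights):
        p = np.array(weights) / sum(weights)
        h = shannon_entropy(p)
        oracle = -sum(x * math.log(x) for x in p)
        assert h == pytest.approx(oracle, abs=1e-9)
        assert h <= math.log(len(p)) + 1e-9
        assert 0.0 <= clonality(p) <= 1.0

    def test_equality_iff_uniform(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(2, 20)
            p = rng.dirichlet(np.ones(n))
            if np.allclose(p, 1 / n):
                continue
            assert shannon_entropy(p) < math.log(n)


class TestRarefaction:
    def test_full_depth_exact(self, small_table):
        curve = rarefaction_curve(
            small_table, [small_table.total_reads], n_reps=20, seed=0
        )
        depth, mean, sd = curve[0]
        assert mean == len(small_table)
        assert sd == 0.0

    def test_depth_one(self, small_table):
        _, mean, _ = rarefaction_curve(small_table, [1], n_reps=20, seed=0)[0]
        assert mean == 1.0

    def test_hypergeometric_expectation(self):
        table = ClonotypeTable(
            "s",
            [Clonotype("CASSA", "V", "J", 50), Clonotype("CASSG", "V", "J", 50)],
        )
        _, mean, _ = rarefaction_curve(table, [10], n_reps=200, seed=1)[0]
        assert 1.9 <= mean <= 2.0

    def test_monotone_and_terminal(self, small_table):
        total = small_table.total_reads
        curve = rarefaction_curve(small_table, [1, 2, 4, total], n_reps=50, seed=2)
        means = [m for _, m, _ in curve]
        assert means == sorted(means)
        assert means[-1] == len(small_table)

    def test_depth_exceeds_reads(self, small_table):
        with pytest.raises(ValidationError):
            rarefaction_curve(small_table, [small_table.total_reads + 1])

    def test_reproducible(self, small_table):
        a = rarefaction_curve(small_table, [3], n_reps=30, seed=5)
        b = rarefaction_curve(small_table, [3], n_reps=30, seed=5)
        assert a == b


class TestSharing:
    def test_identical_tables(self, small_table):
        summary = clonotype_sharing([small_table, small_table])
        assert summary.private_fraction == 0.0

    def test_disjoint_tables(self, small_table):
        other = ClonotypeTable("s2", [Clonotype("CAWWW", "TRBV9", "TRBJ9", 1)])
        summary = clonotype_sharing([small_table, other])
        assert summary.private_fraction == 1.0
        assert summary.private_fraction + summary.shared_fraction == 1.0

    def test_one_of_ten_shared(self):
        shared = Clonotype("CASSSHARED", "TRBV1", "TRBJ1", 1)
        t1 = ClonotypeTable(
            "a",
            [shared] + [Clonotype(f"CASSA{'G' * i}", "TRBV1", "TRBJ1", 1)
                        for i in range(1, 4)],
        )
        t2 = ClonotypeTable(
            "b",
            [shared] + [Clonotype(f"CASSC{'G' * i}", "TRBV1", "TRBJ1", 1)
                        for i in range(1, 4)],
        )
        t3 = ClonotypeTable(
            "c",
            [Clonotype(f"CASSD{'G' * i}", "TRBV1", "TRBJ1", 1) for i in range(1, 4)],
        )
        summary = clonotype_sharing([t1, t2, t3])
        assert summary.n_union == 10
        assert summary.shared_fraction == pytest.approx(0.1)

    def test_requires_two_tables(self, small_table):
        with pytest.raises(EmptyInputError):
            clonotype_sharing([small_table])

    def test_cdr3_only_mode(self):
        t1 = ClonotypeTable("a", [Clonotype("CASSL", "TRBV1", "TRBJ1", 1)])
        t2 = ClonotypeTable("b", [Clonotype("CASSL", "TRBV2", "TRBJ2", 1)])
        assert clonotype_sharing([t1, t2], key="full").private_fraction == 1.0
        assert clonotype_sharing([t1, t2], key="cdr3").private_fraction == 0.0


class TestSegmentUsage:
    def test_v_usage(self):
        table = ClonotypeTable(
            "s",
            [
                Clonotype("CASSAAAAAAAA", "V1", "J1", 1),
                Clonotype("CASSAAAAAAAAAA", "V1", "J2", 1),
                Clonotype("CASSAAAAAAAAAAAA", "V2", "J1", 4),
            ],
        )
        profile = segment_usage(table)
        assert profile.v_usage == {"V1": 2, "V2": 1}
        assert profile.cdr3_length_median == 14
        assert profile.cdr3_length_min == 12
        assert profile.cdr3_length_max == 16
        assert profile.n_singletons == 2
        assert profile.n_multi == 1

    def test_usage_sums_to_n(self, small_table):
        profile = segment_usage(small_table)
        assert sum(profile.v_usage.values()) == profile.n_clonotypes
        assert sum(profile.j_usage.values()) == profile.n_clonotypes
        assert sum(profile.vj_pairing.values()) == profile.n_clonotypes
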