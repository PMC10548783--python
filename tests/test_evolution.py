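import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtconform.evolution import (
    ZAMYATNIN_VOLUMES,
    DomainPartition,
    branch_lengths_in_substitutions,
    bulkiness,
    count_indels,
    count_substitutions,
    first_cys_position,
    kn_ratio,
    lineage_descriptor_table,
    sequence_identity,
    substitution_persistence,
)
from mtconform.synthetic import (
    EvolutionSpec,
    simulate_sequence_evolution,
    tree_from_parent_map,
)

seq_strategy = st.text(alphabet="ACDKN-", min_size=4, max_size=12)


class TestCountSubstitutions:
    def test_identical_sequences_zero(self):
        assert count_substitutions("ACDEF", "ACDEF") == 0

    def test_single_difference(self):
        assert count_substitutions("ACDEF", "ACNEF") == 1

    def test_gap_column_is_indel_not_substitution(self):
        assert count_substitutions("AC-EF", "ACDEF") == 0
        assert count_indels("AC-EF", "ACDEF") == 1

    def test_region_restriction(self):
        assert count_substitutions("AAAA", "TTAA", region=(3, 4)) == 0
        assert count_substitutions("AAAA", "TTAA", region=(1, 2)) == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            count_substitutions("AAA", "AAAA")

    @given(a=seq_strategy, b=seq_strategy)
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_zero_iff_identical(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert count_substitutions(a, b) == count_substitutions(b, a)
        if a == b:
            assert count_substitutions(a, b) == 0


class TestSubstitutionPersistence:
    def test_descendant_equal_to_later_ancestor(self):
        a, b = "ACDEF", "ACNEW"
        assert substitution_persistence(a, b, b) == count_substitutions(a, b)

    def test_descendant_equal_to_earlier_ancestor(self):
        assert substitution_persistence("ACDEF", "ACNEW", "ACDEF") == 0

    def test_matches_bruteforce_enumeration_on_random_triples(self):
        rng = np.random.default_rng(5)
        alphabet = np.array(list("ACDKN"))
        for _ in range(50):
            a, b, d = (
                "".join(rng.choice(alphabet, size=10)) for _ in range(3)
            )
            brute = sum(
                1
                for x, y, z in zip(a, b, d)
                if x != y and x != "-" and y != "-" and z == y
            )
            assert substitution_persistence(a, b, d) == brute


class TestSequenceIdentity:
    def test_identical_under_every_policy(self):
        for policy in ("alignment_columns", "shorter_sequence", "mean_length"):
            assert sequence_identity("ACDK", "ACDK", denominator_policy=policy) == 1.0

    def test_simple_fraction(self):
        assert sequence_identity("AAAA", "AAAT") == 0.75

    def test_gapped_pair_against_hand_enumeration(self):
        a, b = "AC-KN-", "ACDK-C"
        # matches: columns 1,2,4 -> 3; columns with >=1 residue: all 6
        assert sequence_identity(a, b, denominator_policy="alignment_columns") == pytest.approx(3 / 6)
        assert sequence_identity(a, b, denominator_policy="shorter_sequence") == pytest.approx(3 / 4)
        assert sequence_identity(a, b, denominator_policy="mean_length") == pytest.approx(3 / 4.5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("--", "--")


class TestBulkiness:
    def test_empty_region_zero(self):
        assert bulkiness("ACD", region=(2, 1) if False else None) >= 0
        assert bulkiness("", region=None) == 0.0

    def test_glycine_additivity(self):
        assert bulkiness("GG") == pytest.approx(2 * ZAMYATNIN_VOLUMES["G"])

    def test_partition_additivity(self):
        seq = "MKCGTACDKWNCEF"
        part = DomainPartition((1, 5), (6, 7), (8, 14))
        total = bulkiness(seq)
        parts = sum(bulkiness(seq, region=r) for r in part.regions().values())
        assert total == pytest.approx(parts)

    def test_gly_to_trp_strictly_increases(self):
        seq = "ACGKA"
        assert bulkiness(seq.replace("G", "W")) > bulkiness(seq)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            bulkiness("ACX")


class TestKNRatio:
    def test_simple_ratio(self):
        # after the first Cys: 4 K, 2 N
        res = kn_ratio("MKNC" + "KKNKKN")
        assert (res.lys, res.asn) == (4, 2)
        assert res.ratio == pytest.approx(2.0)

    def test_zero_asn_flagged_undefined(self):
        res = kn_ratio("MCKKK")
        assert not res.defined and res.ratio is None and res.lys == 3

    def test_prefix_before_first_cys_excluded(self):
        with_prefix = kn_ratio("KKNNKN" + "CKKNK")
        without = kn_ratio("CKKNK")
        assert (with_prefix.lys, with_prefix.asn) == (without.lys, without.asn)

    def test_no_cys_rejected(self):
        with pytest.raises(ValueError):
            kn_ratio("KKNN")


class TestBranchLengths:
    def test_three_node_path_additivity(self):
        tree = tree_from_parent_map({"root": ["mid"], "mid": ["leaf"]}, "root")
        from mtconform.io_formats import AlignmentSet

        aln = AlignmentSet([
            ("root", "AAAAAA"), ("mid", "TTAAAA"), ("leaf", "TTCCCA")
        ])
        df = branch_lengths_in_substitutions(aln, tree)
        rec = df.set_index("node")
        assert rec.loc["mid", "substitutions_from_parent"] == 2
        assert rec.loc["leaf", "substitutions_from_parent"] == 3
        assert rec.loc["leaf", "cumulative_substitutions_from_root"] == 5

    def test_star_tree_identical_sequences_all_zero(self):
        tree = tree_from_parent_map({"root": ["a", "b", "c"]}, "root")
        from mtconform.io_formats import AlignmentSet

        aln = AlignmentSet([(n, "ACDK") for n in ("root", "a", "b", "c")])
        df = branch_lengths_in_substitutions(aln, tree)
        assert (df["substitutions_from_parent"] == 0).all()

    def test_missing_sequence_names_node(self):
        tree = tree_from_parent_map({"root": ["a", "b"]}, "root")
        from mtconform.errors import FormatError
        from mtconform.io_formats import AlignmentSet

        aln = AlignmentSet([("root", "ACDK"), ("a", "ACDK")])
        with pytest.raises(FormatError, match="'b'"):
            branch_lengths_in_substitutions(aln, tree)

    def test_recovers_simulated_branch_counts_exactly(self):
        """Generator/analyzer round trip on simulated evolution."""
        tree = tree_from_parent_map(
            {"r": ["i1", "d"], "i1": ["a", "b"]}, "r"
        )
        counts = {"i1": 4, "a": 11, "b": 2, "d": 7}
        spec = EvolutionSpec(
            root_sequence="MA" + "CAGCKCGQCT" * 5 + "KN",
            tree=tree,
            branch_counts=counts,
            unique_columns=True,
            seed=17,
        )
        sim = simulate_sequence_evolution(spec)
        df = branch_lengths_in_substitutions(sim.alignment, sim.tree)
        rec = df.set_index("node")["substitutions_from_parent"].to_dict()
        for node, expected in counts.items():
            assert rec[node] == expected
        # with globally unique columns, path sums equal direct root-vs-node counts
        root_seq = sim.alignment.get("r")
        for node in ("a", "b", "d"):
            direct = count_substitutions(root_seq, sim.alignment.get(node))
            cum = df.set_index("node").loc[node, "cumulative_substitutions_from_root"]
            assert direct == cum

    def test_cys_columns_conserved_when_forbidden(self):
        tree = tree_from_parent_map({"r": ["x"]}, "r")
        spec = EvolutionSpec(
            root_sequence="ACCA" * 5,
            tree=tree,
            branch_counts={"x": 8},
            forbid_cys_substitution=True,
            seed=3,
        )
        sim = simulate_sequence_evolution(spec)
        for i, res in enumerate(spec.root_sequence):
            if res == "C":
                assert sim.alignment.get("x")[i] == "C"


class TestLineageFixtureBookkeeping:
    def test_published_substitution_counts_recovered(self, lineage):
        g = lineage.alignment.get
        nd = lineage.partition.n_domain
        assert len(lineage.alignment) == 61
        assert count_substitutions(g("a1CdMT"), g("a2CuMT")) == 11
        assert substitution_persistence(g("a1CdMT"), g("a2CuMT"), g("HpCuMT")) == 7
        assert count_substitutions(g("a2CuMT"), g("a3CuMT")) == 8
        assert substitution_persistence(g("a2CuMT"), g("a3CuMT"), g("HpCuMT")) == 4
        assert count_substitutions(g("a3CuMT"), g("HpUnMT2"), region=nd) == 1
        assert count_substitutions(g("a3CuMT"), g("HpCuMT"), region=nd) == 5
        assert count_substitutions(g("a4CdMT"), g("HpCdMT"), region=nd) == 8

    def test_cd_lineage_cumulative_total(self, lineage):
        df = branch_lengths_in_substitutions(lineage.alignment, lineage.tree)
        rec = df.set_index("node")
        assert rec.loc["HpCdMT", "cumulative_substitutions_from_root"] == 23
        assert rec.loc["a2CdMT", "substitutions_from_parent"] == 0

    def test_deletion_travels_through_indel_channel(self, lineage):
        g = lineage.alignment.get
        assert count_indels(g("a3CuMT"), g("a4UnMT")) == 1
        assert count_substitutions(g("a3CuMT"), g("a4UnMT")) == 7

    def test_descriptor_table_is_complete_and_ordered(self, lineage):
        table = lineage_descriptor_table(
            lineage.alignment, lineage.tree, partition=lineage.partition
        )
        rec = table.set_index("node")
        assert rec.loc["a1CdMT", "identity_to_root"] == 1.0
        assert rec.loc["HpCdMT", "cumulative_substitutions_from_root"] == 23
        # identity never exceeds 1 and falls with substitutions
        assert ((table["identity_to_root"] > 0) & (table["identity_to_root"] <= 1)).all()
        assert rec.loc["HpCuMT", "identity_to_root"] < rec.loc["a2CuMT", "identity_to_root"]
        assert rec.loc["HpCuMT", "lineage"] == "Cu"
        assert {"substitutions_n_domain", "identity_to_root_c_domain"} <= set(table.columns)

    def test_order_invariance_of_counts(self, lineage):
        from mtconform.io_formats import AlignmentSet

        reordered = AlignmentSet(list(reversed(lineage.alignment.sequences)))
        df1 = branch_lengths_in_substitutions(lineage.alignment, lineage.tree)
        df2 = branch_lengths_in_substitutions(reordered, lineage.tree)
        assert df1["substitutions_from_parent"].tolist() == df2["substitutions_from_parent"].tolist()
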