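"""Pairwise identity, greedy OTU clustering, chimera flagging, OTU table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle_helpers as oh
from conftest import random_dna
from planktax.cluster import (OTU, build_otu_table, cluster_greedy,
                              dereplicate, flag_chimeras, pairwise_identity)


def mutate(rng, seq, n):
    arr = list(seq)
    for p in rng.choice(len(arr), size=n, replace=False):
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = random_dna(rng, 300)
        assert pairwise_identity(s, s) == 1.0

    def test_three_substitutions_over_300(self, rng):
        s = random_dna(rng, 300)
        assert pairwise_identity(s, mutate(rng, s, 3)) == pytest.approx(
            297 / 300)

    def test_gap_columns_count_as_mismatches(self):
        # best alignment has one gap column: 4 matches / 5 columns
        assert pairwise_identity("ACGT", "ACGGT") == pytest.approx(4 / 5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(120):
            la = int(rng.integers(1, 61))
            lb = int(rng.integers(max(1, la - 6), min(60, la + 6) + 1))
            a, b = random_dna(rng, la), random_dna(rng, lb)
            assert pairwise_identity(a, b) == pytest.approx(
                oh.identity_oracle(a, b))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=30),
           st.text(alphabet="ACGT", min_size=1, max_size=30))
    def test_identity_properties_hold_on_arbitrary_pairs(self, a, b):
        ident = pairwise_identity(a, b)
        assert 0.0 <= ident <= 1.0
        assert ident == pytest.approx(oh.identity_oracle(a, b))
        assert (ident == 1.0) == (a == b)

    def test_symmetric_in_distance(self, rng):
        # identity is defined on a's coordinates; distances agree both ways
        for _ in range(20):
            a, b = random_dna(rng, 40), random_dna(rng, 43)
            ia, ib = pairwise_identity(a, b), pairwise_identity(b, a)
            assert ia == pytest.approx(ib)


class TestGreedyClustering:
    def test_replicates_collapse_to_one_otu(self, rng):
        s = random_dna(rng, 300)
        reads = [(s, f"S{i % 2}", f"r{i}") for i in range(10)]
        otus = cluster_greedy(reads)
        assert len(otus) == 1
        assert otus[0].total == 10
        assert otus[0].counts == {"S0": 5, "S1": 5}

    def test_identity_threshold_is_inclusive(self, rng):
        s = random_dna(rng, 1000)
        at_990 = mutate(rng, s, 10)   # identity 0.990
        at_989 = mutate(rng, s, 11)   # identity 0.989
        reads = [(s, "S", "a"), (s, "S", "b"), (at_990, "S", "c")]
        assert len(cluster_greedy(reads, 0.990)) == 1
        reads = [(s, "S", "a"), (s, "S", "b"), (at_989, "S", "c")]
        assert len(cluster_greedy(reads, 0.990)) == 2

    def test_matches_bruteforce_replay(self, rng):
        for _ in range(30):
            base = random_dna(rng, 50)
            uniques = {}
            for _ in range(int(rng.integers(3, 15))):
                seq = mutate(rng, base, int(rng.integers(0, 6)))
                uniques[seq] = uniques.get(seq, 0) + int(rng.integers(1, 9))
            reads = [(seq, "S", f"{seq[:6]}:{i}")
                     for seq, c in uniques.items() for i in range(c)]
            otus = cluster_greedy(reads, 0.94)
            expected = oh.greedy_cluster_bruteforce(
                list(uniques.items()), 0.94)
            assert sorted(o.representative for o in otus) == \
                sorted(c[0] for c in expected)
            got_members = {o.representative: sorted(set(
                m.split(":")[0] for m in o.member_ids)) for o in otus}
            exp_members = {c[0]: sorted(set(s[:6] for s in c))
                           for c in expected}
            assert got_members == exp_members

    def test_members_align_to_representative_above_threshold(self, rng):
        base = random_dna(rng, 120)
        reads = []
        for i in range(40):
            reads.append((mutate(rng, base, int(rng.integers(0, 4))),
                          "S", f"r{i}"))
        otus = cluster_greedy(reads, 0.97)
        for o in otus:
            member_seqs = {s for s, _, rid in reads if rid in set(o.member_ids)}
            for s in member_seqs:
                assert pairwise_identity(s, o.representative) >= 0.97

    def test_count_conservation(self, rng):
        reads = [(random_dna(rng, 60), f"S{i % 3}", f"r{i}")
                 for i in range(50)]
        otus = cluster_greedy(reads, 0.9)
        assert sum(o.total for o in otus) == 50


class TestChimeraFlagging:
    def _otu(self, i, seq, total):
        return OTU(otu_id=f"OTU{i:03d}", representative=seq,
                   member_ids=[], counts={"S": total})

    def test_constructed_two_parent_chimera_flagged(self, rng):
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        chimera = a[:150] + b[150:]
        otus = [self._otu(1, a, 100), self._otu(2, b, 80),
                self._otu(3, chimera, 5)]
        kept, flagged = flag_chimeras(otus)
        assert [o.otu_id for o in flagged] == ["OTU003"]
        assert {o.otu_id for o in kept} == {"OTU001", "OTU002"}

    def test_divergent_non_chimera_retained(self, rng):
        seqs = [random_dna(rng, 300) for _ in range(3)]
        otus = [self._otu(i, s, 100 - 10 * i) for i, s in enumerate(seqs)]
        kept, flagged = flag_chimeras(otus)
        assert flagged == []
        assert len(kept) == 3

    def test_simulated_chimeras_recovered_parents_untouched(self):
        """Across seeds, most truth-labelled chimeric OTUs are flagged and
        no parent-taxon OTU is falsely flagged."""
        from planktax.cluster import build_otu_table
        from planktax.qc import QCParams, run_qc
        from planktax.simulate import (SimParams, generate_scenario,
                                       generate_taxon_pool, simulate_reads)
        recalls = []
        for seed in range(5):
            params = SimParams(seed=seed, depth_per_sample=400,
                               chimera_rate=0.05,
                               substitution_error_rate=0.0)
            pool = generate_taxon_pool(6, 3, frac_warm=0.0, params=params,
                                       markers=("18S",))
            scenario = generate_scenario(pool, years=1, params=params)
            scenario.samples = scenario.samples[:1]
            reads, truth = simulate_reads(scenario, "18S", params)
            pairs = list(zip(*next(iter(reads.values()))))
            merged, _ = run_qc(pairs, QCParams())
            otus = cluster_greedy(
                [(m.bases, m.read_id.split(":")[0], m.read_id)
                 for m in merged])
            kept, flagged = flag_chimeras(otus)

            def is_chimeric(otu):
                chim = sum(":chimera~" in m for m in otu.member_ids)
                return chim > len(otu.member_ids) / 2

            truth_chim = [o for o in otus if is_chimeric(o) and o.total >= 2]
            if truth_chim:
                recalls.append(
                    sum(1 for o in truth_chim if o in flagged)
                    / len(truth_chim))
            # parents (pure-taxon OTUs) are never flagged
            assert all(is_chimeric(o) for o in flagged)
        assert np.mean(recalls) >= 0.8


class TestOtuTable:
    def _otu(self, i, counts):
        return OTU(otu_id=f"OTU{i:03d}", representative="ACGT",
                   member_ids=[], counts=counts)

    def test_singleton_boundary(self):
        otus = [self._otu(1, {"A": 1}), self._otu(2, {"A": 1, "B": 1}),
                self._otu(3, {"B": 5})]
        table = build_otu_table(otus)
        assert list(table.index) == ["OTU002", "OTU003"]
        assert table.loc["OTU002"].sum() == 2

    def test_empty_input_gives_empty_table(self):
        assert build_otu_table([]).empty

    def test_count_conservation_audit(self, rng):
        otus = []
        for i in range(20):
            counts = {f"S{j}": int(rng.integers(0, 4)) for j in range(4)}
            otus.append(self._otu(i, counts))
        table = build_otu_table(otus)
        removed = sum(o.total for o in otus if o.total < 2)
        assert table.values.sum() == sum(o.total for o in otus) - removed
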