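"""Phylogenies, conversion detection, positional statistics, fixation."""

import io

import dendropy
import numpy as np
import pytest

from cryptsim.lineage import (
    PhylogenyTree,
    advantage_ratio,
    build_tree,
    count_advantaged_scs,
    detect_monoclonal_conversion,
    export_newick,
    fixation_statistics,
    fixations_per_n_from_distributions,
    positional_distributions,
)


class TestTreeConstruction:
    def test_single_division_gives_one_vertex_two_leaves(self):
        tree = PhylogenyTree([1])
        tree.record_division(1, (2, 3), t=5.0, P=1.0)
        tree.finalize(12.0)
        assert tree.n_vertices() == 1
        assert sorted(tree.leaves()) == [2, 3]
        assert tree.edge_length(2) == pytest.approx(7.0)

    def test_chain_of_three_divisions(self):
        tree = PhylogenyTree([1])
        tree.record_division(1, (2, 3), 4.0, 0.5)
        tree.record_division(2, (4, 5), 9.0, 1.5)
        tree.record_division(4, (6, 7), 15.0, 2.5)
        tree.finalize(20.0)
        assert tree.n_vertices() == 3
        assert len(tree.leaves()) == 4
        # total edge length: root 4 + (2:5) + (3:16) + (4:6) + (5:11) + 5 + 5
        assert tree.total_edge_length() == pytest.approx(4 + 5 + 16 + 6 + 11 + 5 + 5)

    def test_unknown_mother_rejected(self):
        tree = PhylogenyTree([1])
        with pytest.raises(KeyError):
            tree.record_division(99, (2, 3), 1.0, 0.0)

    def test_double_division_rejected(self):
        tree = PhylogenyTree([1])
        tree.record_division(1, (2, 3), 1.0, 0.0)
        with pytest.raises(ValueError):
            tree.record_division(1, (4, 5), 2.0, 0.0)

    def test_replay_bookkeeping(self, rng):
        """Leaf count equals live lineage count after replaying random logs."""
        recs = []
        live = [0]
        next_id = 1
        t = 0.0
        for _ in range(30):
            t += 1.0
            m = int(rng.choice(live))
            d1, d2 = next_id, next_id + 1
            next_id += 2
            recs.append((m, d1, d2, t, float(rng.uniform(0, 5))))
            live.remove(m)
            live += [d1, d2]
        tree = build_tree([0], recs, end_time=t + 1)
        assert sorted(tree.leaves()) == sorted(live)
        assert tree.n_vertices() == 30


class TestConversionDetection:
    def test_single_founder_converts_immediately(self):
        series = [(0.0, np.array([7, 7, 7]))]
        assert detect_monoclonal_conversion(series) == 0.0

    def test_two_persistent_clones_never_convert(self):
        series = [(t, np.array([1, 2])) for t in range(10)]
        assert detect_monoclonal_conversion(series) is None

    def test_first_time_reported(self):
        series = [
            (0.0, np.array([1, 2, 3])),
            (5.0, np.array([1, 1, 2])),
            (9.0, np.array([1, 1, 1])),
            (12.0, np.array([1, 1, 1])),
        ]
        assert detect_monoclonal_conversion(series) == 9.0

    def test_moran_toy_matches_transition_matrix_oracle(self, rng):
        """3-cell neutral Moran model: simulated mean conversion time agrees
        with the absorbing-Markov-chain expectation within 2 s.e."""
        # states of the chain: clone-size partition (1,1,1) or (2,1); one
        # birth-death exchange per step (ordered pair, reproducer != dier)
        # (1,1,1) -> (2,1) always; (2,1) -> absorbed w.p. 1/3, else (2,1)
        Q = np.array([[0.0, 1.0], [0.0, 2.0 / 3.0]])
        expected = np.linalg.solve(np.eye(2) - Q, np.ones(2))[0]

        def simulate():
            founders = np.array([0, 1, 2])
            t = 0
            series = []
            while True:
                series.append((t, founders.copy()))
                if len(set(founders)) == 1:
                    return detect_monoclonal_conversion(series)
                i, j = rng.choice(3, size=2, replace=False)
                founders[j] = founders[i]
                t += 1

        times = np.array([simulate() for _ in range(3000)], dtype=float)
        se = times.std() / np.sqrt(len(times))
        assert abs(times.mean() - expected) < 2 * se


class TestPositionalDistributions:
    def test_all_winners_from_one_bin(self):
        dist = positional_distributions(
            sc_start_P=[np.array([1.2, 2.5]), np.array([1.7, 3.1])],
            division_P=[np.array([2.0]), np.array([3.0])],
            winner_P=[1.4, 1.9],
        )
        assert dist.w[1] == pytest.approx(1.0)
        assert dist.w.sum() == pytest.approx(1.0)

    def test_normalisation(self, rng):
        reps = 6
        dist = positional_distributions(
            [rng.uniform(0, 5, 10) for _ in range(reps)],
            [rng.uniform(0, 8, 40) for _ in range(reps)],
            [float(rng.uniform(0, 4)) for _ in range(reps)],
        )
        assert dist.f.sum() == pytest.approx(1.0)
        assert dist.p.sum() == pytest.approx(1.0)
        assert dist.w.sum() == pytest.approx(1.0)
        assert (dist.f >= 0).all() and (dist.p >= 0).all()

    def test_winner_distribution_recovers_categorical(self, rng):
        """w recovers a known categorical placement within multinomial error."""
        probs = np.array([0.5, 0.3, 0.2])
        n = 400
        winners = rng.choice(3, size=n, p=probs) + 0.5
        dist = positional_distributions(
            [np.array([0.5, 1.5, 2.5])] * n,
            [np.array([1.0])] * n,
            list(winners.astype(float)),
        )
        for b in range(3):
            se = np.sqrt(probs[b] * (1 - probs[b]) / n)
            assert abs(dist.w[b] - probs[b]) < 4 * se

    def test_absent_winners_reported_as_none(self):
        dist = positional_distributions(
            [np.array([1.0])], [np.array([1.0])], [None]
        )
        assert dist.w is None
        with pytest.raises(ValueError):
            advantage_ratio(dist)


class TestAdvantageRatio:
    def test_neutral_identity(self):
        dist = positional_distributions(
            [np.array([0.5, 1.5, 2.5])] * 30,
            [np.array([1.0])] * 30,
            [0.5, 1.5, 2.5] * 10,
        )
        df = advantage_ratio(dist)
        assert np.allclose(df["ratio"], 1.0)

    def test_zero_f_bins_excluded(self):
        dist = positional_distributions(
            [np.array([1.5, 2.5])], [np.array([1.0])], [1.5]
        )
        df = advantage_ratio(dist)
        assert set(df["P_bin"]) == {1, 2}


class TestAdvantagedCount:
    def test_seven_scs_in_winning_bins(self):
        sc_start = [np.array([0.5, 1.5, 1.7, 2.2, 2.8, 3.1, 3.9, 5.5, 6.5])]
        dist = positional_distributions(
            sc_start, [np.array([1.0])], [2.0]
        )
        dist.w = np.zeros(31)
        dist.w[:4] = 0.25  # winners observed in bins 0-3 only
        mean, sd = count_advantaged_scs(sc_start, dist)
        assert mean == 7.0

    def test_w_positive_everywhere_counts_all(self):
        sc_start = [np.array([0.5, 1.5, 8.5])]
        dist = positional_distributions(sc_start, [np.array([1.0])], [0.5])
        dist.w = np.full(31, 1 / 31)
        mean, _ = count_advantaged_scs(sc_start, dist)
        assert mean == 3.0

    def test_matches_brute_force(self, rng):
        sc_start = [rng.uniform(0, 6, 12) for _ in range(5)]
        winners = [float(rng.uniform(0, 3)) for _ in range(5)]
        dist = positional_distributions(
            sc_start, [np.array([1.0])] * 5, winners
        )
        mean, sd = count_advantaged_scs(sc_start, dist)
        good = set(np.floor(winners).astype(int))
        counts = [
            sum(int(np.floor(p)) in good for p in P) for P in sc_start
        ]
        assert mean == pytest.approx(np.mean(counts))


class TestFixationStatistics:
    def test_all_fixed(self):
        st = fixation_statistics(["fixed"] * 5)
        assert st.fixation_probability == 1.0

    def test_neutral_loss_fraction_thirteen_scs(self):
        """Analytic neutral drift: per-clone fixation 1/n, loss 1 - 1/n."""
        # 13 equivalent clones: exactly one fixes per resolved competition
        outcomes = ["fixed"] + ["lost"] * 12
        st = fixation_statistics(outcomes)
        assert st.loss_probability == pytest.approx(12 / 13)
        assert st.fixations_per_n(13) == pytest.approx(1.0)

    def test_censored_separated(self):
        st = fixation_statistics(["fixed", "lost", "censored"])
        assert st.n_resolved == 2 and st.n_censored == 1

    def test_all_censored_undefined(self):
        st = fixation_statistics(["censored", "censored"])
        with pytest.raises(ZeroDivisionError):
            st.fixation_probability

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            fixation_statistics(["maybe"])

    def test_random_placement_gives_unity(self, rng):
        f = rng.dirichlet(np.ones(6))
        w = rng.dirichlet(np.ones(6))
        assert fixations_per_n_from_distributions(f, w, f) == pytest.approx(1.0)


class TestNewickExport:
    def test_single_division_pattern(self):
        tree = PhylogenyTree([1])
        tree.record_division(1, (2, 3), 5.0, 1.0)
        tree.close_leaf(2, 10.0, "specified")
        tree.close_leaf(3, 12.0, "exit")
        nwk, ann = export_newick(tree)
        assert nwk == "(c2:5,c3:7)c1:5;"
        assert set(ann["node"]) == {"c1", "c2", "c3"}

    def test_round_trip_preserves_leaves_and_length(self, rng):
        """Export -> parse (dendropy) -> compare leaf set and total length."""
        tree = PhylogenyTree([0])
        live = [0]
        next_id = 1
        t = 0.0
        for _ in range(50):
            t += float(rng.uniform(0.5, 2.0))
            m = int(rng.choice(live))
            tree.record_division(m, (next_id, next_id + 1), t, 1.0)
            live.remove(m)
            live += [next_id, next_id + 1]
            next_id += 2
        tree.finalize(t + 3.0)
        nwk, _ = export_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == {f"c{c}" for c in tree.leaves()}
        assert parsed.length() == pytest.approx(tree.total_edge_length())

    def test_reexport_idempotent(self):
        tree = PhylogenyTree([1])
        tree.record_division(1, (2, 3), 4.0, 0.0)
        tree.finalize(9.0)
        nwk1, _ = export_newick(tree)
        parsed = dendropy.Tree.get(data=nwk1, schema="newick")
        out = io.StringIO()
        parsed.write(file=out, schema="newick",
                     suppress_rooting=True, suppress_internal_node_labels=False)
        nwk2 = out.getvalue().strip()
        parsed2 = dendropy.Tree.get(data=nwk2, schema="newick")
        assert parsed2.length() == pytest.approx(tree.total_edge_length())

    def test_empty_tree(self):
        nwk, ann = export_newick(PhylogenyTree([]))
        assert nwk == ";" and len(ann) == 0
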