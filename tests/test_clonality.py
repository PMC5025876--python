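"""Clonal grouping, overlap quantification and the bootstrap null model."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

import clonmix as cm
from clonmix.clonality import (
    MODE_PRESERVE_SIZES,
    MODE_UNIFORM_PARTITION,
    VERDICT_FEWER,
    VERDICT_NULL,
    BootstrapResult,
    bootstrap_mixed_clones,
    count_mixed,
    exact_preserve_sizes_null,
    group_clones,
    junction_identity,
    overlap_table,
    relatedness_verdict,
)


class TestGrouping:
    def test_identical_junctions_form_one_clone(self, make_annotated):
        a = make_annotated("s1", [(10, "C")], cdr3_nt="GCTAGATATTAT")
        b = make_annotated("s2", [(20, "A")], cdr3_nt="GCTAGATATTAT")
        clones, unassigned = group_clones([a, b])
        assert len(clones) == 1 and clones[0].size == 2 and not unassigned

    def test_dissimilar_junctions_stay_apart(self, make_annotated):
        a = make_annotated("s1", [], cdr3_nt="GCTAGATATTAT")
        b = make_annotated("s2", [], cdr3_nt="TTGCACGCAGGA")  # identity ~0.17
        assert junction_identity(a.cdr3_nt, b.cdr3_nt) < 0.9
        clones, _ = group_clones([a, b])
        assert len(clones) == 2

    def test_grouping_is_within_mouse(self, make_annotated):
        a = make_annotated("s1", [], cdr3_nt="GCTAGATATTAT", mouse="m1")
        b = make_annotated("s2", [], cdr3_nt="GCTAGATATTAT", mouse="m2")
        clones, _ = group_clones([a, b])
        assert len(clones) == 2

    def test_undefined_cdr3_goes_to_unassigned_pool(self, make_annotated):
        a = make_annotated("s1", [], cdr3_nt="GCTAGATATTAT")
        b = make_annotated("s2", [], cdr3_nt=None)
        b.cdr3_aa = None
        clones, unassigned = group_clones([a, b])
        assert unassigned == ["s2"]

    def test_partition_property(self, long_run):
        ids = [a.seq_id for a in long_run["dataset"] if a.usable]
        seen = [m for c in long_run["clones"] for m in c.member_ids]
        seen += long_run["unassigned"]
        assert sorted(seen) == sorted(ids)

    def test_truth_clone_recovery(self, ref):
        cfg = cm.SimulationConfig(
            seed=5, n_mice=1, clones_per_group=10, clone_size_dist=("fixed", 10),
            np_fraction=0.0, junction_mut_prob=0.1, junction_separation=(0.95, 0.7),
            target_mut_mean=5.0,
        )
        records, truth = cm.simulate_repertoire(cfg, ref)
        dataset = cm.annotate(records, ref)
        # brute-force pairwise junction identities confirm the separation regime
        truth_clone = truth.clone_partition()
        for a, b in itertools.combinations(dataset, 2):
            if len(a.cdr3_nt) != len(b.cdr3_nt):
                continue
            ident = junction_identity(a.cdr3_nt, b.cdr3_nt)
            if truth_clone[a.seq_id] == truth_clone[b.seq_id]:
                assert ident >= 0.95
            else:
                assert ident <= 0.7
        clones, unassigned = group_clones(dataset, threshold=0.90)
        assert not unassigned
        pred = {m: c.clone_id for c in clones for m in c.member_ids}
        ids = [a.seq_id for a in dataset]
        ari = adjusted_rand_score(
            [truth_clone[i] for i in ids], [pred[i] for i in ids]
        )
        assert ari == 1.0

    def test_deterministic_under_input_order(self, long_run):
        reordered = list(reversed(long_run["dataset"]))
        clones_a, _ = group_clones(long_run["dataset"])
        clones_b, _ = group_clones(reordered)
        assert [(c.clone_id, c.member_ids) for c in clones_a] == [
            (c.clone_id, c.member_ids) for c in clones_b
        ]


class TestOverlap:
    def test_singletons_give_no_mixed_clones(self, make_annotated):
        anns = [
            make_annotated(f"s{i}", [], cdr3_nt=nt, subset=sub)
            for i, (nt, sub) in enumerate(
                [("GCTAGATATTAT", "MEMORY"), ("TTGCACGCAGGA", "LONGLIVED_PC")]
            )
        ]
        clones, _ = group_clones(anns)
        summary, detail = overlap_table(clones, "MEMORY", "LONGLIVED_PC")
        assert summary["n_mixed"].sum() == 0 and detail.empty

    def test_mixed_clone_fractions(self, make_clone):
        mixed = make_clone(
            "c1", [f"s{i}" for i in range(6)],
            pairs=[("BM", "LONGLIVED_PC")] * 5 + [("SI_LP", "MEMORY")],
        )
        rest = make_clone(
            "c2", ["t0", "t1", "t2"], pairs=[("SI_LP", "MEMORY")] * 3
        )
        lone = make_clone("c3", ["u0"], pairs=[("BM", "LONGLIVED_PC")])
        summary, detail = overlap_table([mixed, rest, lone], "LONGLIVED_PC", "MEMORY")
        assert summary.loc[0, "n_mixed"] == 1
        assert detail.loc[0, "frac_of_LONGLIVED_PC"] == pytest.approx(5 / 6)
        assert detail.loc[0, "frac_of_MEMORY"] == pytest.approx(1 / 4)

    def test_absent_label_reports_zeros(self, make_clone):
        clone = make_clone("c1", ["s0"], pairs=[("PP", "MEMORY")])
        summary, _ = overlap_table([clone], "MEMORY", "BOOST_PC")
        assert summary.loc[0, "n_BOOST_PC"] == 0 and summary.loc[0, "n_mixed"] == 0

    @pytest.mark.parametrize("mixing,expect_mixed", [(0.0, "none"), (1.0, "all")])
    def test_truth_mixing_extremes(self, ref, mixing, expect_mixed):
        cfg = cm.SimulationConfig(
            seed=8, n_mice=2, clones_per_group=15, clone_size_dist=("fixed", 4),
            mixing_param=mixing, target_mut_mean=3.0,
        )
        _, truth = cm.simulate_repertoire(cfg, ref)
        mixed_flags = [c["mixed"] for c in truth.clones.values()]
        if expect_mixed == "none":
            assert not any(mixed_flags)
        else:
            assert all(mixed_flags)  # every clone has >= 2 members here


def _exact_mean_by_hypergeometric(n_a, sizes):
    """Independent oracle: E[mixed] by linearity + hypergeometric tails."""
    n = sum(sizes)
    mean = 0.0
    for s in sizes:
        p_all_a = hypergeom.pmf(s, n, n_a, s)
        p_no_a = hypergeom.pmf(0, n, n_a, s)
        mean += 1.0 - p_all_a - p_no_a
    return mean


def _partitions(n, largest=None):
    largest = largest or n
    if n == 0:
        yield ()
        return
    for first in range(min(n, largest), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


class TestBootstrap:
    def test_single_clone_two_compartments_is_degenerate(self):
        cells = [("g", "A"), ("g", "B")]
        res = bootstrap_mixed_clones(
            cells, observed_mixed=1, clone_sizes_per_group={"g": [2]},
            n_runs=500, seed=1,
        )
        assert res.degenerate and res.null_mean == 1.0 and res.null_sd == 0.0
        assert relatedness_verdict(res) == VERDICT_NULL

    def test_all_singletons_never_mixed(self):
        cells = [("g", "A"), ("g", "A"), ("g", "B")]
        res = bootstrap_mixed_clones(
            cells, observed_mixed=0, clone_sizes_per_group={"g": [1, 1, 1]},
            n_runs=500, seed=1,
        )
        assert res.degenerate and res.null_mean == 0.0 and res.observed_mixed == 0

    def test_exact_null_matches_hypergeometric_on_all_small_instances(self):
        # every clone-size partition and label count with <= 8 cells
        for n in range(2, 9):
            for sizes in _partitions(n):
                for n_a in range(0, n + 1):
                    labels = [True] * n_a + [False] * (n - n_a)
                    mean, _ = exact_preserve_sizes_null(labels, list(sizes))
                    expected = _exact_mean_by_hypergeometric(n_a, sizes)
                    assert mean == pytest.approx(expected, abs=1e-12)

    def test_simulated_null_mean_within_three_se_of_exact(self):
        labels = [True, True, False, False]
        sizes = [2, 2]
        mean, sd = exact_preserve_sizes_null(labels, sizes)
        assert mean == pytest.approx(4 / 3)  # enumeration of 4!/(2!2!) arrangements
        cells = [("g", "A" if l else "B") for l in labels]
        res = bootstrap_mixed_clones(
            cells, observed_mixed=0, clone_sizes_per_group={"g": sizes},
            n_runs=10_000, seed=9,
        )
        se = sd / np.sqrt(res.n_runs)
        assert abs(res.null_mean - mean) <= 3 * se

    def test_uniform_partition_mode_runs_and_differs(self):
        cells = [("g", lab) for lab in "AABB"]
        res = bootstrap_mixed_clones(
            cells, observed_mixed=0, n_clones_per_group={"g": 2},
            n_runs=2000, mode=MODE_UNIFORM_PARTITION, seed=4,
        )
        assert res.mode == MODE_UNIFORM_PARTITION and res.n_runs == 2000
        assert 0 < res.null_mean < 2

    def test_more_clones_than_cells_rejected(self):
        with pytest.raises(ValueError, match="clones"):
            bootstrap_mixed_clones(
                [("g", "A"), ("g", "B")], observed_mixed=0,
                clone_sizes_per_group={"g": [1, 1, 1]}, n_runs=10, seed=0,
            )

    def test_bit_identical_given_seed(self):
        cells = [("g", "A")] * 10 + [("g", "B")] * 10
        sizes = {"g": [4, 3, 3, 2, 2, 2, 2, 1, 1]}
        a = bootstrap_mixed_clones(cells, 3, clone_sizes_per_group=sizes, n_runs=2000, seed=42)
        b = bootstrap_mixed_clones(cells, 3, clone_sizes_per_group=sizes, n_runs=2000, seed=42)
        assert a == b

    def test_verdicts(self):
        base = dict(
            observed_mixed=5, null_mean=5.0, null_sd=1.0, z=0.0, p_two_sided=1.0,
            empirical_p=1.0, n_runs=100, seed=0, mode=MODE_PRESERVE_SIZES,
        )
        assert relatedness_verdict(BootstrapResult(**base)) == VERDICT_NULL
        low = {**base, "observed_mixed": 0, "z": -5.0, "p_two_sided": 1e-6}
        assert relatedness_verdict(BootstrapResult(**low)) == VERDICT_FEWER

    def test_calibrated_under_the_null(self):
        # modest replicate count here; the full calibration lives in acceptance
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 200
        for r in range(reps):
            cells, sizes, observed = [], {}, 0
            for g in ("g1", "g2", "g3"):
                n = 50
                szs = []
                while sum(szs) < n:
                    szs.append(min(int(rng.geometric(0.4)), n - sum(szs)))
                labs = np.zeros(n, bool)
                labs[: n // 2] = True
                rng.shuffle(labs)
                offsets = np.concatenate([[0], np.cumsum(szs)[:-1]])
                counts_a = np.add.reduceat(labs, offsets)
                sarr = np.array(szs)
                observed += int(((counts_a > 0) & (counts_a < sarr)).sum())
                cells.extend([(g, "A" if l else "B") for l in labs])
                sizes[g] = szs
            res = bootstrap_mixed_clones(
                cells, observed_mixed=observed, clone_sizes_per_group=sizes,
                n_runs=1000, seed=90_000 + r, axis_labels=("A", "B"),
            )
            if not res.degenerate and res.p_two_sided < 0.05:
                rejections += 1
        assert 0.05 - 0.03 <= rejections / reps <= 0.05 + 0.03


def test_count_mixed_agrees_with_truth(ref):
    cfg = cm.SimulationConfig(
        seed=14, n_mice=2, clones_per_group=12, clone_size_dist=("fixed", 4),
        mixing_param=0.5, target_mut_mean=3.0, np_fraction=1.0,
        junction_separation=(0.95, 0.7), junction_mut_prob=0.0,
        subset_a="MEMORY", subset_b="LONGLIVED_PC",
    )
    records, truth = cm.simulate_repertoire(cfg, ref)
    dataset = cm.annotate(records, ref)
    clones, _ = cm.group_clones(dataset)
    observed = count_mixed(clones, "MEMORY", "LONGLIVED_PC")
    assert observed == truth.realized["n_mixed_clones"]
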