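"""Schedules, simulated observers, d', RDM, congruity, clustering, paired t."""

import numpy as np
import pytest
from scipy import stats

from mammotex import (
    RDM,
    DegenerateDataError,
    InputError,
    ObserverModel,
    ParameterError,
    StimulusSet,
    StructuralError,
    build_rdm,
    dprime,
    dprime_from_rates,
    hca,
    make_schedule,
    paired_rating_test,
    rdm_congruity,
    simulate_observer,
    simulate_panel,
)


@pytest.fixture(scope="module")
def stimuli():
    return StimulusSet((
        ("O1", "S1", "normal"),
        ("O2", "S2", "normal"),
        ("O3", "S3", "cancer"),
        ("O4", "S4", "cancer"),
    ))


class TestSchedule:
    def test_every_image_presented_enough(self, stimuli):
        sched = make_schedule(stimuli, 10, experiment=1, seed=0)
        counts = sched.trials["stim_a"].value_counts()
        assert len(counts) == 8
        assert (counts >= 10).all()

    def test_exact_truth_balance(self, stimuli):
        sched = make_schedule(stimuli, 10, experiment=1, seed=0)
        assert sched.trials["truth_synth"].mean() == 0.5

    def test_same_seed_same_order(self, stimuli):
        a = make_schedule(stimuli, 5, experiment=1, seed=3)
        b = make_schedule(stimuli, 5, experiment=1, seed=3)
        assert a.trials.equals(b.trials)

    def test_experiment2_covers_all_unordered_pairs(self, stimuli):
        sched = make_schedule(stimuli, 3, experiment=2, seed=1)
        pairs = {frozenset((a, b)) for a, b in zip(sched.trials["stim_a"], sched.trials["stim_b"])}
        # 8 images: 28 distinct unordered pairs + 8 identical pairs
        assert len(pairs) == 36
        counts = sched.trials.groupby(["stim_a", "stim_b"]).size()
        assert (counts >= 3).all()

    def test_empty_or_invalid_inputs(self, stimuli):
        with pytest.raises(ParameterError):
            make_schedule(stimuli, 0, experiment=1)
        with pytest.raises(ParameterError):
            make_schedule(stimuli, 5, experiment=3)
        with pytest.raises(InputError):
            StimulusSet(())


class TestObserver:
    def test_chance_observer_near_half(self, stimuli):
        sched = make_schedule(stimuli, 1250, experiment=1, seed=0)  # 10,000 trials
        table = simulate_observer(sched, ObserverModel(kind="sdt", delta=0, criterion=0, seed=1))
        rate = table.trials["response"].mean()
        assert 0.48 <= rate <= 0.52

    def test_high_sensitivity_observer_saturates(self, stimuli):
        sched = make_schedule(stimuli, 10, experiment=1, seed=0)
        table = simulate_observer(sched, ObserverModel(kind="sdt", delta=6, criterion=3, seed=2))
        truth = table.trials["truth"].astype(bool)
        resp = table.trials["response"].astype(bool)
        assert (resp[truth]).mean() > 0.95  # hits ~ 1
        assert (resp[~truth]).mean() < 0.05  # false alarms ~ 0

    def test_noiseless_rater_reports_latent(self, stimuli):
        sched = make_schedule(stimuli, 2, experiment=2, seed=0)
        obs = ObserverModel(kind="rater", sigma=0.0, d_pair=10, d_class=45, d_diff=80, seed=0)
        table = simulate_observer(sched, obs)
        for a, b, r in zip(table.trials["stim_a"], table.trials["stim_b"],
                           table.trials["response"]):
            assert r == stimuli.latent_dissimilarity(a, b, 10, 45, 80)

    def test_observer_kind_must_match_experiment(self, stimuli):
        sched = make_schedule(stimuli, 2, experiment=1, seed=0)
        with pytest.raises(InputError):
            simulate_observer(sched, ObserverModel(kind="rater"))


class TestDPrime:
    def test_equal_rates_give_zero(self, stimuli):
        sched = make_schedule(stimuli, 10, experiment=1, seed=0)
        table = simulate_observer(sched, ObserverModel(kind="chance", seed=5))
        df = table.trials.copy()
        df["response"] = True  # h/n_s == f/n_o == 1 with equal n
        from mammotex.psychophys import ResponseTable

        res = dprime(ResponseTable(df, 1, stimuli))
        assert np.allclose(res.table["dprime"], 0.0)

    def test_quantile_oracle_uncorrected(self):
        """Phi(1) = 0.8413 vs F = 0.5 gives d' = 1."""
        assert dprime_from_rates(0.8413, 0.5) == pytest.approx(1.0, abs=1e-3)

    def test_log_linear_correction_at_ceiling(self, stimuli):
        """h=10, f=0 at n=10: H*=10.5/11, F*=0.5/11, d' = 3.381."""
        sched = make_schedule(stimuli, 10, experiment=1, seed=0)
        table = simulate_observer(sched, ObserverModel(kind="chance", seed=5))
        df = table.trials.copy()
        df["response"] = df["truth"].astype(bool)  # perfect observer
        from mammotex.psychophys import ResponseTable

        res = dprime(ResponseTable(df, 1, stimuli))
        expected = stats.norm.ppf(10.5 / 11) - stats.norm.ppf(0.5 / 11)
        assert np.allclose(res.table["dprime"], expected)
        assert res.table["dprime"].iloc[0] == pytest.approx(3.381, abs=1e-3)

    def test_variants_agree_for_symmetric_counts(self, stimuli):
        sched = make_schedule(stimuli, 10, experiment=1, seed=0)
        table = simulate_observer(sched, ObserverModel(kind="sdt", delta=1, seed=3))
        a = dprime(table, "hits_vs_fa").table
        b = dprime(table, "tn_vs_miss").table
        # TN* = 1 - F*, Miss* = 1 - H* at equal n: identical d' by symmetry of Phi^-1
        assert np.allclose(a["dprime"], b["dprime"])

    def test_parameter_recovery(self, stimuli):
        """Mean estimated d' tracks true delta at 200 trials per class."""
        sched = make_schedule(StimulusSet((("O1", "S1", "normal"),)), 200, 1, seed=0)
        for delta in (0.0, 1.0, 2.0):
            ests = []
            for k in range(50):
                obs = ObserverModel(kind="sdt", delta=delta, criterion=delta / 2,
                                    seed=1000 + k)
                ests.append(dprime(simulate_observer(sched, obs)).table["dprime"].iloc[0])
            assert abs(np.mean(ests) - delta) <= 0.15

    def test_chance_design_median_near_zero(self, stimuli):
        """The 4-pair / 10-presentation / 14-observer design at zero sensitivity
        yields per-pair median d' within [-0.2, 0.2] over seeded replicates."""
        medians = []
        for rep in range(10):
            sched = make_schedule(stimuli, 10, experiment=1, seed=rep)
            panel = [ObserverModel(kind="chance", seed=rep * 100 + k) for k in range(14)]
            res = dprime(simulate_panel(sched, panel))
            medians.extend(res.table.groupby("pair")["dprime"].median())
        assert -0.2 <= np.median(medians) <= 0.2


class TestRDM:
    def test_mean_and_symmetry(self, stimuli):
        from mammotex.psychophys import ResponseTable
        import pandas as pd

        rows = []
        for a, b in [("O1", "S1")] * 3:
            rows.append({"subject": "s01", "experiment": 2, "trial": len(rows),
                         "stim_a": a, "stim_b": b, "truth": None, "response": 0.0,
                         "rt": np.nan})
        rows[0]["response"], rows[1]["response"], rows[2]["response"] = 10, 20, 30
        # cover all remaining pairs once
        import itertools

        for a, b in itertools.combinations_with_replacement(stimuli.images, 2):
            if {a, b} == {"O1", "S1"}:
                continue
            rows.append({"subject": "s01", "experiment": 2, "trial": len(rows),
                         "stim_a": a, "stim_b": b, "truth": None, "response": 50.0,
                         "rt": np.nan})
        rdm = build_rdm(ResponseTable(pd.DataFrame(rows), 2, stimuli))
        i, j = rdm.labels.index("O1"), rdm.labels.index("S1")
        assert rdm.matrix[i, j] == 20.0 and rdm.matrix[j, i] == 20.0
        assert np.allclose(rdm.matrix, rdm.matrix.T)
        assert np.all(np.diag(rdm.matrix) == 0.0)

    def test_noiseless_rater_recovers_latent_d(self, stimuli):
        sched = make_schedule(stimuli, 2, experiment=2, seed=4)
        obs = ObserverModel(kind="rater", sigma=0.0, d_pair=10, d_class=45, d_diff=80, seed=0)
        rdm = build_rdm(simulate_observer(sched, obs))
        for i, a in enumerate(rdm.labels):
            for j, b in enumerate(rdm.labels):
                if i != j:
                    assert rdm.matrix[i, j] == stimuli.latent_dissimilarity(a, b, 10, 45, 80)

    def test_entries_within_rating_scale(self, stimuli):
        sched = make_schedule(stimuli, 3, experiment=2, seed=5)
        rdm = build_rdm(simulate_observer(sched, ObserverModel(kind="rater", sigma=30, seed=6)))
        assert rdm.matrix.min() >= 0.0 and rdm.matrix.max() <= 100.0

    def test_estimator_consistency(self, stimuli):
        """Max |RDM - latent D| shrinks as ratings per pair grow."""
        obs = dict(kind="rater", sigma=10.0, d_pair=10, d_class=45, d_diff=80)
        latent = np.array([
            [stimuli.latent_dissimilarity(a, b, 10, 45, 80) for b in stimuli.images]
            for a in stimuli.images
        ])
        errs = []
        for n in (10, 1000):
            sched = make_schedule(stimuli, n, experiment=2, seed=7)
            rdm = build_rdm(simulate_observer(sched, ObserverModel(seed=8, **obs)))
            off = ~np.eye(len(rdm.labels), dtype=bool)
            errs.append(np.abs(rdm.matrix - latent)[off].max())
        assert errs[1] < errs[0]

    def test_unrated_pair_raises_coverage_error(self, stimuli):
        from mammotex import CoverageError
        from mammotex.psychophys import ResponseTable
        import pandas as pd

        df = pd.DataFrame([{"subject": "s01", "experiment": 2, "trial": 0,
                            "stim_a": "O1", "stim_b": "S1", "truth": None,
                            "response": 5.0, "rt": np.nan}])
        with pytest.raises(CoverageError) as err:
            build_rdm(ResponseTable(df, 2, stimuli))
        assert err.value.missing


def _random_rdm(labels, rng):
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.uniform(0, 100, size=len(iu[0]))
    m[iu] = vals
    m.T[iu] = vals
    return RDM(tuple(labels), m)


class TestCongruity:
    def test_identical_rdms_give_rho_one(self, stimuli, rng):
        a = _random_rdm(stimuli.images, rng)
        rho, p = rdm_congruity(a, a, n_perm=200, seed=0)
        assert rho == pytest.approx(1.0)
        assert p <= 0.05

    def test_condition_mismatch_rejected(self, stimuli, rng):
        a = _random_rdm(stimuli.images, rng)
        b = _random_rdm([l + "x" for l in stimuli.images], rng)
        with pytest.raises(StructuralError):
            rdm_congruity(a, b)

    def test_power_under_shared_structure(self, stimuli):
        """Two noisy panels from the same latent D: p <= 0.05 nearly always."""
        hits = 0
        for rep in range(20):
            rdms = []
            for half in range(2):
                sched = make_schedule(stimuli, 10, experiment=2, seed=rep)
                obs = ObserverModel(kind="rater", sigma=5.0, d_pair=10, d_class=45,
                                    d_diff=80, seed=rep * 2 + half)
                rdms.append(build_rdm(simulate_observer(sched, obs)))
            _, p = rdm_congruity(rdms[0], rdms[1], n_perm=200, seed=rep)
            hits += p <= 0.05
        assert hits >= 19

    def test_null_p_roughly_uniform(self, stimuli):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(60):
            a = _random_rdm(stimuli.images, rng)
            b = _random_rdm(stimuli.images, rng)
            ps.append(rdm_congruity(a, b, n_perm=100, seed=int(rng.integers(2**31)))[1])
        assert 0.35 <= np.mean(ps) <= 0.65


def brute_force_average_linkage(d):
    """Independent average-linkage oracle: explicit cluster-pair scan."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best = min(
            ((k, v) for k, v in dist.items() if all(c in clusters for c in k)),
            key=lambda kv: (kv[1], sorted(kv[0])),
        )
        (i, j), h = tuple(best[0]), best[1]
        members = clusters[i] + clusters[j]
        merges.append((sorted((i, j)), h, len(members)))
        del clusters[i], clusters[j]
        for k in list(clusters):
            pts = clusters[k]
            avg = np.mean([d[a, b] for a in members for b in pts])
            dist[frozenset((next_id, k))] = avg
        clusters[next_id] = members
        next_id += 1
    return merges


class TestHCA:
    def test_two_conditions_single_merge(self):
        rdm = RDM(("a", "b"), np.array([[0.0, 7.0], [7.0, 0.0]]))
        tree = hca(rdm)
        assert tree.merges.shape[0] == 1
        assert tree.merges[0, 2] == 7.0

    def test_twins_merge_first_under_latent_model(self, stimuli):
        latent = np.array([
            [stimuli.latent_dissimilarity(a, b, 10, 45, 80) for b in stimuli.images]
            for a in stimuli.images
        ])
        tree = hca(RDM(stimuli.images, latent))
        # first 4 merges join leaves at the twin distance
        first = tree.merges[:4]
        assert np.allclose(first[:, 2], 10.0)
        for row in first:
            a, b = int(row[0]), int(row[1])
            assert a < 8 and b < 8  # leaves, not clusters
            assert stimuli.twin(stimuli.images[a]) == stimuli.images[b]

    def test_heights_non_decreasing(self, stimuli, rng):
        rdm = _random_rdm(stimuli.images, rng)
        tree = hca(rdm)
        assert np.all(np.diff(tree.heights()) >= -1e-12)

    def test_matches_brute_force_oracle(self, stimuli, rng):
        rdm = _random_rdm(stimuli.images, rng)
        tree = hca(rdm)
        oracle = brute_force_average_linkage(rdm.matrix)
        assert np.allclose(tree.merges[:, 2], [h for _, h, _ in oracle])
        assert np.array_equal(tree.merges[:, 3], [s for _, _, s in oracle])

    def test_newick_roundtrip_leaf_names(self, stimuli, rng):
        tree = hca(_random_rdm(stimuli.images, rng))
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for label in stimuli.images:
            assert label in nwk


class TestPairedRating:
    def _table(self, stimuli, responses_by_subject):
        import itertools
        import pandas as pd

        from mammotex.psychophys import ResponseTable

        rows = []
        for subject, fn in responses_by_subject.items():
            for a, b in itertools.combinations_with_replacement(stimuli.images, 2):
                rows.append({"subject": subject, "experiment": 2, "trial": len(rows),
                             "stim_a": a, "stim_b": b, "truth": None,
                             "response": fn(a, b), "rt": np.nan})
        return ResponseTable(pd.DataFrame(rows), 2, stimuli)

    def test_symmetric_ratings_give_zero_t(self, stimuli):
        # rating depends only on the pair indices, not original/synthesized role
        def sym(a, b):
            return 10.0 * abs(stimuli.pair_index(a) - stimuli.pair_index(b))

        t, p, df = paired_rating_test(self._table(stimuli, {"s01": sym, "s02": sym}))
        assert t == 0.0 and df == 1

    def test_zero_variance_nonzero_differences_error(self, stimuli):
        # originals rated uniformly higher by every subject
        def biased(a, b):
            bonus = 5.0 * sum(x.startswith("O") for x in (a, b))
            return 40.0 + bonus

        with pytest.raises(DegenerateDataError):
            paired_rating_test(self._table(
                stimuli, {"s01": biased, "s02": biased, "s03": biased}))

    def test_single_subject_rejected(self, stimuli):
        with pytest.raises(DegenerateDataError):
            paired_rating_test(self._table(stimuli, {"s01": lambda a, b: 1.0}))

    def test_noisy_balanced_panel_not_significant(self, stimuli):
        sched = make_schedule(stimuli, 10, experiment=2, seed=9)
        panel = [ObserverModel(kind="rater", sigma=10, seed=k) for k in range(6)]
        t, p, df = paired_rating_test(simulate_panel(sched, panel))
        assert df == 5
        assert p > 0.05
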