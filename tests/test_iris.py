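import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irislib.exceptions import PreconditionError, ValidationError
from irislib.iris import (
    InteractionSet,
    IrisConfig,
    IrisEnsemble,
    greedy_select,
    rank_candidates,
    run_hillclimb,
    step1_differential,
    step2_eligible,
    train_iris,
)
from irislib.synthetic import CohortSimConfig, simulate_cohorts

from conftest import make_profile


# ---------------------------------------------------------------------------
# Independent oracles

def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all tables (same margins) no more likely than observed."""
    m1, k = a + b, a + c
    n = a + b + c + d
    lo, hi = max(0, k - (n - m1)), min(m1, k)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, m1, k)
    p_obs = stats.hypergeom.pmf(a, n, m1, k)
    return float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())


def bh_stepup_oracle(pvals):
    """Brute-force Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def auc_pairs_oracle(scores, labels):
    """O(n^2) pairwise AUC with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / total


def greedy_oracle(matrix, labels, candidates, direction):
    """Naive stepwise forward search re-implemented with the pairwise AUC."""
    sign = 1 if direction == "RDI" else -1
    selected, remaining, cur = [], list(candidates), 0.5
    while remaining:
        best_auc, best_c = -1.0, None
        for c in remaining:
            frac = matrix.loc[selected + [c]].mean(axis=0).to_numpy()
            auc = auc_pairs_oracle(sign * frac, labels)
            if auc > best_auc + 1e-12:
                best_auc, best_c = auc, c
        if best_auc <= cur + 1e-12:
            break
        selected.append(best_c)
        remaining.remove(best_c)
        cur = best_auc
    return selected


# ---------------------------------------------------------------------------
# Step 1

def _two_group_profile(pre_active, pre_total, post_active, post_total, iid="Mal|CCL2→Macrophage|CCR2"):
    values = [[1.0] * pre_active + [0.0] * (pre_total - pre_active)
              + [1.0] * post_active + [0.0] * (post_total - post_active)]
    samples = [f"s{i}" for i in range(pre_total + post_total)]
    tps = ["pre"] * pre_total + ["post"] * post_total
    resp = ["R"] * pre_total + ["NR"] * post_total
    return make_profile(values, [iid], samples, tps, resp)


class TestStep1:
    def test_worked_fisher_example(self):
        # 8/10 active pre vs 1/10 active post-NR
        profile = _two_group_profile(8, 10, 1, 10)
        table = step1_differential(profile, IrisConfig())
        expected = fisher_two_sided_oracle(8, 2, 1, 9)
        assert table.p_value.iloc[0] == pytest.approx(expected, abs=1e-12)
        assert table.p_value.iloc[0] == pytest.approx(5.4775e-3, rel=1e-3)
        assert table.direction.iloc[0] == "RDI"

    def test_equal_rates_p_one_no_direction(self):
        profile = _two_group_profile(5, 10, 5, 10)
        table = step1_differential(profile, IrisConfig())
        assert table.p_value.iloc[0] == 1.0
        assert table.direction.iloc[0] == "none"

    def test_degenerate_all_active(self):
        profile = _two_group_profile(10, 10, 10, 10)
        table = step1_differential(profile, IrisConfig())
        assert table.p_value.iloc[0] == 1.0
        assert rank_candidates(table, "RDI") == []

    def test_post_responders_excluded(self):
        values = [[1, 1, 0, 0, 1, 0, 1]]
        samples = [f"s{i}" for i in range(7)]
        tps = ["pre", "pre", "pre", "post", "post", "post", "post"]
        resp = ["R", "NR", "R", "NR", "R", "NR", "R"]  # post-R s4, s6 excluded
        profile = make_profile(values, ["Mal|CCL2→Macrophage|CCR2"], samples, tps, resp)
        table = step1_differential(profile, IrisConfig())
        assert table.n_post_nr.iloc[0] == 2
        assert table.n_active_post_nr.iloc[0] == 0

    def test_fdr_within_stratum_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        ids, values = [], []
        for k in range(12):
            ct = ["Mal", "NK"][k % 2]
            ids.append(f"{ct}|L{k}→TCD8|R{k}")
            values.append((rng.random(16) < 0.5).astype(float))
        samples = [f"s{i}" for i in range(16)]
        profile = make_profile(values, ids, samples, ["pre"] * 8 + ["post"] * 8,
                               ["R"] * 8 + ["NR"] * 8)
        table = step1_differential(profile, IrisConfig())
        for _, grp in table.groupby(["ligand_ct", "receptor_ct"]):
            np.testing.assert_allclose(
                grp.fdr.to_numpy(), bh_stepup_oracle(grp.p_value.to_numpy()), atol=1e-12
            )
        assert (table.fdr >= table.p_value - 1e-12).all()

    def test_empty_group_errors(self):
        profile = make_profile([[1, 0]], ["Mal|L→TCD8|R"], ["s0", "s1"],
                               ["pre", "pre"], ["R", "NR"])
        with pytest.raises(PreconditionError):
            step1_differential(profile, IrisConfig())

    def test_fisher_exact_matches_oracle_on_margin_grid(self):
        cfg = IrisConfig()
        for m1 in range(0, 13, 3):
            for m2 in range(1, 13, 3):
                for a in range(m1 + 1):
                    for c in range(m2 + 1):
                        _, p = stats.fisher_exact(
                            [[a, m1 - a], [c, m2 - c]], alternative=cfg.fisher_alternative
                        )
                        assert p == pytest.approx(
                            fisher_two_sided_oracle(a, m1 - a, c, m2 - c), abs=1e-12
                        )


# ---------------------------------------------------------------------------
# Greedy selection

class TestGreedy:
    def test_perfect_single_candidate(self):
        profile = make_profile(
            [[1, 1, 1, 0, 0, 0]], ["i0"], [f"s{i}" for i in range(6)],
            ["pre"] * 6, ["R", "R", "R", "NR", "NR", "NR"],
        )
        labels = [True, True, True, False, False, False]
        sel, trace = greedy_select(profile, labels, ["i0"], "RDI")
        assert sel == ["i0"] and trace == [1.0]

    def test_uninformative_candidates_empty_selection(self):
        profile = make_profile(
            [[1] * 6, [0] * 6], ["i0", "i1"], [f"s{i}" for i in range(6)],
            ["pre"] * 6, ["R", "R", "R", "NR", "NR", "NR"],
        )
        labels = [True, True, True, False, False, False]
        sel, trace = greedy_select(profile, labels, ["i0", "i1"], "RDI")
        assert sel == [] and trace == []

    def test_matches_bruteforce_forward_search(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            mat = pd.DataFrame(
                (rng.random((3, 8)) < 0.5).astype(float),
                index=["i0", "i1", "i2"],
                columns=[f"s{i}" for i in range(8)],
            )
            labels = np.array([True] * 4 + [False] * 4)
            profile = make_profile(mat.values, list(mat.index), list(mat.columns),
                                   ["pre"] * 8, ["R"] * 4 + ["NR"] * 4)
            sel, trace = greedy_select(profile, labels, list(mat.index), "RDI")
            assert sel == greedy_oracle(mat, labels, list(mat.index), "RDI")
            assert all(b > a for a, b in zip(trace, trace[1:]))  # strictly increasing

    def test_rui_direction_flips_sign(self):
        # candidate active in non-responders: informative for RUI, not RDI
        profile = make_profile(
            [[0, 0, 0, 1, 1, 1]], ["i0"], [f"s{i}" for i in range(6)],
            ["pre"] * 6, ["R", "R", "R", "NR", "NR", "NR"],
        )
        labels = [True, True, True, False, False, False]
        assert greedy_select(profile, labels, ["i0"], "RUI")[0] == ["i0"]
        assert greedy_select(profile, labels, ["i0"], "RDI")[0] == []

    def test_single_class_errors(self):
        profile = make_profile([[1, 0]], ["i0"], ["s0", "s1"], ["pre"] * 2, ["R", "R"])
        with pytest.raises(PreconditionError):
            greedy_select(profile, [True, True], ["i0"], "RDI")


# ---------------------------------------------------------------------------
# Hill climbing

def _planted_profile(n=12, rng=None):
    rng = rng or np.random.default_rng(0)
    labels = np.array([True] * (n // 2) + [False] * (n // 2))
    perfect = labels.astype(float)
    noise = (rng.random((4, n)) < 0.4).astype(float)
    values = np.vstack([perfect, noise])
    ids = ["planted"] + [f"noise{j}" for j in range(4)]
    profile = make_profile(values, ids, [f"s{i}" for i in range(n)], ["pre"] * n,
                           ["R" if l else "NR" for l in labels])
    return profile, labels, ids


class TestHillclimb:
    def test_perfect_feature_rewarded_every_iteration(self):
        profile, labels, ids = _planted_profile()
        cfg = IrisConfig(n_iterations=40, n_permutations=200, random_seed=1)
        records, table, iset = run_hillclimb(profile, labels, ids, "RDI", cfg)
        row = table.set_index("interaction_id").loc["planted"]
        assert row.feature_score == cfg.n_iterations  # +1 every iteration
        assert row.p_value < cfg.alpha
        assert "planted" in iset.interaction_ids
        assert all(r.test_auc == 1.0 for r in records)

    def test_null_never_exceeding_gives_p_zero(self):
        profile, labels, ids = _planted_profile()
        cfg = IrisConfig(n_iterations=30, n_permutations=100, random_seed=2)
        _, table, _ = run_hillclimb(profile, labels, ids, "RDI", cfg)
        assert table.set_index("interaction_id").loc["planted", "p_value"] == 0.0

    def test_bit_reproducible(self):
        profile, labels, ids = _planted_profile()
        cfg = IrisConfig(n_iterations=20, n_permutations=100, random_seed=7)
        _, t1, s1 = run_hillclimb(profile, labels, ids, "RDI", cfg)
        _, t2, s2 = run_hillclimb(profile, labels, ids, "RDI", cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert s1.interaction_ids == s2.interaction_ids

    def test_empty_candidates_returns_none(self):
        profile, labels, _ = _planted_profile()
        records, table, iset = run_hillclimb(
            profile, labels, [], "RDI", IrisConfig(n_iterations=5, n_permutations=10)
        )
        assert records == [] and iset is None

    def test_too_few_samples_errors(self):
        profile, labels, ids = _planted_profile(n=4)
        with pytest.raises(PreconditionError):
            run_hillclimb(profile, labels, ids, "RDI", IrisConfig())

    def test_feature_scores_bounded(self):
        profile, labels, ids = _planted_profile()
        cfg = IrisConfig(n_iterations=25, n_permutations=50, random_seed=3)
        _, table, _ = run_hillclimb(profile, labels, ids, "RDI", cfg)
        assert (table.feature_score.abs() <= cfg.n_iterations).all()
        assert table.p_value.between(0, 1).all()

    def test_label_permutation_scores_centered(self):
        # under noise labels the mean observed feature score is near zero
        rng = np.random.default_rng(11)
        means = []
        for seed in range(8):
            mat = (rng.random((6, 18)) < 0.4).astype(float)
            labels = rng.permutation([True] * 9 + [False] * 9)
            profile = make_profile(mat, [f"f{j}" for j in range(6)],
                                   [f"s{i}" for i in range(18)], ["pre"] * 18,
                                   ["R" if l else "NR" for l in labels])
            _, table, _ = run_hillclimb(
                profile, labels, list(profile.matrix.index), "RDI",
                IrisConfig(n_iterations=30, n_permutations=50, random_seed=seed),
            )
            means.append(table.feature_score.mean())
        assert abs(np.mean(means)) < 3.0


# ---------------------------------------------------------------------------
# Ensemble training

@pytest.fixture(scope="module")
def sim():
    cfg = CohortSimConfig(
        n_cohorts=3, n_pre=24, n_post=16, n_interactions=60, n_planted=8,
        n_differential_only=12, random_seed=5,
    )
    return simulate_cohorts(cfg)


class TestTrainIris:
    def test_two_cohorts_give_two_sets(self, sim):
        cohorts, truth, db = sim
        cfg = IrisConfig(n_iterations=20, n_permutations=100, random_seed=1, min_class_step2=2)
        ens = train_iris(cohorts[:2], db, "RDI", cfg)
        assert len(ens.sets) == 2
        pairs = {
            (s.provenance["step2_cohort"], tuple(s.provenance["step1_cohorts"]))
            for s in ens.sets
        }
        assert pairs == {
            ("cohort_00", ("cohort_01",)),
            ("cohort_01", ("cohort_00",)),
        }

    def test_ineligible_cohort_serves_step1_only(self, sim):
        cohorts, truth, db = sim
        # make cohort_00 ineligible by stripping its pre-treatment responders
        import copy

        c0 = cohorts[0]
        samples = c0.samples.copy()
        pre = samples["timepoint"] == "pre"
        samples.loc[pre, "response"] = "NR"
        from irislib.activation import DeconvolvedCohort

        crippled = DeconvolvedCohort(c0.cohort_id, samples, c0.expression)
        cfg = IrisConfig(n_iterations=20, n_permutations=100, random_seed=1, min_class_step2=2)
        ens = train_iris([crippled] + list(cohorts[1:]), db, "RDI", cfg)
        step2_hosts = {s.provenance["step2_cohort"] for s in ens.sets}
        assert "cohort_00" not in step2_hosts
        assert all("cohort_00" in s.provenance["step1_cohorts"] for s in ens.sets)

    def test_single_cohort_errors(self, sim):
        cohorts, _, db = sim
        with pytest.raises(PreconditionError):
            train_iris(cohorts[:1], db, "RDI", IrisConfig())

    def test_ensemble_round_trip(self, sim, tmp_path):
        cohorts, _, db = sim
        cfg = IrisConfig(n_iterations=15, n_permutations=50, random_seed=2, min_class_step2=2)
        ens = train_iris(cohorts, db, "RDI", cfg)
        path = tmp_path / "model.json"
        ens.to_json(path)
        again = IrisEnsemble.from_json(path)
        assert again.direction == ens.direction
        assert [s.interaction_ids for s in again.sets] == [s.interaction_ids for s in ens.sets]


def test_interaction_set_must_be_nonempty():
    with pytest.raises(ValidationError):
        InteractionSet(direction="RDI", interaction_ids=())


def test_config_validation():
    with pytest.raises(ValidationError):
        IrisConfig(reward_auc=0.3, penalty_auc=0.4)
    with pytest.raises(ValidationError):
        IrisConfig(n_folds=1)
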