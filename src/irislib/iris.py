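"""Two-step training of resistance-associated interaction sets.

Step 1 screens for interactions differentially activated between pre-treatment
samples and post-treatment non-responders (Fisher exact test, BH-FDR within
each cell-type pair); step 2 runs a repeated cross-validated greedy forward
selection whose per-iteration rewards accumulate into feature scores, compared
against a permutation null.  Repeating over mutually exclusive step-1/step-2
cohort splits yields an ensemble of interaction sets.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activation import ActivityProfile, DeconvolvedCohort, call_activity, merge_profiles
from .exceptions import PreconditionError, ValidationError
from .interaction_db import InteractionDatabase, parse_interaction_id
from .scoring import auc_rank

Direction = Literal["RDI", "RUI"]


@dataclass(frozen=True)
class IrisConfig:
    fdr_threshold: float = 0.2
    n_iterations: int = 500
    n_permutations: int = 1000
    reward_auc: float = 0.6
    penalty_auc: float = 0.4
    alpha: float = 0.05
    n_folds: int = 3
    random_seed: int = 0
    fisher_alternative: str = "two-sided"
    min_class_step2: int = 3  # min R and NR pre-treatment samples for step-2 eligibility

    def __post_init__(self) -> None:
        if not (0 < self.penalty_auc < self.reward_auc <= 1):
            raise ValidationError("require 0 < penalty_auc < reward_auc <= 1")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        for name in ("n_iterations", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.fdr_threshold <= 1 and 0 < self.alpha <= 1):
            raise ValidationError("fdr_threshold and alpha must lie in (0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class SolutionRecord:
    iteration: int
    fold_assignment: np.ndarray
    test_fold: int
    selected: list[str]
    train_auc_trace: list[float]
    test_auc: float
    reward: int


@dataclass(frozen=True)
class InteractionSet:
    direction: Direction
    interaction_ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.interaction_ids:
            raise ValidationError("InteractionSet must be non-empty")


@dataclass(frozen=True)
class IrisEnsemble:
    sets: tuple[InteractionSet, ...]
    direction: Direction
    config: IrisConfig

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValidationError("ensemble must contain at least one set")
        if any(s.direction != self.direction for s in self.sets):
            raise ValidationError("all ensemble sets must share the ensemble direction")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "direction": self.direction,
            "config": asdict(self.config),
            "sets": [
                {
                    "direction": s.direction,
                    "interaction_ids": list(s.interaction_ids),
                    "provenance": s.provenance,
                }
                for s in self.sets
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "IrisEnsemble":
        payload = json.loads(Path(path).read_text())
        sets = tuple(
            InteractionSet(
                direction=s["direction"],
                interaction_ids=tuple(s["interaction_ids"]),
                provenance=s.get("provenance", {}),
            )
            for s in payload["sets"]
        )
        return cls(sets=sets, direction=payload["direction"], config=IrisConfig(**payload["config"]))


# ---------------------------------------------------------------------------
# Step 1 — differential activation

def step1_differential(profile: ActivityProfile, config: IrisConfig) -> pd.DataFrame:
    """Fisher differential-activation screen: pre-treatment vs post-treatment NR.

    Post-treatment responders are excluded.  BH-FDR is computed separately
    within each (ligand cell type, receptor cell type) stratum.  Returns one
    row per measurable interaction with counts, rates, p, fdr and direction
    (RDI when the pre-treatment rate exceeds the post-NR rate at FDR below the
    configured threshold; RUI symmetric; 'none' otherwise).
    """
    meta = profile.samples
    pre_ids = list(meta.index[meta["timepoint"] == "pre"])
    post_nr_ids = list(
        meta.index[(meta["timepoint"] == "post") & (meta["response"] == "NR")]
    )
    if not pre_ids or not post_nr_ids:
        raise PreconditionError(
            "step 1 requires >=1 pre-treatment and >=1 post-treatment NR sample "
            f"(got {len(pre_ids)} / {len(post_nr_ids)})"
        )
    pre = profile.matrix[pre_ids]
    post = profile.matrix[post_nr_ids]

    rows = []
    for iid in profile.matrix.index:
        a_pre = pre.loc[iid]
        a_post = post.loc[iid]
        n_pre = int(a_pre.notna().sum())
        n_post = int(a_post.notna().sum())
        if n_pre == 0 or n_post == 0:
            continue  # non-measurable in one group: excluded, recorded by absence
        k_pre = int(np.nansum(a_pre.to_numpy(float)))
        k_post = int(np.nansum(a_post.to_numpy(float)))
        table = [[k_pre, n_pre - k_pre], [k_post, n_post - k_post]]
        _, p = stats.fisher_exact(table, alternative=config.fisher_alternative)
        lct, _, rct, _ = parse_interaction_id(iid)
        rows.append(
            {
                "interaction_id": iid,
                "ligand_ct": lct,
                "receptor_ct": rct,
                "n_active_pre": k_pre,
                "n_pre": n_pre,
                "n_active_post_nr": k_post,
                "n_post_nr": n_post,
                "rate_pre": k_pre / n_pre,
                "rate_post_nr": k_post / n_post,
                "p_value": float(p),
            }
        )
    if not rows:
        raise PreconditionError("no measurable interaction in both groups")
    table = pd.DataFrame(rows)

    table["fdr"] = np.nan
    for _, idx in table.groupby(["ligand_ct", "receptor_ct"]).groups.items():
        pvals = table.loc[idx, "p_value"].to_numpy()
        table.loc[idx, "fdr"] = multipletests(pvals, method="fdr_bh")[1]

    diff = table["rate_pre"] - table["rate_post_nr"]
    sig = table["fdr"] < config.fdr_threshold
    table["direction"] = "none"
    table.loc[sig & (diff > 0), "direction"] = "RDI"
    table.loc[sig & (diff < 0), "direction"] = "RUI"
    return table


def rank_candidates(table: pd.DataFrame, direction: Direction) -> list[str]:
    """Candidate list for step 2: ascending stratified FDR, ties by p then input order."""
    sel = table[table["direction"] == direction].copy()
    sel["_order"] = np.arange(len(sel))
    sel = sel.sort_values(["fdr", "p_value", "_order"], kind="stable")
    return list(sel["interaction_id"])


# ---------------------------------------------------------------------------
# Step 2 — hill-climbing aggregative feature selection

def _auc_many(score_rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC (ties 0.5) for a matrix of score vectors."""
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    ranks = stats.rankdata(score_rows, axis=1)
    r_pos = ranks[:, y].sum(axis=1)
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def greedy_select(
    activity: ActivityProfile | pd.DataFrame,
    labels: Sequence[bool],
    candidates: Sequence[str],
    direction: Direction,
) -> tuple[list[str], list[float]]:
    """Greedy forward selection of interactions maximizing response AUC.

    The predictor of a set is the per-sample fraction of its (measurable)
    interactions that are active, negated for RUI sets so that more activation
    of an RDI set ranks responders higher.  Starting from the empty set
    (baseline AUC 0.5), each step adds the candidate giving the largest strict
    AUC increase, ties broken by candidate rank; stops at no improvement.
    """
    mat = activity.matrix if isinstance(activity, ActivityProfile) else activity
    y = np.asarray(labels, dtype=bool)
    if y.size != mat.shape[1]:
        raise ValidationError("labels length must match the number of samples")
    if not y.any() or y.all():
        raise PreconditionError("greedy_select requires both classes in the training samples")
    cand = [c for c in candidates if c in mat.index]
    if not cand:
        return [], []
    A = mat.loc[cand].to_numpy(float)
    M = (~np.isnan(A)).astype(float)
    A0 = np.nan_to_num(A)
    sign = 1.0 if direction == "RDI" else -1.0

    n = A.shape[1]
    cur_sum = np.zeros(n)
    cur_cnt = np.zeros(n)
    cur_auc = 0.5
    selected: list[int] = []
    remaining = list(range(len(cand)))
    trace: list[float] = []
    while remaining:
        rem = np.array(remaining)
        nums = cur_sum[None, :] + A0[rem]
        dens = cur_cnt[None, :] + M[rem]
        frac = np.divide(nums, dens, out=np.zeros_like(nums), where=dens > 0)
        aucs = _auc_many(sign * frac, y)
        best = int(np.argmax(aucs))  # first occurrence = best-ranked candidate
        if aucs[best] <= cur_auc + 1e-12:
            break
        j = remaining.pop(best)
        selected.append(j)
        cur_sum += A0[j]
        cur_cnt += M[j]
        cur_auc = float(aucs[best])
        trace.append(cur_auc)
    return [cand[j] for j in selected], trace


def _set_predictor(
    mat: pd.DataFrame, ids: Sequence[str], direction: Direction
) -> np.ndarray:
    sub = mat.loc[[i for i in ids if i in mat.index]].to_numpy(float)
    cnt = (~np.isnan(sub)).sum(axis=0)
    frac = np.divide(
        np.nansum(sub, axis=0), cnt, out=np.zeros(sub.shape[1]), where=cnt > 0
    )
    return frac if direction == "RDI" else -frac


def _stratified_fold_split(
    y: np.ndarray, n_folds: int, rng: np.random.Generator, max_retries: int = 100
) -> tuple[np.ndarray, int]:
    """Random stratified fold assignment plus a random test fold.

    Resamples (bounded) until both the pooled training folds and the test fold
    contain both classes.
    """
    n = y.size
    for _ in range(max_retries):
        folds = np.empty(n, dtype=int)
        for cls in (True, False):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(idx.size) % n_folds
        test_fold = int(rng.integers(n_folds))
        test = folds == test_fold
        train = ~test
        if (
            y[train].any()
            and (~y[train]).any()
            and y[test].any()
            and (~y[test]).any()
        ):
            return folds, test_fold
    raise PreconditionError(
        "could not produce a stratified fold split with both classes in "
        "training and testing folds"
    )


def run_hillclimb(
    profile_pre: ActivityProfile,
    labels: Sequence[bool],
    candidates: Sequence[str],
    direction: Direction,
    config: IrisConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SolutionRecord], pd.DataFrame, InteractionSet | None]:
    """Repeated 3-fold greedy selection with reward scoring and a permutation null.

    Per iteration the pre-treatment samples are randomly split into
    ``n_folds`` stratified folds (``n_folds - 1`` for training, one held out);
    the greedily selected set is scored on the held-out fold: +1 reward at
    test AUC >= ``reward_auc``, -1 below ``penalty_auc``, else 0, assigned to
    every selected feature.  Feature scores are the per-feature sums over
    iterations.  The null shuffles each iteration's per-feature score vector
    independently across features before summing; the empirical p is the
    strict fraction of null sums exceeding the observed score.  The returned
    set keeps features with p < alpha and positive observed score, falling
    back to the top-scoring feature when none passes (None when there are no
    candidates at all).
    """
    mat = profile_pre.matrix
    y = np.asarray(labels, dtype=bool)
    if y.size != mat.shape[1]:
        raise ValidationError("labels length must match the number of samples")
    if y.size < 2 * config.n_folds:
        raise PreconditionError(
            f"need >= {2 * config.n_folds} pre-treatment samples, got {y.size}"
        )
    if not y.any() or y.all():
        raise PreconditionError("both response classes required")
    cand = [c for c in candidates if c in mat.index]
    if not cand:
        return [], pd.DataFrame(columns=["interaction_id", "feature_score", "p_value"]), None
    if rng is None:
        rng = np.random.default_rng(config.random_seed)

    n_feat = len(cand)
    score_rows = np.zeros((config.n_iterations, n_feat))
    cand_pos = {c: j for j, c in enumerate(cand)}
    records: list[SolutionRecord] = []
    sample_ids = list(mat.columns)
    for it in range(config.n_iterations):
        folds, test_fold = _stratified_fold_split(y, config.n_folds, rng)
        train = folds != test_fold
        train_cols = [sample_ids[i] for i in np.flatnonzero(train)]
        test_cols = [sample_ids[i] for i in np.flatnonzero(~train)]
        selected, trace = greedy_select(mat[train_cols], y[train], cand, direction)
        if selected:
            pred = _set_predictor(mat[test_cols], selected, direction)
            test_auc = auc_rank(pred, y[~train])
        else:
            test_auc = 0.5
        if test_auc >= config.reward_auc:
            reward = 1
        elif test_auc < config.penalty_auc:
            reward = -1
        else:
            reward = 0
        for iid in selected:
            score_rows[it, cand_pos[iid]] = reward
        records.append(
            SolutionRecord(
                iteration=it,
                fold_assignment=folds,
                test_fold=test_fold,
                selected=selected,
                train_auc_trace=trace,
                test_auc=float(test_auc),
                reward=reward,
            )
        )

    observed = score_rows.sum(axis=0)

    # Null: shuffle each iteration's score vector independently across features.
    # Only iterations with a nonzero reward and a nonempty selection contribute.
    null = np.zeros((config.n_permutations, n_feat))
    for it in range(config.n_iterations):
        row = score_rows[it]
        k = int(np.count_nonzero(row))
        if k == 0:
            continue
        v = row[row != 0][0]
        u = rng.random((config.n_permutations, n_feat))
        pos = np.argpartition(u, k - 1, axis=1)[:, :k]
        null[np.arange(config.n_permutations)[:, None], pos] += v

    p_values = (null > observed[None, :]).sum(axis=0) / config.n_permutations

    feature_table = pd.DataFrame(
        {
            "interaction_id": cand,
            "feature_score": observed,
            "p_value": p_values,
        }
    )

    keep = [
        cand[j]
        for j in range(n_feat)
        if p_values[j] < config.alpha and observed[j] > 0
    ]
    if not keep:
        # no feature clears the null: fall back to the greatest feature score
        best = int(np.argmax(observed))
        keep = [cand[best]]
        warnings.warn(
            "no feature passed the permutation filter; falling back to the "
            "single greatest-scoring feature"
        )
    iset = InteractionSet(
        direction=direction,
        interaction_ids=tuple(keep),
        provenance={"n_candidates": n_feat, "config_hash": config.config_hash()},
    )
    return records, feature_table, iset


# ---------------------------------------------------------------------------
# Ensemble training

def step2_eligible(cohort: DeconvolvedCohort, config: IrisConfig) -> bool:
    """A cohort can host step 2 iff its pre-treatment samples contain at least
    ``min_class_step2`` responders and as many non-responders."""
    pre = cohort.samples[cohort.samples["timepoint"] == "pre"]
    n_r = int((pre["response"] == "R").sum())
    n_nr = int((pre["response"] == "NR").sum())
    return n_r >= config.min_class_step2 and n_nr >= config.min_class_step2


def train_iris(
    cohorts: Sequence[DeconvolvedCohort],
    db: InteractionDatabase,
    direction: Direction,
    config: IrisConfig,
) -> IrisEnsemble:
    """Train the ensemble over mutually exclusive step-1 / step-2 cohort splits.

    Each step-2-eligible cohort hosts one hill climb on its pre-treatment
    profile, with step 1 run on the merged pre + post-NR profiles of all the
    *other* cohorts.  Ineligible cohorts still contribute to step 1.
    """
    if len(cohorts) < 2:
        raise PreconditionError("train_iris requires at least two cohorts")
    ids = [c.cohort_id for c in cohorts]
    if len(set(ids)) != len(ids):
        raise ValidationError("cohort ids must be unique")

    profiles_pre: dict[str, ActivityProfile] = {}
    profiles_post: dict[str, ActivityProfile] = {}
    for c in cohorts:
        profiles_pre[c.cohort_id] = call_activity(c, db, "pre")
        if len(c.sample_ids("post")) >= 2:
            profiles_post[c.cohort_id] = call_activity(c, db, "post")

    eligible = [c for c in cohorts if step2_eligible(c, config)]
    if not eligible:
        raise PreconditionError("no cohort is eligible for step-2 feature selection")

    seeds = np.random.SeedSequence(config.random_seed).spawn(len(eligible))
    sets: list[InteractionSet] = []
    for c, seed in zip(eligible, seeds):
        others = [o for o in cohorts if o.cohort_id != c.cohort_id]
        step1_parts: list[ActivityProfile] = []
        for o in others:
            step1_parts.append(profiles_pre[o.cohort_id])
            post = profiles_post.get(o.cohort_id)
            if post is not None:
                nr = list(post.samples.index[post.samples["response"] == "NR"])
                if nr:
                    step1_parts.append(post.subset_samples(nr))
        merged = merge_profiles(step1_parts)
        table = step1_differential(merged, config)
        candidates = rank_candidates(table, direction)

        profile_pre = profiles_pre[c.cohort_id]
        labels = (profile_pre.samples["response"] == "R").to_numpy()
        rng = np.random.default_rng(seed)
        _, _, iset = run_hillclimb(profile_pre, labels, candidates, direction, config, rng)
        if iset is None:
            warnings.warn(
                f"cohort {c.cohort_id}: empty step-1 candidate list; set skipped"
            )
            continue
        prov = dict(iset.provenance)
        prov.update(
            {
                "step1_cohorts": [o.cohort_id for o in others],
                "step2_cohort": c.cohort_id,
            }
        )
        sets.append(
            InteractionSet(direction=direction, interaction_ids=iset.interaction_ids, provenance=prov)
        )
    if not sets:
        raise PreconditionError("training produced no non-empty interaction set")
    return IrisEnsemble(sets=tuple(sets), direction=direction, config=config)
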