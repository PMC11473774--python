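"""Response scores and the evaluation statistics used throughout the pipeline.

Implements the ensemble fraction-of-activated score (raw and z-scaled), the
Youden cut-point / odds-ratio classification, rank-based AUC, the exact
one-sided paired Wilcoxon signed-rank test, one-sided Fisher enrichment of
interaction categories, and the coefficient of variation of AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activation import ActivityProfile
from .exceptions import PreconditionError, ValidationError
from .interaction_db import InteractionDatabase

__all__ = [
    "ScoreVector",
    "CutpointResult",
    "score_samples",
    "select_cutpoint",
    "confusion_counts",
    "odds_ratio",
    "auc_rank",
    "wilcoxon_paired_one_sided",
    "enrichment_fisher",
    "cv_of_aucs",
]


# ---------------------------------------------------------------------------
# AUC

def auc_rank(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUC of ``scores`` for the positive class, ties counted 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise PreconditionError("auc_rank requires both classes present")
    ranks = stats.rankdata(s)
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Ensemble scoring

@dataclass
class ScoreVector:
    """Per-sample ensemble scores: per-set activated fractions, raw mean, z-scaled."""

    per_set: pd.DataFrame  # samples × sets (activated fraction per set)
    raw: pd.Series
    scaled: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.per_set.copy()
        out["raw"] = self.raw
        out["scaled"] = self.scaled
        return out


def score_samples(
    activity: ActivityProfile, ensemble, scale: Literal["z", "minmax"] = "z"
) -> ScoreVector:
    """Fraction of each ensemble set activated per sample, averaged over sets.

    The denominator for each set is restricted to the interactions measurable
    for the sample in question, so per-cohort missingness does not deflate
    scores.  Sets with no measurable interaction in the profile are dropped
    with a warning; the raw score is standardized across the profile's
    samples (``"z"`` = z-score with sample sd, ``"minmax"`` = rescale to
    [0, 1]; a degenerate spread yields all-zero scaled scores with a warning).
    """
    sets = list(getattr(ensemble, "sets"))
    if not sets:
        raise PreconditionError("ensemble has no interaction sets")
    mat = activity.matrix
    fractions = {}
    for k, iset in enumerate(sets):
        ids = [i for i in iset.interaction_ids if i in mat.index]
        if ids:
            sub = mat.loc[ids]
            counts = sub.notna().sum(axis=0)
        else:
            counts = pd.Series(0, index=mat.columns)
        if ids and (counts > 0).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                frac = sub.mean(axis=0, skipna=True)  # NaN where nothing measurable
            frac = frac.fillna(0.0)
        else:
            warnings.warn(f"ensemble set {k} has no measurable interactions; dropped")
            continue
        fractions[f"set_{k}"] = frac
    if not fractions:
        raise PreconditionError("no ensemble set is measurable in this profile")
    per_set = pd.DataFrame(fractions)
    raw = per_set.mean(axis=1)
    spread = raw.std(ddof=1) if scale == "z" else raw.max() - raw.min()
    if not np.isfinite(spread) or spread == 0:
        warnings.warn("raw scores are constant across samples; scaled scores set to 0")
        scaled = pd.Series(0.0, index=raw.index)
    elif scale == "z":
        scaled = (raw - raw.mean()) / spread
    else:
        scaled = (raw - raw.min()) / spread
    return ScoreVector(per_set=per_set, raw=raw, scaled=scaled)


# ---------------------------------------------------------------------------
# Cut point and odds ratio

@dataclass
class CutpointResult:
    """Per-training-cohort optimal thresholds and their mean."""

    per_cohort: dict[str, float]
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_cohort:
            raise PreconditionError("no usable training cohort for cut-point selection")
        self.threshold = float(np.mean(list(self.per_cohort.values())))


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1, midpoint convention.

    A sample is predicted responder iff its score is strictly above the
    threshold.  Candidate thresholds are the midpoints between consecutive
    sorted unique scores plus one sentinel below all scores.
    """
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates.extend((uniq[:-1] + uniq[1:]) / 2.0)
    best_t, best_j = candidates[0], -np.inf
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    for t in candidates:
        pred = scores > t
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def select_cutpoint(
    training_scores: Sequence[tuple[ScoreVector | pd.Series, Sequence[bool]]],
    cohort_ids: Sequence[str] | None = None,
) -> CutpointResult:
    """Optimal cut point per training cohort (Youden's J on scaled scores); mean over cohorts."""
    per_cohort: dict[str, float] = {}
    for k, (scores, labels) in enumerate(training_scores):
        name = cohort_ids[k] if cohort_ids is not None else f"cohort_{k}"
        s = scores.scaled if isinstance(scores, ScoreVector) else pd.Series(scores)
        y = np.asarray(labels, dtype=bool)
        if y.all() or not y.any():
            warnings.warn(f"cut-point: training cohort {name} has a single class; skipped")
            continue
        per_cohort[name] = _youden_threshold(s.to_numpy(float), y)
    return CutpointResult(per_cohort)


def confusion_counts(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> np.ndarray:
    """2×2 confusion matrix [[TP, FN], [FP, TN]] for predict-R iff score > threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pred = s > threshold
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    return np.array([[tp, fn], [fp, tn]])


def odds_ratio(confusion: np.ndarray) -> float:
    """(TP·TN)/(FP·FN) with a Haldane-Anscombe 0.5 correction when any cell is 0."""
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValidationError("confusion must be a non-negative 2x2 table")
    if c.sum() == 0:
        raise PreconditionError("all-zero confusion table")
    if (c == 0).any():
        c = c + 0.5
    return float((c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0]))


# ---------------------------------------------------------------------------
# Exact paired Wilcoxon

def wilcoxon_paired_one_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact one-sided (x > y) paired signed-rank p-value.

    Zero differences are dropped.  The null distribution of the positive rank
    sum is built over all 2^n sign patterns (dynamic-programming enumeration;
    tied |d| get average ranks, doubled to stay integral).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise PreconditionError("all paired differences are zero")
    ranks2 = np.round(2.0 * stats.rankdata(np.abs(d))).astype(int)
    w2_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    # P(W+ >= observed) under uniform sign flips
    return float(counts[w2_obs:].sum() / (2.0 ** n))


# ---------------------------------------------------------------------------
# Enrichment

def enrichment_fisher(
    foreground: Sequence[str],
    background: InteractionDatabase,
    grouping: Literal["ligand_ct", "receptor_ct", "annotation"],
) -> pd.DataFrame:
    """One-sided (greater) Fisher enrichment of each category within the foreground.

    Categories are the values of the chosen grouping field over the background
    database; categories with no background members (including missing
    annotations) are skipped.
    """
    fg = set(foreground)
    if not fg:
        raise PreconditionError("empty foreground")
    unknown = fg - set(background.ids)
    if unknown:
        raise ValidationError(f"foreground ids not in background: {sorted(unknown)[:5]}")
    attr = {
        "ligand_ct": "ligand_cell_type",
        "receptor_ct": "receptor_cell_type",
        "annotation": "annotation",
    }[grouping]
    n_total = len(background)
    n_fg = len(fg)
    cats: dict[str, set[str]] = {}
    for it in background:
        value = getattr(it, attr)
        if value is None:
            continue
        cats.setdefault(value, set()).add(it.interaction_id)
    rows = []
    for cat, members in cats.items():
        a = len(fg & members)
        b = n_fg - a
        c = len(members) - a
        dd = n_total - n_fg - c
        _, p = stats.fisher_exact([[a, b], [c, dd]], alternative="greater")
        rows.append(
            {
                "category": cat,
                "n_foreground": a,
                "n_category": len(members),
                "odds_ratio": odds_ratio(np.array([[a, b], [c, dd]])),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# CV

def cv_of_aucs(aucs: Sequence[float]) -> float:
    """Coefficient of variation in percent: sample sd / mean × 100."""
    a = np.asarray(aucs, dtype=float)
    if a.size < 2:
        raise PreconditionError("cv_of_aucs needs at least two values")
    mean = a.mean()
    if mean == 0:
        raise PreconditionError("cv_of_aucs undefined for zero mean")
    return float(a.std(ddof=1) / mean * 100.0)
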