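"""Binarize interaction activity from deconvolved cell-type-specific expression.

An interaction is *activated* (1) in a sample iff the per-sample expression of
both its ligand side and its receptor side — each evaluated in the stated cell
type, complexes summarized across subunits — is strictly above that side's
median across the samples of the cohort's timepoint group.  Otherwise it is
inactivated (0).  Interactions whose required expression is unavailable are
non-measurable and carry NaN instead of 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import PreconditionError, ValidationError
from .interaction_db import InteractionDatabase

TIMEPOINTS = ("pre", "post")
RESPONSES = ("R", "NR", "unknown")


@dataclass
class DeconvolvedCohort:
    """One cohort of deconvolved expression: per-cell-type genes × samples matrices.

    ``samples`` is indexed by sample_id with columns ``timepoint`` (pre|post)
    and ``response`` (R|NR|unknown); every cell-type matrix must carry exactly
    the same sample columns.
    """

    cohort_id: str
    samples: pd.DataFrame
    expression: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        required = {"timepoint", "response"}
        if not required.issubset(self.samples.columns):
            raise ValidationError(
                f"cohort {self.cohort_id}: sample table needs columns {sorted(required)}"
            )
        bad_tp = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"cohort {self.cohort_id}: bad timepoints {sorted(bad_tp)}")
        bad_rs = set(self.samples["response"]) - set(RESPONSES)
        if bad_rs:
            raise ValidationError(f"cohort {self.cohort_id}: bad responses {sorted(bad_rs)}")
        ids = list(self.samples.index)
        for ct, mat in self.expression.items():
            if list(mat.columns) != ids:
                raise ValidationError(
                    f"cohort {self.cohort_id}: matrix for {ct!r} does not share the "
                    "cohort sample columns"
                )

    def sample_ids(self, timepoint: str | None = None) -> list[str]:
        if timepoint is None or timepoint == "all":
            return list(self.samples.index)
        return list(self.samples.index[self.samples["timepoint"] == timepoint])


@dataclass
class ActivityProfile:
    """Binary interaction × sample activity with NaN marking non-measurable entries."""

    matrix: pd.DataFrame  # interactions × samples; values in {0.0, 1.0, NaN}
    samples: pd.DataFrame  # index sample_id; columns cohort_id, timepoint, response

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValidationError("activity matrix columns must match the sample table index")
        vals = self.matrix.to_numpy(float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValidationError("activity entries must be 0, 1 or NaN")

    @property
    def interaction_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def measurable_mask(self) -> pd.DataFrame:
        return self.matrix.notna()

    def subset_samples(self, sample_ids: Sequence[str]) -> "ActivityProfile":
        ids = list(sample_ids)
        return ActivityProfile(self.matrix[ids], self.samples.loc[ids])


def _side_values(
    cohort: DeconvolvedCohort,
    cell_type: str,
    genes: Sequence[str],
    sample_ids: Sequence[str],
    complex_summary: Literal["mean", "min"],
) -> pd.Series | None:
    """Per-sample summarized expression for one interaction side, or None if absent."""
    mat = cohort.expression.get(cell_type)
    if mat is None:
        return None
    rows = mat.reindex(list(genes)).loc[:, list(sample_ids)].astype(float)
    if complex_summary == "min":
        vals = rows.min(axis=0, skipna=False)
    else:
        # mean over subunits present; a sample is NaN only when every subunit is NaN
        vals = rows.mean(axis=0, skipna=True)
    return vals


def call_activity(
    cohort: DeconvolvedCohort,
    db: InteractionDatabase,
    timepoint_group: Literal["pre", "post", "all"],
    complex_summary: Literal["mean", "min"] = "mean",
    max_na_fraction: float = 0.5,
) -> ActivityProfile:
    """Apply the above-median activation rule within one timepoint group.

    Medians are computed within the requested timepoint group of this cohort
    only (``"all"`` pools pre and post for joint medians).  A side with more
    than ``max_na_fraction`` missing values (or a cell type absent from the
    cohort) renders the interaction non-measurable; isolated NaNs count as
    below-median.
    """
    if timepoint_group not in TIMEPOINTS + ("all",):
        raise ValidationError(f"timepoint_group must be one of {TIMEPOINTS + ('all',)}")
    sample_ids = cohort.sample_ids(timepoint_group)
    if len(sample_ids) < 2:
        raise PreconditionError(
            f"cohort {cohort.cohort_id}: need >=2 samples in group {timepoint_group!r}, "
            f"got {len(sample_ids)}"
        )

    n = len(sample_ids)
    rows = np.full((len(db), n), np.nan)
    for k, it in enumerate(db):
        lig = _side_values(cohort, it.ligand_cell_type, it.ligand_genes, sample_ids, complex_summary)
        rec = _side_values(
            cohort, it.receptor_cell_type, it.receptor_genes, sample_ids, complex_summary
        )
        if lig is None or rec is None:
            continue
        if lig.isna().mean() > max_na_fraction or rec.isna().mean() > max_na_fraction:
            continue
        lig_above = lig > lig.median(skipna=True)  # NaN compares False: below-median
        rec_above = rec > rec.median(skipna=True)
        rows[k] = (lig_above & rec_above).to_numpy(float)

    matrix = pd.DataFrame(rows, index=list(db.ids), columns=sample_ids)
    meta = cohort.samples.loc[sample_ids, ["timepoint", "response"]].copy()
    meta.insert(0, "cohort_id", cohort.cohort_id)
    return ActivityProfile(matrix, meta)


def merge_profiles(profiles: Sequence[ActivityProfile]) -> ActivityProfile:
    """Column-concatenate profiles over the union of their interactions.

    Interactions absent from a source profile stay non-measurable on that
    profile's samples.  Duplicate sample ids across profiles are an error.
    """
    if not profiles:
        raise PreconditionError("merge_profiles needs at least one profile")
    if len(profiles) == 1:
        return ActivityProfile(profiles[0].matrix.copy(), profiles[0].samples.copy())
    all_samples: list[str] = []
    for p in profiles:
        all_samples.extend(p.samples.index)
    if len(set(all_samples)) != len(all_samples):
        dupes = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValidationError(f"duplicate sample ids across profiles: {dupes[:5]}")
    # union of interactions, first-seen order
    union: list[str] = []
    seen: set[str] = set()
    for p in profiles:
        for iid in p.matrix.index:
            if iid not in seen:
                seen.add(iid)
                union.append(iid)
    mats = [p.matrix.reindex(union) for p in profiles]
    matrix = pd.concat(mats, axis=1)
    samples = pd.concat([p.samples for p in profiles], axis=0)
    return ActivityProfile(matrix, samples)


# ---------------------------------------------------------------------------
# I/O

def read_cohort_dir(path: str | Path, cohort_id: str | None = None) -> DeconvolvedCohort:
    """Read a cohort directory: ``samples.tsv`` plus one ``<cell_type>.tsv`` per cell type."""
    path = Path(path)
    meta_path = path / "samples.tsv"
    if not meta_path.exists():
        raise ValidationError(f"{path}: missing samples.tsv")
    samples = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    expression = {}
    for f in sorted(path.glob("*.tsv")):
        if f.name == "samples.tsv":
            continue
        mat = pd.read_csv(f, sep="\t", index_col=0)
        expression[f.stem] = mat.loc[:, list(samples.index)]
    if not expression:
        raise ValidationError(f"{path}: no cell-type expression matrices found")
    return DeconvolvedCohort(cohort_id or path.name, samples, expression)


def write_cohort_dir(cohort: DeconvolvedCohort, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.samples.rename_axis("sample_id").reset_index().to_csv(
        path / "samples.tsv", sep="\t", index=False
    )
    for ct, mat in cohort.expression.items():
        mat.rename_axis("gene").to_csv(path / f"{ct}.tsv", sep="\t")


def write_profile(profile: ActivityProfile, prefix: str | Path) -> None:
    """Serialize as ``<prefix>.tsv`` (matrix, NA = non-measurable) + ``<prefix>.json``."""
    prefix = Path(prefix)
    profile.matrix.rename_axis("interaction_id").to_csv(f"{prefix}.tsv", sep="\t", na_rep="NA")
    meta = {
        "samples": profile.samples.rename_axis("sample_id").reset_index().to_dict("records")
    }
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=1))


def read_profile(prefix: str | Path) -> ActivityProfile:
    prefix = Path(prefix)
    matrix = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col=0, na_values=["NA"])
    meta = json.loads(Path(f"{prefix}.json").read_text())
    samples = pd.DataFrame(meta["samples"]).set_index("sample_id")
    return ActivityProfile(matrix, samples)
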