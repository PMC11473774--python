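"""Single-cell ligand-receptor inference via a cell-type-label permutation null.

The interaction score is the product of the mean ligand-complex expression in
the ligand cell type and the mean receptor-complex expression in the receptor
cell type.  Empirical p-values come from globally shuffling cell-type labels;
activation additionally requires both side means to exceed their medians
across samples.  Also provides the down-sampled pseudo-sample construction
used to turn grouped single cells into bulk-like cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import PreconditionError, ValidationError
from .interaction_db import InteractionDatabase, LRInteraction


@dataclass
class SingleCellDataset:
    """Cells × genes expression with per-cell cell-type (and optional group) labels."""

    expression: pd.DataFrame  # cells × genes, non-negative
    cell_type: pd.Series  # index = cells
    group: pd.Series | None = None  # index = cells
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.cell_type.index):
            raise ValidationError("cell_type index must match expression rows")
        if self.group is not None and not self.expression.index.equals(self.group.index):
            raise ValidationError("group index must match expression rows")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    def subset_cells(self, cells: Sequence[str], sample_id: str | None = None) -> "SingleCellDataset":
        cells = list(cells)
        return SingleCellDataset(
            expression=self.expression.loc[cells],
            cell_type=self.cell_type.loc[cells],
            group=self.group.loc[cells] if self.group is not None else None,
            sample_id=sample_id if sample_id is not None else self.sample_id,
        )


@dataclass(frozen=True)
class SocialConfig:
    n_permutations: int = 100
    alpha: float = 0.05
    downsample_fraction: float = 0.4
    n_pseudo_iterations: int = 200
    random_seed: int = 0
    complex_summary: Literal["mean", "min"] = "mean"

    def __post_init__(self) -> None:
        if not (0 < self.downsample_fraction <= 1):
            raise ValidationError("downsample_fraction must lie in (0, 1]")
        if self.n_permutations <= 0 or self.n_pseudo_iterations <= 0:
            raise ValidationError("iteration counts must be positive")


def _celltype_means(
    expression: np.ndarray, labels: np.ndarray, cell_types: Sequence[str]
) -> np.ndarray:
    """Mean expression per cell type: (types × genes), NaN for absent types."""
    n_types = len(cell_types)
    out = np.full((n_types, expression.shape[1]), np.nan)
    for t, ct in enumerate(cell_types):
        mask = labels == ct
        if mask.any():
            out[t] = expression[mask].mean(axis=0)
    return out


def _side_mean(
    ct_means: np.ndarray,
    ct_index: dict[str, int],
    gene_index: dict[str, int],
    cell_type: str,
    genes: Sequence[str],
    summary: str,
) -> float:
    """Complex-summarized mean expression of one side; genes absent from the
    matrix contribute 0; absent cell type yields NaN."""
    t = ct_index.get(cell_type)
    if t is None or np.isnan(ct_means[t]).all():
        return float("nan")
    vals = np.array([ct_means[t, gene_index[g]] if g in gene_index else 0.0 for g in genes])
    return float(vals.min()) if summary == "min" else float(vals.mean())


def interaction_score(
    dataset: SingleCellDataset,
    interaction: LRInteraction,
    complex_summary: Literal["mean", "min"] = "mean",
) -> float:
    """Mean-ligand × mean-receptor product score; NaN when a cell type is absent."""
    cts = sorted(dataset.cell_type.unique())
    ct_index = {c: i for i, c in enumerate(cts)}
    gene_index = {g: i for i, g in enumerate(dataset.expression.columns)}
    means = _celltype_means(
        dataset.expression.to_numpy(float), dataset.cell_type.to_numpy(), cts
    )
    lig = _side_mean(
        means, ct_index, gene_index, interaction.ligand_cell_type,
        interaction.ligand_genes, complex_summary,
    )
    rec = _side_mean(
        means, ct_index, gene_index, interaction.receptor_cell_type,
        interaction.receptor_genes, complex_summary,
    )
    return lig * rec


def social_permutation_test(
    dataset: SingleCellDataset,
    db: InteractionDatabase,
    config: SocialConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-interaction permutation test on one sample.

    Shuffles cell-type labels globally across all cells (expression fixed) and
    reports the strict fraction of permuted scores exceeding the foreground
    score.  Returns a frame indexed by interaction_id with columns score,
    lig_mean, rec_mean, p_value; interactions with a missing cell type carry
    NaN throughout.
    """
    if dataset.cell_type.nunique() < 2:
        raise PreconditionError("permutation test requires >= 2 cell types")
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    expr = dataset.expression.to_numpy(float)
    labels = dataset.cell_type.to_numpy()
    cts = sorted(pd.unique(labels))
    ct_index = {c: i for i, c in enumerate(cts)}
    gene_index = {g: i for i, g in enumerate(dataset.expression.columns)}

    def all_scores(means: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lig = np.empty(len(db))
        rec = np.empty(len(db))
        for k, it in enumerate(db):
            lig[k] = _side_mean(
                means, ct_index, gene_index, it.ligand_cell_type,
                it.ligand_genes, config.complex_summary,
            )
            rec[k] = _side_mean(
                means, ct_index, gene_index, it.receptor_cell_type,
                it.receptor_genes, config.complex_summary,
            )
        return lig * rec, lig, rec

    fg_means = _celltype_means(expr, labels, cts)
    fg_scores, fg_lig, fg_rec = all_scores(fg_means)

    exceed = np.zeros(len(db))
    for _ in range(config.n_permutations):
        perm = rng.permutation(labels)
        scores, _, _ = all_scores(_celltype_means(expr, perm, cts))
        with np.errstate(invalid="ignore"):
            exceed += (scores > fg_scores).astype(float)
    p = exceed / config.n_permutations
    p[np.isnan(fg_scores)] = np.nan

    return pd.DataFrame(
        {
            "score": fg_scores,
            "lig_mean": fg_lig,
            "rec_mean": fg_rec,
            "p_value": p,
        },
        index=pd.Index(db.ids, name="interaction_id"),
    )


def call_social_activity(
    results: dict[str, pd.DataFrame] | Sequence[tuple[str, pd.DataFrame]],
    config: SocialConfig,
) -> pd.DataFrame:
    """Binarize per-sample permutation results into an interaction × sample matrix.

    A (sample, interaction) is activated iff its empirical p < alpha AND both
    the ligand-side and receptor-side mean expressions are strictly above
    their medians across all samples.  Entries untestable in a sample (NaN
    score) stay NaN.
    """
    items = list(results.items()) if isinstance(results, dict) else list(results)
    if len(items) < 2:
        raise PreconditionError("call_social_activity requires >= 2 samples")
    lig = pd.DataFrame({sid: r["lig_mean"] for sid, r in items})
    rec = pd.DataFrame({sid: r["rec_mean"] for sid, r in items})
    pval = pd.DataFrame({sid: r["p_value"] for sid, r in items})
    lig_med = lig.median(axis=1, skipna=True)
    rec_med = rec.median(axis=1, skipna=True)
    active = (
        pval.lt(config.alpha)
        & lig.gt(lig_med, axis=0)
        & rec.gt(rec_med, axis=0)
    ).astype(float)
    active[pval.isna()] = np.nan
    return active


def make_pseudo_samples(
    dataset: SingleCellDataset,
    config: SocialConfig,
    rng: np.random.Generator | None = None,
) -> list[SingleCellDataset]:
    """Down-sampled pseudo-samples: per group, pool all cells then repeatedly draw
    ``floor(fraction * n)`` cells (minimum 1) per cell type without replacement.

    Yields ``n_groups * n_pseudo_iterations`` datasets, each tagged with a
    deterministic sample_id of the form ``<group>_ps<iteration>``.
    """
    if dataset.group is None:
        raise ValidationError("make_pseudo_samples requires per-cell group labels")
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    out: list[SingleCellDataset] = []
    for g in pd.unique(dataset.group):
        pool = dataset.group.index[dataset.group == g]
        types = dataset.cell_type.loc[pool]
        by_type = {ct: list(types.index[types == ct]) for ct in pd.unique(types)}
        for i in range(config.n_pseudo_iterations):
            chosen: list[str] = []
            for ct, cells in by_type.items():
                k = max(1, int(np.floor(config.downsample_fraction * len(cells))))
                picked = rng.choice(len(cells), size=k, replace=False)
                chosen.extend(cells[j] for j in picked)
            out.append(dataset.subset_cells(chosen, sample_id=f"{g}_ps{i:03d}"))
    return out


# ---------------------------------------------------------------------------
# I/O

def read_single_cell_dir(path: str | Path) -> SingleCellDataset:
    """Read ``expression.tsv`` (cells × genes) + ``cells.tsv`` (cell_id, cell_type[, group])."""
    path = Path(path)
    expr = pd.read_csv(path / "expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(path / "cells.tsv", sep="\t", dtype=str).set_index("cell_id")
    expr = expr.loc[list(meta.index)]
    group = meta["group"] if "group" in meta.columns else None
    return SingleCellDataset(expr, meta["cell_type"], group)


def write_single_cell_dir(dataset: SingleCellDataset, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.expression.rename_axis("cell_id").to_csv(path / "expression.tsv", sep="\t")
    meta = pd.DataFrame({"cell_type": dataset.cell_type})
    if dataset.group is not None:
        meta["group"] = dataset.group
    meta.rename_axis("cell_id").reset_index().to_csv(path / "cells.tsv", sep="\t", index=False)
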