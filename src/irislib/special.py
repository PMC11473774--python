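"""Spatial region segmentation and per-region ligand-receptor inference.

Slides are segmented into ~250 μm regions either by a sliding window over
spot coordinates (overlapping regions, one per spot) or by K-means on cell
coordinates (non-overlapping partition with the region count given by the
area ratio of the puck to a target region).  The single-cell permutation test
then runs independently per region, with activation decided against medians
taken across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import PreconditionError, ValidationError
from .interaction_db import InteractionDatabase
from .scoring import auc_rank
from .social import SingleCellDataset, SocialConfig, call_social_activity, social_permutation_test


@dataclass
class SpatialDataset:
    """Cells with coordinates, cell-type labels and expression; optional spot ids."""

    expression: pd.DataFrame  # cells × genes
    cell_type: pd.Series
    coordinates: pd.DataFrame  # cells × (x, y)
    spot_id: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.expression.index
        if not (idx.equals(self.cell_type.index) and idx.equals(self.coordinates.index)):
            raise ValidationError("cell_type and coordinates must share the expression index")
        if self.spot_id is not None and not idx.equals(self.spot_id.index):
            raise ValidationError("spot_id must share the expression index")
        xy = self.coordinates[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValidationError("coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    def to_single_cell(self, cells: Sequence[str], sample_id: str) -> SingleCellDataset:
        cells = list(cells)
        return SingleCellDataset(
            expression=self.expression.loc[cells],
            cell_type=self.cell_type.loc[cells],
            sample_id=sample_id,
        )


@dataclass(frozen=True)
class SpecialConfig:
    mode: Literal["sliding_window", "kmeans"] = "kmeans"
    window_radius: float = 1.0  # platform units, sliding-window mode
    region_diameter: float = 250.0  # μm
    puck_diameter: float = 3000.0  # μm
    n_permutations: int = 100
    alpha: float = 0.05
    random_seed: int = 0
    min_region_cells: int = 2

    def __post_init__(self) -> None:
        if self.window_radius <= 0 or self.region_diameter <= 0 or self.puck_diameter <= 0:
            raise ValidationError("geometry parameters must be positive")
        if self.mode == "kmeans" and self.region_diameter > self.puck_diameter:
            raise ValidationError("region_diameter must not exceed puck_diameter")

    def social_config(self) -> SocialConfig:
        return SocialConfig(
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            random_seed=self.random_seed,
        )


@dataclass
class Region:
    region_id: str
    center: tuple[float, float]
    cells: tuple[str, ...]


@dataclass
class RegionActivityMatrix:
    """Per-region binarized activity plus activated-set counts and composition."""

    regions: list[Region]
    activity: pd.DataFrame  # interactions × regions
    counts: pd.Series  # activated interactions (within the query set) per region
    counts_scaled: pd.Series
    cell_type_fractions: pd.DataFrame  # regions × cell types


def region_count_kmeans(puck_diameter: float, region_diameter: float) -> int:
    """Number of target-diameter circles fitting a circular puck, by area ratio."""
    if region_diameter <= 0 or puck_diameter <= 0:
        raise ValidationError("diameters must be positive")
    if region_diameter > puck_diameter:
        raise ValidationError("region_diameter must not exceed puck_diameter")
    return int(np.floor((puck_diameter / region_diameter) ** 2))


def _filter_regions(
    dataset: SpatialDataset, regions: list[Region], min_cells: int
) -> list[Region]:
    """Drop regions with < min_cells cells or a single distinct cell type."""
    kept = []
    for r in regions:
        if len(r.cells) < min_cells:
            continue
        if dataset.cell_type.loc[list(r.cells)].nunique() < 2:
            continue
        kept.append(r)
    return kept


def segment_sliding_window(
    dataset: SpatialDataset, config: SpecialConfig, filter_regions: bool = True
) -> list[Region]:
    """One (possibly overlapping) region per spot: all cells of spots within
    Euclidean distance <= window_radius of the focal spot's coordinates."""
    if dataset.spot_id is None:
        raise PreconditionError("sliding-window segmentation requires spot assignments")
    spots = dataset.spot_id.unique()
    if len(spots) == 0:
        raise PreconditionError("no spots in dataset")
    coords = {}
    members = {}
    for s in spots:
        cells = dataset.spot_id.index[dataset.spot_id == s]
        xy = dataset.coordinates.loc[cells, ["x", "y"]].to_numpy(float)
        coords[s] = xy[0]
        members[s] = list(cells)
    spot_xy = np.array([coords[s] for s in spots])
    regions = []
    for i, s in enumerate(spots):
        d = np.linalg.norm(spot_xy - spot_xy[i], axis=1)
        near = [spots[j] for j in np.flatnonzero(d <= config.window_radius)]
        cells = tuple(c for t in near for c in members[t])
        regions.append(Region(region_id=f"spot_{s}", center=tuple(spot_xy[i]), cells=cells))
    if filter_regions:
        regions = _filter_regions(dataset, regions, config.min_region_cells)
    return regions


def segment_kmeans(
    dataset: SpatialDataset,
    config: SpecialConfig,
    n_regions: int | None = None,
    filter_regions: bool = True,
) -> list[Region]:
    """K-means on (x, y) into ``n_regions`` clusters (default from the area-ratio
    rule), 10 restarts, seeded; every cell is assigned to exactly one region
    before single-cell-type regions are dropped."""
    k = n_regions if n_regions is not None else region_count_kmeans(
        config.puck_diameter, config.region_diameter
    )
    if k > dataset.n_cells:
        raise PreconditionError(f"k={k} regions exceed {dataset.n_cells} cells")
    xy = dataset.coordinates[["x", "y"]].to_numpy(float)
    km = KMeans(n_clusters=k, n_init=10, random_state=config.random_seed)
    assign = km.fit_predict(xy)
    regions = []
    cells = np.array(dataset.expression.index)
    for c in range(k):
        mask = assign == c
        if not mask.any():
            continue
        regions.append(
            Region(
                region_id=f"region_{c:03d}",
                center=tuple(km.cluster_centers_[c]),
                cells=tuple(cells[mask]),
            )
        )
    if filter_regions:
        regions = _filter_regions(dataset, regions, config.min_region_cells)
    return regions


def infer_region_activity(
    dataset: SpatialDataset,
    regions: Sequence[Region],
    db: InteractionDatabase,
    config: SpecialConfig,
    interaction_ids: Sequence[str] | None = None,
) -> RegionActivityMatrix:
    """Run the permutation test per region and binarize against across-region medians.

    ``interaction_ids`` restricts the activated-count summaries to a query set
    (e.g. a trained resistance-downregulated set); default is the whole
    database.  Counts are also z-scaled across regions.
    """
    regions = list(regions)
    if len(regions) < 2:
        raise PreconditionError("infer_region_activity requires >= 2 regions")
    seeds = np.random.SeedSequence(config.random_seed).spawn(len(regions))
    social_cfg = config.social_config()
    results = []
    for r, seed in zip(regions, seeds):
        sc = dataset.to_single_cell(r.cells, sample_id=r.region_id)
        res = social_permutation_test(sc, db, social_cfg, rng=np.random.default_rng(seed))
        results.append((r.region_id, res))
    activity = call_social_activity(results, social_cfg)

    ids = list(interaction_ids) if interaction_ids is not None else list(db.ids)
    ids = [i for i in ids if i in activity.index]
    counts = activity.loc[ids].sum(axis=0, skipna=True)
    sd = counts.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        warnings.warn("region counts are constant; scaled counts set to 0")
        scaled = pd.Series(0.0, index=counts.index)
    else:
        scaled = (counts - counts.mean()) / sd

    fractions = pd.DataFrame(
        {
            r.region_id: dataset.cell_type.loc[list(r.cells)].value_counts(normalize=True)
            for r in regions
        }
    ).T.fillna(0.0)
    return RegionActivityMatrix(
        regions=regions,
        activity=activity,
        counts=counts,
        counts_scaled=scaled,
        cell_type_fractions=fractions,
    )


def region_cd8_concordance(
    region_counts: pd.Series | Sequence[float],
    cd8_fraction: pd.Series | Sequence[float],
    threshold: float = 0.0,
) -> float:
    """AUC of activated-interaction counts against binarized CD8 infiltration
    (infiltrated iff fraction > threshold)."""
    counts = np.asarray(region_counts, dtype=float)
    cd8 = np.asarray(cd8_fraction, dtype=float)
    if counts.shape != cd8.shape:
        raise ValidationError("counts and cd8_fraction must align")
    labels = cd8 > threshold
    if not labels.any() or labels.all():
        raise PreconditionError("both infiltrated and desert regions required")
    return auc_rank(counts, labels)


# ---------------------------------------------------------------------------
# I/O

def read_spatial_dir(path: str | Path) -> SpatialDataset:
    """Read ``expression.tsv`` + ``cells.tsv`` (cell_id, x, y, cell_type[, spot_id])."""
    path = Path(path)
    expr = pd.read_csv(path / "expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(path / "cells.tsv", sep="\t").set_index("cell_id")
    expr = expr.loc[list(meta.index)]
    spot = meta["spot_id"].astype(str) if "spot_id" in meta.columns else None
    return SpatialDataset(
        expression=expr,
        cell_type=meta["cell_type"].astype(str),
        coordinates=meta[["x", "y"]].astype(float),
        spot_id=spot,
    )


def write_spatial_dir(dataset: SpatialDataset, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.expression.rename_axis("cell_id").to_csv(path / "expression.tsv", sep="\t")
    meta = pd.DataFrame(
        {
            "x": dataset.coordinates["x"],
            "y": dataset.coordinates["y"],
            "cell_type": dataset.cell_type,
        }
    )
    if dataset.spot_id is not None:
        meta["spot_id"] = dataset.spot_id
    meta.rename_axis("cell_id").reset_index().to_csv(path / "cells.tsv", sep="\t", index=False)
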