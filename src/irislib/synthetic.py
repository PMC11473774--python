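"""Synthetic cohorts, single-cell and spatial datasets with planted signal.

Deconvolved cohorts are generated activation-first: the binary target state of
every interaction in every sample is drawn from configured rates, and the
log-normal expression values are then arranged so that the above-median
activation rule recovers the targets exactly (the top half of each gene's
values is assigned to a superset of the active samples on each side, with the
two sides' extra above-median samples kept disjoint).  Ground-truth tables
record the planted directions so recovery tests need no other oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .activation import DeconvolvedCohort
from .exceptions import PreconditionError, ValidationError
from .interaction_db import DEFAULT_CELL_TYPES, InteractionDatabase, LRInteraction
from .social import SingleCellDataset
from .special import SpatialDataset

_ANNOTATIONS = ("chemotaxis", "checkpoint", "adhesion", "stimulatory", "inhibitory")

_DEFAULT_PAIRS = (
    ("Mal", "TCD8"),
    ("Mal", "Macrophage"),
    ("NK", "skinDC"),
    ("TCD8", "Mal"),
    ("CAF", "Endo"),
    ("pDC", "TCD4"),
    ("Macrophage", "NK"),
    ("Bcell", "TCD4"),
)


def build_database(
    n_interactions: int,
    cell_type_pairs: Sequence[tuple[str, str]] = _DEFAULT_PAIRS,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
) -> InteractionDatabase:
    """Deterministic synthetic interaction universe with unique gene pairs.

    Interaction *i* links ligand gene ``LG<i>`` to receptor gene ``RG<i>`` on
    the ``i % len(pairs)``-th cell-type pair, cycling functional annotations.
    """
    interactions = []
    for i in range(n_interactions):
        lct, rct = cell_type_pairs[i % len(cell_type_pairs)]
        interactions.append(
            LRInteraction(
                ligand_genes=(f"LG{i:04d}",),
                receptor_genes=(f"RG{i:04d}",),
                ligand_cell_type=lct,
                receptor_cell_type=rct,
                annotation=_ANNOTATIONS[i % len(_ANNOTATIONS)],
            )
        )
    return InteractionDatabase(tuple(interactions), tuple(cell_types))


@dataclass(frozen=True)
class CohortSimConfig:
    n_cohorts: int = 4
    n_pre: int = 40
    n_post: int = 30
    responder_fraction: float = 0.4
    n_interactions: int = 300
    n_planted: int = 20
    n_differential_only: int = 60  # differential post-resistance but not predictive
    differential_only_rate: float = 0.40  # their activation rate on the high side
    planted_direction: str = "RDI"
    pre_rate: float = 0.55  # overall planted activation rate in pre-treatment
    responder_gap: float = 0.5  # pre-treatment R-vs-NR activation gap for planted
    post_nr_rate: float = 0.10
    background_rate: float = 0.30
    lognorm_mu: float = 1.0
    lognorm_sigma: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pre_rate", "post_nr_rate", "background_rate", "responder_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_planted + self.n_differential_only > self.n_interactions:
            raise ValidationError(
                "n_planted + n_differential_only cannot exceed n_interactions"
            )
        for name, v in self.rate_table().items():
            if v >= 1.0 and max(self.n_pre, self.n_post) >= 2:
                raise PreconditionError(
                    f"rate {name}={v} demands activation in more than half of the "
                    "samples deterministically; above-median activation frequency "
                    "is bounded by 0.5 within a group"
                )

    def rate_table(self) -> dict[str, float]:
        f = self.responder_fraction
        pre_r = min(self.pre_rate + (1 - f) * self.responder_gap, 0.999)
        pre_nr = max(self.pre_rate - f * self.responder_gap, 0.0)
        return {
            "planted_pre_R": pre_r,
            "planted_pre_NR": pre_nr,
            "planted_post_NR": self.post_nr_rate,
            "planted_post_R": self.pre_rate,
            "background": self.background_rate,
        }


def _plant_group_expression(
    active: np.ndarray,
    rng: np.random.Generator,
    mu: float,
    sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Ligand/receptor expression rows realizing a target binary activation vector.

    Each side's above-median sample set is a superset of the active set padded
    to exactly ``floor(n/2)`` samples; the two pads are disjoint, so the AND of
    the two above-median indicators equals the target exactly.
    """
    n = active.size
    half = n // 2
    act = np.flatnonzero(active)
    if act.size > half:
        raise ValidationError("active set exceeds the floor(n/2) feasibility bound")
    inactive = np.flatnonzero(~active)
    pad = rng.permutation(inactive)
    n_extra = half - act.size
    lig_above = np.concatenate([act, pad[:n_extra]])
    rec_above = np.concatenate([act, pad[n_extra : 2 * n_extra]])

    def realize(above: np.ndarray) -> np.ndarray:
        vals = np.sort(rng.lognormal(mu, sigma, size=n))
        row = np.empty(n)
        below = np.setdiff1d(np.arange(n), above)
        row[rng.permutation(above)] = vals[n - above.size :]
        row[rng.permutation(below)] = vals[: n - above.size]
        return row

    return realize(lig_above), realize(rec_above)


def _draw_active(
    rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample Bernoulli draw, capped at floor(n/2) actives (random eviction)."""
    active = rng.random(rates.size) < rates
    half = rates.size // 2
    excess = int(active.sum()) - half
    if excess > 0:
        on = np.flatnonzero(active)
        drop = rng.choice(on.size, size=excess, replace=False)
        active[on[drop]] = False
    return active


def simulate_cohorts(
    config: CohortSimConfig,
) -> tuple[list[DeconvolvedCohort], pd.DataFrame, InteractionDatabase]:
    """Generate cohorts with planted differential + response-predictive interactions.

    Planted interactions (direction RDI by default) activate at ``pre_rate``
    overall in pre-treatment — enriched in responders by ``responder_gap`` —
    and at ``post_nr_rate`` in post-treatment non-responders; background
    interactions activate at ``background_rate`` everywhere with no response
    dependence.  Returns (cohorts, ground-truth table, database).
    """
    rng = np.random.default_rng(config.random_seed)
    db = build_database(config.n_interactions)
    planted = set(db.ids[: config.n_planted])
    differential_only = set(
        db.ids[config.n_planted : config.n_planted + config.n_differential_only]
    )
    rates = config.rate_table()
    rdi = config.planted_direction == "RDI"

    cohorts = []
    for c in range(config.n_cohorts):
        samples = []
        for k in range(config.n_pre):
            r = rng.random() < config.responder_fraction
            samples.append((f"c{c}_pre_{k:03d}", "pre", "R" if r else "NR"))
        for k in range(config.n_post):
            r = rng.random() < config.responder_fraction
            samples.append((f"c{c}_post_{k:03d}", "post", "R" if r else "NR"))
        meta = pd.DataFrame(samples, columns=["sample_id", "timepoint", "response"]).set_index(
            "sample_id"
        )

        # per cell type: gene rows accumulated across interactions
        expr_rows: dict[str, dict[str, np.ndarray]] = {ct: {} for ct in db.cell_types}
        n_all = len(meta)
        for it in db:
            iid = it.interaction_id
            row_l = np.empty(n_all)
            row_r = np.empty(n_all)
            for tp in ("pre", "post"):
                sel = meta["timepoint"] == tp
                idx = np.flatnonzero(sel.to_numpy())
                resp = (meta.loc[sel, "response"] == "R").to_numpy()
                if iid in planted:
                    if tp == "pre":
                        p_r = rates["planted_pre_R"] if rdi else rates["planted_post_R"]
                        p_nr = rates["planted_pre_NR"] if rdi else rates["planted_post_NR"]
                    else:
                        p_r = rates["planted_post_R"] if rdi else rates["planted_pre_R"]
                        p_nr = rates["planted_post_NR"] if rdi else rates["planted_pre_NR"]
                    group_rates = np.where(resp, p_r, p_nr)
                elif iid in differential_only:
                    # differential between pre and post-NR, but response-blind in pre
                    high, low = config.differential_only_rate, rates["planted_post_NR"]
                    if rdi:
                        if tp == "pre":
                            group_rates = np.full(idx.size, high)
                        else:  # post-treatment NR drops; R keeps the pre level
                            group_rates = np.where(resp, high, low)
                    else:
                        group_rates = np.full(idx.size, low if tp == "pre" else high)
                else:
                    group_rates = np.full(idx.size, rates["background"])
                active = _draw_active(group_rates, rng)
                lig, rec = _plant_group_expression(
                    active, rng, config.lognorm_mu, config.lognorm_sigma
                )
                row_l[idx] = lig
                row_r[idx] = rec
            expr_rows[it.ligand_cell_type][it.ligand_genes[0]] = row_l
            expr_rows[it.receptor_cell_type][it.receptor_genes[0]] = row_r

        expression = {}
        for ct, rows in expr_rows.items():
            if rows:
                expression[ct] = pd.DataFrame(rows, index=list(meta.index)).T
        cohorts.append(DeconvolvedCohort(f"cohort_{c:02d}", meta, expression))

    def klass(iid: str) -> str:
        if iid in planted:
            return "planted"
        if iid in differential_only:
            return "differential_only"
        return "background"

    truth = pd.DataFrame(
        {
            "interaction_id": list(db.ids),
            "planted": [iid in planted for iid in db.ids],
            "class": [klass(iid) for iid in db.ids],
            "direction": [
                config.planted_direction if iid in planted else "none" for iid in db.ids
            ],
        }
    )
    return cohorts, truth, db


@dataclass(frozen=True)
class SingleCellSimConfig:
    groups: tuple[str, ...] = ("naive", "resistant")
    cells_per_type: int = 50
    n_interactions: int = 30
    n_planted: int = 5
    active_groups: tuple[str, ...] = ("naive",)
    effect_size: float = 8.0
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_type <= 0:
            raise ValidationError("cells_per_type must be positive")
        if self.n_planted > self.n_interactions:
            raise ValidationError("n_planted cannot exceed n_interactions")


def simulate_single_cell(
    config: SingleCellSimConfig,
) -> tuple[SingleCellDataset, pd.DataFrame, InteractionDatabase]:
    """Single-cell dataset with planted interactions elevated in chosen groups.

    Each group holds ``cells_per_type`` cells of every cell type used by the
    database; planted interactions get their ligand (receptor) gene multiplied
    by ``effect_size`` in the ligand (receptor) cell type of active groups.
    """
    rng = np.random.default_rng(config.random_seed)
    db = build_database(config.n_interactions)
    planted = set(db.ids[: config.n_planted])
    used_types = sorted(
        {it.ligand_cell_type for it in db} | {it.receptor_cell_type for it in db}
    )
    genes = sorted({g for it in db for g in it.ligand_genes + it.receptor_genes})

    cell_ids, type_labels, group_labels = [], [], []
    for g in config.groups:
        for ct in used_types:
            for k in range(config.cells_per_type):
                cell_ids.append(f"{g}_{ct}_{k:03d}")
                type_labels.append(ct)
                group_labels.append(g)
    n_cells = len(cell_ids)
    expr = rng.lognormal(config.lognorm_mu, config.lognorm_sigma, size=(n_cells, len(genes)))
    expr = pd.DataFrame(expr, index=cell_ids, columns=genes)
    cell_type = pd.Series(type_labels, index=cell_ids)
    group = pd.Series(group_labels, index=cell_ids)

    for it in db:
        if it.interaction_id not in planted:
            continue
        for g in config.active_groups:
            lig_cells = (group == g) & (cell_type == it.ligand_cell_type)
            rec_cells = (group == g) & (cell_type == it.receptor_cell_type)
            expr.loc[lig_cells, list(it.ligand_genes)] *= config.effect_size
            expr.loc[rec_cells, list(it.receptor_genes)] *= config.effect_size

    truth = pd.DataFrame(
        {
            "interaction_id": list(db.ids),
            "planted": [iid in planted for iid in db.ids],
            "active_groups": [
                ",".join(config.active_groups) if iid in planted else "" for iid in db.ids
            ],
        }
    )
    return SingleCellDataset(expr, cell_type, group), truth, db


@dataclass(frozen=True)
class SpatialSimConfig:
    puck_diameter: float = 3000.0
    n_cells: int = 600
    base_cell_types: tuple[str, ...] = ("Mal", "Macrophage", "NK", "skinDC")
    infiltrating_cell_type: str = "TCD8"
    infiltrate_fraction: float = 0.25  # of cells in the infiltrated half
    n_interactions: int = 12
    n_planted: int = 6
    effect_size: float = 8.0
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.puck_diameter <= 0 or self.n_cells <= 0:
            raise PreconditionError("puck geometry and cell count must be positive")


def simulate_spatial(
    config: SpatialSimConfig,
) -> tuple[SpatialDataset, pd.DataFrame, InteractionDatabase]:
    """Disc-shaped slide whose x > 0 half is infiltrated.

    Cells are placed uniformly in the puck.  The infiltrated half additionally
    hosts CD8-like cells and elevated planted-interaction expression, so
    activated counts should rank infiltrated regions above deserts.
    """
    rng = np.random.default_rng(config.random_seed)
    base = config.base_cell_types
    pairs = [(base[i], base[(i + 1) % len(base)]) for i in range(len(base))]
    pairs.append((base[0], config.infiltrating_cell_type))
    db = build_database(config.n_interactions, cell_type_pairs=tuple(pairs))
    planted = set(db.ids[: config.n_planted])
    genes = sorted({g for it in db for g in it.ligand_genes + it.receptor_genes})

    radius = config.puck_diameter / 2.0
    r = radius * np.sqrt(rng.random(config.n_cells))
    theta = rng.random(config.n_cells) * 2 * np.pi
    x, y = r * np.cos(theta), r * np.sin(theta)
    infiltrated = x > 0

    types = np.array(
        [config.base_cell_types[i] for i in rng.integers(len(config.base_cell_types), size=config.n_cells)],
        dtype=object,
    )
    swap = infiltrated & (rng.random(config.n_cells) < config.infiltrate_fraction)
    types[swap] = config.infiltrating_cell_type

    cell_ids = [f"cell_{i:04d}" for i in range(config.n_cells)]
    expr = rng.lognormal(config.lognorm_mu, config.lognorm_sigma, size=(config.n_cells, len(genes)))
    expr = pd.DataFrame(expr, index=cell_ids, columns=genes)
    cell_type = pd.Series(types, index=cell_ids)
    infil = pd.Series(infiltrated, index=cell_ids)

    for it in db:
        if it.interaction_id not in planted:
            continue
        lig_cells = infil & (cell_type == it.ligand_cell_type)
        rec_cells = infil & (cell_type == it.receptor_cell_type)
        expr.loc[lig_cells, list(it.ligand_genes)] *= config.effect_size
        expr.loc[rec_cells, list(it.receptor_genes)] *= config.effect_size

    coords = pd.DataFrame({"x": x, "y": y}, index=cell_ids)
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "infiltrated_half": infiltrated,
            "cell_type": types,
        }
    ).set_index("cell_id")
    dataset = SpatialDataset(expression=expr, cell_type=cell_type, coordinates=coords)
    return dataset, truth, db
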