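"""Curated cell-type-specific ligand-receptor interaction database.

The database is a flat TSV with one directed interaction per row.  Gene
complexes are encoded by joining gene symbols with ``_`` inside a single
cell.  Every interaction carries a deterministic identifier of the form
``ligandCT|ligandGenes→receptorCT|receptorGenes`` so that model files are
diffable and stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .exceptions import ValidationError

#: Default tumor-microenvironment cell-type vocabulary.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "Mal",
    "skinDC",
    "pDC",
    "TCD8",
    "TCD4",
    "Macrophage",
    "NK",
    "Bcell",
    "Endo",
    "CAF",
)

COMPLEX_SEP = "_"
_ARROW = "→"

_REQUIRED_COLUMNS = (
    "ligand_genes",
    "receptor_genes",
    "ligand_cell_type",
    "receptor_cell_type",
    "annotation",
)


def make_interaction_id(
    ligand_cell_type: str,
    ligand_genes: Sequence[str],
    receptor_cell_type: str,
    receptor_genes: Sequence[str],
) -> str:
    """Canonical identifier; a pure function of the four components."""
    return (
        f"{ligand_cell_type}|{COMPLEX_SEP.join(ligand_genes)}"
        f"{_ARROW}"
        f"{receptor_cell_type}|{COMPLEX_SEP.join(receptor_genes)}"
    )


def parse_interaction_id(interaction_id: str) -> tuple[str, tuple[str, ...], str, tuple[str, ...]]:
    """Invert :func:`make_interaction_id`."""
    try:
        left, right = interaction_id.split(_ARROW)
        lct, lg = left.split("|")
        rct, rg = right.split("|")
    except ValueError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"malformed interaction id: {interaction_id!r}") from exc
    return lct, tuple(lg.split(COMPLEX_SEP)), rct, tuple(rg.split(COMPLEX_SEP))


@dataclass(frozen=True)
class LRInteraction:
    """A directed, cell-type-specific ligand→receptor pair."""

    ligand_genes: tuple[str, ...]
    receptor_genes: tuple[str, ...]
    ligand_cell_type: str
    receptor_cell_type: str
    annotation: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_genes", tuple(self.ligand_genes))
        object.__setattr__(self, "receptor_genes", tuple(self.receptor_genes))
        if not self.ligand_genes or any(not g for g in self.ligand_genes):
            raise ValidationError("ligand gene list must be non-empty")
        if not self.receptor_genes or any(not g for g in self.receptor_genes):
            raise ValidationError("receptor gene list must be non-empty")

    @property
    def interaction_id(self) -> str:
        return make_interaction_id(
            self.ligand_cell_type,
            self.ligand_genes,
            self.receptor_cell_type,
            self.receptor_genes,
        )

    @property
    def is_complex(self) -> bool:
        return len(self.ligand_genes) > 1 or len(self.receptor_genes) > 1


@dataclass(frozen=True)
class InteractionDatabase:
    """An ordered collection of :class:`LRInteraction` with a cell-type vocabulary."""

    interactions: tuple[LRInteraction, ...]
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "interactions", tuple(self.interactions))
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        index: dict[str, LRInteraction] = {}
        vocab = set(self.cell_types)
        for i, it in enumerate(self.interactions):
            iid = it.interaction_id
            if iid in index:
                raise ValidationError(f"duplicate interaction id at row {i}: {iid}")
            if it.ligand_cell_type not in vocab:
                raise ValidationError(
                    f"row {i}: unknown ligand cell type {it.ligand_cell_type!r}"
                )
            if it.receptor_cell_type not in vocab:
                raise ValidationError(
                    f"row {i}: unknown receptor cell type {it.receptor_cell_type!r}"
                )
            index[iid] = it
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self) -> Iterator[LRInteraction]:
        return iter(self.interactions)

    def __contains__(self, interaction_id: str) -> bool:
        return interaction_id in self._index

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(it.interaction_id for it in self.interactions)

    def get(self, interaction_id: str) -> LRInteraction:
        try:
            return self._index[interaction_id]
        except KeyError as exc:
            raise KeyError(f"unknown interaction id: {interaction_id}") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interaction_id": [it.interaction_id for it in self.interactions],
                "ligand_genes": [COMPLEX_SEP.join(it.ligand_genes) for it in self.interactions],
                "receptor_genes": [
                    COMPLEX_SEP.join(it.receptor_genes) for it in self.interactions
                ],
                "ligand_cell_type": [it.ligand_cell_type for it in self.interactions],
                "receptor_cell_type": [it.receptor_cell_type for it in self.interactions],
                "annotation": [it.annotation for it in self.interactions],
            }
        )


def subset_database(
    db: InteractionDatabase,
    ligand_ct: str | None = None,
    receptor_ct: str | None = None,
    annotation: str | None = None,
) -> InteractionDatabase:
    """Filter by any combination of ligand cell type, receptor cell type and annotation.

    Absent filters match everything; an empty result is permitted.
    """
    kept = [
        it
        for it in db.interactions
        if (ligand_ct is None or it.ligand_cell_type == ligand_ct)
        and (receptor_ct is None or it.receptor_cell_type == receptor_ct)
        and (annotation is None or it.annotation == annotation)
    ]
    return InteractionDatabase(tuple(kept), db.cell_types)


def load_database(
    path: str | Path,
    cell_type_vocabulary: Sequence[str] | None = None,
) -> InteractionDatabase:
    """Load a TSV database, preserving row order.

    Expected header columns: ligand_genes, receptor_genes, ligand_cell_type,
    receptor_cell_type, annotation.  Complexes are ``_``-joined gene symbols.
    """
    vocab = tuple(cell_type_vocabulary) if cell_type_vocabulary is not None else DEFAULT_CELL_TYPES
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"database {path}: missing columns {missing}")
    interactions = []
    for i, row in enumerate(df.itertuples(index=False)):
        lg = str(row.ligand_genes).strip()
        rg = str(row.receptor_genes).strip()
        if not lg or not rg:
            raise ValidationError(f"database {path}: empty gene field at row {i}")
        ann = str(row.annotation).strip() or None
        interactions.append(
            LRInteraction(
                ligand_genes=tuple(lg.split(COMPLEX_SEP)),
                receptor_genes=tuple(rg.split(COMPLEX_SEP)),
                ligand_cell_type=str(row.ligand_cell_type).strip(),
                receptor_cell_type=str(row.receptor_cell_type).strip(),
                annotation=ann,
            )
        )
    return InteractionDatabase(tuple(interactions), vocab)


def write_database(db: InteractionDatabase, path: str | Path) -> None:
    """Write the TSV form consumed by :func:`load_database` (round-trip safe)."""
    df = db.to_frame().drop(columns=["interaction_id"])
    df["annotation"] = df["annotation"].fillna("")
    df.to_csv(path, sep="\t", index=False)
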