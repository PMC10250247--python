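"""Layered prior-knowledge signaling database.

Interactions come in three layers that mirror the signal-transduction
cascade from the extracellular space to the genome:

* ``LR``  — ligand → receptor binding,
* ``RTF`` — receptor → transcription-factor signal transduction,
* ``TFT`` — transcription factor → target gene regulation.

Every interaction carries a non-empty set of provenance labels naming the
curated resources it was taken from.  Databases are per-species; merging
unions interactions and their source labels, never crossing species.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import ValidationError

LAYERS = ("LR", "RTF", "TFT")

#: layer token -> (role of the source node, role of the destination node)
LAYER_ROLES = {"LR": ("L", "R"), "RTF": ("R", "TF"), "TFT": ("TF", "T")}

_COLUMNS = ["from", "to", "layer", "species", "source"]


@dataclass(frozen=True)
class Interaction:
    """One directed gene-pair interaction in a single layer."""

    from_gene: str
    to_gene: str
    layer: str
    species: str
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if not self.from_gene or not self.to_gene:
            raise ValidationError("interaction gene symbols must be non-empty")
        if self.layer not in LAYERS:
            raise ValidationError(
                f"unknown layer token {self.layer!r} for "
                f"{self.from_gene}->{self.to_gene}; expected one of {LAYERS}"
            )
        if not self.sources:
            raise ValidationError(
                f"interaction {self.from_gene}->{self.to_gene} has no source labels"
            )
        if self.from_gene == self.to_gene:
            raise ValidationError(
                f"self-loop {self.from_gene}->{self.to_gene} in layer {self.layer}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.from_gene, self.to_gene, self.layer)


class SignalingDB:
    """A deduplicated set of layered interactions for one species.

    Duplicate ``(from, to, layer)`` triples passed to the constructor are
    collapsed into a single interaction whose source labels are the union
    of the duplicates' labels.
    """

    def __init__(self, interactions: Iterable[Interaction], species: str):
        self.species = species
        merged: dict[tuple[str, str, str], Interaction] = {}
        for ia in interactions:
            if ia.species != species:
                raise ValidationError(
                    f"interaction {ia.from_gene}->{ia.to_gene} has species "
                    f"{ia.species!r}, database is {species!r}"
                )
            prev = merged.get(ia.key)
            if prev is None:
                merged[ia.key] = ia
            else:
                merged[ia.key] = Interaction(
                    ia.from_gene, ia.to_gene, ia.layer, species,
                    prev.sources | ia.sources,
                )
        self._by_key = merged

    @property
    def interactions(self) -> frozenset[Interaction]:
        return frozenset(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._by_key

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalingDB):
            return NotImplemented
        return self.species == other.species and self._by_key == other._by_key

    def layer(self, layer: str) -> frozenset[Interaction]:
        """All interactions of one layer (``LR``, ``RTF`` or ``TFT``)."""
        if layer not in LAYERS:
            raise ValidationError(f"unknown layer token {layer!r}")
        return frozenset(ia for ia in self._by_key.values() if ia.layer == layer)

    def layer_edges(self, layer: str) -> frozenset[tuple[str, str]]:
        """The (from_gene, to_gene) pairs of one layer."""
        return frozenset((ia.from_gene, ia.to_gene) for ia in self.layer(layer))


def load_db(path: str | Path, species: str) -> SignalingDB:
    """Read a layered interaction table from TSV.

    Expected header: ``from  to  layer  species  source``.  Multiple
    sources may appear either as repeated rows or as a comma-joined
    ``source`` field.  Rows of other species are ignored; zero rows
    surviving the species filter is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"database file not found: {path}")
    interactions: list[Interaction] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            if row["species"].strip() != species:
                continue
            layer = row["layer"].strip()
            if layer not in LAYERS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown layer token {layer!r}"
                )
            sources = frozenset(
                s.strip() for s in row["source"].split(",") if s.strip()
            )
            interactions.append(
                Interaction(row["from"].strip(), row["to"].strip(), layer,
                            species, sources)
            )
    if not interactions:
        raise ValidationError(f"{path}: no interactions for species {species!r}")
    return SignalingDB(interactions, species)


def write_db(db: SignalingDB, path: str | Path) -> None:
    """Write a database to TSV, one row per (interaction, source) pair."""
    rows = []
    for ia in sorted(db.interactions, key=lambda x: x.key):
        for src in sorted(ia.sources):
            rows.append([ia.from_gene, ia.to_gene, ia.layer, ia.species, src])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        writer.writerows(rows)


def merge_dbs(dbs: list[SignalingDB]) -> SignalingDB:
    """Union several same-species databases, unioning source labels.

    Merging is commutative and idempotent on interaction triples, so the
    integrated database never depends on the order resources are added.
    """
    if not dbs:
        raise ValidationError("merge_dbs requires at least one database")
    species = {db.species for db in dbs}
    if len(species) > 1:
        raise ValidationError(f"cannot merge databases of mixed species: {sorted(species)}")
    all_ias: list[Interaction] = []
    for db in dbs:
        all_ias.extend(db.interactions)
    return SignalingDB(all_ias, dbs[0].species)


def db_layer(db: SignalingDB, layer: str) -> frozenset[Interaction]:
    """Functional alias for :meth:`SignalingDB.layer`."""
    return db.layer(layer)
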