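"""Survey codebooks: the mapping from categorical answers to signed dummies.

A codebook declares, for every survey item, which response categories exist
and how each category aligns with the protective knowledge and behaviour
expected during the pandemic: +1 (risk-consistent), -1 (risk-inconsistent)
or 0 (neutral / not informative).  The codebook is the model's operational
definition of "perceiving risk"; everything downstream (risk vectors, scores,
quartiles, the similarity network) is derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: the three conceptual dimensions a risk item may belong to
DIMENSIONS = ("knowledge", "perception_severity", "preventive_practice")

VALID_SIGNS = (-1, 0, 1)


class CodebookError(ValueError):
    """Raised when a codebook file violates the schema."""


@dataclass(frozen=True)
class ItemCoding:
    """Coding of a single survey item.

    Parameters
    ----------
    item_id : str
        Unique identifier of the item (column name in the respondent table).
    dimension : str
        One of :data:`DIMENSIONS`.
    categories : tuple of str
        Response categories in their declared (and dummy-column) order.
    sign_map : dict
        Category label -> sign in {-1, 0, +1}.
    """

    item_id: str
    dimension: str
    categories: tuple
    sign_map: dict

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise CodebookError(
                f"item {self.item_id!r}: unknown dimension {self.dimension!r};"
                f" expected one of {DIMENSIONS}"
            )
        if len(set(self.categories)) != len(self.categories):
            raise CodebookError(f"item {self.item_id!r}: duplicate categories")
        if set(self.sign_map) != set(self.categories):
            raise CodebookError(
                f"item {self.item_id!r}: sign_map keys must match categories"
            )
        for cat, sign in self.sign_map.items():
            if sign not in VALID_SIGNS:
                raise ValueError(
                    f"item {self.item_id!r}, category {cat!r}: sign {sign!r}"
                    " outside {-1, 0, +1}"
                )
        if all(self.sign_map[c] == 0 for c in self.categories):
            raise CodebookError(
                f"item {self.item_id!r}: all categories map to 0; an item that"
                " can never contribute to the risk score is rejected"
            )

    def sign(self, category: str) -> int:
        return self.sign_map[category]


@dataclass
class Codebook:
    """Ordered collection of :class:`ItemCoding` with derived dummy columns."""

    items: list = field(default_factory=list)

    def __post_init__(self):
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CodebookError(f"duplicate item_id(s): {sorted(dupes)}")

    @property
    def item_ids(self) -> list:
        return [it.item_id for it in self.items]

    @property
    def dummy_columns(self) -> list:
        """(item_id, category) pairs: item order, then declared category order."""
        return [(it.item_id, c) for it in self.items for c in it.categories]

    @property
    def n_dummies(self) -> int:
        return sum(len(it.categories) for it in self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemCoding:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.item_ids

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "item_id": it.item_id,
                    "dimension": it.dimension,
                    "categories": list(it.categories),
                    "signs": {c: int(it.sign_map[c]) for c in it.categories},
                }
                for it in self.items
            ]
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "Codebook":
        if not isinstance(doc, dict) or "items" not in doc:
            raise CodebookError("codebook document must contain an 'items' list")
        items = []
        for entry in doc["items"]:
            missing = {"item_id", "dimension", "categories", "signs"} - set(entry)
            if missing:
                raise CodebookError(
                    f"codebook item {entry.get('item_id', '?')!r} missing"
                    f" field(s): {sorted(missing)}"
                )
            items.append(
                ItemCoding(
                    item_id=str(entry["item_id"]),
                    dimension=entry["dimension"],
                    categories=tuple(str(c) for c in entry["categories"]),
                    sign_map={str(k): v for k, v in entry["signs"].items()},
                )
            )
        return cls(items=items)


def load_codebook(path) -> Codebook:
    """Load and validate a YAML codebook.

    The dummy-column order of the returned codebook is a pure function of the
    file: item order as listed, then category order as listed, so re-loading
    always reproduces identical risk matrices.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return Codebook.from_dict(doc)
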