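"""Crossed trait-by-method measurement designs.

An MTMM design maps every binary indicator to exactly one trait factor
(the construct it measures) and one method factor (the way it is
measured).  Traits and methods are crossed: the same set of methods is
used to measure every trait, which is what makes the latent space of the
model high-dimensional and the marginal likelihood hard to integrate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = ["MTMMDesign", "DesignError", "crossed_design", "read_design"]


class DesignError(ValueError):
    """Raised for structurally invalid trait/method designs."""


@dataclass(frozen=True)
class MTMMDesign:
    """Item-to-factor map for a crossed trait x method design.

    Internally items, traits and methods are indexed 0-based; all
    user-facing I/O (design files, response files, printed tables) uses
    the item/trait/method labels, which are 1-based by convention when
    numeric.

    Parameters
    ----------
    trait_of_item, method_of_item
        Integer arrays of length ``n_items`` giving, for each item, the
        index of the trait factor and the method factor it loads on.
    item_labels, trait_labels, method_labels
        Display labels; factor order is the order of these tuples.
    """

    trait_of_item: np.ndarray
    method_of_item: np.ndarray
    item_labels: tuple[str, ...]
    trait_labels: tuple[str, ...]
    method_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.trait_of_item, dtype=int)
        m = np.asarray(self.method_of_item, dtype=int)
        object.__setattr__(self, "trait_of_item", t)
        object.__setattr__(self, "method_of_item", m)
        object.__setattr__(self, "item_labels", tuple(self.item_labels))
        object.__setattr__(self, "trait_labels", tuple(self.trait_labels))
        object.__setattr__(self, "method_labels", tuple(self.method_labels))
        I = t.size
        if I < 1:
            raise DesignError("design must contain at least one item")
        if m.size != I or len(self.item_labels) != I:
            raise DesignError("trait map, method map and item labels must have equal length")
        T, M = len(self.trait_labels), len(self.method_labels)
        if T < 1 or M < 1:
            raise DesignError("at least one trait and one method factor are required")
        if t.min() < 0 or t.max() >= T:
            raise DesignError("trait index out of range")
        if m.min() < 0 or m.max() >= M:
            raise DesignError("method index out of range")
        if set(t.tolist()) != set(range(T)):
            raise DesignError("every trait factor must be measured by at least one item")
        if set(m.tolist()) != set(range(M)):
            raise DesignError("every method factor must be measured by at least one item")
        if len(set(self.item_labels)) != I:
            raise DesignError("item labels must be unique")

    @property
    def n_items(self) -> int:
        return self.trait_of_item.size

    @property
    def n_traits(self) -> int:
        return len(self.trait_labels)

    @property
    def n_methods(self) -> int:
        return len(self.method_labels)

    @property
    def n_latent(self) -> int:
        """Total latent dimensionality T + M."""
        return self.n_traits + self.n_methods

    def item_index(self, item: int | str) -> int:
        """Resolve an item given as 0-based index or label."""
        if isinstance(item, str):
            try:
                return self.item_labels.index(item)
            except ValueError:
                raise DesignError(f"unknown item label {item!r}") from None
        i = int(item)
        if not 0 <= i < self.n_items:
            raise DesignError(f"item index {i} out of range 0..{self.n_items - 1}")
        return i

    @classmethod
    def from_items(cls, items: Iterable[Mapping[str, str]]) -> "MTMMDesign":
        """Build a design from ``{"item":, "trait":, "method":}`` records.

        Factor order is the order of first appearance of each label,
        matching the layout of design files.
        """
        item_labels: list[str] = []
        trait_labels: list[str] = []
        method_labels: list[str] = []
        t_idx: list[int] = []
        m_idx: list[int] = []
        for rec in items:
            try:
                label = str(rec["item"])
                trait = str(rec["trait"])
                method = str(rec["method"])
            except KeyError as exc:
                raise DesignError(f"design record missing key {exc}") from None
            item_labels.append(label)
            if trait not in trait_labels:
                trait_labels.append(trait)
            if method not in method_labels:
                method_labels.append(method)
            t_idx.append(trait_labels.index(trait))
            m_idx.append(method_labels.index(method))
        return cls(np.array(t_idx), np.array(m_idx), tuple(item_labels),
                   tuple(trait_labels), tuple(method_labels))

    def to_items(self) -> list[dict[str, str]]:
        return [
            {"item": self.item_labels[i],
             "trait": self.trait_labels[self.trait_of_item[i]],
             "method": self.method_labels[self.method_of_item[i]]}
            for i in range(self.n_items)
        ]


def crossed_design(trait_labels: Sequence[str], method_labels: Sequence[str],
                   items_per_cell: int = 1) -> MTMMDesign:
    """Fully crossed design with ``items_per_cell`` items per trait-method cell.

    Items are ordered method-major (all traits within the first method,
    then the second method, ...), numbered ``i1, i2, ...``.
    """
    records = []
    n = 0
    for m in method_labels:
        for t in trait_labels:
            for _ in range(items_per_cell):
                n += 1
                records.append({"item": f"i{n}", "trait": t, "method": m})
    return MTMMDesign.from_items(records)


def read_design(path: str | Path) -> MTMMDesign:
    """Read a design from a YAML or JSON file.

    The file holds a list of items (optionally under an ``items:`` key),
    each with ``item``, ``trait`` and ``method`` entries.  Label order of
    first appearance defines factor order.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if isinstance(payload, Mapping):
        payload = payload.get("items", payload)
    if not isinstance(payload, list):
        raise DesignError(f"design file {path} must contain a list of items")
    return MTMMDesign.from_items(payload)


def write_design(design: MTMMDesign, path: str | Path) -> None:
    path = Path(path)
    payload = {"items": design.to_items()}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
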