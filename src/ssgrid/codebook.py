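"""Codebooks: the named categorical dimensions that span a state space.

A codebook declares, for each coded dimension (e.g., *speaker*, *verbal
behavior*), an ordered list of mutually exclusive and exhaustive category
labels. The order of the list fixes the axis order when the dimension is
mapped onto a grid axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["Dimension", "Codebook", "read_codebook", "write_codebook"]


@dataclass(frozen=True)
class Dimension:
    """One coded dimension: a name and its ordered category labels."""

    name: str
    categories: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "categories", tuple(self.categories))
        problems = []
        if not self.name:
            problems.append("dimension name must be non-empty")
        if not self.categories:
            problems.append(f"dimension {self.name!r} has no categories")
        if any(not c for c in self.categories):
            problems.append(f"dimension {self.name!r} has an empty category label")
        if len(set(self.categories)) != len(self.categories):
            problems.append(f"dimension {self.name!r} has duplicate category labels")
        if problems:
            raise ValidationError(problems)

    def index(self, label: str) -> int:
        """Position of ``label`` in the ordered category list."""
        try:
            return self.categories.index(label)
        except ValueError:
            raise ValidationError(
                f"category {label!r} not in dimension {self.name!r}"
            ) from None

    def __len__(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class Codebook:
    """An ordered collection of dimensions sharing one coding scheme.

    Storage permits two or more dimensions; grid construction
    (:func:`ssgrid.grid.make_state_space`) picks exactly two of them.
    """

    dimensions: tuple[Dimension, ...] = field(default_factory=tuple)

    def __post_init__(self):
        dims = tuple(
            d if isinstance(d, Dimension) else Dimension(*d) for d in self.dimensions
        )
        object.__setattr__(self, "dimensions", dims)
        if not dims:
            raise ValidationError("codebook must declare at least one dimension")
        names = [d.name for d in dims]
        if len(set(names)) != len(names):
            raise ValidationError("dimension names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)

    def dimension(self, name: str) -> Dimension:
        for d in self.dimensions:
            if d.name == name:
                return d
        raise ValidationError(f"unknown dimension {name!r}")

    def __len__(self) -> int:
        return len(self.dimensions)


def read_codebook(path) -> Codebook:
    """Load a codebook from a YAML or JSON file.

    Expected document shape::

        dimensions:
          - name: speaker
            categories: [A, B, C, D, E]
          - name: behavior
            categories: [KnowEx, ProbSolve, ...]
    """
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, dict) or "dimensions" not in doc:
        raise ValidationError(f"{path}: codebook file must map 'dimensions' to a list")
    dims = []
    for entry in doc["dimensions"]:
        try:
            dims.append(Dimension(entry["name"], tuple(entry["categories"])))
        except (KeyError, TypeError):
            raise ValidationError(
                f"{path}: each dimension needs 'name' and 'categories'"
            ) from None
    return Codebook(tuple(dims))


def write_codebook(codebook: Codebook, path) -> None:
    """Write a codebook as YAML (or JSON if the path ends in .json)."""
    doc = {
        "dimensions": [
            {"name": d.name, "categories": list(d.categories)}
            for d in codebook.dimensions
        ]
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
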