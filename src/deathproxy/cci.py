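"""Charlson comorbidity index (CCI) scoring from ICD-10 diagnosis codes.

The index maps ICD-10 codes into 17 comorbidity categories and sums the
original Charlson weights (1, 2, 3 or 6) of the categories present.  The
packaged mapping table follows the widely used Sundararajan ICD-10
adaptation and ships as ``data/cci_map.csv`` (one row per code prefix); an
alternate table in the same format can be loaded from file.

Matching is prefix-based, dot-insensitive and case-insensitive: ``I21.9``
matches prefix ``I21``.  A code is assigned to the category of the longest
matching prefix, so ``I25.2`` hits the specific acute-MI prefix ``I252``
rather than any shorter one.  Unmapped codes are ignored.

Three category pairs are hierarchical — diabetes without/with chronic
complications, mild vs moderate/severe liver disease, and any malignancy vs
metastatic solid tumour.  When both members of a pair are present only the
severe member is counted (standard Charlson practice; can be disabled via
``apply_hierarchy=False``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

__all__ = [
    "CharlsonCategory",
    "CCIMap",
    "load_cci_map",
    "default_cci_map",
    "charlson_categories",
    "cci_score",
]

#: (mild, severe): the severe member suppresses the mild one.
HIERARCHY_PAIRS: tuple[tuple[str, str], ...] = (
    ("diabetes_without_complications", "diabetes_with_complications"),
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("any_malignancy", "metastatic_solid_tumour"),
)

_VALID_WEIGHTS = {1, 2, 3, 6}


@dataclass(frozen=True)
class CharlsonCategory:
    name: str
    weight: int
    icd10_prefixes: tuple[str, ...]


@dataclass(frozen=True)
class CCIMap:
    categories: tuple[CharlsonCategory, ...]
    hierarchy_rules: tuple[tuple[str, str], ...] = HIERARCHY_PAIRS
    # prefix (normalised) -> (category name, weight); built once
    _prefix_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = {c.name for c in self.categories}
        for mild, severe in self.hierarchy_rules:
            if mild in names and severe not in names:
                raise ValueError(f"hierarchy pair ({mild}, {severe}) references missing category")
        for cat in self.categories:
            if cat.weight not in _VALID_WEIGHTS:
                raise ValueError(f"{cat.name}: weight {cat.weight} not in {_VALID_WEIGHTS}")
            for p in cat.icd10_prefixes:
                key = _normalise(p)
                if key in self._prefix_index:
                    raise ValueError(f"prefix {p} mapped twice")
                self._prefix_index[key] = cat.name

    @property
    def weights(self) -> dict[str, int]:
        return {c.name: c.weight for c in self.categories}

    def lookup(self, code: str) -> Optional[str]:
        """Category of the longest mapped prefix of ``code``, or None."""
        norm = _normalise(code)
        for length in range(len(norm), 0, -1):
            hit = self._prefix_index.get(norm[:length])
            if hit is not None:
                return hit
        return None


def _normalise(code: str) -> str:
    return code.replace(".", "").replace(" ", "").upper()


def load_cci_map(path_or_rows) -> CCIMap:
    """Build a :class:`CCIMap` from a ``category,weight,prefix`` CSV file
    path or an iterable of row dicts."""
    if isinstance(path_or_rows, (str, bytes)) or hasattr(path_or_rows, "__fspath__"):
        with open(path_or_rows, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    else:
        rows = list(path_or_rows)
    grouped: dict[str, tuple[int, list[str]]] = {}
    for row in rows:
        name, weight, prefix = row["category"], int(row["weight"]), row["prefix"]
        entry = grouped.setdefault(name, (weight, []))
        if entry[0] != weight:
            raise ValueError(f"category {name} has conflicting weights")
        entry[1].append(prefix)
    cats = tuple(
        CharlsonCategory(name, weight, tuple(prefixes))
        for name, (weight, prefixes) in grouped.items()
    )
    return CCIMap(categories=cats)


_DEFAULT: Optional[CCIMap] = None


def default_cci_map() -> CCIMap:
    """The packaged Sundararajan-style ICD-10 mapping with original weights."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.files("deathproxy.data").joinpath("cci_map.csv").open(
            newline="", encoding="utf-8"
        ) as fh:
            _DEFAULT = load_cci_map(csv.DictReader(fh))
    return _DEFAULT


def charlson_categories(
    codes: Iterable[str],
    cci_map: Optional[CCIMap] = None,
    apply_hierarchy: bool = True,
) -> set[str]:
    """Comorbidity categories present in a code list, after hierarchy
    suppression.  Order- and duplicate-invariant; unmapped codes ignored."""
    cci_map = cci_map or default_cci_map()
    found = {cat for cat in (cci_map.lookup(c) for c in codes) if cat is not None}
    if apply_hierarchy:
        for mild, severe in cci_map.hierarchy_rules:
            if severe in found:
                found.discard(mild)
    return found


def cci_score(
    codes: Iterable[str],
    cci_map: Optional[CCIMap] = None,
    apply_hierarchy: bool = True,
) -> int:
    """Sum of weights over the surviving categories (0 for no mapped code)."""
    cci_map = cci_map or default_cci_map()
    weights = cci_map.weights
    return sum(weights[c] for c in charlson_categories(codes, cci_map, apply_hierarchy))
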