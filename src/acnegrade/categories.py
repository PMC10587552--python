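"""Lesion taxonomy: the nine annotated facial lesion categories.

Three categories (papule, pustule, nodule/cyst) are inflammatory acne
lesions; their counts drive the severity-interval prior. The seven
acne-related categories (everything except melasma and nevus) are what the
synthetic generator produces by default.
"""

from __future__ import annotations

from dataclasses import dataclass

CATEGORIES: tuple[str, ...] = (
    "open_comedone",
    "closed_comedone",
    "papule",
    "pustule",
    "nodule_cyst",
    "atrophic_scar",
    "hypertrophic_scar",
    "melasma",
    "nevus",
)

INFLAMMATORY: frozenset[str] = frozenset({"papule", "pustule", "nodule_cyst"})

#: The seven acne-related categories (excludes the two incidental pigmented ones).
ACNE_RELATED: tuple[str, ...] = tuple(
    c for c in CATEGORIES if c not in ("melasma", "nevus")
)

CATEGORY_IDS: dict[str, int] = {name: i + 1 for i, name in enumerate(CATEGORIES)}
ID_TO_CATEGORY: dict[int, str] = {v: k for k, v in CATEGORY_IDS.items()}


@dataclass(frozen=True)
class LesionCategory:
    """One lesion category with its inflammatory flag."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in CATEGORIES:
            raise ValueError(f"unknown lesion category {self.name!r}")

    @property
    def inflammatory(self) -> bool:
        return self.name in INFLAMMATORY


def is_inflammatory(name: str) -> bool:
    if name not in CATEGORIES:
        raise ValueError(f"unknown lesion category {name!r}")
    return name in INFLAMMATORY


def zero_counts() -> dict[str, int]:
    """A counts dict with every category present and zero."""
    return {c: 0 for c in CATEGORIES}


def normalize_counts(counts: dict[str, int] | None) -> dict[str, int]:
    """Fill missing categories with 0 and validate names / non-negativity."""
    out = zero_counts()
    for name, n in (counts or {}).items():
        if name not in CATEGORIES:
            raise ValueError(f"unknown lesion category {name!r}")
        n = int(n)
        if n < 0:
            raise ValueError(f"negative count for {name!r}: {n}")
        out[name] = n
    return out
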