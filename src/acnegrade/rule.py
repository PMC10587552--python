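"""Dermatologist prior: inflammatory lesion counts -> severity grading interval.

Instead of mapping a lesion count to a single grade, the prior assigns each
image an inclusive sub-range [lo, hi] of the 8-level scale, later applied to
the classifier's probability vector as a weight mask. The rule consumes two
pooled quantities: I = papule + pustule count, and N = nodule/cyst count.
Deeper lesions dominate: any nodule/cyst forces the upper intervals
regardless of the superficial inflammatory count.

The default threshold table below is this package's own calibration, modeled
on lesion-counting grading conventions (counting scales bin inflammatory
lesion totals into severity bands); it is fully overrideable via YAML. Rows
are matched first-to-last, first match wins, and a table must be exhaustive
over all count vectors to load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .categories import normalize_counts
from .errors import ConfigError, InvalidMaskError
from .scale import N_GRADES

_INF = math.inf


@dataclass(frozen=True, order=True)
class GradingInterval:
    """Inclusive grade interval [lo, hi] on the 8-level scale."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi <= N_GRADES):
            raise ConfigError(f"invalid interval [{self.lo}, {self.hi}]")

    def __contains__(self, grade: int) -> bool:
        return self.lo <= grade <= self.hi

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1

    @property
    def midpoint(self) -> int:
        # round-half-down midpoint: (1+2)/2 -> 1
        return (self.lo + self.hi) // 2

    @property
    def key(self) -> str:
        """Stable id used to index learnable interval weights."""
        return f"{self.lo}-{self.hi}"


@dataclass(frozen=True)
class RuleRow:
    """Predicate on (I, N) counts mapped to an interval; bounds inclusive."""

    i_min: float = 0
    i_max: float = _INF
    n_min: float = 0
    n_max: float = _INF
    interval: GradingInterval = GradingInterval(1, N_GRADES)

    def matches(self, i_count: int, n_count: int) -> bool:
        return (self.i_min <= i_count <= self.i_max) and (
            self.n_min <= n_count <= self.n_max
        )


#: Default table. I = papule + pustule, N = nodule/cyst; first match wins.
DEFAULT_RULE_ROWS: tuple[RuleRow, ...] = (
    RuleRow(n_min=2, interval=GradingInterval(6, 8)),
    RuleRow(n_min=1, n_max=1, interval=GradingInterval(5, 7)),
    RuleRow(i_min=30, interval=GradingInterval(5, 6)),
    RuleRow(i_min=15, i_max=29, interval=GradingInterval(4, 5)),
    RuleRow(i_min=5, i_max=14, interval=GradingInterval(3, 4)),
    RuleRow(i_min=1, i_max=4, interval=GradingInterval(2, 3)),
    RuleRow(i_min=0, i_max=0, interval=GradingInterval(1, 2)),
)


class GradingRuleConfig:
    """Ordered, exhaustive first-match-wins rule table.

    Exhaustiveness is validated at construction by sweeping (I, N) over a
    grid that covers every finite threshold in the table plus an
    above-all-thresholds sentinel, which is sufficient because row
    predicates are axis-aligned boxes in (I, N).
    """

    def __init__(self, rows=DEFAULT_RULE_ROWS):
        self.rows: tuple[RuleRow, ...] = tuple(rows)
        if not self.rows:
            raise ConfigError("rule table is empty")
        self._validate_exhaustive()

    def _validate_exhaustive(self) -> None:
        def probes(bounds):
            pts = {0}
            for b in bounds:
                if math.isfinite(b):
                    b = int(b)
                    pts.update({max(0, b - 1), b, b + 1})
            pts.add(max(pts) + 10)  # above-all sentinel
            return sorted(pts)

        i_probes = probes([v for r in self.rows for v in (r.i_min, r.i_max)])
        n_probes = probes([v for r in self.rows for v in (r.n_min, r.n_max)])
        for i in i_probes:
            for n in n_probes:
                if not any(r.matches(i, n) for r in self.rows):
                    raise ConfigError(
                        f"rule table not exhaustive: no row matches I={i}, N={n}"
                    )

    def lookup(self, i_count: int, n_count: int) -> GradingInterval:
        for row in self.rows:
            if row.matches(i_count, n_count):
                return row.interval
        raise ConfigError(  # pragma: no cover - excluded by validation
            f"no rule row matches I={i_count}, N={n_count}"
        )

    def distinct_intervals(self) -> list[GradingInterval]:
        """Distinct intervals in table order (stable ids for learnable weights)."""
        seen: dict[str, GradingInterval] = {}
        for row in self.rows:
            seen.setdefault(row.interval.key, row.interval)
        return list(seen.values())

    # -- YAML round trip -------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "GradingRuleConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "rules" not in data:
            raise ConfigError("rule YAML must contain a top-level 'rules' list")
        rows = []
        for entry in data["rules"]:
            when = entry.get("when", {})
            lo, hi = entry["interval"]
            rows.append(
                RuleRow(
                    i_min=when.get("I_min", 0),
                    i_max=when.get("I_max", _INF),
                    n_min=when.get("N_min", 0),
                    n_max=when.get("N_max", _INF),
                    interval=GradingInterval(int(lo), int(hi)),
                )
            )
        return cls(rows)

    def to_yaml(self, path) -> None:
        def bound(v):
            return int(v) if math.isfinite(v) else None

        entries = []
        for r in self.rows:
            when = {}
            for k, v in (
                ("I_min", r.i_min),
                ("I_max", r.i_max),
                ("N_min", r.n_min),
                ("N_max", r.n_max),
            ):
                b = bound(v)
                if b is not None and not (b == 0 and k.endswith("_min")):
                    when[k] = b
            entries.append({"when": when, "interval": [r.interval.lo, r.interval.hi]})
        with open(path, "w") as fh:
            yaml.safe_dump({"rules": entries}, fh, sort_keys=False)

    def table_hash(self) -> str:
        import hashlib

        text = repr([(r.i_min, r.i_max, r.n_min, r.n_max, r.interval.lo, r.interval.hi) for r in self.rows])
        return hashlib.sha256(text.encode()).hexdigest()[:16]


DEFAULT_RULE = GradingRuleConfig()


def inflammatory_pool(counts: dict[str, int]) -> tuple[int, int]:
    """(I, N) = (papule + pustule, nodule/cyst) pooled counts."""
    c = normalize_counts(counts)
    return c["papule"] + c["pustule"], c["nodule_cyst"]


def counts_to_interval(
    counts: dict[str, int], rule: GradingRuleConfig = DEFAULT_RULE
) -> GradingInterval:
    """Map per-category lesion counts to a severity grading interval."""
    i_count, n_count = inflammatory_pool(counts)
    return rule.lookup(i_count, n_count)


def interval_mask(interval: GradingInterval) -> np.ndarray:
    """Binary 8-vector: 1 inside [lo, hi], 0 outside."""
    m = np.zeros(N_GRADES, dtype=float)
    m[interval.lo - 1 : interval.hi] = 1.0
    return m


def mask_to_interval(mask: np.ndarray) -> GradingInterval:
    """Reconstruct the interval from a contiguous binary mask."""
    idx = np.flatnonzero(np.asarray(mask) > 0)
    if idx.size == 0:
        raise InvalidMaskError("mask has no admissible grade")
    lo, hi = int(idx[0]) + 1, int(idx[-1]) + 1
    if idx.size != hi - lo + 1:
        raise InvalidMaskError("mask support is not contiguous")
    return GradingInterval(lo, hi)
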