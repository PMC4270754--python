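"""Declarative GUM-style uncertainty budget with quadrature combination.

Every component is a relative standard uncertainty (%) of the final dose to
water, carried with a unit sensitivity coefficient; Type A (statistical) and
Type B (other) columns of one entry contribute independently.  The combined
standard uncertainty is the root sum of squares over all components and the
expanded uncertainty is the coverage factor k times the combined value.

Reporting convention: the combined value is rounded half-up to two decimals
and the expanded row is quoted as k times that rounded value, matching how
such budget tables are conventionally typeset (internal arithmetic keeps full
precision; :func:`expand` is exact).
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

__all__ = [
    "BudgetEntry",
    "Budget",
    "CombinedUncertainty",
    "combine",
    "expand",
    "inject_type_a",
    "load_budget",
]


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BudgetEntry:
    """One uncertainty source; at least one of the A/B components present."""

    label: str
    group: str = ""
    type_a_percent: float | None = None
    type_b_percent: float | None = None
    reference: str = ""

    def __post_init__(self) -> None:
        if self.type_a_percent is None and self.type_b_percent is None:
            raise ValueError(f"entry {self.label!r}: at least one of Type A/B required")
        for v in (self.type_a_percent, self.type_b_percent):
            if v is not None and v < 0:
                raise ValueError(f"entry {self.label!r}: components must be >= 0")

    @property
    def sum_of_squares(self) -> float:
        return (self.type_a_percent or 0.0) ** 2 + (self.type_b_percent or 0.0) ** 2


@dataclass(frozen=True)
class Budget:
    """An ordered set of uniquely labelled budget entries."""

    entries: tuple[BudgetEntry, ...]
    coverage_k: float = 1.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("budget must contain at least one entry")
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("budget entry labels must be unique")
        if not self.coverage_k > 0:
            raise ValueError("coverage_k must be > 0")
        object.__setattr__(self, "entries", tuple(self.entries))

    def __getitem__(self, label: str) -> BudgetEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)


@dataclass(frozen=True)
class CombinedUncertainty:
    """Combined (k=1) and expanded relative uncertainties plus contributions."""

    combined_percent: float
    k: float
    per_entry: dict[str, float] = field(repr=False)  # label -> squared contribution, %^2

    @property
    def expanded_percent(self) -> float:
        return self.k * self.combined_percent

    def report(self, ndigits: int = 2, k: float | None = None) -> tuple[float, float]:
        """(combined, expanded) as typeset: expanded = k * rounded combined."""
        k = self.k if k is None else k
        if not k > 0:
            raise ValueError(f"coverage factor must be > 0, got {k}")
        combined = _round_half_up(self.combined_percent, ndigits)
        return combined, _round_half_up(k * combined, ndigits)


def combine(budget: Budget) -> CombinedUncertainty:
    """Root-sum-of-squares over all entries' Type A and Type B components."""
    per_entry = {e.label: e.sum_of_squares for e in budget.entries}
    combined = math.sqrt(sum(per_entry.values()))
    return CombinedUncertainty(combined_percent=combined, k=budget.coverage_k, per_entry=per_entry)


def expand(cu: CombinedUncertainty, k: float) -> float:
    """Exact expanded uncertainty k * combined (%); k must be positive."""
    if not k > 0:
        raise ValueError(f"coverage factor must be > 0, got {k}")
    return k * cu.combined_percent


def inject_type_a(budget: Budget, label: str, percent: float) -> Budget:
    """A copy of the budget with one entry's Type A component replaced.

    Lets a measured replicate repeatability stand in for the nominal value
    of, e.g., the dose-determination row.  The original budget is unchanged.
    """
    if percent < 0:
        raise ValueError("Type A component must be >= 0")
    labels = [e.label for e in budget.entries]
    if label not in labels:
        raise ValueError(f"unknown budget entry {label!r}; have {labels}")
    new_entries = tuple(
        replace(e, type_a_percent=percent) if e.label == label else e
        for e in budget.entries
    )
    return replace(budget, entries=new_entries)


def load_budget(path: str | Path | None = None) -> Budget:
    """Load a budget from a TOML file; with no path, the packaged default."""
    if path is None:
        from importlib import resources

        raw = (resources.files("frickedose") / "data" / "default_budget.toml").read_bytes()
        data = tomllib.loads(raw.decode())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    entries = tuple(
        BudgetEntry(
            label=e["label"],
            group=e.get("group", ""),
            type_a_percent=e.get("type_a"),
            type_b_percent=e.get("type_b"),
            reference=e.get("reference", ""),
        )
        for e in data["entry"]
    )
    return Budget(entries=entries, coverage_k=float(data.get("coverage_k", 1.0)))
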