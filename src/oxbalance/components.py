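"""Declarative component roster for the oxidative balance score (OBS).

The OBS sums 22 component scores, each in {0, 1, 2}.  A component is either
*dietary* (17 of them) or *lifestyle* (5), and either an *antioxidant*
(higher intake scores higher) or a *pro-oxidant* (higher intake scores
lower).  Most components are scored against sex-stratified tertile
cut-points; smoking, alcohol and meat use the abstention rule, where
non-consumption earns the maximal score of 2 and consumers are split at the
consumer median.

The default roster ships as ``data/components.yaml`` and can be replaced by
a user file of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

CATEGORIES = ("dietary", "lifestyle")
POLARITIES = ("antioxidant", "prooxidant")
RULES = ("tertile", "abstention_binary")
COMBINES = ("identity", "sum")

#: components for which the abstention rule is permitted in the default roster
ABSTENTION_COMPONENTS = ("smoking", "alcohol", "meat")


class RosterError(ValueError):
    """Invalid component specification or roster."""


@dataclass(frozen=True)
class ComponentSpec:
    """One OBS component: what it is made of and how it is scored."""

    name: str
    category: str
    polarity: str
    rule: str
    source_columns: tuple[str, ...]
    combine: str = "identity"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RosterError(f"{self.name}: unknown category {self.category!r}")
        if self.polarity not in POLARITIES:
            raise RosterError(f"{self.name}: unknown polarity {self.polarity!r}")
        if self.rule not in RULES:
            raise RosterError(f"{self.name}: unknown rule {self.rule!r}")
        if self.combine not in COMBINES:
            raise RosterError(f"{self.name}: unknown combine {self.combine!r}")
        if not self.source_columns:
            raise RosterError(f"{self.name}: no source columns")
        if self.combine == "identity" and len(self.source_columns) != 1:
            raise RosterError(
                f"{self.name}: identity components take exactly one source column"
            )
        object.__setattr__(self, "source_columns", tuple(self.source_columns))

    @property
    def column(self) -> str:
        """Name of the cohort column holding this component's raw value."""
        if self.combine == "sum":
            return self.name
        return self.source_columns[0]

    @property
    def score_column(self) -> str:
        return f"score_{self.name}"


def validate_roster(specs: list[ComponentSpec]) -> None:
    """Check roster-level invariants (uniqueness, abstention whitelist)."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise RosterError("duplicate component names in roster")
    for s in specs:
        if s.rule == "abstention_binary" and s.name not in ABSTENTION_COMPONENTS:
            raise RosterError(
                f"{s.name}: abstention rule only permitted for "
                f"{ABSTENTION_COMPONENTS}"
            )


def load_components(path: str | Path | None = None) -> list[ComponentSpec]:
    """Load a component roster from YAML (default: packaged 22-item roster)."""
    if path is None:
        text = (
            resources.files("oxbalance").joinpath("data/components.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    specs = [
        ComponentSpec(
            name=item["name"],
            category=item["category"],
            polarity=item["polarity"],
            rule=item["rule"],
            source_columns=tuple(item["source_columns"]),
            combine=item.get("combine", "identity"),
        )
        for item in raw["components"]
    ]
    validate_roster(specs)
    return specs


def default_components() -> list[ComponentSpec]:
    """The packaged 22-component roster."""
    return load_components(None)


def dietary_components(specs: list[ComponentSpec]) -> list[ComponentSpec]:
    return [s for s in specs if s.category == "dietary"]


def lifestyle_components(specs: list[ComponentSpec]) -> list[ComponentSpec]:
    return [s for s in specs if s.category == "lifestyle"]
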