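"""Immune phenotype rules: named positive/negative marker combinations.

Each rule lists the markers a cell must be positive for and the markers it
must be negative for. The default rule set covers the common immune
populations recoverable from a CD45-anchored panel: T-cell subsets, NK
cells, B cells, neutrophils, macrophages and dendritic cells, with a
generic "Immune cells" (CD45+ CK56-) fallback. Rules are evaluated most
specific first; the first match wins; cells that are not CD45+ stay
"unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Sequence

import yaml

from .errors import ConfigurationError

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PhenotypeRule:
    name: str
    positive_markers: FrozenSet[str]
    negative_markers: FrozenSet[str]

    def __post_init__(self):
        object.__setattr__(self, "positive_markers",
                           frozenset(self.positive_markers))
        object.__setattr__(self, "negative_markers",
                           frozenset(self.negative_markers))
        if self.positive_markers & self.negative_markers:
            raise ConfigurationError(
                f"rule {self.name!r}: positive and negative sets overlap"
            )

    @property
    def markers(self) -> FrozenSet[str]:
        return self.positive_markers | self.negative_markers

    def matches(self, positive: Iterable[str]) -> bool:
        pos = set(positive)
        return (self.positive_markers <= pos
                and not (self.negative_markers & pos))


def default_rules() -> List[PhenotypeRule]:
    """The standard immune gating table, most specific rules first."""
    r = PhenotypeRule
    return [
        r("CD4+ T cells", {"CD45", "CD3", "CD4"}, {"CD11b"}),
        r("CD8+ T cells", {"CD45", "CD3", "CD8"}, {"CD11b"}),
        r("Natural killer cells", {"CD45", "CD56"}, {"CD3", "CD11b"}),
        r("B cells", {"CD45", "CD20"}, {"CD3", "CD11b"}),
        r("Neutrophils", {"CD45", "CD11b", "CD66b"}, {"CD3"}),
        r("Macrophages", {"CD45", "CD11b", "CD68"}, {"CD3"}),
        r("Dendritic cells", {"CD45", "CD11b", "CD11c"}, {"CD3"}),
        r("Immune cells", {"CD45"}, {"CK56"}),
    ]


def rules_by_name(rules: Sequence[PhenotypeRule]) -> dict:
    return {r.name: r for r in rules}


def load_rules(path) -> List[PhenotypeRule]:
    """Load rules from YAML: a list of {name, positive, negative} entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        PhenotypeRule(e["name"], set(e.get("positive", [])),
                      set(e.get("negative", [])))
        for e in raw
    ]


def save_rules(rules: Sequence[PhenotypeRule], path) -> None:
    raw = [
        {"name": r.name,
         "positive": sorted(r.positive_markers),
         "negative": sorted(r.negative_markers)}
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
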