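"""Sphingolipid species panels.

A panel is the list of measured species with their class membership
(dihydroceramides DCER, ceramides CER, sphingomyelins SM, hexosylceramides
HCER, lactosylceramides LCER) and acyl-chain annotation. Species identifiers
follow the ``<CLASS><carbons>[:<double bonds>]`` convention, e.g. ``CER18``,
``DCER22:2``, ``LCER24:1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

CLASSES = ("DCER", "CER", "SM", "HCER", "LCER")

# Classes retained for network / ratio analyses (sphingomyelins show no
# group differences and are dropped after the volcano screen).
CERAMIDE_CLASSES = ("DCER", "CER", "HCER", "LCER")

_SPECIES_RE = re.compile(r"^(DCER|HCER|LCER|CER|SM)(\d+)(?::(\d+))?$")


@dataclass(frozen=True)
class Species:
    """One measured lipid species."""

    species_id: str
    class_id: str
    chain_carbons: int
    double_bonds: int = 0

    def __post_init__(self) -> None:
        if self.class_id not in CLASSES:
            raise ValueError(f"unknown lipid class {self.class_id!r}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")


def parse_species_id(species_id: str) -> Species:
    """Parse ``CER18`` / ``DCER22:2`` style identifiers into a Species."""
    m = _SPECIES_RE.match(species_id)
    if m is None:
        raise ValueError(f"cannot parse species id {species_id!r}")
    cls, carbons, dbl = m.groups()
    return Species(species_id, cls, int(carbons), int(dbl) if dbl else 0)


@dataclass(frozen=True)
class SpeciesPanel:
    """Ordered collection of unique species spanning one or more classes."""

    entries: tuple[Species, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dupes}")
        if not self.entries:
            raise ValueError("panel must contain at least one species")

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.entries]

    @property
    def class_map(self) -> dict[str, str]:
        return {s.species_id: s.class_id for s in self.entries}

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for s in self.entries:
            if s.class_id not in seen:
                seen.append(s.class_id)
        return seen

    def by_class(self, class_id: str) -> list[str]:
        return [s.species_id for s in self.entries if s.class_id == class_id]

    def subset(self, classes: tuple[str, ...]) -> "SpeciesPanel":
        return SpeciesPanel(tuple(s for s in self.entries if s.class_id in classes))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


_DEFAULT_IDS = {
    # 4 dihydroceramide, 8 ceramide, 7 hexosylceramide, 7 lactosylceramide
    # species; the named ones are those singled out in the analyses, the rest
    # fill plausible acyl-chain lengths.
    "DCER": ["DCER18", "DCER22", "DCER22:2", "DCER24:1"],
    "CER": ["CER16", "CER18", "CER20", "CER22", "CER22:1", "CER24", "CER24:1", "CER26"],
    "HCER": ["HCER16", "HCER18", "HCER20", "HCER22", "HCER22:1", "HCER24", "HCER24:1"],
    "LCER": ["LCER14", "LCER16", "LCER18", "LCER18:1", "LCER22", "LCER24", "LCER24:1"],
}


def default_species_panel(n_sm: int = 8) -> SpeciesPanel:
    """Default serum sphingolipid panel.

    4 DCER + 8 CER + 7 HCER + 7 LCER species plus ``n_sm`` sphingomyelins.

    Parameters
    ----------
    n_sm : number of sphingomyelin species (set 0 to omit the class, as in
        the post-volcano analyses that focus on ceramides and
        glycosphingolipids).
    """
    if n_sm < 0:
        raise ValueError("n_sm must be >= 0")
    entries = [parse_species_id(sid) for ids in _DEFAULT_IDS.values() for sid in ids]
    sm_chains = [14, 16, 18, 20, 22, 24, 26, 28]
    sm_ids = [f"SM{sm_chains[i % 8]}" if i < 8 else f"SM{30 + 2 * (i - 8)}" for i in range(n_sm)]
    entries.extend(parse_species_id(sid) for sid in sm_ids)
    return SpeciesPanel(tuple(entries))
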