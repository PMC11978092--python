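"""Gene-set collections and GMT I/O.

A :class:`GeneSetCollection` carries named gene sets together with a gene
universe. The universe defines the within/outside partition used by the
pathway-difference statistics: for a set ``P`` the genes tested "within" are
``P ∩ universe`` and the genes tested "outside" are ``universe \\ P``.

GMT is the standard tab-separated carrier for gene-set collections
(set name, description, then one gene per column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class GmtParseError(ValueError):
    """Raised when a GMT file is malformed."""


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against.

    Parameters
    ----------
    sets
        Mapping of set name to ordered gene list. Insertion order is the
        column order of downstream feature matrices.
    universe
        Ordered list of all gene identifiers considered. Defaults to the
        union of all set members in first-seen order.
    descriptions
        Optional mapping of set name to the GMT description field.
    """

    sets: dict[str, list[str]]
    universe: list[str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise GmtParseError("no gene sets")
        if self.universe is None:
            seen: dict[str, None] = {}
            for genes in self.sets.values():
                for g in genes:
                    seen.setdefault(g)
            self.universe = list(seen)
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("duplicate genes in universe")
        self._universe_set = frozenset(self.universe)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def within(self, name: str) -> list[str]:
        """Genes of ``name`` that resolve in the universe (within side)."""
        return [g for g in self.sets[name] if g in self._universe_set]

    def outside(self, name: str) -> list[str]:
        """Universe genes not in set ``name`` (outside side)."""
        members = set(self.sets[name])
        return [g for g in self.universe if g not in members]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.universe == other.universe


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each line must carry ``name<TAB>description<TAB>gene[<TAB>gene...]``.
    Set order follows file order. Unless an explicit ``universe`` is given,
    the universe is the union of all set members.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected name, description and at "
                    f"least one gene, got {len(fields)} field(s)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise GmtParseError(f"{path.name}:{lineno}: set {name!r} has no genes")
            if name in sets:
                raise GmtParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = description
    if not sets:
        raise GmtParseError(f"{path.name}: no gene sets")
    return GeneSetCollection(
        sets, universe=list(universe) if universe is not None else None,
        descriptions=descriptions,
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT, preserving set order."""
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
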