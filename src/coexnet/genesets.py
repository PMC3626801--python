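"""Gene-set collections (GMT format) and gene-symbol canonicalization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


def canonical_symbol(symbol: str) -> str:
    """Canonical gene symbol: stripped of surrounding whitespace, upper-case."""
    return str(symbol).strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene categories, each tagged with an annotation source.

    ``categories`` maps a category name to a frozenset of canonical gene
    symbols; ``sources`` maps each category to the annotation source it came
    from (e.g. "GO", "KEGG", "SwissProt", "celltype").  Categories from the
    same source share a population universe during enrichment.
    """

    categories: dict[str, frozenset] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset] = {}
        for name, genes in self.categories.items():
            genes = frozenset(canonical_symbol(g) for g in genes)
            if not genes:
                raise ValueError(f"category {name!r} is empty")
            clean[name] = genes
        self.categories = clean
        for name in self.categories:
            self.sources.setdefault(name, "default")

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    def source_universe(self, source: str) -> frozenset:
        """Union of all genes annotated by any category of ``source``."""
        out: set = set()
        for name, genes in self.categories.items():
            if self.sources[name] == source:
                out |= genes
        return frozenset(out)

    def by_source(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name in self.categories:
            out.setdefault(self.sources[name], []).append(name)
        return out

    @classmethod
    def from_dict(
        cls, categories: Mapping[str, Iterable[str]], source: str = "default"
    ) -> "GeneSetCollection":
        return cls(
            categories={k: frozenset(v) for k, v in categories.items()},
            sources={k: source for k in categories},
        )


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> gene1 <tab> gene2 ...).

    The description field doubles as the source tag unless ``source`` is
    given explicitly.
    """
    categories: dict[str, frozenset] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, description = parts[0], parts[1]
            genes = frozenset(canonical_symbol(g) for g in parts[2:] if g.strip())
            if not genes:
                raise ValueError(f"GMT category {name!r} has no genes")
            categories[name] = genes
            sources[name] = source or (description or "default")
    if not categories:
        raise ValueError(f"no categories found in {path}")
    return GeneSetCollection(categories=categories, sources=sources)


def write_gmt(sets: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(sets.categories):
            genes = sorted(sets.categories[name])
            fh.write("\t".join([name, sets.sources[name], *genes]) + "\n")
    return path
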