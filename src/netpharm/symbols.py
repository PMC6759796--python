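"""Gene-symbol normalization and named target sets.

Databases and publications are inconsistent about hyphenation and case
("IL-6" vs "IL6", "vegfa" vs "VEGFA").  All set arithmetic in this
package runs on a single normalized form: uppercase, hyphens stripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def normalize_symbol(raw: str) -> str:
    """Canonicalize a gene/protein symbol.

    Uppercases, strips surrounding whitespace and removes hyphens, so
    that "IL-6", " il6 " and "IL6" all map to "IL6".  Idempotent.

    Raises
    ------
    ValueError
        If the input is empty (or whitespace/hyphens only).
    """
    if not isinstance(raw, str):
        raise TypeError(f"symbol must be a string, got {type(raw).__name__}")
    out = raw.strip().upper().replace("-", "")
    if not out:
        raise ValueError(f"empty gene symbol: {raw!r}")
    return out


def normalize_symbols(symbols) -> frozenset[str]:
    """Normalize an iterable of symbols into a deduplicated frozenset."""
    return frozenset(normalize_symbol(s) for s in symbols)


@dataclass(frozen=True)
class TargetSet:
    """A named, normalized set of gene/protein symbols.

    Parameters
    ----------
    name : short label ("compound-union", "disease", ...)
    symbols : set of symbols; normalized on construction
    provenance : free-text source tag (database, file, "intersection", ...)
    """

    name: str
    symbols: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", normalize_symbols(self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols

    def __iter__(self):
        return iter(sorted(self.symbols))

    def intersect(self, other: "TargetSet", name: str | None = None) -> "TargetSet":
        return TargetSet(
            name=name or f"{self.name}&{other.name}",
            symbols=self.symbols & other.symbols,
            provenance="intersection",
        )
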