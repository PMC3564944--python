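"""Gene-alias table: many equivalent nomenclatures -> one canonical gene id.

The table is a TSV with columns ``gene_id``, ``namespace``, ``alias``;
namespaces follow the usual fly sources (FlyBase, RefSeq, Entrez, symbol,
CG).  Lookup is case-insensitive across all namespaces.
"""

from __future__ import annotations

import difflib
from typing import IO

from ..errors import AliasLookupError, AmbiguousAliasError, FormatError

NAMESPACES = ("FlyBase", "RefSeq", "Entrez", "symbol", "CG")


class AliasTable:
    def __init__(self) -> None:
        # lower-cased alias -> set of canonical gene ids
        self._index: dict[str, set[str]] = {}
        self.canonical: set[str] = set()

    def add(self, gene_id: str, namespace: str, alias: str) -> None:
        self.canonical.add(gene_id)
        self._index.setdefault(alias.lower(), set()).add(gene_id)

    def resolve(self, alias: str) -> str:
        if not alias:
            raise AliasLookupError("empty alias")
        if alias in self.canonical:
            return alias
        hits = self._index.get(alias.lower(), set())
        if not hits:
            near = difflib.get_close_matches(alias.lower(), self._index, n=3)
            hint = f" (near misses: {', '.join(near)})" if near else ""
            raise AliasLookupError(f"unknown gene alias {alias!r}{hint}")
        if len(hits) > 1:
            raise AmbiguousAliasError(
                f"alias {alias!r} maps to several genes: {sorted(hits)}")
        return next(iter(hits))


def read_alias_table(stream: IO[str]) -> AliasTable:
    table = AliasTable()
    for ln, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise FormatError(f"expected 3 TSV columns, got {len(cols)}", ln)
        gene_id, namespace, alias = cols
        table.add(gene_id, namespace, alias)
    return table
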