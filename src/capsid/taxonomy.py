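"""Rank-annotated taxonomy in the NCBI dump dialect.

Loads ``nodes.dmp``/``names.dmp``-style pipe-delimited files into a
parent-pointer tree over integer taxon ids and answers the ancestry, lineage
and rank-walk queries the classifier needs. Merged/deleted-taxid remapping
files are not supported; inputs must be pre-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

#: Default rank ladder, leaf-most first. Ranks absent from the ladder (NCBI
#: "no rank" clades, strain-level leaves, ...) are transparent during
#: rank-wise walks so they cannot stall an LCA ascent.
DEFAULT_RANKS: tuple[str, ...] = (
    "subspecies",
    "species",
    "subgenus",
    "genus",
    "subfamily",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
)


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str = ""


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxonomyTree:
    """Parent-pointer taxonomy; the root is its own parent."""

    nodes: dict[int, TaxonNode]
    root: int
    ranks: tuple[str, ...] = DEFAULT_RANKS
    _lineage_cache: dict[int, tuple[int, ...]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def lineage(self, taxid: int) -> list[int]:
        """Path root → taxid (inclusive both ends)."""
        cached = self._lineage_cache.get(taxid)
        if cached is None:
            path = []
            t = self.node(taxid).taxid
            while True:
                path.append(t)
                parent = self.node(t).parent
                if parent == t:
                    break
                t = parent
            cached = tuple(reversed(path))
            self._lineage_cache[taxid] = cached
        return list(cached)

    def is_descendant(self, child: int, ancestor: int) -> bool:
        """True iff ancestor lies on lineage(child); reflexive."""
        self.node(ancestor)
        return ancestor in self.lineage(child)

    def lca_pair(self, a: int, b: int) -> int:
        """Deepest node on both lineages."""
        la, lb = self.lineage(a), self.lineage(b)
        lca = la[0]
        for x, y in zip(la, lb):
            if x != y:
                break
            lca = x
        return lca

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Ancestor-or-self of taxid carrying exactly the given rank."""
        for t in reversed(self.lineage(taxid)):
            if self.nodes[t].rank == rank:
                return t
        return None

    def name_of(self, taxid: int) -> str:
        return self.node(taxid).name or str(taxid)


def _split_dump_line(line: str) -> list[str]:
    # NCBI dumps use "\t|\t" separators with a trailing "\t|"; be liberal and
    # also accept bare "|".
    line = line.rstrip("\n").rstrip()
    if line.endswith("|"):
        line = line[:-1]
    return [f.strip("\t ") for f in line.split("|")]


def load_taxonomy(
    nodes_path: str | Path,
    names_path: str | Path | None = None,
    ranks: tuple[str, ...] = DEFAULT_RANKS,
) -> TaxonomyTree:
    """Load a taxonomy from NCBI-dialect nodes/names dump files.

    Raises
    ------
    TaxonomyError
        On an orphan parent (referenced but absent) or a parent-pointer cycle.
    """
    raw: dict[int, tuple[int, str]] = {}
    with open(nodes_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = _split_dump_line(line)
            if len(fields) < 3:
                raise TaxonomyError(f"nodes line {ln}: expected taxid|parent|rank")
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise TaxonomyError(f"nodes line {ln}: non-numeric taxid") from exc
            rank = fields[2] or "no rank"
            raw[taxid] = (parent, rank)

    names: dict[int, str] = {}
    if names_path is not None:
        with open(names_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _split_dump_line(line)
                if len(fields) >= 4 and fields[3] != "scientific name":
                    continue
                try:
                    taxid = int(fields[0])
                except ValueError:
                    continue
                names.setdefault(taxid, fields[1])

    nodes: dict[int, TaxonNode] = {}
    root: int | None = None
    for taxid, (parent, rank) in raw.items():
        if parent not in raw:
            raise TaxonomyError(f"orphan parent {parent} (referenced by taxid {taxid})")
        if parent == taxid:
            if root is not None and root != taxid:
                raise TaxonomyError(f"multiple roots: {root} and {taxid}")
            root = taxid
        nodes[taxid] = TaxonNode(taxid, parent, rank, names.get(taxid, ""))
    if root is None:
        raise TaxonomyError("no root node (self-parented) found")

    # Cycle check: every node must reach the root.
    reaches_root: set[int] = {root}
    for taxid in nodes:
        seen: list[int] = []
        t = taxid
        while t not in reaches_root:
            if t in seen:
                raise TaxonomyError(f"cycle detected through taxid {t}")
            seen.append(t)
            t = nodes[t].parent
        reaches_root.update(seen)

    return TaxonomyTree(nodes=nodes, root=root, ranks=ranks)


def write_taxonomy(
    tree_nodes: dict[int, tuple[int, str, str]],
    nodes_path: str | Path,
    names_path: str | Path,
) -> None:
    """Write {taxid: (parent, rank, name)} in the dump dialect (fixture aid)."""
    with open(nodes_path, "w") as fh:
        for taxid in sorted(tree_nodes):
            parent, rank, _ = tree_nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid in sorted(tree_nodes):
            _, _, name = tree_nodes[taxid]
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
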