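"""Network ingestion and grouped reference-network sets.

Networks are undirected, unweighted gene graphs: the merge and scoring
arithmetic of the fingerprint method is defined on unordered node sets, so
edge directions from directed sources (KGML relations, directed GraphML)
are discarded on read.  Node identity is exact string match of gene
identifiers; no identifier mapping is attempted.

A :class:`ReferenceNetworkSet` holds an *ordered* list of (group, name,
network) entries — the order is the coordinate system of the fingerprint
vector, so it is preserved exactly by loading and subsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

log = logging.getLogger(__name__)

FORMATS = ("edgelist", "graphml", "kgml")

_EXTENSION_FORMAT = {
    ".txt": "edgelist",
    ".tsv": "edgelist",
    ".edgelist": "edgelist",
    ".el": "edgelist",
    ".graphml": "graphml",
    ".xml": "kgml",
    ".kgml": "kgml",
}


@dataclass
class BioNetwork:
    """Named undirected gene network (no self-loops, no duplicate edges)."""

    name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "BioNetwork":
        """Build a network, silently deduplicating and dropping self-loops
        (counts are logged).  ``nodes`` may add isolated nodes."""
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        n_self = 0
        n_in = 0
        for u, v in edges:
            n_in += 1
            u, v = str(u), str(v)
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
        n_dup = n_in - n_self - g.number_of_edges()
        if n_self or n_dup:
            log.info(
                "network %s: dropped %d self-loop(s) and %d duplicate edge(s)",
                name, n_self, n_dup,
            )
        return cls(name=name, graph=g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_sequence(self) -> tuple[int, ...]:
        return tuple(sorted(d for _, d in self.graph.degree))

    def copy(self, name: str | None = None) -> "BioNetwork":
        return BioNetwork(name=name or self.name, graph=self.graph.copy())

    def same_topology(self, other: "BioNetwork") -> bool:
        return self.nodes == other.nodes and self.edges == other.edges


def _infer_format(path: Path) -> str:
    fmt = _EXTENSION_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer network format from extension of {path}")
    return fmt


def read_network(
    path,
    format: str | None = None,
    name: str | None = None,
    expand_entry_cliques: bool = True,
) -> BioNetwork:
    """Read a network file (``edgelist``, ``graphml`` or ``kgml``).

    Edge lists are two whitespace-separated node columns with ``#``
    comments.  KGML parsing keeps gene-type entries only; an entry naming
    several genes is expanded to individual nodes, connected as a clique
    when ``expand_entry_cliques`` (complex-expansion convention, see docs).
    Directions are always discarded; self-loops and duplicates are dropped
    with a logged count.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    net_name = name or path.stem
    if fmt == "edgelist":
        net = _read_edgelist(path, net_name)
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        net = BioNetwork.from_edges(
            net_name,
            ((str(u), str(v)) for u, v in g.edges()),
            nodes=(str(n) for n in g.nodes()),
        )
    else:
        net = _read_kgml(path, net_name, expand_entry_cliques)
    if net.n_nodes == 0:
        raise ValueError(f"empty network in {path}")
    return net


def _read_edgelist(path: Path, name: str) -> BioNetwork:
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) == 1:
                isolated.append(cols[0])
            elif len(cols) >= 2:
                edges.append((cols[0], cols[1]))
            else:  # pragma: no cover - split() never yields 0 tokens here
                raise ValueError(f"{path}:{lineno}: malformed edge line")
    return BioNetwork.from_edges(name, edges, nodes=isolated)


def _read_kgml(path: Path, name: str, expand_entry_cliques: bool) -> BioNetwork:
    from Bio.KEGG.KGML import KGML_parser

    with open(path) as fh:
        pathway = KGML_parser.read(fh)
    entry_genes: dict[str, list[str]] = {}
    for entry in pathway.entries.values():
        if entry.type != "gene":
            continue
        genes = entry.name.split()
        if genes:
            entry_genes[str(entry.id)] = genes
    edges: list[tuple[str, str]] = []
    nodes: list[str] = [g for genes in entry_genes.values() for g in genes]
    if expand_entry_cliques:
        for genes in entry_genes.values():
            edges.extend(
                (genes[i], genes[j])
                for i in range(len(genes))
                for j in range(i + 1, len(genes))
            )
    for rel in pathway.relations:
        g1 = entry_genes.get(str(rel.entry1.id))
        g2 = entry_genes.get(str(rel.entry2.id))
        if g1 and g2:
            edges.extend((a, b) for a in g1 for b in g2 if a != b)
    return BioNetwork.from_edges(name or pathway.name, edges, nodes=nodes)


def write_network(net: BioNetwork, path, format: str | None = None) -> Path:
    """Write as ``edgelist`` or ``graphml`` (both round-trip through
    :func:`read_network`)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write(f"# network: {net.name}\n")
            for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
                fh.write(f"{u}\t{v}\n")
            for n in sorted(net.nodes):
                if net.graph.degree(n) == 0:
                    fh.write(f"{n}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    return path


@dataclass(frozen=True)
class RefEntry:
    group: str
    name: str
    network: BioNetwork


@dataclass
class ReferenceNetworkSet:
    """Ordered, grouped collection of reference ("basic") networks."""

    entries: list[RefEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.group, e.name) for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (group, name) entries: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.group not in seen:
                seen.append(e.group)
        return seen

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def keys(self) -> list[tuple[str, str]]:
        return [(e.group, e.name) for e in self.entries]


def load_refset(manifest) -> ReferenceNetworkSet:
    """Load a reference set from a tab-separated manifest.

    Each data row is ``group <TAB> name <TAB> network-file <TAB> format``;
    relative paths resolve against the manifest's directory.  Entry order
    follows the manifest exactly (it indexes the fingerprint vector).
    """
    manifest = Path(manifest)
    base = manifest.parent
    entries: list[RefEntry] = []
    with open(manifest) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(
                    f"{manifest}:{lineno}: expected 4 tab-separated columns, got {len(cols)}"
                )
            group, name, rel_path, fmt = (c.strip() for c in cols)
            net_path = Path(rel_path)
            if not net_path.is_absolute():
                net_path = base / net_path
            if not net_path.exists():
                raise FileNotFoundError(f"{manifest}:{lineno}: network file {net_path} missing")
            entries.append(
                RefEntry(group=group, name=name, network=read_network(net_path, fmt, name=name))
            )
    return ReferenceNetworkSet(entries=entries)


def select_group(refset: ReferenceNetworkSet, groups: Sequence[str]) -> ReferenceNetworkSet:
    """Filter to the given groups, preserving relative order."""
    known = set(refset.groups)
    unknown = [g for g in groups if g not in known]
    if unknown:
        raise KeyError(f"unknown group(s) {unknown}; available: {sorted(known)}")
    wanted = set(groups)
    return ReferenceNetworkSet(entries=[e for e in refset.entries if e.group in wanted])


def select_networks(refset: ReferenceNetworkSet, names: Sequence[str]) -> ReferenceNetworkSet:
    """Filter to the given network names, preserving relative order."""
    known = set(refset.names)
    unknown = [n for n in names if n not in known]
    if unknown:
        raise KeyError(f"unknown network name(s) {unknown}")
    wanted = set(names)
    return ReferenceNetworkSet(entries=[e for e in refset.entries if e.name in wanted])


def summarize(refset: ReferenceNetworkSet) -> str:
    """Human-readable per-group / per-network summary."""
    lines = [f"{len(refset.groups)} groups, {len(refset)} networks"]
    for group in refset.groups:
        members = [e for e in refset.entries if e.group == group]
        lines.append(f"[{group}] {len(members)} network(s)")
        for e in members:
            lines.append(f"  {e.name}: {e.network.n_nodes} nodes, {e.network.n_edges} edges")
    return "\n".join(lines)


# --- optional online helper (untested; requires network access) -------------

KEGG_REST = "https://rest.kegg.jp"


def fetch_kegg_pathway(pathway_id: str, out_dir) -> Path:  # pragma: no cover
    """Download one KEGG pathway as KGML via the REST API (online helper).

    Writes ``<out_dir>/<pathway_id>.xml`` readable by
    ``read_network(..., format="kgml")``.  Provided for convenience only;
    it is not exercised by the test suite (network access).
    """
    from urllib.request import urlopen

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / f"{pathway_id}.xml"
    with urlopen(f"{KEGG_REST}/get/{pathway_id}/kgml", timeout=60) as resp:
        out.write_bytes(resp.read())
    return out


def build_kegg_refnet(
    pathway_ids: Sequence[str], groups: Sequence[str], out_dir
) -> Path:  # pragma: no cover
    """Download KEGG pathways and write a ``load_refset`` manifest (online helper)."""
    out_dir = Path(out_dir)
    rows = []
    for pid, group in zip(pathway_ids, groups, strict=True):
        fetch_kegg_pathway(pid, out_dir)
        rows.append(f"{group}\t{pid}\t{pid}.xml\tkgml")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
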