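"""Canonical miRNA seed matching and shared-miRNA ceRNA network construction.

A competing-endogenous-RNA (ceRNA) relationship links a lncRNA and an mRNA
when both carry binding sites for the same miRNA, so that either transcript
can titrate the miRNA away from the other. Binding sites are called by
canonical seed complementarity (8mer, 7mer-m8, 7mer-A1) against the miRNA
seed (nucleotides 2–8); the network is the tripartite graph of
miRNA → target edges plus derived lncRNA–mRNA edges labeled with the exact
set of shared miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import networkx as nx

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_COMP = str.maketrans("ACGTU", "TGCAA")


def _norm(seq: str) -> str:
    """Uppercase, RNA→DNA (U→T)."""
    return seq.upper().replace("U", "T")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MiRNABindingSite:
    """One predicted site: where on the target a miRNA seed pairs, and the
    canonical site class."""

    mirna_id: str
    target_id: str
    position: int  # 0-based start of the matched region on the target
    site_type: str
    length: int  # nt of the matched region (7 or 8)

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")


def find_seed_matches(
    mirna_seq: str,
    target_seq: str,
    mirna_id: str = "",
    target_id: str = "",
    site_types: Iterable[str] = SITE_TYPES,
) -> list[MiRNABindingSite]:
    """Scan a target (5'→3') for canonical seed sites of a miRNA (5'→3').

    Site classes, on the target read 5'→3':
    - 7mer-m8: reverse complement of miRNA nucleotides 2–8;
    - 8mer: 7mer-m8 followed by an 'A' (the position opposite miRNA nt 1);
    - 7mer-A1: reverse complement of miRNA nucleotides 2–7 followed by 'A'.

    All sites are reported, overlaps allowed; each position is reported once
    under its strongest class (an 8mer is not also a 7mer-m8, and a 7mer-A1
    nested at the tail of an 8mer/7mer-m8 match is not reported separately).
    U/T are equivalent.
    """
    if len(mirna_seq) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    wanted = set(site_types)
    m = _norm(mirna_seq)
    t = _norm(target_seq)
    core7 = _revcomp(m[1:8])  # pairs miRNA nt 2-8
    core6 = _revcomp(m[1:7])  # pairs miRNA nt 2-7
    sites: list[MiRNABindingSite] = []
    for i in range(len(t)):
        if t[i : i + 7] == core7:
            if i + 7 < len(t) and t[i + 7] == "A" and "8mer" in wanted:
                sites.append(MiRNABindingSite(mirna_id, target_id, i, "8mer", 8))
                continue
            if "7mer-m8" in wanted:
                sites.append(MiRNABindingSite(mirna_id, target_id, i, "7mer-m8", 7))
        elif (
            "7mer-A1" in wanted
            and t[i : i + 6] == core6
            and i + 6 < len(t)
            and t[i + 6] == "A"
            and not (i >= 1 and t[i - 1 : i + 6] == core7)
        ):
            sites.append(MiRNABindingSite(mirna_id, target_id, i, "7mer-A1", 7))
    return sites


def scan_targets(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    site_types: Iterable[str] = SITE_TYPES,
) -> list[MiRNABindingSite]:
    """All seed sites of each miRNA in each target sequence."""
    sites = []
    for (mid, mseq), (tid, tseq) in product(mirnas.items(), targets.items()):
        sites.extend(find_seed_matches(mseq, tseq, mid, tid, site_types))
    return sites


class CeRNANetwork:
    """Tripartite lncRNA / miRNA / mRNA graph.

    miRNA–target edges carry ``kind='binds'``; derived lncRNA–mRNA edges carry
    ``kind='ceRNA'`` and the exact shared-miRNA set. A lncRNA–mRNA edge exists
    iff the two nodes' miRNA neighbourhoods intersect.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # node/edge helpers -------------------------------------------------
    def add_node(self, node_id: str, node_type: str) -> None:
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["node_type"] != node_type:
            raise ValueError(
                f"id {node_id!r} used as both {existing['node_type']} and {node_type}"
            )
        self.graph.add_node(node_id, node_type=node_type)

    def nodes_of_type(self, node_type: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type}

    @property
    def lncrnas(self) -> set[str]:
        return self.nodes_of_type("lncRNA")

    @property
    def mirnas(self) -> set[str]:
        return self.nodes_of_type("miRNA")

    @property
    def mrnas(self) -> set[str]:
        return self.nodes_of_type("mRNA")

    def mirna_neighbors(self, target_id: str) -> set[str]:
        return {
            n
            for n in self.graph.neighbors(target_id)
            if self.graph.nodes[n]["node_type"] == "miRNA"
        }

    def cerna_edges(self) -> list[tuple[str, str, frozenset]]:
        return [
            (u, v, d["shared_mirnas"])
            for u, v, d in self.graph.edges(data=True)
            if d["kind"] == "ceRNA"
        ]

    def binding_edges(self) -> list[tuple[str, str]]:
        return [
            (u, v) for u, v, d in self.graph.edges(data=True) if d["kind"] == "binds"
        ]

    def focal_subnetwork(self, lncrna_id: str) -> "CeRNANetwork":
        """Restrict to one lncRNA, its miRNAs, and the mRNAs it shares them
        with (the single-lncRNA hub view)."""
        sub = CeRNANetwork()
        sub.add_node(lncrna_id, "lncRNA")
        mirnas = self.mirna_neighbors(lncrna_id)
        for m in mirnas:
            sub.add_node(m, "miRNA")
            sub.graph.add_edge(m, lncrna_id, kind="binds")
        for u, v, shared in self.cerna_edges():
            if lncrna_id not in (u, v):
                continue
            other = v if u == lncrna_id else u
            sub.add_node(other, "mRNA")
            for m in shared:
                sub.graph.add_edge(m, other, kind="binds")
            sub.graph.add_edge(lncrna_id, other, kind="ceRNA", shared_mirnas=shared)
        return sub


def build_cerna_network(
    lnc_sites: Iterable[MiRNABindingSite],
    mrna_sites: Iterable[MiRNABindingSite],
    focal_lncrna: str | None = None,
) -> CeRNANetwork:
    """Build the shared-miRNA network from per-class binding-site lists.

    lncRNA and mRNA id spaces must be disjoint. A lncRNA–mRNA edge is created
    for every pair with at least one shared bound miRNA; the edge label is the
    exact intersection of the two miRNA neighbourhoods. ``focal_lncrna``
    restricts the result to one lncRNA's neighbourhood.
    """
    lnc_sites = list(lnc_sites)
    mrna_sites = list(mrna_sites)
    lnc_ids = {s.target_id for s in lnc_sites}
    mrna_ids = {s.target_id for s in mrna_sites}
    clash = lnc_ids & mrna_ids
    if clash:
        raise ValueError(f"ids used as both lncRNA and mRNA: {sorted(clash)}")
    net = CeRNANetwork()
    for sites, ttype in ((lnc_sites, "lncRNA"), (mrna_sites, "mRNA")):
        for s in sites:
            net.add_node(s.mirna_id, "miRNA")
            net.add_node(s.target_id, ttype)
            net.graph.add_edge(s.mirna_id, s.target_id, kind="binds")
    for lnc in sorted(lnc_ids):
        shared_pool = net.mirna_neighbors(lnc)
        for mrna in sorted(mrna_ids):
            shared = frozenset(shared_pool & net.mirna_neighbors(mrna))
            if shared:
                net.graph.add_edge(lnc, mrna, kind="ceRNA", shared_mirnas=shared)
    if focal_lncrna is not None:
        net = net.focal_subnetwork(focal_lncrna)
    return net


# --- export / import ---------------------------------------------------------


def export_network(net: CeRNANetwork, path, fmt: str = "SIF") -> None:
    """Write the network for Cytoscape: SIF rows ``source interaction target``
    (interaction 'binds' or 'ceRNA') or GraphML with node-type and
    shared-miRNA attributes."""
    fmt = fmt.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for u, v in sorted(map(sorted, net.binding_edges())):
                fh.write(f"{u}\tbinds\t{v}\n")
            for u, v, _ in sorted((sorted((u, v)) + [s] for u, v, s in net.cerna_edges())):
                fh.write(f"{u}\tceRNA\t{v}\n")
    elif fmt == "GRAPHML":
        g = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, node_type=d["node_type"])
        for u, v, d in net.graph.edges(data=True):
            attrs = {"kind": d["kind"]}
            if d["kind"] == "ceRNA":
                attrs["shared_mirnas"] = ",".join(sorted(d["shared_mirnas"]))
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (use SIF or GraphML)")


def import_network(path, fmt: str = "SIF") -> CeRNANetwork:
    """Re-read an exported network (round-trips with :func:`export_network`).

    SIF carries no node-type column, so types are reconstructed from edge
    semantics: 'binds' endpoints sort miRNA vs target by the ceRNA edges.
    """
    fmt = fmt.upper()
    net = CeRNANetwork()
    if fmt == "GRAPHML":
        g = nx.read_graphml(path)
        for n, d in g.nodes(data=True):
            net.add_node(n, d["node_type"])
        for u, v, d in g.edges(data=True):
            if d["kind"] == "ceRNA":
                shared = frozenset(x for x in d.get("shared_mirnas", "").split(",") if x)
                net.graph.add_edge(u, v, kind="ceRNA", shared_mirnas=shared)
            else:
                net.graph.add_edge(u, v, kind="binds")
        return net
    if fmt != "SIF":
        raise ValueError(f"unknown format {fmt!r}")
    binds: list[tuple[str, str]] = []
    cerna: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                continue
            u, kind, v = parts
            (binds if kind == "binds" else cerna).append((u, v))
    cerna_nodes = {n for e in cerna for n in e}
    # SIF carries no node-type column; endpoints of ceRNA edges are targets,
    # their 'binds' partners are miRNAs. lncRNA-vs-mRNA is unrecoverable, so
    # targets come back typed mRNA (edge sets still round-trip exactly).
    for u, v in binds:
        mirna, target = (u, v) if v in cerna_nodes else (v, u)
        net.add_node(mirna, "miRNA")
        if target not in net.graph.nodes:
            net.add_node(target, "mRNA")
        net.graph.add_edge(mirna, target, kind="binds")
    for u, v in cerna:
        for n in (u, v):
            if n not in net.graph.nodes:
                net.add_node(n, "mRNA")
        shared = frozenset(
            set(net.mirna_neighbors(u)) & set(net.mirna_neighbors(v))
        )
        net.graph.add_edge(u, v, kind="ceRNA", shared_mirnas=shared)
    return net


def write_site_table(sites: Iterable[MiRNABindingSite], path) -> None:
    """Tab-delimited site table: miRNA, target, position, type."""
    with open(path, "w") as fh:
        fh.write("mirna_id\ttarget_id\tposition\tsite_type\n")
        for s in sorted(sites, key=lambda s: (s.mirna_id, s.target_id, s.position)):
            fh.write(f"{s.mirna_id}\t{s.target_id}\t{s.position}\t{s.site_type}\n")
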