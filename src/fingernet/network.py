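"""Genome-scale metabolic network handling.

SBML ingestion, collapse of cellular compartments into a one-compartment
network, side-compound filtering, node-weighted lightest-path sub-network
extraction from fingerprint seed metabolites, and set algebra between
sub-networks.

The central graph abstraction is the *compound graph*: an undirected
bipartite graph with metabolite and reaction nodes, a reaction linked to
each of its substrates and products.  Metabolite nodes carry a positive
weight (squared degree by default) so that paths avoid promiscuous hub
metabolites; the lightest path between two metabolites minimizes the sum
of node weights along the path.
"""

from __future__ import annotations

import hashlib
import heapq
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from math import inf
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "MergeResult",
    "CompoundGraph",
    "Path",
    "SubNetwork",
    "read_sbml",
    "write_sbml",
    "merge_compartments",
    "build_compound_graph",
    "lightest_path",
    "extract_subnetwork",
    "subnetwork_algebra",
    "map_fingerprint_to_network",
    "export_subnetwork",
    "default_side_compounds",
    "resolve_side_compounds",
    "load_name_mapping",
]

WEIGHT_SCHEMES = ("degree_squared", "degree", "unit")


# ----------------------------------------------------------------------
# data model
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str
    substrates: tuple[tuple[str, float], ...]  # (metabolite id, stoichiometry > 0)
    products: tuple[tuple[str, float], ...]
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", tuple((m, float(s)) for m, s in self.substrates))
        object.__setattr__(self, "products", tuple((m, float(s)) for m, s in self.products))
        for m, s in self.substrates + self.products:
            if s <= 0:
                raise ValueError(f"reaction {self.id}: non-positive stoichiometry for {m}")


@dataclass(frozen=True)
class MetabolicNetwork:
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    name: str = ""
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        mids = [m.id for m in self.metabolites]
        rids = [r.id for r in self.reactions]
        if len(set(mids)) != len(mids):
            raise ValueError("duplicate metabolite ids")
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reaction ids")
        known = set(mids)
        for r in self.reactions:
            for m, _ in r.substrates + r.products:
                if m not in known:
                    raise ValueError(f"reaction {r.id} references unknown metabolite {m}")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)


# ----------------------------------------------------------------------
# SBML I/O (python-libsbml)
# ----------------------------------------------------------------------
def read_sbml(path) -> MetabolicNetwork:
    """Read an SBML Level 2/3 model into a :class:`MetabolicNetwork`.

    Fails atomically: a parse error or a species without a compartment
    raises and no partial network is returned.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        ctx = "; ".join(
            f"line {e.getLine()}: {e.getMessage().strip()}" for e in errors[:5]
        )
        raise ValueError(f"unparseable SBML file {path}: {ctx}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"SBML file {path} contains no model")

    metabolites = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        comp = sp.getCompartment()
        if not comp:
            raise ValueError(f"species {sp.getId()} has no compartment")
        metabolites.append(
            Metabolite(sp.getId(), sp.getName() or sp.getId(), comp)
        )

    def refs(get_ref, n) -> tuple[tuple[str, float], ...]:
        out = []
        for j in range(n):
            ref = get_ref(j)
            stoich = ref.getStoichiometry()
            if stoich != stoich or stoich == 0:  # NaN (unset) or zero -> 1
                stoich = 1.0
            out.append((ref.getSpecies(), abs(stoich)))
        return tuple(out)

    reactions = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        reactions.append(
            Reaction(
                rx.getId(),
                rx.getName() or rx.getId(),
                refs(rx.getReactant, rx.getNumReactants()),
                refs(rx.getProduct, rx.getNumProducts()),
                bool(rx.getReversible()),
            )
        )
    return MetabolicNetwork(
        tuple(metabolites), tuple(reactions), name=model.getId() or ""
    )


def write_sbml(net: MetabolicNetwork, path) -> None:
    """Write the network as SBML Level 3 Version 1."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(re.sub(r"\W", "_", net.name) or "model")
    for comp_id in sorted({m.compartment for m in net.metabolites}):
        c = model.createCompartment()
        c.setId(comp_id)
        c.setConstant(True)
    for m in net.metabolites:
        sp = model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
    for r in net.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for mid, stoich in r.substrates:
            ref = rx.createReactant()
            ref.setSpecies(mid)
            ref.setStoichiometry(stoich)
            ref.setConstant(True)
        for mid, stoich in r.products:
            ref = rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(stoich)
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


# ----------------------------------------------------------------------
# compartment collapsing
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class MergeResult:
    network: MetabolicNetwork
    id_map: dict  # old metabolite id -> merged id
    removed_transport: tuple[str, ...]  # pure-transport reaction ids
    removed_empty: tuple[str, ...]  # reactions left with no participants
    deduplicated: dict  # kept reaction id -> removed duplicate ids


def _base_id(mid: str, compartment: str, pattern: str | None) -> str:
    """Strip the compartment designation from a species id."""
    if pattern:
        return re.sub(pattern, "", mid)
    for suffix in (f"_{compartment}", f"[{compartment}]", f"_{compartment.upper()}"):
        if compartment and mid.endswith(suffix):
            return mid[: -len(suffix)]
    return mid


def merge_compartments(
    net: MetabolicNetwork, suffix_pattern: str | None = None
) -> MergeResult:
    """Collapse all compartments: one record per metabolite species.

    Metabolites identical up to their compartment designation (suffix
    convention, configurable via ``suffix_pattern`` regex) become a single
    record.  After substituting merged ids into the reactions, (a) pure
    transport reactions -- substrate multiset equal to product multiset --
    are removed, and (b) reactions with identical substrate/product
    multisets and reversibility are deduplicated, keeping the
    lexicographically smallest id.  Idempotent: merged ids carry no
    compartment designation, so a second pass changes nothing.
    """
    id_map: dict[str, str] = {}
    merged: dict[str, Metabolite] = {}
    for m in net.metabolites:
        base = _base_id(m.id, m.compartment, suffix_pattern)
        id_map[m.id] = base
        if base not in merged:
            merged[base] = Metabolite(base, m.name, "merged")

    removed_transport: list[str] = []
    removed_empty: list[str] = []
    canon: dict[tuple, Reaction] = {}
    dedup: dict[str, list[str]] = {}
    for r in net.reactions:
        subs = Counter()
        prods = Counter()
        for mid, s in r.substrates:
            subs[id_map[mid]] += s
        for mid, s in r.products:
            prods[id_map[mid]] += s
        if not subs and not prods:
            removed_empty.append(r.id)
            continue
        if subs == prods:
            removed_transport.append(r.id)
            continue
        skey = tuple(sorted(subs.items()))
        pkey = tuple(sorted(prods.items()))
        if r.reversible and pkey < skey:  # direction-free key for reversible
            skey, pkey = pkey, skey
        key = (skey, pkey, r.reversible)
        new = Reaction(
            r.id,
            r.name,
            tuple(sorted(subs.items())),
            tuple(sorted(prods.items())),
            r.reversible,
        )
        if key in canon:
            old = canon[key]
            keep, drop = (old, new) if old.id <= new.id else (new, old)
            canon[key] = keep
            dedup.setdefault(keep.id, []).extend(
                [drop.id] + dedup.pop(drop.id, [])
            )
        else:
            canon[key] = new

    reactions = tuple(sorted(canon.values(), key=lambda r: r.id))
    network = MetabolicNetwork(
        tuple(merged.values()),
        reactions,
        name=f"{net.name}_one_compartment" if net.name else "one_compartment",
        provenance={**net.provenance, "compartments_merged": True},
    )
    return MergeResult(
        network, id_map, tuple(removed_transport), tuple(removed_empty),
        {k: tuple(v) for k, v in dedup.items()},
    )


# ----------------------------------------------------------------------
# compound graph and lightest paths
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CompoundGraph:
    """Undirected bipartite metabolite/reaction graph with node weights."""

    graph: nx.Graph
    weight_scheme: str
    fingerprint: str = ""  # content hash; identifies the parent network

    def __post_init__(self) -> None:
        if not self.fingerprint:
            h = hashlib.sha256()
            for n in sorted(self.graph.nodes):
                h.update(n.encode())
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                h.update(f"{u}|{v}".encode())
            object.__setattr__(self, "fingerprint", h.hexdigest()[:16])

    def node_weight(self, node: str) -> float:
        return self.graph.nodes[node]["weight"]

    @property
    def metabolite_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "metabolite"]

    @property
    def reaction_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "reaction"]


def build_compound_graph(
    net: MetabolicNetwork,
    side_compounds: Iterable[str] = (),
    weight_scheme: str = "degree_squared",
) -> CompoundGraph:
    """Bipartite compound graph over non-side metabolites.

    Side compounds (ubiquitous cofactors) are excluded before any degree
    is computed; reactions keep their remaining edges but are dropped if
    they no longer touch at least one substrate and one product.
    Metabolite node weights are computed from the degree *in this graph*:
    ``degree_squared`` (default, hub-avoiding), ``degree`` or ``unit``.
    Reaction nodes always weigh 1.
    """
    if weight_scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    mids = {m.id for m in net.metabolites}
    side = set(side_compounds)
    unknown = sorted(side - mids)
    if unknown:
        warnings.warn(f"side compounds not in network: {unknown}")
    side &= mids

    g = nx.Graph()
    for m in net.metabolites:
        if m.id not in side:
            g.add_node(m.id, kind="metabolite", name=m.name)
    for r in net.reactions:
        subs = [m for m, _ in r.substrates if m not in side]
        prods = [m for m, _ in r.products if m not in side]
        if not subs or not prods:
            continue
        g.add_node(r.id, kind="reaction", name=r.name)
        for m in set(subs) | set(prods):
            g.add_edge(r.id, m)
    if g.number_of_edges() == 0:
        raise ValueError("compound graph is empty after side-compound filtering")

    for n, d in g.nodes(data=True):
        if d["kind"] == "reaction":
            d["weight"] = 1.0
        else:
            deg = max(g.degree(n), 1)
            d["weight"] = {
                "unit": 1.0,
                "degree": float(deg),
                "degree_squared": float(deg) ** 2,
            }[weight_scheme]
    return CompoundGraph(g, weight_scheme)


@dataclass(frozen=True)
class Path:
    nodes: tuple[str, ...]
    cost: float

    def __bool__(self) -> bool:
        return bool(self.nodes)


def lightest_path(g: CompoundGraph, src: str, dst: str) -> Path:
    """Node-weighted lightest path between two metabolites.

    Minimizes the sum of node weights of all nodes on the path, endpoints
    included.  Implemented as Dijkstra over (cost, node sequence) keys:
    traversing an edge adds the weight of the entered node, and the source
    weight is added once, so the accumulated cost equals the node-weight
    sum.  Ties are broken by the lexicographically smallest node sequence.
    Unreachable targets yield an empty, infinite-cost path.
    """
    graph = g.graph
    for node in (src, dst):
        if node not in graph:
            raise KeyError(f"node {node!r} not in compound graph")
    if src == dst:
        raise ValueError("src and dst must differ")

    heap: list[tuple[float, tuple[str, ...]]] = [(g.node_weight(src), (src,))]
    done: set[str] = set()
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == dst:
            return Path(path, cost)
        for nxt in graph.neighbors(node):
            if nxt not in done:
                heapq.heappush(heap, (cost + g.node_weight(nxt), path + (nxt,)))
    return Path((), inf)


# ----------------------------------------------------------------------
# sub-networks
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SubNetwork:
    """Union of lightest paths connecting a set of seed metabolites."""

    metabolites: frozenset
    reactions: frozenset
    seeds: frozenset
    provenance: dict  # (seed_a, seed_b) -> node sequence of the lightest path
    unreachable_pairs: tuple
    edges: frozenset  # (reaction id, metabolite id)
    parent_fingerprint: str

    @property
    def nodes(self) -> frozenset:
        return self.metabolites | self.reactions

    def is_empty(self) -> bool:
        return not (self.metabolites or self.reactions)


def extract_subnetwork(g: CompoundGraph, seeds: Iterable[str]) -> SubNetwork:
    """Union of lightest paths over all unordered seed pairs."""
    seeds = sorted(set(seeds))
    present = [s for s in seeds if s in g.graph]
    missing = [s for s in seeds if s not in g.graph]
    if len(present) < 2:
        raise ValueError(
            f"need at least 2 mappable seeds, got {len(present)} "
            f"(not in graph: {missing})"
        )
    kinds = nx.get_node_attributes(g.graph, "kind")
    bad = [s for s in present if kinds[s] != "metabolite"]
    if bad:
        raise ValueError(f"seeds must be metabolites, got reaction node(s) {bad}")

    mets: set[str] = set()
    rxns: set[str] = set()
    edges: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], tuple[str, ...]] = {}
    unreachable: list[tuple[str, str]] = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            p = lightest_path(g, a, b)
            if not p:
                unreachable.append((a, b))
                continue
            provenance[(a, b)] = p.nodes
            for node in p.nodes:
                (mets if kinds[node] == "metabolite" else rxns).add(node)
            for u, v in zip(p.nodes, p.nodes[1:]):
                r, m = (u, v) if kinds[u] == "reaction" else (v, u)
                edges.add((r, m))
    return SubNetwork(
        frozenset(mets),
        frozenset(rxns),
        frozenset(present),
        provenance,
        tuple(unreachable),
        frozenset(edges),
        g.fingerprint,
    )


def subnetwork_algebra(a: SubNetwork, b: SubNetwork, op: str) -> SubNetwork:
    """Set algebra on sub-networks from the same parent network.

    ``intersect`` keeps nodes common to both (the machinery shared by two
    exposures), ``difference`` keeps nodes of ``a`` absent from ``b`` (the
    exposure-specific part), ``union`` merges.  The operation is applied
    independently to metabolite, reaction and seed id sets; provenance is
    restricted to recorded paths that survive entirely.
    """
    if op not in {"intersect", "difference", "union"}:
        raise ValueError(f"unknown set operation {op!r}")
    if a.parent_fingerprint != b.parent_fingerprint:
        raise ValueError("sub-networks derive from different parent networks")
    apply = {
        "intersect": lambda x, y: x & y,
        "difference": lambda x, y: x - y,
        "union": lambda x, y: x | y,
    }[op]
    mets = apply(a.metabolites, b.metabolites)
    rxns = apply(a.reactions, b.reactions)
    seeds = apply(a.seeds, b.seeds)
    nodes = mets | rxns
    prov_pool = {**b.provenance, **a.provenance} if op == "union" else a.provenance
    provenance = {
        pair: path
        for pair, path in prov_pool.items()
        if all(n in nodes for n in path)
    }
    edges = frozenset(
        (r, m) for r, m in apply(a.edges, b.edges) if r in rxns and m in mets
    )
    unreachable = tuple(dict.fromkeys(a.unreachable_pairs + b.unreachable_pairs)) \
        if op == "union" else a.unreachable_pairs
    return SubNetwork(mets, rxns, seeds, provenance, unreachable, edges,
                      a.parent_fingerprint)


# ----------------------------------------------------------------------
# fingerprint -> network mapping and packaged resources
# ----------------------------------------------------------------------
def load_name_mapping(path=None) -> dict:
    """Metabolite name -> network id table (lower-cased names).

    The packaged default covers the discriminant metabolite names of the
    study tables with BiGG-style species identifiers.  Duplicate synonyms
    mapping to different ids raise (ambiguity is never silently resolved).
    """
    if path is None:
        path = resources.files("fingernet.data") / "metabolite_network_ids.tsv"
    tab = pd.read_csv(path, sep="\t", comment="#")
    mapping: dict[str, str] = {}
    for name, mid in zip(tab["name"], tab["network_id"]):
        key = str(name).strip().lower()
        if key in mapping and mapping[key] != mid:
            raise ValueError(f"ambiguous synonym {name!r}: {mapping[key]} vs {mid}")
        mapping[key] = str(mid)
    if not mapping:
        raise ValueError("empty name mapping")
    return mapping


def map_fingerprint_to_network(fingerprint, mapping: Mapping[str, str]
                               ) -> tuple[set, list]:
    """Map fingerprint metabolite names to network ids.

    Case-insensitive exact match on curated synonyms.  Returns
    ``(seed id set, unmapped names)``; unmapped names are reported, never
    silently dropped.  ``fingerprint`` may be a Fingerprint object or any
    iterable of metabolite names.
    """
    if not mapping:
        raise ValueError("empty name mapping")
    names = getattr(fingerprint, "metabolites", None)
    if names is None:
        names = list(fingerprint)
    seeds: set[str] = set()
    unmapped: list[str] = []
    for name in sorted(set(names)):
        key = str(name).strip().lower()
        if key in ("", "unassigned"):
            continue
        if key in mapping:
            seeds.add(mapping[key])
        else:
            unmapped.append(name)
    return seeds, unmapped


def default_side_compounds(path=None) -> list[str]:
    """Packaged cofactor list (water, protons, ATP/ADP/AMP, NAD(P)(H),
    CO2, phosphate, O2 ...) as network ids; editable TSV."""
    if path is None:
        path = resources.files("fingernet.data") / "side_compounds.tsv"
    tab = pd.read_csv(path, sep="\t", comment="#")
    return [str(x) for x in tab["network_id"]]


def resolve_side_compounds(net: MetabolicNetwork, ids: Iterable[str]) -> set:
    """Match side-compound ids against the network, case-insensitively on
    id and base id (compartment suffix stripped)."""
    wanted = {str(x).lower() for x in ids}
    out = set()
    for m in net.metabolites:
        base = _base_id(m.id, m.compartment, None).lower()
        if m.id.lower() in wanted or base in wanted or m.name.lower() in wanted:
            out.add(m.id)
    return out


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------
def export_subnetwork(s: SubNetwork, path, fmt: str) -> None:
    """Write a sub-network as SIF, GraphML or TSV.

    SIF rows are ``reaction_id interacts metabolite_id``; GraphML carries
    ``kind`` and ``seed`` node attributes and round-trips through
    :func:`networkx.read_graphml`.
    """
    if s.is_empty():
        raise ValueError("refusing to export an empty sub-network")
    if fmt == "sif":
        with open(path, "w") as fh:
            for r, m in sorted(s.edges):
                fh.write(f"{r}\tinteracts\t{m}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for m in sorted(s.metabolites):
            g.add_node(m, kind="metabolite", seed=m in s.seeds)
        for r in sorted(s.reactions):
            g.add_node(r, kind="reaction", seed=False)
        g.add_edges_from(s.edges)
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\tinteraction\ttarget\tsource_kind\ttarget_kind\n")
            for r, m in sorted(s.edges):
                fh.write(f"{r}\tinteracts\t{m}\treaction\tmetabolite\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
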