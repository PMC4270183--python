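"""Strongly connected components, master-regulator ranking, SCC comparison.

SCCs serve as network stability motifs: a maximal node set with directed
paths both ways between every pair can sustain its own expression state and
is where identity-maintaining genes live. Within an SCC, genes are ranked
by "out-degree interface" (number of outgoing edges staying inside the
SCC); the top-ranked genes are master-regulator candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import FormatError


def _digraph(net) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(sorted(net.nodes))
    for e in net.edges:
        g.add_edge(e.source, e.target)
    return g


@dataclass
class SCCResult:
    """Components of size >= 2 (unless singletons requested) with within-SCC degrees."""

    components: tuple  # tuple of frozensets, largest first
    out_degree: dict  # node -> out edges staying inside its component
    in_degree: dict
    label: str = ""
    singletons_included: bool = False

    def designated(self) -> frozenset:
        if not self.components:
            raise FormatError("network has no strongly connected component of size >= 2")
        return self.components[0]


@dataclass
class MasterRegulatorRanking:
    """Genes of one SCC ordered by out-degree interface (descending)."""

    entries: pd.DataFrame  # gene, out_degree_interface, in_degree
    top_k: int = 3

    @property
    def masters(self) -> list:
        return list(self.entries["gene"].head(self.top_k))


@dataclass
class SCCOverlap:
    """Set algebra and state agreement between two networks' designated SCCs."""

    shared: pd.DataFrame  # gene, state_a, state_b, agree
    unique_to_a: tuple
    unique_to_b: tuple
    counts: dict  # per network: genes, on, off, and optional up/down calls

    @property
    def n_shared_agreeing(self) -> int:
        return int(self.shared["agree"].sum())


def find_sccs(net, include_singletons: bool = False, label: str = "") -> SCCResult:
    """Decompose into strongly connected components (linear time).

    Only components of size >= 2 are reported by default; the singleton
    policy follows the stability-motif reading (a single gene, even
    self-looped, is not treated as a motif unless requested).
    """
    if not net.nodes:
        raise FormatError("empty network")
    g = _digraph(net)
    comps = [frozenset(c) for c in nx.strongly_connected_components(g)]
    if not include_singletons:
        comps = [c for c in comps if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    out_deg, in_deg = {}, {}
    # multiplicity by (source, target, interaction): count edges, not neighbors
    for comp in comps:
        for node in comp:
            out_deg[node] = sum(1 for e in net.edges
                                if e.source == node and e.target in comp)
            in_deg[node] = sum(1 for e in net.edges
                               if e.target == node and e.source in comp)
    return SCCResult(tuple(comps), out_deg, in_deg, label=label,
                     singletons_included=include_singletons)


def out_degree_interface(scc, net, top_k: int = 3) -> MasterRegulatorRanking:
    """Rank SCC genes by outgoing edges that stay within the SCC.

    Ties break lexicographically by gene id, keeping the ranking
    deterministic and invariant to edge-list order.
    """
    scc = frozenset(scc)
    sub = _digraph(net).subgraph(scc)
    if len(scc) >= 2 and not nx.is_strongly_connected(sub):
        raise FormatError("node set is not a strongly connected component of the network")
    rows = []
    for node in sorted(scc):
        out = sum(1 for e in net.edges if e.source == node and e.target in scc)
        inn = sum(1 for e in net.edges if e.target == node and e.source in scc)
        rows.append({"gene": node, "out_degree_interface": out, "in_degree": inn})
    df = pd.DataFrame(rows).sort_values(
        ["out_degree_interface", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    return MasterRegulatorRanking(df, top_k=top_k)


def compare_sccs(res_a: SCCResult, state_a, res_b: SCCResult, state_b,
                 diff_a=None, diff_b=None,
                 component_a: int = 0, component_b: int = 0) -> SCCOverlap:
    """Overlap of the designated (largest by default) SCC of two networks.

    ``state_a``/``state_b`` are the networks' predicted Boolean phenotype
    states; agreement is per shared gene. When differential tables are
    supplied, up/down-regulated counts per SCC are reported as well.
    """
    comp_a = res_a.components[component_a]
    comp_b = res_b.components[component_b]
    shared_genes = sorted(comp_a & comp_b)
    shared = pd.DataFrame(
        {
            "gene": shared_genes,
            "state_a": [state_a.values[g] for g in shared_genes],
            "state_b": [state_b.values[g] for g in shared_genes],
        }
    )
    shared["agree"] = shared["state_a"] == shared["state_b"]
    counts = {}
    for name, comp, state, diff in (("a", comp_a, state_a, diff_a),
                                    ("b", comp_b, state_b, diff_b)):
        entry = {
            "genes": len(comp),
            "on": sum(state.values[g] for g in comp),
            "off": sum(1 - state.values[g] for g in comp),
        }
        if diff is not None:
            t = diff.table.set_index("gene_id")
            in_comp = [g for g in comp if g in t.index]
            entry["up"] = int((t.loc[in_comp, "qde"] >= diff.threshold).sum())
            entry["down"] = int((t.loc[in_comp, "qde"] <= -diff.threshold).sum())
        counts[name] = entry
    return SCCOverlap(
        shared=shared,
        unique_to_a=tuple(sorted(comp_a - comp_b)),
        unique_to_b=tuple(sorted(comp_b - comp_a)),
        counts=counts,
    )
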