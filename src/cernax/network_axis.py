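"""Regulatory network assembly and ceRNA axis nomination.

Cis target pairs of differentially expressed lncRNAs and genes are split
into two co-directional networks (up-up and down-down; discordant pairs
belong to neither).  Passing miRNA sites on DE genes form a miRNA-gene
network whose edges carry the positive/negative pair sign.  Genes shared
between the two kinds of network are candidate ceRNA hubs: for each, any
lncRNA cis-paired to it and any miRNA targeting it combine into an axis
candidate whenever the lncRNA itself carries a passing (sponge) site for
that miRNA.  An axis is direction-consistent when lncRNA and gene move
together and the miRNA moves opposite — the classic sponge pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cernax.cis_target import CisPair
from cernax.diffexpr import DEResult
from cernax.mirna_target import MirnaSite, pair_sign

__all__ = [
    "RegulatoryNetwork",
    "AxisCandidate",
    "build_del_deg_networks",
    "build_des_deg_network",
    "shared_genes",
    "nominate_axes",
]

INTERACTIONS = ("cis", "mirna-target", "sponge")
_EXPECTED_KINDS = {"cis": ("lncRNA", "gene"), "mirna-target": ("miRNA", "gene"),
                   "sponge": ("lncRNA", "miRNA")}


@dataclass
class RegulatoryNetwork:
    """Typed bipartite edge sets over lncRNA, miRNA and gene nodes.

    Edges are (source, interaction, target, sign) with sign in
    {positive, negative, none}; each interaction type is bipartite
    (cis: lncRNA->gene, mirna-target: miRNA->gene, sponge: lncRNA->miRNA)
    and self-edges are rejected.
    """

    edges: set[tuple[str, str, str, str]] = field(default_factory=set)
    node_kind: dict[str, str] = field(default_factory=dict)

    def add_edge(
        self, source: str, interaction: str, target: str, sign: str = "none"
    ) -> None:
        if interaction not in INTERACTIONS:
            raise ValueError(f"unknown interaction {interaction!r}")
        if source == target:
            raise ValueError(f"self-edge on {source!r}")
        src_kind, tgt_kind = _EXPECTED_KINDS[interaction]
        for node, kind in ((source, src_kind), (target, tgt_kind)):
            prior = self.node_kind.setdefault(node, kind)
            if prior != kind:
                raise ValueError(f"node {node!r} used as both {prior} and {kind}")
        self.edges.add((source, interaction, target, sign))

    def targets(self) -> set[str]:
        return {tgt for _src, _kind, tgt, _sign in self.edges}

    def sources(self) -> set[str]:
        return {src for src, _kind, _tgt, _sign in self.edges}

    def to_networkx(self):
        """Export as a typed networkx DiGraph."""
        import networkx as nx

        g = nx.DiGraph()
        for node, kind in self.node_kind.items():
            g.add_node(node, kind=kind)
        for src, kind, tgt, sign in self.edges:
            g.add_edge(src, tgt, interaction=kind, sign=sign)
        return g


@dataclass
class AxisCandidate:
    """A nominated lncRNA -> miRNA -> gene ceRNA triple with its evidence."""

    lnc_id: str
    mirna_id: str
    gene_id: str
    pattern: tuple[str, str, str]  # (lnc_dir, mirna_dir, gene_dir)
    evidence: dict
    consistent: bool
    combined_lfc: float = 0.0


def _direction_map(results: list[DEResult]) -> dict[str, str]:
    return {r.feature_id: r.direction for r in results if r.significant}


def build_del_deg_networks(
    cis_pairs: list[CisPair],
    de_lnc: list[DEResult],
    de_gene: list[DEResult],
) -> tuple[RegulatoryNetwork, RegulatoryNetwork]:
    """Split DE-cis edges into the up-up and down-down networks.

    Pairs whose lncRNA and gene move in opposite directions are excluded
    from both networks.
    """
    lnc_dir = _direction_map(de_lnc)
    gene_dir = _direction_map(de_gene)
    up_net, down_net = RegulatoryNetwork(), RegulatoryNetwork()
    for pair in cis_pairs:
        dl = lnc_dir.get(pair.lnc_id)
        dg = gene_dir.get(pair.mrna_id)
        if dl is None or dg is None:
            continue
        if dl == "Up" and dg == "Up":
            up_net.add_edge(pair.lnc_id, "cis", pair.mrna_id, "positive")
        elif dl == "Down" and dg == "Down":
            down_net.add_edge(pair.lnc_id, "cis", pair.mrna_id, "positive")
    return up_net, down_net


def build_des_deg_network(
    sites: list[MirnaSite],
    de_mirna: list[DEResult],
    de_gene: list[DEResult],
) -> RegulatoryNetwork:
    """One signed edge per (DE miRNA, DE gene) with at least one passing site."""
    mirna_dir = _direction_map(de_mirna)
    gene_dir = _direction_map(de_gene)
    net = RegulatoryNetwork()
    seen: set[tuple[str, str]] = set()
    for site in sites:
        if not site.passes:
            continue
        dm = mirna_dir.get(site.mirna_id)
        dg = gene_dir.get(site.target_id)
        if dm is None or dg is None:
            continue
        key = (site.mirna_id, site.target_id)
        if key in seen:
            continue
        seen.add(key)
        net.add_edge(site.mirna_id, "mirna-target", site.target_id, pair_sign(dm, dg).sign)
    return net


def shared_genes(net_a: RegulatoryNetwork, net_b: RegulatoryNetwork) -> set[str]:
    """Genes appearing as targets in both networks."""
    return net_a.targets() & net_b.targets()


def nominate_axes(
    shared: set[str],
    cis_pairs: list[CisPair],
    mirna_gene_sites: list[MirnaSite],
    sponge_sites: list[MirnaSite],
    de_lnc: list[DEResult],
    de_mirna: list[DEResult],
    de_gene: list[DEResult],
) -> list[AxisCandidate]:
    """Combine evidence at each shared gene into ceRNA axis candidates.

    For a shared gene, each cis-paired lncRNA and each site-supported
    miRNA form a candidate when the lncRNA also carries a passing site
    for that miRNA (the sponge interaction).  Inconsistent direction
    patterns are reported with ``consistent=False`` rather than dropped;
    output is sorted by (consistent desc, summed |log2FC| desc).
    """
    lfc = {r.feature_id: r.log2fc for r in de_lnc + de_mirna + de_gene}
    dir_lnc = _direction_map(de_lnc)
    dir_mirna = _direction_map(de_mirna)
    dir_gene = _direction_map(de_gene)

    cis_by_gene: dict[str, list[CisPair]] = {}
    for p in cis_pairs:
        cis_by_gene.setdefault(p.mrna_id, []).append(p)
    sites_by_gene: dict[str, dict[str, MirnaSite]] = {}
    for s in mirna_gene_sites:
        if s.passes:
            sites_by_gene.setdefault(s.target_id, {}).setdefault(s.mirna_id, s)
    sponge_by_pair: dict[tuple[str, str], MirnaSite] = {}
    for s in sponge_sites:
        if s.passes:
            sponge_by_pair.setdefault((s.target_id, s.mirna_id), s)

    axes: list[AxisCandidate] = []
    for gene in sorted(shared):
        for pair in cis_by_gene.get(gene, []):
            for mirna_id, gsite in sites_by_gene.get(gene, {}).items():
                sponge = sponge_by_pair.get((pair.lnc_id, mirna_id))
                if sponge is None:
                    continue
                dl = dir_lnc.get(pair.lnc_id, "none")
                dm = dir_mirna.get(mirna_id, "none")
                dg = dir_gene.get(gene, "none")
                if "none" in (dl, dm, dg):
                    continue
                axes.append(
                    AxisCandidate(
                        lnc_id=pair.lnc_id,
                        mirna_id=mirna_id,
                        gene_id=gene,
                        pattern=(dl, dm, dg),
                        evidence={
                            "cis_pair": pair,
                            "mirna_gene_site": gsite,
                            "sponge_site": sponge,
                        },
                        consistent=(dl == dg and dm != dg),
                        combined_lfc=sum(
                            abs(lfc.get(f, 0.0)) for f in (pair.lnc_id, mirna_id, gene)
                        ),
                    )
                )
    axes.sort(key=lambda a: (not a.consistent, -a.combined_lfc, a.lnc_id, a.mirna_id, a.gene_id))
    return axes
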