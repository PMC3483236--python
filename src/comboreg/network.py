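"""The inferred regulatory network: typed, signed, p-valued edges.

A :class:`RegulatoryNetwork` is an edge table (one row per retained
regulator→target term with its regression efficacy, t statistic, p value and
credibility tier) plus the vertex kinds. Vertices are TFs, miRNAs or non-TF
protein-coding genes; legal edge kinds are TF→gene, TF→TF, TF→miRNA,
miRNA→gene and miRNA→TF. Exports: lossless TSV/GraphML, sign-only SIF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

EDGE_COLUMNS = [
    "regulator", "regulator_kind", "target", "target_kind",
    "efficacy", "t_statistic", "p_value", "tier",
]

TIER_HIGH, TIER_MEDIUM, TIER_LOW = "high", "medium", "low"


def tier_for_p(p_value: float) -> str:
    """Credibility tier from the term's p value: high p<0.01, medium
    0.01≤p<0.05, low otherwise (terms the selection kept despite p≥0.05)."""
    if p_value < 0.01:
        return TIER_HIGH
    if p_value < 0.05:
        return TIER_MEDIUM
    return TIER_LOW


@dataclass(frozen=True)
class RegulatoryEdge:
    regulator: str
    regulator_kind: str
    target: str
    target_kind: str
    efficacy: float
    t_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError(f"self-loop edge {self.regulator}")

    @property
    def tier(self) -> str:
        return tier_for_p(self.p_value)

    @property
    def sign(self) -> str:
        return "activating" if self.efficacy > 0 else "repressing"


@dataclass
class RegulatoryNetwork:
    """Edge table + vertex kinds of an inferred combinatorial network."""

    edges: pd.DataFrame
    tf_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if list(self.edges.columns) != EDGE_COLUMNS:
            self.edges = self.edges.reindex(columns=EDGE_COLUMNS)
        self.tf_ids = frozenset(self.tf_ids)

    @classmethod
    def from_edges(cls, edges: list[RegulatoryEdge], tf_ids=()) -> "RegulatoryNetwork":
        rows = [
            (e.regulator, e.regulator_kind, e.target, e.target_kind,
             e.efficacy, e.t_statistic, e.p_value, e.tier)
            for e in edges
        ]
        frame = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return cls(frame, tf_ids=frozenset(tf_ids))

    def __len__(self) -> int:
        return len(self.edges)

    def vertex_kind(self, vertex: str) -> str:
        """'TF', 'miRNA' or 'gene' (non-TF protein-coding gene)."""
        if vertex in self.tf_ids:
            return "TF"
        e = self.edges
        if ((e.regulator.eq(vertex) & e.regulator_kind.eq("miRNA")).any()
                or (e.target.eq(vertex) & e.target_kind.eq("miRNA")).any()):
            return "miRNA"
        return "gene"

    @property
    def vertices(self) -> pd.DataFrame:
        ids = sorted(set(self.edges.regulator) | set(self.edges.target))
        return pd.DataFrame(
            {"vertex": ids, "kind": [self.vertex_kind(v) for v in ids]}
        )

    def edge_type_counts(self) -> dict[str, int]:
        """Counts per regulation type (miRNA->gene, TF->gene, TF->miRNA);
        TF targets count under their 'gene' target kind."""
        key = self.edges.regulator_kind + "->" + self.edges.target_kind
        return key.value_counts().to_dict()

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.vertices.itertuples(index=False):
            g.add_node(row.vertex, kind=row.kind)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.regulator, row.target,
                regulator_kind=row.regulator_kind, target_kind=row.target_kind,
                efficacy=float(row.efficacy), t_statistic=float(row.t_statistic),
                p_value=float(row.p_value), tier=row.tier,
                sign="activating" if row.efficacy > 0 else "repressing",
            )
        return g

    # -- exports -----------------------------------------------------------

    def write_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, tf_ids=()) -> "RegulatoryNetwork":
        frame = pd.read_csv(
            path, sep="\t",
            dtype={"regulator": str, "target": str,
                   "regulator_kind": str, "target_kind": str, "tier": str},
        )
        return cls(frame, tf_ids=frozenset(tf_ids))

    def write_sif(self, path) -> None:
        """SIF: regulator <tab> activates|represses <tab> target."""
        with open(path, "w", encoding="utf-8") as handle:
            for row in self.edges.itertuples(index=False):
                relation = "activates" if row.efficacy > 0 else "represses"
                handle.write(f"{row.regulator}\t{relation}\t{row.target}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_digraph(), path)

    @classmethod
    def read_graphml(cls, path) -> "RegulatoryNetwork":
        g = nx.read_graphml(path)
        rows = [
            (u, d["regulator_kind"], v, d["target_kind"],
             d["efficacy"], d["t_statistic"], d["p_value"], d["tier"])
            for u, v, d in g.edges(data=True)
        ]
        frame = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        frame = frame.sort_values(["target", "regulator"], kind="stable",
                                  ignore_index=True)
        tf_ids = frozenset(n for n, d in g.nodes(data=True) if d.get("kind") == "TF")
        return cls(frame, tf_ids=tf_ids)


def export_network(net: RegulatoryNetwork, path, fmt: str) -> Path:
    """Write ``net`` in one of {'tsv', 'sif', 'graphml'}."""
    path = Path(path)
    writers = {"tsv": net.write_tsv, "sif": net.write_sif,
               "graphml": net.write_graphml}
    if fmt not in writers:
        raise ValueError(f"unknown export format: {fmt!r}")
    writers[fmt](path)
    return path
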