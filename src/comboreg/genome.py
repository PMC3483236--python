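"""Candidate regulations and genomic construction of TF→miRNA candidates.

Two sources of forward-predicted candidate edges feed the pipeline directly
(miRNA→gene from seed-match databases, TF→gene from promoter scans). The
third type, TF→miRNA, has to be constructed from genomic coordinates:

* an intragenic miRNA (fully inside a protein-coding gene, same strand) is
  assumed co-transcribed with its host and inherits the host's candidate TFs;
* intergenic miRNAs are chained into genomic clusters (consecutive loci on
  one chromosome/strand separated by at most ``max_gap`` bp, 7.5 kb by
  default), a promoter window (−3 kb/+1 kb around the first member's TSS) is
  assigned to each cluster, and any TF whose binding site overlaps that
  window becomes a candidate regulator of every cluster member.

All coordinates are 0-based half-open (BED convention); the UCSC wgRna
dialect is converted on read.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REGULATOR_KINDS = ("TF", "miRNA")
TARGET_KINDS = ("gene", "miRNA")


class CandidateParseError(ValueError):
    """Malformed candidate-edge file."""


@dataclass(frozen=True, order=True)
class CandidateEdge:
    """A forward-predicted regulator→target relation."""

    regulator: str
    regulator_kind: str
    target: str
    target_kind: str

    def __post_init__(self) -> None:
        if self.regulator_kind not in REGULATOR_KINDS:
            raise ValueError(f"unknown regulator kind: {self.regulator_kind!r}")
        if self.target_kind not in TARGET_KINDS:
            raise ValueError(f"unknown target kind: {self.target_kind!r}")
        if self.regulator_kind == "miRNA" and self.target_kind == "miRNA":
            raise ValueError(
                f"miRNA→miRNA candidate not allowed: {self.regulator}→{self.target}"
            )


class CandidateSet:
    """A deduplicated set of :class:`CandidateEdge`."""

    def __init__(self, edges: Iterable[CandidateEdge] = ()) -> None:
        self._edges: set[CandidateEdge] = set(edges)

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self):
        return iter(sorted(self._edges))

    def __contains__(self, edge: CandidateEdge) -> bool:
        return edge in self._edges

    def add(self, edge: CandidateEdge) -> None:
        self._edges.add(edge)

    def __or__(self, other: "CandidateSet") -> "CandidateSet":
        return CandidateSet(self._edges | other._edges)

    def of_type(self, regulator_kind: str, target_kind: str) -> "CandidateSet":
        return CandidateSet(
            e for e in self._edges
            if e.regulator_kind == regulator_kind and e.target_kind == target_kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.regulator, e.regulator_kind, e.target, e.target_kind) for e in self],
            columns=["regulator", "regulator_kind", "target", "target_kind"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self._edges:
            key = f"{e.regulator_kind}->{e.target_kind}"
            counts[key] = counts.get(key, 0) + 1
        return counts


def read_candidates(path) -> CandidateSet:
    """Read a 4-column TSV (regulator, regulator_kind, target, target_kind).

    Rows are deduplicated; per-type counts are logged. Unknown kind tokens
    and miRNA→miRNA rows raise :class:`CandidateParseError`.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["regulator", "regulator_kind", "target", "target_kind"]
    if list(frame.columns[:4]) != required:
        raise CandidateParseError(
            f"{path}: expected columns {required}, got {list(frame.columns)}"
        )
    edges = CandidateSet()
    for row in frame.itertuples(index=False):
        try:
            edges.add(CandidateEdge(row.regulator, row.regulator_kind,
                                    row.target, row.target_kind))
        except ValueError as exc:
            raise CandidateParseError(f"{path}: {exc}") from None
    logger.info("candidates from %s: %s", path, edges.type_counts())
    return edges


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind overlap of at least 1 bp (half-open intervals)."""
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class MirnaLocus:
    name: str
    location: GenomicInterval
    host_gene: str | None = None

    @property
    def group(self) -> str:
        return "intragenic" if self.host_gene is not None else "intergenic"


@dataclass
class MirnaCluster:
    """Intergenic miRNAs transcribed as one unit, with a shared promoter."""

    members: list[MirnaLocus]
    promoter: GenomicInterval | None = None


def classify_mirna_loci(
    mirnas: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[tuple[str, GenomicInterval]],
) -> list[MirnaLocus]:
    """Split miRNA loci into intragenic and intergenic groups.

    A miRNA fully contained in a protein-coding gene on the same strand is
    intragenic with that gene as host; everything else — outside genes,
    partially overlapping, or embedded on the opposite strand — is
    intergenic. If several genes contain a miRNA, the longest container is
    the host (logged).
    """
    loci = []
    for name, ivl in mirnas:
        hosts = [
            (gname, givl) for gname, givl in genes
            if givl.contains(ivl) and givl.strand == ivl.strand
        ]
        host = None
        if hosts:
            if len(hosts) > 1:
                logger.info("miRNA %s inside %d genes; host = longest", name, len(hosts))
            host = max(hosts, key=lambda h: (len(h[1]), h[0]))[0]
        loci.append(MirnaLocus(name=name, location=ivl, host_gene=host))
    n_intra = sum(l.group == "intragenic" for l in loci)
    logger.info("classified %d miRNA loci: %d intragenic, %d intergenic",
                len(loci), n_intra, len(loci) - n_intra)
    return loci


def inherit_host_tfs(loci: Iterable[MirnaLocus], tf_gene: CandidateSet) -> CandidateSet:
    """Intragenic miRNAs inherit every candidate TF of their host gene."""
    by_target: dict[str, list[str]] = {}
    for e in tf_gene:
        if e.regulator_kind == "TF" and e.target_kind == "gene":
            by_target.setdefault(e.target, []).append(e.regulator)
    out = CandidateSet()
    for locus in loci:
        if locus.host_gene is None:
            continue
        for tf in by_target.get(locus.host_gene, ()):
            out.add(CandidateEdge(tf, "TF", locus.name, "miRNA"))
    return out


def cluster_intergenic(
    loci: Iterable[MirnaLocus], max_gap: int = 7500
) -> list[MirnaCluster]:
    """Chain intergenic miRNAs into clusters per chromosome and strand.

    Single-linkage along the position-sorted loci: consecutive loci whose
    inter-locus gap (next start minus previous end) is at most ``max_gap``
    share a cluster. Members are ordered along the strand (5'→3'). The
    cluster promoter is attached by :func:`cluster_promoter`.
    """
    loci = list(loci)
    if any(l.group != "intergenic" for l in loci):
        raise ValueError("cluster_intergenic expects intergenic loci only")
    clusters: list[MirnaCluster] = []
    keyfn = lambda l: (l.location.chrom, l.location.strand)
    for (chrom, strand), group in itertools.groupby(
        sorted(loci, key=lambda l: (l.location.chrom, l.location.strand,
                                    l.location.start, l.location.end, l.name)),
        key=keyfn,
    ):
        chain: list[MirnaLocus] = []
        for locus in group:
            if chain and locus.location.start - chain[-1].location.end > max_gap:
                clusters.append(_finish_cluster(chain, strand))
                chain = []
            chain.append(locus)
        if chain:
            clusters.append(_finish_cluster(chain, strand))
    return clusters


def _finish_cluster(chain: list[MirnaLocus], strand: str) -> MirnaCluster:
    members = chain if strand == "+" else chain[::-1]  # 5'→3' order
    cluster = MirnaCluster(members=list(members))
    cluster.promoter = cluster_promoter(cluster)
    return cluster


def cluster_promoter(
    c: MirnaCluster, upstream: int = 3000, downstream: int = 1000
) -> GenomicInterval:
    """Promoter of the whole cluster: −``upstream``/+``downstream`` bp around
    the first (5'-most) member's TSS, strand-aware, clipped at 0."""
    if not c.members:
        raise ValueError("empty cluster has no promoter")
    first = c.members[0].location
    if first.strand == "+":
        start, end = first.tss - upstream, first.tss + downstream
    else:
        start, end = first.tss - downstream, first.tss + upstream
    return GenomicInterval(first.chrom, max(0, start), end, first.strand)


def map_tfbs_to_clusters(
    clusters: Iterable[MirnaCluster],
    tfbs: Sequence[tuple[str, GenomicInterval]],
) -> CandidateSet:
    """TFBSs overlapping a cluster promoter (≥1 bp, strand-blind) make the
    TF a candidate regulator of every member of that cluster."""
    out = CandidateSet()
    for cluster in clusters:
        promoter = cluster.promoter or cluster_promoter(cluster)
        for tf, site in tfbs:
            if promoter.overlaps(site):
                for member in cluster.members:
                    out.add(CandidateEdge(tf, "TF", member.name, "miRNA"))
    return out


def build_tf_mirna_candidates(
    mirnas: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[tuple[str, GenomicInterval]],
    tf_gene: CandidateSet,
    tfbs: Sequence[tuple[str, GenomicInterval]],
    max_gap: int = 7500,
    upstream: int = 3000,
    downstream: int = 1000,
) -> CandidateSet:
    """Full TF→miRNA construction: host inheritance + cluster promoter scan."""
    loci = classify_mirna_loci(mirnas, genes)
    inherited = inherit_host_tfs(loci, tf_gene)
    clusters = cluster_intergenic(
        [l for l in loci if l.group == "intergenic"], max_gap=max_gap
    )
    for c in clusters:
        c.promoter = cluster_promoter(c, upstream=upstream, downstream=downstream)
    scanned = map_tfbs_to_clusters(clusters, tfbs)
    merged = inherited | scanned
    logger.info("TF→miRNA candidates: %d inherited + %d promoter-scanned = %d unique",
                len(inherited), len(scanned), len(merged))
    return merged


# ---------------------------------------------------------------------------
# file dialects

def read_bed6(path) -> list[tuple[str, GenomicInterval]]:
    """BED6: chrom, start, end, name, score, strand."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        (row.name_, GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand))
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def read_wgrna(path) -> list[tuple[str, GenomicInterval]]:
    """UCSC wgRna-style table: leading bin column, then chrom, chromStart,
    chromEnd, name, score, strand, ... Coordinates are already 0-based
    half-open; the bin column is dropped."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out = []
    for row in frame.itertuples(index=False):
        _bin, chrom, start, end, name, _score, strand = row[:7]
        out.append((name, GenomicInterval(chrom, int(start), int(end), strand)))
    return out


def write_bed6(path, features: Sequence[tuple[str, GenomicInterval]]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, ivl in features:
            handle.write(
                f"{ivl.chrom}\t{ivl.start}\t{ivl.end}\t{name}\t0\t{ivl.strand}\n"
            )
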