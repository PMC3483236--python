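"""Synthetic study scenarios: planted regulatory truth, decoy candidates,
toy genome layout, and parallel expression matrices.

The generator emulates the inputs of an NCI-60-style panel study at desk
scale: a layered, acyclic true regulatory network whose TF efficacies are
uniform in ±[0.5, 2] (random sign) and miRNA efficacies in −[0.5, 2];
candidate supersets containing every true edge plus uniformly drawn
kind-legal decoys; log2 expression with root regulators i.i.d. N(0, 1) per
sample plus per-row baselines above the platform expression floors, and
each regulated molecule equal to its planted linear combination plus
Gaussian noise; and a single-chromosome genome layout with ~35% of miRNAs
embedded in host genes, the rest intergenic and partly clustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genome import (CandidateEdge, CandidateSet, GenomicInterval,
                     write_bed6)
from .topology import MotifType

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ["regulator", "regulator_kind", "target", "target_kind",
                 "efficacy"]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults mirror the reference study conditions: 59 samples, noise sd
    0.1 (log2 units), 20 true edges in a 200-edge candidate superset
    (decoy multiplier 9), 35% of miRNAs intragenic.
    """

    n_tf: int = 12
    n_mirna: int = 15
    n_gene: int = 50
    n_samples: int = 59
    n_tf_gene: int = 10
    n_mirna_gene: int = 7
    n_tf_mirna: int = 2
    n_tf_tf: int = 1
    decoy_multiplier: int = 9
    noise_sd: float = 0.1
    frac_intragenic: float = 0.35
    # expression baselines keep active rows above the platform floors
    mirna_baseline: tuple[float, float] = (4.0, 6.0)
    mrna_baseline: tuple[float, float] = (9.0, 12.0)
    n_inactive_mirna: int = 0
    n_inactive_mrna: int = 0
    # genome layout
    chrom: str = "chrSim"
    chrom_length: int = 3_000_000
    gene_length: int = 10_000
    mirna_length: int = 100
    cluster_gap: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_mirna", "n_gene", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_true_edges(self) -> int:
        return self.n_tf_gene + self.n_mirna_gene + self.n_tf_mirna + self.n_tf_tf

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tf + 1)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"mir-{i:03d}" for i in range(1, self.n_mirna + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_gene + 1)]


@dataclass
class SyntheticData:
    """Materialized scenario: truth, candidates and genome layout."""

    scenario: SyntheticScenario
    truth: pd.DataFrame                 # TRUTH_COLUMNS
    candidates: CandidateSet
    genes: list[tuple[str, GenomicInterval]]
    mirnas: list[tuple[str, GenomicInterval]]
    tfbs: list[tuple[str, GenomicInterval]]

    def truth_edges(self) -> set[tuple[str, str]]:
        return {(r.regulator, r.target) for r in self.truth.itertuples(index=False)}

    def write(self, outdir) -> dict[str, Path]:
        """Emit the file dialects the pipeline modules read."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "candidates": outdir / "candidates.tsv",
            "truth": outdir / "truth.tsv",
            "genes": outdir / "genes.bed",
            "mirnas": outdir / "mirnas.bed",
            "tfbs": outdir / "tfbs.bed",
            "tf_list": outdir / "tf_list.txt",
        }
        self.candidates.write_tsv(paths["candidates"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_bed6(paths["genes"], self.genes)
        write_bed6(paths["mirnas"], self.mirnas)
        write_bed6(paths["tfbs"], self.tfbs)
        paths["tf_list"].write_text(
            "".join(f"{t}\n" for t in self.scenario.tf_ids), encoding="utf-8")
        return paths


# ---------------------------------------------------------------------------
# truth + candidates

def _legal_pairs(sc: SyntheticScenario) -> dict[str, list[tuple]]:
    tfs, mirs, genes = sc.tf_ids, sc.mirna_ids, sc.gene_ids
    return {
        "TF->gene": [(t, "TF", g, "gene") for t in tfs for g in genes],
        "miRNA->gene": [(m, "miRNA", g, "gene") for m in mirs for g in genes],
        "TF->miRNA": [(t, "TF", m, "miRNA") for t in tfs for m in mirs],
        # forward-layered TF→TF keeps the true network acyclic; a TF target
        # is typed 'gene' (it is its mRNA that is regulated)
        "TF->TF": [(a, "TF", b, "gene")
                   for i, a in enumerate(tfs) for b in tfs[i + 1:]],
        # miRNA→TF pairs occur only as decoys (see decoy pool)
        "miRNA->TF": [(m, "miRNA", t, "gene") for m in mirs for t in tfs],
    }


def _draw_edges(pool, count, rng, taken):
    pool = [p for p in pool if (p[0], p[2]) not in taken]
    if count > len(pool):
        raise ValueError("not enough free regulator/target pairs")
    idx = rng.choice(len(pool), size=count, replace=False)
    chosen = [pool[i] for i in sorted(idx)]
    taken.update((p[0], p[2]) for p in chosen)
    return chosen


def generate_scenario(sc: SyntheticScenario) -> SyntheticData:
    """Draw the planted truth, the decoy superset and the genome layout.

    Reproducible from ``sc.seed``; every true edge is contained in the
    candidate set, and exactly ``decoy_multiplier`` × (number of truths)
    decoys are added from the kind-legal non-true pairs.
    """
    rng = np.random.default_rng(sc.seed)
    pairs = _legal_pairs(sc)
    taken: set[tuple[str, str]] = set()
    truths = []
    for key, count in (("TF->gene", sc.n_tf_gene),
                       ("miRNA->gene", sc.n_mirna_gene),
                       ("TF->miRNA", sc.n_tf_mirna),
                       ("TF->TF", sc.n_tf_tf)):
        for reg, rk, tgt, tk in _draw_edges(pairs[key], count, rng, taken):
            magnitude = rng.uniform(0.5, 2.0)
            if rk == "miRNA":
                eff = -magnitude
            else:
                eff = magnitude * (1 if rng.random() < 0.5 else -1)
            truths.append((reg, rk, tgt, tk, eff))
    truth = pd.DataFrame(truths, columns=TRUTH_COLUMNS)

    decoy_pool = [p for pool in pairs.values() for p in pool
                  if (p[0], p[2]) not in taken and p[0] != p[2]]
    n_decoys = sc.decoy_multiplier * len(truth)
    if n_decoys > len(decoy_pool):
        raise ValueError("decoy multiplier exceeds the legal pair pool")
    idx = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
    candidates = CandidateSet(
        CandidateEdge(*p) for p in truth[TRUTH_COLUMNS[:4]].itertuples(index=False))
    for i in sorted(idx):
        candidates.add(CandidateEdge(*decoy_pool[i]))

    genes, mirnas, tfbs = _generate_layout(sc, rng)
    logger.info("scenario seed=%d: %d true edges, %d candidates",
                sc.seed, len(truth), len(candidates))
    return SyntheticData(scenario=sc, truth=truth, candidates=candidates,
                         genes=genes, mirnas=mirnas, tfbs=tfbs)


def _generate_layout(sc: SyntheticScenario, rng: np.random.Generator):
    """Single-chromosome toy layout: evenly spaced genes, ~35% of miRNAs
    embedded in hosts (same strand), the rest intergenic with some adjacent
    pairs closer than the clustering gap, and one TFBS per cluster seed."""
    spacing = sc.chrom_length // (sc.n_gene + 1)
    if spacing <= sc.gene_length + 20_000:
        raise ValueError("chromosome too crowded for the requested gene count")
    genes = []
    for i, name in enumerate(sc.gene_ids):
        start = spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        genes.append((name, GenomicInterval(sc.chrom, start,
                                            start + sc.gene_length, strand)))
    n_intra = int(round(sc.frac_intragenic * sc.n_mirna))
    host_idx = rng.choice(sc.n_gene, size=n_intra, replace=False)
    mirnas = []
    for name, gi in zip(sc.mirna_ids[:n_intra], sorted(host_idx)):
        _gname, givl = genes[gi]
        start = givl.start + 2_000
        mirnas.append((name, GenomicInterval(sc.chrom, start,
                                             start + sc.mirna_length, givl.strand)))
    # intergenic: drop pairs midway between genes; every second locus is
    # placed within cluster_gap of its predecessor to seed 2-member clusters
    inter_ids = sc.mirna_ids[n_intra:]
    anchor = None
    placed = 0
    for j, name in enumerate(inter_ids):
        if j % 2 == 0:
            gap_idx = placed % (sc.n_gene - 1)
            left = genes[gap_idx][1].end
            right = genes[gap_idx + 1][1].start
            anchor = (left + right) // 2
            strand = "+" if gap_idx % 2 == 0 else "-"
            placed += 1
        else:
            anchor = anchor + sc.mirna_length + sc.cluster_gap
        mirnas.append((name, GenomicInterval(sc.chrom, anchor,
                                             anchor + sc.mirna_length, strand)))
    # one binding site inside each intergenic cluster promoter, TFs cycling
    tfbs = []
    for k, (name, ivl) in enumerate(m for m in mirnas if m[0] in set(inter_ids)):
        tf = sc.tf_ids[k % sc.n_tf]
        pos = max(0, ivl.tss - 500) if ivl.strand == "+" else ivl.tss + 480
        tfbs.append((tf, GenomicInterval(sc.chrom, pos, pos + 20, "+")))
    return genes, mirnas, tfbs


# ---------------------------------------------------------------------------
# expression

def generate_expression(
    data: SyntheticData, seed: int | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Realize the planted linear model as parallel expression matrices.

    Root molecules (no true regulator) are i.i.d. N(0, 1) per sample; every
    regulated molecule is the efficacy-weighted sum of its regulators plus
    N(0, noise_sd²), evaluated in topological order of the true network.
    Should planted motifs have introduced a directed cycle, the generative
    pass severs the last cycle-closing regulation (generation only — the
    emitted truth table is untouched). Per-row baselines lift values above
    the platform expression floors; optional inactive rows sit at a low
    constant to exercise the frequent-expression filter. Returns the
    (miRNA, mRNA) matrix pair with identical sample ids.
    """
    sc = data.scenario
    rng = np.random.default_rng(sc.seed + 1 if seed is None else seed)
    samples = [f"S{i:02d}" for i in range(1, sc.n_samples + 1)]

    regulators_of: dict[str, list[tuple[str, float]]] = {}
    for row in data.truth.itertuples(index=False):
        regulators_of.setdefault(row.target, []).append((row.regulator, row.efficacy))

    all_ids = sc.tf_ids + sc.mirna_ids + sc.gene_ids
    order, dropped = _topological_order(all_ids, regulators_of)
    if dropped:
        logger.warning("expression generation severed %d cycle-closing "
                       "regulation(s)", len(dropped))

    signal: dict[str, np.ndarray] = {}
    for mol in order:
        regs = [(r, e) for r, e in regulators_of.get(mol, ())
                if (r, mol) not in dropped]
        if not regs:
            signal[mol] = rng.normal(0.0, 1.0, sc.n_samples)
        else:
            value = rng.normal(0.0, sc.noise_sd, sc.n_samples) \
                if sc.noise_sd > 0 else np.zeros(sc.n_samples)
            for reg, eff in regs:
                value = value + eff * signal[reg]
            signal[mol] = value

    def build(ids, baseline, n_inactive, prefix, kind):
        lo, hi = baseline
        rows = {m: signal[m] + rng.uniform(lo, hi) for m in ids}
        floor = lo - 4.0
        for i in range(n_inactive):
            rows[f"{prefix}{i:03d}"] = np.full(sc.n_samples, floor)
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        return ExpressionMatrix(frame, kind=kind)

    mirna = build(sc.mirna_ids, sc.mirna_baseline, sc.n_inactive_mirna,
                  "inactive-mir-", "miRNA")
    mrna = build(sc.tf_ids + sc.gene_ids, sc.mrna_baseline, sc.n_inactive_mrna,
                 "INACTIVE", "mRNA")
    return mirna, mrna


def _topological_order(ids, regulators_of):
    """Kahn's algorithm; any residual cycle is broken by severing the
    regulation into the lexicographically first still-blocked molecule."""
    pending = {m: {r for r, _e in regulators_of.get(m, ()) if r != m}
               for m in ids}
    dropped: set[tuple[str, str]] = set()
    order: list[str] = []
    placed: set[str] = set()
    while len(order) < len(ids):
        ready = sorted(m for m in pending if m not in placed
                       and not (pending[m] - placed))
        if not ready:
            victim = min(m for m in pending if m not in placed)
            blocker = min(pending[victim] - placed)
            pending[victim].discard(blocker)
            dropped.add((blocker, victim))
            continue
        order.extend(ready)
        placed.update(ready)
    return order, dropped


# ---------------------------------------------------------------------------
# motif planting

def plant_motifs(
    data: SyntheticData, motif_type: MotifType, count: int,
    seed: int | None = None,
) -> SyntheticData:
    """Add ``count`` vertex-disjoint instances of a circuit type to the truth.

    Instances are built from vertices not touched by any existing true
    edge; efficacy magnitudes are uniform in [0.5, 2] with the type's signs.
    Raises when the scenario lacks enough free vertices of the needed kinds.
    The planted edges are appended to both the truth and the candidate set.
    """
    if count == 0:
        return data
    sc = data.scenario
    rng = np.random.default_rng(sc.seed + 7 if seed is None else seed)
    used = {v for pair in data.truth_edges() for v in pair}
    free = {
        "TF": [v for v in sc.tf_ids if v not in used],
        "miR": [v for v in sc.mirna_ids if v not in used],
        "gene": [v for v in sc.gene_ids if v not in used],
    }
    need = {k: motif_type.kinds.count(k) * count for k in ("TF", "miR", "gene")}
    for k, n in need.items():
        if len(free[k]) < n:
            raise ValueError(f"not enough free {k} vertices to plant {count} motifs")

    kind_token = {"TF": "TF", "miR": "miRNA", "gene": "gene"}
    if motif_type.skeleton == "FFL":
        arcs = [(0, 1), (1, 2), (0, 2)]
    else:
        arcs = [(0, 1), (1, 2), (2, 0)]
    new_rows = []
    new_edges = []
    for _ in range(count):
        nodes = [free[k].pop(0) for k in motif_type.kinds]
        for (i, j), sign in zip(arcs, motif_type.signs):
            reg, tgt = nodes[i], nodes[j]
            rk = kind_token[motif_type.kinds[i]]
            tk = kind_token[motif_type.kinds[j]]
            if tk == "TF":
                tk = "gene"  # a TF target is regulated through its mRNA
            eff = sign * rng.uniform(0.5, 2.0)
            new_rows.append((reg, rk, tgt, tk, eff))
            new_edges.append(CandidateEdge(reg, rk, tgt, tk))
    truth = pd.concat([data.truth, pd.DataFrame(new_rows, columns=TRUTH_COLUMNS)],
                      ignore_index=True)
    candidates = CandidateSet(iter(data.candidates))
    for e in new_edges:
        candidates.add(e)
    return replace(data, truth=truth, candidates=candidates)
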