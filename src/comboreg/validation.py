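"""Credibility assessment of the inferred network.

Three independent checks:

* Permutation FDR — rerun the whole inference on expression matrices whose
  values were randomly permuted within each dataset; edges recovered from
  permuted data are false discoveries by construction, and the per-type FDR
  is the mean permuted edge count over the real edge count.
* Jackknife predictability — leave one sample out, refit the entire
  pipeline (prefilter + selection) for a target, predict the held-out
  sample; the Pearson correlation between measured and predicted values
  measures the model's predictive power.
* Overlap enrichment — hypergeometric or exact binomial upper-tail tests of
  an annotated fraction in a selected set against a universe, for comparing
  validated-edge fractions or gene-set (e.g. cancer-census) overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .genome import CandidateSet
from .inference import (RegressionConfig, fit_target_model, infer_network,
                        prefilter_pairwise)

logger = logging.getLogger(__name__)


@dataclass
class FdrReport:
    """Per-regulation-type permutation false discovery rates.

    ``table`` has one row per edge type plus an 'overall' row, with columns
    mean_shuffled, sd_shuffled, real, fdr_percent, fdr_sd_percent. FDR is
    100 * mean_shuffled / real; NA when the real count is zero.
    """

    table: pd.DataFrame
    n_permutations: int

    @property
    def overall_fdr_percent(self) -> float:
        return float(self.table.loc["overall", "fdr_percent"])


def permute_matrix(
    m: ExpressionMatrix, rng: np.random.Generator, granularity: str = "cell"
) -> ExpressionMatrix:
    """Randomly permute expression values within one dataset.

    ``granularity="cell"`` shuffles the full value grid (destroys gene-wise
    and sample-wise structure alike); ``"row"`` shuffles each row's values
    across samples independently. Either way the dataset's multiset of
    values is preserved exactly.
    """
    values = m.values.copy()
    if granularity == "cell":
        flat = values.ravel()
        rng.shuffle(flat)
        shuffled = flat.reshape(values.shape)
    elif granularity == "row":
        shuffled = np.apply_along_axis(rng.permutation, 1, values)
    else:
        raise ValueError(f"unknown permutation granularity: {granularity!r}")
    return replace(m, data=pd.DataFrame(shuffled, index=m.data.index,
                                        columns=m.data.columns))


def permutation_fdr(
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    candidates: CandidateSet,
    tf_ids,
    cfg: RegressionConfig | None = None,
    n_perm: int = 100,
    seed: int = 0,
    granularity: str = "cell",
) -> FdrReport:
    """Estimate per-type and overall edge FDR by expression permutation."""
    cfg = cfg or RegressionConfig()
    real = infer_network(mirna_matrix, mrna_matrix, candidates, tf_ids, cfg)
    real_counts = real.edge_type_counts()
    types = sorted(set(real_counts) | {"miRNA->gene", "TF->gene", "TF->miRNA"})

    rng = np.random.default_rng(seed)
    shuffled_counts = {t: [] for t in types}
    overall = []
    for i in range(n_perm):
        mir_p = permute_matrix(mirna_matrix, rng, granularity)
        mrna_p = permute_matrix(mrna_matrix, rng, granularity)
        net = infer_network(mir_p, mrna_p, candidates, tf_ids, cfg)
        counts = net.edge_type_counts()
        for t in types:
            shuffled_counts[t].append(counts.get(t, 0))
        overall.append(len(net))

    rows = {}
    for t in types:
        arr = np.asarray(shuffled_counts[t], float)
        rows[t] = (arr.mean(), arr.std(ddof=1) if n_perm > 1 else 0.0,
                   real_counts.get(t, 0))
    arr = np.asarray(overall, float)
    rows["overall"] = (arr.mean(), arr.std(ddof=1) if n_perm > 1 else 0.0, len(real))

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_shuffled", "sd_shuffled", "real"])
    with np.errstate(divide="ignore", invalid="ignore"):
        table["fdr_percent"] = np.where(
            table["real"] > 0, 100.0 * table["mean_shuffled"] / table["real"], np.nan)
        table["fdr_sd_percent"] = np.where(
            table["real"] > 0, 100.0 * table["sd_shuffled"] / table["real"], np.nan)
    table.index.name = "regulation_type"
    return FdrReport(table=table, n_permutations=n_perm)


def jackknife_predictability(
    target_expr: np.ndarray,
    target: str,
    target_kind: str,
    regulators,
    cfg: RegressionConfig | None = None,
) -> float:
    """Leave-one-sample-out predictability of one target's model.

    ``regulators`` is a list of (id, kind, expression row) candidates. For
    every sample the whole modelling chain (prefilter, then multivariate
    selection) is refit on the remaining samples and the held-out value is
    predicted. Returns the Pearson correlation between the measured and
    predicted vectors; NaN when the prediction vector is constant.
    """
    cfg = cfg or RegressionConfig()
    y = np.asarray(target_expr, float)
    n = y.size
    if n < 4:
        raise ValueError("jackknife needs at least 4 samples")
    predicted = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        survivors = []
        for rid, kind, row in regulators:
            row = np.asarray(row, float)
            rec = prefilter_pairwise(y[keep], row[keep], kind, cfg,
                                     regulator=rid, target=target)
            if rec.kept:
                survivors.append((rid, kind, row))
        model = None
        if survivors:
            model = fit_target_model(
                y[keep], target, target_kind,
                [(rid, kind, row[keep]) for rid, kind, row in survivors], cfg)
        if model is None:
            predicted[i] = y[keep].mean()
            continue
        value = model.intercept
        by_id = {rid: row for rid, _k, row in survivors}
        for rid, _kind, eff, _p, _t in model.terms:
            value += eff * by_id[rid][i]
        predicted[i] = value
    if np.ptp(predicted) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(stats.pearsonr(y, predicted).statistic)


@dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int
    annotated_in_universe: int
    sample_size: int
    annotated_in_sample: int
    p_value: float
    mode: str

    @property
    def universe_fraction(self) -> float:
        return self.annotated_in_universe / self.universe_size

    @property
    def sample_fraction(self) -> float:
        return self.annotated_in_sample / self.sample_size


def enrichment_from_counts(
    universe_size: int,
    annotated_in_universe: int,
    sample_size: int,
    annotated_in_sample: int,
    mode: str = "hypergeometric",
    tail: str = "ge",
) -> EnrichmentResult:
    """Upper-tail enrichment test from raw counts.

    ``mode``: 'hypergeometric' (sampling without replacement from the
    universe) or 'binomial' (exact test against the universe fraction).
    ``tail``: 'ge' is the standard p value P(X ≥ observed); 'gt' gives the
    exceedance probability P(X > observed), the convention of R's
    ``phyper(..., lower.tail=FALSE)`` that some published analyses report.
    """
    if universe_size <= 0:
        raise ValueError("empty universe")
    if annotated_in_sample > min(sample_size, annotated_in_universe):
        raise ValueError("annotated-in-sample exceeds possible maximum")
    if tail not in ("ge", "gt"):
        raise ValueError(f"unknown tail: {tail!r}")
    k = annotated_in_sample if tail == "gt" else annotated_in_sample - 1
    if mode == "hypergeometric":
        p = float(stats.hypergeom.sf(k, universe_size, annotated_in_universe,
                                     sample_size))
    elif mode == "binomial":
        p0 = annotated_in_universe / universe_size
        if tail == "ge":
            p = stats.binomtest(annotated_in_sample, sample_size, p0,
                                alternative="greater").pvalue
        else:
            p = float(stats.binom.sf(annotated_in_sample, sample_size, p0))
    else:
        raise ValueError(f"unknown enrichment mode: {mode!r}")
    return EnrichmentResult(universe_size, annotated_in_universe,
                            sample_size, annotated_in_sample, float(p), mode)


def overlap_enrichment(
    universe: set, annotated: set, sample: set,
    mode: str = "hypergeometric", tail: str = "ge",
) -> EnrichmentResult:
    """Enrichment of ``annotated`` items within ``sample`` drawn from
    ``universe`` (``sample`` must be a subset of the universe)."""
    universe, sample = set(universe), set(sample)
    if not sample <= universe:
        raise ValueError("sample must be a subset of the universe")
    annotated_u = set(annotated) & universe
    return enrichment_from_counts(
        len(universe), len(annotated_u), len(sample), len(annotated_u & sample),
        mode=mode, tail=tail,
    )


def validated_fraction(
    edges: pd.DataFrame, gold: set[tuple[str, str]]
) -> tuple[int, int]:
    """(total edges, edges present in a gold-standard pair list); pairs are
    matched after upper-casing both identifiers."""
    normalized = {(r.upper(), t.upper()) for r, t in gold}
    hits = sum(
        (row.regulator.upper(), row.target.upper()) in normalized
        for row in edges.itertuples(index=False)
    )
    return len(edges), hits
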