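"""Network inference by linear-regression filtering of candidate regulations.

The model treats each target molecule's log2 expression level across samples
as a linear function of its candidate regulators' expression levels:

* Pairwise prefilter — a single-regressor OLS of the target on each
  candidate regulator; the candidate survives only if the slope ("regulatory
  efficacy") is significant at ``alpha1`` (two-sided), and for miRNA
  regulators additionally negative, because miRNAs are modelled as acting
  purely by target-mRNA degradation.
* Multivariate selection — the surviving regulators of each target enter a
  multivariate linear model; stepwise selection (bidirectional, AIC) or the
  LASSO (10-fold CV, 1-SE rule, support refit by OLS) picks the ultimate
  regulators. miRNA targets may only have TF regressors.
* Sign elimination — if the final model of a target contains any miRNA term
  with positive efficacy, *all* of that target's regulations are discarded.

Edges carry the partial t statistic and p value of the refitted final model
and a credibility tier (high p<0.01 / medium p<0.05 / low otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .expression import ExpressionMatrix
from .genome import CandidateSet
from .network import RegulatoryEdge, RegulatoryNetwork

logger = logging.getLogger(__name__)

METHODS = ("step", "lasso")


@dataclass(frozen=True)
class RegressionConfig:
    """Knobs of the inference algorithm.

    alpha1
        Significance level of the pairwise prefilter; a candidate with
        slope p value ≤ alpha1 is kept (closed boundary).
    method
        ``"step"`` (bidirectional AIC stepwise, the default) or ``"lasso"``.
    lasso_cv_folds
        Folds for the LASSO penalty cross-validation (1-SE rule).
    random_seed
        Seeds the CV fold shuffling; the stepwise path is deterministic.
    """

    alpha1: float = 0.05
    method: str = "step"
    lasso_cv_folds: int = 10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha1 < 1:
            raise ValueError("alpha1 must be in (0, 1)")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


@dataclass(frozen=True)
class PrefilterRecord:
    regulator: str
    target: str
    efficacy: float
    p_value: float
    kept: bool
    degenerate: bool = False


@dataclass
class TargetModel:
    """Final multivariate model of one target: selected terms + intercept."""

    target: str
    target_kind: str
    terms: list[tuple[str, str, float, float, float]]  # (id, kind, efficacy, p, t)
    intercept: float


def prefilter_pairwise(
    target_expr: np.ndarray,
    regulator_expr: np.ndarray,
    regulator_kind: str,
    cfg: RegressionConfig,
    regulator: str = "",
    target: str = "",
) -> PrefilterRecord:
    """Single-regressor OLS screen of one candidate pair.

    Kept iff the two-sided slope p value is ≤ ``cfg.alpha1`` and, for a
    miRNA regulator, the slope is negative. A zero-variance regulator is
    flagged degenerate and dropped.
    """
    y = np.asarray(target_expr, float)
    x = np.asarray(regulator_expr, float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("expression rows must share ≥3 samples")
    if np.ptp(x) == 0.0:
        return PrefilterRecord(regulator, target, np.nan, np.nan,
                               kept=False, degenerate=True)
    fit = stats.linregress(x, y)
    slope, p = float(fit.slope), float(fit.pvalue)
    if np.isnan(p):  # zero-variance target: no testable relation
        return PrefilterRecord(regulator, target, slope, np.nan,
                               kept=False, degenerate=True)
    kept = p <= cfg.alpha1
    if regulator_kind == "miRNA":
        kept = kept and slope < 0
    return PrefilterRecord(regulator, target, slope, p, kept=kept)


def _design(x_cols: list[np.ndarray]) -> np.ndarray:
    return sm.add_constant(np.column_stack(x_cols), has_constant="add")


def _drop_collinear(
    regulators: list[tuple[str, str, np.ndarray]], n: int
) -> list[tuple[str, str, np.ndarray]]:
    """Greedily drop regressors that add no rank, scanning in id order."""
    kept: list[tuple[str, str, np.ndarray]] = []
    basis: list[np.ndarray] = [np.ones(n)]
    rank = 1
    for reg in sorted(regulators, key=lambda r: r[0]):
        trial = basis + [reg[2]]
        new_rank = np.linalg.matrix_rank(np.column_stack(trial))
        if new_rank > rank:
            kept.append(reg)
            basis, rank = trial, new_rank
        else:
            logger.info("dropping collinear regulator %s for target model", reg[0])
    return kept


def _stepwise_select(y: np.ndarray, regulators, max_terms: int) -> list[int]:
    """Bidirectional stepwise selection minimising AIC, from intercept-only."""
    selected: list[int] = []
    current = sm.OLS(y, np.ones((y.size, 1))).fit().aic

    def aic_of(indices: list[int]) -> float:
        X = _design([regulators[i][2] for i in indices])
        return sm.OLS(y, X).fit().aic

    while True:
        best_move, best_aic = None, current
        for i in range(len(regulators)):
            if i in selected:
                continue
            if len(selected) + 2 >= y.size or len(selected) >= max_terms:
                continue
            a = aic_of(sorted(selected + [i]))
            if a < best_aic - 1e-10:
                best_move, best_aic = ("add", i), a
        for i in selected:
            trial = [j for j in selected if j != i]
            a = (aic_of(trial) if trial
                 else sm.OLS(y, np.ones((y.size, 1))).fit().aic)
            if a < best_aic - 1e-10:
                best_move, best_aic = ("drop", i), a
        if best_move is None:
            return sorted(selected)
        kind, i = best_move
        selected = sorted(selected + [i]) if kind == "add" else [j for j in selected if j != i]
        current = best_aic


def _lasso_select(y: np.ndarray, regulators, cfg: RegressionConfig) -> list[int]:
    """LASSO support at the 1-SE penalty from 10-fold cross-validation."""
    X = np.column_stack([r[2] for r in regulators])
    n = y.size
    folds = min(cfg.lasso_cv_folds, n)
    cv = KFold(n_splits=folds, shuffle=True, random_state=cfg.random_seed)
    lcv = LassoCV(cv=cv, alphas=100, max_iter=50_000).fit(X, y)
    mean_mse = lcv.mse_path_.mean(axis=1)
    se_mse = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
    i_min = int(np.argmin(mean_mse))
    ceiling = mean_mse[i_min] + se_mse[i_min]
    # alphas_ descend; pick the sparsest (largest) penalty within one SE
    within = np.flatnonzero(mean_mse <= ceiling)
    alpha_1se = float(lcv.alphas_[within.min()])
    coefs = Lasso(alpha=alpha_1se, max_iter=50_000).fit(X, y).coef_
    return [i for i in range(len(regulators)) if coefs[i] != 0.0]


def fit_target_model(
    target_expr: np.ndarray,
    target: str,
    target_kind: str,
    surviving_regulators: Sequence[tuple[str, str, np.ndarray]],
    cfg: RegressionConfig,
) -> TargetModel | None:
    """Select and refit the multivariate model of one target.

    ``surviving_regulators`` are (id, kind, expression-row) triples that
    passed the prefilter for this target. Returns ``None`` when the target
    is eliminated: either nothing is selected, or the final model contains a
    miRNA term with positive efficacy (which voids every term of the
    target).
    """
    y = np.asarray(target_expr, float)
    if target_kind == "miRNA":
        surviving_regulators = [r for r in surviving_regulators if r[1] == "TF"]
    regulators = _drop_collinear(
        [(rid, kind, np.asarray(row, float)) for rid, kind, row in surviving_regulators],
        n=y.size,
    )
    if not regulators:
        return None
    max_terms = y.size - 2
    if cfg.method == "step":
        support = _stepwise_select(y, regulators, max_terms)
    else:
        support = _lasso_select(y, regulators, cfg)
        if len(support) > max_terms:  # keep the refit well-posed
            support = support[:max_terms]
    if not support:
        return None
    chosen = [regulators[i] for i in support]
    X = _design([r[2] for r in chosen])
    fit = sm.OLS(y, X).fit()
    terms = [
        (rid, kind, float(fit.params[j + 1]), float(fit.pvalues[j + 1]),
         float(fit.tvalues[j + 1]))
        for j, (rid, kind, _row) in enumerate(chosen)
    ]
    if any(kind == "miRNA" and eff > 0 for _id, kind, eff, _p, _t in terms):
        logger.info("target %s eliminated: positive miRNA efficacy in final model",
                    target)
        return None
    return TargetModel(target=target, target_kind=target_kind, terms=terms,
                       intercept=float(fit.params[0]))


def build_network(
    models: Sequence[TargetModel], tf_ids=()
) -> RegulatoryNetwork:
    """Assemble the edge table: one signed, tiered edge per retained term."""
    edges = []
    for model in models:
        for rid, kind, eff, p, t in model.terms:
            edges.append(RegulatoryEdge(
                regulator=rid, regulator_kind=kind,
                target=model.target, target_kind=model.target_kind,
                efficacy=eff, t_statistic=t, p_value=p,
            ))
    net = RegulatoryNetwork.from_edges(edges, tf_ids=tf_ids)
    net.edges = net.edges.sort_values(
        ["target", "regulator"], kind="stable", ignore_index=True)
    return net


def infer_network(
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    candidates: CandidateSet,
    tf_ids,
    cfg: RegressionConfig | None = None,
) -> RegulatoryNetwork:
    """Run the full inference: prefilter → per-target selection → edge table.

    Both matrices must cover the same samples (order may differ; the miRNA
    matrix is re-indexed to the mRNA sample order). Candidates whose
    regulator or target has no expression row are unusable and logged.
    Self-regulation candidates are excluded before the prefilter.
    Deterministic given ``cfg.random_seed``.
    """
    cfg = cfg or RegressionConfig()
    if set(mirna_matrix.sample_ids) != set(mrna_matrix.sample_ids):
        raise ValueError("miRNA and mRNA matrices cover different sample sets")
    mirna = mirna_matrix.data.reindex(columns=mrna_matrix.sample_ids)
    mrna = mrna_matrix.data
    tf_ids = frozenset(tf_ids)

    def expr_of(mol_id: str, kind: str) -> np.ndarray | None:
        table = mirna if kind == "miRNA" else mrna
        if mol_id in table.index:
            return table.loc[mol_id].to_numpy()
        return None

    per_target: dict[tuple[str, str], list] = {}
    n_unusable = 0
    for edge in candidates:
        if edge.regulator == edge.target:
            continue
        per_target.setdefault((edge.target, edge.target_kind), []).append(edge)

    models = []
    n_prefiltered = 0
    for (target, target_kind), cand_edges in sorted(per_target.items()):
        y = expr_of(target, target_kind)
        if y is None:
            n_unusable += len(cand_edges)
            continue
        survivors = []
        for edge in sorted(cand_edges):
            x = expr_of(edge.regulator, edge.regulator_kind)
            if x is None:
                n_unusable += 1
                continue
            rec = prefilter_pairwise(y, x, edge.regulator_kind, cfg,
                                     regulator=edge.regulator, target=target)
            if rec.kept:
                survivors.append((edge.regulator, edge.regulator_kind, x))
        n_prefiltered += len(survivors)
        if not survivors:
            continue
        model = fit_target_model(y, target, target_kind, survivors, cfg)
        if model is not None:
            models.append(model)

    net = build_network(models, tf_ids=tf_ids)
    logger.info(
        "inference: %d candidates (%d unusable), %d pairs past prefilter, "
        "%d edges in final network (%s)",
        len(candidates), n_unusable, n_prefiltered, len(net),
        net.edge_type_counts(),
    )
    return net
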