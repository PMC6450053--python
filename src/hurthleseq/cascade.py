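"""Cascading benign/suspicious decision logic with Hurthle-adjusted threshold rescue.

For sample *i* with Hurthle-index score ``H_i``, neoplasm-index score
``N_i`` and core benign/suspicious ensemble score ``BS_i``, the call is:

1. **Benign** if ``BS_i < t_BS_nominal``; otherwise
2. initially Suspicious, but **reassigned to Benign** ("rescued") if
   ``H_i > t_H`` and ``N_i < t_N`` and ``t_BS_nominal <= BS_i < t_BS_Hurthle``;
   otherwise
3. **Suspicious**.

The rescue exploits biology: Hurthle cells without neoplasia should be
benign, so Hurthle-positive, neoplasm-negative samples are granted a more
tolerant (higher) benign/suspicious cutoff rather than an automatic benign
call. All inequalities are strict/non-strict exactly as written above.

Thresholds are never hard-coded: they are learned by an exhaustive grid
search over score quantiles that maximizes overall specificity subject to a
sensitivity floor (default > 90%), or supplied via configuration.

This module also provides a documented stand-in for the core B/S ensemble
(a small bagged ensemble of linear SVMs over DE-selected genes whose mean
decision value is the BS score) and the end-to-end training/scoring
pipeline over a cohort.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import expression as expr
from .variant_loh import NI_CHROMOSOMES, VariantSet, loh_feature_table
from .classifiers import CVReport, IndexModel

logger = logging.getLogger(__name__)

BENIGN = "Benign"
SUSPICIOUS = "Suspicious"


@dataclass
class CascadeConfig:
    """The four decision thresholds (plus optional references to the scorers)."""

    t_h: float
    t_n: float
    t_bs_nominal: float
    t_bs_hurthle: float
    hi_model: IndexModel | None = None
    ni_model: IndexModel | None = None
    bs_scorer: "BaggedBSScorer | None" = None

    def __post_init__(self) -> None:
        if self.t_bs_hurthle < self.t_bs_nominal:
            raise ValueError(
                "the Hurthle-adjusted threshold must not be below the nominal one"
            )

    def thresholds_dict(self) -> dict[str, float]:
        return {
            "t_h": self.t_h,
            "t_n": self.t_n,
            "t_bs_nominal": self.t_bs_nominal,
            "t_bs_hurthle": self.t_bs_hurthle,
        }


@dataclass
class CascadeResult:
    """The call for one sample; ``n`` is None for Hurthle-index-negative samples."""

    sample_id: str
    h: float
    n: float | None
    bs: float
    call: str
    rescue_flag: bool
    rule_fired: int

    def __post_init__(self) -> None:
        if self.rescue_flag and (self.call != BENIGN or self.rule_fired != 2):
            raise ValueError("rescue implies a rule-2 benign call")


def cascade_call(
    h: float,
    n: float | None,
    bs: float,
    config: CascadeConfig,
    sample_id: str = "",
) -> CascadeResult:
    """Apply the three-rule decision logic to one sample's score triple.

    ``n`` may be None (or NaN) only when the sample is Hurthle-index
    negative (``h <= t_h``); rule 2 never consults it in that case.
    """
    for name, value in (("H", h), ("BS", bs)):
        if value is None or not math.isfinite(value):
            raise ValueError(f"{name} score must be finite, got {value!r}")
    if bs < config.t_bs_nominal:
        return CascadeResult(sample_id, h, n, bs, BENIGN, False, 1)
    hi_positive = h > config.t_h
    if hi_positive and (n is None or not math.isfinite(n)):
        raise ValueError(
            f"sample {sample_id or '<unnamed>'}: missing N score for a "
            "Hurthle-index-positive sample"
        )
    if (
        hi_positive
        and n < config.t_n
        and config.t_bs_nominal <= bs < config.t_bs_hurthle
    ):
        return CascadeResult(sample_id, h, n, bs, BENIGN, True, 2)
    return CascadeResult(sample_id, h, n if hi_positive else n, bs, SUSPICIOUS, False, 3)


def _benign_mask(
    h: np.ndarray, n: np.ndarray, bs: np.ndarray,
    t_h: float, t_n: float, t_nom: float, t_bsh: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized calls: (benign mask, rescue mask)."""
    rule1 = bs < t_nom
    rescue = (~rule1) & (h > t_h) & (n < t_n) & (bs < t_bsh)
    return rule1 | rescue, rescue


# ---------------------------------------------------------------------------
# Stand-in core benign/suspicious scorer
# ---------------------------------------------------------------------------

@dataclass
class BaggedBSScorer:
    """Stand-in for the core benign/suspicious ensemble.

    A bagged ensemble of linear SVMs trained on bootstrap resamples of the
    cohort over DE-selected genes; the BS score is the mean decision value.
    Interface-compatible with any future faithful ensemble: it only needs a
    ``scores(features)`` method and a ``feature_names`` attribute.
    """

    models: list[IndexModel]
    feature_names: list[str]
    cost: float
    seed: int

    def scores(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            features = features.loc[:, self.feature_names]
        return np.mean([m.decision_scores(features) for m in self.models], axis=0)


def standin_bs_scorer(
    features,
    labels,
    seed: int = 0,
    n_models: int = 12,
    cost_grid: Sequence[float] = clf.DEFAULT_COST_GRID,
    cv_folds: int = 5,
) -> BaggedBSScorer:
    """Fit the stand-in B/S ensemble (deterministic given data and seed).

    A single cost is chosen for all ensemble members by stratified
    cross-validated AUC on the full data, then ``n_models`` linear SVMs are
    trained on bootstrap resamples (redrawn until both classes are present).
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)

    from sklearn.model_selection import StratifiedKFold

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mean_aucs = []
    for cost in cost_grid:
        aucs = []
        for tr, te in cv.split(X, y):
            model = clf.train_linear_svm(X[tr], y[tr], cost, feature_names=names)
            aucs.append(clf.roc_auc(model.decision_scores(X[te]), y[te]))
        mean_aucs.append(np.mean(aucs))
    best = min(
        range(len(cost_grid)),
        key=lambda i: (-np.round(mean_aucs[i], 12), cost_grid[i]),
    )
    cost = float(cost_grid[best])

    models = []
    n = len(y)
    for _ in range(n_models):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2 and np.bincount(y[idx]).min() >= 2:
                break
        else:
            raise RuntimeError("could not draw a bootstrap sample with both classes")
        models.append(clf.train_linear_svm(X[idx], y[idx], cost, feature_names=names))
    logger.info("stand-in B/S ensemble: %d models, cost %g", n_models, cost)
    return BaggedBSScorer(models=models, feature_names=names, cost=cost, seed=seed)


def tune_nominal_threshold(
    bs_scores, truth_malignant, sensitivity_floor: float = 0.90
) -> float:
    """Largest nominal threshold keeping B/S-alone sensitivity above the floor.

    Suspicious means ``BS >= t``, so raising t converts calls to benign;
    this picks the most specific threshold whose sensitivity still exceeds
    the floor (falls back to the most sensitive threshold with a warning if
    no candidate passes).
    """
    bs = np.asarray(bs_scores, dtype=float)
    y = np.asarray(truth_malignant).astype(bool)
    candidates = np.unique(bs)
    best, best_key = None, None
    for t in candidates:
        sens = float((bs[y] >= t).mean())
        if sens > sensitivity_floor:
            spec = float((bs[~y] < t).mean())
            key = (spec, sens)  # most specific, ties to the more sensitive
            if best_key is None or key > best_key:
                best, best_key = t, key
    if best is None:
        warnings.warn(
            "no nominal threshold meets the sensitivity floor; using the minimum score",
            RuntimeWarning,
        )
        best = float(candidates.min())
    return float(best)


@dataclass
class OptimizationReport:
    """Training performance of the selected cascade configuration."""

    sensitivity: float
    specificity: float
    floor_met: bool
    n_rescued: int
    sensitivity_floor: float
    n_configs_evaluated: int


def optimize_thresholds(
    h_scores,
    n_scores,
    bs_scores,
    truth_malignant,
    t_bs_nominal: float | None = None,
    sensitivity_floor: float = 0.90,
    n_quantiles: int = 50,
    optimize_nominal: bool = False,
) -> tuple[CascadeConfig, OptimizationReport]:
    """Exhaustive quantile-grid search for the cascade thresholds.

    Maximizes overall training specificity among configurations whose
    overall sensitivity exceeds ``sensitivity_floor`` (malignant =
    positive = should be Suspicious); ties break toward higher sensitivity,
    then smaller ``t_bs_hurthle``. ``t_bs_nominal`` is normally fixed
    beforehand by the B/S scorer's own sensitivity-targeted tuning; with
    ``optimize_nominal=True`` it joins the grid as a fourth axis.

    If no configuration meets the floor, the maximum-sensitivity
    configuration is returned with a warning.
    """
    h = np.asarray(h_scores, dtype=float)
    n = np.asarray(n_scores, dtype=float)
    bs = np.asarray(bs_scores, dtype=float)
    y = np.asarray(truth_malignant).astype(bool)
    if not (len(h) == len(n) == len(bs) == len(y)):
        raise ValueError("score vectors and labels must have equal length")
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(n)) and np.all(np.isfinite(bs))):
        raise ValueError("scores must be finite")

    if t_bs_nominal is None and not optimize_nominal:
        t_bs_nominal = tune_nominal_threshold(bs, y, sensitivity_floor)

    qs = np.linspace(0.0, 1.0, n_quantiles)
    h_grid = np.unique(np.quantile(h, qs))
    n_grid = np.unique(np.quantile(n, qs))
    if optimize_nominal:
        nom_grid = np.unique(np.quantile(bs, qs))
    else:
        nom_grid = np.array([t_bs_nominal])

    n_mal = int(y.sum())
    n_ben = int((~y).sum())
    if n_mal == 0 or n_ben == 0:
        raise ValueError("need both benign and malignant truth labels")

    best_key = None
    best_cfg = None
    best_perf = None
    fallback_key = None
    fallback_cfg = None
    fallback_perf = None
    n_evaluated = 0

    for t_nom in nom_grid:
        rule1 = bs < t_nom
        r1_ben = int(rule1[~y].sum())   # benign-histology samples already benign-called
        r1_mal = int(rule1[y].sum())
        bsh_grid = np.concatenate([[t_nom], np.unique(bs[bs >= t_nom])])
        bsh_grid = np.unique(np.quantile(bsh_grid, qs)) if len(bsh_grid) > n_quantiles \
            else np.unique(bsh_grid)
        for t_h in h_grid:
            hi_pos = h > t_h
            for t_n in n_grid:
                eligible = (~rule1) & hi_pos & (n < t_n)
                el_ben = np.sort(bs[eligible & ~y])
                el_mal = np.sort(bs[eligible & y])
                for t_bsh in bsh_grid:
                    n_evaluated += 1
                    resc_ben = int(np.searchsorted(el_ben, t_bsh, side="left"))
                    resc_mal = int(np.searchsorted(el_mal, t_bsh, side="left"))
                    spec = (r1_ben + resc_ben) / n_ben
                    sens = (n_mal - r1_mal - resc_mal) / n_mal
                    key = (spec, sens, -t_bsh)
                    if fallback_key is None or (sens, spec) > fallback_perf:
                        fallback_perf = (sens, spec)
                        fallback_key = key
                        fallback_cfg = (t_h, t_n, t_nom, t_bsh)
                    if sens > sensitivity_floor and (
                        best_key is None or key > best_key
                    ):
                        best_key = key
                        best_cfg = (t_h, t_n, t_nom, t_bsh)
                        best_perf = (sens, spec)

    floor_met = best_cfg is not None
    if not floor_met:
        warnings.warn(
            "no threshold configuration meets the sensitivity floor; "
            "returning the maximum-sensitivity configuration",
            RuntimeWarning,
        )
        best_cfg, best_perf = fallback_cfg, fallback_perf
        sens, spec = best_perf
    else:
        sens, spec = best_perf

    t_h, t_n, t_nom, t_bsh = best_cfg
    config = CascadeConfig(
        t_h=float(t_h), t_n=float(t_n),
        t_bs_nominal=float(t_nom), t_bs_hurthle=float(t_bsh),
    )
    benign, rescue = _benign_mask(h, n, bs, *best_cfg)
    report = OptimizationReport(
        sensitivity=float(sens),
        specificity=float(spec),
        floor_met=floor_met,
        n_rescued=int(rescue.sum()),
        sensitivity_floor=sensitivity_floor,
        n_configs_evaluated=n_evaluated,
    )
    logger.info(
        "threshold optimizer: sens %.3f spec %.3f rescued %d (floor %s)",
        sens, spec, report.n_rescued, "met" if floor_met else "NOT met",
    )
    return config, report


# ---------------------------------------------------------------------------
# End-to-end training and scoring
# ---------------------------------------------------------------------------

@dataclass
class TrainedCascade:
    """Everything needed to score a cohort, plus training diagnostics."""

    hi_model: IndexModel
    ni_model: IndexModel
    bs_scorer: BaggedBSScorer
    config: CascadeConfig
    hi_genes: list[str]
    ni_genes: list[str]
    loh_feature_names: list[str]
    cv_reports: dict[str, CVReport]
    optimization: OptimizationReport
    seed: int


def _hi_feature_frame(vst: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    return vst.loc[list(genes)].T


def _ni_feature_frame(
    vst: pd.DataFrame, genes: Sequence[str], loh_features: pd.DataFrame,
    include_loh: bool = True,
) -> pd.DataFrame:
    X = vst.loc[list(genes)].T
    if include_loh:
        X = pd.concat([X, loh_features.loc[X.index]], axis=1)
    return X


def train_cascade(
    expression: expr.ExpressionMatrix,
    variant_sets: Mapping[str, VariantSet],
    labels: pd.DataFrame,
    seed: int = 0,
    sensitivity_floor: float = 0.90,
    include_loh: bool = True,
    n_quantiles: int = 50,
    de_backend: str = "exact",
) -> TrainedCascade:
    """Train the full cascade on a labelled cohort.

    ``labels`` must be indexed by sample_id with boolean columns ``hurthle``,
    ``neoplasm``, ``ni_labelled`` and a ``histology`` column with values
    benign/malignant. Samples missing from ``variant_sets`` get their LOH
    features imputed as 0 with a log message.

    Steps: VST normalization; DE-based feature selection for each index
    (Hurthle contrast over all samples with the 13 mitochondrial
    protein-coding genes force-included; neoplasm contrast over the
    NI-labelled Hurthle-positive subset, augmented with the 16 LOH
    features); nested-CV-tuned linear SVM per index; stand-in B/S ensemble
    on the histology contrast; threshold optimization on training scores
    under the sensitivity floor.
    """
    labels = labels.loc[expression.sample_ids]
    hurthle = labels["hurthle"].astype(bool)
    malignant = (labels["histology"] == "malignant").to_numpy()

    sf = expr.size_factors(expression, pseudo_reference=True)
    vst = expr.vst_transform(expression, sf)

    # --- Hurthle index -----------------------------------------------------
    mito = expr.mito_gene_set(expression.annotation)
    de_h = expr.differential_expression(expression, hurthle, backend=de_backend)
    hi_genes = expr.select_features(de_h, force_include=mito)
    X_hi = _hi_feature_frame(vst, hi_genes)
    hi_folds = min(10, int(min(hurthle.sum(), (~hurthle).sum())))
    if hi_folds < 10:
        logger.warning("reducing HI outer CV folds to %d (small class)", hi_folds)
    hi_model, hi_report = clf.fit_index_model(
        X_hi, hurthle.to_numpy(), seed=seed, outer_folds=hi_folds
    )

    # --- Neoplasm index (NI-labelled Hurthle-positive subset) --------------
    ni_mask = labels["ni_labelled"].astype(bool) & hurthle
    ni_samples = labels.index[ni_mask]
    neoplasm = labels.loc[ni_samples, "neoplasm"].astype(bool)
    sub_counts = expression.counts[ni_samples]
    sub_matrix = expr.ExpressionMatrix(
        counts=sub_counts, annotation=expression.annotation
    )
    de_n = expr.differential_expression(sub_matrix, neoplasm, backend=de_backend)
    try:
        ni_genes = expr.select_features(de_n)
    except ValueError:
        logger.warning(
            "neoplasm contrast yielded no genes at the default thresholds; "
            "keeping the top 25 by p-value"
        )
        ni_genes = list(de_n.table.nsmallest(25, "p_value").index)

    missing = [s for s in expression.sample_ids if s not in variant_sets]
    if missing:
        logger.warning(
            "%d sample(s) missing variant calls; LOH features imputed as 0 "
            "(e.g. %s)", len(missing), missing[:3],
        )
    loh_features = loh_feature_table(
        {s: variant_sets[s] for s in expression.sample_ids if s in variant_sets},
        NI_CHROMOSOMES, impute=0.0,
    ).reindex(expression.sample_ids, fill_value=0.0)

    X_ni = _ni_feature_frame(vst, ni_genes, loh_features, include_loh)
    ni_folds = min(10, int(min(neoplasm.sum(), (~neoplasm).sum())))
    if ni_folds < 10:
        logger.warning("reducing NI outer CV folds to %d (small class)", ni_folds)
    ni_model, ni_report = clf.fit_index_model(
        X_ni.loc[ni_samples], neoplasm.to_numpy(), seed=seed + 1, outer_folds=ni_folds
    )

    # --- stand-in core B/S ensemble ----------------------------------------
    de_bm = expr.differential_expression(expression, pd.Series(malignant,
                                         index=labels.index), backend=de_backend)
    try:
        bs_genes = expr.select_features(de_bm, lfc_cut=0.0, max_genes=200)
    except ValueError:
        logger.warning(
            "histology contrast yielded no FDR-significant genes; "
            "keeping the top 50 by p-value"
        )
        bs_genes = list(de_bm.table.nsmallest(50, "p_value").index)
    X_bs = vst.loc[bs_genes].T
    bs_scorer = standin_bs_scorer(X_bs, malignant.astype(int), seed=seed + 2)

    # --- training scores and threshold optimization ------------------------
    h_scores = hi_model.decision_scores(X_hi)
    n_scores = ni_model.decision_scores(X_ni)
    bs_scores = bs_scorer.scores(X_bs)
    t_nom = tune_nominal_threshold(bs_scores, malignant, sensitivity_floor)
    config, opt_report = optimize_thresholds(
        h_scores, n_scores, bs_scores, malignant,
        t_bs_nominal=t_nom, sensitivity_floor=sensitivity_floor,
        n_quantiles=n_quantiles,
    )
    config.hi_model = hi_model
    config.ni_model = ni_model
    config.bs_scorer = bs_scorer

    return TrainedCascade(
        hi_model=hi_model,
        ni_model=ni_model,
        bs_scorer=bs_scorer,
        config=config,
        hi_genes=list(hi_genes),
        ni_genes=list(ni_genes),
        loh_feature_names=list(loh_features.columns) if include_loh else [],
        cv_reports={"hi": hi_report, "ni": ni_report},
        optimization=opt_report,
        seed=seed,
    )


def score_cohort(
    trained: TrainedCascade,
    expression: expr.ExpressionMatrix,
    variant_sets: Mapping[str, VariantSet],
) -> pd.DataFrame:
    """Score every sample and apply the cascade; one row per sample.

    The neoplasm-index score is reported only for Hurthle-index-positive
    samples (for HI-negative samples it is recorded as absent, not zero);
    internally it is computed for all samples so rule 2 is always decidable.
    """
    if expression.normalized is None:
        expr.vst_transform(expression)
    vst = expression.normalized
    loh_features = loh_feature_table(
        {s: variant_sets[s] for s in expression.sample_ids if s in variant_sets},
        NI_CHROMOSOMES, impute=0.0,
    ).reindex(expression.sample_ids, fill_value=0.0)
    X_hi = _hi_feature_frame(vst, trained.hi_genes)
    include_loh = bool(trained.loh_feature_names)
    X_ni = _ni_feature_frame(vst, trained.ni_genes, loh_features, include_loh)
    X_bs = vst.loc[trained.bs_scorer.feature_names].T

    h = trained.hi_model.decision_scores(X_hi)
    n = trained.ni_model.decision_scores(X_ni)
    bs = trained.bs_scorer.scores(X_bs)

    rows = []
    for i, sid in enumerate(expression.sample_ids):
        res = cascade_call(float(h[i]), float(n[i]), float(bs[i]),
                           trained.config, sample_id=sid)
        hi_positive = h[i] > trained.config.t_h
        rows.append(
            {
                "sample_id": sid,
                "H": res.h,
                "N": res.n if hi_positive else np.nan,
                "BS": res.bs,
                "call": res.call,
                "rescue_flag": res.rescue_flag,
                "rule_fired": res.rule_fired,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def run_pipeline(
    cohort_dir,
    out_dir,
    seed: int = 0,
    sensitivity_floor: float = 0.90,
    n_quantiles: int = 50,
    write_figures: bool = True,
) -> pd.DataFrame:
    """Train on a cohort directory, score it, and write results + report.

    The cohort directory must follow the :func:`hurthleseq.synthdata.write_cohort`
    layout (counts.tsv, annotation.tsv, labels.tsv, vcf/<sample>.vcf).
    Writes ``results.tsv``, ``report.txt``, ``thresholds.json`` and, when
    ``write_figures`` is set, score-distribution / ROC / LOH-heatmap PNGs.
    """
    from .synthdata import read_cohort
    from . import reporting

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expression, variant_sets, labels = read_cohort(cohort_dir)
    trained = train_cascade(
        expression, variant_sets, labels, seed=seed,
        sensitivity_floor=sensitivity_floor, n_quantiles=n_quantiles,
    )
    results = score_cohort(trained, expression, variant_sets)
    results.to_csv(out_dir / "results.tsv", sep="\t", na_rep="NA")
    with open(out_dir / "thresholds.json", "w") as fh:
        payload = trained.config.thresholds_dict()
        payload.update(asdict(trained.optimization))
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    reporting.write_report(out_dir, trained, results, labels,
                           variant_sets, figures=write_figures)
    return results
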