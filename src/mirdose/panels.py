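"""Biomarker-panel discovery by exhaustive logistic-panel search.

The wrapper procedure (a Biomarker Discovery Process at a binomial decision
point) ranks candidate features by how often repeated random forests place
them among the top importances, enumerates every 2-10-feature subpanel of
the highest-ranked feature groups, fits each subpanel as a logistic model of
the binary outcome, and scores it by cross-validated ROC AUC under two
schemes: repeated stratified 70:30 train/test splits (RSBMR) and stratified
k-fold. Panels are screened at AUC > 0.80 (strict) and likelihood-ratio
p < 0.05.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .logistic import PanelLogit, PanelModel

log = logging.getLogger(__name__)


@dataclass
class CandidateRanking:
    """Per-feature selection frequencies and the retained seed panels."""

    frequencies: pd.Series  # feature -> count over repetitions
    seed_panels: list[tuple[str, ...]]
    n_reps: int


@dataclass(frozen=True)
class PanelEvaluation:
    method: str  # "RSBMR" or "kfold"
    features: tuple[str, ...]
    mean_auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    mcfadden_r2: float
    fit_p: float
    n_iterations: int
    model: PanelModel | None = None
    separated: bool = False


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, float).ravel()
    if len(y) != len(X):
        raise ValueError("X and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    return y


def rank_candidates_rf(
    X: pd.DataFrame,
    y,
    n_reps: int = 2000,
    top_panels: int = 200,
    panel_size: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> CandidateRanking:
    """Rank features by selection frequency over repeated random forests.

    Each repetition trains a forest on a bootstrap resample of the cohort
    (redrawn until both classes are present) and records the ``panel_size``
    features with the highest importance. Features are ranked by cumulative
    selection frequency; the recorded top-importance groups, ranked by how
    often they recur and then by their members' frequencies, become the seed
    panels for subpanel enumeration.
    """
    y = _check_xy(X, y)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    features = np.asarray(X.columns)
    panel_size = min(panel_size, len(features))
    counts: Counter[str] = Counter()
    group_counts: Counter[tuple[str, ...]] = Counter()
    Xv = X.to_numpy(float)
    for _ in range(n_reps):
        while True:
            idx = rng.integers(0, len(y), len(y))
            if len(np.unique(y[idx])) == 2:
                break
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(Xv[idx], y[idx])
        imp = forest.feature_importances_
        order = np.lexsort((features, -imp))[:panel_size]
        top = tuple(sorted(features[order]))
        counts.update(top)
        group_counts[top] += 1

    freq = pd.Series(counts, dtype=float).reindex(features, fill_value=0.0)
    freq = freq.sort_values(ascending=False, kind="mergesort")

    def group_key(item):
        group, cnt = item
        member_freq = sum(freq[g] for g in group)
        return (-cnt, -member_freq, group)

    seed_panels = [g for g, _ in sorted(group_counts.items(), key=group_key)]
    return CandidateRanking(freq, seed_panels[:top_panels], n_reps)


def enumerate_subpanels(
    seed_panels,
    min_size: int = 2,
    max_size: int = 10,
) -> list[tuple[str, ...]]:
    """Every feature subset of each seed panel with min_size <= |s| <= max_size.

    Subsets are deduplicated across seed panels and returned in a
    deterministic order (by size, then lexically).
    """
    if isinstance(seed_panels[0], str):
        seed_panels = [tuple(seed_panels)]
    out: set[tuple[str, ...]] = set()
    for panel in seed_panels:
        panel = tuple(sorted(set(panel)))
        if len(panel) < min_size:
            raise ValueError(
                f"seed panel {panel} smaller than min_size={min_size}"
            )
        for size in range(min_size, min(max_size, len(panel)) + 1):
            out.update(itertools.combinations(panel, size))
    return sorted(out, key=lambda s: (len(s), s))


def fit_logistic(
    X: pd.DataFrame, y, features
) -> tuple[PanelModel, float, float]:
    """Fit one panel on the full cohort; (model, McFadden R2, LR p)."""
    features = tuple(features)
    if not 2 <= len(features) <= 10:
        raise ValueError("panel size must lie in [2, 10]")
    y = _check_xy(X, y)
    res = PanelLogit(y, X[list(features)].to_numpy(float), features).fit()
    return res.panel_model(), res.mcfadden_r2, res.fit_p


def _youden_sens_spec(y_true, prob) -> tuple[float, float]:
    fpr, tpr, _ = roc_curve(y_true, prob)
    j = int(np.argmax(tpr - fpr))
    return float(tpr[j]), float(1.0 - fpr[j])


def evaluate_rsbmr(
    X: pd.DataFrame,
    y,
    features,
    split: float = 0.70,
    n_repeats: int = 10,
    seed: int = 0,
) -> PanelEvaluation:
    """Repeated stratified 70:30 split evaluation of one panel.

    Per repeat: fit on the training split, score the held-out split by AUC
    and by sensitivity/specificity at the Youden-optimal threshold; report
    means over repeats. The AUC CI is the 2.5/97.5 percentile interval of
    the per-repeat AUCs. Full-cohort fit supplies the coefficients,
    McFadden R2 and LR p.
    """
    features = tuple(features)
    y = _check_xy(X, y)
    n_min = min(int(y.sum()), int((1 - y).sum()))
    if n_min < 2:
        raise ValueError("a class is too small to stratify a 70:30 split")
    Xp = X[list(features)].to_numpy(float)
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=split, random_state=seed
    )
    aucs, sens, spec = [], [], []
    for train, test in splitter.split(Xp, y):
        res = PanelLogit(y[train], Xp[train], features).fit()
        prob = res.predict(Xp[test])
        aucs.append(roc_auc_score(y[test], prob))
        se, sp = _youden_sens_spec(y[test], prob)
        sens.append(se)
        spec.append(sp)
    full = PanelLogit(y, Xp, features).fit()
    ci = tuple(np.quantile(aucs, [0.025, 0.975]))
    return PanelEvaluation(
        "RSBMR",
        features,
        float(np.mean(aucs)),
        (float(ci[0]), float(ci[1])),
        float(np.mean(sens)),
        float(np.mean(spec)),
        full.mcfadden_r2,
        full.fit_p,
        n_repeats,
        full.panel_model(),
        full.separated,
    )


def evaluate_kfold(
    X: pd.DataFrame,
    y,
    features,
    k: int = 10,
    seed: int = 0,
) -> PanelEvaluation:
    """Stratified k-fold evaluation of one panel (mean per-fold AUC)."""
    features = tuple(features)
    y = _check_xy(X, y)
    if k >= len(y):
        raise ValueError("k must be smaller than the cohort size")
    if k < 2:
        raise ValueError("k must be >= 2")
    Xp = X[list(features)].to_numpy(float)
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, sens, spec, skipped = [], [], [], 0
    for train, test in folds.split(Xp, y):
        if len(np.unique(y[test])) < 2:
            skipped += 1
            continue
        res = PanelLogit(y[train], Xp[train], features).fit()
        prob = res.predict(Xp[test])
        aucs.append(roc_auc_score(y[test], prob))
        se, sp = _youden_sens_spec(y[test], prob)
        sens.append(se)
        spec.append(sp)
    if skipped:
        warnings.warn(f"{skipped} folds had one class and were skipped", stacklevel=2)
    if not aucs:
        raise ValueError("no fold had both classes; AUC undefined")
    full = PanelLogit(y, Xp, features).fit()
    ci = tuple(np.quantile(aucs, [0.025, 0.975]))
    return PanelEvaluation(
        "kfold",
        features,
        float(np.mean(aucs)),
        (float(ci[0]), float(ci[1])),
        float(np.mean(sens)),
        float(np.mean(spec)),
        full.mcfadden_r2,
        full.fit_p,
        len(aucs),
        full.panel_model(),
        full.separated,
    )


def screen_panels(
    evaluations,
    auc_min: float = 0.80,
    p_max: float = 0.05,
) -> list[PanelEvaluation]:
    """Retain panels with mean AUC strictly above ``auc_min`` and fit p below
    ``p_max``; sort by AUC descending, ties by fewer features then lexically."""
    kept = [
        e for e in evaluations if e.mean_auc > auc_min and e.fit_p < p_max
    ]
    return sorted(kept, key=lambda e: (-e.mean_auc, len(e.features), e.features))


@dataclass
class DiscoveryConfig:
    """Knobs of the full discovery run (defaults follow the study protocol;
    tests and the bundled demo use reduced repetition counts)."""

    n_forest_reps: int = 2000
    top_panels: int = 200
    panel_size: int = 10
    n_trees: int = 100
    min_size: int = 2
    max_size: int = 10
    rsbmr_split: float = 0.70
    rsbmr_repeats: int = 10
    kfold_k: int = 10
    auc_min: float = 0.80
    p_max: float = 0.05


def discover_panels(
    X: pd.DataFrame,
    y,
    config: DiscoveryConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run the full discovery: rank, enumerate, fit, evaluate, screen.

    Returns the screened, ranked panel lists for both evaluation schemes.
    """
    config = config or DiscoveryConfig()
    y = _check_xy(X, y)
    ranking = rank_candidates_rf(
        X,
        y,
        n_reps=config.n_forest_reps,
        top_panels=config.top_panels,
        panel_size=config.panel_size,
        n_trees=config.n_trees,
        seed=seed,
    )
    subpanels = enumerate_subpanels(
        ranking.seed_panels, config.min_size, config.max_size
    )
    log.info(
        "discovery: %d seed panels -> %d unique subpanels",
        len(ranking.seed_panels),
        len(subpanels),
    )
    rsbmr = [
        evaluate_rsbmr(X, y, s, config.rsbmr_split, config.rsbmr_repeats, seed)
        for s in subpanels
    ]
    kfold = [evaluate_kfold(X, y, s, config.kfold_k, seed) for s in subpanels]
    return {
        "RSBMR": screen_panels(rsbmr, config.auc_min, config.p_max),
        "kfold": screen_panels(kfold, config.auc_min, config.p_max),
        "ranking": ranking,
    }
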