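"""Four-way factorial ANOVA per miRNA over dose, time, sex and survival.

The model is fitted to normalized log2 expression with every sample as an
independent row and time since irradiation as a four-level factor including
the pre-irradiation baseline. All 15 main effects and interactions of
RD (dose), TSI (time), Sex and RRiF (survival) are tested with Type II sums
of squares, which are order-invariant and appropriate for this unbalanced
design (sex ratios differ between groups and survival is partially
confounded with dose). Terms whose design columns are fully aliased are
flagged rather than reported with numbers. Effect sizes are classical
eta-squared (term SS over total SS). No multiple-testing correction is
applied; screening uses raw p-values at the stated alpha.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import StudyDesign

log = logging.getLogger(__name__)

#: Factor label -> metadata column.
FACTORS = {"RD": "dose_gy", "TSI": "timepoint", "Sex": "sex", "RRiF": "survived"}

#: The 15 tested terms, in report order.
TERMS: tuple[tuple[str, ...], ...] = tuple(
    subset
    for size in (1, 2, 3, 4)
    for subset in itertools.combinations(tuple(FACTORS), size)
)


def term_label(term: tuple[str, ...]) -> str:
    return "*".join(term)


def _sum_to_zero(series: pd.Series) -> tuple[np.ndarray, int]:
    """Sum-to-zero contrast columns for a categorical column; (n x (L-1), L)."""
    levels = sorted(pd.unique(series), key=str)
    n, L = len(series), len(levels)
    out = np.zeros((n, max(L - 1, 0)))
    index = {lv: i for i, lv in enumerate(levels)}
    codes = series.map(index).to_numpy()
    for j in range(L - 1):
        out[codes == j, j] = 1.0
        out[codes == L - 1, j] = -1.0
    return out, L


def _interaction(blocks: list[np.ndarray]) -> np.ndarray:
    """Column-wise tensor product of contrast blocks."""
    out = blocks[0]
    for b in blocks[1:]:
        out = (out[:, :, None] * b[:, None, :]).reshape(len(b), -1)
    return out


def _ortho_basis(x: np.ndarray, tol_factor: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space, rank-revealing."""
    q, r, _ = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * tol_factor if diag.size else 0.0
    rank = int((diag > tol).sum())
    return q[:, :rank]


@dataclass
class DeSet:
    """Per-term significant feature lists and their deduplicated union."""

    alpha: float
    per_term: dict[str, list[str]]
    union: list[str]


class FactorialAnova:
    """Per-feature factorial ANOVA model over the cohort covariates.

    Parameters
    ----------
    values : DataFrame, features x samples
        Normalized expression (log2 CPM) or any per-sample response matrix.
    meta : DataFrame
        Sample metadata with columns sample_id, dose_gy, timepoint, sex,
        survived; rows are matched to ``values`` columns by sample_id.
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame):
        meta = meta.set_index("sample_id").loc[list(values.columns)]
        self.values = values
        self.meta = meta
        self.blocks: dict[str, np.ndarray] = {}
        self.levels: dict[str, int] = {}
        for label, col in FACTORS.items():
            block, L = _sum_to_zero(meta[col])
            self.blocks[label] = block
            self.levels[label] = L
            if L < 2:
                log.warning("factor %s has a single observed level", label)
        self._prepare()

    def _term_block(self, term: tuple[str, ...]) -> np.ndarray:
        return _interaction([self.blocks[f] for f in term])

    def _prepare(self) -> None:
        n = self.values.shape[1]
        intercept = np.ones((n, 1))
        term_cols = {t: self._term_block(t) for t in TERMS}

        def basis(terms):
            cols = [intercept] + [term_cols[t] for t in terms if term_cols[t].size]
            return _ortho_basis(np.hstack(cols))

        self._q_full = basis(list(TERMS))
        self._df_res = n - self._q_full.shape[1]
        self._pairs = {}
        for t in TERMS:
            base_terms = [u for u in TERMS if not set(t) <= set(u)]
            q_base = basis(base_terms)
            q_with = basis(base_terms + [t])
            self._pairs[t] = (q_base, q_with)

    def fit(self, alpha: float = 0.05) -> "FactorialAnovaResults":
        y = self.values.to_numpy(float).T  # samples x features
        yc = y - y.mean(axis=0)
        ss_total = (yc**2).sum(axis=0)
        total_ss_sq = (y**2).sum(axis=0)

        def rss(q):
            proj = q.T @ y
            return total_ss_sq - (proj**2).sum(axis=0)

        rss_full = rss(self._q_full)
        records = []
        for t in TERMS:
            label = term_label(t)
            expected_df = int(np.prod([self.levels[f] - 1 for f in t]))
            q_base, q_with = self._pairs[t]
            df_t = q_with.shape[1] - q_base.shape[1]
            if df_t == 0 or self._df_res <= 0:
                for feat in self.values.index:
                    records.append((feat, label, 0, np.nan, np.nan, np.nan, "aliased"))
                continue
            ss_t = np.clip(rss(q_base) - rss(q_with), 0.0, None)
            ms_res = rss_full / self._df_res
            with np.errstate(divide="ignore", invalid="ignore"):
                f_stat = (ss_t / df_t) / ms_res
                eta = np.where(ss_total > 0, ss_t / ss_total, 0.0)
            # constant features: no variance anywhere -> F = 0, p = 1
            f_stat = np.where(ss_total <= 1e-12, 0.0, f_stat)
            p = stats.f.sf(f_stat, df_t, self._df_res)
            p = np.where(ss_total <= 1e-12, 1.0, p)
            flag = "ok" if df_t == expected_df else "partially-aliased"
            for i, feat in enumerate(self.values.index):
                records.append((feat, label, df_t, f_stat[i], p[i], eta[i], flag))

        table = pd.DataFrame(
            records,
            columns=["feature", "term", "df", "F", "p", "eta_squared", "flag"],
        )
        return FactorialAnovaResults(table, alpha, self._df_res)


@dataclass
class FactorialAnovaResults:
    """Per-feature, per-term F tests, p-values and eta-squared effect sizes."""

    table: pd.DataFrame
    alpha: float
    df_resid: int

    def significant(self, term: str | None = None, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.alpha if alpha is None else alpha
        sig = self.table[self.table["p"] < alpha]
        if term is not None:
            sig = sig[sig["term"] == term]
        return sig

    def de_union(self, alpha: float | None = None) -> DeSet:
        alpha = self.alpha if alpha is None else alpha
        per_term: dict[str, list[str]] = {}
        for t in TERMS:
            label = term_label(t)
            sub = self.table[(self.table["term"] == label) & (self.table["p"] < alpha)]
            per_term[label] = sorted(sub["feature"].unique())
        union = sorted(set().union(*per_term.values())) if per_term else []
        return DeSet(alpha, per_term, union)

    def effect_size_summary(self) -> tuple[float, float]:
        eta = self.table["eta_squared"].dropna()
        if eta.empty:
            raise ValueError("all terms inestimable; no effect sizes to summarize")
        mean = float(eta.mean())
        cv = float(eta.std(ddof=1) / mean) if len(eta) > 1 and mean > 0 else 0.0
        return mean, cv

    def summary(self) -> str:
        de = self.de_union()
        lines = [
            "Four-way factorial ANOVA (Type II SS)",
            f"features: {self.table['feature'].nunique()}   "
            f"residual df: {self.df_resid}   alpha: {self.alpha}",
            f"{'term':<18}{'df':>4}{'n significant':>16}{'flag':>20}",
        ]
        for t in TERMS:
            label = term_label(t)
            sub = self.table[self.table["term"] == label]
            lines.append(
                f"{label:<18}{sub['df'].iloc[0]:>4}"
                f"{len(de.per_term.get(label, [])):>16}{sub['flag'].iloc[0]:>20}"
            )
        lines.append(f"DE union: {len(de.union)} features")
        return "\n".join(lines)


def fit_four_way_anova(
    values: pd.DataFrame, meta: pd.DataFrame, alpha: float = 0.05
) -> FactorialAnovaResults:
    """Fit the 15-term factorial ANOVA to a features x samples matrix."""
    return FactorialAnova(values, meta).fit(alpha=alpha)


def curate_de_union(results: FactorialAnovaResults, alpha: float = 0.05) -> DeSet:
    """Union of features significant in at least one term, duplicates removed."""
    if results.table.empty:
        raise ValueError("empty ANOVA results")
    return results.de_union(alpha=alpha)


def effect_size_summary(results: FactorialAnovaResults) -> tuple[float, float]:
    """Mean and coefficient of variation of all reported eta-squared values."""
    return results.effect_size_summary()


@dataclass(frozen=True)
class PowerReport:
    alpha: float
    mean_eta_squared: float
    eta_cv: float
    n_samples: int
    estimated_power: float
    method: str = "monte-carlo-anova"


def estimate_power_by_simulation(
    design: StudyDesign,
    target_eta2: float,
    alpha: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
) -> PowerReport:
    """Monte-Carlo power of the dose term at a target eta-squared.

    Simulates Gaussian responses on the full sampling design, adds a dose
    effect scaled so the expected eta-squared of the RD term equals
    ``target_eta2``, and reports the fraction of replicates in which the RD
    term is rejected at ``alpha``.
    """
    if not 0 <= target_eta2 < 1:
        raise ValueError("target_eta2 must lie in [0, 1)")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    from .synthetic import SimulationConfig, simulate_cohort, PlantedTruth

    cfg = SimulationConfig(planted=PlantedTruth(), seed=seed)
    _, meta, _ = simulate_cohort(cfg, design)
    n = len(meta)
    rng = np.random.default_rng(seed)

    doses = np.sort(meta["dose_gy"].unique())
    pattern = meta["dose_gy"].map(
        dict(zip(doses, np.linspace(-1, 1, len(doses))))
    ).to_numpy()
    pattern = pattern - pattern.mean()
    if target_eta2 > 0:
        ss_target = target_eta2 / (1 - target_eta2) * (n - 1)
        beta = np.sqrt(ss_target / (pattern**2).sum())
    else:
        beta = 0.0

    y = rng.standard_normal((n, n_reps)) + beta * pattern[:, None]
    values = pd.DataFrame(
        y.T, index=[f"rep-{i:04d}" for i in range(n_reps)],
        columns=meta["sample_id"].to_numpy(),
    )
    results = fit_four_way_anova(values, meta, alpha=alpha)
    rd = results.table[results.table["term"] == "RD"]
    power = float((rd["p"] < alpha).mean())
    eta = rd["eta_squared"].to_numpy()
    mean_eta = float(eta.mean())
    cv = float(eta.std(ddof=1) / mean_eta) if mean_eta > 0 else 0.0
    return PowerReport(alpha, mean_eta, cv, n, power)
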