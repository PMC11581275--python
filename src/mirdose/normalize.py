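"""Count prefiltering, TMM scaling, CPM, and baseline log2 fold change.

The TMM (trimmed mean of M-values) implementation follows the canonical
definition: the reference sample is the one whose upper-quartile count
fraction is closest to the cohort mean, per-sample factors are
precision-weighted means of log2 expression ratios after trimming the
extremes of the M (log-ratio) and A (log-abundance) distributions, and the
factor vector is rescaled to geometric mean 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def prefilter_features(counts: pd.DataFrame, min_nonzero_frac: float = 0.40) -> pd.DataFrame:
    """Keep features detected (count > 0) in at least ``min_nonzero_frac`` of samples.

    The boundary is inclusive: a feature non-zero in exactly 40% of samples
    is retained under the default threshold. Feature order is preserved.
    """
    if not 0 < min_nonzero_frac <= 1:
        raise ValueError("min_nonzero_frac must lie in (0, 1]")
    if counts.empty:
        warnings.warn("prefilter called on an empty matrix", stacklevel=2)
        return counts.copy()
    frac = (counts > 0).sum(axis=1) / counts.shape[1]
    kept = counts.loc[frac >= min_nonzero_frac]
    log.info("prefilter kept %d of %d features", kept.shape[0], counts.shape[0])
    return kept.copy()


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    sample_ids: tuple[str, ...]
    library_sizes: np.ndarray
    factors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "lib_size": self.library_sizes,
                "tmm_factor": self.factors,
            }
        )


def _trimmed_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping ranks in [floor(n*trim)+1, n+1-(floor(n*trim)+1)]."""
    n = len(values)
    lo = np.floor(n * trim) + 1
    hi = n + 1 - lo
    # average ranks for ties, 1-based
    order = values.argsort(kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    return (ranks >= lo) & (ranks <= hi)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """TMM scaling factors for a features x samples count matrix."""
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have positive library size")

    # Reference: upper quartile of count fractions closest to the mean.
    uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, nj = y[:, j], lib[j]
        keep = (yj > 0) & (yr > 0)
        if not keep.any():
            warnings.warn(
                f"sample {counts.columns[j]!r} shares no expressed features with "
                "the reference; factor set to 1.0",
                stacklevel=2,
            )
            continue
        pj, pr = yj[keep] / nj, yr[keep] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # delta-method variance of M; weight = inverse variance
        w = (nj - yj[keep]) / (nj * yj[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        sel = _trimmed_mask(m, trim_m) & _trimmed_mask(a, trim_a)
        if not sel.any() or np.allclose(m[sel], 0.0):
            continue
        factors[j] = 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))

    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(tuple(counts.columns), lib, factors)


def cpm(counts: pd.DataFrame, factors: NormalizationFactors) -> pd.DataFrame:
    """Counts per million over TMM-effective library sizes."""
    if tuple(counts.columns) != factors.sample_ids:
        raise ValueError("count matrix and normalization factors are misaligned")
    eff = factors.library_sizes * factors.factors
    return counts / eff * 1e6


def log2fc_baseline(
    cpm_values: pd.DataFrame, meta: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-animal log2 fold change of CPM against the pre-irradiation sample.

    Columns are the post-irradiation samples; each value is
    log2((cpm_post + pc) / (cpm_pre_same_animal + pc)). Animals without
    exactly one baseline sample are excluded with a log message.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    meta = meta.set_index("sample_id", drop=False)
    pre = meta[meta["timepoint"] == "pre"]
    baseline = {}
    for animal, grp in pre.groupby("animal_id"):
        if len(grp) == 1:
            baseline[animal] = grp["sample_id"].iloc[0]
        else:
            log.warning("animal %s has %d baseline samples; excluded", animal, len(grp))

    cols, values = [], []
    for sid in cpm_values.columns:
        row = meta.loc[sid]
        if row["timepoint"] == "pre":
            continue
        base_sid = baseline.get(row["animal_id"])
        if base_sid is None:
            log.warning("animal %s lacks a baseline; sample %s excluded",
                        row["animal_id"], sid)
            continue
        cols.append(sid)
        values.append(
            np.log2((cpm_values[sid] + pseudocount) / (cpm_values[base_sid] + pseudocount))
        )
    fc = pd.concat(values, axis=1) if values else pd.DataFrame(index=cpm_values.index)
    fc.columns = cols
    fc.index.name = cpm_values.index.name
    return fc


def normalized_log2_cpm(
    cpm_values: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(CPM + pseudocount), the per-sample expression scale used by the ANOVA."""
    return np.log2(cpm_values + pseudocount)
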