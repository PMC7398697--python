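"""Per-position differential 5'-end analysis and cleavage-site calling.

The contrast is the TS strain at 44 degC (RNase E inactive) against the
wild type at 44 degC (RNase E active): a genuine cleavage position loses
its 5'-end signal when the nuclease is switched off, so sites appear as
positions strongly *depleted* in TS-44.

The test is a per-position negative-binomial Wald test on
median-of-ratios-normalised counts: condition means are plugged in as the
NB means, the standard error of the log2 ratio comes from the delta method
under NB(mu, alpha) with a per-position method-of-moments dispersion, and
p-values are Benjamini-Hochberg corrected across all positions passing the
coverage filter.  Calling applies the canonical thresholds: coverage >= 20
reads, |fold change| >= 3, adjusted p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage_io import SampleDesign, select_samples
from .errors import InputError, NormalizationError

DISPERSION_FLOOR = 1e-8
_LN2 = np.log(2.0)


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For sample j, sf_j is the median over positions (restricted to rows
    where every sample has a positive count, so the geometric mean is
    positive) of count_ij divided by the row geometric mean.
    """
    counts = matrix.to_numpy(dtype=np.float64)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise NormalizationError(
            "no position has positive counts in every sample; cannot form the "
            "geometric-mean reference (consider a pseudo-reference fallback)"
        )
    logc = np.log(counts[allpos])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    return matrix / sf.reindex(matrix.columns).to_numpy()


def estimate_dispersion(
    matrix: pd.DataFrame,
    sf: pd.Series,
    condition_samples: Sequence[Sequence[str]],
) -> np.ndarray:
    """Per-position NB dispersion alpha by method of moments.

    Within each replicate group, alpha_c = max(floor, (s^2 - mu) / mu^2)
    from the mean and variance of normalised counts across that group's
    replicates; groups are combined by an average weighted with their
    residual degrees of freedom (n_c - 1).  The floor (1e-8) is applied
    per group so that an under-dispersed draw in one group cannot cancel
    genuine overdispersion seen in another.
    """
    norm = normalize(matrix, sf)
    num = np.zeros(len(matrix), dtype=np.float64)
    wsum = 0.0
    for samples in condition_samples:
        if len(samples) < 2:
            raise InputError("need >= 2 replicates per condition for dispersion")
        sub = norm[list(samples)].to_numpy(dtype=np.float64)
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_c = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        w = len(samples) - 1
        num += w * np.maximum(alpha_c, DISPERSION_FLOOR)
        wsum += w
    return num / wsum


def position_filter(
    matrix: pd.DataFrame,
    contrast_samples: Sequence[str],
    min_coverage: int = 20,
) -> np.ndarray:
    """Coverage filter: raw count >= min_coverage in >= 1 contrast library."""
    sub = matrix[list(contrast_samples)].to_numpy()
    return (sub >= min_coverage).any(axis=1)


def nb_test(
    matrix: pd.DataFrame,
    sf: pd.Series,
    dispersion: np.ndarray,
    design: Sequence[SampleDesign],
    numerator: tuple[str, int] = ("TS", 44),
    denominator: tuple[str, int] = ("WT", 44),
) -> pd.DataFrame:
    """Per-position NB Wald test of the numerator vs denominator condition.

    Condition means are plug-in estimates on normalised counts with a
    pseudo-count of 0.5 added to each condition total before the ratio,
    bounding the log2 fold change when one condition is all zero.  Returns
    a DataFrame indexed like ``matrix`` with columns base_mean, log2fc, se,
    p.
    """
    num_ids = select_samples(design, *numerator)
    den_ids = select_samples(design, *denominator)
    if len(num_ids) < 2 or len(den_ids) < 2:
        raise InputError("need >= 2 samples on each side of the contrast")
    norm = normalize(matrix, sf)
    a = norm[num_ids].to_numpy(dtype=np.float64)
    b = norm[den_ids].to_numpy(dtype=np.float64)
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = (a.sum(axis=1) + 0.5) / n_a
    mean_b = (b.sum(axis=1) + 0.5) / n_b
    log2fc = np.log2(mean_a / mean_b)
    alpha = np.asarray(dispersion, dtype=np.float64)
    # delta method: var(ln mean_c) ~ (1/mu_c + alpha) / n_c under NB(mu, alpha)
    var_log = (1.0 / mean_a + alpha) / n_a + (1.0 / mean_b + alpha) / n_b
    se = np.sqrt(var_log) / _LN2
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = np.concatenate([a, b], axis=1).mean(axis=1)
    return pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc, "se": se, "p": p},
        index=matrix.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} (m/j) p_(j), clipped at 1, in input order.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1:
        raise InputError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=np.float64)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class CleavageSiteSet:
    """Called cleavage sites plus the thresholds that produced them.

    ``table`` is indexed by (chrom, pos0, strand) and carries the test
    statistics; annotation steps append class_label / gene_id /
    motif_window columns.
    """

    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)
    contrast: str = "TS_44_vs_WT_44"

    def __len__(self) -> int:
        return len(self.table)

    def keys(self) -> set[tuple[str, int, str]]:
        return set(self.table.index)


def call_cleavage_sites(
    tests: pd.DataFrame,
    min_fold_change: float = 3.0,
    max_padj: float = 0.05,
    direction: str = "depleted",
    require_null_at_30: bool = False,
) -> CleavageSiteSet:
    """Apply the fold-change and FDR thresholds to the tested positions.

    ``direction='depleted'`` (default) keeps positions whose 5'-end signal
    drops in the inactive-nuclease condition: log2fc <= -log2(min_fold_change).
    ``direction='both'`` relaxes to the absolute fold change.  ``tests``
    must carry a ``padj`` column (see :func:`bh_adjust`).  With
    ``require_null_at_30`` a site must additionally show
    |FC| < min_fold_change between the strains at 30 degC, where both
    nucleases are active (needs a ``log2fc_30`` column).
    """
    if "padj" not in tests.columns:
        raise InputError("tests must carry a 'padj' column; run bh_adjust first")
    if direction not in ("depleted", "both"):
        raise InputError(f"direction must be 'depleted' or 'both', got {direction!r}")
    lfc_cut = np.log2(min_fold_change)
    if direction == "depleted":
        keep = tests["log2fc"] <= -lfc_cut
    else:
        keep = tests["log2fc"].abs() >= lfc_cut
    keep &= tests["padj"] <= max_padj
    if require_null_at_30:
        if "log2fc_30" not in tests.columns:
            raise InputError(
                "require_null_at_30 needs a 'log2fc_30' column (30 degC libraries)"
            )
        keep &= tests["log2fc_30"].abs() < lfc_cut
    table = tests.loc[keep].copy()
    return CleavageSiteSet(
        table=table,
        thresholds={
            "min_fold_change": min_fold_change,
            "max_padj": max_padj,
            "direction": direction,
            "require_null_at_30": require_null_at_30,
        },
    )


def condition_log2fc(
    matrix: pd.DataFrame,
    sf: pd.Series,
    design: Sequence[SampleDesign],
    numerator: tuple[str, int],
    denominator: tuple[str, int],
) -> np.ndarray:
    """Plain log2 ratio of pseudo-counted condition means (no test).

    Used for the optional permissive-temperature control: at 30 degC both
    strains carry an active nuclease, so a genuine cleavage site should
    show no strain difference there.
    """
    num_ids = select_samples(design, *numerator)
    den_ids = select_samples(design, *denominator)
    norm = normalize(matrix, sf)
    a = norm[num_ids].to_numpy(dtype=np.float64)
    b = norm[den_ids].to_numpy(dtype=np.float64)
    mean_a = (a.sum(axis=1) + 0.5) / a.shape[1]
    mean_b = (b.sum(axis=1) + 0.5) / b.shape[1]
    return np.log2(mean_a / mean_b)


def run_differential(
    matrix: pd.DataFrame,
    design: Sequence[SampleDesign],
    min_coverage: int = 20,
    numerator: tuple[str, int] = ("TS", 44),
    denominator: tuple[str, int] = ("WT", 44),
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter, normalise, test and BH-adjust in one pass.

    Size factors are estimated on the full matrix; the coverage filter and
    the test are restricted to the contrast libraries.  Dispersion, being
    a property of the position rather than of the condition, is pooled
    over every replicate group in the design (all strain x temperature
    combinations), which stabilises the per-position estimate.  Returns
    the results table over filtered positions and the size factors.
    """
    sf = size_factors(matrix)
    contrast_ids = select_samples(design, *numerator) + select_samples(
        design, *denominator
    )
    mask = position_filter(matrix, contrast_ids, min_coverage=min_coverage)
    sub = matrix.loc[mask]
    groups = sorted({(d.strain, d.temperature) for d in design})
    cond_ids = [select_samples(design, *g) for g in groups]
    alpha = estimate_dispersion(sub, sf, cond_ids)
    res = nb_test(sub, sf, alpha, design, numerator=numerator, denominator=denominator)
    res["padj"] = bh_adjust(res["p"].to_numpy())
    # permissive-temperature control ratio, if 30 degC libraries exist
    num30 = (numerator[0], 30)
    den30 = (denominator[0], 30)
    if select_samples(design, *num30) and select_samples(design, *den30):
        res["log2fc_30"] = condition_log2fc(sub, sf, design, num30, den30)
    return res, sf
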