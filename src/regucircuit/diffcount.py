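"""Negative-binomial differential testing for sequencing count matrices.

One engine serves three kinds of features: gene expression counts, read
counts over promoter windows, and read counts over CRE regions.  The model
for feature *i* in sample *s* is

    y_is ~ NB(mu_is, alpha_i),   Var = mu + alpha * mu^2,
    log mu_is = x_s' beta_i + log(size_factor_s),

with the condition (and optionally time) encoded in the design row ``x_s``.
Size factors come from the median-of-ratios estimator.  Per-feature
dispersions start from a pooled within-group method-of-moments estimate
with a floor; because that estimate is extremely noisy at typical replicate
numbers (and an under-estimate inflates the test statistic), the working
dispersion takes the maximum of the per-feature value and a robustly fitted
mean-dispersion trend ``a0 + a1/mu`` — a deliberately conservative rule, in
the spirit of the classic count-model packages, rather than an
empirical-Bayes shrinkage.  The condition effect is assessed with a Wald
test on the fitted GLM coefficient against a standard normal reference, and
p-values are adjusted across tested features with Benjamini-Hochberg.

There is no posterior dispersion shrinkage, no outlier replacement and no
independent filtering; these are the main expected divergences from heavier
differential-expression machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DiffConfig",
    "DiffResult",
    "size_factors",
    "estimate_dispersion",
    "fit_dispersion_trend",
    "working_dispersion",
    "nb_test",
    "nb_test_two_factor",
    "read_counts_tsv",
    "write_results_tsv",
]

CONDITIONS = ("control", "mutant")


@dataclass
class DiffConfig:
    """Knobs of the differential test.

    alpha            significance threshold on the (adjusted) p-value.
    use_adjusted     call significance on BH-adjusted p-values (expression
                     convention) or on raw p-values (the acetylation
                     convention of the upstream study design).
    min_dispersion   floor for the per-feature dispersion estimate.
    interaction      include a genotype x time interaction in the two-factor
                     design (the default additive design tests the shared
                     genotype effect).
    """

    alpha: float = 0.05
    use_adjusted: bool = True
    min_dispersion: float = 1e-8
    interaction: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_dispersion <= 0:
            raise ValueError("min_dispersion must be positive")


@dataclass(frozen=True)
class DiffResult:
    """Per-feature test outcome (one row of the result frame)."""

    feature_id: str
    base_mean: float
    log2fc: float
    p_value: float
    p_adjusted: float
    status: str  # up / down / ns


@dataclass
class CountMatrix:
    """Integer feature x sample counts with per-sample condition/time labels."""

    counts: pd.DataFrame
    condition: pd.Series
    time: pd.Series | None = None

    def __post_init__(self) -> None:
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            missing = list(self.condition.index[self.condition.isna()])
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}")
        if self.time is not None:
            self.time = self.time.reindex(self.counts.columns)
            if self.time.isna().any():
                missing = list(self.time.index[self.time.isna()])
                raise ValueError(f"samples without time label: {missing}")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(
            self.counts[samples].copy(),
            self.condition.loc[samples].copy(),
            None if self.time is None else self.time.loc[samples].copy(),
        )

    def subset_time(self, time_label: str) -> "CountMatrix":
        if self.time is None:
            raise ValueError("matrix has no time labels")
        keep = [s for s in self.sample_ids if self.time[s] == time_label]
        if not keep:
            raise ValueError(f"no samples at time {time_label!r}")
        return self.subset_samples(keep)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        """Load a counts TSV (first column: feature id) and a sample sheet.

        The sample sheet is TSV with columns ``sample_id``, ``condition`` and
        optionally ``time``.
        """
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        sheet = sheet.set_index("sample_id")
        time = sheet["time"] if "time" in sheet.columns else None
        return cls(counts, sheet["condition"], time)


def read_counts_tsv(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    return CountMatrix.from_tsv(counts_path, samples_path)


# ---------------------------------------------------------------------------
# Normalization and dispersion
# ---------------------------------------------------------------------------


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For every feature positive in all samples, compute the ratio of each
    sample's count to the feature's geometric mean; the factor of a sample is
    the median of its ratios.
    """
    m = counts.counts.to_numpy(dtype=float)
    all_positive = (m > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; size factors "
            "are undefined (consider a pseudo-reference fallback upstream)"
        )
    logm = np.log(m[all_positive])
    log_ratios = logm - logm.mean(axis=1, keepdims=True)
    factors = np.median(np.exp(log_ratios), axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _group_labels(counts: CountMatrix) -> pd.Series:
    if counts.time is None:
        return counts.condition
    return counts.condition.str.cat(counts.time, sep=":")


def estimate_dispersion(
    counts: CountMatrix, factors: pd.Series, min_dispersion: float = 1e-8
) -> pd.Series:
    """Per-feature method-of-moments dispersion, pooled within groups.

    On normalized counts y/s, with the within-group variance pooled across
    condition (x time) groups, alpha_hat = max((s2 - mean) / mean^2, floor).
    Constant or empty features land on the floor.
    """
    norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    groups = _group_labels(counts)
    ss = np.zeros(norm.shape[0])
    dof = 0
    for g in sorted(groups.unique()):
        cols = np.asarray(groups == g)
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        sub = norm[:, cols]
        ss += sub.var(axis=1, ddof=1) * (n_g - 1)
        dof += n_g - 1
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = ss / dof if dof > 0 else np.zeros_like(mu)
        alpha = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
    alpha = np.maximum(alpha, min_dispersion)
    return pd.Series(alpha, index=counts.feature_ids, name="dispersion")


def _within_group_moments(
    counts: CountMatrix, factors: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group variance and grand mean of normalized counts."""
    norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    groups = _group_labels(counts)
    ss = np.zeros(norm.shape[0])
    dof = 0
    for g in sorted(groups.unique()):
        cols = np.asarray(groups == g)
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        ss += norm[:, cols].var(axis=1, ddof=1) * (n_g - 1)
        dof += n_g - 1
    s2 = ss / dof if dof > 0 else np.zeros(norm.shape[0])
    return s2, norm.mean(axis=1)


def fit_dispersion_trend(
    s2: np.ndarray, base_mean: np.ndarray, min_dispersion: float = 1e-8
) -> np.ndarray:
    """Mean-dispersion trend ``alpha(mu) = a0 + a1/mu`` across features.

    The NB variance law gives ``s2 - mu = a0 * mu^2 + a1 * mu``; the
    coefficients are fitted by trimmed least squares in this response space
    (never dividing by a noisy ``mu^2`` per feature, which is what biases
    naive trend fits), then clipped to be non-negative.  With too few
    informative features the trend degenerates to zero.
    """
    mask = base_mean > 5
    if mask.sum() < 10:
        return np.zeros_like(base_mean)
    mu = base_mean[mask]
    r = s2[mask] - mu
    A = np.column_stack([mu**2, mu])

    with np.errstate(invalid="ignore", divide="ignore"):
        per_feature = np.clip((s2[mask] - mu) / mu**2, 0.0, None)
    alpha_pilot = float(np.median(per_feature))
    keep = np.ones(len(mu), dtype=bool)
    coef = np.zeros(2)
    for _ in range(4):
        # weight by the inverse squared pilot NB variance so every feature
        # contributes on the dispersion scale, not the count-variance scale
        sigma2 = np.maximum(mu + alpha_pilot * mu**2, 1e-8)
        w = 1.0 / sigma2**2
        Aw = A[keep] * w[keep, None]
        ata = Aw.T @ A[keep]
        atr = Aw.T @ r[keep]
        coef = np.linalg.solve(ata + 1e-12 * np.eye(2), atr)
        pred = A @ coef
        keep = np.abs(r - pred) <= 4.0 * sigma2 * np.sqrt(2.0)  # ~4 sd of s2
        if keep.sum() < 10:
            keep = np.ones(len(mu), dtype=bool)
        alpha_pilot = max(
            float(np.median(np.clip(pred / np.maximum(mu**2, 1e-8), 0.0, None))),
            min_dispersion,
        )
    coef = np.maximum(coef, 0.0)
    return coef[0] + coef[1] / np.maximum(base_mean, 1e-8)


def working_dispersion(
    counts: CountMatrix, factors: pd.Series, min_dispersion: float = 1e-8
) -> pd.Series:
    """Dispersion used by the tests: the fitted trend, with a MoM escape.

    The per-feature method-of-moments value is far too noisy at typical
    replicate numbers, and an under-estimate inflates the Wald statistic, so
    each feature uses the trend value at its mean — unless its own estimate
    exceeds twice the trend, in which case the (higher, conservative)
    per-feature value is kept.
    """
    mom = estimate_dispersion(counts, factors, min_dispersion)
    s2, base_mean = _within_group_moments(counts, factors)
    trend = fit_dispersion_trend(s2, base_mean, min_dispersion)
    mom_arr = mom.to_numpy()
    alpha = np.where(mom_arr > 2.0 * trend, mom_arr, trend)
    alpha = np.maximum(alpha, min_dispersion)
    return pd.Series(alpha, index=counts.feature_ids, name="dispersion")


# ---------------------------------------------------------------------------
# Vectorized NB GLM fitting (IRLS across all features simultaneously)
# ---------------------------------------------------------------------------


def _fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 80,
    tol: float = 1e-10,
):
    """Fit per-feature NB log-link GLMs with known dispersions.

    y: (features, samples); X: (samples, p); offset: (samples,);
    alpha: (features,).  Returns (beta, se) of shapes (features, p).
    Fisher scoring with the expected information; steps are damped and the
    linear predictor clipped so separated features (a group of all zeros)
    stay finite instead of diverging.
    """
    n_feat, n_samp = y.shape
    p = X.shape[1]
    alpha = np.asarray(alpha, dtype=float)[:, None]
    beta = np.zeros((n_feat, p))
    mean0 = (y / np.exp(offset)[None, :]).mean(axis=1)
    beta[:, 0] = np.log(np.maximum(mean0, 1e-8))
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -40.0, 40.0)
        mu = np.exp(eta)
        denom = 1.0 + alpha * mu
        w = mu / denom
        info = np.einsum("fn,ni,nj->fij", w, X, X) + 1e-10 * eye
        score = np.einsum("fn,ni->fi", (y - mu) / denom, X)
        delta = np.linalg.solve(info, score[..., None])[..., 0]
        np.clip(delta, -3.0, 3.0, out=delta)
        beta += delta
        if np.max(np.abs(delta)) < tol:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -40.0, 40.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    info = np.einsum("fn,ni,nj->fij", w, X, X) + 1e-10 * eye
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.einsum("fii->fi", cov), 0.0))
    return beta, se


def _require_replicates(labels: pd.Series, minimum: int = 2) -> None:
    sizes = labels.value_counts()
    for level in CONDITIONS:
        if sizes.get(level, 0) < minimum:
            raise ValueError(
                f"need at least {minimum} replicates per condition; "
                f"{level!r} has {sizes.get(level, 0)}"
            )


def _wald_results(
    counts: CountMatrix,
    X: np.ndarray,
    coef_index: int,
    config: DiffConfig,
) -> pd.DataFrame:
    factors = size_factors(counts)
    disp = working_dispersion(counts, factors, config.min_dispersion)
    y = counts.counts.to_numpy(dtype=float)
    tested = y.sum(axis=1) > 0
    offset = np.log(factors.to_numpy())

    n, p = X.shape
    norm = y / factors.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)
    is_mut = np.asarray(counts.condition == "mutant")

    log2fc = np.zeros(y.shape[0])
    p_value = np.ones(y.shape[0])

    if tested.any():
        beta, se = _fit_nb_glm(y[tested], X, offset, disp.to_numpy()[tested])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta[:, coef_index] / np.maximum(se[:, coef_index], 1e-300)
        pv = 2.0 * stats.norm.sf(np.abs(z))
        lfc = beta[:, coef_index] / np.log(2.0)
        # report a pseudo-count ratio for features with an all-zero group,
        # where the GLM coefficient is at the separation boundary
        mm = norm[tested][:, is_mut].mean(axis=1)
        mc = norm[tested][:, ~is_mut].mean(axis=1)
        zero_group = (mm == 0) | (mc == 0)
        lfc = np.where(zero_group, np.log2((mm + 0.5) / (mc + 0.5)), lfc)
        log2fc[tested] = lfc
        p_value[tested] = pv

    p_adjusted = np.ones(y.shape[0])
    if tested.any():
        p_adjusted[tested] = multipletests(p_value[tested], method="fdr_bh")[1]

    crit = p_adjusted if config.use_adjusted else p_value
    sig = tested & (crit < config.alpha)
    status = np.where(sig & (log2fc > 0), "up", np.where(sig & (log2fc < 0), "down", "ns"))

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p_value": p_value,
            "p_adjusted": p_adjusted,
            "status": status,
        },
        index=pd.Index(counts.feature_ids, name="feature_id"),
    )


def nb_test(counts: CountMatrix, config: DiffConfig | None = None) -> pd.DataFrame:
    """Single-factor NB Wald test of mutant vs control.

    Returns a frame indexed by feature id with columns ``base_mean``,
    ``log2fc`` (log2 mutant/control), ``p_value``, ``p_adjusted`` (BH) and
    ``status`` in {up, down, ns}.  Features with all-zero counts are not
    tested and reported as ns with p = 1.
    """
    config = config or DiffConfig()
    _require_replicates(counts.condition)
    X = np.column_stack(
        [
            np.ones(len(counts.sample_ids)),
            np.asarray(counts.condition == "mutant", dtype=float),
        ]
    )
    return _wald_results(counts, X, coef_index=1, config=config)


def nb_test_two_factor(
    counts: CountMatrix, config: DiffConfig | None = None
) -> pd.DataFrame:
    """Two-factor (genotype + time) NB Wald test on the genotype coefficient.

    The additive design shares the genotype effect across time points; with
    ``config.interaction`` a genotype x time interaction is added and the
    test still targets the genotype main effect (at the reference time).
    """
    config = config or DiffConfig()
    if counts.time is None:
        raise ValueError("two-factor design requires per-sample time labels")
    _require_replicates(counts.condition)
    cells = counts.condition.str.cat(counts.time, sep=":")
    times = sorted(counts.time.unique())
    for cond in CONDITIONS:
        for t in times:
            if (cells == f"{cond}:{t}").sum() < 2:
                raise ValueError(f"design cell {cond}:{t} has fewer than 2 replicates")
    geno = np.asarray(counts.condition == "mutant", dtype=float)
    cols = [np.ones(len(counts.sample_ids)), geno]
    for t in times[1:]:
        cols.append(np.asarray(counts.time == t, dtype=float))
    if config.interaction:
        for t in times[1:]:
            cols.append(geno * np.asarray(counts.time == t, dtype=float))
    X = np.column_stack(cols)
    return _wald_results(counts, X, coef_index=1, config=config)


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", float_format="%.6g")
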