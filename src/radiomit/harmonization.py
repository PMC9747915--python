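"""Empirical-Bayes location/scale batch-effect removal for feature tables.

``combat`` implements the parametric empirical-Bayes harmonizer: per-feature
linear model (intercept + protected covariates + batch indicators),
standardization to residual scale, EB shrinkage of per-batch additive effects
(normal prior) and multiplicative effects (inverse-gamma prior) via the
iterative conditional update, then removal and restoration of scale and
protected terms.

``nested_combat`` extends it to several batch variables by applying ComBat
sequentially, trying every ordering of the variables and keeping the ordering
whose output has the fewest features still flagged by the k-sample
Anderson-Darling test for any batch variable; features that remain flagged are
discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from radiomit.types import FeatureTable

__all__ = [
    "CombatModel",
    "ADRecord",
    "HarmonizationResult",
    "combat",
    "ad_test",
    "ad_record",
    "count_significant",
    "nested_combat",
]

# significance grid of the k-sample Anderson-Darling critical values
_AD_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])


@dataclass
class CombatModel:
    """Estimated ComBat parameters for one batch variable."""

    batch_levels: list
    gamma_hat: pd.DataFrame  # raw per-batch location, levels x features
    delta2_hat: pd.DataFrame  # raw per-batch variance
    gamma_star: pd.DataFrame  # EB-shrunk location
    delta2_star: pd.DataFrame  # EB-shrunk variance
    var_pooled: pd.Series
    grand_mean: pd.Series
    covariate_coefs: pd.DataFrame | None
    n_iterations: dict


@dataclass
class ADRecord:
    """Per (feature, batch variable) Anderson-Darling statistics.

    ``table`` has a row per feature and a (statistic, p) column pair per
    batch variable; ``significant`` flags p < alpha.
    """

    statistics: pd.DataFrame  # features x batch variables
    pvalues: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.pvalues < self.alpha


@dataclass
class HarmonizationResult:
    harmonized: FeatureTable
    selected_order: tuple[str, ...]
    permutation_counts: dict[tuple[str, ...], int]
    ad_before: ADRecord
    ad_after: ADRecord
    retained: list[str]
    discarded: list[str]
    models: list[CombatModel] = field(default_factory=list)


def _encode_covariates(covariates: pd.DataFrame | None, index) -> pd.DataFrame | None:
    if covariates is None or covariates.shape[1] == 0:
        return None
    cov = covariates.loc[index].copy()
    non_numeric = cov.columns[[not pd.api.types.is_numeric_dtype(cov[c]) for c in cov.columns]]
    if len(non_numeric):
        cov = pd.get_dummies(cov, columns=list(non_numeric), drop_first=True, dtype=float)
    return cov.astype(float)


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank >= design.shape[1]:
        return
    kept: list[int] = []
    collinear: list[str] = []
    for j in range(design.shape[1]):
        cand = design[:, kept + [j]]
        if np.linalg.matrix_rank(cand) > len(kept):
            kept.append(j)
        else:
            collinear.append(names[j])
    raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def combat(
    features: FeatureTable,
    batch: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    parametric: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[FeatureTable, CombatModel]:
    """Harmonize a feature table for one batch variable.

    Parameters
    ----------
    features : FeatureTable
        Patients x features matrix.
    batch : array-like, one level per patient
        Every level must contain at least 2 patients.
    covariates : DataFrame, optional
        Protected covariates (biological variables of interest); their fitted
        effects are preserved in the output. Categorical columns are one-hot
        encoded internally. Must be full rank together with the batch design.
    parametric : bool
        Only the parametric EB variant is implemented.

    Returns the harmonized table and the fitted :class:`CombatModel`.
    """
    if not parametric:
        raise NotImplementedError("only parametric empirical-Bayes ComBat is implemented")
    X = features.values.to_numpy(dtype=float)
    n, p = X.shape
    batch = pd.Series(np.asarray(batch), index=features.values.index)
    levels = sorted(batch.unique().tolist())
    counts = batch.value_counts()
    singletons = [lv for lv in levels if counts[lv] < 2]
    if singletons:
        raise ValueError(f"batch level(s) with < 2 patients: {singletons}")

    if len(levels) == 1:
        model = CombatModel(
            batch_levels=levels,
            gamma_hat=pd.DataFrame(0.0, index=levels, columns=features.feature_names),
            delta2_hat=pd.DataFrame(1.0, index=levels, columns=features.feature_names),
            gamma_star=pd.DataFrame(0.0, index=levels, columns=features.feature_names),
            delta2_star=pd.DataFrame(1.0, index=levels, columns=features.feature_names),
            var_pooled=pd.Series(X.var(axis=0), index=features.feature_names),
            grand_mean=pd.Series(X.mean(axis=0), index=features.feature_names),
            covariate_coefs=None,
            n_iterations={},
        )
        return FeatureTable(features.values.copy(), dict(features.families)), model

    onehot = np.stack([(batch.to_numpy() == lv).astype(float) for lv in levels], axis=1)
    cov = _encode_covariates(covariates, features.values.index)
    if cov is not None:
        design = np.hstack([onehot, cov.to_numpy()])
        names = [f"batch[{lv}]" for lv in levels] + list(cov.columns)
    else:
        design = onehot
        names = [f"batch[{lv}]" for lv in levels]
    _check_full_rank(design, names)

    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    nb = len(levels)
    n_per = np.array([counts[lv] for lv in levels], dtype=float)
    grand_mean = (n_per / n) @ beta[:nb]  # (p,)
    stand_mean = np.tile(grand_mean, (n, 1))
    if cov is not None:
        stand_mean = stand_mean + cov.to_numpy() @ beta[nb:]

    resid = X - design @ beta
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd_pooled = np.sqrt(var_pooled)

    s_data = (X - stand_mean) / sd_pooled

    gamma_hat = np.zeros((nb, p))
    delta2_hat = np.zeros((nb, p))
    for i, lv in enumerate(levels):
        rows = batch.to_numpy() == lv
        gamma_hat[i] = s_data[rows].mean(axis=0)
        delta2_hat[i] = s_data[rows].var(axis=0, ddof=1)

    gamma_star = np.zeros_like(gamma_hat)
    delta2_star = np.ones_like(delta2_hat)
    n_iterations: dict = {}
    for i, lv in enumerate(levels):
        g_hat = gamma_hat[i]
        d2_hat = delta2_hat[i]
        gamma_bar = g_hat.mean()
        tau2 = g_hat.var(ddof=1)
        m = d2_hat.mean()
        s2 = d2_hat.var(ddof=1)
        a_prior = (2 * s2 + m**2) / s2 if s2 > 0 else 2.0
        b_prior = (m * s2 + m**3) / s2 if s2 > 0 else m

        rows = s_data[batch.to_numpy() == lv]
        n_i = rows.shape[0]
        g_old = g_hat.copy()
        d_old = d2_hat.copy()
        it = 0
        for it in range(1, max_iter + 1):
            g_new = (n_i * tau2 * g_hat + d_old * gamma_bar) / (n_i * tau2 + d_old)
            sum2 = ((rows - g_new) ** 2).sum(axis=0)
            d_new = (b_prior + 0.5 * sum2) / (n_i / 2.0 + a_prior - 1.0)
            change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        gamma_star[i] = g_old
        delta2_star[i] = np.maximum(d_old, 1e-12)
        n_iterations[lv] = it

    adjusted = s_data.copy()
    for i, lv in enumerate(levels):
        rows = batch.to_numpy() == lv
        adjusted[rows] = (s_data[rows] - gamma_star[i]) / np.sqrt(delta2_star[i])
    X_adj = adjusted * sd_pooled + stand_mean

    cols = features.feature_names
    model = CombatModel(
        batch_levels=levels,
        gamma_hat=pd.DataFrame(gamma_hat, index=levels, columns=cols),
        delta2_hat=pd.DataFrame(delta2_hat, index=levels, columns=cols),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=cols),
        delta2_star=pd.DataFrame(delta2_star, index=levels, columns=cols),
        var_pooled=pd.Series(var_pooled, index=cols),
        grand_mean=pd.Series(grand_mean, index=cols),
        covariate_coefs=(
            pd.DataFrame(beta[nb:], index=list(cov.columns), columns=cols)
            if cov is not None
            else None
        ),
        n_iterations=n_iterations,
    )
    harmonized = FeatureTable(
        pd.DataFrame(X_adj, index=features.values.index, columns=cols),
        dict(features.families),
    )
    return harmonized, model


def ad_test(values: np.ndarray, batch: np.ndarray) -> tuple[float, float]:
    """k-sample Anderson-Darling test (midrank/tie-adjusted variant).

    Returns the normalized statistic and an uncapped p-value obtained by the
    standard quadratic log-significance interpolation over the tabulated
    critical values (extrapolated beyond the table and clamped to [0, 1],
    rather than floored/capped as some library implementations do).
    """
    values = np.asarray(values, dtype=float)
    batch = np.asarray(batch)
    levels = pd.unique(batch)
    if len(levels) < 2:
        raise ValueError("ad_test needs at least two batch levels")
    samples = [values[batch == lv] for lv in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each batch level needs at least 2 observations")
    if np.ptp(values) == 0:
        return float("nan"), 1.0  # constant feature: no distributional difference
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.anderson_ksamp(samples, midrank=True)
    statistic = float(res.statistic)
    critical = np.asarray(res.critical_values, dtype=float)
    log_sig = np.log(_AD_SIG)
    if critical[0] <= statistic <= critical[-1]:
        coefs = np.polyfit(critical, log_sig, 2)
        log_p = float(np.polyval(coefs, statistic))
    elif statistic < critical[0]:
        slope = (log_sig[1] - log_sig[0]) / (critical[1] - critical[0])
        log_p = float(log_sig[0] + slope * (statistic - critical[0]))
    else:
        slope = (log_sig[-1] - log_sig[-2]) / (critical[-1] - critical[-2])
        log_p = float(log_sig[-1] + slope * (statistic - critical[-1]))
    return statistic, float(np.clip(np.exp(log_p), 0.0, 1.0))


def ad_record(
    features: FeatureTable,
    cohort_batches: pd.DataFrame,
    alpha: float = 0.05,
) -> ADRecord:
    """AD statistics for every (feature, batch variable) pair."""
    stats_df = pd.DataFrame(
        index=features.feature_names, columns=cohort_batches.columns, dtype=float
    )
    p_df = stats_df.copy()
    X = features.values
    for var in cohort_batches.columns:
        batch = cohort_batches[var].loc[X.index].to_numpy()
        for feat in X.columns:
            s, p = ad_test(X[feat].to_numpy(), batch)
            stats_df.loc[feat, var] = s
            p_df.loc[feat, var] = p
    return ADRecord(stats_df, p_df, alpha)


def count_significant(record: ADRecord, alpha: float | None = None) -> int:
    """Number of features significant for ANY batch variable."""
    alpha = record.alpha if alpha is None else alpha
    return int((record.pvalues < alpha).any(axis=1).sum())


def nested_combat(
    features: FeatureTable,
    cohort_batches: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> HarmonizationResult:
    """Sequential multi-batch harmonization with AD-based order selection.

    Every permutation of the batch-variable columns is applied sequentially;
    the permutation whose output has the fewest AD-significant features (any
    variable, at ``alpha``) wins, ties going to the first permutation in the
    lexicographic order of the columns as given. Features still significant
    after the winning sequence are discarded from the harmonized table.
    """
    variables = list(cohort_batches.columns)
    if not variables:
        raise ValueError("no batch variables given")
    if len(variables) > 5:
        raise ValueError("factorial order search limited to <= 5 batch variables")

    ad_before = ad_record(features, cohort_batches, alpha)

    best: tuple[tuple[str, ...], FeatureTable, ADRecord, list[CombatModel]] | None = None
    counts: dict[tuple[str, ...], int] = {}
    errors: list[str] = []
    for order in permutations(variables):
        try:
            table = features
            models = []
            for var in order:
                table, model = combat(
                    table, cohort_batches[var].loc[table.values.index], covariates
                )
                models.append(model)
            rec = ad_record(table, cohort_batches, alpha)
            counts[order] = count_significant(rec, alpha)
            if best is None or counts[order] < counts[best[0]]:
                best = (order, table, rec, models)
        except ValueError as exc:  # propagate per-permutation combat failures
            errors.append(f"{order}: {exc}")
    if best is None:
        raise ValueError("all permutations failed: " + "; ".join(errors))

    order, table, rec_after, models = best
    flags = rec_after.significant.any(axis=1)
    discarded = [f for f in features.feature_names if flags.get(f, False)]
    retained = [f for f in features.feature_names if f not in set(discarded)]
    return HarmonizationResult(
        harmonized=table.subset_features(retained),
        selected_order=order,
        permutation_counts=counts,
        ad_before=ad_before,
        ad_after=rec_after,
        retained=retained,
        discarded=discarded,
        models=models,
    )
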