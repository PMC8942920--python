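"""Group-level statistical profiling of morphometric measurements.

Provides the three profiling outputs used for nuclear phenotyping:
per-group pairwise Pearson correlation matrices with two-sided p-values and
significance tiers, PCA of z-scored parameters (sign-pinned for
determinism), and group comparisons by pairwise Welch t-tests (unequal
variances) plus a one-way ANOVA. P-values are reported raw, as is customary
for these correlation matrices; a Benjamini–Hochberg adjustment is available
but off by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: Default parameter set profiled (nuclear + chromocenter parameters;
#: euchromatin parameters are omitted as euchromatin dominates every
#: nucleus and adds little contrast).
DEFAULT_PARAMS = (
    "size_um2", "content_nu", "density_nu",
    "size_cc_um2", "content_cc", "density_cc",
    "heterogeneity", "rhf", "n_cc",
)


def significance_tier(p: float) -> str:
    for cutoff, stars in SIGNIFICANCE_TIERS:
        if p < cutoff:
            return stars
    return ""


@dataclass
class GroupCorrelations:
    r: dict[str, pd.DataFrame]
    p: dict[str, pd.DataFrame]

    def tiers(self, group: str) -> pd.DataFrame:
        return self.p[group].map(
            lambda v: "" if np.isnan(v) else significance_tier(v)
        )


def correlate(
    records: pd.DataFrame,
    group_col: str,
    params: tuple[str, ...] = DEFAULT_PARAMS,
) -> GroupCorrelations:
    """Per-group pairwise Pearson r and two-sided p-values.

    Zero-variance parameters yield NaN entries (undefined correlation, not
    zero). Each group needs at least 3 records.
    """
    params = [p for p in params if p in records.columns]
    r_by, p_by = {}, {}
    for group, sub in records.groupby(group_col, sort=True):
        data = sub[params].to_numpy(dtype=float)
        n = data.shape[0]
        if n < 3:
            raise InsufficientDataError(
                f"group {group!r} has {n} records; correlation needs >= 3"
            )
        k = len(params)
        r = np.full((k, k), np.nan)
        p = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i, k):
                xi, xj = data[:, i], data[:, j]
                ok = np.isfinite(xi) & np.isfinite(xj)
                if ok.sum() < 3 or xi[ok].std() == 0 or xj[ok].std() == 0:
                    continue
                if i == j:
                    r[i, j], p[i, j] = 1.0, 0.0
                    continue
                res = stats.pearsonr(xi[ok], xj[ok])
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
        r_by[group] = pd.DataFrame(r, index=params, columns=params)
        p_by[group] = pd.DataFrame(p, index=params, columns=params)
    return GroupCorrelations(r=r_by, p=p_by)


@dataclass
class PCAProfile:
    scores: pd.DataFrame           # per-record component coordinates (+ group)
    loadings: pd.DataFrame         # per-parameter loadings
    explained_variance_ratio: np.ndarray
    dropped: tuple[str, ...] = ()


def pca_profile(
    records: pd.DataFrame,
    group_col: str | None = None,
    params: tuple[str, ...] = DEFAULT_PARAMS,
    n_components: int | None = None,
) -> PCAProfile:
    """PCA on z-scored parameters over all records.

    Constant parameters are dropped with a warning. Component signs are
    pinned so the largest-magnitude loading of each component is positive,
    making the decomposition fully deterministic.
    """
    from sklearn.decomposition import PCA

    params = [p for p in params if p in records.columns]
    data = records[params].to_numpy(dtype=float)
    keep, dropped = [], []
    for i, name in enumerate(params):
        col = data[:, i]
        if not np.all(np.isfinite(col)) or col.std() == 0:
            dropped.append(name)
        else:
            keep.append(i)
    if dropped:
        warnings.warn(
            f"dropping constant/non-finite parameters from PCA: {dropped}",
            stacklevel=2,
        )
    params = [params[i] for i in keep]
    if len(params) < 2 or len(records) < 3:
        raise InsufficientDataError("PCA needs >= 2 varying parameters and >= 3 records")
    data = data[:, keep]
    z = (data - data.mean(axis=0)) / data.std(axis=0)

    n_components = n_components or min(len(params), len(records))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T  # parameters × components
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    comp_names = [f"PC{j + 1}" for j in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, columns=comp_names, index=records.index)
    if group_col is not None:
        scores_df[group_col] = records[group_col].to_numpy()
    loadings_df = pd.DataFrame(loadings, index=params, columns=comp_names)
    return PCAProfile(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped=tuple(dropped),
    )


def welch_anova_tests(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Welch t-tests plus one-way ANOVA on a dict of samples.

    Returns one row per group pair (test='welch_t') and one overall row
    (test='anova'); all p-values two-sided.
    """
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise InsufficientDataError(
            "group comparison needs >= 2 groups with >= 2 records each"
        )
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    rows = []
    for ga, gb in itertools.combinations(sorted(arrays), 2):
        res = stats.ttest_ind(arrays[ga], arrays[gb], equal_var=False)
        rows.append(
            {"test": "welch_t", "group_a": ga, "group_b": gb,
             "statistic": float(res.statistic), "p_value": float(res.pvalue),
             "tier": significance_tier(float(res.pvalue))}
        )
    f = stats.f_oneway(*arrays.values())
    rows.append(
        {"test": "anova", "group_a": "", "group_b": "",
         "statistic": float(f.statistic), "p_value": float(f.pvalue),
         "tier": significance_tier(float(f.pvalue))}
    )
    return pd.DataFrame(rows)


def compare_groups(
    records: pd.DataFrame,
    group_col: str,
    param: str,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Welch pairwise + ANOVA comparison of one parameter across groups."""
    groups = {
        str(g): sub[param].to_numpy(dtype=float)
        for g, sub in records.groupby(group_col, sort=True)
    }
    table = welch_anova_tests(groups)
    if bh_adjust:
        pairwise = table["test"] == "welch_t"
        adj = stats.false_discovery_control(table.loc[pairwise, "p_value"].to_numpy())
        table.loc[pairwise, "p_adjusted"] = adj
    table["parameter"] = param
    return table


def group_summary(
    records: pd.DataFrame,
    group_col: str,
    params: tuple[str, ...] = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Per-group mean/median/quartiles for each parameter (long form)."""
    params = [p for p in params if p in records.columns]
    rows = []
    for group, sub in records.groupby(group_col, sort=True):
        for p in params:
            v = sub[p].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            rows.append(
                {"group": group, "parameter": p, "n": v.size,
                 "mean": v.mean(), "median": float(np.median(v)),
                 "q1": float(np.percentile(v, 25)), "q3": float(np.percentile(v, 75)),
                 "sd": v.std(ddof=1) if v.size > 1 else 0.0}
            )
    return pd.DataFrame(rows)
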