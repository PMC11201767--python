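"""Laminar statistics: zone summaries, depth-profile fits, model comparison,
ANOVA, t-tests, size-ranked binning, coupling regression, and culture fractions.

The regression abscissa throughout is the integer zone index 1-6 (the study's
unit of analysis), not continuous depth. "Density" is reported both as the
positive fraction (primary response) and as positives per mm².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "ModelComparison",
    "CouplingResult",
    "BinnedProfile",
    "InsufficientDataError",
    "AnalysisError",
    "adjusted_r2",
    "zone_summary",
    "fit_linear",
    "fit_quadratic",
    "compare_models",
    "two_way_anova",
    "unpaired_t",
    "size_ranked_profile",
    "coupling_regression",
    "subset_intensity_profiles",
    "culture_fractions",
]


class InsufficientDataError(ValueError):
    pass


class AnalysisError(ValueError):
    pass


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted coefficient of determination, 1 - (1 - r²)(n - 1)/(n - k - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass
class FitResult:
    """Polynomial depth-profile fit: coefficients in increasing order
    (intercept, slope[, curvature])."""

    coefficients: tuple
    stderr: tuple
    n: int
    r2: float
    adjusted_r2: float
    slope_p: float | None
    vertex: float | None
    df_resid: int
    ss_resid: float

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1


@dataclass
class ModelComparison:
    preferred: str  # "linear" | "quadratic"
    f_stat: float
    p_value: float
    df: tuple


@dataclass
class CouplingResult:
    slope: float
    intercept: float
    r2: float
    n: int
    sampled_ids: list
    seed: int | None


@dataclass
class BinnedProfile:
    bins: pd.DataFrame  # bin, n, mean_area, mean_intensity
    fit: FitResult | None  # None with only 2 bins (no residual df for the slope test)
    bin_size: int
    n_dropped: int


def _ols_poly(x, y, degree: int) -> FitResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    X = np.vander(x, degree + 1, increasing=True)
    model = sm.OLS(y, X).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        r2, slope_p = 0.0, 1.0
    else:
        r2 = float(model.rsquared)
        slope_p = float(model.pvalues[1])
    coeffs = tuple(float(c) for c in model.params)
    vertex = None
    if degree == 2 and coeffs[2] != 0:
        vertex = -coeffs[1] / (2.0 * coeffs[2])
    return FitResult(
        coefficients=coeffs,
        stderr=tuple(float(s) for s in model.bse),
        n=n,
        r2=r2,
        adjusted_r2=adjusted_r2(r2, n, degree),
        slope_p=slope_p if degree == 1 else None,
        vertex=vertex,
        df_resid=int(model.df_resid),
        ss_resid=float(model.ssr),
    )


def fit_linear(x, y) -> FitResult:
    """OLS of y on the zone index with a two-sided zero-slope t-test."""
    if len(np.asarray(x)) < 3:
        raise InsufficientDataError("linear fit requires n >= 3")
    return _ols_poly(x, y, 1)


def fit_quadratic(x, y) -> FitResult:
    """OLS on (1, z, z²); vertex -b/(2c), adjusted r² with k = 2."""
    if len(np.asarray(x)) < 4:
        raise InsufficientDataError("quadratic fit requires n >= 4")
    return _ols_poly(x, y, 2)


def compare_models(linear: FitResult, quadratic: FitResult) -> ModelComparison:
    """Partial F-test for the added quadratic term; preference by adjusted r²."""
    if linear.n != quadratic.n:
        raise AnalysisError("model comparison requires fits on identical data (same n)")
    n = linear.n
    df2 = n - 3
    if quadratic.ss_resid <= 0:
        f = np.inf
        p = 0.0
    else:
        f = (linear.ss_resid - quadratic.ss_resid) / (quadratic.ss_resid / df2)
        p = float(stats.f.sf(f, 1, df2))
    preferred = "quadratic" if quadratic.adjusted_r2 > linear.adjusted_r2 else "linear"
    return ModelComparison(preferred=preferred, f_stat=float(f), p_value=p, df=(1, df2))


def zone_summary(
    cells: pd.DataFrame,
    zone_areas_mm2,
    positive_col: str = "damage_positive",
    zone_col: str = "zone",
) -> pd.DataFrame:
    """Per case × zone counts, positive fraction and density per mm².

    ``zone_areas_mm2`` maps zone index -> area in mm² (shared across cases).
    Cells with zone 0/NaN are excluded and logged; zones with no cells yield
    a record with NaN fraction.
    """
    df = cells.copy()
    unassigned = df[zone_col].isna() | (df[zone_col] == 0)
    if unassigned.any():
        logger.warning("zone_summary: excluding %d unassigned cells", int(unassigned.sum()))
        df = df[~unassigned]
    areas = {int(z): float(a) for z, a in dict(enumerate(zone_areas_mm2, start=1)).items()} \
        if not isinstance(zone_areas_mm2, dict) else {int(k): float(v) for k, v in zone_areas_mm2.items()}
    records = []
    for (case, cond), grp in df.groupby(["case_id", "condition"], sort=True):
        for z in range(1, 7):
            sub = grp[grp[zone_col] == z]
            n_tot = len(sub)
            n_pos = int(sub[positive_col].sum())
            area = areas.get(z, np.nan)
            if n_tot == 0:
                logger.warning("zone_summary: case %s zone %d has no cells", case, z)
            records.append(
                {
                    "case_id": case,
                    "condition": cond,
                    "zone": z,
                    "n_total": n_tot,
                    "n_positive": n_pos,
                    "area_mm2": area,
                    "fraction": n_pos / n_tot if n_tot else np.nan,
                    "density_per_mm2": n_pos / area if (n_tot and area > 0) else np.nan,
                    "total_density_per_mm2": n_tot / area if area > 0 else np.nan,
                }
            )
    return pd.DataFrame(records)


def two_way_anova(records: pd.DataFrame, response: str) -> pd.DataFrame:
    """Condition × zone ANOVA with Type II sums of squares.

    Observations are case × zone summaries; the design may be unbalanced
    (e.g. 4 AD vs 3 UC cases). A constant response yields zero sums of
    squares with F and p reported missing.
    """
    df = records.dropna(subset=[response]).copy()
    for cond, grp in df.groupby("condition"):
        if grp["case_id"].nunique() < 2:
            raise AnalysisError(
                f"condition {cond!r} has fewer than 2 cases; no residual degrees of freedom"
            )
    y = df[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        idx = ["C(condition)", "C(zone)", "C(condition):C(zone)", "Residual"]
        return pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": np.nan, "PR(>F)": np.nan}, index=idx
        )
    model = smf.ols(f"{response} ~ C(condition) * C(zone)", data=df).fit()
    table = anova_lm(model, typ=2)
    return table


def unpaired_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default, Welch by flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("unpaired t-test requires n >= 2 in each group")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def size_ranked_profile(
    cells: pd.DataFrame,
    intensity_col: str = "i53bp1",
    bin_size: int = 100,
    area_col: str = "nuclear_area",
    id_col: str = "cell_id",
) -> BinnedProfile:
    """Rank cells by nuclear area, average the marker over consecutive bins.

    Ties in area are broken by cell id; cells beyond the last full bin are
    dropped. The returned fit is the OLS of bin mean intensity on bin rank
    with a zero-slope test.
    """
    df = cells.sort_values([area_col, id_col], kind="mergesort").reset_index(drop=True)
    n_bins = len(df) // bin_size
    if n_bins < 2:
        raise InsufficientDataError(
            f"need at least 2 full bins of {bin_size}; got {len(df)} cells"
        )
    used = df.iloc[: n_bins * bin_size]
    ranks = np.repeat(np.arange(1, n_bins + 1), bin_size)
    bins = (
        used.assign(bin=ranks)
        .groupby("bin")
        .agg(
            n=(id_col, "size"),
            mean_area=(area_col, "mean"),
            mean_intensity=(intensity_col, "mean"),
        )
        .reset_index()
    )
    fit = fit_linear(bins["bin"], bins["mean_intensity"]) if n_bins >= 3 else None
    return BinnedProfile(
        bins=bins, fit=fit, bin_size=bin_size, n_dropped=len(df) - n_bins * bin_size
    )


def coupling_regression(
    cells: pd.DataFrame,
    per_case_n: int = 100,
    seed: int | None = 0,
    x_col: str = "i53bp1",
    y_col: str = "p16_nuclear",
    positive_col: str | None = "damage_positive",
    id_col: str = "cell_id",
) -> CouplingResult:
    """Per-cell marker-coupling regression on a random sample of cells per case.

    Cells are restricted to the damage-positive subset (unless
    ``positive_col`` is None, meaning pre-filtered input), then up to
    ``per_case_n`` cells are drawn per case without replacement (seeded), and
    nuclear p16 is regressed on 53BP1 intensity over the pooled sample.
    """
    df = cells if positive_col is None else cells[cells[positive_col].astype(bool)]
    rng = np.random.default_rng(seed)
    picked = []
    for case in sorted(cells["case_id"].unique()):
        grp = df[df["case_id"] == case]
        if len(grp) == 0:
            raise AnalysisError(f"case {case!r} has no eligible cells")
        if len(grp) < per_case_n:
            logger.warning(
                "coupling_regression: case %s has only %d eligible cells (< %d); using all",
                case, len(grp), per_case_n,
            )
            picked.append(grp)
        else:
            idx = rng.choice(len(grp), size=per_case_n, replace=False)
            picked.append(grp.iloc[np.sort(idx)])
    if not picked:
        raise AnalysisError("no cases present")
    sample = pd.concat(picked, ignore_index=True)
    fit = fit_linear(sample[x_col], sample[y_col])
    return CouplingResult(
        slope=fit.coefficients[1],
        intercept=fit.coefficients[0],
        r2=fit.r2,
        n=len(sample),
        sampled_ids=sample[id_col].tolist(),
        seed=seed,
    )


def subset_intensity_profiles(
    cells: pd.DataFrame,
    subset: str = "positive",
    compartment: str = "nuclear",
    positive_col: str = "damage_positive",
    zone_col: str = "zone",
    value_cols: dict | None = None,
) -> tuple[pd.DataFrame, FitResult]:
    """Per-zone per-case mean p16 of a 53BP1 subset, plus its depth fit.

    ``subset`` is "positive" or "negative"; ``compartment`` "nuclear" or
    "annulus" selects the p16 column (override via ``value_cols``). The fit
    regresses case-zone mean intensity on zone index. Empty zone/case cells
    are reported missing and logged.
    """
    value_cols = value_cols or {"nuclear": "p16_nuclear", "annulus": "p16_cytoplasmic"}
    if compartment not in value_cols:
        raise AnalysisError(f"unknown compartment {compartment!r}; options: {sorted(value_cols)}")
    col = value_cols[compartment]
    mask = cells[positive_col].astype(bool)
    df = cells[mask if subset == "positive" else ~mask]
    means = (
        df.groupby(["case_id", "condition", zone_col])[col]
        .mean()
        .rename("mean_intensity")
        .reset_index()
    )
    # ensure every case x zone appears, missing where empty
    cases = cells[["case_id", "condition"]].drop_duplicates()
    full = cases.merge(pd.DataFrame({zone_col: range(1, 7)}), how="cross")
    means = full.merge(means, on=["case_id", "condition", zone_col], how="left")
    n_missing = int(means["mean_intensity"].isna().sum())
    if n_missing:
        logger.warning("subset_intensity_profiles: %d empty case-zone cells", n_missing)
    valid = means.dropna(subset=["mean_intensity"])
    fit = fit_linear(valid[zone_col], valid["mean_intensity"])
    return means, fit


def culture_fractions(culture: pd.DataFrame) -> dict:
    """Replicate-level positive fractions, condition means ± SEM, pairwise
    unpaired t-tests on gamma-H2AX fractions, and the per-cell p27 vs
    gamma-H2AX regression within each condition."""
    reps = (
        culture.groupby(["condition", "replicate_id"])
        .agg(
            n=("cell_id", "size"),
            gh2ax_fraction=("gh2ax_positive", "mean"),
            p27_fraction=("p27_positive", "mean"),
        )
        .reset_index()
    )
    counts = reps.groupby("condition")["replicate_id"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise AnalysisError(f"conditions {bad} have a single replicate; SEM undefined")
    summary = (
        reps.groupby("condition")
        .agg(
            n_replicates=("replicate_id", "nunique"),
            gh2ax_fraction=("gh2ax_fraction", "mean"),
            gh2ax_sem=("gh2ax_fraction", "sem"),
            p27_fraction=("p27_fraction", "mean"),
            p27_sem=("p27_fraction", "sem"),
        )
        .reset_index()
    )
    conds = summary["condition"].tolist()
    pairwise = []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            a = reps.loc[reps["condition"] == conds[i], "gh2ax_fraction"]
            b = reps.loc[reps["condition"] == conds[j], "gh2ax_fraction"]
            t, p = unpaired_t(a, b)
            pairwise.append({"a": conds[i], "b": conds[j], "t": t, "p": p})
    regressions = {}
    for cond, grp in culture.groupby("condition"):
        regressions[cond] = fit_linear(grp["gh2ax_intensity"], grp["p27_intensity"])
    return {
        "replicates": reps,
        "summary": summary,
        "pairwise_gh2ax": pd.DataFrame(pairwise),
        "p27_on_gh2ax": regressions,
    }
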