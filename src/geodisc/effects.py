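"""Annual tenure-effect estimation with random-intercept mixed models.

For each year the matched sample is fit with

    y = b0 + b1 * treated + beta' Z + alpha_stratum + e

where ``y`` is carbon density (t C/ha), ``treated`` the tenure dummy, ``Z``
the five spatial-location covariates (plus region dummies when the landscape
has several regions), and ``alpha`` a random intercept per matched sub-group.
Covariate fixed effects are centered on the control-arm means of the matched
sample, so the fixed intercept ``b0`` is the adjusted mean annual carbon
density of other lands (the baseline) and ``b1`` the adjusted tenure-vs-other
difference (the temporal or spatial effect).  Estimation is REML with Wald
95% confidence intervals.

Falsification (placebo) tests refit the same model with one matching
covariate as the outcome; effects indistinguishable from zero support the
as-if-random treatment assignment that matching is meant to deliver.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .cem import MatchedSet
from .landscape import COVARIATES, LandscapeGrid, carbon_col

logger = logging.getLogger(__name__)

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class EffectEstimate:
    """Fixed-effect products of one annual model fit."""

    year: int | None
    tenure_class: str
    outcome: str
    b0: float
    b1: float
    se_b0: float
    se_b1: float
    ci_b0: tuple[float, float]
    ci_b1: tuple[float, float]
    p_value: float
    beta: dict[str, float]
    n_units: int
    n_strata: int
    df: float = np.inf  # reference-distribution degrees of freedom
    singular_fallback: bool = False
    standardized: float | None = None  # falsification: b1 / pre-match pooled SD

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def covers_zero(self) -> bool:
        lo, hi = self.ci_b1
        return lo <= 0.0 <= hi


def percent_effect(estimate: EffectEstimate) -> float:
    """Effect relative to the baseline, 100 * b1 / b0 (%).

    Display convention rounds to the nearest integer, e.g. b1 = 37 on a
    baseline b0 = 39 reads as a 95% larger stock.  Undefined for b0 <= 0.
    """
    if estimate.b0 <= 0:
        raise ValueError("percent effect undefined for non-positive baseline")
    return 100.0 * estimate.b1 / estimate.b0


def _design(
    table: pd.DataFrame,
    matched: MatchedSet,
    outcome: str,
    covariates: tuple[str, ...],
    include_region: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (y, X, groups, names) for the matched sample.

    Covariate columns (and region dummies) are centered on control-arm means
    so the intercept is the adjusted control mean.
    """
    assign = matched.assignments()
    idx = table.set_index("cell_id")
    sub = idx.loc[assign["cell_id"]].reset_index()
    sub["treated"] = assign["treated"].to_numpy()
    sub["stratum"] = assign["stratum"].to_numpy()

    y = sub[outcome].to_numpy(dtype=float)
    cols = [np.ones(len(sub)), sub["treated"].to_numpy(dtype=float)]
    names = ["const", "treated"]
    ctrl = sub["treated"].to_numpy() == 0
    for cov in covariates:
        v = sub[cov].to_numpy(dtype=float)
        cols.append(v - v[ctrl].mean())
        names.append(cov)
    if include_region and "region" in sub.columns and sub["region"].nunique() > 1:
        dummies = pd.get_dummies(sub["region"], drop_first=True, dtype=float)
        for rname in dummies.columns:
            v = dummies[rname].to_numpy()
            cols.append(v - v[ctrl].mean())
            names.append(f"region[{rname}]")
    X = np.column_stack(cols)
    return y, X, sub["stratum"].to_numpy(), names


def _package(
    params, bse, names, matched, year, outcome, n_units, n_strata, df, fallback
) -> EffectEstimate:
    # t reference with between-within df (n_strata - 2): Wald inference with a
    # normal reference is anti-conservative when few matched sub-groups carry
    # the random intercept
    b0, b1 = float(params[0]), float(params[1])
    se0, se1 = float(bse[0]), float(bse[1])
    crit = float(stats.t.ppf(0.975, df)) if np.isfinite(df) else _Z95
    if se1 > 0:
        p = float(2 * stats.t.sf(abs(b1) / se1, df))
    else:
        p = 1.0 if b1 == 0 else 0.0
    beta = {n: float(v) for n, v in zip(names[2:], params[2:])}
    return EffectEstimate(
        year=year,
        tenure_class=matched.treatment_class,
        outcome=outcome,
        b0=b0,
        b1=b1,
        se_b0=se0,
        se_b1=se1,
        ci_b0=(b0 - crit * se0, b0 + crit * se0),
        ci_b1=(b1 - crit * se1, b1 + crit * se1),
        p_value=p,
        beta=beta,
        n_units=n_units,
        n_strata=n_strata,
        df=df,
        singular_fallback=fallback,
    )


def fit_effect(
    matched: MatchedSet,
    grid: LandscapeGrid,
    year: int | None = None,
    outcome: str | None = None,
    covariates: tuple[str, ...] = COVARIATES,
    include_region: bool = True,
) -> EffectEstimate:
    """Fit the random-intercept model on the matched sample for one outcome.

    ``outcome`` defaults to the carbon column of ``year``.  Requires at least
    two retained strata.  A singular random-effect fit (stratum variance at
    the boundary or numerical failure) falls back to the equivalent ordinary
    least-squares fit and is flagged.
    """
    if matched.is_empty:
        raise ValueError("cannot fit on an empty matched set")
    if matched.n_strata < 2:
        raise ValueError("need at least 2 matched strata to fit a mixed model")
    if outcome is None:
        if year is None:
            raise ValueError("either year or outcome must be given")
        outcome = carbon_col(year)

    y, X, groups, names = _design(grid.table, matched, outcome, covariates, include_region)
    n_units, n_strata = len(y), len(np.unique(groups))

    if np.ptp(y) == 0.0:
        # degenerate outcome: every unit identical; exact answer, no model fit
        zeros = np.zeros(X.shape[1])
        params = zeros.copy()
        params[0] = y[0]
        return _package(params, zeros, names, matched, year, outcome,
                        n_units, n_strata, np.inf, False)

    # guard collinear columns (e.g. a covariate constant within the sample)
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
    X = X[:, keep]
    names = [names[j] for j in keep]

    if n_units < X.shape[1] + 3:
        raise ValueError(
            f"too few matched units ({n_units}) for {X.shape[1]} fixed effects"
        )

    df = max(n_strata - 2, 1)
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
        params, bse = res.params[: X.shape[1]], res.bse[: X.shape[1]]
        if not (np.all(np.isfinite(params[:2])) and np.all(np.isfinite(bse[:2]))):
            raise np.linalg.LinAlgError("non-finite mixed-model estimates")
    except (np.linalg.LinAlgError, ValueError) as err:
        logger.warning("mixed model fit failed (%s); falling back to OLS", err)
        fallback = True
        res = sm.OLS(y, X).fit()
        params, bse = res.params, res.bse
        df = max(int(res.df_resid), 1)

    return _package(
        np.asarray(params), np.asarray(bse),
        names, matched, year, outcome, n_units, n_strata, df, fallback,
    )


@dataclass
class TemporalSeries:
    """Annual effect estimates for one tenure class, matched once."""

    tenure_class: str
    estimates: list[EffectEstimate]

    @property
    def years(self) -> list[int]:
        return [e.year for e in self.estimates]

    @property
    def b1(self) -> np.ndarray:
        return np.array([e.b1 for e in self.estimates])

    @property
    def effect_change(self) -> float:
        """b1 in the last year minus b1 in the first year (t C/ha)."""
        return float(self.estimates[-1].b1 - self.estimates[0].b1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "year": e.year,
                    "tenure": e.tenure_class,
                    "b0": e.b0,
                    "b1": e.b1,
                    "se_b1": e.se_b1,
                    "ci_lo": e.ci_b1[0],
                    "ci_hi": e.ci_b1[1],
                    "pct": percent_effect(e) if e.b0 > 0 else np.nan,
                    "p_value": e.p_value,
                    "n_units": e.n_units,
                    "n_strata": e.n_strata,
                }
                for e in self.estimates
            ]
        )


def temporal_series(
    grid: LandscapeGrid,
    matched: MatchedSet,
    years: tuple[int, ...] | None = None,
    covariates: tuple[str, ...] = COVARIATES,
    include_region: bool = True,
) -> TemporalSeries:
    """One annual effect estimate per year on a single matched sample.

    Matching is performed once on the time-invariant covariates and reused
    across years, so year-to-year differences in b1 reflect outcome dynamics
    rather than sample drift.
    """
    years = grid.years if years is None else years
    if not years:
        raise ValueError("no years requested")
    ests = [
        fit_effect(matched, grid, year=y, covariates=covariates,
                   include_region=include_region)
        for y in years
    ]
    return TemporalSeries(tenure_class=matched.treatment_class, estimates=ests)


def falsification_test(
    matched: MatchedSet,
    grid: LandscapeGrid,
    covariate: str,
    covariates: tuple[str, ...] = COVARIATES,
    include_region: bool = True,
) -> EffectEstimate:
    """Placebo fit with a matching covariate as the outcome.

    The tested covariate is excluded from the fixed effects; the remaining
    four stay in.  The estimate carries a standardized effect (b1 over the
    pre-matching pooled SD of the covariate) so magnitudes are comparable
    across covariates with different units.
    """
    if covariate not in covariates:
        raise ValueError(f"{covariate!r} is not a matching covariate")
    others = tuple(c for c in covariates if c != covariate)
    est = fit_effect(
        matched, grid, outcome=covariate, covariates=others,
        include_region=include_region,
    )
    sub = grid.table[
        (grid.table["tenure"] == matched.treatment_class)
        | (grid.table["tenure"] == "OTHER")
    ]
    t = sub.loc[sub["tenure"] == matched.treatment_class, covariate].to_numpy(float)
    c = sub.loc[sub["tenure"] == "OTHER", covariate].to_numpy(float)
    pooled = float(np.sqrt((t.var(ddof=1) + c.var(ddof=1)) / 2.0))
    est.standardized = est.b1 / pooled if pooled > 0 else 0.0
    return est
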