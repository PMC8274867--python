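"""Coarsened exact matching (CEM) with balance diagnostics.

Each covariate is coarsened into bins (fixed-width, explicit cutpoints, or
categorical identity); units sharing the joint coarsened key across all
covariates (plus any extra exact-match keys, e.g. administrative region or a
spatial tile) form a matching sub-group (stratum).  Strata lacking at least
one treated and one control unit are pruned.  The retained strata serve both
as the matched sample and as the random-intercept grouping of the effect
models downstream.

Balance before and after matching is assessed with standardized mean
differences (SMD) and Kolmogorov-Smirnov (KS) statistics; the pooled SD in
the SMD denominator is fixed at its pre-matching value so before/after values
are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import COVARIATES

logger = logging.getLogger(__name__)


class SpecError(ValueError):
    """Invalid coarsening specification."""


@dataclass(frozen=True)
class CoarseningSpec:
    """How to coarsen one covariate.

    mode ``fixed_width``: bin = floor((v - anchor) / width), half-open
    intervals [anchor + k·w, anchor + (k+1)·w).  mode ``cutpoints``: half-open
    intervals between strictly increasing cutpoints, with open-ended bins
    beyond either end.  mode ``exact_categorical``: identity.
    """

    mode: str = "fixed_width"
    width: float | None = None
    cutpoints: tuple[float, ...] | None = None
    anchor: float = 0.0

    def __post_init__(self):
        if self.mode == "fixed_width":
            if self.width is None or self.width <= 0:
                raise SpecError("fixed_width requires width > 0")
        elif self.mode == "cutpoints":
            if not self.cutpoints or len(self.cutpoints) < 1:
                raise SpecError("cutpoints mode requires at least one cutpoint")
            cp = np.asarray(self.cutpoints, dtype=float)
            if not np.all(np.diff(cp) > 0):
                raise SpecError("cutpoints must be strictly increasing")
        elif self.mode != "exact_categorical":
            raise SpecError(f"unknown coarsening mode {self.mode!r}")


#: default coarsening choices: 100 m elevation intervals, 5-degree slope
#: intervals, 5 km intervals for the three distance covariates.  The slope
#: and distance widths are configurable placeholders, not reference values.
DEFAULT_SPECS: dict[str, CoarseningSpec] = {
    "elevation": CoarseningSpec(mode="fixed_width", width=100.0),
    "slope": CoarseningSpec(mode="fixed_width", width=5.0),
    "dist_roads": CoarseningSpec(mode="fixed_width", width=5.0),
    "dist_settlements": CoarseningSpec(mode="fixed_width", width=5.0),
    "dist_rivers": CoarseningSpec(mode="fixed_width", width=5.0),
}


def coarsen(values, spec: CoarseningSpec) -> np.ndarray:
    """Map covariate values to integer bin indices under ``spec``."""
    v = np.asarray(values)
    if spec.mode == "fixed_width":
        return np.floor((v.astype(float) - spec.anchor) / spec.width).astype(np.int64)
    if spec.mode == "cutpoints":
        # searchsorted(right) puts v == cutpoint into the upper bin: [c_i, c_{i+1})
        cp = np.asarray(spec.cutpoints, dtype=float)
        bins = np.searchsorted(cp, v.astype(float), side="right")
        n_outside = int(((bins == 0) | (bins == len(cp))).sum())
        if n_outside:
            logger.debug("%d values fell in open-ended end bins", n_outside)
        return bins.astype(np.int64)
    # exact_categorical: identity on category codes
    codes, _ = pd.factorize(v, sort=True)
    return codes.astype(np.int64)


@dataclass
class MatchedSet:
    """CEM output: retained strata and bookkeeping.

    ``strata`` maps the joint coarsened key to (treated cell_ids, control
    cell_ids); every retained stratum has at least one unit in each arm.
    """

    treatment_class: str
    specs: dict[str, CoarseningSpec]
    strata: dict[tuple, tuple[list, list]]
    n_treated_before: int
    n_control_before: int
    extra_exact: tuple[str, ...] = ()

    @property
    def is_empty(self) -> bool:
        return not self.strata

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def treated_ids(self) -> list:
        return [i for t, _ in self.strata.values() for i in t]

    @property
    def control_ids(self) -> list:
        return [i for _, c in self.strata.values() for i in c]

    @property
    def n_treated(self) -> int:
        return len(self.treated_ids)

    @property
    def n_control(self) -> int:
        return len(self.control_ids)

    @property
    def n_pruned_treated(self) -> int:
        return self.n_treated_before - self.n_treated

    @property
    def n_pruned_control(self) -> int:
        return self.n_control_before - self.n_control

    def assignments(self) -> pd.DataFrame:
        """Tidy frame: cell_id, stratum index, treated flag."""
        rows = []
        for s, (key, (t_ids, c_ids)) in enumerate(self.strata.items()):
            rows.extend({"cell_id": i, "stratum": s, "treated": 1} for i in t_ids)
            rows.extend({"cell_id": i, "stratum": s, "treated": 0} for i in c_ids)
        return pd.DataFrame(rows, columns=["cell_id", "stratum", "treated"])


def build_matched_set(
    table: pd.DataFrame,
    treatment_class: str,
    specs: dict[str, CoarseningSpec] | None = None,
    extra_exact: tuple[str, ...] = (),
    covariates: tuple[str, ...] = COVARIATES,
) -> MatchedSet:
    """Form CEM strata of ``treatment_class`` cells vs other lands.

    Control pool is strictly tenure == OTHER; cells under any different tenure
    class are excluded so controls are never themselves protected.  Strata are
    keyed by the joint coarsened covariate bins plus any ``extra_exact``
    categorical columns; strata without both arms are pruned.
    """
    specs = dict(DEFAULT_SPECS if specs is None else specs)
    sub = table[(table["tenure"] == treatment_class) | (table["tenure"] == "OTHER")]
    treated = sub["tenure"].to_numpy() == treatment_class
    n_t, n_c = int(treated.sum()), int((~treated).sum())
    if n_t == 0 or n_c == 0:
        raise ValueError(
            f"need at least one {treatment_class} and one OTHER cell to match"
        )

    key_cols = [coarsen(sub[c].to_numpy(), specs[c]) for c in covariates]
    for col in extra_exact:
        codes, _ = pd.factorize(sub[col], sort=True)
        key_cols.append(codes.astype(np.int64))
    keys = list(zip(*(col.tolist() for col in key_cols)))

    ids = sub["cell_id"].tolist()
    groups: dict[tuple, tuple[list, list]] = {}
    for key, cid, is_t in zip(keys, ids, treated.tolist()):
        t_ids, c_ids = groups.setdefault(key, ([], []))
        (t_ids if is_t else c_ids).append(cid)
    strata = {k: v for k, v in sorted(groups.items()) if v[0] and v[1]}
    if not strata:
        logger.warning(
            "CEM produced no stratum with both arms for %s", treatment_class
        )
    return MatchedSet(
        treatment_class=treatment_class,
        specs=specs,
        strata=strata,
        n_treated_before=n_t,
        n_control_before=n_c,
        extra_exact=tuple(extra_exact),
    )


# ---------------------------------------------------------------------------
# Balance diagnostics


def _smd(t: np.ndarray, c: np.ndarray, pooled_sd: float) -> float:
    diff = float(np.mean(t) - np.mean(c))
    if pooled_sd == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / pooled_sd


def _ks(t: np.ndarray, c: np.ndarray) -> float:
    # sup distance between arm-wise empirical CDFs
    allv = np.concatenate([t, c])
    allv.sort()
    cdf_t = np.searchsorted(np.sort(t), allv, side="right") / len(t)
    cdf_c = np.searchsorted(np.sort(c), allv, side="right") / len(c)
    return float(np.abs(cdf_t - cdf_c).max())


@dataclass
class BalanceReport:
    treatment_class: str
    rows: pd.DataFrame  # covariate, smd_before, smd_after, ks_before, ks_after
    n_treated_before: int
    n_control_before: int
    n_treated_after: int
    n_control_after: int

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            f"balance for {self.treatment_class}: "
            f"T {self.n_treated_before}->{self.n_treated_after}, "
            f"C {self.n_control_before}->{self.n_control_after}"
        ]
        for _, r in self.rows.iterrows():
            lines.append(
                f"  {r['covariate']:<18} SMD {r['smd_before']:+.3f} -> {r['smd_after']:+.3f}"
                f"   KS {r['ks_before']:.3f} -> {r['ks_after']:.3f}"
            )
        return "\n".join(lines)


def balance_report(
    table: pd.DataFrame,
    matched: MatchedSet,
    covariates: tuple[str, ...] = COVARIATES,
) -> BalanceReport:
    """SMD and KS per covariate, before vs after matching.

    SMD = (mean_T - mean_C) / pooled SD, with the pooled SD taken from the
    pre-matching sample in both rows.  Zero pooled SD with equal means gives
    SMD 0; with unequal means it is flagged infinite.
    """
    if matched.is_empty:
        raise ValueError("matched set is empty")
    sub = table[
        (table["tenure"] == matched.treatment_class) | (table["tenure"] == "OTHER")
    ]
    t_before = sub[sub["tenure"] == matched.treatment_class]
    c_before = sub[sub["tenure"] == "OTHER"]
    idx = table.set_index("cell_id")
    t_after = idx.loc[matched.treated_ids]
    c_after = idx.loc[matched.control_ids]

    rows = []
    for cov in covariates:
        tb, cb = t_before[cov].to_numpy(float), c_before[cov].to_numpy(float)
        ta, ca = t_after[cov].to_numpy(float), c_after[cov].to_numpy(float)
        # pooled SD of the pre-matching sample, held fixed across before/after
        pooled = float(np.sqrt((tb.var(ddof=1) + cb.var(ddof=1)) / 2.0))
        rows.append(
            {
                "covariate": cov,
                "smd_before": _smd(tb, cb, pooled),
                "smd_after": _smd(ta, ca, pooled),
                "ks_before": _ks(tb, cb),
                "ks_after": _ks(ta, ca),
            }
        )
    return BalanceReport(
        treatment_class=matched.treatment_class,
        rows=pd.DataFrame(rows),
        n_treated_before=len(t_before),
        n_control_before=len(c_before),
        n_treated_after=matched.n_treated,
        n_control_after=matched.n_control,
    )


def check_balance(
    report: BalanceReport, smd_threshold: float = 0.1, ks_threshold: float = 0.1
) -> pd.DataFrame:
    """Pass/fail per covariate on after-matching |SMD| and KS.

    Failure is logged as a warning, not raised: imbalance degrades but does
    not invalidate the matched analysis, and the covariates re-enter the
    effect models as fixed effects.
    """
    out = report.rows.copy()
    out["smd_pass"] = out["smd_after"].abs() <= smd_threshold
    out["ks_pass"] = out["ks_after"] <= ks_threshold
    out["pass"] = out["smd_pass"] & out["ks_pass"]
    for _, r in out[~out["pass"]].iterrows():
        logger.warning(
            "covariate %s imbalanced after matching (SMD %.3f, KS %.3f)",
            r["covariate"],
            r["smd_after"],
            r["ks_after"],
        )
    return out[["covariate", "smd_after", "ks_after", "smd_pass", "ks_pass", "pass"]]


def width_search(
    table: pd.DataFrame,
    treatment_class: str,
    candidate_scales: tuple[float, ...] = (1.0, 0.5, 0.25),
    base_specs: dict[str, CoarseningSpec] | None = None,
    smd_threshold: float = 0.1,
    ks_threshold: float = 0.1,
    covariates: tuple[str, ...] = COVARIATES,
) -> tuple[MatchedSet, BalanceReport]:
    """Optional grid-search helper over proportionally finer bin widths.

    Tries each scale factor on all fixed-width specs, coarsest first, and
    returns the first matched set whose balance check passes every covariate;
    if none passes, returns the finest non-empty result.
    """
    base = dict(DEFAULT_SPECS if base_specs is None else base_specs)
    best = None
    for scale in candidate_scales:
        specs = {
            k: (
                CoarseningSpec(mode="fixed_width", width=s.width * scale, anchor=s.anchor)
                if s.mode == "fixed_width"
                else s
            )
            for k, s in base.items()
        }
        matched = build_matched_set(table, treatment_class, specs, covariates=covariates)
        if matched.is_empty:
            continue
        report = balance_report(table, matched, covariates)
        best = (matched, report)
        flags = check_balance(report, smd_threshold, ks_threshold)
        if bool(flags["pass"].all()):
            return matched, report
    if best is None:
        raise ValueError("no candidate coarsening produced a non-empty match")
    return best
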