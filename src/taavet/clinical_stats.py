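"""Clinical association statistics for TMA groupings.

Exact 2x2 contingency testing (Fisher), Pearson chi-squared for larger
tables, Spearman rank correlation, Kaplan-Meier estimation with median
survival, the two-group log-rank test, and the association battery that
drives them over a TMA cohort.

Conventions
-----------
* Fisher's two-sided p uses the point-probability method: the sum of
  hypergeometric probabilities of all tables with the observed margins whose
  point probability does not exceed that of the observed table (with a
  1 + 1e-7 relative tolerance against floating-point ties).
* Median survival is the smallest event time at which the Kaplan-Meier
  estimate falls to 0.5 or below; undefined if the curve never reaches 0.5.
* Spearman's p is exact (full permutation) for n <= 8 and uses the
  t-approximation otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from taavet.expression_filter import ValidationError
from taavet.ihc import IntensityGroup, TMASample

__all__ = [
    "SurvivalCurve",
    "fisher_exact_2x2",
    "chi_squared_test",
    "spearman_rho",
    "km_curve",
    "logrank_test",
    "association_battery",
]

_FISHER_RELTOL = 1.0 + 1e-7


def _validate_counts(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError("contingency counts must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    return arr


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of counts.

    With row margin r1, column margin c1 and grand total N fixed, the
    top-left count a follows a hypergeometric distribution; the two-sided p
    sums P(a') over all admissible a' whose point probability is <= that of
    the observed a (point-probability convention).  A zero margin carries no
    information and yields p = 1.
    """
    arr = _validate_counts(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValidationError("empty contingency table")
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log hypergeometric pmf over the support
    logpmf = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - support + 1)
        - gammaln(n - r1 - c1 + support + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * _FISHER_RELTOL].sum())
    return min(p, 1.0)


def chi_squared_test(table: Sequence[Sequence[int]]) -> tuple[float, float, int]:
    """Pearson chi-squared test of independence (no continuity correction).

    Returns ``(statistic, p_value, df)`` with expected counts from the
    margins and df = (r-1)(c-1).  A zero expected cell is an error; use the
    exact test instead.
    """
    arr = _validate_counts(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("chi-squared needs at least a 2x2 table")
    if arr.sum() == 0:
        raise ValidationError("empty contingency table")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected == 0).any():
        raise ValidationError(
            "zero expected cell count; use the exact test for sparse tables"
        )
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p), int(df)


def _rank_average(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rank correlation with tie-averaged ranks.

    rho is the Pearson correlation of the average ranks.  The p-value is
    exact by full permutation of one margin for n <= 8 (two-sided,
    |rho_perm| >= |rho_obs|), and the usual t-approximation for larger n.
    Constant input has no defined rank correlation and raises.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    n = xa.size
    if n < 2:
        raise ValidationError("need at least 2 observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValidationError("constant input: Spearman rho is undefined")
    rx, ry = _rank_average(xa), _rank_average(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        # exact two-sided permutation distribution of rho
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum())
        count = 0
        total = 0
        ry_c = ry - ry.mean()
        sy = np.sqrt((ry_c**2).sum())
        target = abs(rho) * (1 - 1e-12)
        for perm in itertools.permutations(range(n)):
            r = float(rx_c @ ry_c[list(perm)]) / (denom * sy)
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(float(p), 1.0)


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier product-limit curve.

    ``times`` is the ordered grid of observed times (events and censorings),
    ``survival`` the estimate at each time, ``at_risk`` the risk-set size
    just before each time.  ``median`` is the smallest *event* time with
    S <= 0.5, or None if the curve never falls that low.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    event_times: np.ndarray
    median: Optional[float]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier estimate of the survival function.

    Censored observations leave the risk set without producing a step.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if (t < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    grid = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(tbl.index).to_numpy(dtype=float)
    at_risk = tbl["at_risk"].to_numpy(dtype=float)
    event_mask = tbl["observed"].to_numpy() > 0
    event_times = grid[event_mask]
    median: Optional[float] = None
    for et in event_times:
        s = surv[np.searchsorted(grid, et)]
        if s <= 0.5:
            median = float(et)
            break
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        event_times=event_times,
        median=median,
    )


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-squared statistic on 1 df, p).

    With no events in either group the test carries no information:
    statistic 0, p = 1 (with a warning).
    """
    from lifelines.statistics import logrank_test as _lifelines_logrank

    ta, ea = np.asarray(group_a[0], dtype=float), np.asarray(group_a[1], dtype=bool)
    tb, eb = np.asarray(group_b[0], dtype=float), np.asarray(group_b[1], dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank is uninformative")
        return 0.0, 1.0
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if np.isnan(stat):
        return 0.0, 1.0
    return stat, min(max(p, np.nextafter(0, 1)), 1.0)


# ---------------------------------------------------------------------------
# Association battery over a TMA cohort
# ---------------------------------------------------------------------------

_BINARY_COVARIATES = {
    "grade": lambda s: None if s.grade is None else ("3" if s.grade >= 3 else "<=2"),
    "t_stage": lambda s: None if s.t_stage is None else ("3+" if s.t_stage >= 3 else "<3"),
    "perit_carc": lambda s: None if s.perit_carc is None else ("yes" if s.perit_carc else "no"),
    "residual_tumor": lambda s: None
    if s.residual_tumor is None
    else ("yes" if s.residual_tumor else "no"),
    "platinum_response": lambda s: s.platinum_response
    if s.platinum_response in ("yes", "no")
    else None,
}

_GROUPINGS = {
    # negative/weak vs moderate/strong consensus staining
    "intensity-dichotomy": lambda s: s.intensity_group.value,
    # Q < 150 (none-to-heterogeneous) vs Q >= 150 (high, homogeneous)
    "q-bin": lambda s: "q>=150" if s.q >= 150 else "q<150",
}


def association_battery(
    samples: Iterable[TMASample],
    test_policy: str = "auto",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run the exploratory clinical association battery over a TMA cohort.

    For every antigen and each grouping (intensity dichotomy; Q-Score split
    at 150) the binary clinical covariates are tested for association
    (Fisher's exact for 2x2 under the default ``auto`` policy, chi-squared
    otherwise or when ``test_policy='chi2'``), and progression-free survival
    is compared by the log-rank test.

    No multiple-testing correction is applied by default (exploratory
    analysis); ``bonferroni=True`` adds an adjusted-p column.
    """
    if test_policy not in ("auto", "fisher", "chi2"):
        raise ValidationError(f"unknown test policy {test_policy!r}")
    rows: list[dict] = []
    by_antigen: dict[str, list[TMASample]] = {}
    for s in samples:
        if s.assessable:
            by_antigen.setdefault(s.antigen, []).append(s)

    for antigen in sorted(by_antigen):
        cohort = by_antigen[antigen]
        for gname, gfun in _GROUPINGS.items():
            for cname, cfun in _BINARY_COVARIATES.items():
                pairs = [(gfun(s), cfun(s)) for s in cohort if cfun(s) is not None]
                if not pairs:
                    continue
                g_levels = sorted({g for g, _ in pairs})
                c_levels = sorted({c for _, c in pairs})
                if len(g_levels) < 2 or len(c_levels) < 2:
                    continue
                table = np.array(
                    [
                        [sum(1 for g, c in pairs if g == gl and c == cl) for cl in c_levels]
                        for gl in g_levels
                    ]
                )
                use_fisher = test_policy == "fisher" or (
                    test_policy == "auto" and table.shape == (2, 2)
                )
                if use_fisher:
                    p = fisher_exact_2x2(table)
                    rows.append(
                        dict(antigen=antigen, grouping=gname, covariate=cname,
                             test="fisher_exact", statistic=np.nan, p=p)
                    )
                else:
                    try:
                        stat, p, _ = chi_squared_test(table)
                    except ValidationError:
                        continue
                    rows.append(
                        dict(antigen=antigen, grouping=gname, covariate=cname,
                             test="chi_squared", statistic=stat, p=p)
                    )
            # log-rank on PFS between the two grouping levels
            with_surv = [
                s for s in cohort if s.pfs_months is not None and s.pfs_event is not None
            ]
            levels = sorted({gfun(s) for s in with_surv})
            if len(levels) == 2:
                ga = [(s.pfs_months, s.pfs_event) for s in with_surv if gfun(s) == levels[0]]
                gb = [(s.pfs_months, s.pfs_event) for s in with_surv if gfun(s) == levels[1]]
                stat, p = logrank_test(
                    ([t for t, _ in ga], [e for _, e in ga]),
                    ([t for t, _ in gb], [e for _, e in gb]),
                )
                rows.append(
                    dict(antigen=antigen, grouping=gname, covariate="pfs",
                         test="logrank", statistic=stat, p=p)
                )
    df = pd.DataFrame(
        rows, columns=["antigen", "grouping", "covariate", "test", "statistic", "p"]
    )
    if bonferroni and len(df):
        df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(df))
    return df
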