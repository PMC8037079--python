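"""Score-development procedure: dichotomize, screen, select.

The development pipeline mirrors how simple additive clinical scores are
built from registry data:

1. Each candidate variable is dichotomized.  For continuous measures the
   cut-off is searched over a small clinically sensible grid, choosing the
   least extreme cut-off whose exposed-group mortality reaches a target
   (default 30%).
2. For each dichotomy a 2x2 exposure-by-outcome table is formed and the
   univariable odds ratio with a 95% Wald confidence interval is computed.
   Optionally, a multivariable logistic model supplies adjusted odds
   ratios instead.
3. Candidates whose odds ratio exceeds a threshold (default 2.0) become
   one-point criteria of the final additive score.

Odds ratios are crude cross-product ratios by default; a Haldane-Anscombe
continuity correction (k = 0.5 added to each cell) is available for tables
with zero cells.  The logistic model is fit by iteratively reweighted
least squares with an explicit divergence guard, so perfect separation
surfaces as a diagnostic error rather than a silently absurd coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .scores import ScoreDefinition, threshold_criterion
from .types import Cohort, DomainError, PatientRecord

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Logistic fit diverged, typically from (quasi-)separation."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure-by-outcome counts: a/b exposed died/survived, c/d unexposed."""

    a: int
    b: int
    c: int
    d: int
    label_exposed: str = "exposed"
    label_unexposed: str = "unexposed"
    n_unevaluable: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    mortality_exposed: float
    mortality_unexposed: float
    n_exposed: int
    n_unexposed: int
    degenerate: bool = False  # zero cell without continuity correction


def contingency(
    cohort: Cohort,
    predicate: Callable[[PatientRecord], Optional[bool]],
    label_exposed: str = "exposed",
    label_unexposed: str = "unexposed",
) -> ContingencyTable2x2:
    """Cross-tabulate a dichotomized predictor against in-hospital death.

    Records where the predicate is unevaluable (missing inputs) are dropped
    from the table and counted in ``n_unevaluable``.
    """
    a = b = c = d = dropped = 0
    for record in cohort.records:
        exposed = predicate(record)
        if exposed is None:
            dropped += 1
        elif exposed:
            a += record.died_in_hospital
            b += not record.died_in_hospital
        else:
            c += record.died_in_hospital
            d += not record.died_in_hospital
    return ContingencyTable2x2(
        a=a, b=b, c=c, d=d,
        label_exposed=label_exposed,
        label_unexposed=label_unexposed,
        n_unevaluable=dropped,
    )


def table_from_group_rates(
    n_exposed: int,
    mortality_exposed: float,
    n_unexposed: int,
    mortality_unexposed: float,
    **labels,
) -> ContingencyTable2x2:
    """Reconstruct a 2x2 table from subgroup sizes and mortality proportions.

    Deaths are rounded to the nearest integer, which is how a table printed
    with one-decimal rates is inverted back to counts.
    """
    a = round(mortality_exposed * n_exposed)
    c = round(mortality_unexposed * n_unexposed)
    return ContingencyTable2x2(
        a=a, b=n_exposed - a, c=c, d=n_unexposed - c, **labels
    )


def odds_ratio(
    table: ContingencyTable2x2, continuity: float = 0.0
) -> OddsRatioResult:
    """Odds ratio with a 95% Wald confidence interval.

    OR = ((a+k)(d+k)) / ((b+k)(c+k)) with k the continuity correction
    (default 0), CI = exp(ln OR +/- 1.96*SE),
    SE = sqrt(sum of reciprocal corrected cells).  With k = 0 and any zero
    cell the OR is infinite, zero or undefined and the CI is reported as
    NaN, flagged via ``degenerate`` rather than silently dropped.
    """
    k = continuity
    a, b, c, d = table.a + k, table.b + k, table.c + k, table.d + k
    mortality_exposed = table.a / table.n_exposed if table.n_exposed else math.nan
    mortality_unexposed = table.c / table.n_unexposed if table.n_unexposed else math.nan
    if min(a, b, c, d) <= 0:
        if b * c == 0 and a * d == 0:
            or_value = math.nan
        elif b * c == 0:
            or_value = math.inf
        else:
            or_value = 0.0
        return OddsRatioResult(
            or_value=or_value,
            ci_low=math.nan,
            ci_high=math.nan,
            mortality_exposed=mortality_exposed,
            mortality_unexposed=mortality_unexposed,
            n_exposed=table.n_exposed,
            n_unexposed=table.n_unexposed,
            degenerate=True,
        )
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_value)
    return OddsRatioResult(
        or_value=or_value,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        mortality_exposed=mortality_exposed,
        mortality_unexposed=mortality_unexposed,
        n_exposed=table.n_exposed,
        n_unexposed=table.n_unexposed,
    )


@dataclass(frozen=True)
class CutoffResult:
    variable: str
    cutoff: float
    direction: str  # 'ge' or 'le'
    mortality_exposed: float
    n_exposed: int


#: Candidate cut-off grids searched for the continuous measures, with the
#: direction in which larger exposure means worse status.
DEFAULT_GRIDS: dict[str, tuple[Sequence[float], str]] = {
    "age": ((65, 70, 75, 80, 85), "ge"),
    "gcs": ((8, 12, 13), "le"),
    "max_ais": ((3, 4, 5), "ge"),
    "asa": ((2, 3), "ge"),
}


def cutoff_search(
    cohort: Cohort,
    variable: str,
    candidate_cutoffs: Optional[Sequence[float]] = None,
    direction: Optional[str] = None,
    target_mortality: float = 0.30,
) -> Optional[CutoffResult]:
    """Least extreme cut-off whose exposed-group mortality reaches the target.

    "Least extreme" is the qualifying cut-off exposing the most patients
    (lowest threshold for '>=' variables, highest for '<=').  Returns None
    when no cut-off on the grid qualifies.
    """
    if candidate_cutoffs is None or direction is None:
        if variable not in DEFAULT_GRIDS:
            raise DomainError(
                f"no default cut-off grid for {variable!r}; pass candidate_cutoffs"
            )
        grid, default_dir = DEFAULT_GRIDS[variable]
        candidate_cutoffs = candidate_cutoffs if candidate_cutoffs is not None else grid
        direction = direction or default_dir
    if not candidate_cutoffs:
        raise DomainError("candidate cut-off grid must be nonempty")

    best: Optional[CutoffResult] = None
    for cutoff in candidate_cutoffs:
        criterion = threshold_criterion(variable, cutoff, direction)
        table = contingency(cohort, criterion.predicate)
        if table.n_exposed == 0:
            continue
        mortality = table.a / table.n_exposed
        if mortality >= target_mortality:
            candidate = CutoffResult(
                variable=variable,
                cutoff=cutoff,
                direction=direction,
                mortality_exposed=mortality,
                n_exposed=table.n_exposed,
            )
            if best is None or candidate.n_exposed > best.n_exposed:
                best = candidate
    return best


@dataclass(frozen=True)
class LogisticFit:
    coef: np.ndarray  # includes intercept at index 0
    se: np.ndarray
    n_iter: int
    converged: bool
    n: int

    @property
    def odds_ratios(self) -> np.ndarray:
        """exp(beta_j) for the predictors (intercept excluded)."""
        return np.exp(self.coef[1:])

    def or_ci(self, z: float = Z_95) -> np.ndarray:
        lo = np.exp(self.coef[1:] - z * self.se[1:])
        hi = np.exp(self.coef[1:] + z * self.se[1:])
        return np.column_stack([lo, hi])


def logistic_fit(
    design: np.ndarray,
    outcome: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    min_events_per_param: int = 10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``design`` is n x p without an intercept column (one is prepended).
    Convergence when max |delta beta| < tol.  Divergence or coefficients
    wandering beyond |beta| > 30 raises :class:`SeparationError` — with
    binary predictors that is the signature of perfect separation.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise DomainError("design and outcome lengths differ")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DomainError("outcome must be binary 0/1")
    if n < min_events_per_param * (p + 1):
        raise DomainError(
            f"n = {n} too small for {p} predictors (need >= {min_events_per_param * (p + 1)})"
        )
    if np.any(X.std(axis=0) == 0):
        raise DomainError("constant predictor column in design matrix")

    Xi = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xi @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        XtWX = Xi.T @ (Xi * w[:, None])
        try:
            delta = np.linalg.solve(XtWX, Xi.T @ (y - mu))
        except np.linalg.LinAlgError as err:
            raise SeparationError(
                "singular information matrix (separation or collinearity)"
            ) from err
        beta = beta + delta
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "coefficients diverged (|beta| > 30): possible perfect separation"
            )
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        raise SeparationError(f"IRLS did not converge in {max_iter} iterations")

    eta = Xi @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(Xi.T @ (Xi * w[:, None]))
    return LogisticFit(
        coef=beta, se=np.sqrt(np.diag(cov)), n_iter=it, converged=True, n=n
    )


#: Canonical candidate order for the screening report and criterion selection.
CANDIDATE_ORDER = (
    "age",
    "max_ais",
    "prbc_pre_icu",
    "asa",
    "gcs",
    "sex",
    "mechanism",
    "sbp",
)


@dataclass(frozen=True)
class CandidateCriterion:
    """One row of the screening report: a dichotomized candidate with its OR."""

    variable: str
    cutoff: float
    direction: str
    odds: OddsRatioResult
    selected: bool = False
    n_unevaluable: int = 0

    @property
    def name(self) -> str:
        if self.variable == "prbc_pre_icu":
            return "prbc_pre_icu"
        if self.variable == "sex":
            return "male_sex"
        if self.variable == "mechanism":
            return "penetrating_mechanism"
        return f"{self.variable}_{self.direction}_{int(self.cutoff)}"

    def criterion(self):
        if self.variable in ("sex", "mechanism"):
            from .scores import Criterion

            return Criterion(
                self.name,
                _candidate_predicate(self.variable, self.cutoff, self.direction),
            )
        return threshold_criterion(self.variable, self.cutoff, self.direction)


def _candidate_predicate(variable: str, cutoff: float, direction: str):
    if variable == "sex":
        from .types import Sex

        return lambda r: None if r.sex is Sex.UNKNOWN else r.sex is Sex.MALE
    if variable == "mechanism":
        from .types import Mechanism

        return lambda r: (
            None if r.mechanism is Mechanism.UNKNOWN
            else r.mechanism is Mechanism.PENETRATING
        )
    return threshold_criterion(variable, cutoff, direction).predicate


def screen_candidates(
    cohort: Cohort,
    target_mortality: float = 0.30,
    mode: str = "univariable",
    continuity: float = 0.0,
) -> list[CandidateCriterion]:
    """Dichotomize every candidate variable and compute its odds ratio.

    ``mode='univariable'`` reports crude 2x2-table odds ratios (one table
    per candidate, per-variable complete cases).  ``mode='multivariable'``
    additionally fits a joint logistic model on the complete-case subset
    and replaces each OR with the exponentiated adjusted coefficient.
    Selection flags are not set here; see :func:`select_criteria`.
    """
    if mode not in ("univariable", "multivariable"):
        raise DomainError(f"unknown mode {mode!r}")

    dichotomies: list[tuple[str, float, str]] = []
    for variable in CANDIDATE_ORDER:
        if variable in DEFAULT_GRIDS:
            found = cutoff_search(cohort, variable, target_mortality=target_mortality)
            if found is None:
                continue
            dichotomies.append((variable, found.cutoff, found.direction))
        elif variable == "sbp":
            dichotomies.append(("sbp", 90, "le"))
        else:  # prbc_pre_icu, sex, mechanism: natural dichotomies
            dichotomies.append((variable, 1, "ge"))

    candidates: list[CandidateCriterion] = []
    preds = {
        var: _candidate_predicate(var, cut, direction)
        for var, cut, direction in dichotomies
    }
    for variable, cutoff, direction in dichotomies:
        table = contingency(cohort, preds[variable])
        candidates.append(
            CandidateCriterion(
                variable=variable,
                cutoff=cutoff,
                direction=direction,
                odds=odds_ratio(table, continuity=continuity),
                n_unevaluable=table.n_unevaluable,
            )
        )

    if mode == "multivariable":
        rows, ys = [], []
        for record in cohort.records:
            vals = [preds[c.variable](record) for c in candidates]
            if any(v is None for v in vals):
                continue
            rows.append([float(v) for v in vals])
            ys.append(float(record.died_in_hospital))
        fit = logistic_fit(np.array(rows), np.array(ys))
        ci = fit.or_ci()
        adjusted = []
        for j, cand in enumerate(candidates):
            adjusted.append(
                replace(
                    cand,
                    odds=replace(
                        cand.odds,
                        or_value=float(fit.odds_ratios[j]),
                        ci_low=float(ci[j, 0]),
                        ci_high=float(ci[j, 1]),
                    ),
                )
            )
        candidates = adjusted
    return candidates


def select_criteria(
    candidates: Sequence[CandidateCriterion],
    or_threshold: float = 2.0,
) -> ScoreDefinition:
    """Keep candidates with OR > threshold as one-point score criteria.

    Output order is the fixed canonical candidate order regardless of input
    order.  An empty selection yields an empty (zero-point) score.
    """
    order = {v: i for i, v in enumerate(CANDIDATE_ORDER)}
    chosen = sorted(
        (c for c in candidates if c.odds.or_value > or_threshold),
        key=lambda c: order.get(c.variable, len(order)),
    )
    return ScoreDefinition(
        name="developed_score",
        criteria=tuple(c.criterion() for c in chosen),
    )
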