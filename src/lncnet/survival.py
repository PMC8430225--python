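"""Univariate Cox fits, the risk-score model, Kaplan-Meier and log-rank.

The prognostic readout of a gene set is a linear risk score

    RiskScore(patient) = sum_i r_i * Exp(i, patient)

where ``r_i`` is the univariate Cox proportional-hazards coefficient of
gene ``i`` (log hazard per expression unit) and ``Exp(i)`` its expression.
Patients are split at the mean risk score (strictly above -> "high"), the
two groups' Kaplan-Meier curves are compared with the log-rank test, and
the hazard ratio is reported in the Mantel-Cox form (O1/E1)/(O2/E2).

Cox fitting maximises the Breslow partial likelihood by Newton-Raphson from
beta = 0 (score tolerance 1e-8, at most 50 iterations); the standard error
comes from the observed information and the p-value from a two-sided Wald
z-test.  Event-time ties use the Breslow approximation throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

_NR_TOL = 1e-8
_NR_MAX_ITER = 50
_BETA_BOUND = 50.0  # |beta| past this indicates a monotone likelihood


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check (time, event) invariants; drop rows with missing values,
    logging the count."""
    for col in ("time", "event"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table lacks column {col!r}")
    if clinical.index.has_duplicates:
        raise ValidationError("duplicate sample ids in clinical table")
    n0 = len(clinical)
    clinical = clinical.dropna(subset=["time", "event"])
    if len(clinical) < n0:
        logger.info("dropped %d samples with missing time/event", n0 - len(clinical))
    if (clinical["time"] < 0).any():
        raise ValidationError("negative survival times")
    if not clinical["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0 (censored) or 1 (death)")
    return clinical


@dataclass(frozen=True)
class CoxFit:
    """One univariate proportional-hazards fit."""

    beta: float
    se: float
    hr: float
    p: float
    n_events: int
    converged: bool
    loglik: float


def _breslow_derivatives(beta: float, x: np.ndarray, time: np.ndarray,
                         event: np.ndarray):
    """Log partial likelihood, score and information under Breslow ties.

    Arrays must be sorted by time ascending; the risk set at an event time
    is every subject with time >= that time (ties included on both sides).
    """
    eta = beta * x
    eta_max = eta.max()
    w = np.exp(eta - eta_max)  # stabilised
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum((w * x)[::-1])[::-1]
    c2 = np.cumsum((w * x * x)[::-1])[::-1]
    first = np.searchsorted(time, time, side="left")  # start of each tie group
    ev = event.astype(bool)
    f = first[ev]
    xb = x[ev]
    mean = c1[f] / c0[f]
    loglik = float(np.sum(beta * xb - (np.log(c0[f]) + eta_max)))
    score = float(np.sum(xb - mean))
    info = float(np.sum(c2[f] / c0[f] - mean ** 2))
    return loglik, score, info


def cox_partial_loglik(beta: float, x, time, event) -> float:
    """Breslow log partial likelihood at ``beta`` (exposed for oracles and
    diagnostics)."""
    x, time, event = _as_survival_arrays(x, time, event)
    order = np.argsort(time, kind="mergesort")
    return _breslow_derivatives(beta, x[order], time[order], event[order])[0]


def _as_survival_arrays(x, time, event):
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if not (x.shape == time.shape == event.shape) or x.ndim != 1:
        raise ValidationError("x, time and event must be equal-length vectors")
    if np.any(time < 0):
        raise ValidationError("negative survival times")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValidationError("event must be 0/1")
    return x, time, event


def cox_univariate(x, time, event) -> CoxFit:
    """Newton-Raphson maximisation of the Breslow partial likelihood for a
    single covariate, started at beta = 0."""
    x, time, event = _as_survival_arrays(x, time, event)
    n_events = int(event.sum())
    if n_events < 2:
        raise DegenerateDataError(f"need >= 2 events, got {n_events}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant covariate")
    order = np.argsort(time, kind="mergesort")
    xs, ts, es = x[order], time[order], event[order]

    beta = 0.0
    converged = False
    loglik, score, info = _breslow_derivatives(beta, xs, ts, es)
    for _ in range(_NR_MAX_ITER):
        if abs(score) < _NR_TOL:
            converged = True
            break
        if info <= 0:
            break
        step = score / info
        # halve overshooting steps so the likelihood never decreases
        for _ in range(20):
            new_ll, new_score, new_info = _breslow_derivatives(beta + step, xs, ts, es)
            if new_ll >= loglik - 1e-12:
                break
            step /= 2.0
        beta += step
        loglik, score, info = new_ll, new_score, new_info
        if abs(beta) > _BETA_BOUND:
            logger.warning("cox_univariate: |beta| > %g, likelihood looks "
                           "monotone; flagged non-converged", _BETA_BOUND)
            break
    else:
        if abs(score) < _NR_TOL:
            converged = True
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxFit(beta=float(beta), se=se, hr=float(np.exp(beta)), p=p,
                  n_events=n_events, converged=converged, loglik=float(loglik))


@dataclass
class RiskModel:
    """Per-gene Cox coefficients defining a linear risk score."""

    gene_ids: list
    coefs: list
    threshold: float | None = None  # mean risk score once fitted

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.coefs):
            raise ValidationError("gene_ids and coefs differ in length")
        if not all(np.isfinite(self.coefs)):
            raise ValidationError("non-finite coefficient")

    @classmethod
    def from_univariate_cox(cls, expr: pd.DataFrame, clinical: pd.DataFrame,
                            gene_ids: list) -> tuple["RiskModel", pd.DataFrame]:
        """Fit one Cox model per gene on the shared samples and assemble the
        risk model; also returns the per-gene fit table."""
        clinical = validate_clinical(clinical)
        samples = [s for s in expr.columns if s in clinical.index]
        if len(samples) < 3:
            raise ValidationError("fewer than 3 samples shared by expression "
                                  "and clinical tables")
        time = clinical.loc[samples, "time"].values
        event = clinical.loc[samples, "event"].values
        rows = []
        coefs = []
        kept = []
        for g in gene_ids:
            if g not in expr.index:
                raise ValidationError(f"gene {g!r} missing from expression matrix")
            fit = cox_univariate(expr.loc[g, samples].values, time, event)
            rows.append((g, fit.beta, fit.se, fit.hr, fit.p, fit.n_events,
                         fit.converged))
            coefs.append(fit.beta)
            kept.append(g)
        table = pd.DataFrame(rows, columns=[
            "gene_id", "beta", "se", "hr", "p", "n_events", "converged"])
        return cls(gene_ids=kept, coefs=coefs), table


def risk_score(expr: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Per-sample RiskScore = sum_i r_i * Exp(i)."""
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise ValidationError(f"genes missing from expression matrix: {missing}")
    if not model.gene_ids:
        return pd.Series(0.0, index=expr.columns, name="risk_score")
    mat = expr.loc[model.gene_ids].values.astype(float)
    scores = np.asarray(model.coefs, dtype=float) @ mat
    return pd.Series(scores, index=expr.columns, name="risk_score")


def stratify_by_mean(values: pd.Series) -> pd.Series:
    """"high" iff strictly above the mean, "low" otherwise (value == mean is
    "low"; the boundary rule is fixed for determinism)."""
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise ValidationError("need >= 2 samples to stratify")
    mean = values.mean()
    labels = pd.Series(np.where(values.values > mean, "high", "low"),
                       index=values.index, name="group")
    if (labels == "low").all():
        logger.warning("degenerate mean split: every sample labelled 'low'")
    return labels


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit Kaplan-Meier estimate: rows (time, survival) at each
    distinct event time, starting from S(0) = 1."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    surv = 1.0
    rows = [(0.0, 1.0)]
    for t in np.unique(time[event == 1]):
        at_risk = int(np.sum(time >= t))
        deaths = int(np.sum((time == t) & (event == 1)))
        surv *= 1.0 - deaths / at_risk
        rows.append((float(t), surv))
    return pd.DataFrame(rows, columns=["time", "survival"])


@dataclass
class SurvivalComparison:
    """Two-group log-rank comparison with KM curves and Mantel-Cox HR."""

    group_labels: pd.Series = field(repr=False)
    chi2: float = 0.0
    p: float = 1.0
    hr: float = float("nan")          # Mantel-Cox (O1/E1)/(O2/E2), high vs low
    hr_cox: float = float("nan")      # Cox fit on the group indicator
    o1: float = 0.0
    e1: float = 0.0
    o2: float = 0.0
    e2: float = 0.0
    km_curves: dict = field(default_factory=dict, repr=False)


def km_logrank(groups, time, event, group1: str = "high") -> SurvivalComparison:
    """Log-rank test between exactly two groups.

    chi2 = (O1 - E1)^2 / V with the hypergeometric variance summed over
    distinct event times; p from chi-square on 1 df; HR in the Mantel-Cox
    form with ``group1`` (default "high") as the numerator group.  A group
    with zero events leaves the HR not estimable (NaN) but the chi2 is
    still reported.
    """
    groups = pd.Series(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if not (len(groups) == time.size == event.size):
        raise ValidationError("groups, time and event must align")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly two groups, got {levels}")
    if group1 in levels:
        other = levels[0] if levels[1] == group1 else levels[1]
        levels = [group1, other]
    g1 = (groups.values == levels[0])

    event_times = np.unique(time[event == 1])
    o1 = e1 = var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_t = int(at_risk.sum())
        n1_t = int((at_risk & g1).sum())
        d_t = int(((time == t) & (event == 1)).sum())
        d1_t = int(((time == t) & (event == 1) & g1).sum())
        o1 += d1_t
        e1 += d_t * n1_t / n_t
        if n_t > 1:
            var += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    total_events = float(event.sum())
    o2 = total_events - o1
    e2 = total_events - e1
    if var > 0:
        chi2 = (o1 - e1) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    if o1 > 0 and o2 > 0 and e1 > 0 and e2 > 0:
        hr = (o1 / e1) / (o2 / e2)
    else:
        hr = float("nan")
        logger.info("Mantel-Cox HR not estimable (a group has zero events)")
    try:
        hr_cox = cox_univariate(g1.astype(float), time, event).hr
    except DegenerateDataError:
        hr_cox = float("nan")
    curves = {lvl: km_curve(time[groups.values == lvl], event[groups.values == lvl])
              for lvl in levels}
    return SurvivalComparison(
        group_labels=groups, chi2=float(chi2), p=p, hr=float(hr),
        hr_cox=float(hr_cox), o1=float(o1), e1=float(e1), o2=float(o2),
        e2=float(e2), km_curves=curves)
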