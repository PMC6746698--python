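"""Survival stratification machinery for score-based prognostic models.

Implements the downstream analysis of a per-patient prognostic score:
Kaplan-Meier product-limit curves, the two-group log-rank test, optimal
cut-point search (the cut maximizing the log-rank statistic on a modelling
subset), Cox proportional-hazards fits with Wald tests, Harrell's
concordance index, and a seeded k-fold cross-validation harness.

Orientation convention: the TILAb score is protective — higher scores
associate with longer disease-free survival — so subjects below the
cut-point form the high-risk group and, unless an explicit risk (e.g. a Cox
linear predictor) is supplied, the concordance index is computed on
risk = -score.  This keeps c > 0.5 meaning "predictive".

The log-rank statistic is computed by a vectorized implementation of the
standard hypergeometric-moments form: the cut-point scan evaluates it for
every admissible candidate split, so it is on the hot path.  Kaplan-Meier
estimation is delegated to lifelines, Cox fits to statsmodels' proportional
hazards regression (Efron or Breslow tie handling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from tilab.errors import ConvergenceError, ValidationError

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CutpointResult",
    "StratificationResult",
    "CoxCovariate",
    "CoxResult",
    "FoldResult",
    "CrossValidationResult",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "stratify",
    "cox_fit",
    "concordance_index",
    "cross_validate",
    "read_cohort_csv",
    "write_cohort_csv",
]

RiskGroup = Literal["high_risk", "low_risk"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in months, event flag, score, covariates."""

    subject_id: str
    time: float
    event: int
    score: float
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.time > 0):
            raise ValidationError(f"subject {self.subject_id}: time must be positive")
        if self.event not in (0, 1):
            raise ValidationError(f"subject {self.subject_id}: event must be 0 or 1")
        if not np.isfinite(self.score):
            raise ValidationError(f"subject {self.subject_id}: score is not finite")


def _times_events(records: Sequence[SurvivalRecord]):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve as a right-continuous step function."""

    times: np.ndarray          # distinct observed times, ascending, with leading 0
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray        # number at risk just before each time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier estimate of the survival function."""
    if len(records) == 0:
        raise ValidationError("at least one record required")
    t, e = _times_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("both groups must be non-empty")
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    chi2 = _logrank_chi2(
        np.concatenate([ta, tb]),
        np.concatenate([ea, eb]),
        np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)]),
    )
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return chi2, p


def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_a: np.ndarray) -> float:
    """Vectorized two-group log-rank chi-square.

    At each distinct event time: observed events in group A vs the
    hypergeometric expectation d * nA / n, variance
    d (nA/n)(1 - nA/n)(n - d)/(n - 1).
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(float)
    a = in_a[order].astype(float)

    uniq, start = np.unique(t, return_index=True)
    # events and group-A events per distinct time
    d = np.add.reduceat(e, start)
    d_a = np.add.reduceat(e * a, start)
    # at-risk counts just before each distinct time
    n_total = t.size
    removed = np.add.reduceat(np.ones_like(e), start)
    removed_a = np.add.reduceat(a, start)
    n_at = n_total - np.concatenate([[0.0], np.cumsum(removed)[:-1]])
    n_a_at = a.sum() - np.concatenate([[0.0], np.cumsum(removed_a)[:-1]])

    mask = d > 0
    d, d_a, n_at, n_a_at = d[mask], d_a[mask], n_at[mask], n_a_at[mask]
    frac = n_a_at / n_at
    o_minus_e = float(np.sum(d_a - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1 - frac) * (n_at - d) / (n_at - 1)
    var = float(np.nansum(np.where(n_at > 1, var_terms, 0.0)))
    if var <= 0:
        return 0.0
    return o_minus_e**2 / var


@dataclass(frozen=True)
class CutpointResult:
    """Outcome of the optimal cut-point search."""

    cutpoint: float
    chi2: float
    p_value: float
    n_candidates: int


def optimal_cutpoint(
    records: Sequence[SurvivalRecord],
    min_group_frac: float = 0.1,
) -> CutpointResult:
    """Find the score cut-point maximizing the log-rank separation.

    Candidates are midpoints between consecutive distinct sorted scores,
    filtered so each side holds at least ``min_group_frac`` of subjects.
    Ties in the statistic break toward the smaller cut-point.  The scan
    performs no multiple-testing adjustment, so the winning p-value is
    optimistic; validate on a held-out subset.
    """
    if not (0 < min_group_frac < 0.5):
        raise ValidationError("min_group_frac must lie in (0, 0.5)")
    scores = np.array([r.score for r in records], dtype=float)
    n = scores.size
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValidationError("need at least 2 distinct scores to search a cut-point")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    times, events = _times_events(records)
    min_n = min_group_frac * n
    best: tuple[float, float] | None = None  # (chi2, cutpoint)
    n_admissible = 0
    for c in candidates:
        low = scores < c
        n_low = int(low.sum())
        if n_low < min_n or (n - n_low) < min_n:
            continue
        n_admissible += 1
        chi2 = _logrank_chi2(times, events, low)
        if best is None or chi2 > best[0] + 1e-15:
            best = (chi2, float(c))
    if best is None:
        raise ValidationError(
            "no admissible cut-point: every candidate leaves a group below "
            f"min_group_frac={min_group_frac}"
        )
    chi2, cut = best
    return CutpointResult(
        cutpoint=cut,
        chi2=chi2,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        n_candidates=n_admissible,
    )


@dataclass(frozen=True)
class StratificationResult:
    """Two-group stratification of a cohort at a score cut-point."""

    cutpoint: float
    group: tuple[RiskGroup, ...]
    logrank_chi2: float
    p_value: float
    km_curves: dict[RiskGroup, KMCurve]


def stratify(records: Sequence[SurvivalRecord], cutpoint: float) -> StratificationResult:
    """Split a cohort at a cut-point (low score = high risk) and test separation."""
    groups: list[RiskGroup] = [
        "high_risk" if r.score < cutpoint else "low_risk" for r in records
    ]
    high = [r for r, g in zip(records, groups) if g == "high_risk"]
    low = [r for r, g in zip(records, groups) if g == "low_risk"]
    if not high or not low:
        raise ValidationError("cut-point leaves one group empty")
    chi2, p = logrank_test(high, low)
    return StratificationResult(
        cutpoint=cutpoint,
        group=tuple(groups),
        logrank_chi2=chi2,
        p_value=p,
        km_curves={"high_risk": km_estimate(high), "low_risk": km_estimate(low)},
    )


@dataclass(frozen=True)
class CoxCovariate:
    """One covariate's effect in a Cox model (hazard-ratio scale)."""

    name: str
    coef: float
    se: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    wald_p: float
    separation_flag: bool = False


@dataclass(frozen=True)
class CoxResult:
    """A fitted Cox proportional-hazards model."""

    covariates: tuple[CoxCovariate, ...]
    overall_wald_chi2: float
    overall_p: float
    c_index: float
    c_index_ci: tuple[float, float]
    ties: str
    linear_predictor: np.ndarray


def _design_matrix(
    records: Sequence[SurvivalRecord], covariate_names: Sequence[str]
) -> pd.DataFrame:
    """Build the Cox design: 'score' plus named covariates; categoricals are
    dummy-coded with the lexicographically first level as reference."""
    cols: dict[str, object] = {}
    for name in covariate_names:
        if name == "score":
            cols[name] = [r.score for r in records]
        else:
            vals = [r.covariates.get(name) for r in records]
            if any(v is None for v in vals):
                raise ValidationError(f"covariate {name!r} missing for some subjects")
            cols[name] = vals
    df = pd.DataFrame(cols)
    numeric = df.select_dtypes(include=[np.number])
    categorical = df.drop(columns=numeric.columns)
    parts = [numeric]
    for name in categorical.columns:
        levels = sorted(categorical[name].astype(str).unique())
        dummies = pd.get_dummies(
            pd.Categorical(categorical[name].astype(str), categories=levels),
            prefix=name, drop_first=True, dtype=float,
        )
        parts.append(dummies)
    X = pd.concat(parts, axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValidationError(f"covariates constant across subjects: {const}")
    return X


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariate_names: Sequence[str] = ("score",),
    ties: Literal["efron", "breslow"] = "efron",
) -> CoxResult:
    """Fit a Cox proportional-hazards model by partial-likelihood maximization.

    Hazard ratios are exp(coef) with normal-theory 95% CIs; per-covariate and
    global significance use Wald tests.  Monotone partial likelihood
    (complete separation) is flagged per covariate and its CI reported
    unbounded rather than silently huge.
    """
    if len(records) < 10:
        raise ValidationError("cox_fit requires n >= 10")
    if ties not in ("efron", "breslow"):
        raise ValidationError("ties must be 'efron' or 'breslow'")
    t, e = _times_events(records)
    X = _design_matrix(records, covariate_names)
    model = PHReg(t, X.to_numpy(dtype=float), status=e, ties=ties)
    try:
        res = model.fit(maxiter=100, disp=False)
    except np.linalg.LinAlgError as exc:  # singular information matrix
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    beta = np.asarray(res.params, dtype=float)
    grad = np.asarray(model.score(beta), dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ConvergenceError("Cox fit produced non-finite coefficients")
    if float(np.linalg.norm(grad)) > 1e-4 * max(1.0, float(np.linalg.norm(beta))):
        raise ConvergenceError(
            f"Cox fit did not converge: |grad| = {np.linalg.norm(grad):.3g}"
        )
    se = np.asarray(res.bse, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)

    z975 = stats.norm.ppf(0.975)
    covs: list[CoxCovariate] = []
    for i, name in enumerate(X.columns):
        sep = bool(abs(beta[i]) > 15 or se[i] > 1e3)
        lo = math.exp(beta[i] - z975 * se[i]) if not sep else 0.0
        hi = math.exp(beta[i] + z975 * se[i]) if not sep else math.inf
        wald_p = float(2 * stats.norm.sf(abs(beta[i] / se[i]))) if se[i] > 0 else float("nan")
        covs.append(
            CoxCovariate(
                name=str(name),
                coef=float(beta[i]),
                se=float(se[i]),
                hazard_ratio=math.exp(beta[i]),
                ci_lower=lo,
                ci_upper=hi,
                wald_p=wald_p,
                separation_flag=sep,
            )
        )
    try:
        overall = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        overall = float("nan")
    overall_p = float(stats.chi2.sf(overall, df=beta.size))
    lp = X.to_numpy(dtype=float) @ beta
    c, ci = concordance_index(records, risk=lp)
    return CoxResult(
        covariates=tuple(covs),
        overall_wald_chi2=overall,
        overall_p=overall_p,
        c_index=c,
        c_index_ci=ci,
        ties=ties,
        linear_predictor=lp,
    )


def concordance_index(
    records: Sequence[SurvivalRecord],
    risk: Sequence[float] | None = None,
) -> tuple[float, tuple[float, float]]:
    """Harrell's concordance index with a 95% CI.

    Usable pairs are those whose ordering is known: the shorter time carries
    an event (a subject censored at the same time as another's event counts
    as the later of the two).  Risk ties count 1/2.  When ``risk`` is omitted
    the protective-score convention risk = -score applies.  The CI is a
    normal approximation with a jackknife standard error, truncated to [0, 1].
    """
    n = len(records)
    if n < 2:
        raise ValidationError("concordance needs at least 2 subjects")
    t, e = _times_events(records)
    if e.sum() == 0:
        raise ValidationError("concordance needs at least one event")
    r = (
        -np.array([rec.score for rec in records], dtype=float)
        if risk is None
        else np.asarray(risk, dtype=float)
    )

    # usable ordered pairs (i earlier with event, j later)
    ti = t[:, None]
    tj = t[None, :]
    ei = e[:, None].astype(bool)
    ej = e[None, :].astype(bool)
    usable = (ei & (ti < tj)) | (ei & ~ej & (ti == tj))
    np.fill_diagonal(usable, False)
    if not usable.any():
        raise ValidationError("no usable pairs for concordance")
    ri = r[:, None]
    rj = r[None, :]
    s = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0)) * usable
    w_row = usable.sum(axis=1).astype(float)
    w_col = usable.sum(axis=0).astype(float)
    s_row = s.sum(axis=1)
    s_col = s.sum(axis=0)
    W = float(w_row.sum())
    S = float(s_row.sum())
    c = S / W

    # leave-one-out jackknife over subjects
    w_i = W - w_row - w_col
    s_i = S - s_row - s_col
    ok = w_i > 0
    c_i = np.where(ok, s_i / np.where(w_i > 0, w_i, 1.0), c)
    m = c_i.mean()
    se = math.sqrt(max((n - 1) / n * float(np.sum((c_i - m) ** 2)), 0.0))
    z975 = stats.norm.ppf(0.975)
    return float(c), (float(max(0.0, c - z975 * se)), float(min(1.0, c + z975 * se)))


@dataclass(frozen=True)
class FoldResult:
    """One cross-validation fold's test-subset performance."""

    fold: int
    cutpoint: float
    test_chi2: float
    test_p: float
    c_index: float
    n_test: int
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class CrossValidationResult:
    seed: int
    k: int
    folds: tuple[FoldResult, ...]
    assignment: np.ndarray  # fold index per subject, in input order


def cross_validate(
    records: Sequence[SurvivalRecord],
    k: int = 3,
    seed: int = 0,
    min_group_frac: float = 0.1,
) -> CrossValidationResult:
    """k-fold cross-validation of the cut-point prognostic model.

    Subjects are shuffled into k near-equal folds by a seeded generator; per
    fold, the optimal cut-point is learned on the other k-1 folds and
    evaluated on the held-out fold (log-rank p of the induced split and
    c-index of -score).  Folds with no events, or on which the learned
    cut-point leaves a group empty, are flagged rather than dropped.
    """
    n = len(records)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n < 2 * k:
        raise ValidationError(f"cohort of {n} too small for k={k} (need >= 2 per fold)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(perm, k)):
        assignment[idx] = f

    folds: list[FoldResult] = []
    for f in range(k):
        test = [records[i] for i in range(n) if assignment[i] == f]
        train = [records[i] for i in range(n) if assignment[i] != f]
        flags: list[str] = []
        if sum(r.event for r in test) == 0:
            flags.append("no events in test fold")
        cut = optimal_cutpoint(train, min_group_frac=min_group_frac)
        high = [r for r in test if r.score < cut.cutpoint]
        low = [r for r in test if r.score >= cut.cutpoint]
        if not high or not low:
            flags.append("cut-point leaves a test group empty")
            chi2, p = float("nan"), float("nan")
        else:
            chi2, p = logrank_test(high, low)
        try:
            c, _ = concordance_index(test)
        except ValidationError:
            flags.append("c-index undefined on test fold")
            c = float("nan")
        folds.append(
            FoldResult(
                fold=f,
                cutpoint=cut.cutpoint,
                test_chi2=chi2,
                test_p=p,
                c_index=c,
                n_test=len(test),
                flags=tuple(flags),
            )
        )
    return CrossValidationResult(seed=seed, k=k, folds=tuple(folds), assignment=assignment)


def read_cohort_csv(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival cohort: header ``subject_id,time_months,event,score[,covariate...]``."""
    df = pd.read_csv(path)
    required = ["subject_id", "time_months", "event", "score"]
    if list(df.columns[:4]) != required:
        raise ValidationError(f"cohort CSV must start with columns {required}")
    extra = list(df.columns[4:])
    return [
        SurvivalRecord(
            subject_id=str(row["subject_id"]),
            time=float(row["time_months"]),
            event=int(row["event"]),
            score=float(row["score"]),
            covariates={name: row[name] for name in extra},
        )
        for _, row in df.iterrows()
    ]


def write_cohort_csv(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    extra = sorted({k for r in records for k in r.covariates})
    rows = [
        {
            "subject_id": r.subject_id,
            "time_months": r.time,
            "event": r.event,
            "score": r.score,
            **{k: r.covariates.get(k) for k in extra},
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
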