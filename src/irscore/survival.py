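"""Survival machinery for dichotomized scores: Kaplan-Meier, log-rank, and a
two-group Cox proportional-hazards fit, all implemented from first principles.

The Cox model here is the single-binary-covariate special case (high = 1,
low = 0) maximized by Newton-Raphson on the partial log-likelihood with Efron
(default) or Breslow handling of tied event times.  For a binary covariate the
risk-set sums reduce to counts, so each iteration is a closed-form pass over
the distinct event times.

Rank-based association tests (Spearman, Mann-Whitney, Kruskal-Wallis) are
standard steps and delegate to scipy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import SurvivalTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# grouping

@dataclass
class GroupAssignment:
    """High/low split of samples at the median of a scoring variable.

    Values strictly above the median go to "high"; values at or below it go
    to "low" (deterministic tie rule).
    """

    group: pd.Series  # index sample_id, values "high"/"low"
    threshold: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group.index)

    def indicator(self) -> pd.Series:
        return (self.group == "high").astype(int)


def dichotomize_by_median(values: pd.Series) -> GroupAssignment:
    """Split samples at the median: value > median -> high, else low."""
    if len(values) < 4:
        raise ValueError(f"need >= 4 samples to dichotomize, got {len(values)}")
    med = float(np.median(values.to_numpy(dtype=float)))
    group = pd.Series(np.where(values > med, "high", "low"), index=values.index)
    if (group == "high").sum() == 0:
        raise ValueError("no value exceeds the median (constant or degenerate vector)")
    return GroupAssignment(group=group, threshold=med)


# ---------------------------------------------------------------------------
# Cox PH, binary covariate

@dataclass
class CoxResult:
    log_hr: float
    se: float
    z: float
    p: float
    n: int
    n_events: int
    converged: bool
    ties_method: str

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        zq = scipy.stats.norm.ppf(0.5 + level / 2)
        return (np.exp(self.log_hr - zq * self.se), np.exp(self.log_hr + zq * self.se))


def _align(groups: GroupAssignment, surv: SurvivalTable):
    """(time, event, x) arrays over the samples shared by both inputs.

    Fast path when the group assignment and survival table already carry the
    same samples in the same order (the common case inside the pipeline).
    """
    g_ids = groups.sample_ids
    s_ids = surv.sample_ids
    if g_ids == s_ids:
        x = (groups.group.to_numpy() == "high").astype(int)
        return surv.time, surv.event, x
    sset = set(s_ids)
    common = [s for s in g_ids if s in sset]
    if not common:
        raise ValueError("no overlap between group assignment and survival table")
    sub = surv.data.loc[common]
    x = (groups.group.loc[common].to_numpy() == "high").astype(int)
    return sub["time"].to_numpy(dtype=float), sub["event"].to_numpy(dtype=int), x


def _event_time_tables(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Per distinct event time: d (events), m1 (events in arm 1), n1/n0 at risk.

    Subjects censored at an event time remain in that time's risk set
    (events processed before same-time censorings).  Risk-set counts come
    from sorted searchsorted passes, so the whole table is O(n log n).
    """
    ev_times = time[event == 1]
    etimes, inv = np.unique(ev_times, return_inverse=True)
    d = np.bincount(inv, minlength=len(etimes)).astype(float)
    m1 = np.bincount(inv, weights=x[event == 1].astype(float),
                     minlength=len(etimes))
    all_sorted = np.sort(time)
    arm1_sorted = np.sort(time[x == 1])
    n_at = len(time) - np.searchsorted(all_sorted, etimes, side="left")
    n1 = (len(arm1_sorted) - np.searchsorted(arm1_sorted, etimes, side="left")).astype(float)
    n0 = n_at - n1
    return etimes, d, m1, n1, n0


def _efron_fractions(d: np.ndarray, ties: str):
    """Flattened (time index, r/d fraction) pairs for the tie corrections."""
    counts = d.astype(int)
    idx = np.repeat(np.arange(len(d)), counts)
    if ties == "efron":
        c = np.concatenate([np.arange(k) / k for k in counts]) if len(counts) else np.empty(0)
    else:  # breslow: every tied event sees the full risk-set sum
        c = np.zeros(int(counts.sum()))
    return idx, c


def _cox_derivatives(beta: float, d, m1, n1, n0, ties: str, frac=None):
    """(loglik, score, information) of the binary-covariate partial likelihood."""
    idx, c = _efron_fractions(d, ties) if frac is None else frac
    eb = np.exp(beta)
    S, Sp = n1 * eb + n0, n1 * eb            # risk-set sum and its derivative
    E, Ep = m1 * eb + (d - m1), m1 * eb      # event-subset sum and derivative
    D = S[idx] - c * E[idx]
    p = (Sp[idx] - c * Ep[idx]) / D
    ll = float(np.sum(m1) * beta - np.sum(np.log(D)))
    U = float(np.sum(m1) - np.sum(p))
    I = float(np.sum(p * (1.0 - p)))
    return ll, U, I


def fit_cox_binary(
    groups: GroupAssignment,
    surv: SurvivalTable,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Maximum-partial-likelihood fit of hazard(high)/hazard(low).

    Under monotone likelihood (all the information pushes the estimate to
    +/- infinity) the fit is flagged non-converged, log_hr is a signed
    infinity, and the p-value falls back to the score test at beta = 0.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    time, event, x = _align(groups, surv)
    if not np.isfinite(time).all():
        raise ValueError("non-finite survival times")
    n, n_events = len(time), int(event.sum())
    if n_events == 0:
        raise ValueError("no events: Cox model is undefined")

    etimes, d, m1, n1, n0 = _event_time_tables(time, event, x)
    frac = _efron_fractions(d, ties)
    _, U0, I0 = _cox_derivatives(0.0, d, m1, n1, n0, ties, frac)
    score_chi2 = U0**2 / I0 if I0 > 0 else 0.0
    score_p = float(scipy.stats.chi2.sf(score_chi2, 1))

    beta, converged = 0.0, False
    for _ in range(max_iter):
        _, U, I = _cox_derivatives(beta, d, m1, n1, n0, ties, frac)
        if I <= 0 or not np.isfinite(U):
            break
        step = U / I
        beta += step
        if abs(beta) > 20:  # monotone likelihood: estimate diverging
            break
        if abs(step) < tol:
            converged = True
            break

    if not converged:
        sentinel = np.inf if U0 > 0 else -np.inf
        return CoxResult(log_hr=float(sentinel), se=np.inf, z=np.nan, p=score_p,
                         n=n, n_events=n_events, converged=False, ties_method=ties)
    _, _, I = _cox_derivatives(beta, d, m1, n1, n0, ties, frac)
    se = 1.0 / np.sqrt(I)
    z = beta / se
    p = float(2.0 * scipy.stats.norm.sf(abs(z)))
    return CoxResult(log_hr=float(beta), se=float(se), z=float(z), p=p,
                     n=n, n_events=n_events, converged=True, ties_method=ties)


def cox_partial_loglik(beta: float, groups: GroupAssignment, surv: SurvivalTable,
                       ties: str = "efron") -> float:
    """Partial log-likelihood at a given log-HR (exposed for profiling/tests)."""
    time, event, x = _align(groups, surv)
    _, d, m1, n1, n0 = _event_time_tables(time, event, x)
    ll, _, _ = _cox_derivatives(beta, d, m1, n1, n0, ties)
    return float(ll)


# ---------------------------------------------------------------------------
# log-rank

def logrank_test(groups: GroupAssignment, surv: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test with the hypergeometric variance.

    Returns (chi_square, p) with p from chi-square on 1 df.  Depends on times
    only through their ordering, so it is invariant to common monotone
    transforms of time.
    """
    time, event, x = _align(groups, surv)
    if event.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    if len(np.unique(x)) < 2:
        raise ValueError("both groups must be nonempty")

    _, d, m1, n1, n0 = _event_time_tables(time, event, x)
    n = n1 + n0
    O = m1.sum()
    E = (d * n1 / n).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * (n1 / n) * (n0 / n) * (n - d) / (n - 1)
    V = np.nan_to_num(v, nan=0.0).sum()
    if V == 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(scipy.stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit survival curve: S(0) = 1, drops only at event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "events": self.events})


def plot_km_curves(curves: dict[str, "KMCurve"], path, title: str = "",
                   time_unit: str = "time") -> None:
    """Basic diagnostic step plot of one or more KM curves (PNG/PDF)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(curve.times, curve.survival, where="post", label=label)
    ax.set_xlabel(time_unit)
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_estimate(surv: SurvivalTable) -> KMCurve:
    """Kaplan-Meier estimator; censoring at an event time is processed after
    the events at that time (the standard risk-set convention)."""
    time, event = surv.time, surv.event
    if len(time) == 0:
        raise ValueError("empty survival table")
    etimes = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in etimes], dtype=int)
    d = np.array([((time == t) & (event == 1)).sum() for t in etimes], dtype=int)
    surv_prob = np.cumprod(1.0 - d / at_risk) if len(etimes) else np.array([])
    return KMCurve(
        times=np.concatenate([[0.0], etimes]),
        survival=np.concatenate([[1.0], surv_prob]),
        at_risk=np.concatenate([[len(time)], at_risk]).astype(int),
        events=np.concatenate([[0], d]).astype(int),
    )


# ---------------------------------------------------------------------------
# rank-based association tests (scipy-backed)

def rank_correlation(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def two_group_test(values_a, values_b, paired: bool = False) -> float:
    """Two-group comparison p-value.

    The default is the Mann-Whitney rank-sum test (two independent groups,
    exact where feasible, normal approximation with tie correction otherwise).
    ``paired=True`` switches to the Wilcoxon signed-rank test for genuinely
    paired measurements.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length vectors")
        return float(scipy.stats.wilcoxon(a, b).pvalue)
    return float(scipy.stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def k_group_test(values, labels) -> float:
    """Kruskal-Wallis p-value across k groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations")
    return float(scipy.stats.kruskal(*groups).pvalue)
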