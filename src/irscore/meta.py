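"""Inverse-variance meta-analysis of per-cohort Cox fits and signature
selection/classification.

Each signature's per-cohort log hazard ratios (high vs low at the cohort's
own NES median) are pooled across cohorts.  The random-effects model uses the
DerSimonian-Laird moment estimator of the between-cohort variance,

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),   w = 1/se^2,

with Q the fixed-effects heterogeneity statistic.  Signatures whose pooled
two-sided p-value falls below alpha are selected and classified as
prognostically good (pooled HR < 1) or bad (pooled HR > 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .survival import CoxResult

logger = logging.getLogger(__name__)


@dataclass
class MetaResult:
    signature: str
    pooled_log_hr: float
    pooled_se: float
    p: float
    model: str                   # "fixed" or "random_dl"
    Q: float
    tau2: float
    I2: float                    # percent
    k: int
    fixed_log_hr: float = np.nan  # always recorded alongside
    fixed_se: float = np.nan
    fixed_p: float = np.nan
    per_cohort: list[CoxResult] = field(default_factory=list)

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        zq = scipy.stats.norm.ppf(0.5 + level / 2)
        return (float(np.exp(self.pooled_log_hr - zq * self.pooled_se)),
                float(np.exp(self.pooled_log_hr + zq * self.pooled_se)))


@dataclass
class SignatureVerdict:
    signature: str
    selected: bool
    direction: str               # "good", "bad", or "none"
    pooled_hr: float
    p: float

    @property
    def sign(self) -> int:
        """+1 for good, -1 for bad contribution to the IRScore signed sum."""
        if self.direction == "good":
            return 1
        if self.direction == "bad":
            return -1
        return 0


def meta_pool(results: list[CoxResult], model: str = "random_dl",
              signature: str = "") -> MetaResult:
    """Pool per-cohort log hazard ratios by inverse variance.

    Non-converged fits must be excluded by the caller; this function requires
    every SE to be finite and positive.  k = 1 passes the single estimate
    through with Q = 0, tau^2 = 0.
    """
    if model not in ("fixed", "random_dl"):
        raise ValueError(f"unknown meta-analysis model {model!r}")
    if len(results) == 0:
        raise ValueError("no cohort estimates to pool")
    y = np.array([r.log_hr for r in results], dtype=float)
    se = np.array([r.se for r in results], dtype=float)
    if not (np.isfinite(y).all() and np.isfinite(se).all() and (se > 0).all()):
        raise ValueError("all estimates must be finite with se > 0 "
                         "(exclude non-converged fits upstream)")
    k = len(y)
    w = 1.0 / se**2
    fixed = float(np.sum(w * y) / np.sum(w))
    fixed_se = float(np.sqrt(1.0 / np.sum(w)))
    Q = float(np.sum(w * (y - fixed) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0

    if model == "random_dl":
        ws = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(ws * y) / np.sum(ws))
        pooled_se = float(np.sqrt(1.0 / np.sum(ws)))
    else:
        pooled, pooled_se = fixed, fixed_se

    def _p(est, s):
        return float(2.0 * scipy.stats.norm.sf(abs(est / s)))

    return MetaResult(signature=signature, pooled_log_hr=pooled,
                      pooled_se=pooled_se, p=_p(pooled, pooled_se), model=model,
                      Q=Q, tau2=float(tau2), I2=float(I2), k=k,
                      fixed_log_hr=fixed, fixed_se=fixed_se,
                      fixed_p=_p(fixed, fixed_se), per_cohort=list(results))


def select_signatures(meta: list[MetaResult], alpha: float = 0.05,
                      fdr: bool = False) -> list[SignatureVerdict]:
    """Select signatures with pooled p < alpha; classify by pooled HR.

    No multiple-testing correction by default (the raw-threshold rule);
    ``fdr=True`` switches the threshold to Benjamini-Hochberg-adjusted
    p-values at the same alpha.
    """
    pvals = np.array([m.p for m in meta], dtype=float)
    if fdr and len(pvals):
        crit = _bh_adjust(pvals)
    else:
        crit = pvals
    verdicts = []
    for m, pc in zip(meta, crit):
        selected = bool(pc < alpha)
        if not selected:
            direction = "none"
        elif m.pooled_log_hr < 0:
            direction = "good"
        else:
            direction = "bad"
        verdicts.append(SignatureVerdict(signature=m.signature, selected=selected,
                                         direction=direction,
                                         pooled_hr=m.pooled_hr, p=m.p))
    n_sel = sum(v.selected for v in verdicts)
    n_good = sum(v.direction == "good" for v in verdicts)
    logger.info("selected %d/%d signatures (%d good, %d bad)",
                n_sel, len(verdicts), n_good, n_sel - n_good)
    return verdicts


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def meta_table(meta: list[MetaResult], verdicts: list[SignatureVerdict]) -> pd.DataFrame:
    """Flat per-signature summary table (the TSV the CLI writes)."""
    vmap = {v.signature: v for v in verdicts}
    rows = []
    for m in meta:
        v = vmap[m.signature]
        lo, hi = m.ci()
        rows.append({"signature": m.signature, "k": m.k, "pooled_hr": m.pooled_hr,
                     "ci_low": lo, "ci_high": hi, "p": m.p, "Q": m.Q,
                     "tau2": m.tau2, "I2": m.I2, "direction": v.direction,
                     "selected": v.selected})
    return pd.DataFrame(rows).set_index("signature")
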