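"""IRScore computation, survival stratification, and the fit/score estimator.

The IRScore of a sample is the signed sum of its normalized enrichment
scores over the selected prognostic signatures:

    IRScore = sum_{i=1..M} NES_i  -  sum_{j=1..N} NES_j

where i runs over the M prognostically good signatures (pooled HR < 1) and j
over the N prognostically bad ones (pooled HR > 1).  Samples are stratified
into high/low IRScore groups at the cohort's own median.

``IRScorer`` packages the whole selection pipeline as a scikit-learn style
estimator: ``fit`` consumes training cohorts (enrichment -> NES -> per-cohort
median-split Cox -> DerSimonian-Laird meta-analysis -> selection) and stores
the signature verdicts; ``score_cohort`` applies the frozen verdict list to a
new cohort, recomputing enrichment and NES within that cohort.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import CohortDataset, EnrichmentMatrix, ExpressionMatrix, IRScoreTable, SignatureCollection, SurvivalTable
from .enrichment import enrich_cohort
from .meta import MetaResult, SignatureVerdict, meta_pool, select_signatures
from .survival import (
    CoxResult,
    GroupAssignment,
    KMCurve,
    dichotomize_by_median,
    fit_cox_binary,
    km_estimate,
    logrank_test,
    rank_correlation,
    two_group_test,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# score computation

def compute_irscore(nes: EnrichmentMatrix, verdicts: list[SignatureVerdict],
                    dichotomize: bool = True) -> IRScoreTable:
    """Signed sum of NES rows over the selected signatures, per sample.

    Raises if any selected signature is missing from the NES matrix.  The
    high/low grouping recomputes the median within the scored cohort; a
    degenerate (constant) score vector surfaces the dichotomization error.
    """
    if nes.variant != "nes":
        raise ValueError("compute_irscore expects a NES-variant enrichment matrix")
    selected = [v for v in verdicts if v.selected]
    if not selected:
        raise ValueError("no selected signatures: IRScore is undefined")
    missing = [v.signature for v in selected if v.signature not in nes.scores.index]
    if missing:
        raise KeyError(f"selected signatures missing from NES matrix: {missing}")

    good = [v.signature for v in selected if v.direction == "good"]
    bad = [v.signature for v in selected if v.direction == "bad"]
    score = (nes.scores.loc[good].sum(axis=0) if good else 0.0)
    score = score - (nes.scores.loc[bad].sum(axis=0) if bad else 0.0)
    score = pd.Series(score, index=nes.scores.columns, name="irscore", dtype=float)

    if dichotomize:
        assignment = dichotomize_by_median(score)
        group, threshold = assignment.group, assignment.threshold
    else:
        group = pd.Series("low", index=score.index)
        threshold = float("nan")
    table = pd.DataFrame({"irscore": score, "group": group})
    return IRScoreTable(table=table, n_good=len(good), n_bad=len(bad),
                        threshold=threshold, good_signatures=good, bad_signatures=bad)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class StratificationReport:
    """High-vs-low survival contrast of an IRScore grouping."""

    cox: CoxResult
    logrank_chi2: float
    logrank_p: float
    km_high: KMCurve
    km_low: KMCurve
    n_high: int
    n_low: int

    @property
    def hr(self) -> float:
        return self.cox.hr

    def summary(self) -> dict:
        lo, hi = self.cox.ci() if self.cox.converged else (float("nan"),) * 2
        return {"hr_high_vs_low": self.hr, "hr_ci_low": lo, "hr_ci_high": hi,
                "cox_p": self.cox.p, "logrank_chi2": self.logrank_chi2,
                "logrank_p": self.logrank_p, "n_high": self.n_high, "n_low": self.n_low}


def evaluate_stratification(scores: IRScoreTable, surv: SurvivalTable) -> StratificationReport:
    """KM curves per group, log-rank p, and the high-vs-low Cox HR."""
    groups = GroupAssignment(group=scores.group, threshold=scores.threshold)
    if scores.group.nunique() < 2:
        raise ValueError("need both high and low groups for stratification")
    common = [s for s in scores.group.index if s in set(surv.sample_ids)]
    sub = surv.subset(common)
    cox = fit_cox_binary(groups, sub)
    chi2, p = logrank_test(groups, sub)
    high_ids = [s for s in common if scores.group[s] == "high"]
    low_ids = [s for s in common if scores.group[s] == "low"]
    return StratificationReport(
        cox=cox, logrank_chi2=chi2, logrank_p=p,
        km_high=km_estimate(sub.subset(high_ids)),
        km_low=km_estimate(sub.subset(low_ids)),
        n_high=len(high_ids), n_low=len(low_ids),
    )


def associate_with_signature(scores: IRScoreTable, feature: pd.Series,
                             mode: str = "correlation") -> dict:
    """Associate the IRScore with an external per-sample feature.

    ``correlation`` mode reports Spearman rho and p on matched samples;
    ``group_compare`` reports the rank-sum p between high and low groups
    together with group medians of the feature.
    """
    common = scores.table.index.intersection(feature.index)
    if len(common) < 4:
        raise ValueError(f"only {len(common)} matched samples (need >= 4)")
    x = scores.irscore.loc[common]
    f = feature.loc[common].astype(float)
    if mode == "correlation":
        rho, p = rank_correlation(x, f)
        return {"mode": mode, "rho": rho, "p": p, "n": len(common)}
    if mode == "group_compare":
        g = scores.group.loc[common]
        hi, lo = f[g == "high"], f[g == "low"]
        return {"mode": mode, "p": two_group_test(hi, lo),
                "median_high": float(hi.median()), "median_low": float(lo.median()),
                "n": len(common)}
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# the full selection pipeline

def per_cohort_cox(nes_by_cohort: dict[str, EnrichmentMatrix],
                   surv_by_cohort: dict[str, SurvivalTable],
                   ties: str = "efron") -> dict[str, dict[str, CoxResult]]:
    """Univariate Cox (high vs low at the cohort NES median) for every
    (signature, cohort) pair.  Degenerate rows and failed fits are skipped
    with a log record, never imputed."""
    out: dict[str, dict[str, CoxResult]] = {}
    for cname, nes in nes_by_cohort.items():
        surv = surv_by_cohort[cname]
        for sig in nes.scores.index:
            row = nes.scores.loc[sig]
            try:
                groups = dichotomize_by_median(row)
                res = fit_cox_binary(groups, surv, ties=ties)
            except ValueError as exc:
                logger.debug("cohort %s signature %s: Cox skipped (%s)", cname, sig, exc)
                continue
            out.setdefault(sig, {})[cname] = res
    return out


def run_selection(
    cohorts: list[CohortDataset],
    signatures: SignatureCollection,
    method: str = "gsva",
    alpha: float = 0.25,
    meta_model: str = "random_dl",
    select_alpha: float = 0.05,
    ties: str = "efron",
) -> tuple[list[MetaResult], list[SignatureVerdict], dict[str, EnrichmentMatrix], pd.DataFrame]:
    """Enrich each cohort, fit per-signature Cox models, pool, select.

    Returns (meta results, verdicts, per-cohort NES, per-cohort Cox table).
    """
    names = [c.name for c in cohorts]
    if len(set(names)) != len(names):
        raise ValueError("cohort names must be unique")
    nes_by_cohort: dict[str, EnrichmentMatrix] = {}
    for cohort in cohorts:
        _, nes = enrich_cohort(cohort.expression, signatures, method=method, alpha=alpha)
        nes_by_cohort[cohort.name] = nes
    surv_by_cohort = {c.name: c.survival for c in cohorts}
    cox = per_cohort_cox(nes_by_cohort, surv_by_cohort, ties=ties)
    cox_table = pd.DataFrame([
        {"cohort": cname, "signature": sig, "hr": r.hr, "log_hr": r.log_hr,
         "se": r.se, "p": r.p, "n": r.n, "n_events": r.n_events,
         "converged": r.converged}
        for sig, per_cohort in cox.items() for cname, r in per_cohort.items()
    ])

    metas: list[MetaResult] = []
    n_dropped = 0
    for sig, per_cohort in cox.items():
        usable = [r for r in per_cohort.values() if r.converged and np.isfinite(r.se)]
        n_dropped += len(per_cohort) - len(usable)
        if not usable:
            logger.warning("signature %s: no converged Cox fit in any cohort", sig)
            continue
        metas.append(meta_pool(usable, model=meta_model, signature=sig))
    if n_dropped:
        logger.info("excluded %d non-converged per-cohort Cox fits", n_dropped)
    verdicts = select_signatures(metas, alpha=select_alpha)
    return metas, verdicts, nes_by_cohort, cox_table


class IRScorer(BaseEstimator):
    """Multi-cohort immune-signature scorer (scikit-learn style).

    Parameters
    ----------
    gene_sets:
        SignatureCollection (or name -> gene-list mapping) to score.
    method:
        Single-sample enrichment algorithm, ``"gsva"`` (default) or
        ``"ssgsea"``.
    alpha:
        ssGSEA rank-weight exponent.
    meta_model:
        ``"random_dl"`` (DerSimonian-Laird random effects, default) or
        ``"fixed"``; the selection p-value comes from this model.
    select_alpha:
        Raw p-value threshold for signature selection.
    ties:
        Cox tie handling, ``"efron"`` or ``"breslow"``.

    Attributes (after fit)
    ----------------------
    verdicts_ : list of SignatureVerdict (one per pooled signature)
    meta_results_ : list of MetaResult
    nes_ : dict cohort name -> NES EnrichmentMatrix of the training cohorts
    n_good_, n_bad_ : counts of selected good/bad signatures
    """

    def __init__(self, gene_sets=None, method: str = "gsva", alpha: float = 0.25,
                 meta_model: str = "random_dl", select_alpha: float = 0.05,
                 ties: str = "efron"):
        self.gene_sets = gene_sets
        self.method = method
        self.alpha = alpha
        self.meta_model = meta_model
        self.select_alpha = select_alpha
        self.ties = ties

    def _collection(self) -> SignatureCollection:
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided")
        if isinstance(self.gene_sets, SignatureCollection):
            return self.gene_sets
        return SignatureCollection(dict(self.gene_sets))

    def fit(self, cohorts: list[CohortDataset], y=None) -> "IRScorer":
        metas, verdicts, nes, cox_table = run_selection(
            cohorts, self._collection(), method=self.method, alpha=self.alpha,
            meta_model=self.meta_model, select_alpha=self.select_alpha,
            ties=self.ties,
        )
        self.meta_results_ = metas
        self.verdicts_ = verdicts
        self.nes_ = nes
        self.cox_table_ = cox_table
        self.n_good_ = sum(v.direction == "good" for v in verdicts)
        self.n_bad_ = sum(v.direction == "bad" for v in verdicts)
        return self

    def score_cohort(self, expression: ExpressionMatrix) -> IRScoreTable:
        """Apply the frozen verdict list to a new cohort.

        Enrichment and NES are recomputed within the new cohort (each cohort
        is scored on its own scale) and the median split is taken at the new
        cohort's own median.
        """
        self._check_fitted()
        _, nes = enrich_cohort(expression, self._collection(),
                               method=self.method, alpha=self.alpha)
        return compute_irscore(nes, self.verdicts_)

    def score_nes(self, nes: EnrichmentMatrix) -> IRScoreTable:
        """Apply the frozen verdict list to precomputed NES."""
        self._check_fitted()
        return compute_irscore(nes, self.verdicts_)

    def evaluate(self, expression: ExpressionMatrix, surv: SurvivalTable) -> StratificationReport:
        return evaluate_stratification(self.score_cohort(expression), surv)

    def _check_fitted(self) -> None:
        if not hasattr(self, "verdicts_"):
            raise RuntimeError("IRScorer is not fitted; call fit(cohorts) first")

    def save_verdicts(self, path: str | Path) -> None:
        """Serialize the verdict list (JSON) so scoring runs are reproducible."""
        self._check_fitted()
        payload = [vars(v) for v in self.verdicts_]
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def load_verdicts(path: str | Path) -> list[SignatureVerdict]:
        payload = json.loads(Path(path).read_text())
        return [SignatureVerdict(**item) for item in payload]
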