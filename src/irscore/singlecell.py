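"""Cell-resolution IRScore and the CD103/CD39 double-positive analysis.

Cluster- and patient-level scores are computed on average expression
profiles; cell-level scores run ssGSEA per cell.  Sparse single-cell columns
are rank-degenerate (most genes tie at zero), so per-cell ssGSEA ranks only
the cell's detected (nonzero) genes by default; a rank-all-genes mode is
available.

The double-positive analysis gates cells on the tissue-residency marker
CD103 (*ITGAE*) and the ectonucleotidase CD39 (*ENTPD1*): DP if both exceed
the positivity threshold, DN if neither does, SP otherwise.  Cluster and
group enrichment of DP over DN membership is summarized as log2 odds ratios
with Fisher exact p-values.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import EnrichmentMatrix, ExpressionMatrix, IRScoreTable, SignatureCollection
from .enrichment import normalize_to_nes, ssgsea_scores
from .meta import SignatureVerdict
from .scoring import compute_irscore

logger = logging.getLogger(__name__)


def average_by_group(expr: ExpressionMatrix, labels: pd.Series) -> ExpressionMatrix:
    """Per-gene arithmetic mean of expression within each label.

    ``labels`` is indexed by cell/sample ID; every column of ``expr`` must be
    labeled.  Labels with zero cells are simply absent from the output.
    """
    missing = [c for c in expr.sample_ids if c not in labels.index]
    if missing:
        raise ValueError(f"unlabeled cells: {missing[:10]}")
    lab = labels.loc[expr.sample_ids]
    means = expr.data.T.groupby(lab.to_numpy()).mean().T
    means.columns = means.columns.astype(str)
    return ExpressionMatrix(means, scale_tag="linear")


def _single_cell_es(values: np.ndarray, gene_ids: np.ndarray,
                    sets: dict[str, set], alpha: float) -> dict[str, float]:
    """Closed-form ssGSEA scores for one cell over its nonzero genes."""
    n = len(values)
    rho = scipy.stats.rankdata(values)
    order = np.argsort(-values, kind="stable")   # gene_ids pre-sorted lexicographically
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(1, n + 1)
    npos1 = (n - pos + 1).astype(float)
    total = n * (n + 1) / 2.0
    w = rho ** alpha
    out = {}
    for name, genes in sets.items():
        mask = np.isin(gene_ids, list(genes))
        m = int(mask.sum())
        if m < 2 or m == n:
            out[name] = 0.0
            continue
        W = w[mask].sum()
        es = (w[mask] * npos1[mask]).sum() / W - (total - npos1[mask].sum()) / (n - m)
        out[name] = float(es)
    return out


def score_cells(
    expr: ExpressionMatrix,
    sigs: SignatureCollection,
    verdicts: list[SignatureVerdict],
    alpha: float = 0.25,
    rank_mode: str = "nonzero",
) -> IRScoreTable:
    """Per-cell IRScore with median grouping over cells.

    NES scaling is across cells; cells where a signature matches fewer than
    two detected genes contribute a zero raw score for that signature (logged).
    """
    if rank_mode not in ("nonzero", "all"):
        raise ValueError(f"unknown rank_mode {rank_mode!r}")
    if rank_mode == "all":
        raw = ssgsea_scores(expr, sigs, alpha=alpha)
    else:
        data = expr.data.sort_index(kind="stable")
        gene_ids = data.index.to_numpy()
        X = data.to_numpy(dtype=float)
        sets = {name: set(sigs[name]) for name in sigs.names}
        n_degenerate = 0
        cols = {}
        for j, cell in enumerate(data.columns):
            nz = X[:, j] > 0
            if nz.sum() < 2:
                logger.warning("cell %s has < 2 detected genes; all scores zero", cell)
                cols[cell] = {name: 0.0 for name in sets}
                n_degenerate += 1
                continue
            cols[cell] = _single_cell_es(X[nz, j], gene_ids[nz], sets, alpha)
        scores = pd.DataFrame(cols).loc[list(sets)]
        raw = EnrichmentMatrix(scores, variant="raw_es", method="ssgsea_nonzero")
        if n_degenerate:
            logger.warning("%d cells with degenerate (all-zero) scores", n_degenerate)
    nes = normalize_to_nes(raw)
    return compute_irscore(nes, verdicts)


def classify_dp(
    expr: ExpressionMatrix,
    marker_a: str = "ITGAE",
    marker_b: str = "ENTPD1",
    threshold: float = 0.0,
) -> pd.Series:
    """DP/DN/SP gate per cell on two marker genes.

    DP: both markers above ``threshold``; DN: neither above; SP: exactly one.
    The default threshold 0 counts any detected transcript as expressing.
    """
    for marker in (marker_a, marker_b):
        if marker not in expr.data.index:
            raise KeyError(f"marker gene {marker!r} absent from expression matrix")
    a = expr.data.loc[marker_a] > threshold
    b = expr.data.loc[marker_b] > threshold
    cls = np.where(a & b, "DP", np.where(~a & ~b, "DN", "SP"))
    return pd.Series(cls, index=expr.data.columns, name="dp_class")


def enrichment_odds_ratio(table, correction: float = 0.5) -> tuple[float, float]:
    """log2 odds ratio and Fisher exact p for a 2x2 contingency table.

    The Haldane-Anscombe ``correction`` is added to every cell only when some
    cell is zero (so finite ORs are reported unperturbed); the p-value always
    comes from the exact test on the uncorrected counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    a, b, c, d = t.ravel()
    if (t == 0).any():
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    log2_or = float(np.log2((a * d) / (b * c)))
    p = float(scipy.stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])
    return log2_or, p


def dp_enrichment_by_label(dp_class: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """DP-vs-DN enrichment of each label level (cluster, group, cell type).

    For each level L the 2x2 table is [[DP in L, DP not in L],
    [DN in L, DN not in L]]; SP cells do not enter the contrast.  Swapping the
    DP/DN labels negates every log2 OR.
    """
    common = dp_class.index.intersection(labels.index)
    dp = dp_class.loc[common]
    lab = labels.loc[common]
    keep = dp.isin(["DP", "DN"])
    dp, lab = dp[keep], lab[keep]
    rows = []
    for level in sorted(lab.unique(), key=str):
        in_level = lab == level
        tab = [[int(((dp == "DP") & in_level).sum()), int(((dp == "DP") & ~in_level).sum())],
               [int(((dp == "DN") & in_level).sum()), int(((dp == "DN") & ~in_level).sum())]]
        log2_or, p = enrichment_odds_ratio(tab)
        rows.append({"label": level, "dp_in": tab[0][0], "dp_out": tab[0][1],
                     "dn_in": tab[1][0], "dn_out": tab[1][1],
                     "log2_or": log2_or, "p": p})
    return pd.DataFrame(rows).set_index("label")
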