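"""Single-sample gene-set enrichment: ssGSEA and GSVA, plus NES scaling.

Both scoring algorithms are implemented from their published definitions.

ssGSEA (Barbie-style): within each sample genes are ranked by expression; the
enrichment score is the sum over all list positions of the difference between
the weighted cumulative fraction of set genes (weight = rank value ** alpha)
and the uniform cumulative fraction of non-set genes.  Because each gene's
cumulative contribution is counted once per remaining position, the sum
collapses to a closed form,

    ES = sum_{g in S} w_g * (N - pos_g + 1) / W  -  sum_{g not in S} (N - pos_g + 1) / (N - m),

with w_g = rho_g**alpha, rho_g the (average, ascending) rank value, pos_g the
walk position (1 = highest expression), W = sum of set weights, m = |S|.  The
test suite checks this against a literal running-sum oracle.

GSVA (Haenzelmann-style): a per-gene Gaussian-kernel CDF across samples turns
expression into relative ranks; per sample, genes are ordered by decreasing
kernel CDF, given the symmetric rank statistic |N/2 - position|, and a
weighted Kolmogorov-Smirnov random walk is taken down the list.  The score is
the "mx.diff" convention: maximum positive deviation plus maximum negative
deviation of the walk.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import ndtr
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import EnrichmentMatrix, ExpressionMatrix, SignatureCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# signature matching

@dataclass
class _MatchedSets:
    names: list[str]
    masks: list[np.ndarray]  # bool over rows of the (lex-sorted) gene axis
    dropped: list[str] = field(default_factory=list)


def _match_signatures(
    gene_index: pd.Index, sigs: SignatureCollection, min_genes: int = 2
) -> _MatchedSets:
    """Exact-string, case-sensitive matching of signatures onto the gene axis.

    Signatures with fewer than ``min_genes`` matched genes are dropped with a
    warning; a signature covering the entire gene universe is an error (no
    complement to walk against).
    """
    matched = _MatchedSets(names=[], masks=[])
    n = len(gene_index)
    for name in sigs.names:
        mask = gene_index.isin(sigs[name])
        k = int(mask.sum())
        if k < min_genes:
            logger.warning(
                "signature %r matched %d/%d genes (< %d); dropped",
                name, k, len(sigs[name]), min_genes,
            )
            matched.dropped.append(name)
            continue
        if k == n:
            raise ValueError(f"signature {name!r} covers all {n} genes in the matrix")
        matched.names.append(name)
        matched.masks.append(np.asarray(mask))
    if not matched.names:
        raise ValueError("no signature matched >= 2 genes in the expression matrix")
    return matched


def _lex_sorted(expr: ExpressionMatrix) -> pd.DataFrame:
    # lexicographic gene order fixes tie-breaking in the walk order
    return expr.data.sort_index(kind="stable")


def _walk_positions(X: np.ndarray) -> np.ndarray:
    """1-based walk positions per column: 1 = highest value.

    Rows must already be in lexicographic gene order; the stable sort then
    breaks expression ties lexicographically.
    """
    order = np.argsort(-X, axis=0, kind="stable")
    pos = np.empty_like(order)
    cols = np.arange(X.shape[1])
    pos[order, cols] = np.arange(1, X.shape[0] + 1)[:, None]
    return pos


# ---------------------------------------------------------------------------
# ssGSEA

def ssgsea_scores(
    expr: ExpressionMatrix,
    sigs: SignatureCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> EnrichmentMatrix:
    """ssGSEA raw enrichment scores (signatures x samples).

    Scores depend only on within-sample ranks, so any strictly increasing
    per-sample transform of the expression leaves them unchanged.  With
    ``normalize=True`` the whole score matrix is divided by its range
    (the optional final rescaling; off by default).
    """
    data = _lex_sorted(expr)
    X = data.to_numpy(dtype=float)
    n_genes, _ = X.shape
    matched = _match_signatures(data.index, sigs)

    rho = scipy.stats.rankdata(X, axis=0)          # ascending average ranks
    pos = _walk_positions(X)
    npos1 = (n_genes - pos + 1).astype(float)      # positions remaining incl. own
    total_npos1 = n_genes * (n_genes + 1) / 2.0
    w = rho ** alpha

    rows = []
    for mask in matched.masks:
        m = int(mask.sum())
        W = w[mask].sum(axis=0)
        A = (w[mask] * npos1[mask]).sum(axis=0)
        B = npos1[mask].sum(axis=0)
        es = A / W - (total_npos1 - B) / (n_genes - m)
        rows.append(es)
    scores = pd.DataFrame(np.vstack(rows), index=matched.names, columns=data.columns)
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return EnrichmentMatrix(scores, variant="raw_es", method="ssgsea",
                            degenerate_signatures=matched.dropped)


def ssgsea_single_sample(
    values: pd.Series, sigs: SignatureCollection, alpha: float = 0.25
) -> pd.Series:
    """ssGSEA for one sample given as a gene-indexed Series."""
    expr = ExpressionMatrix(values.to_frame("s"), scale_tag="linear")
    return ssgsea_scores(expr, sigs, alpha=alpha).scores["s"]


# ---------------------------------------------------------------------------
# GSVA

def _kernel_cdf(X: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel sample-level CDF estimate.

    For gene i and sample j:  z_ij = mean_k Phi((x_ij - x_ik) / h_i), with
    bandwidth h_i = sd_i / 4.  Constant genes get z = 0.5 everywhere.
    """
    sd = X.std(axis=1, ddof=1)
    z = np.full_like(X, 0.5, dtype=float)
    ok = np.flatnonzero(sd > 0)
    for start in range(0, len(ok), 256):  # chunk genes to bound the n^2 buffer
        idx = ok[start:start + 256]
        h = (sd[idx] / 4.0)[:, None, None]
        diff = (X[idx][:, :, None] - X[idx][:, None, :]) / h
        z[idx] = ndtr(diff).mean(axis=2)  # diff[g, j, k] = (x_gj - x_gk)/h_g
    return z


def gsva_scores(
    expr: ExpressionMatrix, sigs: SignatureCollection, tau: float = 1.0
) -> EnrichmentMatrix:
    """GSVA raw enrichment scores (signatures x samples), mx.diff convention."""
    data = _lex_sorted(expr)
    X = data.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError(
            "GSVA needs >= 3 samples (the kernel CDF is estimated across "
            "samples); use ssgsea_scores for per-sample scoring"
        )
    matched = _match_signatures(data.index, sigs)

    z = _kernel_cdf(X)
    pos = _walk_positions(z)                       # 1 = largest kernel CDF
    r = np.abs(n_genes / 2.0 - pos) ** tau         # symmetric rank statistic
    order = np.argsort(pos, axis=0, kind="stable")  # walk order: decreasing z

    rows = []
    for mask in matched.masks:
        m = int(mask.sum())
        wsum = r[mask].sum(axis=0)
        inc = np.where(mask[:, None], r / wsum, -1.0 / (n_genes - m))
        walk = np.cumsum(np.take_along_axis(inc, order, axis=0), axis=0)
        es = np.maximum(walk, 0).max(axis=0) + np.minimum(walk, 0).min(axis=0)
        rows.append(es)
    scores = pd.DataFrame(np.vstack(rows), index=matched.names, columns=data.columns)
    return EnrichmentMatrix(scores, variant="raw_es", method="gsva",
                            degenerate_signatures=matched.dropped)


# ---------------------------------------------------------------------------
# NES

def normalize_to_nes(es: EnrichmentMatrix, scope: str = "per_cohort") -> EnrichmentMatrix:
    """Z-scale each signature row across a cohort's samples (ddof=1).

    Rows with zero sample standard deviation become all-zero and are recorded
    in ``degenerate_signatures``.  Scaling is within-cohort by design: each
    cohort is scored on its own scale before any cross-cohort synthesis.
    """
    if scope != "per_cohort":
        raise ValueError(f"unknown NES scope {scope!r}")
    X = es.scores.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("NES scaling needs >= 2 samples")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    sd[flat] = 1.0
    nes = (X - mean) / sd
    nes[flat] = 0.0
    degenerate = list(es.scores.index[flat])
    if degenerate:
        logger.warning("NES: %d constant signature rows set to zero: %s",
                       len(degenerate), degenerate[:5])
    out = pd.DataFrame(nes, index=es.scores.index, columns=es.scores.columns)
    return EnrichmentMatrix(out, variant="nes", method=es.method,
                            degenerate_signatures=sorted(set(es.degenerate_signatures) | set(degenerate)))


def enrich_cohort(
    expr: ExpressionMatrix,
    sigs: SignatureCollection,
    method: str = "gsva",
    alpha: float = 0.25,
) -> tuple[EnrichmentMatrix, EnrichmentMatrix]:
    """Raw enrichment + within-cohort NES in one call."""
    if method == "gsva":
        raw = gsva_scores(expr, sigs)
    elif method == "ssgsea":
        raw = ssgsea_scores(expr, sigs, alpha=alpha)
    else:
        raise ValueError(f"unknown enrichment method {method!r}")
    return raw, normalize_to_nes(raw)


# ---------------------------------------------------------------------------
# sklearn-style transformers (samples x genes orientation, per convention)

class _EnrichmentTransformer(TransformerMixin, BaseEstimator):
    """Shared plumbing: X is a samples x genes DataFrame, output is a
    samples x signatures DataFrame of enrichment scores."""

    def __init__(self, gene_sets: SignatureCollection | dict | None = None):
        self.gene_sets = gene_sets

    def _collection(self) -> SignatureCollection:
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided")
        if isinstance(self.gene_sets, SignatureCollection):
            return self.gene_sets
        return SignatureCollection(dict(self.gene_sets))

    @staticmethod
    def _as_expr(X) -> ExpressionMatrix:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame with gene-ID columns")
        return ExpressionMatrix(X.T, scale_tag="linear")

    def fit(self, X, y=None):
        self._collection()
        self.n_features_in_ = X.shape[1]
        return self

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self._collection().names, dtype=object)


class SSGSEA(_EnrichmentTransformer):
    """ssGSEA as a stateless sklearn transformer."""

    def __init__(self, gene_sets=None, alpha: float = 0.25, normalize: bool = False):
        super().__init__(gene_sets)
        self.alpha = alpha
        self.normalize = normalize

    def transform(self, X) -> pd.DataFrame:
        es = ssgsea_scores(self._as_expr(X), self._collection(),
                           alpha=self.alpha, normalize=self.normalize)
        return es.scores.T


class GSVA(_EnrichmentTransformer):
    """GSVA as a stateless sklearn transformer."""

    def __init__(self, gene_sets=None, tau: float = 1.0):
        super().__init__(gene_sets)
        self.tau = tau

    def transform(self, X) -> pd.DataFrame:
        es = gsva_scores(self._as_expr(X), self._collection(), tau=self.tau)
        return es.scores.T


class NESScaler(TransformerMixin, BaseEstimator):
    """Within-cohort z-scaling of enrichment columns (ddof=1), stateless:
    the cohort being transformed defines its own scale."""

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        es = EnrichmentMatrix(X.T, variant="raw_es")
        return normalize_to_nes(es).scores.T
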