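"""Synthetic study generators with known ground truth.

Three generators mirror the three data modalities the pipeline consumes:

* ``generate_cohorts`` — K bulk cohorts with planted prognostic signatures.
  Each signature s has a per-sample latent activity a_sj ~ N(0,1); its genes
  read mu_g + lambda * a_sj + N(0, sigma^2), background genes mu_g + noise.
  Survival follows a proportional-hazards model with exponential baseline:
  the log-hazard linear predictor is eta_j = sum_s d_s * beta * a_sj with
  d_s = -1 for good signatures (higher activity -> lower hazard, pooled
  HR < 1 through the real pipeline) and +1 for bad ones; event times are
  drawn by inverse transform, T = -log(U) / (h0 * exp(eta)), with
  independent exponential censoring.

* ``generate_single_cells`` — negative-binomial count matrices with
  cluster structure, a planted DP population carrying CD103/CD39 marker
  counts and an up-shifted cytotoxic/exhausted signature block.

* ``generate_cytometry`` — event-level intensity mixtures over clusters with
  Dirichlet per-sample frequencies and a planted frequency shift on target
  clusters in the high group.

Every generator is a pure function of (config, seed).  Per-cohort randomness
comes from seed substreams keyed by cohort index, so adding a cohort never
perturbs earlier cohorts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytof import CytometryFrame
from .datatypes import CohortDataset, ExpressionMatrix, SignatureCollection, SurvivalTable

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the multi-cohort survival generator.

    Defaults emulate a seven-cohort bulk transcriptomics study of ~200
    patients per cohort with a catalogue of 100 candidate signatures of which
    40 carry real prognostic signal (20 protective, 20 deleterious).
    """

    n_cohorts: int = 7
    n_samples: int = 200
    n_good: int = 20
    n_bad: int = 20
    n_null: int = 60
    genes_per_signature: int = 10
    n_background_genes: int = 500
    beta: float = 0.8           # per-signature log-hazard effect magnitude
    lam: float = 1.0            # loading of latent activity on signature genes
    sigma: float = 1.0          # gene-level noise sd (log2 scale)
    h0: float = 0.1             # exponential baseline hazard
    censor_rate: float = 0.05   # exponential censoring rate
    baseline_mean: float = 6.0  # mean log2 expression of a gene
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "n_samples", "n_good", "n_bad",
                     "genes_per_signature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_null < 0 or self.n_background_genes < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_signatures(self) -> int:
        return self.n_good + self.n_bad + self.n_null


@dataclass
class GroundTruth:
    """Planted structure stored alongside every generated study."""

    directions: dict[str, str]                 # signature -> good/bad/null
    signatures: SignatureCollection
    activities: dict[str, pd.DataFrame]        # cohort -> signatures x samples
    eta: dict[str, pd.Series]                  # cohort -> linear predictor
    event_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def planted(self) -> list[str]:
        return [s for s, d in self.directions.items() if d != "null"]


def _signature_plan(cfg: SimulationConfig) -> tuple[SignatureCollection, dict[str, str]]:
    gene_sets: dict[str, list[str]] = {}
    directions: dict[str, str] = {}
    idx = 0
    for kind, count in (("GOOD", cfg.n_good), ("BAD", cfg.n_bad), ("NULL", cfg.n_null)):
        for i in range(count):
            name = f"{kind}_{i + 1:02d}"
            genes = [f"SIG{idx:03d}_G{g:02d}" for g in range(cfg.genes_per_signature)]
            gene_sets[name] = genes
            directions[name] = kind.lower()
            idx += 1
    return SignatureCollection(gene_sets, source_tag="synthetic"), directions


def generate_cohorts(cfg: SimulationConfig) -> tuple[list[CohortDataset], GroundTruth]:
    """Generate K independent cohorts with planted good/bad signatures."""
    sigs, directions = _signature_plan(cfg)
    sig_names = sigs.names
    all_genes = [g for name in sig_names for g in sigs[name]]
    all_genes += [f"BG_{i:04d}" for i in range(cfg.n_background_genes)]

    # gene baselines from their own substream: shared across cohorts, stable
    # under changes to n_cohorts
    mu_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(10_000,)))
    mu = mu_rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(all_genes))

    d = np.array([{"good": -1.0, "bad": 1.0, "null": 0.0}[directions[s]]
                  for s in sig_names])
    cohorts: list[CohortDataset] = []
    truth = GroundTruth(directions=directions, signatures=sigs, activities={}, eta={})
    for k in range(cfg.n_cohorts):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(k,)))
        name = f"cohort_{k + 1}"
        samples = [f"C{k + 1}_S{j + 1:03d}" for j in range(cfg.n_samples)]

        a = rng.standard_normal((cfg.n_signatures, cfg.n_samples))
        X = np.empty((len(all_genes), cfg.n_samples))
        X[:] = mu[:, None]
        gps = cfg.genes_per_signature
        for s in range(cfg.n_signatures):
            X[s * gps:(s + 1) * gps] += cfg.lam * a[s]
        X += rng.normal(0.0, cfg.sigma, size=X.shape)

        eta = (d[:, None] * cfg.beta * a).sum(axis=0)
        u = rng.uniform(size=cfg.n_samples)
        t_event = -np.log(u) / (cfg.h0 * np.exp(eta))
        t_censor = rng.exponential(1.0 / cfg.censor_rate, size=cfg.n_samples)
        event = (t_event <= t_censor).astype(int)
        time = np.minimum(t_event, t_censor)
        frac = event.mean()
        if frac < 0.05:
            logger.warning("cohort %s: event fraction %.3f < 5%%; selection power "
                           "will be degenerate", name, frac)

        expr = ExpressionMatrix(pd.DataFrame(X, index=all_genes, columns=samples),
                                scale_tag="log2")
        surv = SurvivalTable(pd.DataFrame({"time": time, "event": event}, index=samples))
        cohorts.append(CohortDataset(name, expr, surv))
        truth.activities[name] = pd.DataFrame(a, index=sig_names, columns=samples)
        truth.eta[name] = pd.Series(eta, index=samples)
        truth.event_fraction[name] = float(frac)
    return cohorts, truth


# ---------------------------------------------------------------------------
# single cells

def generate_single_cells(
    n_cells: int = 500,
    n_genes: int = 200,
    n_clusters: int = 4,
    dp_fraction: float = 0.3,
    sp_fraction: float = 0.0,
    marker_shift: float = 5.0,
    signature_block_size: int = 20,
    signature_shift: float = 2.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SignatureCollection]:
    """Negative-binomial count matrix with a planted DP population.

    DP cells carry nonzero ITGAE/ENTPD1 marker means (``marker_shift``) and a
    2**signature_shift fold up-shift on a cytotoxic/exhausted signature
    block; all other cells have exactly zero marker means, so the DP gate at
    threshold 0 recovers the truth exactly.  Returns (counts, per-cell
    annotation with cluster/patient/dp_class truth, signature collection
    holding the planted block and a size-matched null block).
    """
    if not 0 <= dp_fraction <= 1 or not 0 <= sp_fraction <= 1 - dp_fraction:
        raise ValueError("dp_fraction/sp_fraction must partition [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"SC_G{i:04d}" for i in range(n_genes)]
    block = [f"CTX_G{i:02d}" for i in range(signature_block_size)]
    null_block = [f"NULLSC_G{i:02d}" for i in range(signature_block_size)]
    all_genes = genes + block + null_block + ["ITGAE", "ENTPD1"]
    cells = [f"cell_{i:04d}" for i in range(n_cells)]

    clusters = rng.integers(0, n_clusters, size=n_cells)
    patients = rng.integers(0, 3, size=n_cells)
    n_dp = int(round(dp_fraction * n_cells))
    n_sp = int(round(sp_fraction * n_cells))
    dp_class = np.array(["DN"] * n_cells, dtype=object)
    order = rng.permutation(n_cells)
    dp_idx, sp_idx = order[:n_dp], order[n_dp:n_dp + n_sp]
    dp_class[dp_idx] = "DP"
    dp_class[sp_idx] = "SP"

    base = rng.lognormal(mean=0.5, sigma=0.8, size=len(all_genes))
    cluster_factor = rng.lognormal(mean=0.0, sigma=0.4, size=(len(all_genes), n_clusters))
    mean = base[:, None] * cluster_factor[:, clusters]

    gene_pos = {g: i for i, g in enumerate(all_genes)}
    for g in block:
        mean[gene_pos[g], dp_idx] *= 2.0 ** signature_shift
    for marker in ("ITGAE", "ENTPD1"):
        mean[gene_pos[marker]] = 0.0
        mean[gene_pos[marker], dp_idx] = marker_shift
    if n_sp:  # SP cells express exactly one marker
        half = len(sp_idx) // 2
        mean[gene_pos["ITGAE"], sp_idx[:half]] = marker_shift
        mean[gene_pos["ENTPD1"], sp_idx[half:]] = marker_shift

    r = dispersion
    counts = np.where(mean > 0,
                      rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12))), 0)
    # marker channels are noiseless in the gating sense: a cell planted as
    # expressing a marker always has >= 1 count, so the DP/DN/SP gate at
    # threshold 0 recovers the planted classes exactly
    for marker in ("ITGAE", "ENTPD1"):
        i = gene_pos[marker]
        counts[i] = np.where(mean[i] > 0, np.maximum(counts[i], 1), 0)
    expr = ExpressionMatrix(pd.DataFrame(counts.astype(float), index=all_genes,
                                         columns=cells), scale_tag="counts")
    annot = pd.DataFrame({"cluster": [f"cl{c}" for c in clusters],
                          "patient": [f"pt{p}" for p in patients],
                          "dp_class": dp_class}, index=cells)
    sigs = SignatureCollection({"CYTOTOX_EXHAUSTED": block, "NULL_BLOCK": null_block},
                               source_tag="synthetic")
    return expr, annot, sigs


# ---------------------------------------------------------------------------
# cytometry

def generate_cytometry(
    n_high: int = 7,
    n_low: int = 6,
    n_clusters: int = 8,
    n_markers: int = 10,
    events_per_sample: int = 1500,
    delta: float = 0.15,
    target_clusters: tuple[str, ...] = ("cl0",),
    concentration: float = 200.0,
    seed: int = 0,
) -> tuple[CytometryFrame, pd.Series, pd.Series]:
    """Event-level intensity mixture with a planted cluster-frequency shift.

    High-group samples have the target clusters' mean frequency raised by
    ``delta`` in total (renormalizing the rest proportionally).  Returns
    (raw frame, per-event cluster labels, sample -> group mapping).
    """
    rng = np.random.default_rng(seed)
    cluster_names = [f"cl{i}" for i in range(n_clusters)]
    targets = [cluster_names.index(t) for t in target_clusters]

    base = rng.dirichlet(np.full(n_clusters, 5.0))
    pi_high = base.copy()
    pi_high[targets] += delta / len(targets)
    others = [i for i in range(n_clusters) if i not in targets]
    pi_high[others] *= (1.0 - pi_high[targets].sum()) / base[others].sum()
    if (pi_high < 0).any() or pi_high.sum() > 1 + 1e-9:
        raise ValueError("planted delta pushes frequencies out of the simplex")

    marker_logmean = rng.normal(1.0, 0.8, size=(n_clusters, n_markers))
    markers = [f"M{i:02d}" for i in range(n_markers)]

    frames, labels, sample_ids, groups = [], [], [], {}
    for group, n_s, pi in (("high", n_high, pi_high), ("low", n_low, base)):
        for s in range(n_s):
            sample = f"{group}_{s + 1:02d}"
            groups[sample] = group
            freq = rng.dirichlet(concentration * pi)
            cl = rng.choice(n_clusters, size=events_per_sample, p=freq)
            intensity = rng.lognormal(mean=marker_logmean[cl], sigma=0.5)
            frames.append(intensity)
            labels.append([cluster_names[c] for c in cl])
            sample_ids += [sample] * events_per_sample
    data = pd.DataFrame(np.vstack(frames), columns=markers)
    frame = CytometryFrame(data=data, sample_id=pd.Series(sample_ids),
                           transform_state="raw")
    cluster_labels = pd.Series(np.concatenate(labels), index=data.index)
    return frame, cluster_labels, pd.Series(groups)
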