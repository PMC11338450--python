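"""Evaluation metrics: expression recovery, clustering, and false signals.

Recovery is RMSE/PCC between an imputed matrix and the log-normalized true
counts; clustering quality is K-means ARI/NMI against known group labels;
over-imputation is assessed by percentile-threshold binarization with FPR and
F-score against the true zero pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .core import Hyperparams, fit, impute
from .io_preprocess import CountMatrix, log_normalize, preprocess
from .similarity import build_graphs
from .simulate import SimTruth


def recovery_metrics(imputed: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """RMSE and global Pearson correlation over all (flattened) entries.

    ``truth`` should be the log-normalized true counts.  A constant input
    makes the correlation undefined; it is reported as 0 with a warning.
    """
    imputed = np.asarray(imputed, float)
    truth = np.asarray(truth, float)
    if imputed.shape != truth.shape:
        raise ValueError(f"shape mismatch: {imputed.shape} vs {truth.shape}")
    diff = imputed - truth
    rmse = float(np.sqrt(np.mean(diff * diff)))
    a, b = imputed.ravel(), truth.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant input: Pearson correlation undefined, reporting 0")
        pcc = 0.0
    else:
        pcc = float(np.corrcoef(a, b)[0, 1])
    return rmse, pcc


def cluster_and_score(
    imputed: np.ndarray,
    true_labels: np.ndarray,
    n_clusters: int | None = None,
    seed: int = 0,
    n_init: int = 20,
) -> tuple[float, float]:
    """Seeded K-means over cells (columns), scored by ARI and NMI."""
    imputed = np.asarray(imputed, float)
    true_labels = np.asarray(true_labels)
    if imputed.shape[1] != len(true_labels):
        raise ValueError("label count must match number of cells (columns)")
    if n_clusters is None:
        n_clusters = len(np.unique(true_labels))
    if imputed.shape[1] < n_clusters:
        raise ValueError("fewer cells than clusters")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    pred = km.fit_predict(imputed.T)
    ari = float(adjusted_rand_score(true_labels, pred))
    nmi = float(normalized_mutual_info_score(true_labels, pred))
    return ari, nmi


def false_signal_eval(
    imputed: np.ndarray, true_counts: np.ndarray, percentile: float
) -> tuple[float, float]:
    """Binarize at an imputed-value percentile; score FPR and F1.

    The threshold is the given percentile of all imputed entries; entries
    strictly above it are predicted non-zero.  Positives are entries whose
    true count is non-zero.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    imputed = np.asarray(imputed, float)
    true_counts = np.asarray(true_counts, float)
    if imputed.shape != true_counts.shape:
        raise ValueError("shape mismatch")
    threshold = float(np.percentile(imputed, percentile))
    predicted = imputed > threshold
    positive = true_counts > 0
    n_true_zero = int(np.sum(~positive))
    if n_true_zero == 0:
        raise ValueError("no true zeros: FPR undefined (use simulated data)")
    fp = int(np.sum(predicted & ~positive))
    tn = n_true_zero - fp
    tp = int(np.sum(predicted & positive))
    fn = int(np.sum(positive)) - tp
    fpr = fp / (fp + tn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    fscore = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return float(fpr), float(fscore)


# ---------------------------------------------------------------------------
# End-to-end pipelines on simulated data
# ---------------------------------------------------------------------------


def _processed_and_labels(
    sim: SimTruth, min_cells: int, n_top: int
) -> tuple[np.ndarray, np.ndarray, "object"]:
    """Preprocess observed counts; align labels with surviving cells."""
    counts = sim.observed_count_matrix()
    processed = preprocess(counts, min_cells=min_cells, n_top=n_top)
    cell_index = {c: i for i, c in enumerate(counts.cell_ids)}
    kept = np.array([cell_index[c] for c in processed.cell_ids])
    return processed.values, sim.group_labels[kept], processed


def raw_clustering_baseline(
    sim: SimTruth,
    min_cells: int = 3,
    n_top: int = 2000,
    seed: int = 0,
    n_init: int = 20,
) -> tuple[float, float]:
    """ARI/NMI of K-means on the un-imputed log-normalized matrix."""
    values, labels, _ = _processed_and_labels(sim, min_cells, n_top)
    return cluster_and_score(values, labels, seed=seed, n_init=n_init)


def k_sweep(
    sim: SimTruth,
    k_values,
    hyper_base: Hyperparams | None = None,
    seed: int = 0,
    min_cells: int = 3,
    n_top: int = 2000,
    max_iter: int = 300,
    tol: float = 1e-4,
    n_init: int = 20,
) -> pd.DataFrame:
    """Fit/impute/cluster at each requested latent dimension.

    Returns a tidy table with one row per requested ``k`` (duplicates give
    duplicate rows); a failing fit is recorded with ``failed=True`` and NaN
    scores while the sweep continues.
    """
    if hyper_base is None:
        hyper_base = Hyperparams(k=2)
    values, labels, _ = _processed_and_labels(sim, min_cells, n_top)
    graphs = build_graphs(values)
    rows = []
    for k in k_values:
        try:
            hyper = Hyperparams(k=int(k), sigma=hyper_base.sigma,
                                alpha=hyper_base.alpha, beta=hyper_base.beta,
                                lam=hyper_base.lam)
            model = fit(values, graphs, hyper, init_seed=seed,
                        max_iter=max_iter, tol=tol)
            imputed = impute(values, model, mode="full")
            ari, nmi = cluster_and_score(imputed, labels, seed=seed, n_init=n_init)
            rows.append(dict(k=int(k), ari=ari, nmi=nmi, failed=False))
        except Exception:  # noqa: BLE001 - record and continue
            rows.append(dict(k=int(k), ari=np.nan, nmi=np.nan, failed=True))
    return pd.DataFrame(rows)


def normalized_truth(sim: SimTruth, gene_ids: list[str] | None = None,
                     cell_ids: list[str] | None = None) -> np.ndarray:
    """Log-normalized true counts, optionally restricted to given genes/cells.

    Used as the reference matrix for recovery metrics so imputed and true
    values are compared on the same scale.
    """
    counts = CountMatrix(
        sim.true_counts.astype(float),
        [f"gene{i}" for i in range(sim.true_counts.shape[0])],
        [f"cell{j}" for j in range(sim.true_counts.shape[1])],
    )
    processed = log_normalize(counts)
    g_index = {g: i for i, g in enumerate(processed.gene_ids)}
    c_index = {c: i for i, c in enumerate(processed.cell_ids)}
    gi = [g_index[g] for g in (gene_ids or processed.gene_ids)]
    ci = [c_index[c] for c in (cell_ids or processed.cell_ids)]
    return processed.values[np.ix_(gi, ci)]
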