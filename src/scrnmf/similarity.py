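"""Gene-gene and cell-cell similarity graphs for the factorization penalties.

Each graph entry is the average of cosine similarity and Pearson correlation,
clipped at zero after averaging so every term feeding the multiplicative
updates stays non-negative.  Diagonals are forced to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preprocess import ProcessedMatrix


@dataclass
class SimilarityGraphs:
    """Symmetric similarity matrices with entries in [0, 1], unit diagonal."""

    K_G: np.ndarray  # gene-gene, (G, G)
    K_C: np.ndarray  # cell-cell, (C, C)

    def __post_init__(self) -> None:
        for name, k in (("K_G", self.K_G), ("K_C", self.K_C)):
            k = np.asarray(k, dtype=float)
            if k.ndim != 2 or k.shape[0] != k.shape[1]:
                raise ValueError(f"{name} must be square")
            if np.abs(k - k.T).max(initial=0.0) > 1e-10:
                raise ValueError(f"{name} must be symmetric")
            if k.size and (k.min() < 0 or k.max() > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")


def cosine_sim(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of the rows of ``vectors``.

    All-zero rows get self-similarity 1 and cross-similarity 0.
    """
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    unit = v / safe[:, None]
    sim = unit @ unit.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.clip(sim, -1.0, 1.0, out=sim)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return sim


def corr_sim(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of the rows of ``vectors``.

    Constant rows correlate 0 with everything else and 1 with themselves.
    """
    v = np.asarray(vectors, dtype=float)
    if v.shape[1] < 2:
        raise ValueError("vectors must have length >= 2")
    centered = v - v.mean(axis=1, keepdims=True)
    # correlation of centered vectors == their cosine similarity
    return cosine_sim(centered)


def build_graphs(x: ProcessedMatrix | np.ndarray) -> SimilarityGraphs:
    """Average-of-cosine-and-correlation graphs over genes and over cells."""
    values = x.values if isinstance(x, ProcessedMatrix) else np.asarray(x, float)
    if values.size == 0:
        raise ValueError("cannot build graphs from an empty matrix")

    def _graph(rows: np.ndarray) -> np.ndarray:
        avg = (cosine_sim(rows) + corr_sim(rows)) / 2.0
        np.clip(avg, 0.0, 1.0, out=avg)
        np.fill_diagonal(avg, 1.0)
        return avg

    return SimilarityGraphs(K_G=_graph(values), K_C=_graph(values.T))


def export_graphs(graphs: SimilarityGraphs, kg_path, kc_path) -> None:
    """Dump both graphs as dense CSV for inspection."""
    pd.DataFrame(graphs.K_G).to_csv(kg_path, index=False)
    pd.DataFrame(graphs.K_C).to_csv(kc_path, index=False)
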