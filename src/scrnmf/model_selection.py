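"""Hyperparameter search by masked-entry reconstruction error.

A fixed random 10 % of the non-zero entries are zeroed out, candidate
configurations are fitted on the masked matrix, and each is scored by the
RMSE between its imputed values and the held-out entries.  One shared mask is
used across all candidates so scores are directly comparable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .core import Hyperparams, fit, impute
from .io_preprocess import ProcessedMatrix
from .similarity import SimilarityGraphs


@dataclass
class MaskSet:
    """Positions and original values of held-out entries."""

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SearchSpace:
    k_choices: tuple = (2, 10, 20, 30, 40, 50)
    sigma_grid: tuple = tuple(10.0 ** e for e in range(-5, 4))   # 1e-5 .. 1e3
    alpha_grid: tuple = tuple(10.0 ** e for e in range(-5, 2))   # 1e-5 .. 10
    beta_grid: tuple = tuple(10.0 ** e for e in range(-5, 2))
    lam_grid: tuple = tuple(10.0 ** e for e in range(-5, 2))
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_choices", "sigma_grid", "alpha_grid", "beta_grid", "lam_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def size(self) -> int:
        return (
            len(self.k_choices) * len(self.sigma_grid) * len(self.alpha_grid)
            * len(self.beta_grid) * len(self.lam_grid)
        )

    def sample(self, rng: np.random.Generator) -> list[Hyperparams]:
        """Draw ``n_samples`` configurations, without replacement when the
        grid is large enough."""
        grids = (self.k_choices, self.sigma_grid, self.alpha_grid,
                 self.beta_grid, self.lam_grid)
        if self.n_samples < self.size:
            flat = rng.choice(self.size, size=self.n_samples, replace=False)
        else:
            flat = rng.integers(0, self.size, size=self.n_samples)
        configs = []
        for idx in flat:
            coords = []
            rem = int(idx)
            for grid in reversed(grids):
                rem, pos = divmod(rem, len(grid))
                coords.append(grid[pos])
            lam, beta, alpha, sigma, k = coords
            configs.append(Hyperparams(k=int(k), sigma=sigma, alpha=alpha,
                                       beta=beta, lam=lam))
        return configs


def mask_nonzeros(
    x: ProcessedMatrix | np.ndarray, fraction: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, MaskSet]:
    """Zero out ``round(fraction * nnz)`` uniformly chosen non-zero entries.

    Returns the masked matrix (a copy) and the mask with held-out values.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    values = x.values if isinstance(x, ProcessedMatrix) else np.asarray(x, float)
    rows, cols = np.nonzero(values)
    nnz = len(rows)
    if nnz == 0:
        raise ValueError("matrix has no non-zero entries to mask")
    n_mask = int(round(fraction * nnz))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(nnz, size=n_mask, replace=False)
    mask = MaskSet(rows=rows[chosen], cols=cols[chosen],
                   values=values[rows[chosen], cols[chosen]].copy())
    masked = values.copy()
    masked[mask.rows, mask.cols] = 0.0
    return masked, mask


def masked_rmse(imputed: np.ndarray, mask: MaskSet) -> float:
    """RMSE between imputed values and the held-out originals."""
    if len(mask) == 0:
        raise ValueError("mask is empty")
    diff = imputed[mask.rows, mask.cols] - mask.values
    return float(np.sqrt(np.mean(diff * diff)))


def random_search(
    x: ProcessedMatrix | np.ndarray,
    graphs: SimilarityGraphs,
    space: SearchSpace,
    mask_fraction: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-4,
    init_seed: int = 0,
) -> tuple[Hyperparams, pd.DataFrame]:
    """Random hyperparameter search scored by shared-mask RMSE.

    Returns the best configuration (lowest masked RMSE, ties to the earlier
    sample) and a leaderboard of every sampled configuration.  A failing fit
    scores +inf and the search continues.  Fully seeded.
    """
    rng = np.random.default_rng(space.seed)
    masked, mask = mask_nonzeros(x, fraction=mask_fraction, seed=space.seed)
    configs = space.sample(rng)
    records = []
    for i, hyper in enumerate(configs):
        try:
            model = fit(masked, graphs, hyper, init_seed=init_seed,
                        max_iter=max_iter, tol=tol)
            score = masked_rmse(impute(masked, model, mode="full"), mask)
        except Exception as exc:  # noqa: BLE001 - any single failure scores inf
            score = float("inf")
            records.append(dict(sample=i, k=hyper.k, sigma=hyper.sigma,
                                alpha=hyper.alpha, beta=hyper.beta,
                                lam=hyper.lam, rmse=score, error=str(exc)))
            continue
        records.append(dict(sample=i, k=hyper.k, sigma=hyper.sigma,
                            alpha=hyper.alpha, beta=hyper.beta,
                            lam=hyper.lam, rmse=score, error=""))
    leaderboard = pd.DataFrame.from_records(records)
    best_idx = int(np.argmin(leaderboard["rmse"].to_numpy()))
    return configs[best_idx], leaderboard
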