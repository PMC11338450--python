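"""Robust graph-regularized NMF solver.

The model approximates a log-normalized expression matrix ``X`` (genes x
cells) by ``W @ H`` with non-negative factors, fitting observed non-zero
entries under an L2 loss and zero entries under a bounded correntropy-induced
loss (C-loss), with graph-consistency penalties on both factors and a penalty
discouraging large reconstructions at zeros:

    J(W, H) = 1/2 * sum_{X!=0} (X - WH)^2
            + 1/2 * sum_{X==0} closs(X - WH)
            + alpha/2 * ||K_G - W W^T||_F^2
            + beta/2  * ||K_C - H^T H||_F^2
            + lam/2   * sum_{X==0} (WH)^2

Minimization alternates a half-quadratic reweighting of the C-loss (closed
form: weight = exp(-r^2 / 2 sigma^2) on zero entries) with one multiplicative
update of W then H per outer iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import ProcessedMatrix
from .similarity import SimilarityGraphs

EPS = 1e-12


class NumericalError(RuntimeError):
    """Raised when an update produces a non-finite factor entry."""


@dataclass
class Hyperparams:
    """Solver hyperparameters: latent dimension and penalty weights."""

    k: int
    sigma: float = 1.0
    alpha: float = 0.1
    beta: float = 0.1
    lam: float = 0.1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if min(self.alpha, self.beta, self.lam) < 0:
            raise ValueError("alpha, beta and lam must be >= 0")


@dataclass
class HQState:
    """Per-entry weights of the half-quadratic subproblem.

    ``M`` is 1 on non-zero entries and ``exp(-r^2 / 2 sigma^2)`` on zero
    entries; ``P`` is the indicator of zero entries.
    """

    M: np.ndarray
    P: np.ndarray


@dataclass
class FactorModel:
    """Fitted non-negative factors plus diagnostics."""

    W: np.ndarray
    H: np.ndarray
    hyper: Hyperparams
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _as_array(x) -> np.ndarray:
    if isinstance(x, ProcessedMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def closs(residual, sigma: float):
    """Correntropy-induced loss ``1 - exp(-r^2 / (2 sigma^2))``.

    Bounded in [0, 1), even in the residual, and ~ r^2/(2 sigma^2) for small
    residuals.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = np.asarray(residual, dtype=float)
    # -expm1 avoids cancellation for tiny residuals (1 - exp(-z) with z ~ 0)
    out = -np.expm1(-(r * r) / (2.0 * sigma * sigma))
    return float(out) if out.ndim == 0 else out


def hq_weights(x, W: np.ndarray, H: np.ndarray, sigma: float) -> HQState:
    """Closed-form half-quadratic weights for the current reconstruction."""
    xv = _as_array(x)
    wh = W @ H
    if xv.shape != wh.shape:
        raise ValueError(f"shape mismatch: X {xv.shape} vs WH {wh.shape}")
    zero = xv == 0
    resid = xv - wh
    M = np.ones_like(xv)
    M[zero] = np.exp(-(resid[zero] ** 2) / (2.0 * sigma * sigma))
    return HQState(M=M, P=zero.astype(float))


def objective(
    x,
    W: np.ndarray,
    H: np.ndarray,
    graphs: SimilarityGraphs | None,
    hyper: Hyperparams,
    zero_loss: str = "closs",
) -> float:
    """Evaluate the full objective J(W, H)."""
    xv = _as_array(x)
    wh = W @ H
    if xv.shape != wh.shape:
        raise ValueError(f"shape mismatch: X {xv.shape} vs WH {wh.shape}")
    zero = xv == 0
    resid = xv - wh
    obj = 0.5 * float(np.sum(resid[~zero] ** 2))
    if zero_loss == "closs":
        obj += 0.5 * float(np.sum(closs(resid[zero], hyper.sigma)))
    elif zero_loss == "l2":
        obj += 0.5 * float(np.sum(resid[zero] ** 2))
    else:
        raise ValueError(f"unknown zero_loss: {zero_loss!r}")
    if hyper.alpha > 0 or hyper.beta > 0:
        if graphs is None:
            raise ValueError("graphs required when alpha or beta > 0")
        obj += 0.5 * hyper.alpha * float(np.sum((graphs.K_G - W @ W.T) ** 2))
        obj += 0.5 * hyper.beta * float(np.sum((graphs.K_C - H.T @ H) ** 2))
    obj += 0.5 * hyper.lam * float(np.sum(wh[zero] ** 2))
    return obj


def update_factors(
    x,
    W: np.ndarray,
    H: np.ndarray,
    hq: HQState,
    graphs: SimilarityGraphs | None,
    hyper: Hyperparams,
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative step for W, then for H using the new W.

    Denominators are floored at ``EPS``; factor entries are floored at
    ``EPS`` so multiplicative updates never die at exact zero.
    """
    xv = _as_array(x)
    M, P = hq.M, hq.P
    alpha, beta, lam = hyper.alpha, hyper.beta, hyper.lam
    if (alpha > 0 or beta > 0) and graphs is None:
        raise ValueError("graphs required when alpha or beta > 0")

    MX = M * xv
    WH = W @ H
    num_W = MX @ H.T
    den_W = (M * WH) @ H.T
    if lam > 0:
        den_W = den_W + lam * ((P * WH) @ H.T)
    if alpha > 0:
        num_W = num_W + alpha * (graphs.K_G @ W)
        den_W = den_W + alpha * (W @ (W.T @ W))
    W_new = W * (num_W / np.maximum(den_W, EPS))
    if not np.all(np.isfinite(W_new)):
        raise NumericalError("non-finite entries produced in factor W")
    W_new = np.maximum(W_new, EPS)

    WH = W_new @ H
    num_H = W_new.T @ MX
    den_H = W_new.T @ (M * WH)
    if lam > 0:
        den_H = den_H + lam * (W_new.T @ (P * WH))
    if beta > 0:
        num_H = num_H + beta * (H @ graphs.K_C)
        den_H = den_H + beta * ((H @ H.T) @ H)
    H_new = H * (num_H / np.maximum(den_H, EPS))
    if not np.all(np.isfinite(H_new)):
        raise NumericalError("non-finite entries produced in factor H")
    H_new = np.maximum(H_new, EPS)
    return W_new, H_new


def init_factors(
    x, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform(0,1) factors scaled by sqrt(mean(X)/k), strictly positive."""
    xv = _as_array(x)
    rng = np.random.default_rng(seed)
    scale = float(np.sqrt(max(xv.mean(), EPS) / k))
    W = np.maximum(rng.uniform(size=(xv.shape[0], k)) * scale, EPS)
    H = np.maximum(rng.uniform(size=(k, xv.shape[1])) * scale, EPS)
    return W, H


def fit(
    x,
    graphs: SimilarityGraphs | None,
    hyper: Hyperparams,
    init_seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    zero_loss: str = "closs",
    monotone_safeguard: bool = True,
) -> FactorModel:
    """Fit the factor model by half-quadratic alternation.

    Each outer iteration recomputes the half-quadratic weights at the current
    factors and then takes one multiplicative step on W and one on H.  Stops
    when the relative objective change falls below ``tol`` or ``max_iter`` is
    reached.  Fully deterministic for a given ``init_seed``.

    ``monotone_safeguard`` keeps the recorded objective trace non-increasing:
    a candidate step that would raise the objective (the plain multiplicative
    rule is not monotone for large graph weights, where the quartic penalties
    can make it overshoot) is damped geometrically toward the current iterate
    until the objective no longer increases.  The multiplicative step is a
    positively-rescaled negative gradient direction, so a small enough
    damping factor always descends; if none of the tried factors helps, the
    step is rejected and iteration stops.  Whenever the plain step already
    decreases the objective it is accepted unchanged, so well-behaved regimes
    (e.g. the classical-NMF degenerate case) are untouched.

    ``zero_loss='l2'`` replaces the C-loss on zeros with a plain L2 loss
    (all half-quadratic weights pinned at 1) — the ablation baseline.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    xv = _as_array(x)
    W, H = init_factors(xv, hyper.k, init_seed)
    trace = [objective(xv, W, H, graphs, hyper, zero_loss=zero_loss)]
    zero_mask = (xv == 0).astype(float)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if zero_loss == "closs":
            hq = hq_weights(xv, W, H, hyper.sigma)
        else:
            hq = HQState(M=np.ones_like(xv), P=zero_mask)
        W_cand, H_cand = update_factors(xv, W, H, hq, graphs, hyper)
        obj = objective(xv, W_cand, H_cand, graphs, hyper, zero_loss=zero_loss)
        if monotone_safeguard and obj > trace[-1]:
            gamma, accepted = 0.5, False
            while gamma > 1e-6:
                W_try = (1.0 - gamma) * W + gamma * W_cand
                H_try = (1.0 - gamma) * H + gamma * H_cand
                obj_try = objective(xv, W_try, H_try, graphs, hyper,
                                    zero_loss=zero_loss)
                if obj_try <= trace[-1]:
                    W_cand, H_cand, obj, accepted = W_try, H_try, obj_try, True
                    break
                gamma *= 0.5
            if not accepted:  # no damping helps: stop at the current iterate
                converged = True
                n_iter -= 1
                break
        W, H = W_cand, H_cand
        trace.append(obj)
        if abs(trace[-2] - trace[-1]) / max(abs(trace[-2]), EPS) < tol:
            converged = True
            break
    return FactorModel(
        W=W, H=H, hyper=hyper, objective_trace=trace, n_iter=n_iter, converged=converged
    )


def impute(x, model: FactorModel, mode: str = "full") -> np.ndarray:
    """Reconstruct the matrix from the fitted factors.

    ``mode='full'`` returns ``W @ H`` everywhere; ``mode='zeros_only'`` keeps
    observed non-zero entries and substitutes ``W @ H`` only at zeros.
    """
    xv = _as_array(x)
    wh = model.W @ model.H
    if xv.shape != wh.shape:
        raise ValueError(f"shape mismatch: X {xv.shape} vs model {wh.shape}")
    if mode == "full":
        return wh
    if mode == "zeros_only":
        return np.where(xv != 0, xv, wh)
    raise ValueError(f"unknown impute mode: {mode!r}")


# ---------------------------------------------------------------------------
# Checkpointing (text-only bundle)
# ---------------------------------------------------------------------------


def save_model(model: FactorModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "W.csv", model.W, delimiter=",")
    np.savetxt(directory / "H.csv", model.H, delimiter=",")
    pd.DataFrame({"objective": model.objective_trace}).to_csv(
        directory / "objective_trace.csv", index_label="iteration"
    )
    meta = {
        "k": model.hyper.k,
        "sigma": model.hyper.sigma,
        "alpha": model.hyper.alpha,
        "beta": model.hyper.beta,
        "lam": model.hyper.lam,
        "n_iter": model.n_iter,
        "converged": model.converged,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> FactorModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    W = np.loadtxt(directory / "W.csv", delimiter=",", ndmin=2)
    H = np.loadtxt(directory / "H.csv", delimiter=",", ndmin=2)
    trace = pd.read_csv(directory / "objective_trace.csv")["objective"].tolist()
    hyper = Hyperparams(
        k=meta["k"], sigma=meta["sigma"], alpha=meta["alpha"],
        beta=meta["beta"], lam=meta["lam"],
    )
    return FactorModel(
        W=W, H=H, hyper=hyper, objective_trace=trace,
        n_iter=meta["n_iter"], converged=meta["converged"],
    )
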