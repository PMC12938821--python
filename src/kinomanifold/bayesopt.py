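"""KAL-guided Bayesian optimization over the latent space.

A Gaussian-process surrogate (Matérn 5/2) models the KAL score as a
black-box function of the latent coordinates; Expected Improvement is
maximized by multi-start L-BFGS-B within a bounding box; runs stop at a
step budget or when the best score plateaus.  Initialization is either
unbiased (uniform draws in the box) or biased (encoded reference ligands
evaluated first, injecting prior knowledge of the target manifold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass
class KernelConfig:
    length_scale: float = 1.0
    signal_variance: float = 1.0
    noise: float = 1e-4
    optimize_hyperparameters: bool = True


class GpSurrogate:
    """Matérn 5/2 Gaussian process over latent points, fitted by sklearn.

    Hyperparameters are set by maximum marginal likelihood when
    ``optimize_hyperparameters`` is on; otherwise the given values are kept
    (used between periodic refits during a BO run).
    """

    def __init__(self, Z: np.ndarray, y: np.ndarray, config: Optional[KernelConfig] = None,
                 kernel=None, seed: int = 0):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        y = np.asarray(y, dtype=float)
        if Z.shape[0] < 2:
            raise ValueError("need at least 2 points to fit a surrogate")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite targets")
        config = config or KernelConfig()
        if kernel is None:
            kernel = ConstantKernel(config.signal_variance) * Matern(
                length_scale=config.length_scale, nu=2.5
            ) + WhiteKernel(noise_level=config.noise, noise_level_bounds=(1e-10, 1e1))
        optimizer = "fmin_l_bfgs_b" if config.optimize_hyperparameters else None
        self.gp = GaussianProcessRegressor(
            kernel=kernel, optimizer=optimizer, normalize_y=False,
            random_state=seed, alpha=1e-10,
        )
        self.gp.fit(Z, y)
        self.Z, self.y = Z, y

    @property
    def kernel_(self):
        return self.gp.kernel_

    def posterior(self, Z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation at query points."""
        mean, sd = self.gp.predict(np.atleast_2d(Z), return_std=True)
        return mean, sd


def fit_gp(Z, y, config: Optional[KernelConfig] = None, seed: int = 0) -> GpSurrogate:
    return GpSurrogate(Z, y, config=config, seed=seed)


def expected_improvement(mean, sd, best: float, xi: float = 0.0):
    """Closed-form EI for maximization.

    EI = (mean - best - xi) * Phi(u) + sd * phi(u), u = (mean - best - xi)/sd;
    the sd = 0 limit is max(mean - best - xi, 0).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    improve = mean - best - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(sd > 0, improve / np.where(sd > 0, sd, 1.0), 0.0)
    ei = np.where(sd > 0, improve * norm.cdf(u) + sd * norm.pdf(u), np.maximum(improve, 0.0))
    return ei if ei.shape else float(ei)


@dataclass
class BoConfig:
    """Per-dimension box, initialization sizes, and stopping rules.

    Defaults mirror the full-scale protocol (1500 acquisition steps, plateau
    when the best score improves by < 0.001 over 100 consecutive steps,
    hyperparameter refits every 100 steps); desk-scale runs shrink
    ``max_steps`` and the init counts while keeping the protocol intact.
    """

    bounds: np.ndarray  # (d, 2)
    n_init_random: int = 20
    n_init_seeded: int = 0
    max_steps: int = 1500
    plateau_window: int = 100
    plateau_tol: float = 1e-3
    refit_period: int = 100
    xi: float = 0.01
    acquisition_restarts: int = 10
    history_cap: int = 1000  # GP fitted on a subsample above this
    seed: int = 0

    def __post_init__(self):
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if not np.all(self.bounds[:, 0] < self.bounds[:, 1]):
            raise ValueError("bounds must satisfy lower < upper")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


def latent_bounds(Z: np.ndarray, margin: float = 0.10) -> np.ndarray:
    """Per-dimension [min, max] of an embedded library, expanded by a margin."""
    Z = np.atleast_2d(Z)
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    return np.stack([lo - margin * span, hi + margin * span], axis=1)


def propose_next(surrogate: GpSurrogate, config: BoConfig,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Maximize EI by multi-start bounded L-BFGS-B; always within bounds."""
    rng = rng or np.random.default_rng(config.seed)
    best_y = float(np.max(surrogate.y))
    d = config.bounds.shape[0]

    def neg_ei(x):
        mean, sd = surrogate.posterior(x.reshape(1, -1))
        return -float(expected_improvement(mean[0], sd[0], best_y, config.xi))

    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    starts = rng.uniform(lo, hi, size=(config.acquisition_restarts, d))
    best_x, best_val = None, np.inf
    for x0 in starts:
        res = minimize(neg_ei, x0, method="L-BFGS-B", bounds=config.bounds)
        if res.fun < best_val:
            best_val, best_x = float(res.fun), np.clip(res.x, lo, hi)
    if best_x is None or not np.isfinite(best_val):  # every restart failed
        probes = rng.uniform(lo, hi, size=(max(64, config.acquisition_restarts), d))
        vals = [neg_ei(p) for p in probes]
        best_x = probes[int(np.argmin(vals))]
    return best_x


@dataclass
class BoRun:
    """Evaluation history, best-so-far trajectory and decoded-molecule ledger."""

    Z: np.ndarray
    scores: np.ndarray
    best_trajectory: np.ndarray
    molecules: list  # aligned with history; None where undecodable/not decoded
    stop_reason: str
    n_init: int

    @property
    def best_score(self) -> float:
        return float(self.best_trajectory[-1])

    @property
    def best_point(self) -> np.ndarray:
        return self.Z[int(np.argmax(self.scores))]


def run_bo(
    objective: Callable[[np.ndarray], float],
    config: BoConfig,
    seed_points: Optional[np.ndarray] = None,
    decode_hook: Optional[Callable[[np.ndarray], object]] = None,
) -> BoRun:
    """Iterate propose/evaluate/refit until the budget or a plateau.

    ``objective`` maps a latent vector to a score in [0, 1] (typically the
    KAL of the decoded molecule, with undecodable vectors scoring 0).
    Biased mode passes encoded reference ligands as ``seed_points``; they are
    evaluated and enter the GP before any acquisition step.  ``decode_hook``
    (latent -> molecule or None) fills the decoded ledger.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    d = config.bounds.shape[0]

    init = []
    if seed_points is not None and len(seed_points):
        init.append(np.atleast_2d(np.asarray(seed_points, dtype=float)))
    if config.n_init_random > 0:
        init.append(rng.uniform(lo, hi, size=(config.n_init_random, d)))
    Z = np.vstack(init) if init else np.empty((0, d))
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 initialization points")
    n_init = Z.shape[0]

    def safe_eval(z):
        try:
            return float(objective(z))
        except Exception:
            return np.nan

    scores = np.array([safe_eval(z) for z in Z])
    valid = np.isfinite(scores)
    scores[~valid] = np.nanmin(scores[valid]) if valid.any() else 0.0

    kernel = None
    surrogate = None
    stop_reason = "max_steps"
    best_hist = [float(np.max(scores[: i + 1])) for i in range(len(scores))]

    for step in range(config.max_steps):
        refit_hp = kernel is None or (step % config.refit_period == 0)
        Zfit, yfit = Z, scores
        if len(Z) > config.history_cap:
            top = np.argsort(scores)[-config.history_cap // 2:]
            rest = rng.choice(
                np.setdiff1d(np.arange(len(Z)), top),
                size=config.history_cap - len(top), replace=False)
            keep = np.concatenate([top, rest])
            Zfit, yfit = Z[keep], scores[keep]
        cfg = KernelConfig(optimize_hyperparameters=refit_hp)
        surrogate = GpSurrogate(Zfit, yfit, config=cfg,
                                kernel=None if refit_hp else kernel, seed=config.seed)
        kernel = surrogate.kernel_

        z_next = propose_next(surrogate, config, rng)
        # repeated proposal (within tolerance of an evaluated point) -> jitter
        if np.min(np.linalg.norm(Z - z_next, axis=1)) < 1e-9:
            z_next = np.clip(z_next + rng.normal(0, 1e-3 * (hi - lo)), lo, hi)
        y_next = safe_eval(z_next)
        if not np.isfinite(y_next):
            continue  # failed evaluation: logged by omission, step skipped
        Z = np.vstack([Z, z_next])
        scores = np.append(scores, y_next)
        best_hist.append(max(best_hist[-1], y_next))

        w = config.plateau_window
        if step + 1 > w and best_hist[-1] - best_hist[-1 - w] < config.plateau_tol:
            stop_reason = "plateau"
            break

    molecules = [decode_hook(z) if decode_hook else None for z in Z]
    return BoRun(
        Z=Z, scores=scores, best_trajectory=np.array(best_hist),
        molecules=molecules, stop_reason=stop_reason, n_init=n_init,
    )


def make_latent_objective(vae, kal_model, decode_policy, seed: int = 0):
    """KAL-of-decoded-molecule objective; undecodable latent vectors score 0.

    Returns ``(objective, decode_hook)``; each call uses a per-vector seed
    derived from the vector so evaluations are deterministic.
    """
    from .kal import kal_score
    from .latent_core import decode_with_retries
    from dataclasses import replace

    def _policy_for(z):
        h = int(abs(hash(tuple(np.round(z, 6)))) % (2**31))
        return replace(decode_policy, seed=(seed + h) % (2**31))

    def decode_hook(z):
        mol, _ = decode_with_retries(vae, z, _policy_for(z))
        return mol

    def objective(z):
        mol = decode_hook(z)
        return 0.0 if mol is None else kal_score(kal_model, mol)

    return objective, decode_hook
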