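"""Single-exponential learning-curve fitting via particle swarm + local polish.

Baseline-adjusted SLA curves are fitted to ``y(n) = a * exp(b * n) + c``
(1-based stride index ``n``, ``b < 0`` for decay) by minimizing the sum of
squared errors.  A global-best particle swarm explores the bounded parameter
box; the swarm optimum is then polished with a bounded trust-region
least-squares step so that refits are deterministic under a fixed seed and
match derivative-free reference optimizers to high precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ..stride import StrideSeries

__all__ = ["PsoConfig", "ExponentialFit", "fit_exponential", "fit_exponential_batch"]

# parameter box: |a|, |c| <= 1 (SLA units), b strictly negative per-stride rate
_B_EPS = 1e-6


@dataclass(frozen=True)
class PsoConfig:
    """Particle-swarm settings for the exponential fit.

    Defaults are stand-ins for the published swarm settings (50 particles,
    500 iterations) with standard constriction-style coefficients; the
    ``fast()`` preset trades swarm budget for speed in large simulation
    studies and relies on the local polish for final precision.
    """

    n_particles: int = 50
    n_iters: int = 500
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618
    bounds_a: tuple[float, float] = (-1.0, 1.0)
    bounds_b: tuple[float, float] = (-1.0, -_B_EPS)
    bounds_c: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    polish: bool = True

    @classmethod
    def fast(cls, seed: int = 0) -> "PsoConfig":
        """Reduced swarm for replicate simulations (polish does the precision)."""
        return cls(n_particles=16, n_iters=40, seed=seed)

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds_a[0], self.bounds_b[0], self.bounds_c[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds_a[1], self.bounds_b[1], self.bounds_c[1]])


@dataclass
class ExponentialFit:
    """Fitted ``y = a*exp(b*n) + c`` with diagnostics."""

    a: float
    b: float
    c: float
    sse: float
    n_strides: int
    seed: int
    pso_sse: float
    polished: bool
    at_bounds: tuple[bool, bool, bool]
    b_identifiable: bool = True
    meta: dict = field(default_factory=dict)

    def predict(self, n) -> np.ndarray:
        """Model value at (1-based) stride indices ``n``."""
        n = np.asarray(n, dtype=float)
        return self.a * np.exp(self.b * n) + self.c

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def _as_sla_array(series) -> np.ndarray:
    if isinstance(series, StrideSeries):
        y = series.sla
    else:
        y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if y.size < 60:
        raise ValueError(
            f"need at least 60 strides to fit (got {y.size}): Early (6-30) and "
            "Late (last 30) windows would overlap")
    return y


def _seed_particles(y: np.ndarray, cfg: PsoConfig) -> np.ndarray:
    """Deterministic starting points: constant fit and a heuristic decay."""
    tail = float(np.mean(y[-30:]))
    head = float(np.mean(y[:5]))
    a0 = np.clip(head - tail, cfg.bounds_a[0], cfg.bounds_a[1])
    return np.array([
        [0.0, -1e-2, float(np.mean(y))],          # constant-fit guard
        [a0, -0.01, tail],                         # head/tail heuristic
        [a0, -0.001, tail],
    ])


def _pso_batch(ys: np.ndarray, cfg: PsoConfig) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized global-best PSO over S series sharing one stride grid.

    Parameters are positions in the (a, b, c) box; returns per-series best
    positions (S, 3) and their SSE (S,).
    """
    S, N = ys.shape
    n = np.arange(1.0, N + 1.0)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.lower, cfg.upper
    span = hi - lo
    P = cfg.n_particles

    pos = lo + span * rng.random((S, P, 3))
    for s in range(S):
        seeds = _seed_particles(ys[s], cfg)
        k = min(len(seeds), P)
        pos[s, :k] = seeds[:k]
    vel = (rng.random((S, P, 3)) - 0.5) * span * 0.2
    vmax = span * 0.5

    def sse(p):
        # p: (S, P, 3) -> (S, P)
        e = np.exp(p[..., 1:2] * n)                      # (S, P, N)
        r = p[..., 0:1] * e + p[..., 2:3] - ys[:, None, :]
        return np.einsum("spn,spn->sp", r, r)

    pbest = pos.copy()
    pbest_val = sse(pos)
    gidx = np.argmin(pbest_val, axis=1)
    gbest = pbest[np.arange(S), gidx]                    # (S, 3)
    gbest_val = pbest_val[np.arange(S), gidx]

    for _ in range(cfg.n_iters):
        r1 = rng.random((S, P, 3))
        r2 = rng.random((S, P, 3))
        vel = (cfg.inertia * vel
               + cfg.cognitive * r1 * (pbest - pos)
               + cfg.social * r2 * (gbest[:, None, :] - pos))
        np.clip(vel, -vmax, vmax, out=vel)
        pos = np.clip(pos + vel, lo, hi)
        val = sse(pos)
        improved = val < pbest_val
        pbest_val = np.where(improved, val, pbest_val)
        pbest = np.where(improved[..., None], pos, pbest)
        gidx = np.argmin(pbest_val, axis=1)
        cand = pbest_val[np.arange(S), gidx]
        upd = cand < gbest_val
        gbest_val = np.where(upd, cand, gbest_val)
        gbest = np.where(upd[:, None], pbest[np.arange(S), gidx], gbest)

    return gbest, gbest_val


def _polish(y: np.ndarray, x0: np.ndarray, cfg: PsoConfig) -> tuple[np.ndarray, float, bool]:
    n = np.arange(1.0, y.size + 1.0)

    def resid(p):
        return p[0] * np.exp(p[1] * n) + p[2] - y

    def jac(p):
        e = np.exp(p[1] * n)
        return np.column_stack([e, p[0] * n * e, np.ones_like(n)])

    try:
        res = least_squares(resid, x0, jac=jac, bounds=(cfg.lower, cfg.upper),
                            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-12)
        return res.x, float(2.0 * res.cost), True
    except Exception:  # pragma: no cover - defensive
        return x0, float(np.sum(resid(x0) ** 2)), False


def _finalize(y: np.ndarray, best: np.ndarray, best_sse: float,
              cfg: PsoConfig) -> ExponentialFit:
    pso_sse = best_sse
    polished = False
    if cfg.polish:
        xp, sse_p, ok = _polish(y, best, cfg)
        if ok and sse_p <= best_sse:
            best, best_sse, polished = xp, sse_p, True
    # invariant guard: never worse than the best constant fit
    const_sse = float(np.sum((y - np.mean(y)) ** 2))
    if best_sse > const_sse:
        best = np.array([0.0, -1e-2, float(np.mean(y))])
        best_sse = const_sse
    a, b, c = (float(v) for v in best)
    tol = 1e-9
    at_bounds = (
        abs(a - cfg.bounds_a[0]) < tol or abs(a - cfg.bounds_a[1]) < tol,
        abs(b - cfg.bounds_b[0]) < tol or abs(b - cfg.bounds_b[1]) < tol,
        abs(c - cfg.bounds_c[0]) < tol or abs(c - cfg.bounds_c[1]) < tol,
    )
    return ExponentialFit(
        a=a, b=b, c=c, sse=float(best_sse), n_strides=y.size, seed=cfg.seed,
        pso_sse=float(pso_sse), polished=polished, at_bounds=at_bounds,
        b_identifiable=abs(a) > 1e-6)


def fit_exponential(series, cfg: PsoConfig | None = None) -> ExponentialFit:
    """Fit ``y = a*exp(b*n) + c`` to one baseline-adjusted SLA series.

    Parameters
    ----------
    series : StrideSeries or 1-D array
        Baseline-adjusted SLA values, one per stride (>= 60 strides).
    cfg : PsoConfig, optional
        Swarm settings; deterministic under a fixed ``cfg.seed``.
    """
    cfg = cfg or PsoConfig()
    y = _as_sla_array(series)
    best, best_sse = _pso_batch(y[None, :], cfg)
    return _finalize(y, best[0], float(best_sse[0]), cfg)


def fit_exponential_batch(series_list, cfg: PsoConfig | None = None) -> list[ExponentialFit]:
    """Fit many equal-length series at once (vectorized swarm, per-series polish)."""
    cfg = cfg or PsoConfig()
    ys = [_as_sla_array(s) for s in series_list]
    lengths = {y.size for y in ys}
    if len(lengths) == 1:
        Y = np.stack(ys)
        bests, sses = _pso_batch(Y, cfg)
        return [_finalize(y, bests[i], float(sses[i]), cfg) for i, y in enumerate(ys)]
    return [fit_exponential(y, cfg) for y in ys]
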