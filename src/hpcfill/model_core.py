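"""Hierarchical predictive-estimator network: energy, dynamics, inference.

The network minimizes a coding length

    E = sum_m (1/sigma2) ||M_m (I_m - U1 r1_m)||^2
      + (1/sigma2_td) ||r_cat - U2 r2||^2
      + sum_m g(r1_m; alpha1) + g(r2; alpha2) + h(U1) + h(U2)

over the level-1 states r1_m (one per tiled module m, shared basis U1),
and the level-2 state r2 that predicts the concatenated level-1 state
r_cat. g(r) = alpha * sum log(1 + r_i^2) is the sparse prior,
h(U) = lambda * sum U_ij^2 the Gaussian weight prior, and M_m the
module-local feed-forward mask (all-ones for the intact network; zero over
the blind spot for the lesioned one). State inference runs the gradient
flow dr/dt = -(k1/2) dE/dr to a steady state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import TilingGeometry, tile_patch, untile

__all__ = [
    "NetworkParams",
    "HPCNetwork",
    "InferenceResult",
    "sparse_prior",
    "sparse_prior_deriv",
    "coding_length",
    "state_derivative",
    "relax_to_steady_state",
    "perceptual_image",
    "level2_rf_in_image_space",
]


@dataclass(frozen=True)
class NetworkParams:
    """Model parameters (defaults are the study's printed values)."""

    k1: float = 1.0
    k2: float = 3.0
    sigma2: float = 3.0
    sigma2_td: float = 10.0
    alpha1: float = 0.05
    alpha2: float = 0.1
    lam: float = 0.0025
    sigma2_goal: float = 0.05
    gamma: float = 0.02

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "sigma2", "sigma2_td", "lam",
                     "sigma2_goal", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("alpha must be non-negative")


def sparse_prior_deriv(r: np.ndarray, alpha: float) -> np.ndarray:
    """g'(r_i) = 2 alpha r_i / (1 + r_i^2), elementwise."""
    r = np.asarray(r, dtype=float)
    return 2.0 * alpha * r / (1.0 + r * r)


def sparse_prior(r: np.ndarray, alpha: float) -> float:
    """g(r) = alpha * sum_i log(1 + r_i^2)."""
    r = np.asarray(r, dtype=float)
    return float(alpha * np.log1p(r * r).sum())


@dataclass
class HPCNetwork:
    """Tiling geometry plus the level-1 (shared) and level-2 bases.

    ``U1`` has shape (sub_size^2, n1) and is shared by all modules; ``U2``
    has shape (n_modules * n1, n2) or may be ``None`` for a single-level
    network. ``ff_mask`` is a {0,1} indicator over the input patch zeroing
    feed-forward error flow (``None`` means all-ones / intact).
    """

    U1: np.ndarray
    U2: np.ndarray | None = None
    geometry: TilingGeometry = field(default_factory=TilingGeometry)
    params: NetworkParams = field(default_factory=NetworkParams)
    ff_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.U1 = np.asarray(self.U1, dtype=float)
        if self.U1.shape[0] != self.geometry.sub_dim:
            raise ValueError("U1 input dimension must equal sub_size^2")
        if self.U2 is not None:
            self.U2 = np.asarray(self.U2, dtype=float)
            expected = self.geometry.n_modules * self.U1.shape[1]
            if self.U2.shape[0] != expected:
                raise ValueError(
                    f"U2 must have {expected} rows (n_modules * n1), "
                    f"got {self.U2.shape[0]}"
                )
        if self.ff_mask is not None:
            self.ff_mask = np.asarray(self.ff_mask, dtype=float)
            p = self.geometry.patch_size
            if self.ff_mask.shape != (p, p):
                raise ValueError("ff_mask must match the patch size")

    @property
    def n1(self) -> int:
        return self.U1.shape[1]

    @property
    def n2(self) -> int:
        return 0 if self.U2 is None else self.U2.shape[1]

    def module_masks(self) -> np.ndarray:
        """Per-module flattened feed-forward masks, shape (n_modules, sub_dim)."""
        g = self.geometry
        if self.ff_mask is None:
            return np.ones((g.n_modules, g.sub_dim))
        return tile_patch(self.ff_mask, g).reshape(g.n_modules, g.sub_dim)

    def weight_prior(self) -> float:
        """h(U1) + h(U2) = lambda * sum of squared entries."""
        h = float(np.sum(self.U1**2))
        if self.U2 is not None:
            h += float(np.sum(self.U2**2))
        return self.params.lam * h


@dataclass
class InferenceResult:
    """Steady-state inference output for one input patch."""

    r1: np.ndarray            # (n_modules, n1)
    r2: np.ndarray | None     # (n2,) or None
    E_trace: np.ndarray       # coding length per accepted iteration
    iterations: int
    converged: bool
    final_grad_norm: float


def _patch_tiles(patch: np.ndarray, geometry: TilingGeometry) -> np.ndarray:
    """Flatten a patch into (n_modules, sub_dim, 1) module inputs."""
    tiles = tile_patch(patch, geometry)
    return tiles.reshape(geometry.n_modules, geometry.sub_dim, 1)


def _energy_state(X, r1, r2, U1, U2, masks, p) -> float:
    """State-dependent part of E, summed over the batch axis."""
    pred = np.einsum("dn,mnb->mdb", U1, r1)
    err = masks[:, :, None] * (X - pred)
    E = float(np.sum(err * err)) / p.sigma2
    E += p.alpha1 * float(np.log1p(r1 * r1).sum())
    if U2 is not None:
        rcat = r1.reshape(-1, r1.shape[2])
        td = rcat - U2 @ r2
        E += float(np.sum(td * td)) / p.sigma2_td
        E += p.alpha2 * float(np.log1p(r2 * r2).sum())
    return E


def _state_deriv_batch(X, r1, r2, U1, U2, masks, p):
    """dr/dt = -(k1/2) dE/dr for all states, batched over the last axis."""
    pred = np.einsum("dn,mnb->mdb", U1, r1)
    err = masks[:, :, None] * (X - pred)
    dr1 = (p.k1 / p.sigma2) * np.einsum("dn,mdb->mnb", U1, err)
    dr1 -= 0.5 * p.k1 * sparse_prior_deriv(r1, p.alpha1)
    dr2 = None
    if U2 is not None:
        B = r1.shape[2]
        rcat = r1.reshape(-1, B)
        td_pred = U2 @ r2
        td_err = rcat - td_pred
        dr1 += (p.k1 / p.sigma2_td) * (td_pred - rcat).reshape(r1.shape)
        dr2 = (p.k1 / p.sigma2_td) * (U2.T @ td_err)
        dr2 -= 0.5 * p.k1 * sparse_prior_deriv(r2, p.alpha2)
    return dr1, dr2


def _relax_batch(
    X,
    U1,
    U2,
    masks,
    params,
    r1=None,
    r2=None,
    step: float = 0.05,
    tol: float = 1e-4,
    max_iter: int = 2000,
    step_max: float = 2.0,
):
    """Gradient-flow relaxation with backtracking (guarantees E descent).

    X has shape (n_modules, sub_dim, B). Returns
    (r1, r2, E_trace, iterations, converged, final_grad_norm).
    """
    nm, d, B = X.shape
    n1 = U1.shape[1]
    if r1 is None:
        r1 = np.zeros((nm, n1, B))
    else:
        r1 = np.array(r1, dtype=float)
    if U2 is not None:
        r2 = np.zeros((U2.shape[1], B)) if r2 is None else np.array(r2, dtype=float)
    else:
        r2 = None

    E = _energy_state(X, r1, r2, U1, U2, masks, params)
    trace = [E]
    it = 0
    converged = False
    gmax = np.inf
    while it < max_iter:
        dr1, dr2 = _state_deriv_batch(X, r1, r2, U1, U2, masks, params)
        gmax = float(np.max(np.abs(dr1)))
        if dr2 is not None:
            gmax = max(gmax, float(np.max(np.abs(dr2))))
        if gmax <= tol:
            converged = True
            break
        # backtracking: never accept an energy increase
        while True:
            r1_new = r1 + step * dr1
            r2_new = None if r2 is None else r2 + step * dr2
            E_new = _energy_state(X, r1_new, r2_new, U1, U2, masks, params)
            if E_new <= E + 1e-12:
                break
            step *= 0.5
            if step < 1e-14:  # stalled at numerical precision
                return r1, r2, np.array(trace), it, gmax <= tol, gmax
        r1, r2, E = r1_new, r2_new, E_new
        trace.append(E)
        step = min(step * 1.1, step_max)
        it += 1
    return r1, r2, np.array(trace), it, converged, gmax


def solve_states(
    X: np.ndarray,
    U1: np.ndarray,
    U2: np.ndarray | None,
    masks: np.ndarray,
    params: NetworkParams,
    tol: float = 1e-3,
    max_iter: int = 2000,
):
    """Minimize the state energy directly (quasi-Newton).

    Same fixed points as the gradient flow, but far faster on the stiff
    quadratic bulk of E; used by the training loops. Per-batch-item
    problems are independent, so one joint solve over the concatenated
    state vector is exact. Returns (r1, r2, iterations, grad_max).
    """
    from scipy.optimize import minimize

    nm, d, B = X.shape
    n1 = U1.shape[1]
    n2 = 0 if U2 is None else U2.shape[1]
    sz1 = nm * n1 * B

    def unpack(v):
        r1 = v[:sz1].reshape(nm, n1, B)
        r2 = v[sz1:].reshape(n2, B) if U2 is not None else None
        return r1, r2

    def fun(v):
        r1, r2 = unpack(v)
        E = _energy_state(X, r1, r2, U1, U2, masks, params)
        dr1, dr2 = _state_deriv_batch(X, r1, r2, U1, U2, masks, params)
        parts = [dr1.ravel()] if dr2 is None else [dr1.ravel(), dr2.ravel()]
        return E, -(2.0 / params.k1) * np.concatenate(parts)

    res = minimize(
        fun,
        np.zeros(sz1 + n2 * B),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 2.0 * tol / params.k1, "ftol": 1e-14},
    )
    r1, r2 = unpack(res.x)
    dr1, dr2 = _state_deriv_batch(X, r1, r2, U1, U2, masks, params)
    gmax = float(np.max(np.abs(dr1)))
    if dr2 is not None:
        gmax = max(gmax, float(np.max(np.abs(dr2))))
    return r1, r2, int(res.nit), gmax


def coding_length(
    patch: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray | None,
    network: HPCNetwork,
    include_weight_prior: bool = True,
) -> float:
    """Total coding length E for one input patch and candidate states."""
    g = network.geometry
    X = _patch_tiles(patch, g)
    r1 = np.asarray(r1, dtype=float).reshape(g.n_modules, network.n1, 1)
    r2c = None
    if network.U2 is not None:
        if r2 is None:
            raise ValueError("network has a level 2 but r2 is None")
        r2c = np.asarray(r2, dtype=float).reshape(network.n2, 1)
    E = _energy_state(X, r1, r2c, network.U1, network.U2,
                      network.module_masks(), network.params)
    if include_weight_prior:
        E += network.weight_prior()
    return E


def state_derivative(
    patch: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray | None,
    network: HPCNetwork,
):
    """Joint state derivative; equals -(k1/2) dE/dr componentwise."""
    g = network.geometry
    X = _patch_tiles(patch, g)
    r1 = np.asarray(r1, dtype=float).reshape(g.n_modules, network.n1, 1)
    r2c = None
    if network.U2 is not None:
        r2c = np.asarray(r2, dtype=float).reshape(network.n2, 1)
    dr1, dr2 = _state_deriv_batch(X, r1, r2c, network.U1, network.U2,
                                  network.module_masks(), network.params)
    dr1 = dr1[:, :, 0]
    dr2 = None if dr2 is None else dr2[:, 0]
    return dr1, dr2


def _relax_lbfgs(X, U1, U2, masks, params, r1, r2, tol, max_iter):
    """Monotone quasi-Newton descent to the steady state.

    Each accepted iterate satisfies an Armijo decrease, so the recorded
    energy trace is non-increasing; the fixed point is the same as the
    gradient flow's.
    """
    from scipy.optimize import minimize

    nm, d, B = X.shape
    n1 = U1.shape[1]
    n2 = 0 if U2 is None else U2.shape[1]
    sz1 = nm * n1 * B

    def unpack(v):
        r1v = v[:sz1].reshape(nm, n1, B)
        r2v = v[sz1:].reshape(n2, B) if U2 is not None else None
        return r1v, r2v

    def fun(v):
        r1v, r2v = unpack(v)
        E = _energy_state(X, r1v, r2v, U1, U2, masks, params)
        dr1, dr2 = _state_deriv_batch(X, r1v, r2v, U1, U2, masks, params)
        parts = [dr1.ravel()] if dr2 is None else [dr1.ravel(), dr2.ravel()]
        return E, -(2.0 / params.k1) * np.concatenate(parts)

    parts0 = [np.zeros((nm, n1, B)) if r1 is None else r1]
    if U2 is not None:
        parts0.append(np.zeros((n2, B)) if r2 is None else r2)
    v0 = np.concatenate([a.ravel() for a in parts0])
    trace = [fun(v0)[0]]
    res = minimize(
        fun, v0, jac=True, method="L-BFGS-B",
        callback=lambda xk: trace.append(fun(xk)[0]),
        options={"maxiter": max_iter, "gtol": 2.0 * tol / params.k1,
                 "ftol": 0.0},
    )
    r1f, r2f = unpack(res.x)
    dr1, dr2 = _state_deriv_batch(X, r1f, r2f, U1, U2, masks, params)
    gmax = float(np.max(np.abs(dr1)))
    if dr2 is not None:
        gmax = max(gmax, float(np.max(np.abs(dr2))))
    return r1f, r2f, np.array(trace), int(res.nit), gmax <= tol, gmax


def relax_to_steady_state(
    patch: np.ndarray,
    network: HPCNetwork,
    init_r1: np.ndarray | None = None,
    init_r2: np.ndarray | None = None,
    step: float = 0.05,
    tol: float = 1e-4,
    max_iter: int = 2000,
    method: str = "lbfgs",
) -> InferenceResult:
    """Relax all states jointly to a steady state.

    ``method="lbfgs"`` (default) descends the energy with a monotone
    quasi-Newton scheme — fast and robust to the stiff level-1/level-2
    coupling. ``method="euler"`` integrates the gradient flow by forward
    Euler with backtracking step control (``step`` is its initial step
    size). Both record the coding length per accepted iteration
    (non-increasing) and stop when the derivative max-norm falls below
    ``tol``.
    """
    if step <= 0 or tol <= 0:
        raise ValueError("step and tol must be positive")
    if method not in ("lbfgs", "euler"):
        raise ValueError(f"unknown method {method!r}")
    g = network.geometry
    X = _patch_tiles(patch, g)
    r1 = None if init_r1 is None else np.asarray(init_r1, float).reshape(
        g.n_modules, network.n1, 1)
    r2 = None
    if network.U2 is not None and init_r2 is not None:
        r2 = np.asarray(init_r2, float).reshape(network.n2, 1)
    if method == "euler":
        r1f, r2f, trace, iters, conv, gmax = _relax_batch(
            X, network.U1, network.U2, network.module_masks(), network.params,
            r1=r1, r2=r2, step=step, tol=tol, max_iter=max_iter,
        )
    else:
        r1f, r2f, trace, iters, conv, gmax = _relax_lbfgs(
            X, network.U1, network.U2, network.module_masks(), network.params,
            r1=r1, r2=r2, tol=tol, max_iter=max_iter,
        )
    return InferenceResult(
        r1=r1f[:, :, 0],
        r2=None if r2f is None else r2f[:, 0],
        E_trace=trace + network.weight_prior(),
        iterations=iters,
        converged=conv,
        final_grad_norm=gmax,
    )


def perceptual_image_from_states(network: HPCNetwork, r1: np.ndarray) -> np.ndarray:
    """Render the level-1 predictions U1 r1_m as a patch (overlap-averaged)."""
    g = network.geometry
    r1 = np.asarray(r1, dtype=float).reshape(g.n_modules, network.n1)
    preds = (network.U1 @ r1.T).T.reshape(g.n_modules, g.sub_size, g.sub_size)
    return untile(preds, g)


def perceptual_image(network: HPCNetwork, result: InferenceResult) -> np.ndarray:
    """The "perceptual image" of a steady state."""
    return perceptual_image_from_states(network, result.r1)


def level2_rf_in_image_space(network: HPCNetwork, j: int) -> np.ndarray:
    """Project level-2 basis column j through U1 into pixel space."""
    if network.U2 is None:
        raise ValueError("network has no level 2")
    if not (0 <= j < network.n2):
        raise ValueError("neuron index out of range")
    col = network.U2[:, j].reshape(network.geometry.n_modules, network.n1)
    return perceptual_image_from_states(network, col)
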