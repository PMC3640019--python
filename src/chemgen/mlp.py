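"""Feed-forward perceptron regression trained with resilient backpropagation.

The network has one hidden layer of sigmoid units and a single sigmoid output
unit, so predictions always lie in (0, 1) -- the range of the normalized IC50
response.  Training minimizes the batch sum of squared errors with RPROP
(resilient backpropagation): every weight carries its own step size, which
grows by ``eta_plus`` while the partial derivative keeps its sign and shrinks
by ``eta_minus`` when the sign flips (the update is suppressed for that
iteration, and the stored derivative zeroed so the shrink happens once).
Weights move by the negative gradient *sign* times the step, making the
method robust to the badly scaled gradients of saturated sigmoids.

Model complexity -- the number of hidden units ``h`` and the stopping
iteration ``t`` -- is chosen as the global minimum of the cross-train RMSE
landscape recorded over every (h, t) pair of the search grid, with ties broken
toward the smaller network and earlier iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["RpropState", "rprop_update", "RpropMLPRegressor"]

# Riedmiller's standard constants, used by the reference implementations
ETA_PLUS = 1.2
ETA_MINUS = 0.5
DELTA_INIT = 0.1
DELTA_MIN = 1e-6
DELTA_MAX = 50.0


@dataclass
class RpropState:
    """Per-weight adaptive step sizes and the previous gradient."""

    step: np.ndarray
    prev_grad: np.ndarray

    @classmethod
    def init(cls, shape, delta_init: float = DELTA_INIT) -> "RpropState":
        return cls(step=np.full(shape, delta_init), prev_grad=np.zeros(shape))


def rprop_update(
    grad: np.ndarray,
    state: RpropState,
    eta_plus: float = ETA_PLUS,
    eta_minus: float = ETA_MINUS,
    delta_min: float = DELTA_MIN,
    delta_max: float = DELTA_MAX,
) -> np.ndarray:
    """One RPROP step; mutates ``state`` and returns the weight increment.

    Sign agreement between the current and previous partial derivative grows
    the step by ``eta_plus``; a sign flip shrinks it by ``eta_minus`` and
    suppresses the weight change for this iteration (the stored derivative is
    zeroed so the step is not shrunk twice).  Steps stay inside
    [``delta_min``, ``delta_max``]; a zero derivative leaves both the step and
    the weight unchanged.
    """
    sign_prod = grad * state.prev_grad
    same, flip = sign_prod > 0, sign_prod < 0
    state.step = np.clip(
        state.step * np.where(same, eta_plus, np.where(flip, eta_minus, 1.0)),
        delta_min,
        delta_max,
    )
    delta_w = np.where(flip, 0.0, -np.sign(grad) * state.step)
    state.prev_grad = np.where(flip, 0.0, grad)
    return delta_w


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Network:
    """Weights of one input -> hidden -> output sigmoid network."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator, init_scale: float):
        self.W1 = rng.uniform(-init_scale, init_scale, size=(n_in, n_hidden))
        self.b1 = rng.uniform(-init_scale, init_scale, size=n_hidden)
        self.w2 = rng.uniform(-init_scale, init_scale, size=(n_hidden, 1))
        self.b2 = rng.uniform(-init_scale, init_scale, size=1)

    def forward(self, X: np.ndarray):
        H = _sigmoid(X @ self.W1 + self.b1)
        yhat = _sigmoid(H @ self.w2 + self.b2).ravel()
        return H, yhat

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1]

    def gradients(self, X: np.ndarray, y: np.ndarray):
        """Batch gradients of 1/2 * sum of squared errors."""
        H, yhat = self.forward(X)
        delta_out = (yhat - y) * yhat * (1.0 - yhat)  # (n,)
        g_w2 = H.T @ delta_out[:, None]
        g_b2 = np.array([delta_out.sum()])
        delta_hid = (delta_out[:, None] * self.w2.T) * H * (1.0 - H)  # (n, h)
        g_W1 = X.T @ delta_hid
        g_b1 = delta_hid.sum(axis=0)
        return (g_W1, g_b1, g_w2, g_b2), yhat

    def params(self):
        return (self.W1, self.b1, self.w2, self.b2)

    def copy_params(self):
        return tuple(p.copy() for p in self.params())

    def set_params(self, params):
        self.W1, self.b1, self.w2, self.b2 = (p.copy() for p in params)


class RpropMLPRegressor(RegressorMixin, BaseEstimator):
    """Multi-layer perceptron for normalized responses, trained with RPROP.

    Parameters
    ----------
    hidden_units : sequence of int, default ``range(1, 31)``
        Candidate hidden-layer sizes; the landscape search trains each one.
    max_iter : int, default 400
        Maximum RPROP iterations per candidate architecture.
    init_scale : float, default 0.5
        Weights are initialized uniformly in ``[-init_scale, init_scale]``.
    validation_fraction : float, default 0.125
        Fraction of the training data split off as the cross-train set when
        none is supplied to :meth:`fit` (one bin of eight).
    random_state : int or None
        Seeds weight initialization and the internal cross-train split.

    Attributes
    ----------
    hidden_units_ : int
        Selected hidden-layer size (the landscape argmin).
    n_iter_ : int
        Selected stopping iteration (1-based).
    crosstrain_rmse_surface_ : ndarray of shape (len(hidden_units), max_iter)
        Cross-train RMSE recorded after every iteration of every candidate.
    coefs_, intercepts_ : list of ndarray
        Weight matrices and bias vectors of the selected network.
    """

    def __init__(
        self,
        hidden_units=tuple(range(1, 31)),
        max_iter: int = 400,
        eta_plus: float = ETA_PLUS,
        eta_minus: float = ETA_MINUS,
        delta_init: float = DELTA_INIT,
        delta_min: float = DELTA_MIN,
        delta_max: float = DELTA_MAX,
        init_scale: float = 0.5,
        validation_fraction: float = 0.125,
        random_state=None,
    ):
        self.hidden_units = hidden_units
        self.max_iter = max_iter
        self.eta_plus = eta_plus
        self.eta_minus = eta_minus
        self.delta_init = delta_init
        self.delta_min = delta_min
        self.delta_max = delta_max
        self.init_scale = init_scale
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        """Train over the (hidden units, iterations) grid and keep the argmin.

        ``X_val`` / ``y_val`` form the cross-train set used exclusively to
        select the architecture and stopping iteration; if omitted, a seeded
        ``validation_fraction`` split of (X, y) is used.
        """
        X, y = check_X_y(X, y, dtype=float)
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("targets must be normalized responses strictly inside (0, 1)")
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(y))))
            if len(y) - n_val < 1:
                raise ValueError("too few instances to split off a cross-train set")
            order = rng.permutation(len(y))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val = check_array(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)
        if len(y_val) < 2:
            raise ValueError("cross-train set must contain at least 2 instances")

        grid = [int(h) for h in np.atleast_1d(self.hidden_units)]
        if any(h < 1 for h in grid):
            raise ValueError("hidden unit counts must be >= 1")
        surface = np.full((len(grid), self.max_iter), np.nan)
        best = None  # (rmse, h_pos, t, params)
        for hi, h in enumerate(grid):
            net = _Network(X.shape[1], h, np.random.default_rng(rng.integers(2**31)), self.init_scale)
            states = [RpropState.init(p.shape, self.delta_init) for p in net.params()]
            best_h = None
            for t in range(self.max_iter):
                grads, _ = net.gradients(X, y)
                for p, g, st in zip(net.params(), grads, states):
                    p += rprop_update(
                        g, st, self.eta_plus, self.eta_minus, self.delta_min, self.delta_max
                    )
                resid = net.predict(X_val) - y_val
                rmse = float(np.sqrt(np.mean(resid**2)))
                surface[hi, t] = rmse
                if best_h is None or rmse < best_h[0]:
                    best_h = (rmse, t + 1, net.copy_params())
            if best is None or best_h[0] < best[0]:
                best = (best_h[0], hi, best_h[1], best_h[2])

        rmse, hi, t, params = best
        self.hidden_units_ = grid[hi]
        self.n_iter_ = t
        self.crosstrain_rmse_ = rmse
        self.crosstrain_rmse_surface_ = surface
        self.hidden_grid_ = grid
        self.coefs_ = [params[0], params[2]]
        self.intercepts_ = [params[1], params[3]]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Normalized responses in (0, 1)."""
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        H = _sigmoid(X @ self.coefs_[0] + self.intercepts_[0])
        return _sigmoid(H @ self.coefs_[1] + self.intercepts_[1]).ravel()
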