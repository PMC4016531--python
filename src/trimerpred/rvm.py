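"""Relevance vector machine: sparse Bayesian kernel classification.

The model is y(x) = sum_i a_i phi_i(x) + b with a logistic link
sigma(y) = 1 / (1 + exp(-y)).  Each weight a_i carries its own precision
hyperparameter gamma_i under a zero-mean Gaussian prior; maximising the
marginal likelihood drives most gamma_i to infinity, pruning the
corresponding basis functions and leaving a small set of relevance vectors.
Unlike the max-margin classifier, the basis matrix need not be positive
semidefinite.

Fitting uses sequential sparse Bayesian learning: starting from the bias
basis alone, each outer iteration re-finds the posterior mode of the active
weights (Newton/IRLS under the Laplace approximation), computes the
sparsity/quality statistics s_m and q_m of every basis against the current
working response, and applies the single add / re-estimate / delete action
with the largest analytic marginal-likelihood gain.  Actions with
non-positive gain are never taken, so the likelihood is non-decreasing.
Everything is deterministic — no random initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RVMModel", "fit_rvm", "predict_rvm", "sigmoid", "design_matrix"]

GAMMA_MAX = 1e12
_BIAS_INIT_GAMMA = 1e-6
_JITTER = 1e-12


def sigmoid(y: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic sigmoid."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(y, dtype=float)))


def design_matrix(kernel: np.ndarray) -> np.ndarray:
    """Append the constant bias column to a kernel matrix."""
    kernel = np.asarray(kernel, dtype=float)
    return np.hstack([kernel, np.ones((kernel.shape[0], 1))])


@dataclass
class RVMModel:
    """Fitted sparse Bayesian classifier.

    ``weights`` has one entry per design column (bias last); pruned entries
    are exactly 0.  ``gamma`` holds the final precisions of the retained
    bases, aligned with ``active``.  ``ll_history`` records the Laplace
    marginal log-likelihood after each outer iteration.
    """

    weights: np.ndarray
    active: np.ndarray  # indices into design columns, bias included if retained
    gamma: np.ndarray
    converged: bool
    n_iter: int
    ll_history: list[float] = field(default_factory=list)

    @property
    def n_relevance(self) -> int:
        """Retained kernel basis functions (bias column not counted)."""
        bias_idx = len(self.weights) - 1
        return int(np.sum(self.active != bias_idx))

    def decision(self, basis_rows: np.ndarray) -> np.ndarray:
        basis_rows = np.atleast_2d(np.asarray(basis_rows, dtype=float))
        if basis_rows.shape[1] != len(self.weights):
            raise ValueError(
                f"basis row length {basis_rows.shape[1]} != "
                f"{len(self.weights)} design columns"
            )
        return basis_rows @ self.weights


def _irls_mode(
    phi: np.ndarray,
    t01: np.ndarray,
    gamma: np.ndarray,
    w0: np.ndarray,
    max_inner: int = 100,
    grad_tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton search for the posterior mode of the weights at fixed gamma.

    Returns (w_map, H) with H the negative Hessian at the mode; backtracks on
    the penalised log-likelihood so every step ascends.
    """
    w = w0.copy()
    A = np.diag(gamma)

    def objective(w: np.ndarray) -> float:
        y = phi @ w
        ll = -np.sum(np.logaddexp(0.0, -np.where(t01 == 1.0, y, -y)))
        return ll - 0.5 * w @ (gamma * w)

    obj = objective(w)
    H = None
    for _ in range(max_inner):
        s = sigmoid(phi @ w)
        g = phi.T @ (t01 - s) - gamma * w
        b = np.clip(s * (1.0 - s), _JITTER, None)
        H = (phi.T * b) @ phi + A
        if np.max(np.abs(g)) < grad_tol:
            break
        step = np.linalg.solve(H, g)
        lam, improved = 1.0, False
        for _ in range(30):
            w_new = w + lam * step
            obj_new = objective(w_new)
            if obj_new >= obj - 1e-12:
                w, obj, improved = w_new, obj_new, True
                break
            lam *= 0.5
        if not improved:
            break
    if H is None:
        s = sigmoid(phi @ w)
        b = np.clip(s * (1.0 - s), _JITTER, None)
        H = (phi.T * b) @ phi + A
    return w, H


def _marginal_ll(
    phi: np.ndarray, t01: np.ndarray, gamma: np.ndarray, w: np.ndarray, H: np.ndarray
) -> float:
    """Laplace approximation of the marginal log-likelihood at the mode."""
    y = phi @ w
    data_ll = -np.sum(np.logaddexp(0.0, -np.where(t01 == 1.0, y, -y)))
    sign, logdet_h = np.linalg.slogdet(H)
    if sign <= 0:  # mode Hessian should be PD; guard tiny numerics
        logdet_h = np.sum(np.log(np.clip(np.diag(H), 1e-300, None)))
    return float(
        data_ll - 0.5 * w @ (gamma * w) + 0.5 * np.sum(np.log(gamma)) - 0.5 * logdet_h
    )


def fit_rvm(
    design: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> RVMModel:
    """Fit the sparse Bayesian classifier on a design matrix.

    ``design`` holds the basis responses row-per-example (kernel columns plus
    a trailing bias column, see :func:`design_matrix`); ``labels`` are +-1
    with both classes present.  Non-convergence within ``max_iter`` returns a
    model flagged ``converged=False`` rather than raising.
    """
    design = np.asarray(design, dtype=float)
    labels = np.asarray(labels)
    if design.shape[0] != len(labels):
        raise ValueError(
            f"design rows {design.shape[0]} != number of labels {len(labels)}"
        )
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    t01 = (labels > 0).astype(float)

    n_cols = design.shape[1]
    bias_idx = n_cols - 1
    active: list[int] = [bias_idx]
    gamma = np.array([_BIAS_INIT_GAMMA])
    w, H = _irls_mode(design[:, active], t01, gamma, np.zeros(1))
    ll = _marginal_ll(design[:, active], t01, gamma, w, H)
    ll_history: list[float] = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # sparsity (S) and quality (Q) of every basis against the working
        # response of the current linearisation
        phi_a = design[:, active]
        sigma = np.linalg.inv(H)
        yhat = sigmoid(phi_a @ w)
        b = np.clip(yhat * (1.0 - yhat), _JITTER, None)
        bt_hat = b * (phi_a @ w) + (t01 - yhat)  # = B t_working
        C = design.T @ (b[:, None] * phi_a)  # (M, A)
        S_all = np.einsum("nm,nm->m", design, b[:, None] * design) - np.einsum(
            "ma,ab,mb->m", C, sigma, C
        )
        proj = sigma @ (phi_a.T @ bt_hat)
        Q_all = design.T @ bt_hat - C @ proj
        S_all = np.clip(S_all, _JITTER, None)

        gamma_full = np.full(n_cols, np.inf)
        gamma_full[active] = gamma
        is_active = np.isfinite(gamma_full)
        denom = np.where(is_active, gamma_full - S_all, 1.0)
        denom = np.where(np.abs(denom) < _JITTER, _JITTER, denom)
        s_all = np.where(is_active, gamma_full * S_all / denom, S_all)
        q_all = np.where(is_active, gamma_full * Q_all / denom, Q_all)
        theta = q_all**2 - s_all

        # analytic marginal-likelihood gain of each candidate action under
        # the current linearisation
        candidates: list[tuple[float, int, str]] = []
        for m in range(n_cols):
            if not is_active[m] and theta[m] > 0:  # add
                dl = 0.5 * (
                    (Q_all[m] ** 2 - S_all[m]) / S_all[m]
                    + np.log(S_all[m] / Q_all[m] ** 2)
                )
                action = "add"
            elif is_active[m] and theta[m] > 0:  # re-estimate gamma
                g_new = s_all[m] ** 2 / theta[m]
                d = 1.0 / g_new - 1.0 / gamma_full[m]
                if abs(d) < _JITTER:
                    continue
                dl = 0.5 * (
                    Q_all[m] ** 2 / (S_all[m] + 1.0 / d)
                    - np.log1p(S_all[m] * d)
                )
                action = "reest"
            elif is_active[m] and theta[m] <= 0 and len(active) > 1:  # delete
                dl = 0.5 * (
                    Q_all[m] ** 2 / (S_all[m] - gamma_full[m])
                    - np.log1p(-S_all[m] / gamma_full[m])
                )
                action = "delete"
            else:
                continue
            if np.isfinite(dl) and dl > tol:
                candidates.append((float(dl), m, action))
        candidates.sort(reverse=True)

        # the analytic gain holds only for the frozen linearisation, so each
        # action is trial-applied and kept only if the re-linearised Laplace
        # likelihood actually improves; this keeps the history monotone and
        # stops re-estimate/re-estimate cycling
        accepted = False
        for dl, m, action in candidates[:8]:
            a_new, g_new_v, w_new = list(active), gamma.copy(), w.copy()
            if action == "add":
                a_new.append(m)
                g_new_v = np.append(g_new_v, min(s_all[m] ** 2 / theta[m], GAMMA_MAX))
                w_new = np.append(w_new, 0.0)
            elif action == "reest":
                g_new_v[a_new.index(m)] = min(s_all[m] ** 2 / theta[m], GAMMA_MAX)
            else:
                k = a_new.index(m)
                a_new.pop(k)
                g_new_v = np.delete(g_new_v, k)
                w_new = np.delete(w_new, k)
            w_try, H_try = _irls_mode(design[:, a_new], t01, g_new_v, w_new)
            ll_try = _marginal_ll(design[:, a_new], t01, g_new_v, w_try, H_try)
            if ll_try > ll + tol:
                active, gamma, w, H, ll = a_new, g_new_v, w_try, H_try, ll_try
                ll_history.append(ll)
                accepted = True
                break
        if not accepted:
            converged = True
            break

    weights = np.zeros(n_cols)
    weights[np.array(active)] = w
    return RVMModel(
        weights=weights,
        active=np.array(sorted(active)),
        gamma=gamma[np.argsort(active)],
        converged=converged,
        n_iter=it,
        ll_history=ll_history,
    )


def predict_rvm(model: RVMModel, basis_row: np.ndarray) -> tuple[float, int]:
    """Probability sigma(y) that the example is a positive, and its +-1 label.

    The label is +1 iff the probability exceeds 0.5 (y > 0); exactly 0.5 maps
    to -1, the conservative tie-break.
    """
    y = float(model.decision(basis_row)[0])
    p = float(sigmoid(y))
    return p, (1 if p > 0.5 else -1)
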