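"""Penalized logistic GLM estimation of auditory classification images.

The listener's template beta and bias c are the maximum a posteriori
solution of

    min_{beta, c}  -sum_i [ r_i log p_i + (1 - r_i) log(1 - p_i) ]
                   + (lambda/2) * beta' K beta,
    p_i = logit^-1( <S_i, beta> + c ),

where S_i is the trial-i stimulus cochleogram (pixel vector), r_i the
binary response, and K a two-dimensional smoothness penalty on the
time-frequency grid (the bias is never penalized).  K = L'L with L the
discrete 2-D Laplacian under reflecting (Neumann) boundaries, so the
prior acts as data-driven low-pass filtering of the template.

Because the adaptive staircase pins performance near 79% correct, raw
trial sets are heavily imbalanced between correct and incorrect
categorizations, which distorts the estimated template; estimation is
therefore preceded by :func:`balance_trials`, which discards randomly
chosen correct trials until the counts match (~4,200 trials survive
out of a full 10,000-trial run).

The solver is penalized iteratively reweighted least squares (Newton)
with step-halving; the Newton systems are solved directly on small
pixel grids and by conjugate gradients on large ones.  The penalty
weight is selected by minimizing the mean 10-fold cross-validated
deviance across listeners, one shared value for all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg
from scipy.special import expit, logit

PROB_CLIP = 1e-12  # probabilities clipped to [PROB_CLIP, 1 - PROB_CLIP]


@dataclass
class TrialTable:
    """Per-trial design matrix and responses for one listener."""

    X: np.ndarray                 # n_trials x n_pixels cochleogram vectors
    response: np.ndarray          # binary, 0 = 'da', 1 = 'ga'
    correct: np.ndarray           # bool
    grid_shape: tuple[int, int]
    target_id: np.ndarray | None = None
    target_class: np.ndarray | None = None
    snr_db: np.ndarray | None = None
    session: np.ndarray | None = None
    balanced: bool = False
    listener_id: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.response = np.asarray(self.response, dtype=int)
        self.correct = np.asarray(self.correct, dtype=bool)
        if self.X.ndim != 2 or len(self.response) != len(self.X):
            raise ValueError("design matrix and responses are inconsistent")
        if not np.isin(self.response, [0, 1]).all():
            raise ValueError("responses must be binary")
        if self.X.shape[1] != self.grid_shape[0] * self.grid_shape[1]:
            raise ValueError("grid shape does not match pixel count")

    @property
    def n_trials(self) -> int:
        return len(self.response)

    def subset(self, idx) -> "TrialTable":
        def take(a):
            return None if a is None else np.asarray(a)[idx]
        return TrialTable(X=self.X[idx], response=self.response[idx],
                          correct=self.correct[idx],
                          grid_shape=self.grid_shape,
                          target_id=take(self.target_id),
                          target_class=take(self.target_class),
                          snr_db=take(self.snr_db), session=take(self.session),
                          balanced=self.balanced,
                          listener_id=self.listener_id)


def table_from_log(log, listener_id: str = "") -> TrialTable:
    """Build a TrialTable from a simulated ExperimentLog."""
    t = log.trials
    return TrialTable(X=log.design, response=t["response"].to_numpy(),
                      correct=t["correct"].to_numpy(dtype=bool),
                      grid_shape=log.grid_shape,
                      target_id=t["target_id"].to_numpy(),
                      target_class=t["target_class"].to_numpy(),
                      snr_db=t["snr_db"].to_numpy(),
                      session=t["session"].to_numpy(),
                      listener_id=listener_id)


def balance_trials(table: TrialTable, rng) -> TrialTable:
    """Equalize correct and error counts by random discard of correct trials.

    Trial order is otherwise preserved.  Raises if the table contains no
    error trials (balancing undefined) and is a no-op when already
    balanced.
    """
    n_err = int((~table.correct).sum())
    n_cor = int(table.correct.sum())
    if n_err == 0:
        raise ValueError("cannot balance a table with zero error trials")
    if n_cor <= n_err:
        return replace_balanced(table)
    correct_idx = np.flatnonzero(table.correct)
    keep_correct = rng.choice(correct_idx, size=n_err, replace=False)
    keep = np.zeros(table.n_trials, dtype=bool)
    keep[~table.correct] = True
    keep[keep_correct] = True
    out = table.subset(np.flatnonzero(keep))
    return replace_balanced(out)


def replace_balanced(table: TrialTable) -> TrialTable:
    table.balanced = True
    return table


def laplacian_penalty(grid_shape: tuple[int, int],
                      ridge: float = 1e-6) -> sparse.csr_matrix:
    """K = L'L with L the 2-D grid Laplacian, Neumann boundaries.

    A tiny ridge makes K positive definite: the Laplacian alone is blind
    to the constant mode, and a proper prior should shrink everything in
    the penalty-dominated limit.  The ridge is far too small to affect
    smoothing at working penalty weights.
    """

    def lap1d(n):
        main = np.full(n, 2.0)
        main[0] = main[-1] = 1.0  # reflecting boundary
        return sparse.diags([main, -np.ones(n - 1), -np.ones(n - 1)],
                            [0, 1, -1])

    nt, nf = grid_shape
    L = sparse.kron(lap1d(nt), sparse.eye(nf)) + sparse.kron(
        sparse.eye(nt), lap1d(nf))
    K = (L.T @ L) + ridge * sparse.eye(nt * nf)
    return K.tocsr()


@dataclass
class ACIModel:
    """A fitted classification image: template, bias, and fit diagnostics."""

    template: np.ndarray          # weight map on the grid
    bias: float
    penalty_weight: float
    penalty_matrix_spec: str
    converged: bool
    final_objective: float
    n_trials_used: int
    n_iterations: int = 0
    listener_id: str = ""

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.template.ravel() + self.bias)


def _penalized_nll(X, r, K, lam, beta, c):
    eta = X @ beta + c
    # log(1 + e^eta) - r*eta, numerically stable
    nll = float(np.sum(np.logaddexp(0.0, eta) - r * eta))
    if lam > 0:
        nll += 0.5 * lam * float(beta @ (K @ beta))
    return nll


_K_FACTOR_CACHE: dict = {}


def _k_solver(grid_shape):
    """Cached sparse LU factorization of the penalty matrix K."""
    if grid_shape not in _K_FACTOR_CACHE:
        from scipy.sparse.linalg import splu
        _K_FACTOR_CACHE[grid_shape] = splu(
            laplacian_penalty(grid_shape).tocsc())
    return _K_FACTOR_CACHE[grid_shape]


def _newton_direction_woodbury(X, w, g_beta, g_c, lam, grid_shape):
    """Exact Newton step when trials are far fewer than pixels.

    The Hessian block for beta is lam*K + X'WX; its inverse is applied
    through the Woodbury identity using a cached factorization of K (an
    n x n inner solve instead of a p x p one), and the unpenalized bias
    is folded in by bordered elimination.
    """
    solver = _k_solver(grid_shape)
    n = len(w)
    # Z = (lam K)^-1 X' ;  inner matrix C = W^-1 + X Z  (SPD, n x n)
    Z = solver.solve(X.T) / lam
    C = Z.T @ X.T
    C[np.diag_indices(n)] += 1.0 / w
    C_chol = np.linalg.cholesky(C)

    def a_inv(v):
        kv = solver.solve(v) / lam
        t = np.linalg.solve(C_chol.T, np.linalg.solve(C_chol, X @ kv))
        return kv - Z @ t

    b = X.T @ w                      # Hessian border: d^2/(d beta d c)
    s = float(w.sum())
    ai_g = a_inv(g_beta)
    ai_b = a_inv(b)
    denom = s - float(b @ ai_b)
    d_c = (g_c - float(b @ ai_g)) / denom
    d_beta = ai_g - ai_b * d_c
    return -d_beta, -float(d_c)


def fit_aci(table: TrialTable, penalty_weight: float,
            tol: float = 1e-6, max_iter: int = 200,
            dense_cutoff: int = 700) -> ACIModel:
    """MAP fit of the smoothness-penalized logistic GLM.

    Newton / IRLS with step-halving (the penalized objective decreases
    monotonically); convergence when the per-trial gradient sup-norm
    falls below ``tol``.  Newton systems are solved densely when the
    pixel count is at most ``dense_cutoff``, otherwise by conjugate
    gradients with the penalized Hessian as a linear operator.
    """
    if penalty_weight < 0:
        raise ValueError("penalty_weight must be nonnegative")
    if not table.balanced:
        warnings.warn("fitting an unbalanced trial table", stacklevel=2)
    r = table.response.astype(np.float64)
    if r.min() == r.max():
        raise ValueError("degenerate table: all responses identical")
    X = table.X
    n, p = X.shape
    K = laplacian_penalty(table.grid_shape)
    lam = float(penalty_weight)

    beta = np.zeros(p)
    c = float(logit(np.clip(r.mean(), 1e-3, 1 - 1e-3)))
    obj = _penalized_nll(X, r, K, lam, beta, c)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta + c
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        g_beta = X.T @ (mu - r) + lam * (K @ beta)
        g_c = float(np.sum(mu - r))
        gnorm = max(np.abs(g_beta).max(), abs(g_c)) / n
        if gnorm < tol:
            converged = True
            break
        # Newton direction on (beta, c) jointly
        if lam > 0 and p > dense_cutoff and n < p // 2:
            d_beta, d_c = _newton_direction_woodbury(
                X, w, g_beta, g_c, lam, table.grid_shape)
        elif p <= dense_cutoff:
            H = X.T @ (X * w[:, None])
            if lam > 0:
                H = H + lam * K.toarray()
            Hfull = np.empty((p + 1, p + 1))
            Hfull[:p, :p] = H
            Hfull[:p, p] = Hfull[p, :p] = X.T @ w
            Hfull[p, p] = w.sum()
            gfull = np.concatenate([g_beta, [g_c]])
            try:
                step = np.linalg.solve(Hfull, gfull)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(Hfull, gfull, rcond=None)[0]
            d_beta, d_c = -step[:p], -float(step[p])
        else:
            xw = X.T @ w

            def hv(v):
                vb, vc = v[:p], v[p]
                hb = X.T @ (w * (X @ vb)) + lam * (K @ vb) + xw * vc
                hc = float(xw @ vb) + w.sum() * vc
                return np.concatenate([hb, [hc]])

            A = LinearOperator((p + 1, p + 1), matvec=hv)
            gfull = np.concatenate([g_beta, [g_c]])
            sol, _ = cg(A, gfull, rtol=1e-8, maxiter=2 * p)
            d_beta, d_c = -sol[:p], -float(sol[p])
        # step-halving safeguard
        t = 1.0
        for _ in range(40):
            new_obj = _penalized_nll(X, r, K, lam, beta + t * d_beta,
                                     c + t * d_c)
            if new_obj <= obj:
                break
            t *= 0.5
        else:
            break
        beta = beta + t * d_beta
        c = c + t * d_c
        obj = new_obj
    return ACIModel(template=beta.reshape(table.grid_shape), bias=c,
                    penalty_weight=lam,
                    penalty_matrix_spec="laplacian2d-neumann",
                    converged=converged, final_objective=obj,
                    n_trials_used=n, n_iterations=it,
                    listener_id=table.listener_id)


def deviance_of_probs(probabilities: np.ndarray,
                      responses: np.ndarray) -> float:
    """-2 log-likelihood of Bernoulli responses under given probabilities."""
    p = np.asarray(probabilities, dtype=np.float64)
    r = np.asarray(responses, dtype=np.float64)
    if p.shape != r.shape:
        raise ValueError("probabilities and responses differ in length")
    p = np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
    return float(-2.0 * np.sum(r * np.log(p) + (1 - r) * np.log(1 - p)))


def stratified_folds(responses: np.ndarray, n_folds: int, rng,
                     max_redraws: int = 20) -> list[np.ndarray]:
    """Response-stratified fold assignment; re-drawn if a fold is one-class."""
    from sklearn.model_selection import StratifiedKFold

    r = np.asarray(responses)
    for attempt in range(max_redraws):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        folds = [test for _, test in skf.split(np.zeros(len(r)), r)]
        if all(0 < r[f].mean() < 1 for f in folds):
            return folds
        warnings.warn(f"single-class fold on attempt {attempt}; re-drawing")
    raise RuntimeError("could not build two-class folds")


def cv_deviance(table: TrialTable, penalty_weight: float, n_folds: int = 10,
                rng=None, tol: float = 1e-6) -> float:
    """Mean held-out deviance over response-stratified folds."""
    rng = rng if rng is not None else np.random.default_rng(0)
    folds = stratified_folds(table.response, n_folds, rng)
    devs = []
    for test_idx in folds:
        train_mask = np.ones(table.n_trials, dtype=bool)
        train_mask[test_idx] = False
        model = fit_aci(table.subset(np.flatnonzero(train_mask)),
                        penalty_weight, tol=tol)
        p = model.predict_proba(table.X[test_idx])
        devs.append(deviance_of_probs(p, table.response[test_idx]))
    return float(np.mean(devs))


def default_penalty_grid(n: int = 15) -> np.ndarray:
    """Log-spaced penalty grid spanning six orders of magnitude."""
    return np.geomspace(1e0, 1e6, n)


def select_penalty(tables, penalty_grid=None, n_folds: int = 10,
                   seed: int = 0, tol: float = 1e-5):
    """Shared penalty weight minimizing mean CV deviance across listeners.

    Ties break toward the larger (smoother) value; a minimum at either
    grid edge triggers a warning.  Returns (lambda, mean-deviance curve).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one trial table")
    grid = np.asarray(default_penalty_grid() if penalty_grid is None
                      else penalty_grid, dtype=float)
    if len(grid) < 2:
        raise ValueError("penalty grid needs at least two values")
    curve = np.empty(len(grid))
    for j, lam in enumerate(grid):
        devs = [cv_deviance(t, lam, n_folds,
                            np.random.default_rng([seed, i]), tol=tol)
                for i, t in enumerate(tables)]
        curve[j] = np.mean(devs)
    best = np.flatnonzero(curve == curve.min())[-1]  # tie -> smoother
    order = np.argsort(grid)
    if best in (order[0], order[-1]):
        warnings.warn("CV-deviance minimum at penalty-grid boundary")
    return float(grid[best]), curve


def zscore_aci(model: ACIModel) -> np.ndarray:
    """Z-score the template over all pixels (sample sd; bias excluded)."""
    beta = model.template
    sd = beta.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("template has zero variance; z-scoring undefined")
    return (beta - beta.mean()) / sd
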