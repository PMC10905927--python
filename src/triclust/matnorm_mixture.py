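"""Mixtures of matrix-variate Gaussian distributions, fitted by EM.

Each gene contributes a J x Tc matrix Y (experiments x non-reference time
points, Tc = T - 1 after the ALR transform).  Conditional on component k,

    Y ~ MN(M_k, Sigma_k, Psi_k),  i.e.  vec(Y) ~ N(vec(M_k), Psi_k (x) Sigma_k),

with a J x Tc mean matrix M_k, a diagonal row (experiment) covariance
Sigma_k with component- and experiment-specific variances, and a Tc x Tc
column (time) correlation matrix Psi_k — either a general correlation
matrix or the AR1 restriction Psi[t, s] = rho_k^|t-s|.  The unit diagonal
of Psi carries the identifiability constraint; scale lives in Sigma.

The Kronecker structure makes the covariance far more parsimonious than an
unrestricted multivariate Gaussian on vec(Y): for J = 2 and Tc = 5 the
separate row/column covariances need 2*3/2 + 5*6/2 = 18 parameters versus
10*11/2 = 55 for the general 10 x 10 matrix.

Model selection uses BIC / ICL in the per-observation scaling

    BIC(K) = -l/n + nu_K/(2n) * ln n,      ICL(K) = BIC(K) + entropy,

with l the total log-likelihood, nu_K the free-parameter count and
entropy = -(1/n) sum_i sum_k tau_ik ln tau_ik; smaller is better.  The
conventional -2l + nu ln n value is reported alongside (the ranking over
K is identical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

__all__ = [
    "CovarianceSpec",
    "ComponentParams",
    "MatrixMixtureModel",
    "FitResult",
    "ar1_correlation",
    "matnorm_logpdf",
    "mixture_loglik",
    "posterior_probs",
    "em_fit",
    "refit_ar1",
    "count_parameters",
    "bic",
    "icl",
    "bic_conventional",
    "entropy",
    "select_k",
    "map_assign",
    "model_to_json",
    "model_from_json",
]

LOG2PI = np.log(2.0 * np.pi)
VARIANCE_FLOOR = 1e-10
PSI_RIDGE = 1e-10
RHO_BOUND = 0.999


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class CovarianceSpec:
    """Covariance structure: diagonal experiment covariance always; column
    (time) correlation either a general correlation matrix or AR1."""

    column_structure: str = "general"  # "general" or "ar1"

    def __post_init__(self) -> None:
        if self.column_structure not in ("general", "ar1"):
            raise ValueError("column_structure must be 'general' or 'ar1'")


def ar1_correlation(rho: float, t: int) -> np.ndarray:
    """AR1 correlation matrix Psi[t, s] = rho^|t-s|."""
    if not -1.0 < rho < 1.0:
        raise ValueError("AR1 parameter rho must lie in (-1, 1)")
    idx = np.arange(t)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class ComponentParams:
    """One mixture component: mean matrix M (J x Tc), diagonal experiment
    variances sigma2 (J,), time correlation psi (Tc x Tc) or its AR1 rho."""

    M: np.ndarray
    sigma2: np.ndarray
    psi: np.ndarray
    rho: float | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.M.ndim != 2:
            raise ValueError("mean M must be a J x Tc matrix")
        if np.any(self.sigma2 <= 0):
            raise ValueError("experiment variances must be strictly positive")
        if not np.allclose(self.psi, self.psi.T, atol=1e-10):
            raise ValueError("psi must be symmetric")
        if not np.allclose(np.diag(self.psi), 1.0, atol=1e-8):
            raise ValueError("psi must have unit diagonal (correlation matrix)")
        if self.rho is not None and not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")


@dataclass
class MatrixMixtureModel:
    K: int
    pi: np.ndarray
    components: list[ComponentParams]
    spec: CovarianceSpec = field(default_factory=CovarianceSpec)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if len(self.components) != self.K or self.pi.shape != (self.K,):
            raise ValueError("component count mismatch")
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("component sizes must be positive and sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.components[0].M.shape


@dataclass
class FitResult:
    model: MatrixMixtureModel
    tau: np.ndarray          # n x K posterior matrix
    loglik: float            # total log-likelihood
    loglik_trace: list[float]
    nu: int                  # free-parameter count
    converged: bool
    n_iter: int
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.tau.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return map_assign(self.tau)


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def _psi_inv_logdet(psi: np.ndarray) -> tuple[np.ndarray, float]:
    psi = psi + PSI_RIDGE * np.eye(psi.shape[0])
    try:
        chol = np.linalg.cholesky(psi)
    except np.linalg.LinAlgError:
        smallest = float(np.linalg.eigvalsh(psi)[0])
        raise ValueError(
            f"column correlation matrix is not positive definite "
            f"(smallest eigenvalue {smallest:.3e})"
        ) from None
    inv = np.linalg.inv(psi)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return inv, logdet


def _stack_logpdf(Y: np.ndarray, M: np.ndarray, sigma2: np.ndarray,
                  psi_inv: np.ndarray, psi_logdet: float) -> np.ndarray:
    """Matrix-normal log-density for a stack of observations (n, J, Tc)."""
    j, t = M.shape
    R = Y - M[None, :, :]
    W = R / sigma2[None, :, None]
    quad = np.einsum("njt,ts,njs->n", W, psi_inv, R)
    const = j * t * LOG2PI + t * np.sum(np.log(sigma2)) + j * psi_logdet
    return -0.5 * (const + quad)


def matnorm_logpdf(Y: np.ndarray, params: ComponentParams) -> float | np.ndarray:
    """Log-density of the matrix normal MN(M, diag(sigma2), psi).

    Equals the J*Tc-dimensional multivariate normal log-density of vec(Y)
    with covariance Psi (x) Sigma:

        -(J Tc / 2) ln 2pi - (Tc/2) ln|Sigma| - (J/2) ln|Psi|
        - 1/2 tr(Psi^-1 (Y-M)^T Sigma^-1 (Y-M)).

    Accepts a single J x Tc matrix or a stack (n, J, Tc).
    """
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 2
    if single:
        Y = Y[None]
    if Y.shape[1:] != params.M.shape:
        raise ValueError(f"observation shape {Y.shape[1:]} does not match mean "
                         f"shape {params.M.shape}")
    psi_inv, psi_logdet = _psi_inv_logdet(params.psi)
    out = _stack_logpdf(Y, params.M, params.sigma2, psi_inv, psi_logdet)
    return float(out[0]) if single else out


def _log_component_matrix(Y: np.ndarray, model: MatrixMixtureModel) -> np.ndarray:
    """n x K matrix of ln pi_k + ln phi_k(Y_i)."""
    n = Y.shape[0]
    out = np.empty((n, model.K))
    for k, comp in enumerate(model.components):
        psi_inv, psi_logdet = _psi_inv_logdet(comp.psi)
        out[:, k] = np.log(model.pi[k]) + _stack_logpdf(
            Y, comp.M, comp.sigma2, psi_inv, psi_logdet)
    return out


def _as_stack(data) -> np.ndarray:
    arr = data.data if hasattr(data, "data") else np.asarray(data, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a (n, J, Tc) stack of observations")
    return np.asarray(arr, dtype=float)


def mixture_loglik(data, model: MatrixMixtureModel) -> float:
    """Total log-likelihood sum_i ln sum_k pi_k phi_k(Y_i), via log-sum-exp."""
    Y = _as_stack(data)
    return float(logsumexp(_log_component_matrix(Y, model), axis=1).sum())


def posterior_probs(data, model: MatrixMixtureModel) -> np.ndarray:
    """n x K posterior matrix tau_ik = pi_k phi_k(Y_i) / sum_l pi_l phi_l(Y_i)."""
    Y = _as_stack(data)
    logmat = _log_component_matrix(Y, model)
    return np.exp(logmat - logsumexp(logmat, axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

class _DegenerateStart(RuntimeError):
    pass


def _weighted_mean(Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.einsum("n,njt->jt", w, Y) / w.sum()


def _sigma2_update(R: np.ndarray, w: np.ndarray, psi_inv: np.ndarray) -> np.ndarray:
    t = R.shape[2]
    num = np.einsum("n,njt,ts,njs->j", w, R, psi_inv, R)
    return np.maximum(num / (t * w.sum()), VARIANCE_FLOOR)


def _column_crossprod(R: np.ndarray, w: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    j = R.shape[1]
    W = R / sigma2[None, :, None]
    return np.einsum("n,njt,njs->ts", w, W, R) / (j * w.sum())


def _ar1_profile_rho(S: np.ndarray, old_rho: float) -> float:
    """Minimise logdet Psi(rho) + tr(Psi(rho)^-1 S) over rho in (-1, 1).

    Uses the closed forms |Psi| = (1 - rho^2)^(Tc-1) and the tridiagonal
    inverse of the AR1 correlation matrix, so each objective evaluation is
    O(1) given three precomputed scalars.  Falls back to the previous rho
    if the bounded search does not improve on it (generalised EM).
    """
    t = S.shape[0]
    if t == 1:
        return 0.0
    s_all = float(np.trace(S))
    s_inner = s_all - float(S[0, 0]) - float(S[-1, -1])
    s_lag1 = float(np.sum(np.diag(S, 1)))

    def objective(rho: float) -> float:
        one = 1.0 - rho * rho
        trace_term = (s_all + rho * rho * s_inner - 2.0 * rho * s_lag1) / one
        return (t - 1) * np.log(one) + trace_term

    res = minimize_scalar(objective, bounds=(-RHO_BOUND, RHO_BOUND),
                          method="bounded", options={"xatol": 1e-6})
    cand = float(res.x)
    old = float(np.clip(old_rho, -RHO_BOUND, RHO_BOUND))
    return cand if objective(cand) <= objective(old) else old


def _component_q(Y: np.ndarray, w: np.ndarray, comp: ComponentParams) -> float:
    psi_inv, psi_logdet = _psi_inv_logdet(comp.psi)
    return float(w @ _stack_logpdf(Y, comp.M, comp.sigma2, psi_inv, psi_logdet))


def _m_step_component(Y: np.ndarray, w: np.ndarray, comp: ComponentParams,
                      spec: CovarianceSpec) -> ComponentParams:
    """Conditional-maximisation sweep for one component.

    The mean update is exact.  Covariance moves are accepted only if the
    component's tau-weighted log-density does not decrease (generalised EM),
    which protects the monotone log-likelihood guarantee against the
    unit-diagonal rescaling of the column factor.
    """
    M = _weighted_mean(Y, w)
    R = Y - M[None, :, :]
    t = R.shape[2]
    psi_inv, _ = _psi_inv_logdet(comp.psi)
    sigma2 = _sigma2_update(R, w, psi_inv)

    # fallback: keep old column correlation but the exact sigma update given it
    candidates = [ComponentParams(M=M, sigma2=sigma2, psi=comp.psi, rho=comp.rho)]
    S = _column_crossprod(R, w, sigma2)
    if spec.column_structure == "ar1":
        rho = _ar1_profile_rho(S, comp.rho if comp.rho is not None else 0.0)
        candidates.append(ComponentParams(M=M, sigma2=sigma2,
                                          psi=ar1_correlation(rho, t), rho=rho))
    else:
        d = np.maximum(np.diag(S), VARIANCE_FLOOR)
        psi = S / np.sqrt(np.outer(d, d))
        np.fill_diagonal(psi, 1.0)
        scale = float(np.exp(np.mean(np.log(d))))
        candidates.append(ComponentParams(
            M=M, sigma2=np.maximum(sigma2 * scale, VARIANCE_FLOOR), psi=psi))
        # the normalise-S move is a heuristic projection onto the correlation
        # family; also propose its AR1 member so the general search dominates
        # the restricted one and never stalls below the AR1 optimum
        if t > 1:
            rho0 = float(np.clip(np.mean(np.diag(comp.psi, 1)), -RHO_BOUND, RHO_BOUND))
            rho = _ar1_profile_rho(S, rho0)
            candidates.append(ComponentParams(M=M, sigma2=sigma2,
                                              psi=ar1_correlation(rho, t)))

    best = ComponentParams(M=M, sigma2=comp.sigma2, psi=comp.psi, rho=comp.rho)
    best_q = _component_q(Y, w, best)
    for cand in candidates:
        q = _component_q(Y, w, cand)
        if q >= best_q:
            best, best_q = cand, q
    # exact sigma resweep given the accepted column correlation
    psi_inv_new, _ = _psi_inv_logdet(best.psi)
    resweep = ComponentParams(M=M, sigma2=_sigma2_update(R, w, psi_inv_new),
                              psi=best.psi, rho=best.rho)
    if _component_q(Y, w, resweep) >= best_q:
        best = resweep
    return best


def _m_step(Y: np.ndarray, tau: np.ndarray, model: MatrixMixtureModel) -> MatrixMixtureModel:
    n, k = tau.shape
    j, t = Y.shape[1], Y.shape[2]
    nk = tau.sum(axis=0)
    if np.any(nk < j + t):
        raise _DegenerateStart("a component's effective size fell below J + Tc")
    comps = [_m_step_component(Y, tau[:, kk], model.components[kk], model.spec)
             for kk in range(k)]
    return MatrixMixtureModel(K=k, pi=nk / n, components=comps, spec=model.spec)


def _init_model_from_tau(Y: np.ndarray, tau: np.ndarray,
                         spec: CovarianceSpec) -> MatrixMixtureModel:
    n, k = tau.shape
    j, t = Y.shape[1], Y.shape[2]
    nk = tau.sum(axis=0)
    if np.any(nk < j + t):
        raise _DegenerateStart("initial assignment leaves a component too small")
    comps = []
    for kk in range(k):
        w = tau[:, kk]
        M = _weighted_mean(Y, w)
        R = Y - M[None, :, :]
        sigma2 = np.maximum(
            np.einsum("n,njt->j", w, R * R) / (t * w.sum()), VARIANCE_FLOOR)
        rho = 0.0 if spec.column_structure == "ar1" else None
        comps.append(ComponentParams(M=M, sigma2=sigma2, psi=np.eye(t), rho=rho))
    return MatrixMixtureModel(K=k, pi=nk / n, components=comps, spec=spec)


def _e_step(Y: np.ndarray, model: MatrixMixtureModel) -> tuple[np.ndarray, float]:
    logmat = _log_component_matrix(Y, model)
    norm = logsumexp(logmat, axis=1)
    tau = np.exp(logmat - norm[:, None])
    return tau, float(norm.sum())


def _run_em(Y: np.ndarray, tau0: np.ndarray, spec: CovarianceSpec, tol: float,
            max_iter: int):
    model = _init_model_from_tau(Y, tau0, spec)
    trace: list[float] = []
    tau, ll = _e_step(Y, model)
    trace.append(ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        model = _m_step(Y, tau, model)
        tau, ll_new = _e_step(Y, model)
        trace.append(ll_new)
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            converged = True
            ll = ll_new
            break
        ll = ll_new
    return model, tau, trace, converged, it


def _kmeans_tau(Y: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    flat = Y.reshape(Y.shape[0], -1)
    labels = KMeans(n_clusters=k, n_init=3, random_state=seed % (2**32)).fit_predict(flat)
    return _one_hot(labels, k)


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    tau = np.zeros((labels.size, k))
    tau[np.arange(labels.size), labels] = 1.0
    return tau


def em_fit(data, K: int, spec: CovarianceSpec | None = None, n_starts: int = 10,
           tol: float = 1e-8, max_iter: int = 500, seed: int = 0,
           init_tau: np.ndarray | None = None) -> FitResult:
    """Fit a K-component matrix-variate Gaussian mixture by EM.

    The first start initialises from k-means on the vectorised observations;
    the remaining starts use random hard assignments.  The best start by
    final log-likelihood wins.  Degenerate starts (a component's effective
    size below J + Tc) are abandoned and replaced, up to a bounded budget.
    ``init_tau`` overrides the start schedule (single start from the given
    posterior), used by the AR1 refinement.
    """
    Y = _as_stack(data)
    spec = spec or CovarianceSpec()
    n, j, t = Y.shape
    if K >= n:
        raise ValueError(f"K = {K} must be smaller than the number of observations n = {n}")
    if K < 1:
        raise ValueError("K must be at least 1")
    rng = np.random.default_rng(seed)

    queue: list[np.ndarray] = []
    if init_tau is not None:
        queue.append(np.asarray(init_tau, dtype=float))
    elif K == 1:
        queue.append(np.ones((n, 1)))
    else:
        try:
            queue.append(_kmeans_tau(Y, K, seed))
        except Exception:
            pass
        while len(queue) < n_starts:
            queue.append(_one_hot(rng.integers(0, K, size=n), K))

    best = None
    failures: list[str] = []
    attempts, budget = 0, max(len(queue), n_starts)
    while queue and attempts < 3 * budget:
        tau0 = queue.pop(0)
        attempts += 1
        try:
            result = _run_em(Y, tau0, spec, tol, max_iter)
        except _DegenerateStart as exc:
            failures.append(str(exc))
            if init_tau is None and K > 1:
                queue.append(_one_hot(rng.integers(0, K, size=n), K))
            continue
        if best is None or result[2][-1] > best[2][-1]:
            best = result
    if best is None:
        raise RuntimeError(
            f"all EM starts failed for K = {K}: "
            f"{failures[-1] if failures else 'no usable starts'}")

    model, tau, trace, converged, it = best
    nu = count_parameters(K, j, t, model.spec)
    return FitResult(model=model, tau=tau, loglik=trace[-1], loglik_trace=trace,
                     nu=nu, converged=converged, n_iter=it, seed=seed)


def refit_ar1(data, full_fit: FitResult, tol: float = 1e-8,
              max_iter: int = 500) -> FitResult:
    """AR1-restricted refinement initialised from a general-correlation fit.

    Each component's initial rho is the average lag-1 entry of the fitted
    general correlation matrix; EM then runs under the AR1 constraint.
    Being a submodel, the refined log-likelihood cannot exceed the general
    fit's maximum.
    """
    if full_fit.model.spec.column_structure != "general":
        raise ValueError("refit_ar1 expects a fit with general column correlation")
    Y = _as_stack(data)
    j, t = Y.shape[1], Y.shape[2]
    spec = CovarianceSpec(column_structure="ar1")
    comps = []
    for comp in full_fit.model.components:
        rho0 = 0.0
        if t > 1:
            rho0 = float(np.clip(np.mean(np.diag(comp.psi, 1)), -RHO_BOUND, RHO_BOUND))
        comps.append(ComponentParams(M=comp.M, sigma2=comp.sigma2,
                                     psi=ar1_correlation(rho0, t), rho=rho0))
    model = MatrixMixtureModel(K=full_fit.model.K, pi=full_fit.model.pi,
                               components=comps, spec=spec)
    trace: list[float] = []
    tau, ll = _e_step(Y, model)
    trace.append(ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            model = _m_step(Y, tau, model)
        except _DegenerateStart as exc:
            raise RuntimeError(f"AR1 refinement degenerated: {exc}") from exc
        tau, ll_new = _e_step(Y, model)
        trace.append(ll_new)
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            converged = True
            ll = ll_new
            break
        ll = ll_new
    nu = count_parameters(model.K, j, t, spec)
    return FitResult(model=model, tau=tau, loglik=trace[-1], loglik_trace=trace,
                     nu=nu, converged=converged, n_iter=it, seed=full_fit.seed)


# ---------------------------------------------------------------------------
# parameter counting and information criteria
# ---------------------------------------------------------------------------

def count_parameters(K: int, J: int, Tcols: int, spec_or_variant) -> int:
    """Free-parameter counts for the covariance variants and the full model.

    Variants:
      * "separate-covariances": one general matrix-normal covariance pair,
        J(J+1)/2 + Tc(Tc+1)/2 covariance parameters;
      * "vectorised-covariance": unrestricted covariance of vec(Y),
        J*Tc (J*Tc + 1)/2;
      * a CovarianceSpec (the workflow model): full mixture count
        K*J*Tc means + (K-1) sizes + K*J diagonal variances +
        K*Tc(Tc-1)/2 correlations (general) or K AR1 parameters.
    """
    if min(K, J, Tcols) < 1:
        raise ValueError("dimensions must be positive")
    if isinstance(spec_or_variant, CovarianceSpec):
        nu = K * J * Tcols + (K - 1) + K * J
        if spec_or_variant.column_structure == "general":
            nu += K * Tcols * (Tcols - 1) // 2
        else:
            nu += K
        return nu
    if spec_or_variant == "separate-covariances":
        return J * (J + 1) // 2 + Tcols * (Tcols + 1) // 2
    if spec_or_variant == "vectorised-covariance":
        d = J * Tcols
        return d * (d + 1) // 2
    raise ValueError(f"unknown parameter-count variant: {spec_or_variant!r}")


def entropy(tau: np.ndarray) -> float:
    """Per-observation classification entropy -(1/n) sum tau ln tau (>= 0)."""
    tau = np.asarray(tau, dtype=float)
    safe = np.clip(tau, 1e-300, 1.0)
    return float(-(tau * np.log(safe)).sum() / tau.shape[0])


def bic(fit: FitResult) -> float:
    """Per-observation BIC: -l/n + nu/(2n) ln n (smaller is better)."""
    n = fit.n
    return -fit.loglik / n + fit.nu / (2.0 * n) * np.log(n)


def icl(fit: FitResult) -> float:
    """Per-observation ICL = BIC + classification entropy (smaller is better)."""
    return bic(fit) + entropy(fit.tau)


def bic_conventional(fit: FitResult) -> float:
    """Conventional BIC, -2l + nu ln n; same ranking over K as bic()."""
    return -2.0 * fit.loglik + fit.nu * np.log(fit.n)


def select_k(data, spec: CovarianceSpec | None = None, k_range=range(1, 11),
             criterion: str = "ICL", seed: int = 0, n_starts: int = 10,
             tol: float = 1e-8, max_iter: int = 500):
    """Fit each K in k_range; return (best FitResult, criterion table).

    For the AR1 structure each K is first fitted with a general column
    correlation and then refined under the AR1 restriction, mirroring the
    workflow's initialisation strategy.  Selection minimises the chosen
    per-observation criterion; failed K values are skipped and reported
    only if every fit fails.
    """
    import pandas as pd

    if criterion not in ("ICL", "BIC"):
        raise ValueError("criterion must be 'ICL' or 'BIC'")
    spec = spec or CovarianceSpec()
    k_list = list(k_range)
    if not k_list:
        raise ValueError("k_range must be non-empty")
    rows = []
    fits: dict[int, FitResult] = {}
    errors = []
    general = CovarianceSpec(column_structure="general")
    for k in k_list:
        try:
            fit = em_fit(data, k, general, n_starts=n_starts, tol=tol,
                         max_iter=max_iter, seed=seed + k)
            if spec.column_structure == "ar1":
                fit = refit_ar1(data, fit, tol=tol, max_iter=max_iter)
        except Exception as exc:
            errors.append(f"K={k}: {exc}")
            continue
        fits[k] = fit
        rows.append({"K": k, "loglik": fit.loglik, "nu": fit.nu,
                     "BIC": bic(fit), "ICL": icl(fit), "converged": fit.converged})
    if not fits:
        raise RuntimeError("every fit in k_range failed: " + "; ".join(errors))
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table[criterion].idxmin(), "K"])
    return fits[best_k], table


def map_assign(posteriors: np.ndarray) -> np.ndarray:
    """Maximum-a-posteriori labels (0-based); ties go to the lowest index."""
    tau = np.asarray(posteriors, dtype=float)
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    return np.argmax(tau, axis=1)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def model_to_json(fit: FitResult, path) -> None:
    m = fit.model
    payload = {
        "K": m.K,
        "column_structure": m.spec.column_structure,
        "pi": m.pi.tolist(),
        "components": [
            {"M": c.M.tolist(), "sigma2": c.sigma2.tolist(),
             "psi": c.psi.tolist(), "rho": c.rho}
            for c in m.components
        ],
        "loglik": fit.loglik,
        "nu": fit.nu,
        "n": fit.n,
        "BIC": bic(fit),
        "ICL": icl(fit),
        "BIC_conventional": bic_conventional(fit),
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "seed": fit.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def model_from_json(path) -> MatrixMixtureModel:
    with open(path) as fh:
        payload = json.load(fh)
    comps = [
        ComponentParams(M=np.array(c["M"]), sigma2=np.array(c["sigma2"]),
                        psi=np.array(c["psi"]), rho=c["rho"])
        for c in payload["components"]
    ]
    return MatrixMixtureModel(
        K=payload["K"], pi=np.array(payload["pi"]), components=comps,
        spec=CovarianceSpec(column_structure=payload["column_structure"]),
    )
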