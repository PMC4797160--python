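"""Cormack–Jolly–Seber likelihood, fitting, and estimability diagnostics.

The CJS model estimates apparent survival ``phi`` (surviving and staying in
the study reach over an interval) and detection probability ``p`` (being
found, given alive and present) from encounter histories, conditioning on
each animal's release.  Both parameters live on the logit scale as linear
functions of the design columns (groups, time, individual covariates, and
time covariates such as ice thickness).

The likelihood is evaluated at the individual level because individual
covariates (e.g. Fulton condition) preclude pooling into sufficient
statistics; an m-array formulation is provided in :mod:`wintercmr.marray`
for covariate-free models and as an independent cross-check.

Terminal parameters of time-dependent models are confounded (only the
product ``phi_{T-1} * p_T`` is identified); the fitter reports the numerical
rank of the Hessian and flags the confound rather than pretending the full
parameter count is estimable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import dual_annealing, minimize
from scipy.special import expit

from .design import CJSData, DesignMatrices, DesignSpec, build_design

__all__ = [
    "chi_tail",
    "individual_loglik",
    "total_loglik",
    "CJSFit",
    "fit",
    "count_estimable",
    "real_estimates",
]

_EPS = 1e-12


def chi_tail(phi_row: np.ndarray, p_row: np.ndarray) -> np.ndarray:
    """Probability of never being detected after each occasion.

    ``phi_row[t]`` is survival over interval t -> t+1 and ``p_row[t]`` the
    detection probability at occasion t+1 (0-based), so both have length
    T-1.  Returns ``chi`` of length T with ``chi[T-1] = 1`` and

        chi[t] = (1 - phi[t]) + phi[t] * (1 - p[t+1]) * chi[t+1].
    """
    phi_row = np.asarray(phi_row, dtype=float)
    p_row = np.asarray(p_row, dtype=float)
    T = len(phi_row) + 1
    chi = np.ones(T)
    for t in range(T - 2, -1, -1):
        chi[t] = (1.0 - phi_row[t]) + phi_row[t] * (1.0 - p_row[t]) * chi[t + 1]
    return chi


def individual_loglik(bits: np.ndarray, phi_row: np.ndarray, p_row: np.ndarray) -> float:
    """Log-probability of one encounter history, conditional on release.

    ``bits`` starts with the marking occasion (bits[0] == 1).  Between the
    release and the last detection the animal is known alive; afterwards the
    chi tail absorbs every unobserved fate.
    """
    bits = np.asarray(bits, dtype=int)
    phi_row = np.clip(np.asarray(phi_row, dtype=float), _EPS, 1 - _EPS)
    p_row = np.clip(np.asarray(p_row, dtype=float), _EPS, 1 - _EPS)
    last = int(np.max(np.nonzero(bits)[0]))
    ll = 0.0
    for t in range(last):
        y = bits[t + 1]
        ll += np.log(phi_row[t]) + y * np.log(p_row[t]) + (1 - y) * np.log(1.0 - p_row[t])
    return float(ll + np.log(chi_tail(phi_row, p_row)[last]))


def _probabilities(dm: DesignMatrices, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b_phi, b_p = dm.split(np.asarray(beta, dtype=float))
    phi = expit(np.einsum("ntq,q->nt", dm.X_phi, b_phi))
    p = expit(np.einsum("ntq,q->nt", dm.X_p, b_p))
    return np.clip(phi, _EPS, 1 - _EPS), np.clip(p, _EPS, 1 - _EPS)


def _total_negll_batch(data: CJSData, dm: DesignMatrices):
    """Closure: beta (..., q) -> -loglik (...), vectorised over individuals."""
    n, T = data.histories.shape
    y = data.histories[:, 1:]  # (n, T-1), occasions 2..T
    last = data.last_detection
    alive = np.arange(T - 1)[None, :] < last[:, None]  # interval inside known-alive span
    q_phi = dm.X_phi.shape[2]
    idx_n = np.arange(n)

    def negll(beta):
        beta = np.asarray(beta, dtype=float)
        phi = expit(np.einsum("ntq,...q->...nt", dm.X_phi, beta[..., :q_phi]))
        p = expit(np.einsum("ntq,...q->...nt", dm.X_p, beta[..., q_phi:]))
        phi = np.clip(phi, _EPS, 1 - _EPS)
        p = np.clip(p, _EPS, 1 - _EPS)
        chi = np.ones(phi.shape[:-1] + (T,))
        for t in range(T - 2, -1, -1):
            chi[..., t] = (1.0 - phi[..., t]) + phi[..., t] * (1.0 - p[..., t]) * chi[..., t + 1]
        obs = np.log(phi) + y * np.log(p) + (1 - y) * np.log(1.0 - p)
        ll = np.sum(obs * alive, axis=(-2, -1)) + np.sum(np.log(chi[..., idx_n, last]), axis=-1)
        return -ll

    return negll


def total_loglik(beta: np.ndarray, data: CJSData, dm: DesignMatrices) -> float:
    """Summed individual CJS log-likelihood under a design and coefficients."""
    return -float(_total_negll_batch(data, dm)(np.asarray(beta, dtype=float)))


def _finite_diff_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    q = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((q, q))
    f0 = f(x)
    for i in range(q):
        ei = np.zeros(q)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, q):
            ej = np.zeros(q)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


@dataclass
class CJSFit:
    """A fitted CJS model: coefficients, covariance, and diagnostics."""

    spec: DesignSpec
    data: CJSData
    dm: DesignMatrices
    beta: np.ndarray
    log_likelihood: float
    hessian: np.ndarray
    converged: bool
    c_hat: float = 1.0
    method: str = "individual"
    # rank threshold sits far above the finite-difference noise floor (~1e-7
    # relative) and far below any genuinely estimable eigenvalue
    eig_threshold_rel: float = 1e-6
    messages: list[str] = field(default_factory=list)
    _eig: tuple | None = field(default=None, repr=False)

    def _eigen(self):
        if self._eig is None:
            Hs = 0.5 * (self.hessian + self.hessian.T)
            w, V = np.linalg.eigh(Hs)
            self._eig = (w, V)
        return self._eig

    @property
    def n_params(self) -> int:
        return len(self.beta)

    @property
    def n_estimable(self) -> int:
        w, _ = self._eigen()
        if not len(w):
            return 0
        return int(np.sum(w > self.eig_threshold_rel * max(w.max(), _EPS)))

    @property
    def covariance(self) -> np.ndarray:
        """Inverse Hessian on the estimable subspace (pseudo-inverse), times c-hat."""
        w, V = self._eigen()
        thr = self.eig_threshold_rel * max(w.max(), _EPS) if len(w) else 0.0
        inv = np.where(w > thr, 1.0 / np.where(w > thr, w, 1.0), 0.0)
        return self.c_hat * (V * inv) @ V.T

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.covariance), 0.0))

    @property
    def weak_parameters(self) -> list[str]:
        """Design columns loading on the numerical null space (non-estimable)."""
        w, V = self._eigen()
        if not len(w):
            return []
        thr = self.eig_threshold_rel * max(w.max(), _EPS)
        null = V[:, w <= thr]
        if null.shape[1] == 0:
            return []
        load = np.abs(null).max(axis=1)
        return [lab for lab, l in zip(self.dm.labels, load) if l > 0.3]

    @property
    def terminal_confounded(self) -> bool:
        """True when the phi(T-1)/p(T) product confound is among the deficiencies."""
        n_int = self.data.T - 1
        tag = f"t{n_int}"
        return any(tag in lab for lab in self.weak_parameters)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.dm.labels, "beta": self.beta, "se": self.se}
        )

    @property
    def aic_inputs(self) -> dict:
        return {
            "log_likelihood": self.log_likelihood,
            "K": self.n_estimable,
            "n_eff": self.data.n_released,
        }


def _column_scales(*design_arrays) -> np.ndarray:
    """Root-mean-square of each design column, for optimizer preconditioning.

    Raw covariates (e.g. structural complexity ~ 19-46) make the logit
    surface badly conditioned; optimizing in unit-RMS column space avoids
    quasi-Newton stalls while leaving reported coefficients on the original
    scale.
    """
    scales = []
    for X in design_arrays:
        if X.shape[2]:
            rms = np.sqrt(np.mean(X**2, axis=(0, 1)))
            scales.append(np.where(rms > 0, rms, 1.0))
    return np.concatenate(scales) if scales else np.ones(0)


def _optimize(negll, q, n_starts, seed, tol, use_annealing, x0=None, jac=None):
    rng = np.random.default_rng(seed)
    best_ok = None
    best_any = None
    x0 = np.zeros(q) if x0 is None else np.asarray(x0, dtype=float)
    for _ in range(max(1, n_starts)):
        res = minimize(negll, x0, jac=jac, method="BFGS", options={"gtol": 1e-6, "maxiter": 2000})
        ok = res.success or np.max(np.abs(res.jac)) < 1e-3
        if best_any is None or res.fun < best_any.fun - tol:
            best_any = res
        if ok and (best_ok is None or res.fun < best_ok.fun - tol):
            best_ok = res
        if best_ok is not None:
            break  # converged; further jittered restarts add nothing
        x0 = rng.normal(0.0, 0.5, size=q)  # jittered restart
    res, ok = (best_ok, True) if best_ok is not None else (best_any, False)
    if not ok and use_annealing:
        # simulated-annealing fallback for non-convergent quasi-Newton runs
        bounds = [(-15.0, 15.0)] * q
        res_sa = dual_annealing(negll, bounds, seed=int(rng.integers(2**31 - 1)), maxiter=300)
        res_pol = minimize(negll, res_sa.x, method="BFGS", options={"gtol": 1e-6})
        if res_pol.fun < res.fun:
            res, ok = res_pol, res_pol.success or np.max(np.abs(res_pol.jac)) < 1e-3
    return res, ok


def fit(
    spec: DesignSpec | str,
    data: CJSData,
    n_starts: int = 25,
    seed: int = 0,
    tol: float = 1e-8,
    use_annealing: bool = True,
    compute_hessian: bool = True,
) -> CJSFit:
    """Maximum-likelihood CJS fit on the logit scale.

    Quasi-Newton from zero coefficients, with jittered restarts (up to
    ``n_starts``) while unconverged and a simulated-annealing fallback.
    Standard errors come from the inverse Hessian restricted to its
    numerically estimable subspace.
    """
    if isinstance(spec, str):
        spec = DesignSpec.parse(spec)
    dm = build_design(spec, data)
    q = dm.n_params
    if q == 0:
        raise ValueError("model has no parameters")
    negll_batch = _total_negll_batch(data, dm)
    scale = _column_scales(dm.X_phi, dm.X_p)

    def negll_s(beta_s):
        return float(negll_batch(beta_s / scale))

    def grad_s(beta_s):
        h = np.sqrt(np.finfo(float).eps) * (1.0 + np.abs(beta_s))
        pts = np.concatenate([beta_s[None, :], beta_s[None, :] + np.diag(h)], axis=0)
        vals = negll_batch(pts / scale)
        return (vals[1:] - vals[0]) / h

    res, ok = _optimize(negll_s, q, n_starts, seed, tol, use_annealing, jac=grad_s)
    res.x = res.x / scale

    def negll(beta):
        return float(negll_batch(beta))
    messages = [] if ok else [f"optimizer did not fully converge: {res.message}"]
    H = _finite_diff_hessian(negll, res.x) if compute_hessian else np.zeros((q, q))
    out = CJSFit(
        spec=spec,
        data=data,
        dm=dm,
        beta=res.x,
        log_likelihood=-res.fun,
        hessian=H,
        converged=bool(ok),
        messages=messages,
    )
    if compute_hessian and out.n_estimable < q:
        out.messages.append(
            f"{q - out.n_estimable} of {q} parameters not estimable"
            + (" (terminal phi/p confound)" if out.terminal_confounded else "")
        )
    return out


def count_estimable(fitted: CJSFit) -> int:
    """Number of estimable parameters: the numerical rank of the Hessian."""
    return fitted.n_estimable


def real_estimates(
    fitted: CJSFit,
    covariate_values: dict | None = None,
) -> pd.DataFrame:
    """Real-scale phi and p per group and interval/occasion with delta-method SEs.

    Individual covariates are held at their data means unless overridden via
    ``covariate_values``.
    """
    data = fitted.data
    levels = data.group_levels
    cov = {}
    for c in data.covariates.columns:
        cov[c] = float(data.covariates[c].mean())
    if covariate_values:
        cov.update(covariate_values)
    T = data.T
    ref = CJSData(
        histories=np.ones((len(levels), T), dtype=int),
        groups=np.array(levels),
        covariates=pd.DataFrame({c: [v] * len(levels) for c, v in cov.items()}),
        time_covariates=data.time_covariates,
    )
    dm_ref = build_design(fitted.spec, ref)
    b_phi, b_p = fitted.dm.split(fitted.beta)
    Sigma = fitted.covariance
    q_phi = fitted.dm.X_phi.shape[2]
    rows = []
    for side, X, b, off in (("phi", dm_ref.X_phi, b_phi, 0), ("p", dm_ref.X_p, b_p, q_phi)):
        S = Sigma[off : off + len(b), off : off + len(b)]
        for gi, g in enumerate(levels):
            eta = X[gi] @ b
            real = expit(eta)
            var_eta = np.einsum("tq,qr,tr->t", X[gi], S, X[gi])
            se = real * (1.0 - real) * np.sqrt(np.maximum(var_eta, 0.0))
            for t in range(T - 1):
                rows.append(
                    {
                        "parameter": side,
                        "group": g,
                        # interval t+1 for phi; occasion t+2 for p (1-based)
                        "index": t + 1 if side == "phi" else t + 2,
                        "estimate": float(real[t]),
                        "se": float(se[t]),
                    }
                )
    return pd.DataFrame(rows)
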