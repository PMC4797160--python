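"""m-array (reduced sufficient-statistic) form of the CJS likelihood.

When a model has no individual covariates, every fish in a group shares the
same survival/detection rows and the encounter data collapse to the classic
m-array: for each release cohort (animals detected at occasion t), the
counts of first re-detection at each later occasion, plus the never-seen
remainder.  The multinomial likelihood over these cells is algebraically
identical to the summed individual likelihood — that identity is used as a
cross-check — and is far cheaper to evaluate, which matters for the
simulation-heavy median c-hat procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, xlogy

from .cjs import CJSFit, _EPS, _column_scales, _finite_diff_hessian, _optimize
from .design import CJSData, DesignSpec, build_design

__all__ = ["build_marray", "marray_loglik", "marray_deviance", "fit_marray"]


@dataclass
class MArray:
    """Releases R[t] and first-recapture counts m[t, j] (0-based occasions)."""

    releases: np.ndarray  # (T-1,) animals detected (and re-released) at occasions 0..T-2
    m: np.ndarray  # (T-1, T), m[t, j] = first re-detection at occasion j > t

    @property
    def never_seen(self) -> np.ndarray:
        return self.releases - self.m.sum(axis=1)


def build_marray(histories: np.ndarray) -> MArray:
    """Collapse 0/1 encounter histories (first column = marking) to an m-array."""
    H = np.asarray(histories, dtype=int)
    n, T = H.shape
    R = np.zeros(T - 1, dtype=int)
    m = np.zeros((T - 1, T), dtype=int)
    for i in range(n):
        occ = np.nonzero(H[i])[0]
        for a, b in zip(occ[:-1], occ[1:]):
            R[a] += 1
            m[a, b] += 1
        if occ[-1] < T - 1:
            R[occ[-1]] += 1  # final release, never seen again
    return MArray(releases=R, m=m)


def _cell_probs(phi_row: np.ndarray, p_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P[t, j] of first re-detection at j given release at t, and chi[t].

    log P[t, j] = sum_{k=t..j-1} log phi_k + sum_{k=t..j-2} log(1-p_{k+1})
                  + log p_j, evaluated via cumulative sums.
    """
    T = len(phi_row) + 1
    phi = np.clip(phi_row, _EPS, 1 - _EPS)
    p = np.clip(p_row, _EPS, 1 - _EPS)
    lphi = np.log(phi)
    lq = np.log1p(-p)
    cs_phi = np.concatenate([[0.0], np.cumsum(lphi)])  # cs_phi[j] = sum of lphi[:j]
    cs_q = np.concatenate([[0.0], np.cumsum(lq)])
    t_idx = np.arange(T - 1)[:, None]
    j_idx = np.arange(T)[None, :]
    with np.errstate(invalid="ignore"):
        logP = (
            cs_phi[np.minimum(j_idx, T - 1)] - cs_phi[t_idx]
            + cs_q[np.maximum(j_idx - 1, 0)] - cs_q[np.minimum(t_idx, T - 2)]
            + np.log(p)[np.minimum(j_idx - 1, T - 2)]
        )
    P = np.where(j_idx > t_idx, np.exp(logP), 0.0)
    chi = np.ones(T)
    for t in range(T - 2, -1, -1):
        chi[t] = (1.0 - phi[t]) + phi[t] * (1.0 - p[t]) * chi[t + 1]
    return P, chi[: T - 1]


def marray_loglik(arr: MArray, phi_row: np.ndarray, p_row: np.ndarray) -> float:
    """Multinomial log-likelihood of an m-array under per-interval phi and p."""
    P, chi = _cell_probs(np.asarray(phi_row, float), np.asarray(p_row, float))
    return float(np.sum(xlogy(arr.m, P)) + np.sum(xlogy(arr.never_seen, chi)))


def _saturated_loglik(arr: MArray) -> float:
    """Log-likelihood with every multinomial cell at its observed proportion."""
    R = arr.releases.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.sum(xlogy(arr.m, arr.m / np.where(R > 0, R, 1.0)[:, None]))
        nv = arr.never_seen.astype(float)
        ll += np.sum(xlogy(nv, nv / np.where(R > 0, R, 1.0)))
    return float(ll)


def marray_deviance(arrays: list[MArray], loglik: float) -> float:
    """Deviance 2*(saturated - model) summed over (group) m-arrays."""
    return 2.0 * (sum(_saturated_loglik(a) for a in arrays) - loglik)


def _batched_negll(arrays: list[MArray], Xphi_g: np.ndarray, Xp_g: np.ndarray, q_phi: int):
    """Closure computing -loglik over all group m-arrays in one vectorised pass."""
    G = len(arrays)
    T = Xphi_g.shape[1] + 1
    m = np.stack([a.m for a in arrays])  # (G, T-1, T)
    never = np.stack([a.never_seen for a in arrays]).astype(float)  # (G, T-1)
    valid = np.arange(T)[None, None, :] > np.arange(T - 1)[None, :, None]
    jm1 = np.maximum(np.arange(T) - 1, 0)
    jm2 = np.minimum(jm1, T - 2)
    m_mask = valid & (m > 0)
    nv_mask = never > 0

    def negll_batch(beta):
        """beta (..., q) -> -loglik (...)."""
        beta = np.asarray(beta, dtype=float)
        phi = np.clip(expit(np.einsum("gtq,...q->...gt", Xphi_g, beta[..., :q_phi])), _EPS, 1 - _EPS)
        p = np.clip(expit(np.einsum("gtq,...q->...gt", Xp_g, beta[..., q_phi:])), _EPS, 1 - _EPS)
        zeros = np.zeros(phi.shape[:-1] + (1,))
        cs_phi = np.concatenate([zeros, np.cumsum(np.log(phi), axis=-1)], axis=-1)
        cs_q = np.concatenate([zeros, np.cumsum(np.log1p(-p), axis=-1)], axis=-1)
        logP = (
            (cs_phi + cs_q[..., jm1] + np.log(p)[..., jm2])[..., None, :]
            - (cs_phi[..., : T - 1] + cs_q[..., : T - 1])[..., :, None]
        )
        chi = np.ones(phi.shape[:-1] + (T,))
        for t in range(T - 2, -1, -1):
            chi[..., t] = (1.0 - phi[..., t]) + phi[..., t] * (1.0 - p[..., t]) * chi[..., t + 1]
        ll = np.sum(np.where(m_mask, m * logP, 0.0), axis=(-3, -2, -1))
        ll = ll + np.sum(np.where(nv_mask, never * np.log(chi[..., : T - 1]), 0.0), axis=(-2, -1))
        return -ll

    return negll_batch


def _group_design(spec: DesignSpec, data: CJSData):
    """Collapse the design to one representative per group (no individual covariates)."""
    dm = build_design(spec, data)
    reps = []
    for g in data.group_levels:
        idx = np.nonzero(data.groups == g)[0]
        X_phi_g = dm.X_phi[idx]
        X_p_g = dm.X_p[idx]
        if not (np.allclose(X_phi_g, X_phi_g[:1]) and np.allclose(X_p_g, X_p_g[:1])):
            raise ValueError(
                "m-array fitting requires all individuals in a group to share design rows "
                "(no individual covariates)"
            )
        reps.append(idx[0])
    reps = np.array(reps)
    return dm, dm.X_phi[reps], dm.X_p[reps]


def fit_marray(
    spec: DesignSpec | str,
    data: CJSData,
    n_starts: int = 25,
    seed: int = 0,
    tol: float = 1e-8,
    use_annealing: bool = True,
    compute_hessian: bool = True,
    x0: np.ndarray | None = None,
) -> CJSFit:
    """Fit a covariate-free CJS model through its m-array likelihood.

    Returns the same :class:`~wintercmr.cjs.CJSFit` container as the
    individual-level fitter; the ``method`` attribute records the route.
    ``x0`` warm-starts the optimizer (useful for refits of simulated data).
    """
    if isinstance(spec, str):
        spec = DesignSpec.parse(spec)
    dm, Xphi_g, Xp_g = _group_design(spec, data)
    arrays = [
        build_marray(data.histories[data.groups == g]) for g in data.group_levels
    ]
    q_phi = dm.X_phi.shape[2]
    q = dm.n_params
    negll_batch = _batched_negll(arrays, Xphi_g, Xp_g, q_phi)
    scale = _column_scales(Xphi_g, Xp_g)

    def negll_s(beta_s):
        return float(negll_batch(beta_s / scale))

    def grad_s(beta_s):
        # forward differences, all q perturbations in one vectorised pass
        h = np.sqrt(np.finfo(float).eps) * (1.0 + np.abs(beta_s))
        pts = np.concatenate([beta_s[None, :], beta_s[None, :] + np.diag(h)], axis=0)
        vals = negll_batch(pts / scale)
        return (vals[1:] - vals[0]) / h

    x0_s = None if x0 is None else np.asarray(x0) * scale
    res, ok = _optimize(negll_s, q, n_starts, seed, tol, use_annealing, x0=x0_s, jac=grad_s)
    res.x = res.x / scale

    def negll(beta):
        return float(negll_batch(beta))
    H = _finite_diff_hessian(negll, res.x) if compute_hessian else np.zeros((q, q))
    out = CJSFit(
        spec=spec,
        data=data,
        dm=dm,
        beta=res.x,
        log_likelihood=-res.fun,
        hessian=H,
        converged=bool(ok),
        method="marray",
        messages=[] if ok else [f"optimizer did not fully converge: {res.message}"],
    )
    out.marrays = arrays  # per-group sufficient statistics, for deviance/GOF
    return out
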