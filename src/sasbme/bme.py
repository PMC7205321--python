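"""Bayesian/Maximum-Entropy (BME) ensemble reweighting.

Given per-frame model intensities and one or more experimental curves,
BME finds frame weights w minimizing

    L(w) = chi^2(w)/2 - theta * S(w),

where S(w) = -sum_j w_j log(w_j / w0_j) is the relative entropy to the
prior weights w0 (the negative Kullback-Leibler divergence) and theta
balances trust in the data against trust in the simulation.  The
effective fraction of prior frames retained is phi_eff = exp(S), and
-ln(phi_eff) (in kBT) is a free-energy-like measure of how much the
prior had to be perturbed — an estimate of the force-field error as
seen by the data.

The minimization is performed in the dual: with whitened residual
matrix A_ji = I_sim,j,i / sigma_i and data b_i = I_exp,i / sigma_i, the
stationary weights have the exponential-family form

    w_j(lam) = w0_j exp(-sum_i lam_i A_ji) / Z(lam),

and lam minimizes the smooth convex dual

    Gamma(lam) = log Z(lam) + lam . b + (theta/2) |lam|^2 .

This is solved with L-BFGS-B using the analytic gradient
b + theta*lam - <A>_w(lam).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, xlogy

from .scattering import ScatteringCurve

logger = logging.getLogger(__name__)


class BMEConvergenceError(RuntimeError):
    """Dual minimization failed; carries the best iterate found."""

    def __init__(self, message: str, result: "BMEResult | None" = None):
        super().__init__(message)
        self.result = result


def _as_simplex(w: np.ndarray, name: str = "weights", tol: float = 1e-8) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if np.any(w < -1e-12):
        raise ValueError(f"{name} must be non-negative")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 (got {w.sum()!r})")
    return np.clip(w, 0.0, None)


def relative_entropy(w: np.ndarray, w0: np.ndarray) -> float:
    """S(w) = -sum_j w_j log(w_j/w0_j), in nats; 0*log(0) = 0; S <= 0.

    Frames with prior weight zero must have posterior weight zero
    (absolute continuity)."""
    w = _as_simplex(w, "w")
    w0 = _as_simplex(w0, "w0")
    if w.shape != w0.shape:
        raise ValueError("w and w0 must have equal length")
    bad = (w > 0) & (w0 == 0)
    if np.any(bad):
        raise ValueError(
            f"support violation: frames {np.flatnonzero(bad).tolist()} have w > 0 but w0 = 0"
        )
    ok = w > 0
    return float(-np.sum(xlogy(w[ok], w[ok] / w0[ok])))


def phi_eff(S: float) -> float:
    """Effective fraction of prior frames retained, exp(S) in (0, 1]."""
    return float(np.exp(S))


def forcefield_error(phi: float) -> float:
    """Free-energy-like force-field error -ln(phi_eff), in kBT."""
    if not 0.0 < phi <= 1.0:
        raise ValueError(f"phi_eff must be in (0, 1], got {phi}")
    return float(-np.log(phi))


def _stack_datasets(
    intensity_matrix: np.ndarray | Sequence[np.ndarray],
    datasets: ScatteringCurve | Sequence[ScatteringCurve],
    dataset_weights: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate (matrix, data) pairs into whitened (A, b) and sigma."""
    if isinstance(datasets, ScatteringCurve):
        datasets = [datasets]
        intensity_matrix = [np.asarray(intensity_matrix)]
    else:
        datasets = list(datasets)
        intensity_matrix = [np.asarray(m) for m in intensity_matrix]
    if len(datasets) != len(intensity_matrix):
        raise ValueError("one intensity matrix required per dataset")
    if dataset_weights is None:
        dataset_weights = [1.0] * len(datasets)
    blocks_a, blocks_b = [], []
    n_frames = intensity_matrix[0].shape[0]
    for mat, data, dw in zip(intensity_matrix, datasets, dataset_weights):
        if data.sigma is None:
            raise ValueError(f"dataset {data.label!r} lacks uncertainties")
        if mat.shape != (n_frames, data.n_points):
            raise ValueError(
                f"intensity matrix shape {mat.shape} does not match "
                f"({n_frames} frames, {data.n_points} points)"
            )
        s = np.sqrt(dw)
        blocks_a.append(s * mat / data.sigma)
        blocks_b.append(s * data.I / data.sigma)
    return np.concatenate(blocks_a, axis=1), np.concatenate(blocks_b), np.ones(0)


def chi2_of_weights(
    w: np.ndarray,
    intensity_matrix: np.ndarray | Sequence[np.ndarray],
    datasets: ScatteringCurve | Sequence[ScatteringCurve],
) -> float:
    """chi^2(w) = sum_i ((sum_j w_j I_sim,j,i - I_exp,i)/sigma_i)^2,
    summed over all provided datasets."""
    A, b, _ = _stack_datasets(intensity_matrix, datasets)
    w = _as_simplex(w)
    res = w @ A - b
    return float(np.dot(res, res))


@dataclass
class BMEResult:
    """Refined weights and diagnostics at one value of theta."""

    theta: float
    weights: np.ndarray
    S: float
    chi2: float
    chi2_r: float
    phi_eff: float
    n_data: int
    K: int
    converged: bool = True
    grad_norm: float = np.nan

    def __post_init__(self) -> None:
        if abs(self.phi_eff - np.exp(self.S)) > 1e-10:
            raise ValueError("phi_eff must equal exp(S)")


@dataclass
class ScanResult:
    """Theta scan table (theta decreasing) and the selected theta."""

    table: pd.DataFrame
    results: list[BMEResult]
    theta_selected: float
    selection_method: str

    @property
    def selected(self) -> BMEResult:
        idx = int(np.argmin(np.abs(self.table["theta"].to_numpy() - self.theta_selected)))
        return self.results[idx]


def bme_minimize(
    theta: float,
    w0: np.ndarray,
    intensity_matrix: np.ndarray | Sequence[np.ndarray],
    datasets: ScatteringCurve | Sequence[ScatteringCurve],
    K: int = 2,
    dataset_weights: Sequence[float] | None = None,
    grad_tol: float = 1e-8,
    maxiter: int = 2000,
) -> BMEResult:
    """Minimize L(w) = chi^2(w)/2 - theta*S(w) over the simplex.

    Deterministic for fixed inputs.  ``K`` only affects the reported
    reduced chi-square (degrees of freedom M - K).  Raises
    :class:`BMEConvergenceError` (carrying the best iterate) if the dual
    solver does not reach the gradient tolerance.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    w0 = _as_simplex(w0, "w0")
    A, b, _ = _stack_datasets(intensity_matrix, datasets, dataset_weights)
    if A.shape[0] != len(w0):
        raise ValueError("prior weights length must equal the number of frames")
    m = A.shape[1]
    if m <= K:
        raise ValueError(f"need M > K (M = {m}, K = {K})")

    support = w0 > 0
    logw0 = np.log(w0[support])
    As = A[support]

    def weights_of(lam: np.ndarray) -> np.ndarray:
        logits = logw0 - As @ lam
        w = np.zeros_like(w0)
        w[support] = np.exp(logits - logsumexp(logits))
        return w

    def dual(lam: np.ndarray):
        logits = logw0 - As @ lam
        lz = logsumexp(logits)
        ws = np.exp(logits - lz)
        grad = b + theta * lam - ws @ As
        value = lz + np.dot(lam, b) + 0.5 * theta * np.dot(lam, lam)
        return value, grad

    res = minimize(
        dual,
        x0=np.zeros(m),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-16, "gtol": min(grad_tol, 1e-10)},
    )
    # Polish with Newton steps if L-BFGS stops short of the tolerance.
    lam = res.x
    for _ in range(50):
        _, grad = dual(lam)
        gnorm = float(np.max(np.abs(grad)))
        if gnorm <= grad_tol:
            break
        logits = logw0 - As @ lam
        ws = np.exp(logits - logsumexp(logits))
        mean_a = ws @ As
        cov = (As * ws[:, None]).T @ As - np.outer(mean_a, mean_a)
        hess = theta * np.eye(m) + cov
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        lam = lam - step
    _, grad = dual(lam)
    gnorm = float(np.max(np.abs(grad)))

    w = weights_of(lam)
    S = relative_entropy(w, w0)
    res_vec = w @ A - b
    chi2_val = float(np.dot(res_vec, res_vec))
    result = BMEResult(
        theta=float(theta),
        weights=w,
        S=S,
        chi2=chi2_val,
        chi2_r=chi2_val / (m - K),
        phi_eff=float(np.exp(S)),
        n_data=m,
        K=K,
        converged=gnorm <= grad_tol,
        grad_norm=gnorm,
    )
    if not result.converged:
        raise BMEConvergenceError(
            f"BME dual solve did not converge at theta = {theta} "
            f"(max |grad| = {gnorm:.2e} > {grad_tol})",
            result=result,
        )
    return result


def theta_scan(
    theta_grid: Sequence[float],
    w0: np.ndarray,
    intensity_matrix: np.ndarray | Sequence[np.ndarray],
    datasets: ScatteringCurve | Sequence[ScatteringCurve],
    K: int = 2,
    dataset_weights: Sequence[float] | None = None,
    flat_chi2_window: float = 0.1,
) -> ScanResult:
    """Solve BME along a decreasing theta grid and select the elbow.

    Selection follows the L-curve logic used when choosing theta by eye:
    theta is lowered as long as the drop in chi2_r is substantial, and
    the scan stops where the loss of prior frames outpaces the gain in
    fit — operationally, at the first grid segment where the relative
    decrease of chi2_r falls below the relative decrease of phi_eff
    (both on log scale, so the criterion is scale-free).  If the whole
    scan is flat (chi2_r range below ``flat_chi2_window``, e.g. a prior
    that already fits), the largest theta is returned.  Per-theta solver
    failures are recorded, not propagated.
    """
    thetas = np.asarray(list(theta_grid), dtype=float)
    if len(thetas) < 3:
        raise ValueError("theta grid needs at least 3 points")
    if np.any(np.diff(thetas) >= 0):
        raise ValueError("theta grid must be strictly decreasing")
    results: list[BMEResult] = []
    for th in thetas:
        try:
            r = bme_minimize(th, w0, intensity_matrix, datasets, K=K,
                             dataset_weights=dataset_weights)
        except BMEConvergenceError as err:
            logger.warning("theta = %g: %s (keeping best iterate)", th, err)
            r = err.result
        results.append(r)
        logger.info("theta=%-10g chi2_r=%-10.4g phi_eff=%.4g", th, r.chi2_r, r.phi_eff)
    table = pd.DataFrame(
        {
            "theta": thetas,
            "chi2_r": [r.chi2_r for r in results],
            "phi_eff": [r.phi_eff for r in results],
            "converged": [r.converged for r in results],
        }
    )
    chi2_r = table["chi2_r"].to_numpy()
    phi = table["phi_eff"].to_numpy()
    if chi2_r[0] - chi2_r[-1] < flat_chi2_window:
        selected, method = float(thetas[0]), "flat-curve:max-theta"
    else:
        log_chi = np.log(np.maximum(chi2_r, 1e-12))
        log_phi = np.log(np.maximum(phi, 1e-300))
        selected, method = float(thetas[-1]), "diminishing-returns:min-theta"
        for k in range(len(thetas) - 1):
            gain = log_chi[k] - log_chi[k + 1]      # relative chi2_r drop
            cost = log_phi[k] - log_phi[k + 1]      # relative phi_eff drop
            if gain < cost:
                selected, method = float(thetas[k]), "diminishing-returns"
                break
    return ScanResult(table=table, results=results, theta_selected=selected,
                      selection_method=method)


def default_theta_grid(lo: float = 1.0, hi: float = 1e5, n: int = 30) -> np.ndarray:
    """Logarithmic theta grid, decreasing from hi to lo."""
    return np.logspace(np.log10(hi), np.log10(lo), n)
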