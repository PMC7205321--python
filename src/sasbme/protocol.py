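"""Global nuisance-parameter estimation, solvent-quality scan, and
SAXS/SANS cross-validation.

Fitting a scale and background freely for every conformation would
drastically overfit the data, so a single global set is estimated per
ensemble with a six-step algorithm: (1) fit each frame individually
with the nuisance parameters free; (2) reweight the ensemble over a
theta grid; (3) form weighted-average parameters <p>_w = sum_i w_i p_i
per theta; (4) recompute each frame's curve with the parameters fixed
to the average; (5) evaluate the reduced chi-square of the weighted
model with M - 2 degrees of freedom; (6) refit scale and background on
the averaged curve per theta and keep the theta that minimizes it.

The solvent-quality scan selects the generator's kappa (the analogue of
rescaling protein-water interactions in the force field) as the value
whose *unreweighted* ensemble average best fits the data.  The
cross-validation routine reweights against a training dataset only and
tracks held-out chi-square per theta, the standard guard against
overfitting the reweighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bme import BMEConvergenceError, ScanResult, bme_minimize
from .contrast import ContrastSpec, DEFAULT_SLD, SLDConstants, excess_scattering_lengths
from .generator import Ensemble, GeneratorConfig, sample_ensemble
from .scattering import (
    NuisanceParams,
    ScatteringCurve,
    ensemble_average_curve,
    fit_scale_background,
    frame_intensity_matrix,
)
from .topology import Topology

logger = logging.getLogger(__name__)


@dataclass
class ProtocolResult:
    """Outcome of the six-step global-parameter algorithm."""

    global_params: NuisanceParams
    per_theta: pd.DataFrame  # theta, chi2_r_fixed, chi2_r_refit, scale, background, phi_eff
    best_theta: float
    results: list

    def __post_init__(self) -> None:
        if self.best_theta not in set(self.per_theta["theta"]):
            raise ValueError("best_theta must appear in the per-theta table")


@dataclass
class CrossValReport:
    """Training and held-out chi-square along the theta path."""

    training_label: str
    table: pd.DataFrame  # theta, chi2_r_train, chi2_r_<label>...


def _per_frame_free_fits(
    raw_matrix: np.ndarray, data: ScatteringCurve
) -> tuple[np.ndarray, np.ndarray, int]:
    """Step (1): per-frame WLS fits of (scale, background); failures
    (degenerate frames) are skipped and counted."""
    n_frames = raw_matrix.shape[0]
    scales = np.full(n_frames, np.nan)
    backgrounds = np.full(n_frames, np.nan)
    failures = 0
    for j in range(n_frames):
        model = ScatteringCurve(q=data.q, I=raw_matrix[j])
        try:
            p = fit_scale_background(model, data)
            scales[j], backgrounds[j] = p.scale, p.background
        except ValueError:
            failures += 1
    return scales, backgrounds, failures


def global_parameter_protocol(
    ensemble: Ensemble,
    raw_matrix: np.ndarray,
    data: ScatteringCurve,
    theta_grid: np.ndarray | None = None,
    K: int = 2,
    refinement_passes: int = 0,
) -> ProtocolResult:
    """Six-step global nuisance-parameter estimation.

    ``raw_matrix`` holds the per-frame model intensities before any
    scale/background is applied (one row per frame, on ``data``'s q
    grid, already smeared if the data carry resolution widths).

    The reweighting is a single pass by default; ``refinement_passes``
    optionally re-solves the weights with the parameter-averaged curves
    and re-averages, per theta.
    """
    if theta_grid is None:
        theta_grid = np.logspace(np.log10(500.0), 0.0, 15)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if len(theta_grid) == 0:
        raise ValueError("theta grid must not be empty")
    m = data.n_points

    scales, backgrounds, failures = _per_frame_free_fits(raw_matrix, data)
    ok = np.isfinite(scales)
    if failures:
        logger.warning("%d/%d per-frame fits failed and were skipped", failures, len(ok))
    if failures > 0.5 * len(ok):
        raise RuntimeError(
            f"{failures} of {len(ok)} per-frame fits failed (> 50%); aborting"
        )
    # frames that failed keep the median parameters so shapes stay aligned
    scales[~ok] = np.nanmedian(scales)
    backgrounds[~ok] = np.nanmedian(backgrounds)

    fitted_matrix = scales[:, None] * raw_matrix + backgrounds[:, None]
    w0 = ensemble.weights

    rows = []
    results = []
    for theta in theta_grid:
        try:
            r = bme_minimize(theta, w0, fitted_matrix, data, K=K)
        except BMEConvergenceError as err:
            logger.warning("protocol: theta=%g did not converge; using best iterate", theta)
            r = err.result
        w = r.weights
        s_avg = float(np.dot(w, scales))            # step (3)
        b_avg = float(np.dot(w, backgrounds))
        for _ in range(refinement_passes):
            fixed = s_avg * raw_matrix + b_avg
            try:
                r = bme_minimize(theta, w0, fixed, data, K=K)
            except BMEConvergenceError as err:
                r = err.result
            w = r.weights
            s_avg = float(np.dot(w, scales))
            b_avg = float(np.dot(w, backgrounds))
        fixed = s_avg * raw_matrix + b_avg           # step (4)
        avg_curve = ensemble_average_curve(fixed, w, data.q)
        res = (avg_curve.I - data.I) / data.sigma
        chi2_r_fixed = float(np.dot(res, res)) / (m - 2)   # step (5), M - 2
        refit = fit_scale_background(avg_curve, data)      # step (6)
        res2 = (refit.apply(avg_curve.I) - data.I) / data.sigma
        chi2_r_refit = float(np.dot(res2, res2)) / (m - 2)
        rows.append(
            {
                "theta": theta,
                "chi2_r_fixed": chi2_r_fixed,
                "chi2_r_refit": chi2_r_refit,
                "scale": refit.scale * s_avg,
                "background": refit.scale * b_avg + refit.background,
                "phi_eff": r.phi_eff,
            }
        )
        results.append(r)
    table = pd.DataFrame(rows)
    best_idx = int(table["chi2_r_refit"].idxmin())
    best = table.iloc[best_idx]
    return ProtocolResult(
        global_params=NuisanceParams(scale=best["scale"], background=best["background"]),
        per_theta=table,
        best_theta=float(best["theta"]),
        results=results,
    )


def solvent_quality_scan(
    kappa_grid: np.ndarray,
    base_config: GeneratorConfig,
    topology: Topology,
    data: ScatteringCurve,
    contrast: ContrastSpec,
    constants: SLDConstants = DEFAULT_SLD,
    K: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Chi-square of the *unreweighted* ensemble average versus kappa.

    For each kappa an ensemble is generated (same seed and size as
    ``base_config``), the uniform-weight average curve is fitted with a
    global scale and background, and the reduced chi-square recorded.
    Returns the scan table and the minimizing kappa.  Generator failures
    are logged and the scan continues.
    """
    kappa_grid = np.asarray(kappa_grid, dtype=float)
    if len(kappa_grid) < 1:
        raise ValueError("kappa grid must not be empty")
    delta_b = excess_scattering_lengths(topology, contrast, constants)
    rows = []
    for kappa in kappa_grid:
        try:
            cfg = replace(base_config, kappa=float(kappa))
            ens = sample_ensemble(topology, cfg)
            matrix = frame_intensity_matrix(
                ens.coordinates, delta_b, data.q, sigma_q=data.sigma_q
            )
            avg = ensemble_average_curve(matrix, ens.weights, data.q)
            params = fit_scale_background(avg, data)
            res = (params.apply(avg.I) - data.I) / data.sigma
            chi2_r = float(np.dot(res, res)) / (data.n_points - K)
            rows.append({"kappa": kappa, "chi2_r": chi2_r})
        except Exception as err:  # noqa: BLE001 - scan must survive bad grid points
            logger.warning("kappa = %g failed: %s", kappa, err)
            rows.append({"kappa": kappa, "chi2_r": np.nan})
    table = pd.DataFrame(rows)
    if table["chi2_r"].isna().all():
        raise RuntimeError("all kappa grid points failed")
    best = float(table.loc[table["chi2_r"].idxmin(), "kappa"])
    return table, best


def crossvalidate(
    training: ScatteringCurve,
    training_matrix: np.ndarray,
    validation: list[ScatteringCurve],
    validation_matrices: list[np.ndarray],
    w0: np.ndarray,
    theta_grid: np.ndarray,
    K: int = 2,
) -> CrossValReport:
    """Reweight against the training curve only; per theta, report the
    training chi2_r and each held-out chi2_r computed with the training
    weights (scale and background refit per validation curve)."""
    n_frames = training_matrix.shape[0]
    for mat in validation_matrices:
        if mat.shape[0] != n_frames:
            raise ValueError("validation matrices must have the training frame count")
    if len(validation) != len(validation_matrices):
        raise ValueError("one matrix required per validation curve")
    def refit_chi2_r(mat: np.ndarray, curve: ScatteringCurve, w: np.ndarray) -> float:
        avg = ensemble_average_curve(mat, w, curve.q)
        params = fit_scale_background(avg, curve)
        res = (params.apply(avg.I) - curve.I) / curve.sigma
        return float(np.dot(res, res)) / (curve.n_points - K)

    rows = []
    for theta in np.asarray(theta_grid, dtype=float):
        try:
            r = bme_minimize(theta, w0, training_matrix, training, K=K)
        except BMEConvergenceError as err:
            r = err.result
        # training chi2_r goes through the same scale/background refit as
        # the held-out curves, so validation == training is an identity
        row = {
            "theta": theta,
            "chi2_r_train": refit_chi2_r(training_matrix, training, r.weights),
            "phi_eff": r.phi_eff,
        }
        for k, (curve, mat) in enumerate(zip(validation, validation_matrices)):
            label = curve.label or f"val{k}"
            row[f"chi2_r_{label}"] = refit_chi2_r(mat, curve, r.weights)
        rows.append(row)
    return CrossValReport(
        training_label=training.label or "training", table=pd.DataFrame(rows)
    )
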