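"""Shared fixtures: a toy three-domain topology and the seeded ensembles
and simulated datasets used by the recovery and cross-validation tests.

Heavy ensembles are session-scoped so the Monte-Carlo cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

import sasbme as sb
from sasbme.generator import GeneratorConfig

#: study-condition constants for the recovery fixture
KAPPA_TRUTH = 2.0
KAPPA_BIASED_PRIOR = 1.0
KAPPA_FAR_PRIOR = 0.5
N_FRAMES = 500
SAXS_NOISE = 0.01
SANS_NOISE = 0.05

Q_SAXS = np.linspace(0.01, 0.3, 60)
Q_SANS = np.linspace(0.015, 0.2, 30)
SANS_WIDTHS = np.full(len(Q_SANS), 0.005)


@pytest.fixture(scope="session")
def toy_topology():
    return sb.build_toy_topology(8)


@pytest.fixture(scope="session")
def truth_ensemble(toy_topology):
    """The truth condition: good-solvent ensemble at kappa* = 2."""
    return sb.sample_ensemble(
        toy_topology, GeneratorConfig(kappa=KAPPA_TRUTH, n_frames=N_FRAMES, seed=11)
    )


@pytest.fixture(scope="session")
def xray_spec():
    return sb.ContrastSpec(probe="xray")


@pytest.fixture(scope="session")
def xray_delta_b(toy_topology, xray_spec):
    return sb.excess_scattering_lengths(toy_topology, xray_spec)


@pytest.fixture(scope="session")
def saxs_data(truth_ensemble, xray_spec):
    """High signal-to-noise SAXS-like dataset from the truth ensemble."""
    return sb.simulate_dataset(
        truth_ensemble, truth_ensemble.weights, xray_spec, Q_SAXS,
        noise_scale=SAXS_NOISE, seed=11, label="saxs",
    )


@pytest.fixture(scope="session")
def biased_prior(toy_topology):
    """A 'good enough' biased prior: too-compact kappa = 1 ensemble."""
    return sb.sample_ensemble(
        toy_topology, GeneratorConfig(kappa=KAPPA_BIASED_PRIOR, n_frames=N_FRAMES, seed=12)
    )


@pytest.fixture(scope="session")
def biased_prior_matrix(biased_prior, xray_delta_b):
    return sb.frame_intensity_matrix(biased_prior.coordinates, xray_delta_b, Q_SAXS)


@pytest.fixture(scope="session")
def far_prior(toy_topology):
    """A poor prior: sticky-domain kappa = 0.5 ensemble."""
    return sb.sample_ensemble(
        toy_topology, GeneratorConfig(kappa=KAPPA_FAR_PRIOR, n_frames=N_FRAMES, seed=13)
    )


@pytest.fixture(scope="session")
def far_prior_matrix(far_prior, xray_delta_b):
    return sb.frame_intensity_matrix(far_prior.coordinates, xray_delta_b, Q_SAXS)


@pytest.fixture(scope="session")
def recovery_fixture(truth_ensemble, xray_spec, xray_delta_b):
    """Weight-recovery problem with known generative truth: the same
    frames under a compact/expanded two-population truth mixture versus
    a uniform prior.  Returns (data, intensity_matrix, w0, truth_w)."""
    truth_w = sb.two_population_truth(truth_ensemble, compact_fraction=0.3)
    data = sb.simulate_dataset(
        truth_ensemble, truth_w, xray_spec, Q_SAXS,
        noise_scale=SAXS_NOISE, seed=17, label="recovery",
    )
    matrix = sb.frame_intensity_matrix(truth_ensemble.coordinates, xray_delta_b, Q_SAXS)
    return data, matrix, truth_ensemble.weights, truth_w


@pytest.fixture(scope="session")
def sans_analogues(toy_topology, truth_ensemble):
    """SANS contrast-variation analogues of the truth ensemble: chain A
    deuterated, measured at 0% D2O (all domains visible) and 42% D2O
    (hydrogenated chains matched out: only the rigid A domain visible),
    with per-point resolution widths and SANS-like noise."""
    out = {}
    for f, seed in ((0.0, 21), (0.42, 22)):
        spec = sb.ContrastSpec(probe="neutron", f_d2o=f, deuteration={"A": 1.0})
        data = sb.simulate_dataset(
            truth_ensemble, truth_ensemble.weights, spec, Q_SANS,
            noise_scale=SANS_NOISE, resolution_widths=SANS_WIDTHS, seed=seed,
            label=f"sans{int(100 * f)}",
        )
        out[f] = (spec, data)
    return out


@pytest.fixture(scope="session")
def kappa_ladder(toy_topology):
    """Mean radius of gyration per (kappa, seed): 4 solvent qualities x
    5 seeds at 300 frames, for monotonicity checks."""
    from sasbme.analysis import compute_cvs

    table: dict[tuple[float, int], float] = {}
    for kappa in (0.5, 1.0, 2.0, 4.0):
        for seed in range(5):
            ens = sb.sample_ensemble(
                toy_topology, GeneratorConfig(kappa=kappa, n_frames=300, seed=40 + seed)
            )
            table[(kappa, seed)] = float(compute_cvs(ens).rg.mean())
    return table
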