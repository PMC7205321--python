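"""Synthetic multi-domain ensembles and simulated scattering datasets.

The generator is a Metropolis Monte-Carlo sampler over a toy bead model:
three rigid domains joined by flexible linkers, with harmonic bonds
along the chain, hard-core repulsion between non-bonded beads, and a
square-well attraction between beads of different rigid domains whose
depth is eps0/kappa.  The single dimensionless parameter kappa plays
the role of solvent quality: large kappa weakens inter-domain
attraction (good solvent, expanded conformations), small kappa makes
domains sticky (poor solvent, compact conformations) — the same
compact-to-expanded phenomenology obtained by rescaling protein-water
interactions in a coarse-grained force field.

Rigid bodies are propagated as (rotation, centroid) pairs applied to
fixed body-frame coordinates, so intra-domain geometry is preserved to
floating-point accuracy across the whole trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .contrast import ContrastSpec, DEFAULT_SLD, SLDConstants, excess_scattering_lengths
from .scattering import ScatteringCurve, ensemble_average_curve, frame_intensity_matrix
from .topology import Topology

logger = logging.getLogger(__name__)

try:  # jitted inner loop; the numpy path below is the reference behaviour
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _pair_energy_kernel(coords, mi, oi, hc2, att, lo2, hi2, bonds, bond_r0,
                        bond_k, well_depth):
    e = 0.0
    for t in range(bonds.shape[0]):
        i, j = bonds[t, 0], bonds[t, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += bond_k * (d - bond_r0[t]) ** 2
    hits = 0
    for t in range(mi.shape[0]):
        i, j = mi[t], oi[t]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < hc2[t]:
            return np.inf
        if att[t] and lo2[t] <= d2 < hi2[t]:
            hits += 1
    return e - well_depth * hits


if njit is not None:
    _pair_energy_kernel = njit(cache=True)(_pair_energy_kernel)


@dataclass(frozen=True)
class GeneratorConfig:
    """Monte-Carlo sampling parameters.

    kappa is the solvent-quality parameter (>0; inter-domain well depth
    is eps0/kappa, so larger kappa means a better solvent and more
    expanded ensembles).  Energies are in units of kBT, lengths in Å.
    """

    kappa: float = 1.0
    n_frames: int = 1000
    mc_steps_per_frame: int = 20
    burn_in_sweeps: int = 200
    eps0: float = 0.2           # kBT; square-well depth at kappa = 1
    well_width: float = 6.0     # Å beyond hard-core contact
    bond_k: float = 1.0         # kBT / Å^2
    hard_core_scale: float = 0.8
    domain_translation_step: float = 2.0   # Å
    domain_rotation_step: float = 0.25     # rad
    linker_step: float = 1.2               # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.kappa == 0:
            raise ValueError(
                "kappa = 0 means infinitely deep inter-domain attraction and is "
                "undefined; use a small positive kappa for a very poor solvent"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.mc_steps_per_frame < 1:
            raise ValueError("mc_steps_per_frame must be >= 1")


@dataclass
class Ensemble:
    """Frames x beads x 3 coordinates with per-frame prior weights."""

    topology: Topology
    coordinates: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[1:] != (
            self.topology.n_beads,
            3,
        ):
            raise ValueError("coordinates must have shape (n_frames, n_beads, 3)")
        if self.weights is None:
            self.weights = np.full(self.n_frames, 1.0 / self.n_frames)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_frames,):
            raise ValueError("weights must have one entry per frame")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


class _Mover:
    """Precomputed interaction lists for one move unit (a rigid domain or
    a single linker bead): the beads it moves, flat non-bonded pair lists
    (moved index, other index) with their thresholds, and the bonds it
    stretches."""

    __slots__ = ("idx", "mi", "oi", "hc2", "well_lo2", "well_hi2", "is_att",
                 "bond_pairs", "bond_r0")

    def __init__(self, idx, mi, oi, hc2, well_lo2, well_hi2, is_att, bond_pairs, bond_r0):
        self.idx = idx
        self.mi = mi
        self.oi = oi
        self.hc2 = hc2
        self.well_lo2 = well_lo2
        self.well_hi2 = well_hi2
        self.is_att = is_att
        self.bond_pairs = bond_pairs
        self.bond_r0 = bond_r0


class _MCState:
    """Internal Monte-Carlo state: rigid bodies + mobile linker beads."""

    def __init__(self, topology: Topology, config: GeneratorConfig):
        self.top = topology
        self.cfg = config
        ref = topology.reference_coords
        self.coords = ref.copy()
        self.domains = list(topology.domains.items())
        self.body_frames = {}
        for label, idx in self.domains:
            centroid = ref[idx].mean(axis=0)
            self.body_frames[label] = ref[idx] - centroid
        self.well_depth = config.eps0 / config.kappa

        n = topology.n_beads
        radii = topology.bead_radii
        contact = radii[:, None] + radii[None, :]
        hard_core = config.hard_core_scale * contact
        domain_of = np.full(n, "-", dtype=object)
        for label, idx in self.domains:
            domain_of[idx] = label
        bonds = np.array([(i, j) for i, j, _ in topology.bonds], dtype=int).reshape(-1, 2)
        bond_r0 = np.array([r0 for _, _, r0 in topology.bonds])
        nb_mask = np.ones((n, n), dtype=bool)
        np.fill_diagonal(nb_mask, False)
        for _, idx in self.domains:
            nb_mask[np.ix_(idx, idx)] = False
        for i, j in bonds:
            nb_mask[i, j] = nb_mask[j, i] = False
        in_domain = domain_of != "-"
        attract_mask = (
            nb_mask
            & (domain_of[:, None] != domain_of[None, :])
            & in_domain[:, None]
            & in_domain[None, :]
        )

        def make_mover(idx: np.ndarray) -> _Mover:
            moved = np.zeros(n, dtype=bool)
            moved[idx] = True
            # flat list of non-bonded pairs (moved bead, outside partner)
            sub = nb_mask[idx] & ~moved[None, :]
            rows, cols = np.nonzero(sub)
            mi = idx[rows].astype(np.int64)
            oi = cols.astype(np.int64)
            touch = (
                np.isin(bonds[:, 0], idx) | np.isin(bonds[:, 1], idx)
                if len(bonds)
                else np.zeros(0, bool)
            )
            return _Mover(
                idx=idx,
                mi=mi,
                oi=oi,
                hc2=hard_core[mi, oi] ** 2,
                well_lo2=hard_core[mi, oi] ** 2,
                well_hi2=(contact[mi, oi] + config.well_width) ** 2,
                is_att=attract_mask[mi, oi],
                bond_pairs=(bonds[touch] if len(bonds) else bonds).astype(np.int64),
                bond_r0=bond_r0[touch] if len(bonds) else bond_r0,
            )

        self.domain_movers = {label: make_mover(idx) for label, idx in self.domains}
        self.linker_movers = {
            int(b): make_mover(np.array([int(b)])) for b in topology.linker_indices
        }
        self.linker_partners = {}
        for b in topology.linker_indices:
            b = int(b)
            partners = [j for i, j, _ in topology.bonds if i == b] + [
                i for i, j, _ in topology.bonds if j == b
            ]
            self.linker_partners[b] = partners

    # -- energy -------------------------------------------------------------

    def _mover_energy(self, mv: _Mover) -> float:
        """Bond + non-bonded energy of every interaction touching the mover.
        Moved-moved pairs never appear here: within a rigid domain they are
        fixed, and each linker bead moves alone."""
        return float(
            _pair_energy_kernel(
                self.coords, mv.mi, mv.oi, mv.hc2, mv.is_att, mv.well_lo2,
                mv.well_hi2, mv.bond_pairs, mv.bond_r0,
                self.cfg.bond_k, self.well_depth,
            )
        )

    # -- moves --------------------------------------------------------------

    def try_domain_move(self, rng: np.random.Generator, label: str) -> bool:
        mv = self.domain_movers[label]
        idx = mv.idx
        old = self.coords[idx].copy()
        e_old = self._mover_energy(mv)
        centroid = old.mean(axis=0)
        shift = rng.normal(0.0, self.cfg.domain_translation_step, 3)
        rotvec = rng.normal(0.0, self.cfg.domain_rotation_step, 3)
        self.coords[idx] = (old - centroid) @ Rotation.from_rotvec(rotvec).as_matrix().T \
            + centroid + shift
        if self._accept(rng, self._mover_energy(mv) - e_old):
            return True
        self.coords[idx] = old
        return False

    def try_linker_move(self, rng: np.random.Generator, bead: int) -> bool:
        mv = self.linker_movers[bead]
        old = self.coords[bead].copy()
        e_old = self._mover_energy(mv)
        partners = self.linker_partners[bead]
        if rng.random() < 0.5 or len(partners) < 2:
            self.coords[bead] = old + rng.normal(0.0, self.cfg.linker_step, 3)
        else:
            # crankshaft: rotate about the axis through the two bonded partners
            a, b = self.coords[partners[0]], self.coords[partners[1]]
            axis = b - a
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                self.coords[bead] = old + rng.normal(0.0, self.cfg.linker_step, 3)
            else:
                angle = rng.uniform(-np.pi, np.pi)
                rot = Rotation.from_rotvec(axis / norm * angle)
                self.coords[bead] = rot.apply(old - a) + a
        if self._accept(rng, self._mover_energy(mv) - e_old):
            return True
        self.coords[bead] = old
        return False

    @staticmethod
    def _accept(rng: np.random.Generator, delta_e: float) -> bool:
        if not np.isfinite(delta_e):
            return False
        return delta_e <= 0 or rng.random() < np.exp(-delta_e)

    def sweep(self, rng: np.random.Generator) -> tuple[int, int]:
        """One sweep: attempt a rigid move of every domain and one move of
        every linker bead, in fixed order (determinism under the seed)."""
        accepted = attempted = 0
        for label, _ in self.domains:
            accepted += self.try_domain_move(rng, label)
            attempted += 1
        for bead in self.top.linker_indices:
            accepted += self.try_linker_move(rng, int(bead))
            attempted += 1
        return accepted, attempted

    def snap_rigid(self) -> None:
        """Re-anchor each domain to its body frame (removes the slow
        floating-point drift of composed rotations): fit the optimal
        rotation of the reference body onto the current coordinates."""
        for label, idx in self.domains:
            current = self.coords[idx]
            centroid = current.mean(axis=0)
            body = self.body_frames[label]
            if len(idx) == 1:
                self.coords[idx] = centroid
                continue
            rot, _ = Rotation.align_vectors(current - centroid, body)
            self.coords[idx] = rot.apply(body) + centroid


def sample_ensemble(topology: Topology, config: GeneratorConfig) -> Ensemble:
    """Sample an ensemble by Metropolis Monte Carlo.

    Frames are recorded every ``mc_steps_per_frame`` sweeps after
    ``burn_in_sweeps`` equilibration sweeps; prior weights are uniform.
    Output is a deterministic function of (topology, config).
    """
    rng = np.random.default_rng(config.seed)
    state = _MCState(topology, config)
    accepted = attempted = 0
    for _ in range(config.burn_in_sweeps):
        a, t = state.sweep(rng)
        accepted += a
        attempted += t
    frames = np.empty((config.n_frames, topology.n_beads, 3))
    for f in range(config.n_frames):
        for _ in range(config.mc_steps_per_frame):
            a, t = state.sweep(rng)
            accepted += a
            attempted += t
        state.snap_rigid()
        frames[f] = state.coords
    rate = accepted / max(attempted, 1)
    logger.info(
        "sampled %d frames (kappa=%g, seed=%d): MC acceptance %.1f%%",
        config.n_frames, config.kappa, config.seed, 100 * rate,
    )
    return Ensemble(
        topology=topology,
        coordinates=frames,
        provenance={"config": asdict(config), "acceptance_rate": rate},
    )


# ---------------------------------------------------------------------------
# Simulated experimental datasets


#: Noise presets: sigma(q) = noise_scale * (a*I0 + b*sqrt(I(q)*I0)).
NOISE_BASELINE_A = 0.1
NOISE_SHOT_B = 0.9


def simulate_dataset(
    ensemble: Ensemble,
    truth_weights: np.ndarray,
    contrast: ContrastSpec,
    q_grid: np.ndarray,
    noise_scale: float,
    resolution_widths: np.ndarray | None = None,
    seed: int = 0,
    constants: SLDConstants = DEFAULT_SLD,
    noise_a: float = NOISE_BASELINE_A,
    noise_b: float = NOISE_SHOT_B,
    label: str = "",
) -> ScatteringCurve:
    """Simulate an experimental curve from a truth-weighted ensemble.

    The noiseless model is the truth-weighted Debye average (smeared if
    resolution widths are given); independent Gaussian noise is added
    with sigma(q) = noise_scale*(a*I0 + b*sqrt(I(q)*I0)), a baseline
    plus a shot-noise-like term that decreases with intensity.  With
    noise_scale = 0 the returned curve is exactly the forward model
    (sigma columns still populated for fitting).
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    truth_weights = np.asarray(truth_weights, dtype=float)
    if truth_weights.shape != (ensemble.n_frames,):
        raise ValueError("truth_weights must have one entry per frame")
    if np.any(truth_weights < 0) or abs(truth_weights.sum() - 1.0) > 1e-8:
        raise ValueError("truth_weights must lie on the simplex")
    q_grid = np.asarray(q_grid, dtype=float)
    delta_b = excess_scattering_lengths(ensemble.topology, contrast, constants)
    matrix = frame_intensity_matrix(
        ensemble.coordinates, delta_b, q_grid, sigma_q=resolution_widths
    )
    model = ensemble_average_curve(matrix, truth_weights, q_grid, label=label)
    i0 = float(np.sum(delta_b)) ** 2
    if i0 == 0.0:
        # zero net contrast (e.g. at a global match point): scale noise to
        # the strongest model intensity instead
        i0 = float(np.max(np.abs(model.I))) or 1.0
    sigma = noise_scale * (noise_a * i0 + noise_b * np.sqrt(np.abs(model.I) * i0))
    if noise_scale == 0.0:
        # exact forward model; carry a nominal 1% sigma so fits remain defined
        sigma = np.full_like(model.I, 0.01 * i0)
        noisy = model.I.copy()
    else:
        rng = np.random.default_rng(seed)
        noisy = model.I + rng.normal(0.0, 1.0, len(q_grid)) * sigma
    return ScatteringCurve(
        q=q_grid,
        I=noisy,
        sigma=sigma,
        sigma_q=None if resolution_widths is None else np.asarray(resolution_widths, float),
        label=label,
    )


def two_population_truth(
    ensemble: Ensemble,
    compact_fraction: float = 0.3,
    cv: np.ndarray | None = None,
) -> np.ndarray:
    """Default truth weights for recovery tests: a compact/expanded
    two-population mixture.  Frames are split at the median of a size
    coordinate (radius of gyration unless ``cv`` is given); the compact
    half shares ``compact_fraction`` of the mass uniformly, the expanded
    half the rest."""
    if not 0.0 <= compact_fraction <= 1.0:
        raise ValueError("compact_fraction must be in [0, 1]")
    if cv is None:
        coords = ensemble.coordinates
        centered = coords - coords.mean(axis=1, keepdims=True)
        cv = np.sqrt((centered**2).sum(axis=(1, 2)) / coords.shape[1])
    cv = np.asarray(cv, dtype=float)
    compact = cv <= np.median(cv)
    w = np.empty(ensemble.n_frames)
    n_c = int(compact.sum())
    w[compact] = compact_fraction / max(n_c, 1)
    w[~compact] = (1.0 - compact_fraction) / max(ensemble.n_frames - n_c, 1)
    return w / w.sum()
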