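"""Bead-model topology for toy multi-domain proteins.

A topology describes three rigid domains (chains A, B, C) joined by two
flexible linkers, mirroring the architecture of RRM-repeat proteins such
as TIA-1: a compact folded domain, a flexible linker, another domain, a
second linker, and a third domain.  Linker beads belong to the chain of
the domain that follows them, so the chain labels partition the beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHAIN_LABELS = ("A", "B", "C")


@dataclass(frozen=True)
class Topology:
    """Static bead attributes shared by every frame of an ensemble.

    Attributes
    ----------
    chains : array of str, shape (n_beads,)
        Chain label per bead, one of ``A``/``B``/``C``.
    roles : array of str, shape (n_beads,)
        ``"domain"`` for beads inside a rigid body, ``"linker"`` otherwise.
    volumes : array of float, shape (n_beads,)
        Reference bead volume in Å^3 (sets the bead scattering length
        together with a contrast and the hard-core size of the bead).
    domains : dict chain label -> int array
        Bead indices forming the rigid body of each chain.
    bonds : tuple of (i, j, rest_length)
        Harmonic-bond connectivity along the chain, rest lengths in Å.
    reference_coords : array, shape (n_beads, 3)
        Deterministic build-time coordinates (Å); the generator's start
        state and the source of the rigid-body internal geometry.
    """

    chains: np.ndarray
    roles: np.ndarray
    volumes: np.ndarray
    domains: dict[str, np.ndarray]
    bonds: tuple[tuple[int, int, float], ...]
    reference_coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.chains)
        if not (len(self.roles) == len(self.volumes) == n):
            raise ValueError("chain/role/volume arrays must have equal length")
        if self.reference_coords.shape != (n, 3):
            raise ValueError("reference_coords must have shape (n_beads, 3)")
        seen: set[int] = set()
        for label, idx in self.domains.items():
            if label not in CHAIN_LABELS:
                raise ValueError(f"unknown chain label {label!r}")
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"domain bead sets overlap at indices {sorted(overlap)}")
            seen.update(idx.tolist())
            if not np.all(self.chains[idx] == label):
                raise ValueError(f"domain {label} contains beads of another chain")
        if not self._bond_graph_connected():
            raise ValueError("bond graph (with rigid domains contracted) is disconnected")

    @property
    def n_beads(self) -> int:
        return len(self.chains)

    @property
    def linker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == "linker")

    def bead_radius(self, i: int) -> float:
        return float((3.0 * self.volumes[i] / (4.0 * np.pi)) ** (1.0 / 3.0))

    @property
    def bead_radii(self) -> np.ndarray:
        return (3.0 * self.volumes / (4.0 * np.pi)) ** (1.0 / 3.0)

    def _bond_graph_connected(self) -> bool:
        # Union-find over beads; rigid domains count as internally connected.
        parent = list(range(self.n_beads))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a: int, b: int) -> None:
            parent[find(a)] = find(b)

        for idx in self.domains.values():
            for k in idx[1:]:
                union(int(idx[0]), int(k))
        for i, j, _ in self.bonds:
            union(i, j)
        roots = {find(i) for i in range(self.n_beads)}
        return len(roots) == 1


def _compact_cluster(n: int, spacing: float) -> np.ndarray:
    """Deterministic compact bead cluster: the n simple-cubic lattice sites
    closest to the origin, centred and scaled to the given spacing."""
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    m = 1
    while (2 * m + 1) ** 3 < n:
        m += 1
    axes = np.arange(-m, m + 1)
    grid = np.array(np.meshgrid(axes, axes, axes, indexing="ij")).reshape(3, -1).T
    # Stable deterministic order: by distance, then lexicographic.
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], (grid**2).sum(axis=1)))
    pts = grid[order[:n]].astype(float) * spacing
    return pts - pts.mean(axis=0)


def build_toy_topology(
    n_beads_per_domain: int,
    linker_lengths: tuple[int, int] = (3, 3),
    bead_volume: float = 100.0,
) -> Topology:
    """Build the three-domain A-linker-B-linker-C bead architecture.

    Domains are compact cubic-lattice clusters of ``n_beads_per_domain``
    beads; linkers are straight bead chains.  The construction is a pure
    function of its arguments.  Bead spacing is the hard-sphere contact
    distance implied by ``bead_volume``.
    """
    if n_beads_per_domain < 1:
        raise ValueError("n_beads_per_domain must be >= 1")
    if len(linker_lengths) != 2 or any(l < 1 for l in linker_lengths):
        raise ValueError("linker_lengths must be two positive integers")
    if bead_volume <= 0:
        raise ValueError("bead_volume must be positive")

    radius = (3.0 * bead_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    spacing = 2.0 * radius
    cluster = _compact_cluster(n_beads_per_domain, spacing)
    extent = cluster[:, 0].max() - cluster[:, 0].min()

    chains: list[str] = []
    roles: list[str] = []
    coords: list[np.ndarray] = []
    domains: dict[str, np.ndarray] = {}
    bonds: list[tuple[int, int, float]] = []

    cursor = 0.0  # running x-position of the next segment's left edge
    prev_attach = -1  # bead index the next segment bonds to
    # Linker beads belong to the chain of the following domain, so the
    # chain labels partition the beads (linker1 -> B, linker2 -> C).
    segments = [
        ("A", "domain", n_beads_per_domain),
        ("B", "linker", linker_lengths[0]),
        ("B", "domain", n_beads_per_domain),
        ("C", "linker", linker_lengths[1]),
        ("C", "domain", n_beads_per_domain),
    ]
    for label, role, count in segments:
        start = len(chains)
        if role == "domain":
            seg = cluster + np.array([cursor + extent / 2.0, 0.0, 0.0])
            # attachment beads: leftmost to previous, rightmost to next
            left = start + int(np.argmin(seg[:, 0]))
            right = start + int(np.argmax(seg[:, 0]))
            if prev_attach >= 0:
                bonds.append((prev_attach, left, spacing))
            prev_attach = right
            cursor += extent + spacing
            domains.setdefault(label, np.arange(start, start + count))
        else:
            xs = cursor + spacing * np.arange(count)
            seg = np.column_stack([xs, np.zeros(count), np.zeros(count)])
            bonds.append((prev_attach, start, spacing))
            for k in range(count - 1):
                bonds.append((start + k, start + k + 1, spacing))
            prev_attach = start + count - 1
            cursor += spacing * count
        chains.extend([label] * count)
        roles.extend([role] * count)
        coords.append(seg)

    return Topology(
        chains=np.array(chains),
        roles=np.array(roles),
        volumes=np.full(len(chains), float(bead_volume)),
        domains=domains,
        bonds=tuple(bonds),
        reference_coords=np.concatenate(coords, axis=0),
    )
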