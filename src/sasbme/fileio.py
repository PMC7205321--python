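"""File formats: 3/4-column scattering text, multi-model PDB ensembles,
weight/table outputs, and the pipeline configuration.

Scattering curves are whitespace-delimited text with '#' comment
headers: columns q, I, sigma and, for SANS, a fourth column with the
per-point resolution width sigma_q.  Ensembles are written as
multi-model PDB (one MODEL per frame, beads as pseudo-atoms with chain
IDs A/B/C) with a JSON sidecar holding what PDB cannot: bead volumes,
roles, domain ranges and bond connectivity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .generator import Ensemble
from .scattering import PairDistribution, ScatteringCurve
from .topology import Topology


class CurveFormatError(ValueError):
    """A scattering text file violates the format contract."""


def read_curve(path: str | Path, expected_columns: int | None = None) -> ScatteringCurve:
    """Read a q / I / sigma [/ sigma_q] whitespace text file.

    Enforces numeric rows, strictly increasing q and positive sigma,
    reporting offending line numbers.
    """
    path = Path(path)
    rows: list[list[float]] = []
    n_cols = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            try:
                values = [float(v) for v in fields]
            except ValueError as err:
                raise CurveFormatError(f"{path}:{lineno}: non-numeric row: {stripped!r}") from err
            if n_cols is None:
                n_cols = len(values)
                if n_cols not in (3, 4):
                    raise CurveFormatError(
                        f"{path}:{lineno}: expected 3 or 4 columns, found {n_cols}"
                    )
                if expected_columns is not None and n_cols != expected_columns:
                    raise CurveFormatError(
                        f"{path}:{lineno}: expected {expected_columns} columns, found {n_cols}"
                    )
            elif len(values) != n_cols:
                raise CurveFormatError(
                    f"{path}:{lineno}: inconsistent column count ({len(values)} vs {n_cols})"
                )
            rows.append([lineno] + values)
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    arr = np.array(rows)
    linenos, q, I, sigma = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    bad = np.flatnonzero(np.diff(q) <= 0)
    if len(bad):
        raise CurveFormatError(
            f"{path}:{int(linenos[bad[0] + 1])}: q not strictly increasing"
        )
    bad = np.flatnonzero(sigma <= 0)
    if len(bad):
        raise CurveFormatError(f"{path}:{int(linenos[bad[0]])}: sigma must be > 0")
    sigma_q = arr[:, 4] if arr.shape[1] == 5 else None
    return ScatteringCurve(q=q, I=I, sigma=sigma, sigma_q=sigma_q, label=path.stem)


def write_curve(path: str | Path, curve: ScatteringCurve, header: str = "") -> None:
    path = Path(path)
    cols = [curve.q, curve.I]
    names = ["q[1/Angstrom]", "I(q)"]
    if curve.sigma is not None:
        cols.append(curve.sigma)
        names.append("sigma")
    if curve.sigma_q is not None:
        if curve.sigma is None:
            raise ValueError("cannot write sigma_q without sigma (4-column format)")
        cols.append(curve.sigma_q)
        names.append("sigma_q[1/Angstrom]")
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        fh.write("# " + "  ".join(names) + "\n")
        for row in zip(*cols):
            fh.write("  ".join(f"{v: .8e}" for v in row) + "\n")


def write_pair_distribution(path: str | Path, pr: PairDistribution) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# pair distance distribution; bin width {pr.bin_width} Angstrom\n")
        fh.write(f"# excluded self-term: {pr.self_term:.8e}\n")
        fh.write("# r[Angstrom]  p(r)\n")
        for r, p in zip(pr.r, pr.p):
            fh.write(f"{r: .6e}  {p: .8e}\n")


def write_weights(path: str | Path, weights: np.ndarray) -> None:
    with Path(path).open("w") as fh:
        fh.write("# frame  weight\n")
        for i, w in enumerate(np.asarray(weights, dtype=float)):
            fh.write(f"{i:d}  {w:.12e}\n")


def read_weights(path: str | Path) -> np.ndarray:
    data = np.loadtxt(path)
    return np.atleast_2d(data)[:, 1]


# ---------------------------------------------------------------------------
# Ensembles as multi-model PDB + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".topology.json")


def write_ensemble(path: str | Path, ensemble: Ensemble) -> None:
    """One MODEL per frame; beads as CA pseudo-atoms with chain IDs."""
    path = Path(path)
    top = ensemble.topology
    n = top.n_beads
    template = AtomArray(n)
    template.chain_id = top.chains.astype("U4")
    template.res_id = np.arange(1, n + 1)
    template.res_name = np.array(["BEA"] * n)
    template.atom_name = np.array(["CA"] * n)
    template.element = np.array(["C"] * n)
    template.hetero = np.ones(n, dtype=bool)
    stack = AtomArrayStack(ensemble.n_frames, n)
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = ensemble.coordinates
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    sidecar = {
        "volumes": top.volumes.tolist(),
        "roles": top.roles.tolist(),
        "chains": top.chains.tolist(),
        "domains": {k: v.tolist() for k, v in top.domains.items()},
        "bonds": [[int(i), int(j), float(r)] for i, j, r in top.bonds],
        "reference_coords": top.reference_coords.tolist(),
        "weights": ensemble.weights.tolist(),
        "provenance": ensemble.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_ensemble(path: str | Path) -> Ensemble:
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as err:
        raise ValueError(f"{path}: malformed PDB: {err}") from err
    side = json.loads(_sidecar_path(path).read_text())
    topology = Topology(
        chains=np.array(side["chains"]),
        roles=np.array(side["roles"]),
        volumes=np.array(side["volumes"], dtype=float),
        domains={k: np.array(v, dtype=int) for k, v in side["domains"].items()},
        bonds=tuple((int(i), int(j), float(r)) for i, j, r in side["bonds"]),
        reference_coords=np.array(side["reference_coords"], dtype=float),
    )
    coords = stack.coord
    if coords.ndim == 2:
        coords = coords[None]
    pdb_chains = np.asarray(stack.chain_id)
    if not np.all(pdb_chains == topology.chains):
        raise ValueError(f"{path}: PDB chain labels disagree with the sidecar topology")
    return Ensemble(
        topology=topology,
        coordinates=coords,
        weights=np.array(side["weights"], dtype=float),
        provenance=side.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# Pipeline configuration


#: Recognized top-level config keys and per-section keys.
_CONFIG_SCHEMA: dict[str, set[str]] = {
    "generator": {
        "kappa", "n_frames", "mc_steps_per_frame", "burn_in_sweeps", "eps0",
        "well_width", "bond_k", "hard_core_scale", "domain_translation_step",
        "domain_rotation_step", "linker_step", "seed",
    },
    "topology": {"n_beads_per_domain", "linker_lengths", "bead_volume"},
    "contrasts": set(),     # list of named contrast specs
    "theta_grid": {"lo", "hi", "n"},
    "noise": {"noise_scale", "noise_a", "noise_b"},
    "seed": set(),
    "output_dir": set(),
    "datasets": set(),      # label -> {path, probe, f_d2o, deuteration}
}


def load_config(path: str | Path) -> dict:
    """Load and validate the YAML pipeline config; unknown keys are
    rejected with the offending key named.  Round-trips losslessly."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key, value in raw.items():
        if key not in _CONFIG_SCHEMA:
            raise ValueError(f"{path}: unknown config key {key!r}")
        allowed = _CONFIG_SCHEMA[key]
        if allowed and isinstance(value, dict):
            for sub in value:
                if sub not in allowed:
                    raise ValueError(f"{path}: unknown config key {key}.{sub!r}")
    return raw


def save_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
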