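"""Synthetic two-protomer structures and elastic-network ensembles.

Everything downstream is validated on fixtures from this module: a compact
toy dimer with minimal backbone atoms, a spring graph over its Cα sites, and
Gaussian ensembles whose displacement covariance is the (scaled)
pseudo-inverse of the weighted Kirchhoff matrix — so every fluctuation
statistic has a closed-form oracle. Frames are independent draws; the
statistics under test (distance variance, RMSF, occupancies) are
time-order-invariant, so temporal correlation is deliberately omitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .errors import RangeError, ValidationError
from .topology import (
    StructureModel,
    TopologySpec,
    Trajectory,
    write_dcd,
    write_structure,
)

CA_SPACING = 3.8  # Å, consecutive-residue Cα distance


# ---------------------------------------------------------------------------
# toy dimer geometry


def build_toy_dimer(residues_per_protomer: int,
                    domains: dict[str, tuple[int, int]] | None = None,
                    seed: int = 0,
                    offset: int = 15,
                    mutations: list[int] | None = None,
                    ) -> tuple[StructureModel, TopologySpec]:
    """Two identical chains A/B folded as compact serpentine walks.

    Each residue carries N, CA, C, O (alanine); consecutive Cα are 3.8 Å
    apart on a jittered cubic grid, so most non-adjacent pairs sit beyond
    the 5 Å connectivity gate. Domain ranges default to four contiguous
    quarters named NTD/LMD/SMD/CTD.
    """
    n = int(residues_per_protomer)
    if n < 10:
        raise ValidationError("need at least 10 residues per protomer")
    if domains is None:
        bounds = [1 + round(f * n) for f in (0.0, 0.25, 0.5, 0.75)] + [n]
        domains = {
            "NTD": (bounds[0], bounds[1]),
            "LMD": (bounds[1] + 1, bounds[2]),
            "SMD": (bounds[2] + 1, bounds[3]),
            "CTD": (bounds[3] + 1, bounds[4]),
        }
    spec = TopologySpec(chains={"A": "A", "B": "B"}, offset=offset,
                        domains=domains, mutations=mutations or [])
    lo, hi = spec.span
    if (lo, hi) != (1, n):
        raise ValidationError(
            f"domain ranges must cover 1..{n}, got {lo}..{hi}")

    rng = np.random.default_rng(seed)
    ca = _serpentine(n, rng)
    side = ca[:, 0].max() - ca[:, 0].min()
    shift = np.array([side + 2 * CA_SPACING, 0.0, 0.0])

    names, elements, resids, resnames, chains, coords = [], [], [], [], [], []
    for chain, offset_vec in (("A", np.zeros(3)), ("B", shift)):
        for i in range(n):
            for name, el, pos in _residue_atoms(ca, i):
                names.append(name)
                elements.append(el)
                resids.append(i + 1)
                resnames.append("ALA")
                chains.append(chain)
                coords.append(pos + offset_vec)
    model = StructureModel(
        atom_names=np.array(names),
        elements=np.array(elements),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames),
        chains=np.array(chains),
        coords=np.array(coords),
    )
    return model, spec


def _serpentine(n: int, rng) -> np.ndarray:
    """Self-avoiding boustrophedon walk on a cubic grid, lightly jittered."""
    m = max(2, math.ceil(n ** (1 / 3)))
    pts = []
    for z in range(m):
        for yi in range(m):
            y = yi if z % 2 == 0 else m - 1 - yi
            xs = range(m) if (z * m + yi) % 2 == 0 else range(m - 1, -1, -1)
            for x in xs:
                pts.append((x, y, z))
                if len(pts) == n:
                    break
            if len(pts) == n:
                break
        if len(pts) == n:
            break
    grid = np.asarray(pts, dtype=float) * CA_SPACING
    return grid + rng.normal(scale=0.25, size=grid.shape)


def _residue_atoms(ca: np.ndarray, i: int):
    """Minimal plausible backbone placement around Cα i along the walk."""
    n = len(ca)
    t = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
    t = t / (np.linalg.norm(t) or 1.0)
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    pos_ca = ca[i]
    pos_n = pos_ca - 1.2 * t + 0.8 * u
    pos_c = pos_ca + 1.2 * t + 0.6 * u
    pos_o = pos_c + 1.1 * u
    pos_h = pos_n - 0.9 * u  # amide H, pointing away from the carbonyl side
    return [("N", "N", pos_n), ("CA", "C", pos_ca), ("C", "C", pos_c),
            ("O", "O", pos_o), ("H", "H", pos_h)]


# ---------------------------------------------------------------------------
# ideal peptide builder (for secondary-structure / H-bond test geometries)


def build_ideal_peptide(n_residues: int, phi: float, psi: float,
                        chain: str = "A", omega: float = 180.0) -> StructureModel:
    """Poly-alanine chain with uniform backbone dihedrals (degrees).

    ``phi=-57, psi=-47`` gives an ideal α-helix; ``phi=-120, psi=120`` an
    extended strand. Standard bond lengths/angles; carbonyl O placed in the
    peptide plane.
    """
    b_nca, b_cac, b_cn, b_co = 1.458, 1.525, 1.329, 1.231
    a_ncac, a_cacn, a_cnca, a_caco = 111.2, 116.2, 121.7, 120.8

    coords = [np.array([0.0, 0.0, 0.0]),                    # N0
              np.array([b_nca, 0.0, 0.0])]                  # CA0
    # C0 in the xy-plane
    ang = math.radians(180.0 - a_ncac)
    coords.append(coords[1] + b_cac * np.array([math.cos(ang), math.sin(ang), 0.0]))

    atoms: list[tuple[int, str, str, np.ndarray]] = [
        (1, "N", "N", coords[0]), (1, "CA", "C", coords[1]), (1, "C", "C", coords[2])]
    n_prev, ca_prev, c_prev = coords

    for i in range(1, n_residues):
        n_i = _nerf(n_prev, ca_prev, c_prev, b_cn, a_cacn, psi)
        ca_i = _nerf(ca_prev, c_prev, n_i, b_nca, a_cnca, omega)
        c_i = _nerf(c_prev, n_i, ca_i, b_cac, a_ncac, phi)
        # carbonyl O of residue i-1: in the peptide plane, opposite the new N
        o_prev = _nerf(ca_prev, n_i, c_prev, b_co, 123.0, 180.0)
        atoms.append((i, "O", "O", o_prev))
        atoms.append((i + 1, "N", "N", n_i))
        atoms.append((i + 1, "CA", "C", ca_i))
        atoms.append((i + 1, "C", "C", c_i))
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i
    # last carbonyl O: extend along the N->C direction mirrored
    o_last = _nerf(n_prev, ca_prev, c_prev, b_co, a_caco, psi + 180.0)
    atoms.append((n_residues, "O", "O", o_last))

    order = {"N": 0, "CA": 1, "C": 2, "O": 3}
    atoms.sort(key=lambda rec: (rec[0], order[rec[1]]))
    return StructureModel(
        atom_names=np.array([a[1] for a in atoms]),
        elements=np.array([a[2] for a in atoms]),
        resids=np.array([a[0] for a in atoms], dtype=int),
        resnames=np.array(["ALA"] * len(atoms)),
        chains=np.array([chain] * len(atoms)),
        coords=np.array([a[3] for a in atoms]),
    )


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A-B-C, |CD|, angle(BCD) and torsion(ABCD)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# spring graph / GNM sampling


@dataclass
class SpringGraph:
    """Symmetric, non-negative weighted couplings between Cα sites."""

    weights: np.ndarray   # (n, n) symmetric, zero diagonal
    cutoff: float = 10.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValidationError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValidationError("spring constants must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def kirchhoff(self) -> np.ndarray:
        gamma = -self.weights.copy()
        np.fill_diagonal(gamma, self.weights.sum(axis=1))
        return gamma


def build_spring_graph(structure: StructureModel, cutoff: float = 10.0,
                       k: float = 1.0) -> SpringGraph:
    """Distance-cutoff springs of uniform stiffness over Cα sites."""
    ca = structure.coords[structure.ca_indices()]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    w = np.where((d > 0) & (d <= cutoff), k, 0.0)
    return SpringGraph(weights=w, cutoff=cutoff)


def perturb_springs(springs: SpringGraph, position: int, factor: float) -> SpringGraph:
    """Scale every coupling incident to ``position`` (0-based serial) by ``factor``.

    The synthetic analogue of a point mutation: ``factor < 1`` weakens the
    site's mechanical embedding, ``factor > 1`` stiffens it.
    """
    if factor < 0:
        raise ValidationError("factor must be >= 0")
    if not (0 <= position < springs.n_nodes):
        raise RangeError(f"position {position} not a node (n={springs.n_nodes})")
    w = springs.weights.copy()
    w[position, :] *= factor
    w[:, position] *= factor
    return SpringGraph(weights=w, cutoff=springs.cutoff)


def perturb_region(springs: SpringGraph, position: int, factor: float,
                   neighbor_factor: float | None = None) -> SpringGraph:
    """Local mutation analogue: weaken the site strongly, its contacts mildly.

    Scales couplings incident to ``position`` by ``factor`` and those incident
    to its direct spring neighbors by ``neighbor_factor`` (default
    ``sqrt(factor)``), emulating a destabilizing substitution that loosens a
    whole contact shell rather than a single node.
    """
    if neighbor_factor is None:
        neighbor_factor = math.sqrt(factor)
    neighbors = np.nonzero(springs.weights[position] > 0)[0]
    out = perturb_springs(springs, position, factor)
    for nb in neighbors:
        out = perturb_springs(out, int(nb), neighbor_factor)
    return out


@dataclass
class EnsembleSpec:
    """Sampling parameters for a synthetic multi-replica ensemble."""

    n_replicas: int
    frames_per_replica: int
    spacing_ps: float
    temperature_factor: float
    seed: int

    def __post_init__(self):
        if min(self.n_replicas, self.frames_per_replica) < 1:
            raise ValidationError("replica and frame counts must be positive")
        if self.spacing_ps <= 0 or self.temperature_factor <= 0:
            raise ValidationError("spacing and temperature factor must be positive")


def gnm_covariance(springs: SpringGraph, temperature_factor: float):
    """Eigen-factorization of the per-component displacement covariance.

    Returns ``(modes, scales)`` with covariance = modes @ diag(scales²) @ modesᵀ
    = temperature_factor × pseudo-inverse of the Kirchhoff matrix; zero modes
    (rigid translation of each connected component) are excluded.
    """
    gamma = springs.kirchhoff()
    evals, evecs = np.linalg.eigh(gamma)
    tol = max(1e-9, 1e-9 * float(evals[-1]))
    n_comp, _ = connected_components(springs.weights > 0, directed=False)
    nonzero = evals > tol
    if int(np.sum(~nonzero)) != n_comp:
        raise ValidationError(
            "spring graph singular beyond rigid modes (disconnected sites?)")
    scales = np.sqrt(temperature_factor / evals[nonzero])
    return evecs[:, nonzero], scales


def sample_gnm_trajectory(structure: StructureModel, springs: SpringGraph,
                          spec: EnsembleSpec) -> list[Trajectory]:
    """Draw independent Gaussian frames about the input geometry.

    Site displacements are isotropic per Cartesian component with covariance
    ``temperature_factor × pinv(Kirchhoff)``; all atoms of a residue move
    rigidly with its Cα so local backbone geometry is preserved. Replica
    seeds are spawned deterministically from ``spec.seed``.
    """
    ca_idx = structure.ca_indices()
    if springs.n_nodes != len(ca_idx):
        raise ValidationError("spring graph size != residue count")
    for chain in structure.chain_ids():
        sel = [i for i, (c, _) in enumerate(structure.residues()) if c == chain]
        block = springs.weights[np.ix_(sel, sel)] > 0
        n_comp, _ = connected_components(block, directed=False)
        if n_comp != 1:
            raise ValidationError(f"spring graph disconnected within protomer {chain}")

    modes, scales = gnm_covariance(springs, spec.temperature_factor)
    n_sites = springs.n_nodes
    # map every atom to its residue serial
    residue_of_atom = np.empty(structure.n_atoms, dtype=int)
    for serial, (chain, resid) in enumerate(structure.residues()):
        residue_of_atom[(structure.chains == chain) & (structure.resids == resid)] = serial

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicas)
    out = []
    for r, seq in enumerate(seeds, start=1):
        rng = np.random.default_rng(seq)
        z = rng.standard_normal((spec.frames_per_replica, len(scales), 3))
        disp = np.einsum("nk,fkc->fnc", modes * scales, z)  # (F, n_sites, 3)
        frames = structure.coords[None, :, :] + disp[:, residue_of_atom, :]
        out.append(Trajectory(coords=frames, spacing_ps=spec.spacing_ps,
                              replica=str(r)))
    return out


# ---------------------------------------------------------------------------
# fixture bundles


def write_fixture(structure: StructureModel, topology: TopologySpec,
                  trajectories: list[Trajectory], out_dir,
                  spec: EnsembleSpec | None = None) -> dict:
    """Write topology.pdb, rep{i}.dcd, topology.yaml and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb = out / "topology.pdb"
    write_structure(structure, pdb)
    topology.to_yaml(out / "topology.yaml")
    traj_files = []
    for i, traj in enumerate(trajectories, start=1):
        path = out / f"rep{i}.dcd"
        write_dcd(structure, traj, pdb, path)
        traj_files.append(path.name)
    manifest = {
        "topology": pdb.name,
        "config": "topology.yaml",
        "trajectories": traj_files,
        "spacing_ps": trajectories[0].spacing_ps if trajectories else None,
        "ensemble_spec": (dataclass_asdict(spec) if spec else None),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def dataclass_asdict(obj):
    import dataclasses

    return dataclasses.asdict(obj)
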