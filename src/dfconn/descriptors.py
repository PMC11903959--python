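"""Per-residue structural descriptors: RMSF, H-bond occupancy, secondary
structure frequencies and relative solvent accessibility."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .ss import SS_CLASSES, assign_frame_ss
from .topology import BACKBONE_HEAVY, MetaTrajectory, StructureModel
from .fluctuations import PerResidueScalar


# ---------------------------------------------------------------------------
# RMSF


def compute_rmsf(meta: MetaTrajectory, structure: StructureModel,
                 atom_filter: str = "backbone") -> PerResidueScalar:
    """Backbone RMSF about the arithmetic mean structure of the ensemble.

    RMSF_i = sqrt( mean over frames and the residue's selected atoms of the
    squared Cartesian deviation from the mean structure ).
    """
    if meta.n_frames < 2:
        raise InsufficientDataError("RMSF needs >= 2 frames")
    if atom_filter == "backbone":
        names = BACKBONE_HEAVY
    elif atom_filter == "ca":
        names = ("CA",)
    else:
        raise ValueError(f"unknown atom filter {atom_filter!r}")
    ref = meta.coords.mean(axis=0)
    sq = np.sum((meta.coords - ref) ** 2, axis=2)  # (F, A)
    msd_per_atom = sq.mean(axis=0)                 # (A,)
    values = []
    for chain, resid in structure.residues():
        idx = structure.atom_indices(chain, resid, names=names)
        if len(idx) == 0:
            values.append(np.nan)
        else:
            values.append(float(np.sqrt(msd_per_atom[idx].mean())))
    return PerResidueScalar(values=np.array(values), axis=structure.axis_map(),
                            label="RMSF")


# ---------------------------------------------------------------------------
# hydrogen-bond occupancy


@dataclass
class HBondOccupancy:
    donor: tuple[str, int, str]     # chain, resid, atom name (heavy)
    hydrogen: str
    acceptor: tuple[str, int, str]
    occupancy: float
    mean_distance: float            # Å, over frames where the bond is formed
    mean_angle: float               # degrees, same frames

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError("occupancy must lie in [0, 1]")


def hbond_occupancy(meta: MetaTrajectory, structure: StructureModel,
                    selection: set[tuple[str, int]] | None = None,
                    dist_cut: float = 3.0, angle_cut: float = 135.0,
                    distance_mode: str = "heavy") -> list[HBondOccupancy]:
    """Fraction of frames each donor–acceptor pair satisfies the geometry.

    A bond counts in a frame iff the donor→acceptor distance is ≤ ``dist_cut``
    and the donor–H–acceptor angle is ≥ ``angle_cut``. ``distance_mode`` picks
    the distance atom: ``"heavy"`` (donor N/O → acceptor, the conventional
    3.0 Å default) or ``"hydrogen"`` (H → acceptor). Pairs are restricted to
    those where either partner's residue is in ``selection`` (all pairs if
    None) and reported only when occupancy > 0, sorted descending.
    """
    if distance_mode not in ("heavy", "hydrogen"):
        raise ValueError(f"unknown distance mode {distance_mode!r}")
    donors = _find_donors(structure)
    if not donors:
        raise ConfigurationError(
            "no hydrogens bound to N/O found in the topology; add explicit "
            "hydrogens to use H-bond analysis")
    acceptors = [i for i in range(structure.n_atoms)
                 if structure.elements[i] in ("N", "O")]

    def in_sel(atom):
        if selection is None:
            return True
        return (str(structure.chains[atom]), int(structure.resids[atom])) in selection

    results = []
    n_frames = meta.n_frames
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            same_res = (structure.chains[a_idx] == structure.chains[d_idx]
                        and structure.resids[a_idx] == structure.resids[d_idx])
            if same_res or not (in_sel(d_idx) or in_sel(a_idx)):
                continue
            dpos = meta.coords[:, d_idx, :]
            hpos = meta.coords[:, h_idx, :]
            apos = meta.coords[:, a_idx, :]
            ref = dpos if distance_mode == "heavy" else hpos
            dist = np.linalg.norm(apos - ref, axis=1)
            angle = _angle_deg(dpos, hpos, apos)
            formed = (dist <= dist_cut) & (angle >= angle_cut)
            occ = float(np.count_nonzero(formed)) / n_frames
            if occ > 0:
                results.append(HBondOccupancy(
                    donor=(str(structure.chains[d_idx]),
                           int(structure.resids[d_idx]),
                           str(structure.atom_names[d_idx])),
                    hydrogen=str(structure.atom_names[h_idx]),
                    acceptor=(str(structure.chains[a_idx]),
                              int(structure.resids[a_idx]),
                              str(structure.atom_names[a_idx])),
                    occupancy=occ,
                    mean_distance=float(dist[formed].mean()),
                    mean_angle=float(angle[formed].mean()),
                ))
    results.sort(key=lambda h: -h.occupancy)
    return results


def _find_donors(structure: StructureModel) -> list[tuple[int, int]]:
    """(heavy, hydrogen) index pairs: H within 1.25 Å of an N/O of its residue."""
    pairs = []
    for chain, resid in structure.residues():
        idx = structure.atom_indices(chain, resid)
        heavies = [i for i in idx if structure.elements[i] in ("N", "O")]
        hydros = [i for i in idx if structure.elements[i] == "H"]
        for h in hydros:
            if not heavies:
                continue
            dists = [np.linalg.norm(structure.coords[h] - structure.coords[d])
                     for d in heavies]
            best = int(np.argmin(dists))
            if dists[best] <= 1.25:
                pairs.append((heavies[best], h))
    return pairs


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle at b (degrees) for stacked coordinate arrays."""
    u = a - b
    v = c - b
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_table_tsv(bonds: list[HBondOccupancy], path) -> None:
    with open(path, "w") as fh:
        fh.write("donor\thydrogen\tacceptor\toccupancy\tmean_dist\tmean_angle\n")
        for b in bonds:
            d = "{}:{}@{}".format(*b.donor)
            a = "{}:{}@{}".format(*b.acceptor)
            fh.write(f"{d}\t{b.hydrogen}\t{a}\t{b.occupancy:.4f}"
                     f"\t{b.mean_distance:.3f}\t{b.mean_angle:.1f}\n")


# ---------------------------------------------------------------------------
# secondary-structure frequency


@dataclass
class SSFrequency:
    """Per-residue frequency of the 8 classes over frames (rows sum to 1)."""

    frequencies: np.ndarray   # (N, 8) in SS_CLASSES order
    axis: object

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(f < 0) or not np.allclose(f.sum(axis=1), 1.0):
            raise ValidationError("SS frequencies must be >= 0 and sum to 1")
        self.frequencies = f

    def frequency(self, chain: str, resid: int, ss_class: str) -> float:
        return float(self.frequencies[self.axis.index(chain, resid),
                                      SS_CLASSES.index(ss_class)])

    def to_tsv(self, path) -> None:
        header = ["chain", "resid"] + [c if c != "-" else "coil" for c in SS_CLASSES]
        header += ["helix_pooled"]  # H+G+I, for reports quoting "helix" content
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for i, (chain, resid) in enumerate(self.axis.residues):
                row = self.frequencies[i]
                pooled = row[0] + row[1] + row[2]
                cells = [chain, str(resid)] + [f"{v:.4f}" for v in row]
                cells.append(f"{pooled:.4f}")
                fh.write("\t".join(cells) + "\n")


def ss_frequency(meta: MetaTrajectory, structure: StructureModel) -> SSFrequency:
    """Aggregate per-frame 8-class assignments into per-residue frequencies."""
    n_res = len(structure.residues())
    counts = np.zeros((n_res, len(SS_CLASSES)), dtype=float)
    class_index = {c: k for k, c in enumerate(SS_CLASSES)}
    for k in range(meta.n_frames):
        labels = assign_frame_ss(structure, meta.coords[k])
        for i, lab in enumerate(labels):
            counts[i, class_index[lab]] += 1
    return SSFrequency(frequencies=counts / meta.n_frames,
                       axis=structure.axis_map())


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake–Rupley)

VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
_DEFAULT_RADIUS = 1.70

# Theoretical Gly-X-Gly maximum accessibilities (Å²), Tien et al. 2013.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                  n_points: int = 960) -> np.ndarray:
    """Per-atom accessible surface areas (Å²) by sphere-point rejection."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    unit = _sphere_points(n_points)
    expanded = radii + probe
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        d_ij = np.linalg.norm(coords - coords[i], axis=1)
        neighbors = np.nonzero((d_ij < expanded[i] + expanded) & (d_ij > 0))[0]
        for j in neighbors:
            accessible &= (np.linalg.norm(pts - coords[j], axis=1)
                           >= expanded[j])
            if not accessible.any():
                break
        areas[i] = (accessible.mean() * 4.0 * np.pi * expanded[i] ** 2)
    return areas


def relative_sasa(structure: StructureModel, residue: tuple[str, int],
                  probe: float = 1.4, n_points: int = 960) -> float:
    """Residue SASA in context divided by its Gly-X-Gly maximum, clamped to [0, 1].

    Heavy atoms only; hydrogens are ignored as in the common convention.
    """
    chain, resid = residue
    heavy = np.nonzero(structure.elements != "H")[0]
    res_atoms = structure.atom_indices(chain, resid)
    res_heavy = [a for a in res_atoms if structure.elements[a] != "H"]
    if not res_heavy:
        raise ValidationError(f"residue {chain}:{resid} has no heavy atoms")
    resname = str(structure.resnames[res_heavy[0]])
    if resname not in MAX_ASA:
        raise KeyError(f"no maximum-accessibility entry for residue type {resname}")
    radii = np.array([VDW_RADII.get(str(e), _DEFAULT_RADIUS)
                      for e in structure.elements[heavy]])
    areas = shrake_rupley(structure.coords[heavy], radii, probe=probe,
                          n_points=n_points)
    pos = {int(a): k for k, a in enumerate(heavy)}
    total = float(sum(areas[pos[a]] for a in res_heavy))
    return float(np.clip(total / MAX_ASA[resname], 0.0, 1.0))
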