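"""Structures, trajectories and frame bookkeeping.

This module owns the reference geometry (:class:`StructureModel`), the
residue-numbering and domain semantics (:class:`TopologySpec`), raw replica
trajectories (:class:`Trajectory`) and the superposed concatenation of their
equilibrated portions (:class:`MetaTrajectory`).

Residue identity is always the pair ``(chain, resid)`` with 1-based PDB
numbering; every matrix downstream is indexed by a dense 0-based serial whose
mapping to ``(chain, resid)`` travels with the data as an :class:`AxisMap`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import (
    EmptySelectionError,
    ParseError,
    RangeError,
    UnderdeterminedError,
    ValidationError,
)

BACKBONE_HEAVY = ("N", "CA", "C", "O")

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


# ---------------------------------------------------------------------------
# axis map


class AxisMap:
    """Bijection between matrix serial indices and ``(chain, resid)`` pairs."""

    def __init__(self, residues: Sequence[tuple[str, int]]):
        self.residues: list[tuple[str, int]] = [(str(c), int(r)) for c, r in residues]
        self._index = {key: i for i, key in enumerate(self.residues)}
        if len(self._index) != len(self.residues):
            raise ValidationError("duplicate (chain, resid) in axis map")

    def __len__(self) -> int:
        return len(self.residues)

    def __eq__(self, other) -> bool:
        return isinstance(other, AxisMap) and self.residues == other.residues

    def index(self, chain: str, resid: int) -> int:
        try:
            return self._index[(chain, resid)]
        except KeyError:
            raise RangeError(f"residue {chain}:{resid} not in axis map") from None

    def labels(self) -> list[str]:
        return [f"{c}:{r}" for c, r in self.residues]

    def chains(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.residues:
            if c not in seen:
                seen.append(c)
        return seen

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("serial\tchain\tresid\n")
            for i, (c, r) in enumerate(self.residues):
                fh.write(f"{i}\t{c}\t{r}\n")


# ---------------------------------------------------------------------------
# structure model


@dataclass
class StructureModel:
    """All ATOM records of a PDB model, column-oriented."""

    atom_names: np.ndarray      # (n_atoms,) str
    elements: np.ndarray        # (n_atoms,) str
    resids: np.ndarray          # (n_atoms,) int, 1-based PDB numbering
    resnames: np.ndarray        # (n_atoms,) str
    chains: np.ndarray          # (n_atoms,) str
    coords: np.ndarray          # (n_atoms, 3) float, Å
    bfactors: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates in structure")
        self._validate_ordering()

    def _validate_ordering(self) -> None:
        for chain in self.chain_ids():
            resids = self.resids[self.chains == chain]
            # strictly increasing over residue boundaries
            boundaries = resids[np.r_[True, np.diff(resids) != 0]]
            if np.any(np.diff(boundaries) <= 0):
                raise ValidationError(
                    f"residue indices not strictly increasing in chain {chain}"
                )

    # -- residue-level views -------------------------------------------------

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.chains:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residues(self) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        prev = None
        for c, r in zip(self.chains, self.resids):
            key = (str(c), int(r))
            if key != prev:
                out.append(key)
                prev = key
        return out

    def axis_map(self) -> AxisMap:
        return AxisMap(self.residues())

    def atom_indices(self, chain: str, resid: int, names: Iterable[str] | None = None):
        mask = (self.chains == chain) & (self.resids == resid)
        if names is not None:
            mask &= np.isin(self.atom_names, list(names))
        return np.nonzero(mask)[0]

    def ca_indices(self) -> np.ndarray:
        """One Cα index per residue, in residue (serial) order."""
        idx = []
        for chain, resid in self.residues():
            ca = self.atom_indices(chain, resid, names=("CA",))
            if len(ca) != 1:
                raise ValidationError(
                    f"residue {chain}:{resid} has {len(ca)} CA atoms (need exactly 1)"
                )
            idx.append(ca[0])
        return np.asarray(idx, dtype=int)

    def backbone_indices(self, residues: Iterable[tuple[str, int]] | None = None):
        keys = set(residues) if residues is not None else None
        mask = np.isin(self.atom_names, BACKBONE_HEAVY)
        if keys is not None:
            inres = np.fromiter(
                ((str(c), int(r)) in keys for c, r in zip(self.chains, self.resids)),
                dtype=bool,
                count=self.n_atoms,
            )
            mask &= inres
        return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# topology spec


@dataclass
class TopologySpec:
    """Chain→protomer semantics, numbering offset, domain ranges, mutations.

    ``offset`` is model numbering minus human numbering (15 for the zebrafish
    structure vs the human protein). Domain ranges are inclusive, in model
    numbering, identical for both protomers.
    """

    chains: dict[str, str]                     # chain id -> protomer label
    offset: int
    domains: dict[str, tuple[int, int]]        # name -> (first, last) inclusive
    mutations: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.domains = {k: (int(a), int(b)) for k, (a, b) in self.domains.items()}
        ranges = sorted(self.domains.values())
        for (a, b) in ranges:
            if a > b:
                raise ValidationError(f"empty domain range {a}-{b}")
        for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
            if a2 <= b1:
                raise ValidationError("domain ranges overlap")
            if a2 != b1 + 1:
                raise ValidationError(f"gap between domains at {b1}..{a2}")
        for m in self.mutations:
            self.domain_of(m)  # raises if outside

    @property
    def span(self) -> tuple[int, int]:
        ranges = sorted(self.domains.values())
        return ranges[0][0], ranges[-1][1]

    def domain_of(self, position: int) -> str:
        for name, (a, b) in self.domains.items():
            if a <= position <= b:
                return name
        lo, hi = self.span
        raise RangeError(f"position {position} outside domain span {lo}-{hi}")

    # -- YAML round trip -----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "chains": dict(self.chains),
            "offset": int(self.offset),
            "domains": {k: [int(a), int(b)] for k, (a, b) in self.domains.items()},
            "mutations": [int(m) for m in self.mutations],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TopologySpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            chains=dict(data["chains"]),
            offset=int(data["offset"]),
            domains={k: (int(v[0]), int(v[1])) for k, v in data["domains"].items()},
            mutations=[int(m) for m in data.get("mutations", [])],
        )


def map_numbering(position: int, direction: str, topology: TopologySpec) -> int:
    """Convert between model and human numbering by the constant offset.

    ``direction`` is ``"model_to_human"`` or ``"human_to_model"``. The round
    trip is the identity. Positions outside the topology span raise
    :class:`RangeError`.
    """
    lo, hi = topology.span
    if direction == "model_to_human":
        if not (lo <= position <= hi):
            raise RangeError(f"model position {position} outside span {lo}-{hi}")
        return position - topology.offset
    if direction == "human_to_model":
        model = position + topology.offset
        if not (lo <= model <= hi):
            raise RangeError(f"human position {position} maps outside span {lo}-{hi}")
        return model
    raise ValueError(f"unknown direction {direction!r}")


def assign_domain(position: int, topology: TopologySpec) -> str:
    """Domain label (e.g. NTD/LMD/SMD/CTD) of a model-numbering position."""
    return topology.domain_of(position)


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM records; insertion codes and altlocs rejected)


def load_structure(path) -> StructureModel:
    """Parse ATOM records of a PDB file into a :class:`StructureModel`.

    Only the first MODEL is read. Altloc or insertion codes raise
    :class:`ParseError`; a polymer residue without exactly one Cα raises
    :class:`ValidationError`.
    """
    names, elements, resids, resnames, chains, coords, bfactors = (
        [], [], [], [], [], [], [])
    in_model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model += 1
                if in_model > 1:
                    break
                continue
            if rec == "ENDMDL":
                break
            if rec != "ATOM  ":
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: line {lineno}: truncated ATOM record")
            altloc = line[16]
            if altloc not in (" ", ""):
                raise ParseError(
                    f"{path}: line {lineno}: altloc '{altloc}' not supported"
                )
            icode = line[26]
            if icode not in (" ", ""):
                raise ParseError(
                    f"{path}: line {lineno}: insertion code '{icode}' not supported"
                )
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                resid = int(line[22:26])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            name = line[12:16].strip()
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _guess_element(name)
            try:
                bf = float(line[60:66])
            except (ValueError, IndexError):
                bf = 0.0
            names.append(name)
            elements.append(element)
            resids.append(resid)
            resnames.append(line[17:20].strip())
            chains.append(line[21])
            coords.append((x, y, z))
            bfactors.append(bf)
    if not names:
        raise ParseError(f"{path}: no ATOM records found")
    model = StructureModel(
        atom_names=np.array(names),
        elements=np.array(elements),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames),
        chains=np.array(chains),
        coords=np.array(coords, dtype=float),
        bfactors=np.array(bfactors, dtype=float),
    )
    _check_ca_presence(model)
    return model


def _guess_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if stripped[:1] in ("H",):
        return "H"
    return stripped[:1]


def _check_ca_presence(model: StructureModel) -> None:
    for chain, resid in model.residues():
        sel = (model.chains == chain) & (model.resids == resid)
        resname = model.resnames[sel][0]
        if resname not in _AA3:
            continue
        n_ca = int(np.sum(model.atom_names[sel] == "CA"))
        if n_ca != 1:
            raise ValidationError(
                f"polymer residue {chain}:{resid} ({resname}) has {n_ca} CA atoms"
            )


def write_structure(model: StructureModel, path, coords: np.ndarray | None = None,
                    bfactors: np.ndarray | None = None) -> None:
    """Write a StructureModel as a single-model PDB file."""
    xyz = model.coords if coords is None else np.asarray(coords, dtype=float)
    bf = bfactors if bfactors is not None else (
        model.bfactors if model.bfactors is not None else np.zeros(model.n_atoms))
    with open(path, "w") as fh:
        for i in range(model.n_atoms):
            name = model.atom_names[i]
            # PDB convention: 1-2 char names start in column 14
            pname = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                "ATOM  {serial:>5d} {name:4s} {res:<3s} {chain}{resid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          "
                "{el:>2s}\n".format(
                    serial=(i + 1) % 100000,
                    name=pname,
                    res=model.resnames[i],
                    chain=model.chains[i],
                    resid=model.resids[i],
                    x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                    occ=1.00, bf=bf[i], el=model.elements[i],
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Ordered, time-stamped coordinate frames congruent with a structure.

    Frame ``k`` of a freshly produced replica carries timestamp
    ``(k + 1) * spacing_ps`` — the convention under which a 300 ns run written
    every 10 ps holds exactly 30000 frames.
    """

    coords: np.ndarray            # (n_frames, n_atoms, 3)
    spacing_ps: float
    replica: str
    times_ps: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("trajectory coords must have shape (F, A, 3)")
        if self.spacing_ps <= 0:
            raise ValidationError("frame spacing must be positive")
        if self.times_ps is None:
            self.times_ps = (np.arange(self.n_frames) + 1) * float(self.spacing_ps)
        else:
            self.times_ps = np.asarray(self.times_ps, dtype=float)
            if len(self.times_ps) != self.n_frames:
                raise ValidationError("times_ps length != frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.spacing_ps / 1000.0


@dataclass
class MetaTrajectory:
    """Concatenated, superposed frames with per-frame provenance."""

    coords: np.ndarray                       # (n_frames, n_atoms, 3)
    provenance: list[tuple[str, int, float]]  # (replica, source_index, time_ps)
    reference: str                            # description of reference frame
    selection: np.ndarray                     # atom indices used for superposition

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def provenance_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("meta_index\treplica\tsource_index\ttime_ps\n")
            for i, (rep, src, t) in enumerate(self.provenance):
                fh.write(f"{i}\t{rep}\t{src}\t{t:g}\n")


def select_equilibrated(traj: Trajectory, discard_ns: float, stride: int) -> Trajectory:
    """Drop the leading ``discard_ns`` and keep every ``stride``-th frame.

    Frames with timestamp strictly greater than the discard time are retained;
    striding restarts at the first retained frame. Output spacing is
    ``spacing * stride``.
    """
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    discard_ps = float(discard_ns) * 1000.0
    keep = np.nonzero(traj.times_ps > discard_ps)[0]
    if len(keep) == 0:
        raise EmptySelectionError(
            f"discarding {discard_ns} ns leaves no frames "
            f"(trajectory covers {traj.total_time_ns} ns)"
        )
    keep = keep[::stride]
    return Trajectory(
        coords=traj.coords[keep],
        spacing_ps=traj.spacing_ps * stride,
        replica=traj.replica,
        times_ps=traj.times_ps[keep],
    )


# ---------------------------------------------------------------------------
# superposition (Kabsch)


def superpose(frame: np.ndarray, reference: np.ndarray,
              selection: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``frame`` onto ``reference``.

    The optimal rotation/translation is computed over ``selection`` (atom
    indices, identical meaning in both frames) and applied to *all* atoms.
    Returns the transformed frame and the RMSD over the selection.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise UnderdeterminedError(
            f"superposition needs >= 3 atoms, got {selection.size}")
    if frame.shape != reference.shape:
        raise ValidationError("frame and reference shapes differ")
    x = frame[selection]
    y = reference[selection]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    rot = _kabsch_rotation(x - xc, y - yc)
    moved = (frame - xc) @ rot.T + yc
    rmsd = float(np.sqrt(np.mean(np.sum((moved[selection] - y) ** 2, axis=1))))
    return moved, rmsd


def _kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing ||R p - q|| for centered point sets."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


# ---------------------------------------------------------------------------
# meta-trajectory assembly


def build_meta_trajectory(
    trajs: Sequence[Trajectory],
    structure: StructureModel,
    ss_classes: tuple[str, ...] = ("H", "G", "I", "E", "B"),
) -> MetaTrajectory:
    """Concatenate replicas and superpose every frame on a common reference.

    The reference is the first frame of the first replica; the fit selection
    is the backbone (N, CA, C, O) of residues assigned a helix or strand
    class in that reference frame. If the reference has fewer than one
    secondary-structure residue (possible for toy folds), the selection
    falls back to all backbone heavy atoms.
    """
    from .ss import assign_frame_ss  # local import to avoid a cycle

    if len(trajs) == 0:
        raise ValidationError("need at least one trajectory")
    n_atoms = structure.n_atoms
    for t in trajs:
        if t.n_atoms != n_atoms:
            raise ValidationError(
                f"replica {t.replica}: atom count {t.n_atoms} != structure {n_atoms}"
            )

    reference = trajs[0].coords[0]
    ss = assign_frame_ss(structure, reference)
    residues = structure.residues()
    ss_residues = [residues[i] for i, c in enumerate(ss) if c in ss_classes]
    selection = structure.backbone_indices(ss_residues) if ss_residues else np.array([], int)
    if selection.size < 3:
        selection = structure.backbone_indices()
    if selection.size < 3:
        raise ValidationError("structure has no backbone atoms to superpose on")

    frames = []
    provenance: list[tuple[str, int, float]] = []
    for t in trajs:
        for k in range(t.n_frames):
            moved, _ = superpose(t.coords[k], reference, selection)
            frames.append(moved)
            provenance.append((str(t.replica), k, float(t.times_ps[k])))
    return MetaTrajectory(
        coords=np.asarray(frames),
        provenance=provenance,
        reference=f"replica {trajs[0].replica} frame 0",
        selection=selection,
    )


# ---------------------------------------------------------------------------
# trajectory file I/O (DCD via MDAnalysis; multi-MODEL PDB natively)


def load_trajectory(topology_path, traj_path, spacing_ps: float,
                    replica: str = "1") -> Trajectory:
    """Read DCD/XTC (via MDAnalysis) or multi-MODEL PDB frames."""
    traj_path = Path(traj_path)
    if traj_path.suffix.lower() == ".pdb":
        coords = _read_multimodel_pdb(traj_path)
    else:
        import MDAnalysis as mda

        u = mda.Universe(str(topology_path), str(traj_path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
    return Trajectory(coords=coords, spacing_ps=spacing_ps, replica=replica)


def write_dcd(structure: StructureModel, traj: Trajectory, topology_path, out_path):
    """Write frames as DCD using MDAnalysis against the PDB topology."""
    import MDAnalysis as mda

    u = mda.Universe(str(topology_path))
    with mda.Writer(str(out_path), n_atoms=structure.n_atoms) as w:
        for k in range(traj.n_frames):
            u.atoms.positions = traj.coords[k]
            w.write(u.atoms)


def _read_multimodel_pdb(path) -> np.ndarray:
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ATOM  ":
                current.append((float(line[30:38]), float(line[38:46]),
                                float(line[46:54])))
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
    if current:
        frames.append(current)
    if not frames:
        raise ParseError(f"{path}: no frames found")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise ValidationError(f"{path}: inconsistent atom counts across MODELs")
    return np.asarray(frames, dtype=float)
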