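"""Distance-fluctuation matrices and mechanical connectivity.

The pairwise score is the population variance, over the meta-trajectory, of
the Cα–Cα distance of each residue pair: small values mark pairs that move
quasi-rigidly. A protein-wide threshold (mean local fluctuation, LF) and a
5 Å mean-distance gate turn the matrix into a per-residue connectivity count
η; mutant-vs-wild-type comparison yields Δη, a percentage difference matrix,
and per-position column projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InsufficientDataError, RangeError, ValidationError
from .topology import AxisMap, MetaTrajectory, StructureModel


@dataclass
class DFMatrix:
    """Symmetric residue-pair distance-variance matrix (Ų)."""

    values: np.ndarray
    axis: AxisMap
    source: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.axis), len(self.axis)):
            raise ValidationError("matrix shape does not match axis map")
        if not np.allclose(v, v.T):
            raise ValidationError("DF matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("DF diagonal must be exactly 0")
        if np.any(v < 0):
            raise ValidationError("DF entries must be non-negative")
        self.values = v


@dataclass
class MeanDistanceMatrix:
    """Frame-averaged Cα–Cα distances (Å), same axis map as the DF matrix."""

    values: np.ndarray
    axis: AxisMap

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.axis), len(self.axis)):
            raise ValidationError("matrix shape does not match axis map")
        self.values = v


@dataclass
class ConnectivityProfile:
    """Per-residue mechanical connectivity η with its defining threshold."""

    eta: np.ndarray            # (N,) int
    lf: float                  # scalar threshold, Ų
    lf_per_residue: np.ndarray
    gate: float                # Å
    axis: AxisMap


@dataclass
class DiffMatrix:
    """Mutant-minus-WT matrix; True in ``mask`` marks undefined entries."""

    values: np.ndarray
    mask: np.ndarray
    axis: AxisMap
    wt_source: str = ""
    mut_source: str = ""
    units: str = "%"


@dataclass
class PerResidueScalar:
    """A labeled per-residue track (η, Δη, P_mut, RMSF, ...)."""

    values: np.ndarray
    axis: AxisMap
    label: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.axis):
            raise ValidationError("track length does not match axis map")

    def to_tsv(self, path, topology=None) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresid_model\tresid_human\tdomain\tvalue\n")
            for (chain, resid), v in zip(self.axis.residues, self.values):
                human = resid - topology.offset if topology else ""
                try:
                    domain = topology.domain_of(resid) if topology else ""
                except Exception:
                    domain = ""
                val = "" if np.isnan(v) else f"{v:.6g}"
                fh.write(f"{chain}\t{resid}\t{human}\t{domain}\t{val}\n")


# ---------------------------------------------------------------------------
# DF computation (single streaming pass over frames)


def compute_df(meta: MetaTrajectory, structure: StructureModel,
               source: str = "") -> tuple[DFMatrix, MeanDistanceMatrix]:
    """Population variance and mean of all pairwise Cα distances.

    Streams frame by frame (Welford update on the condensed distance vector),
    so memory scales with the number of residue pairs, not frames.
    """
    if meta.n_frames < 2:
        raise InsufficientDataError(
            f"DF needs >= 2 frames, got {meta.n_frames}")
    ca_idx = structure.ca_indices()
    axis = structure.axis_map()

    mean = None
    m2 = None
    count = 0
    for k in range(meta.n_frames):
        d = pdist(meta.coords[k, ca_idx, :])
        count += 1
        if mean is None:
            mean = d.copy()
            m2 = np.zeros_like(d)
        else:
            delta = d - mean
            mean += delta / count
            m2 += delta * (d - mean)
    var = m2 / count  # population variance
    np.maximum(var, 0.0, out=var)
    df = DFMatrix(values=squareform(var), axis=axis, source=source)
    dist = MeanDistanceMatrix(values=squareform(mean), axis=axis)
    return df, dist


# ---------------------------------------------------------------------------
# LF threshold


def local_fluctuation_threshold(df: DFMatrix, mode: str = "window",
                                ) -> tuple[float, np.ndarray]:
    """Mean local fluctuation threshold and the per-residue values behind it.

    ``mode="window"`` averages DF over the up-to-four same-chain sequence
    neighbors at offsets ±1 and ±2 (clipped at termini); ``mode="exact"``
    uses only the residues at offsets ±2.
    """
    if mode not in ("window", "exact"):
        raise ValueError(f"unknown LF mode {mode!r}")
    offsets = (-2, -1, 1, 2) if mode == "window" else (-2, 2)
    axis = df.axis
    n = len(axis)
    serial = {key: i for i, key in enumerate(axis.residues)}
    lf_i = np.full(n, np.nan)
    chain_len = {}
    for c, _ in axis.residues:
        chain_len[c] = chain_len.get(c, 0) + 1
    for c, ln in chain_len.items():
        if ln < 3:
            raise ValidationError(f"chain {c} shorter than 3 residues")
    for i, (chain, resid) in enumerate(axis.residues):
        vals = [df.values[i, serial[(chain, resid + o)]]
                for o in offsets if (chain, resid + o) in serial]
        if not vals:
            raise ValidationError(f"residue {chain}:{resid} has no sequence neighbors")
        lf_i[i] = float(np.mean(vals))
    return float(np.mean(lf_i)), lf_i


# ---------------------------------------------------------------------------
# connectivity


def connectivity_profile(df: DFMatrix, dist: MeanDistanceMatrix,
                         lf: float | None = None, gate: float = 5.0,
                         lf_mode: str = "window") -> ConnectivityProfile:
    """Count, per residue, partners farther than ``gate`` Å with DF below LF.

    Both gates are strict inequalities; pairs may span protomers. When ``lf``
    is not supplied it is computed from ``df`` with ``lf_mode``.
    """
    if df.axis != dist.axis:
        raise ValidationError("DF and mean-distance matrices use different axes")
    if lf is None:
        lf, lf_i = local_fluctuation_threshold(df, mode=lf_mode)
    else:
        _, lf_i = local_fluctuation_threshold(df, mode=lf_mode)
    connected = (dist.values > gate) & (df.values < lf)
    np.fill_diagonal(connected, False)
    eta = connected.sum(axis=1).astype(int)
    return ConnectivityProfile(eta=eta, lf=float(lf), lf_per_residue=lf_i,
                               gate=float(gate), axis=df.axis)


def delta_connectivity(mut: ConnectivityProfile,
                       wt: ConnectivityProfile) -> PerResidueScalar:
    """Δη = η_mut − η_WT, each profile thresholded by its own system's LF."""
    if mut.axis != wt.axis:
        raise ValidationError("connectivity profiles use different axes")
    return PerResidueScalar(values=(mut.eta - wt.eta).astype(float),
                            axis=mut.axis, label="delta_eta")


def percent_delta_df(mut: DFMatrix, wt: DFMatrix,
                     floor: float = 1e-6) -> DiffMatrix:
    """100 × (DF_mut − DF_WT) / DF_WT, masked where DF_WT is below ``floor``.

    Positive entries mark pairs losing mechanical coordination in the mutant,
    negative entries pairs gaining it. The diagonal is always masked.
    """
    if mut.axis != wt.axis:
        raise ValidationError("DF matrices use different axes")
    mask = wt.values < floor
    np.fill_diagonal(mask, True)
    values = np.zeros_like(wt.values)
    np.divide(mut.values - wt.values, wt.values, out=values, where=~mask)
    values *= 100.0
    values[mask] = np.nan
    return DiffMatrix(values=values, mask=mask, axis=wt.axis,
                      wt_source=wt.source, mut_source=mut.source)


def project_column(diff: DiffMatrix, position: tuple[str, int],
                   protomer_label: str | None = None) -> PerResidueScalar:
    """Extract the difference-matrix column at a mutated position.

    The track is labeled ``P_mut<protomer>`` from the position's chain (or an
    explicit ``protomer_label``); masked entries become NaN and propagate.
    """
    chain, resid = position
    idx = diff.axis.index(chain, resid)
    col = diff.values[:, idx].copy()
    col[diff.mask[:, idx]] = np.nan
    label = f"P_mut{protomer_label or chain}"
    return PerResidueScalar(values=col, axis=diff.axis, label=label)


# ---------------------------------------------------------------------------
# matrix export


def matrix_to_tsv(values: np.ndarray, axis: AxisMap, path,
                  mask: np.ndarray | None = None, fmt: str = "%.6g") -> None:
    """Dense TSV with chain:resid labels; masked cells exported empty."""
    labels = axis.labels()
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            cells = []
            for j in range(len(labels)):
                if (mask is not None and mask[i, j]) or np.isnan(values[i, j]):
                    cells.append("")
                else:
                    cells.append(fmt % values[i, j])
            fh.write(lab + "\t" + "\t".join(cells) + "\n")
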