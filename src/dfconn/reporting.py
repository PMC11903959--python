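"""Domain aggregation, B-factor projection and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptors, fluctuations
from .errors import RangeError, ValidationError
from .fluctuations import PerResidueScalar
from .topology import (
    StructureModel,
    TopologySpec,
    build_meta_trajectory,
    load_structure,
    load_trajectory,
    select_equilibrated,
    write_structure,
)

log = logging.getLogger("dfconn")


# ---------------------------------------------------------------------------
# domain aggregation


def aggregate_by_domain(track: PerResidueScalar,
                        topology: TopologySpec) -> pd.DataFrame:
    """Mean/sum/count of a per-residue track per (protomer, domain).

    Masked (NaN) residues are excluded from mean and sum and tallied in
    ``n_masked``. A residue outside every domain range raises RangeError.
    """
    rows = {}
    for (chain, resid), value in zip(track.axis.residues, track.values):
        protomer = topology.chains.get(chain, chain)
        domain = topology.domain_of(resid)  # raises RangeError outside span
        key = (protomer, domain)
        rows.setdefault(key, []).append(value)
    records = []
    for (protomer, domain), vals in sorted(rows.items()):
        arr = np.asarray(vals, dtype=float)
        good = arr[~np.isnan(arr)]
        records.append({
            "protomer": protomer,
            "domain": domain,
            "mean": float(good.mean()) if len(good) else np.nan,
            "sum": float(good.sum()),
            "count": int(len(good)),
            "n_masked": int(np.isnan(arr).sum()),
        })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# B-factor projection


def write_bfactor_pdb(structure: StructureModel, track: PerResidueScalar,
                      path) -> None:
    """Write the track into the B-factor column of every atom of each residue.

    Values must fit the fixed-width %6.2f column (|v| <= 999.99); masked
    residues get 0.00 and are listed in a ``<path>.masked.tsv`` sidecar.
    """
    values = {key: v for key, v in zip(track.axis.residues, track.values)}
    bf = np.zeros(structure.n_atoms)
    masked: list[tuple[str, int]] = []
    for chain, resid in structure.residues():
        v = values.get((chain, resid), np.nan)
        if np.isnan(v):
            masked.append((chain, resid))
            v = 0.0
        elif abs(v) > 999.99:
            raise ValidationError(
                f"value {v:g} at {chain}:{resid} exceeds the B-factor column "
                "width; rescale the track before writing")
        idx = structure.atom_indices(chain, resid)
        bf[idx] = round(v, 2)
    write_structure(structure, path, bfactors=bf)
    sidecar = Path(str(path) + ".masked.tsv")
    with open(sidecar, "w") as fh:
        fh.write("chain\tresid\n")
        for chain, resid in masked:
            fh.write(f"{chain}\t{resid}\n")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class SystemInput:
    """One simulated system: topology PDB + per-replica trajectory files."""

    name: str
    topology_pdb: str
    trajectories: list[str]
    spacing_ps: float = 10.0


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs, mirroring the CLI flags."""

    systems: list[SystemInput]
    topology_spec: TopologySpec
    out_dir: str
    discard_ns: float = 100.0
    stride: int = 5
    gate: float = 5.0
    lf_mode: str = "window"
    pct_floor: float = 1e-6
    hbond_dist: float = 3.0
    hbond_angle: float = 135.0
    run_descriptors: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.systems:
            raise ValidationError("no systems declared")
        for sys_in in self.systems:
            if not Path(sys_in.topology_pdb).exists():
                raise ValidationError(f"missing topology: {sys_in.topology_pdb}")
            for t in sys_in.trajectories:
                if not Path(t).exists():
                    raise ValidationError(f"missing trajectory: {t}")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.gate <= 0:
            raise ValidationError("distance gate must be positive")


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis and write all tables + a checksum manifest.

    One system: DF/LF/η + descriptors. Two systems: the first is treated as
    wild type, the second as mutant, adding Δη, the percentage difference
    matrix and per-mutation column projections.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.topology_spec

    per_system = {}
    for sys_in in config.systems:
        t0 = time.time()
        structure = load_structure(sys_in.topology_pdb)
        trajs = [
            select_equilibrated(
                load_trajectory(sys_in.topology_pdb, p, sys_in.spacing_ps,
                                replica=str(i + 1)),
                config.discard_ns, config.stride)
            for i, p in enumerate(sys_in.trajectories)
        ]
        meta = build_meta_trajectory(trajs, structure)
        log.info("stage=meta system=%s frames=%d atoms=%d wall=%.2fs",
                 sys_in.name, meta.n_frames, meta.n_atoms, time.time() - t0)

        t0 = time.time()
        df, dist = fluctuations.compute_df(meta, structure, source=sys_in.name)
        profile = fluctuations.connectivity_profile(
            df, dist, gate=config.gate, lf_mode=config.lf_mode)
        log.info("stage=df system=%s N=%d LF=%.4f wall=%.2fs",
                 sys_in.name, len(df.axis), profile.lf, time.time() - t0)

        prefix = out / sys_in.name
        fluctuations.matrix_to_tsv(df.values, df.axis, f"{prefix}_df.tsv")
        fluctuations.matrix_to_tsv(dist.values, dist.axis, f"{prefix}_meand.tsv")
        df.axis.to_tsv(f"{prefix}_axis.tsv")
        eta_track = PerResidueScalar(values=profile.eta.astype(float),
                                     axis=df.axis, label="eta")
        eta_track.to_tsv(f"{prefix}_eta.tsv", topology=spec)
        aggregate_by_domain(eta_track, spec).to_csv(
            f"{prefix}_eta_by_domain.tsv", sep="\t", index=False)

        if config.run_descriptors:
            t0 = time.time()
            rmsf = descriptors.compute_rmsf(meta, structure)
            rmsf.to_tsv(f"{prefix}_rmsf.tsv", topology=spec)
            ssf = descriptors.ss_frequency(meta, structure)
            ssf.to_tsv(f"{prefix}_ss.tsv")
            mut_residues = {(c, m) for m in spec.mutations for c in spec.chains}
            try:
                bonds = descriptors.hbond_occupancy(
                    meta, structure, selection=mut_residues or None,
                    dist_cut=config.hbond_dist, angle_cut=config.hbond_angle)
                descriptors.hbond_table_tsv(bonds, f"{prefix}_hbonds.tsv")
            except Exception as exc:  # topology without hydrogens
                log.warning("stage=hbond system=%s skipped: %s", sys_in.name, exc)
            log.info("stage=descriptors system=%s wall=%.2fs",
                     sys_in.name, time.time() - t0)

        per_system[sys_in.name] = (structure, df, dist, profile)

    if len(config.systems) >= 2:
        wt_name = config.systems[0].name
        mut_name = config.systems[1].name
        structure, df_wt, _, prof_wt = per_system[wt_name]
        _, df_mut, _, prof_mut = per_system[mut_name]
        delta = fluctuations.delta_connectivity(prof_mut, prof_wt)
        delta.to_tsv(out / "delta_eta.tsv", topology=spec)
        aggregate_by_domain(delta, spec).to_csv(
            out / "delta_eta_by_domain.tsv", sep="\t", index=False)
        pct = fluctuations.percent_delta_df(df_mut, df_wt, floor=config.pct_floor)
        fluctuations.matrix_to_tsv(pct.values, pct.axis,
                                   out / "pct_delta_df.tsv", mask=pct.mask)
        for m in spec.mutations:
            for chain in spec.chains:
                proj = fluctuations.project_column(pct, (chain, m))
                proj.to_tsv(out / f"P_mut{chain}_{m}.tsv", topology=spec)
                # percentage columns can exceed the %6.2f B-factor width;
                # rescale by a power of ten and log the factor
                scaled = proj
                peak = np.nanmax(np.abs(proj.values)) if np.any(
                    ~np.isnan(proj.values)) else 0.0
                if peak > 999.99:
                    decades = int(np.ceil(np.log10(peak / 999.99)))
                    scaled = PerResidueScalar(
                        values=proj.values / 10 ** decades,
                        axis=proj.axis, label=proj.label)
                    log.info("stage=bfactor track=%s scale=1e-%d",
                             proj.label, decades)
                write_bfactor_pdb(structure, scaled,
                                  out / f"P_mut{chain}_{m}.pdb")

    manifest = _build_manifest(out, config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ReportBundle(out_dir=out, manifest=manifest)


def _build_manifest(out: Path, config: AnalysisConfig) -> dict:
    files = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(out))] = _sha256(p)
    return {
        "files": files,
        "parameters": {
            "discard_ns": config.discard_ns,
            "stride": config.stride,
            "gate": config.gate,
            "lf_mode": config.lf_mode,
            "pct_floor": config.pct_floor,
            "hbond_dist": config.hbond_dist,
            "hbond_angle": config.hbond_angle,
            "seed": config.seed,
        },
        "systems": [s.name for s in config.systems],
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
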