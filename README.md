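# dfconn

Distance-fluctuation connectivity analysis of homodimeric protein MD
ensembles: from raw replica trajectories to per-residue mechanical
connectivity profiles, mutant-vs-wild-type difference maps, and the
supporting per-residue descriptors (backbone RMSF, hydrogen-bond occupancy,
8-class secondary-structure frequencies, relative solvent accessibility).

The pairwise score is the population variance, over an ensemble, of the
Cα–Cα distance of every residue pair ("DF"). Pairs farther than 5 Å on
average yet with DF below the protein-wide mean local fluctuation (LF) are
*mechanically connected*; the per-residue count of such partners is the
connectivity index η. Comparing two systems yields Δη, a percentage DF
difference matrix, and per-position column projections (`P_mut`) mappable
onto the structure via the B-factor column.

Because production MD trajectories are rarely redistributable, the package
ships a first-class synthetic generator: a toy two-protomer structure, a
distance-cutoff spring graph over its Cα sites, and Gaussian ensembles whose
displacement covariance is the pseudo-inverse of the weighted Kirchhoff
matrix — so every statistic has a closed-form or brute-force oracle, and
"mutations" are realized as local perturbations of coupling strengths.

## Layout

| module                | contents |
|-----------------------|----------|
| `dfconn.topology`     | PDB/DCD I/O, numbering & domain semantics, frame selection, Kabsch superposition, meta-trajectory assembly |
| `dfconn.synthetic`    | toy dimer builder, ideal-peptide builder, spring graphs, GNM-style ensemble sampling, fixture bundles |
| `dfconn.fluctuations` | DF & mean-distance matrices, LF threshold, η, Δη, %ΔDF, column projections |
| `dfconn.descriptors`  | RMSF, H-bond occupancy (3.0 Å / 135° gates), Kabsch–Sander SS frequencies, Shrake–Rupley relative SASA |
| `dfconn.reporting`    | domain aggregation, B-factor PDB export, end-to-end pipeline with manifest |
| `dfconn.cli`          | `dfconn` command-line interface |

## CLI

```sh
# one-command synthetic demo: fixtures + WT-vs-mutant comparison
dfconn demo --out scratch/demo --seed 0

# generate fixture bundles only
dfconn fixtures --out scratch/fx --residues 40 --replicas 3 --frames 300 \
    --seed 0 --mutate 20

# analyze a real system (PDB topology + DCD/XTC replicas + YAML config)
dfconn analyze --topology topo.pdb --trajectory rep1.dcd --trajectory rep2.dcd \
    --config topology.yaml --out report/ --discard-ns 100 --stride 5

# mutant vs wild type
dfconn compare --wt-topology wt.pdb --wt-trajectory wt1.dcd \
    --mut-topology mut.pdb --mut-trajectory mut1.dcd \
    --config topology.yaml --out report/
```

The topology config (YAML) declares chain→protomer labels, the constant
model↔human numbering offset, inclusive domain ranges and mutated positions:

```yaml
chains: {A: A, B: B}
offset: 15
domains:
  NTD: [85, 310]
  LMD: [311, 470]
  SMD: [471, 586]
  CTD: [587, 719]
mutations: [615]
```

Outputs are TSV matrices/tracks with `chain:resid` labels, an axis-map TSV,
per-domain aggregate tables, B-factor-encoded PDB projections, and a
`manifest.json` with SHA-256 checksums (re-running an identical config
reproduces identical checksums).

## Conventions

- Residues are identified by `(chain, resid)` with 1-based PDB numbering;
  matrices carry a serial↔residue axis map.
- Frame `k` of a production replica is stamped `(k+1) × spacing`; discarding
  keeps frames with time strictly greater than the cutoff, and striding
  restarts at the first retained frame.
- DF uses the population (1/M) variance. Both connectivity gates are strict
  inequalities. The LF neighborhood is the inclusive ±2 window by default
  (`--lf-mode exact` uses only the residues at ±2).
- %ΔDF is masked (exported as empty cells, never ±inf) wherever the
  wild-type DF falls below a floor (default 1e-6 Ų).
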