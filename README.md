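# chaintrace

De novo backbone tracing and ligand/water detection for near-atomic-resolution
cryoEM-style density maps, exercisable end-to-end on synthetic data.

The tracing pipeline reduces above-threshold density to a fixed number of
pseudoatoms (CA surrogates), solves a traveling-salesperson problem over them
to propose a backbone path, and refines the path against protein-geometry
constraints. A decoy-ensemble mode re-traces the map across a bracket of
density thresholds and a schedule of positional-noise levels, averages the
resulting paths, and writes a per-residue connectivity probability (percent)
into the B-factor column of a CA-only PDB — 100 (stable, shown blue in most
viewers) through 75 (white) down to 50 or below (red). A companion tool masks
the protein model out of the map, seeds the residual density, filters
candidates by model distance and half-map voxel consistency, mean-shift
clusters the survivors, and classifies clusters as waters/ions or ligands.

## Layout

| module | contents |
| --- | --- |
| `chaintrace.map_core` | MRC/CCP4 I/O (axis-order normalized), Gaussian low-pass filter, model masking, half-map consistency masks |
| `chaintrace.fixtures` | synthetic ground truth: CA traces (helix / strand / helix-turn-helix / random-walk), simulated maps, half-map pairs, planted ligands/waters/inconsistent blobs |
| `chaintrace.pseudoatoms` | density-to-points reduction (kmeans / sc / ac / ms / gmm), positional perturbation, CA-only PDB round-trip |
| `chaintrace.path_solver` | edge matrices (optionally density-weighted), exact TSP for small n plus deterministic greedy/2-opt/Or-opt/ILS, cycle-to-path cutting, iterative refinement |
| `chaintrace.prob_model` | decoy ensembles, optimal node correspondence, average model, connectivity probabilities, B-factor-encoded PDB output |
| `chaintrace.threading` | forward/backward sequence threading scored against local density, simple all-atom (N, C, O, CB) construction |
| `chaintrace.ligand_finder` | residual-density seeding, filtering, clustering, water/ligand classification, 2 PDB + 2 MRC outputs, template fit scoring |
| `chaintrace.cli` | the two command-line entry points and the full-pipeline helpers |

## CLI

Backbone tracing (`map` `threshold` `nres` are positional):

```sh
chaintrace map.mrc 0.35 120 \
    --seq_file seq.txt --reverse --all_atom \
    --prob_model --bracket 0.3,0.4,0.05 --tsp_runs 0 --tsp_runs 1.5 \
    --seed 1 --out_prefix run1
```

Key options (defaults in parentheses): `--pa_type` (kmeans), `--noise` (0),
`--map_weight` (off), `--filt` (off, 4.5 A low-pass when set), `--or_time`
(30 s TSP cap), `--pa_file` to load a precomputed CA-only model instead of
seeding.

Ligand/water detection:

```sh
chaintrace-ligands map.mrc model.pdb 0.3 \
    --half1 half1.mrc --half2 half2.mrc \
    --bandwidth_weight 10 --model_dist 5 --half_thresh 0.5 \
    --out_prefix lig
```

writes `lig_waters.pdb`, `lig_ligands.pdb`, `lig_waters.mrc`,
`lig_ligands.mrc`. Use `--bandwidth_weight` above 30 for finer
(higher-resolution) maps.

A single `--seed` governs every stochastic stage; identical configurations
produce byte-identical coordinate output.

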