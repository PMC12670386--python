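# trajsite

Receptor–ligand trajectory analysis toolkit for membrane-receptor binding
studies: rigid-body superposition metrics (RMSD, region-attributed
"RMSD share", per-residue RMSF), diketone-ligand conformer classification
and clustering, docking search-box construction and pose statistics,
residue–ligand contact occupancy/retention, and computational alanine-scan
contact-loss reporting — plus a synthetic-data generator that produces toy
receptor–ligand systems with fully configured ground truth so every
statistic in the pipeline is testable offline.

## Layout

| module | what it does |
| --- | --- |
| `trajsite.core` | atoms/topology/trajectory data model, PDB/GRO and plain-frames I/O, residue-range region annotation, frame sampling |
| `trajsite.superpose` | Kabsch superposition, RMSD series with fit/measure selections, RMSD-share attribution (`100×(1−RMSD_excl/RMSD_full)`), per-residue RMSF |
| `trajsite.conformer` | O–O distance descriptor, cis/trans classification (cis iff d ≤ 0.32 nm), aligned-coordinate PCA, k-means, medoid centroid conformers |
| `trajsite.docking` | principal-axis rotation, two-centroid docking-box construction (15×15×25 Å default), PDBQT-style pose I/O, affinity filters, representative-pose selection (mean Jaccard of contact sets) |
| `trajsite.contacts` | 4 Å residue contacts (KD-tree fast path + brute-force oracle), interaction probability, conserved-contact retention, hydrophobic C–C and geometric H-bond occurrences |
| `trajsite.alascan` | alanine side-chain truncation, position/site contact-loss metrics, external energy-table summaries |
| `trajsite.synth` | deterministic synthetic receptors, trajectories and pose sets with known occupancies, cis fraction, mobile regions and contact sets |
| `trajsite.cli` | `trajsite` command: simulate / unbound / ligand / dockprep / posestats / complex / alascan / report |

Units are nm and ns internally; Å appears only at PDB/PDBQT boundaries and
in docking-box output (the docking-engine convention).

## CLI

Every stage is driven by one YAML config (thresholds, region ranges,
windows, seeds; see `trajsite.config.DEFAULT_CONFIG`) and writes TSV tables
plus a deterministic `summary_<stage>.json`:

```sh
trajsite simulate  -c config.yaml -o out      # synthetic system + poses
trajsite unbound   -c config.yaml -o out      # RMSD / share / RMSF tables
trajsite ligand    -c config.yaml -o out      # O-O distances, PCA, clusters
trajsite dockprep  -c config.yaml -o out      # rotated structure + Vina box
trajsite posestats -c config.yaml -o out      # affinity filter, contact stats
trajsite complex   -c config.yaml -o out      # retention + occupancy + cis
trajsite alascan   -c config.yaml -o out      # WT-vs-mutant contact losses
trajsite report    -c config.yaml -o out      # merge stage summaries
```

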