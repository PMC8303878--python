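# confcube

Detection and thermodynamic ranking of conformational states across large
ensembles of short molecular-dynamics replicas.

A common design for studying fast, field-driven conformational changes (for
example a voltage-sensing domain, VSD, under a nanosecond pulsed electric
field) is to branch many independent replicas from one equilibrated
structure and let each relax into whatever final state it reaches. The
question then becomes: *how many distinct conformational states did the
ensemble visit, and what are their relative free energies?* `confcube`
implements a complete analysis pipeline for that question, exercised
end-to-end on a synthetic trajectory generator with planted, known basins so
every stage is testable without running any MD.

## Method

For the `F` frames pooled from all stability-screened replicas the package
builds the **tuple cube**: one triple per ordered frame pair (X, Y),

```
tuple(X, Y) = ( RMSD_XY , Φ_0X , Φ_0Y )
```

where `RMSD_XY` is the least-squares-fit (Kabsch) RMSD between the two
frames and `Φ_0X` is the fraction of native contacts of frame X relative to
the initial frame of its replica. The cube holds exactly `F²` entries, each
with full frame provenance. K-means (Lloyd's algorithm, with the number of
clusters `k` chosen by the elbow of the explained-variance curve) partitions
the cube into states; interpreting each cluster's tuple count `P_i` as an
occupancy, the standard free-energy difference between states is the
Boltzmann population ratio

```
ΔG°(i, j) = −R T ln(P_i / P_j),   R = 8.314 J mol⁻¹ K⁻¹.
```

Each cluster's representative conformation is the source frame of the tuple
closest to the maximum of a Gaussian kernel density estimate over the
cluster, and is characterized by radius of gyration, Shrake–Rupley SASA,
α-helix content and named residue distances. A membrane module measures
bilayer thickness `d` (z-separation of the leaflet phosphate-marker centres
of mass) and estimates the transmembrane potential `ΔV = E·d` for an applied
field `E`.

## Worked example

Generate a synthetic 4-basin ensemble (10 replicas, 8 frames each) plus a
toy bilayer, then run the full pipeline:

```
confcube simulate --out demo --n-replicas 10 --frames 8 \
    --switch-frame 2 --seed 7 --dt-ps 2000
cat > demo/config.yaml <<EOF
manifest: demo/manifest.txt
bilayer_pdb: demo/bilayer.pdb
output_dir: demo/run
field_V_per_nm: 0.2
stability_tolerance_nm: 0.08
lowess_frac: 0.5
fixed_k: 4
n_restarts: 5
seed: 7
EOF
confcube all --config demo/config.yaml
```

The run directory then contains, among other provenance-stamped artifacts,
`report.md` with:

* bilayer summary `Mean thickness: 3.882 +/- 0.031 nm` — the generator
  planted 3.883 nm, and with `field_V_per_nm: 0.2` this gives
  ΔV = 0.2 × 3.882 ≈ 0.78 V;
* a 10 × 10-replica stability screen (all selected here), an 80-frame tuple
  cube of 6400 tuples, and four clusters of 2128 / 2016 / 1584 / 672 tuples;
* the pairwise free-energy table (J/mol), e.g. ΔG°(1,2) = −139.3 and
  ΔG°(1,4) = −2970.8 — the gap between the two largest states is far below
  thermal energy (RT ≈ 2577 J/mol at 310 K), i.e. they interconvert freely
  on the sampled timescale;
* a characterization table: the compact states show ~90 % helix content and
  RGyr ≈ 1.78 nm while the displaced/unfolded state jumps to RGyr ≈ 3.07 nm
  with the planted residue-distance increase (12.3 Å → 91.5 Å for the
  10–140 pair).

The same stages are available as library calls (`confcube.cube`,
`confcube.cluster` with sklearn-style `TupleKMeans` / `ElbowKMeans`
estimators) for use in notebooks and pipelines.

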