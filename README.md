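# chemspace3d

Chemical space mapping for small-molecule libraries: standardize an SDF or
SMILES library, compute five molecular fingerprints, project them to 3D by
PCA, bin the projection onto a color-coded 300³ grid, search nearest
neighbors in the original fingerprint spaces, and export a portable 3D
scene (JSON + self-contained HTML viewer).

## Fingerprints

| kind  | length | describes     | components                                              |
|-------|--------|---------------|---------------------------------------------------------|
| mqn   | 42     | constitution  | atom/bond/polarity/topology counts                      |
| smifp | 34     | structure     | character counts of the canonical SMILES                |
| apfp  | 20     | shape         | atom pairs per topological distance 1–20, / HAC         |
| xfp   | 55     | pharmacophore | category atom pairs per distance 0–10, 5 blocks         |
| sfp   | 1024   | substructure  | hashed linear paths of 1–7 bonds, binary                |

Scalar fingerprints are compared with the city-block distance, `sfp` with
the Tanimoto coefficient.

## CLI

```bash
# deterministic synthetic library (no download needed)
chemspace3d --seed 7 fixtures --n 500 --out library.smi

# full pipeline: standardize -> fingerprint -> PCA -> grid -> color -> export
chemspace3d run --in library.smi --out-dir out/ --fp mqn --descriptor ring_count

# individual stages
chemspace3d prepare --in library.smi --out clean.smi --rejections rej.tsv
chemspace3d fingerprint --kind mqn --in clean.smi --out mqn.csv
chemspace3d project --in mqn.csv --k 3 --model-out model.json --coords-out coords.csv
chemspace3d grid --coords coords.csv --n-bins 300 --out grid.json
chemspace3d search --library clean.smi --query "CCOc1ccccc1" --fp mqn --k 10

# overlay up to 1000 external molecules into the fitted space
chemspace3d run --in library.smi --out-dir out/ --overlay externals.smi
```

`run` writes `standardized.smi`, `rejections.tsv`, `fingerprints.csv`,
`model.json`, `coords.csv`, `grid.json`, `scene.json`, `scene.html`,
`diagnostics.json` (variance coverage per k, projected-vs-original distance
correlation, single-occupancy fractions) and `run.log`. Open `scene.html`
in any browser — it is self-contained, no network access needed.

## Standardization rules

Valence check (RDKit sanitization), counterion removal (keep the largest
fragment by heavy-atom count; ties by mass, then canonical SMILES),
rule-based pH 7.4 charging (deprotonate carboxylic/sulfonic/sulfinic
acids, one phosphate proton, tetrazoles; protonate aliphatic amines,
amidines, guanidines), removal of molecules above 50 heavy atoms, and
deduplication on the stereo-aware canonical SMILES.

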