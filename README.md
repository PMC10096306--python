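# bicompdta

Drug–target binding-affinity regression from a **bi-measure protein
encoding**: every protein is represented by its similarities to a
reference panel, where each similarity is the product of two independent
channels — a normalized Smith–Waterman local-alignment score and a
compression-based similarity (1 − normalized compression distance under
LZMA). Alignment captures positional homology; compression captures
repeat structure and global composition that alignment misses. Ligands
are label-encoded SMILES strings fed through a small convolutional
branch whose final layer is a depthwise-separable convolution (6.4×
fewer weights than a standard one at the same width). The two branches
feed a fully connected head that predicts affinity (e.g. pKd).

The network is implemented in pure NumPy with manual backpropagation —
no deep-learning framework is needed — and every run is bit-reproducible
from its seed.

## Worked example

```python
from bicompdta.synthetic import SyntheticSpec, generate_dataset
from bicompdta.encoder import BiCompProteinEncoder
from bicompdta.pipeline import run_experiment

# A small synthetic dataset with 3 planted protein families.
spec = SyntheticSpec(n_families=3, members_per_family=4, protein_length=120,
                     n_ligands=8, seed=42)
ds, truth = generate_dataset(spec)
print(f"{len(ds.proteins)} proteins, {len(ds.ligands)} ligands, {len(ds.records)} affinities")

# The combined similarity separates families sharply.
enc = BiCompProteinEncoder().fit(ds.proteins)
vec = enc.transform([ds.proteins[0]])[0]
print("  same family:", [round(float(v), 3) for v in vec[:4]])
print("  other family:", [round(float(v), 3) for v in vec[4:8]])

# Train and evaluate on one warm fold.
result = run_experiment({
    "data": {"synthetic": {"n_families": 3, "members_per_family": 6,
                           "protein_length": 120, "n_ligands": 16, "seed": 42}},
    "split": {"mode": "warm", "n_folds": 5, "max_folds": 1},
    "model": {"epochs": 15},
})
m = result["metrics"]
print(f"CI={m['ci']:.3f}  MSE={m['mse']:.3f}  rm2={m['rm2']:.3f}  AUPR={m['aupr']:.3f}")
```

Output (deterministic):

```
12 proteins, 8 ligands, 96 affinities
  same family: [1.0, 0.388, 0.426, 0.432]
  other family: [0.012, 0.012, 0.012, 0.011]
CI=0.858  MSE=0.206  rm2=0.950  AUPR=1.000
```

In-family similarities (~0.4 off-diagonal) stand far above between-family
ones (~0.01), and the trained model ranks held-out pairs well above
chance.

## Command line

```bash
bicompdta synth --seed 0 --out data/          # generate a synthetic dataset
bicompdta encode ...                          # similarity matrices / vectors
bicompdta split ...                           # warm / cold fold manifests
bicompdta train ... / evaluate ...            # fit and score a model
bicompdta ablate ...                          # product vs sw_only vs ncd_only
bicompdta straw ...                           # shuffled-label controls
bicompdta report ...                          # summarize a results directory
```

Run `bicompdta <command> --help` for options. Experiments are configured
by YAML/dict overrides merged over `bicompdta.pipeline.reference_config()`.

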