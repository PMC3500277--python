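# ssescore

Knowledge-based energy potentials for protein models reduced to idealized
secondary structure elements (SSEs). Models keep only their helices and
strands; every residue is represented by a single side-chain anchor point
(C-beta, H-alpha2 for glycine). Twelve scoring terms — eight statistical
potentials derived by inverse-Boltzmann conversion of training-set feature
histograms, three clash/closure penalty terms, and a secondary-structure
prediction agreement score — combine into a weighted consensus energy that
enriches for native-like SSE arrangements in decoy sets.

## What is in the box

| module | contents |
| --- | --- |
| `ssescore.model_io` | PDB parsing (Biopython-backed), anchor resolution, SSE fragment decomposition, `.ss2` prediction files |
| `ssescore.packing_geometry` | shortest connection between fragment axes, contact weight, twist dihedral, offset angles, interaction-weight pair selection |
| `ssescore.statistics_builder` | histograms → energy tables (inverse Boltzmann, per-term backgrounds and pseudo-count rules), table training and (de)serialization |
| `ssescore.energy_terms` | the twelve scoring terms and penalty-parameter fitting |
| `ssescore.consensus_enrichment` | weighted consensus, RMSD100, enrichment with balanced cross-validation subsets, simulated-annealing weight optimization |
| `ssescore.synthetic_fixtures` | ideal SSE geometry, toy topologies, perturbation decoys, fixture training database, synthetic predictions |
| `ssescore.cli` | `ssescore` command-line entry point |

A table set trained on the bundled 50-protein synthetic fixture database plus
matching clash parameters ship in `ssescore/data/` (regenerate with
`python scripts/build_bundled_data.py`).

## CLI

```sh
# write a synthetic fixture database (PDB + .ss2 files)
ssescore make-fixtures --n 50 --seed 17 --out fixtures/

# score models: per-term values and the weighted consensus
ssescore score fixtures/*.pdb --ss-pred psipred:fixtures/fix000_two_helix_bundle.ss2 --out scores.csv

# train energy tables (and clash parameters) from a model directory
ssescore train fixtures/ --out tables.json --params-out params.json

# cross-validated enrichment of a labeled score matrix
ssescore enrich --matrix matrix.csv --fraction 0.1 --seed 0 --out report.csv

# simulated-annealing weight optimization
ssescore optimize-weights --matrix matrix.csv --seed 0 --out weights.json
```

Every command takes `--config run.yaml` mirroring its flags (explicit flags
win) and logs its parameters and seed.

## Library example

```python
import numpy as np
from ssescore import (default_clash_params, default_tables, score_all,
                      weighted_sum, WeightSet)
from ssescore.synthetic_fixtures import make_fixture_database, make_decoy

tables = default_tables()
params = default_clash_params()
native = make_fixture_database(1, seed=17)[0]
decoy = make_decoy(native, np.random.default_rng(0))

weights = WeightSet()  # consensus defaults
for model in (native, decoy):
    print(weighted_sum(score_all(model, tables, params), weights))
```
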