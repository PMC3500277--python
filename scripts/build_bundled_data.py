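"""Regenerate the bundled fixture-trained data files.

Run from the repository root:

    python scripts/build_bundled_data.py

Writes ``src/ssescore/data/fixture_tables.json`` (energy tables trained on
the 50-protein synthetic fixture database, seed 17) and
``src/ssescore/data/default_params.json`` (clash/loop-closure parameters
fitted on the same database, with the loop-closure line lifted to cover all
native loops).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from ssescore import energy_terms, features, statistics_builder
from ssescore.synthetic_fixtures import make_fixture_database

SEED = 17
N_PROTEINS = 50


def main() -> None:
    out_dir = Path(__file__).resolve().parent.parent / "src" / "ssescore" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)

    db = make_fixture_database(N_PROTEINS, seed=SEED)
    tables = statistics_builder.train_tables(db)
    tables.to_json(out_dir / "fixture_tables.json")

    # 0.25 A margin: fixture geometry is jittered per seed, and natives from
    # other seeds must not be penalized by thresholds fitted on this one
    aa_min = np.maximum(
        energy_terms.fit_aa_min_distances(db, min_count=1) - 0.25, 0.5
    )
    samples = [(n, d) for m in db for n, _, d in features.loop_features(m)]
    per_length: dict[int, float] = {}
    for n, d in samples:
        per_length[n] = max(per_length.get(n, 0.0), d)
    xs = np.array(sorted(per_length))
    ys = np.array([per_length[n] for n in xs])
    slope, intercept = np.polyfit(xs, ys, 1)
    if slope < 0:  # longer loops must never tighten the constraint
        slope = 0.0
    # lift the line so every native loop in the database is bridgeable
    resid = ys - (slope * xs + intercept)
    intercept += float(resid.max()) + 0.5

    params = energy_terms.ClashParams(
        aa_min_distance=aa_min,
        loop_closure_slope=float(slope),
        loop_closure_intercept=float(intercept),
    )
    params.to_json(out_dir / "default_params.json")
    print(f"wrote tables + params for {N_PROTEINS} fixtures (seed {SEED}) "
          f"loop d_max = {slope:.2f} n + {intercept:.2f}")


if __name__ == "__main__":
    main()
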