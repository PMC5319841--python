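#!/usr/bin/env python
"""Generate the standard synthetic study world and persist it.

Writes annual covariate rasters, the desert mask, the true suitability
surface, the focal-species range, and the occurrence/bioassay tables to
``results/world/``, and prints the data volumes (presences, background
classes) analogous to a compiled-database summary table.
"""

from pathlib import Path

from vectorsdm.occurrence import records_from_dataframe
from vectorsdm.pipeline import default_capability
from vectorsdm.synthetic import SyntheticWorldConfig, generate_world

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "world"


def main() -> None:
    config = SyntheticWorldConfig(seed=SEED)
    world = generate_world(config)
    world.save(OUT)

    df = world.occurrence
    records = records_from_dataframe(df)
    cap = default_capability(records, config.focal_species)
    capable = df.id_methods == "PCR_ALL"
    n_presence = int(df.is_presence_truth.sum())
    n_class1 = int((capable & ~df.is_presence_truth).sum())
    n_class2 = int((~capable).sum())
    print(f"world written to {OUT}")
    print(f"surveys: {len(df)} records at {df[['x','y']].drop_duplicates().shape[0]} locations")
    print(f"presence points: {n_presence}")
    print(f"background points: {n_class1 + n_class2} (class 1: {n_class1}, class 2: {n_class2})")
    print(f"bioassay records: {len(world.bioassay)}")
    print(f"active covariate bands: "
          f"{[world.stack.band_names[b] for b in world.ground_truth['active_bands']]}")


if __name__ == "__main__":
    main()
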