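"""Generate a small synthetic landscape and inspect its ground truth.

Builds a 1 x 1 km world at 2 m/px with 8 species (3 of them "context"
species whose niche depends on terrain ruggedness rather than the elevation
point value), samples 800 biased occurrences, and prints the exported truth.
"""

import convsdm

world = convsdm.generate_world(
    extent=1000.0, resolution=2.0, n_species=8, n_context=3,
    n_occurrences=800, seed=42,
)

print(f"world: {world.n_px} x {world.n_px} px at {world.resolution} m/px")
print(f"layers: {[lyr.name for lyr in world.layers]}")
print(f"environment rasters: {[lyr.name for lyr in world.env_rasters]} "
      f"at {world.env_rasters[0].resolution} m/px")
print(f"occurrences: {len(world.occurrences)} "
      f"({world.occurrences['species_id'].nunique()} species observed)")

# the trait table IS the niche optima used for sampling — downstream stages
# can be validated against it exactly
print("\nspecies traits (niche optima; NaN = dimension not in the niche):")
print(world.trait_table().round(3).to_string())

print("\nper-occurrence truth (first 5 rows):")
print(world.truth.head().round(3).to_string(index=False))
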