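"""Burrow morphometrics from a synthetic CT volume.

Carves archetype-specific burrow systems into a bright sediment matrix,
segments them by threshold-based seed-point region growing, and prints the
three morphometrics for each functional archetype.
"""

from bioturbaton import (
    analyze_volume,
    archetype,
    make_burrow_volume,
)

for name in ("gallery_diffuser", "u_tube", "i_shaft", "mixture"):
    volume, truth = make_burrow_volume(archetype(name), shape_zyx=(160, 72, 72), seed=3)
    m = analyze_volume(volume, min_component_voxels=30)
    print(
        f"{name:16s}  B_max = {m.B_max_cm:5.2f} cm   B_SA = {m.B_SA_cm2:6.1f} cm^2   "
        f"B_vol = {m.B_vol_cm3:5.2f} cm^3   systems = {m.n_components} "
        f"(true: {truth.n_burrow_systems})"
    )
# B_max reflects the archetypes' depth niches: branched galleries reach the
# bottom of the profile (~7.5 cm), U-tubes stay surficial (~2.6 cm) and
# vertical shafts sit between (~3.3 cm).  B_SA and B_vol scale with burrow
# count and radius, which is why the many-burrowed U-tube dweller can rival
# deeper species in wall area.
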