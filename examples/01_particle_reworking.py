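"""Particle reworking from a synthetic f-SPI profile image.

Generates a UV profile photograph of an aquarium colonised by a deep
gallery-building polychaete, runs the tracer/interface/metrics chain, and
compares the result with the generator's exact ground truth.
"""

import numpy as np

from bioturbaton import (
    archetype,
    detect_interface,
    detect_tracers,
    make_profile_image,
    reworking_metrics,
)

image, truth = make_profile_image(
    archetype("gallery_diffuser"), width_px=300, height_px=1500, seed=1, n_particles=2000
)

mask = detect_tracers(image)
interface = detect_interface(image)
metrics = reworking_metrics(mask, interface, image.pixel_size_cm)

print(f"tracer pixels detected : {mask.n_tracer_px}")
print(f"L_med  = {metrics.L_med_cm:.3f} cm   (typical short-term mixing depth)")
print(f"L_mean = {metrics.L_mean_cm:.3f} cm   (time-integrated mixing)")
print(f"L_max  = {metrics.L_max_cm:.3f} cm   (rare deep transport events)")
print(f"SBR    = {metrics.SBR_cm:.3f} cm   (surface relief)")
print()
print("ground truth (brute force over every placed tracer pixel):")
print(
    f"L_med = {np.median(truth.tracer_depths):.3f}, "
    f"L_mean = {truth.tracer_depths.mean():.3f}, "
    f"L_max = {truth.tracer_depths.max():.3f} cm"
)
# L_med/L_mean sit well above zero because routine burial follows a
# half-normal kernel; L_max reaches several cm because a small fraction of
# tracers is carried down burrow tracks.
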