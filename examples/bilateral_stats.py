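"""Compare density-maximum location and MAR between sides and subjects.

Builds a cohort of three phantom subjects whose high-density patches differ
in size (geodesic radius 3.6 / 4.0 / 4.4 mm), each with a left limb and an
exactly mirrored right limb.  Location is summarised per limb as the mean
grid coordinate over all detected maxima (stable under mirroring, unlike the
primary flag when the two patches tie in area).  Expected outcome: sides are
indistinguishable, while subjects differ in MAR — and because mirrored limbs
are perfectly symmetric, within-subject variance is exactly zero, so the
between-subject F is infinite: a degenerate but correct verdict.
"""

import numpy as np
import pandas as pd

import ctoam

rows = []
for i, (subject, radius) in enumerate([("dog1", 3.6), ("dog2", 4.0), ("dog3", 4.4)]):
    maxima_spec = tuple(
        ctoam.MaximumSpec(m.ridge, m.axial_fraction, m.angle_deg, radius, m.hu_peak)
        for m in ctoam.default_maxima()
    )
    spec = ctoam.PhantomSpec(seed=100 + i, noise_sd=30.0, maxima=maxima_spec)
    left, _ = ctoam.generate_phantom(spec)
    for side, volume in [("left", left), ("right", ctoam.mirror_phantom(left))]:
        for view, va in ctoam.analyse_volume(volume, subject_id=subject, side=side).items():
            xy = [ctoam.mirror_coords(m.grid_xy, side) for m in va.maxima]
            rows.append({"subject": subject, "side": side, "view": view,
                         "mar": va.mar.mar,
                         "grid_x": float(np.mean([c[0] for c in xy])),
                         "grid_y": float(np.mean([c[1] for c in xy])),
                         "total_pixels": va.mar.total_surface_pixels,
                         "max_pixels": va.mar.max_area_pixels})

records = pd.DataFrame(rows)
print("summary, mean (SD) per side and view:")
print(ctoam.summarise(records).to_string(index=False), "\n")

# Sides hold the same three subjects, so means match: t = 0, p = 1 for MAR
# (or 'test undefined' where both sides are identical constants).
print(ctoam.compare_sides(records), "\n")

# Subjects genuinely differ in patch size: the MAR omnibus test rejects, and
# Bonferroni-adjusted pairwise comparisons identify every pair.
import warnings

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    print(ctoam.compare_subjects(records))
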