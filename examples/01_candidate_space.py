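"""Enumerate the 36 candidate electrode geometries.

Each candidate pairs a disc diameter D (2.0-4.5 mm) with an edge-to-edge
gap Q (0.5-3.0 mm) on a 0.5 mm lattice.  The printed area is the
bounding rectangle (2D+Q) x (3D+2Q) of the 3 x 2 array, the skin patch
the configuration occupies on the fingertip.
"""

from etrec import bounding_area_cm2, enumerate_configs

configs = enumerate_configs()
print(f"{len(configs)} candidate configurations\n")
print(f"{'label':<10}{'D (mm)':>8}{'Q (mm)':>8}{'area (cm^2)':>13}")
for c in configs[:6] + configs[-3:]:
    print(f"{c.label:<10}{c.diameter_mm:>8.1f}{c.spacing_mm:>8.1f}{bounding_area_cm2(c):>13.3f}")
areas = [bounding_area_cm2(c) for c in configs]
print(f"\ncoverage area spans {min(areas):.3f} to {max(areas):.2f} cm^2")
print("small arrays concentrate current; large ones spread it over the fingertip pad")
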