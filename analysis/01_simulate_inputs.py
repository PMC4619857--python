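#!/usr/bin/env python
"""Build the synthetic study inputs.

Creates a 2562-vertex spherical template (4 icosahedral subdivision
levels at 70 mm radius), six geodesic seed patches standing in for the
bilateral primary visual (CAL), primary auditory (HES) and olfactory
(OLF) cortices, and a 35-vs-35 cohort matching the study demographics,
with a coupling difference of 0.4 between the right auditory seed and an
antipodal "medial motor" target patch. Inputs are large, so they go under
scratch/inputs/; downstream drivers read them from there.
"""

import json
from pathlib import Path

import numpy as np

from scnsurf import simulate
from scnsurf.mesh import build_icosphere, seed_patch, write_labels, write_obj

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "inputs"

SEED_CENTERS = {"CAL_L": 0, "CAL_R": 40, "HES_L": 300, "HES_R": 700,
                "OLF_L": 1200, "OLF_R": 1600}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mesh = build_icosphere(4, radius=70.0)
    seeds = [seed_patch(mesh, c, 15.0, name) for name, c in SEED_CENTERS.items()]
    hes_r = next(s for s in seeds if s.name == "HES_R")

    # target: antipodal to the auditory seed, playing the medial motor area
    far = int(np.argmax(np.linalg.norm(
        mesh.vertex_coords - mesh.vertex_coords[SEED_CENTERS["HES_R"]], axis=1)))
    target = seed_patch(mesh, far, 15.0, "motor_target")

    spec = simulate.insomnia_cohort_spec(
        seed_region=hes_r, rng_seed=20240921,
        b0=simulate.patch_field(mesh, target, 0.2),
        delta_b=simulate.patch_field(mesh, target, 0.4))
    cohort = simulate.sample_cohort(spec)
    data = simulate.generate_thickness(mesh, cohort, spec)

    write_obj(mesh, OUT / "mesh.obj")
    write_labels(seeds, OUT / "labels.tsv")
    write_labels([target], OUT / "target.tsv")
    simulate.write_cohort(cohort, OUT / "cohort.tsv")
    simulate.write_thickness(data, OUT / "thickness.tsv")
    simulate.write_spec_sidecar(spec, OUT / "simulation_spec.json")

    print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_triangles} triangles, "
          f"area {mesh.total_area():.0f} mm^2")
    print(f"cohort: {len(cohort)} subjects "
          f"({(cohort.group == 1).sum()} PI / {(cohort.group == 0).sum()} HC)")
    print(f"seeds: {', '.join(f'{s.name}({len(s)})' for s in seeds)}")
    print(f"coupling: HES_R -> motor_target ({len(target)} vertices), "
          f"b0=0.2, delta_b=0.4")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
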