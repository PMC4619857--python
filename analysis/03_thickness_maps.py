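#!/usr/bin/env python
"""Vertex-wise thickness analysis: group difference and PSQI correlation.

Fits the per-vertex GLMs (group or PSQI, controlling age, sex and global
mean thickness), applies RFT cluster correction to both tails, and writes
a map summary to results/thickness_summary.tsv. On this null-thickness
cohort (no injected group offset) nothing should survive correction, and
the uncorrected trend masks should cover roughly 5% of vertices per tail.
"""

from pathlib import Path

import pandas as pd

from scnsurf import glm, rft
from scnsurf.pipeline import load_mesh
from scnsurf.simulate import read_cohort, read_thickness

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "scratch" / "inputs"
RESULTS = ROOT / "results"


def main() -> None:
    if not (INPUTS / "thickness.tsv").exists():
        raise SystemExit("run analysis/01_simulate_inputs.py first")
    RESULTS.mkdir(exist_ok=True)
    mesh = load_mesh(INPUTS / "mesh.obj")
    cohort = read_cohort(INPUTS / "cohort.tsv")
    data = read_thickness(INPUTS / "thickness.tsv", mesh, cohort)

    maps = {
        "group_difference": glm.thickness_group_map(
            data.matrix, cohort.group.to_numpy(float),
            cohort.age.to_numpy(float), cohort.sex.to_numpy(float)),
        "psqi_correlation": glm.thickness_psqi_map(
            data.matrix, cohort.psqi.to_numpy(float),
            cohort.age.to_numpy(float), cohort.sex.to_numpy(float)),
    }
    rows = []
    for name, sm in maps.items():
        est = rft.estimate_smoothness(sm.residuals, mesh, df=sm.df,
                                      exclude=sm.infinite)
        for tail in ("positive", "negative"):
            ct = rft.cluster_fwe(sm, est, mesh, 0.001, tail)
            trend = rft.uncorrected_mask(sm, 0.05, tail)
            rows.append({
                "map": name, "tail": tail, "df": sm.df,
                "fwhm_mm": round(est.fwhm, 2),
                "n_clusters": len(ct),
                "n_fwe_significant": int(len(ct.significant(0.05))),
                "trend_fraction": round(float(trend.mean()), 4),
            })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "thickness_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nNo FWE-significant thickness differences are expected here: the "
          "generator injects no group effect on thickness itself, mirroring "
          "the emulated study, where raw thickness maps showed only "
          "uncorrected trends.")


if __name__ == "__main__":
    main()
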