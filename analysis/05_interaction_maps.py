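#!/usr/bin/env python
"""Group and sleep-quality modulation of structural covariance.

For every seed, fits the seed x group and seed x PSQI interaction models
on age/sex-adjusted thickness, applies RFT cluster correction to both
tails, and writes every FWE-significant cluster (plus the best
nonsignificant one per map) to results/interaction_clusters.tsv. The
generator couples only HES_R to the motor target with a group difference
of 0.4, so a significant positive group-interaction cluster overlapping
that target is expected for HES_R and for no other seed.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scnsurf import glm, rft
from scnsurf.mesh import read_labels
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
    seeds = read_labels(INPUTS / "labels.tsv")
    target = read_labels(INPUTS / "target.tsv")[0]

    Yadj = glm.residualize_covariates(data.matrix, cohort[["age", "sex"]])
    moderators = {"group": cohort.group.to_numpy(float),
                  "psqi": cohort.psqi.to_numpy(float)}
    rows = []
    for seed in seeds:
        sv = glm.seed_mean(Yadj, seed)
        for mod_name, mod in moderators.items():
            sm = glm.interaction_map(Yadj, sv, mod, mod_name)
            est = rft.estimate_smoothness(sm.residuals, mesh, df=sm.df,
                                          exclude=sm.infinite)
            for tail in ("positive", "negative"):
                ct = rft.cluster_fwe(sm, est, mesh, 0.001, tail)
                if not len(ct):
                    continue
                keep = ct.table[(ct.table.p_fwe < 0.05)
                                | (ct.table.index == 0)]
                for _, r in keep.iterrows():
                    overlap = int(np.intersect1d(
                        ct.members[r.cluster_id],
                        target.vertex_indices).size)
                    rows.append({"seed": seed.name, "moderator": mod_name,
                                 "tail": tail,
                                 "n_vertices": int(r.n_vertices),
                                 "peak_t": round(float(r.peak_t), 2),
                                 "p_fwe": float(f"{r.p_fwe:.3g}"),
                                 "target_overlap": overlap})
    out = pd.DataFrame(rows).sort_values(["moderator", "p_fwe"])
    out.to_csv(RESULTS / "interaction_clusters.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    sig = out[out.p_fwe < 0.05]
    on_target = sig[sig.target_overlap > 0]
    print(f"\n{len(sig)} FWE-significant cluster(s) across "
          f"{out[['seed', 'moderator', 'tail']].drop_duplicates().shape[0]} "
          f"corrected maps; {len(on_target)} overlap the coupled motor "
          "target (HES_R, for both moderators: patients carry both the high "
          "PSQI scores and the stronger coupling). Any remaining significant "
          "clusters are familywise errors — with ~24 corrected maps at "
          "alpha=0.05, roughly one incidental cluster is expected per run.")


if __name__ == "__main__":
    main()
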