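"""End-to-end orchestration of the structural covariance analysis.

One run executes, in order: load or simulate inputs; demographics tests;
vertex-wise thickness group-difference and thickness-PSQI maps; age/sex
residualization; per-seed per-group covariance maps; seed x group
interaction maps; seed x PSQI modulation maps; and, for every map and both
tails, RFT cluster correction plus an uncorrected trend mask. Outputs are
flat TSV/JSON files under the run directory and a RunReport indexing them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, glm, rft, simulate
from .mesh import (SeedRegion, SurfaceMesh, read_labels, read_obj,
                   write_labels, write_obj)

log = logging.getLogger("scnsurf")

ANALYSES = ("thickness", "scn_per_group", "group_interaction", "psqi_modulation")
TAILS = {"positive": "increased", "negative": "decreased"}


class PipelineError(RuntimeError):
    """Raised with the failing stage name when a pipeline stage aborts."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    out_dir: str
    mesh_path: str | None = None
    thickness_path: str | None = None
    cohort_path: str | None = None
    labels_path: str | None = None
    simulation: simulate.SimulationSpec | None = None
    seeds: tuple[str, ...] = ()            # empty -> all labels present
    analyses: tuple[str, ...] = ANALYSES
    cluster_forming_p: float = 0.001
    fwe_alpha: float = 0.05
    uncorrected_trend_p: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ValueError("at least one analysis must be selected")
        for a in self.analyses:
            if a not in ANALYSES:
                raise ValueError(f"unknown analysis {a!r}")
        for name, v in (("fwe_alpha", self.fwe_alpha),
                        ("uncorrected_trend_p", self.uncorrected_trend_p),
                        ("cluster_forming_p", self.cluster_forming_p)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_json_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_json_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Index of a completed run: per analysis/seed/tail output files,
    demographics table, and provenance."""

    out_dir: str
    config_hash: str
    rng_seed: int
    version: str
    demographics: pd.DataFrame
    files: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"out_dir": self.out_dir, "config_hash": self.config_hash,
                "rng_seed": self.rng_seed, "version": self.version,
                "files": self.files}


def demographics_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographic summary with between-group tests, laid out as
    one row per characteristic (n, sex split, age, PSQI).

    Sex uses a Pearson chi-square; age a two-tailed pooled t test; PSQI a
    one-tailed pooled t test for patients scoring higher.
    """
    groups = sorted(cohort["group"].unique())
    if len(groups) != 2:
        raise ValueError("demographics require exactly two groups")
    hc = cohort[cohort["group"] == simulate.HC]
    pi = cohort[cohort["group"] == simulate.PI]
    if len(hc) == 0 or len(pi) == 0:
        raise ValueError("both groups must be non-empty")

    sex_test = glm.chi_square_2x2(
        int((pi["sex"] == simulate.MALE).sum()), int((pi["sex"] == simulate.FEMALE).sum()),
        int((hc["sex"] == simulate.MALE).sum()), int((hc["sex"] == simulate.FEMALE).sum()))
    if pi["age"].std(ddof=1) > 0 and hc["age"].std(ddof=1) > 0:
        age_test = glm.two_sample_t(pi["age"].mean(), pi["age"].std(ddof=1), len(pi),
                                    hc["age"].mean(), hc["age"].std(ddof=1), len(hc),
                                    tails=2)
        psqi_test = glm.two_sample_t(pi["psqi"].mean(), pi["psqi"].std(ddof=1), len(pi),
                                     hc["psqi"].mean(), hc["psqi"].std(ddof=1), len(hc),
                                     tails=1)
    else:
        raise ValueError("degenerate (zero-variance) age in one group")

    def ms(s):
        return f"{s.mean():.2f}, {s.std(ddof=1):.2f}"

    return pd.DataFrame([
        {"characteristic": "n", "PI": str(len(pi)), "HC": str(len(hc)),
         "p": np.nan, "test": ""},
        {"characteristic": "sex_male_female",
         "PI": f"{int((pi['sex'] == 1).sum())}/{int((pi['sex'] == 0).sum())}",
         "HC": f"{int((hc['sex'] == 1).sum())}/{int((hc['sex'] == 0).sum())}",
         "p": sex_test["p"], "test": "chi-square"},
        {"characteristic": "age_mean_sd", "PI": ms(pi["age"]), "HC": ms(hc["age"]),
         "p": age_test["p"], "test": "two-tailed two-sample t"},
        {"characteristic": "psqi_mean_sd", "PI": ms(pi["psqi"]), "HC": ms(hc["psqi"]),
         "p": psqi_test["p"], "test": "one-tailed two-sample t"},
    ])


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        spec = dataclasses.replace(config.simulation, rng_seed=config.rng_seed)
        mesh = _default_mesh()
        if spec.seed_region is None:
            raise PipelineError("simulate: simulation spec needs a seed_region")
        cohort = simulate.sample_cohort(spec)
        data = simulate.generate_thickness(mesh, cohort, spec)
        seeds = [spec.seed_region]
        return mesh, cohort, data, seeds
    if not (config.mesh_path and config.thickness_path and config.cohort_path
            and config.labels_path):
        raise PipelineError("load: need mesh, thickness, cohort and label paths "
                            "when no simulation spec is given")
    mesh = load_mesh(config.mesh_path)
    cohort = simulate.read_cohort(config.cohort_path)
    data = simulate.read_thickness(config.thickness_path, mesh, cohort)
    seeds = read_labels(config.labels_path)
    for s in seeds:
        s.validate_against(mesh)
    if config.seeds:
        by_name = {s.name: s for s in seeds}
        missing = [n for n in config.seeds if n not in by_name]
        if missing:
            raise PipelineError(f"load: seed labels not in label file: {missing}")
        seeds = [by_name[n] for n in config.seeds]
    return mesh, cohort, data, seeds


def _default_mesh() -> SurfaceMesh:
    from .mesh import build_icosphere
    return build_icosphere(4, radius=70.0)


def load_mesh(path) -> SurfaceMesh:
    p = str(path)
    if p.endswith(".gii"):
        from .mesh import read_gifti_surface
        return read_gifti_surface(p)
    return read_obj(p)


def _correct_and_write(name: str, sm: glm.StatMap, mesh: SurfaceMesh,
                       config: RunConfig, out: Path, files: dict,
                       smoothness=None) -> None:
    """RFT cluster correction + trend masks for both tails of one map."""
    if smoothness is None:
        smoothness = rft.estimate_smoothness(sm.residuals, mesh, df=sm.df,
                                             exclude=sm.infinite)
    glm.write_statmap(sm, out / f"{name}_statmap.tsv", out / f"{name}_statmap.json",
                      extra_meta={"fwhm": smoothness.fwhm,
                                  "resels": smoothness.resels.tolist()})
    entry = {"statmap": f"{name}_statmap.tsv", "tails": {}}
    for tail, label in TAILS.items():
        ct = rft.cluster_fwe(sm, smoothness, mesh,
                             cluster_forming_p=config.cluster_forming_p, tail=tail)
        rft.write_cluster_table(ct, out / f"{name}_{label}_clusters.tsv",
                                out / f"{name}_{label}_clusters.json")
        mask = rft.uncorrected_mask(sm, config.uncorrected_trend_p, tail=tail)
        rft.write_mask(mask, out / f"{name}_{label}_trend_mask.tsv")
        entry["tails"][label] = {
            "clusters": f"{name}_{label}_clusters.tsv",
            "trend_mask": f"{name}_{label}_trend_mask.tsv",
            "n_significant": int((ct.table["p_fwe"] < config.fwe_alpha).sum()),
        }
    files[name] = entry


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute the full pipeline; deterministic given config.rng_seed.

    Any stage failure removes partial outputs and raises PipelineError
    naming the stage.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "load"
        mesh, cohort, data, seeds = _load_inputs(config)
        Y = data.matrix
        files: dict = {}

        stage = "demographics"
        demo = demographics_report(cohort)
        demo.to_csv(out / "demographics.tsv", sep="\t", index=False,
                    float_format="%.6g")
        files["demographics"] = "demographics.tsv"

        group = cohort["group"].to_numpy(float)
        age = cohort["age"].to_numpy(float)
        sex = cohort["sex"].to_numpy(float)
        psqi = cohort["psqi"].to_numpy(float)

        if "thickness" in config.analyses:
            stage = "thickness"
            log.info("vertex-wise thickness group and PSQI maps")
            _correct_and_write("thickness_group",
                               glm.thickness_group_map(Y, group, age, sex),
                               mesh, config, out, files)
            _correct_and_write("thickness_psqi",
                               glm.thickness_psqi_map(Y, psqi, age, sex),
                               mesh, config, out, files)

        stage = "residualize"
        Yadj = glm.residualize_covariates(Y, cohort[["age", "sex"]])

        for seed in seeds:
            sname = seed.name
            sv = glm.seed_mean(Yadj, seed)
            if "scn_per_group" in config.analyses:
                stage = f"scn_per_group:{sname}"
                for gcode, gname in ((simulate.HC, "HC"), (simulate.PI, "PI")):
                    rows = group == gcode
                    _correct_and_write(f"scn_{sname}_{gname}",
                                       glm.scn_map(Yadj[rows], sv[rows]),
                                       mesh, config, out, files)
            if "group_interaction" in config.analyses:
                stage = f"group_interaction:{sname}"
                _correct_and_write(f"interaction_{sname}_group",
                                   glm.interaction_map(Yadj, sv, group, "group"),
                                   mesh, config, out, files)
            if "psqi_modulation" in config.analyses:
                stage = f"psqi_modulation:{sname}"
                _correct_and_write(f"interaction_{sname}_psqi",
                                   glm.interaction_map(Yadj, sv, psqi, "psqi"),
                                   mesh, config, out, files)

        stage = "report"
        report = RunReport(out_dir=str(out), config_hash=config.config_hash(),
                           rng_seed=config.rng_seed, version=__version__,
                           demographics=demo, files=files)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)
        with open(out / "run_config.json", "w") as fh:
            json.dump(config.to_json_dict(), fh, indent=1, sort_keys=True)
        return report
    except Exception as exc:
        if created and out.exists():
            shutil.rmtree(out)
        else:
            for f in out.glob("*"):
                if f.is_file():
                    f.unlink()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"{stage}: {exc}") from exc


def simulate_inputs(spec: simulate.SimulationSpec, mesh: SurfaceMesh,
                    out_dir) -> dict:
    """Write mesh/cohort/thickness/labels files for a simulation spec and
    return their paths (the CLI `simulate` subcommand)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec.seed_region is None:
        raise ValueError("simulation spec needs a seed_region")
    cohort = simulate.sample_cohort(spec)
    data = simulate.generate_thickness(mesh, cohort, spec)
    paths = {"mesh": out / "mesh.obj", "cohort": out / "cohort.tsv",
             "thickness": out / "thickness.tsv", "labels": out / "labels.tsv",
             "spec": out / "simulation_spec.json"}
    write_obj(mesh, paths["mesh"])
    simulate.write_cohort(cohort, paths["cohort"])
    simulate.write_thickness(data, paths["thickness"])
    write_labels([spec.seed_region], paths["labels"])
    simulate.write_spec_sidecar(spec, paths["spec"])
    return {k: str(v) for k, v in paths.items()}
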