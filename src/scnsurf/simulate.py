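"""Synthetic cohorts and cortical-thickness fields.

The generative model mirrors the assumptions of seed-based structural
covariance analysis. Each subject i carries a latent seed factor
L_i ~ Normal(0, seed_signal_sd); thickness at vertex v is

    T_i(v) = mu(v) + a_age(v)*age_i + a_sex(v)*sex_i
             + 1[v in seed]*L_i + (b0(v) + delta_b(v)*group_i)*L_i
             + eps_i(v),

where eps is white Gaussian noise smoothed on the mesh to a requested
FWHM. The latent-factor construction makes the true seed-to-target
covariance slope an explicit parameter: regressing target thickness on the
seed mean recovers b0(v) in controls and b0(v)+delta_b(v) in patients, so
delta_b(v) is exactly the group-interaction coefficient the downstream
model estimates.

Demographics emulate a two-group insomnia case-control design: PSQI sleep
scores are truncated, rounded normals (patients on [5, 21], controls on
[0, 4], enforcing the control-inclusion rule PSQI < 5), ages are normals
truncated to [18, 80], and sex is Bernoulli per group. Truncated-normal
locations are moment-matched so the post-truncation mean equals the
configured group mean.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .mesh import SeedRegion, SurfaceMesh

HC, PI = 0, 1
FEMALE, MALE = 0, 1

_LN2_4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class GroupParams:
    """Demographic distribution parameters for one group."""

    n: int
    age_mean: float
    age_sd: float
    sex_p_male: float
    psqi_mean: float
    psqi_sd: float
    psqi_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 subjects per group")
        lo, hi = self.psqi_range
        if not (0 <= lo < hi <= 21):
            raise ValueError("psqi_range must be within the 0-21 instrument range")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic cohort + thickness simulation.

    Effect fields (baseline_mean, a_age, a_sex, b0, delta_b) may be scalars
    or per-vertex arrays; scalars are broadcast over the mesh.
    """

    hc: GroupParams
    pi: GroupParams
    baseline_mean: float | np.ndarray = 2.5      # mm, typical cortical thickness
    a_age: float | np.ndarray = -0.005           # mm per year (age-related thinning)
    a_sex: float | np.ndarray = 0.0              # mm (male minus female)
    seed_region: SeedRegion | None = None
    seed_signal_sd: float = 0.3                  # mm, latent seed factor SD
    b0: float | np.ndarray = 0.0                 # coupling slope in controls
    delta_b: float | np.ndarray = 0.0            # PI-minus-HC coupling difference
    noise_sd: float = 0.1                        # mm, white noise SD pre-smoothing
    noise_fwhm: float | None = None              # mm; None -> 4x mean edge length
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_fwhm is not None and self.noise_fwhm < 0:
            raise ValueError("noise_fwhm must be non-negative")
        if self.seed_signal_sd < 0:
            raise ValueError("seed_signal_sd must be non-negative")

    def to_json_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, SeedRegion):
                return {"name": x.name, "vertex_indices": x.vertex_indices.tolist()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, GroupParams):
                d[f.name] = dataclasses.asdict(v)
            else:
                d[f.name] = conv(v)
        return d


def insomnia_cohort_spec(seed_region: SeedRegion | None = None,
                      rng_seed: int = 0, **overrides) -> SimulationSpec:
    """Spec emulating the reference insomnia case-control design: 35 patients
    (PSQI 12.57 +/- 3.93, age 39.3 +/- 8.6, 5 M / 30 F) versus 35 controls
    (PSQI 2.26 +/- 1.36 with all scores < 5, age 34.9 +/- 10.7, 9 M / 26 F).
    """
    base = dict(
        hc=GroupParams(n=35, age_mean=34.9, age_sd=10.7, sex_p_male=9 / 35,
                       psqi_mean=2.26, psqi_sd=1.36, psqi_range=(0, 4)),
        pi=GroupParams(n=35, age_mean=39.3, age_sd=8.6, sex_p_male=5 / 35,
                       psqi_mean=12.57, psqi_sd=3.93, psqi_range=(5, 21)),
        seed_region=seed_region,
        rng_seed=rng_seed,
    )
    base.update(overrides)
    return SimulationSpec(**base)


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Truncated normal on [lo, hi] with scale sd and location solved so the
    truncated mean equals `mean` (moment matching)."""
    if not lo < hi:
        raise ValueError("impossible truncation bounds")
    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean
    if not lo <= mean <= hi:
        raise ValueError(f"target mean {mean} outside truncation bounds [{lo}, {hi}]")
    loc = optimize.brentq(trunc_mean, lo - 10 * sd, hi + 10 * sd)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def sample_cohort(spec: SimulationSpec) -> pd.DataFrame:
    """Draw a cohort table: subject_id, group (HC=0/PI=1), age, sex (F=0/M=1),
    psqi (integer). Deterministic given spec.rng_seed."""
    rng = np.random.default_rng([spec.rng_seed, 0])
    rows = []
    for gcode, gname, gp in ((HC, "HC", spec.hc), (PI, "PI", spec.pi)):
        ages = _matched_truncnorm(gp.age_mean, gp.age_sd, 18, 80).rvs(
            gp.n, random_state=rng)
        sexes = (rng.random(gp.n) < gp.sex_p_male).astype(int)
        lo, hi = gp.psqi_range
        psqi = np.rint(_matched_truncnorm(gp.psqi_mean, gp.psqi_sd, lo, hi).rvs(
            gp.n, random_state=rng)).astype(int)
        for i in range(gp.n):
            rows.append((f"{gname}{i + 1:03d}", gcode, float(ages[i]),
                         int(sexes[i]), int(psqi[i])))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "age", "sex", "psqi"])
    assert df["psqi"].between(0, 21).all()
    return df


class FieldSmoother:
    """Iterated neighbor-averaging diffusion on a mesh, calibrated to an
    approximately Gaussian kernel of a requested FWHM.

    One iteration applies y <- (1-lam)*x + lam*mean(neighbors of x), a lazy
    random-walk step whose squared displacement is lam * E[edge length^2].
    After k steps the kernel is near-Gaussian with per-axis variance
    k*lam*E[d^2]/2, hence FWHM = sqrt(4 ln2 * k * lam * E[d^2]); the number
    of iterations is the rounding of k = fwhm^2 / (4 ln2 * lam * E[d^2]).
    FWHM 0 is the identity; constant fields are exact fixed points because
    the operator rows sum to one.
    """

    def __init__(self, mesh: SurfaceMesh, fwhm: float, lam: float = 0.5):
        if fwhm < 0:
            raise ValueError("fwhm must be non-negative")
        if not 0 < lam <= 1:
            raise ValueError("lam must be in (0, 1]")
        self.fwhm = float(fwhm)
        e = mesh.edges()
        mean_sq_edge = float(np.mean(mesh.edge_lengths() ** 2))
        self.n_iter = (0 if fwhm == 0 else
                       max(1, round(fwhm ** 2 / (_LN2_4 * lam * mean_sq_edge))))
        n = mesh.n_vertices
        adj = sparse.csr_matrix(
            (np.ones(2 * len(e)),
             (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n))
        deg = np.asarray(adj.sum(axis=1)).ravel()
        avg = sparse.diags(1.0 / deg) @ adj
        self._op = (sparse.eye(n) * (1 - lam) + lam * avg).tocsr()

    def __call__(self, values: np.ndarray) -> np.ndarray:
        out = np.asarray(values, dtype=float)
        for _ in range(self.n_iter):
            out = out @ self._op.T
        return out


def smooth_field(mesh: SurfaceMesh, values: np.ndarray, fwhm: float) -> np.ndarray:
    """Smooth per-vertex field(s) (shape (..., V)) to approximately Gaussian
    spatial autocorrelation of the given FWHM (mm)."""
    return FieldSmoother(mesh, fwhm)(values)


def default_noise_fwhm(mesh: SurfaceMesh) -> float:
    """Default noise smoothness: four times the mean edge length."""
    return 4.0 * float(mesh.edge_lengths().mean())


@dataclass(frozen=True)
class ThicknessDataset:
    """Subjects x vertices thickness matrix bound to a mesh and cohort."""

    matrix: np.ndarray
    mesh: SurfaceMesh
    cohort: pd.DataFrame

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.cohort), self.mesh.n_vertices):
            raise ValueError(
                f"thickness matrix shape {m.shape} inconsistent with cohort "
                f"({len(self.cohort)}) and mesh ({self.mesh.n_vertices})")
        if not np.isfinite(m).all():
            raise ValueError("thickness matrix contains non-finite values")


def _as_field(x, n_vertices: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return np.full(n_vertices, float(arr))
    if arr.shape != (n_vertices,):
        raise ValueError("effect field length does not match mesh")
    return arr


def patch_field(mesh: SurfaceMesh, region: SeedRegion, value: float,
                background: float = 0.0) -> np.ndarray:
    """Per-vertex field equal to `value` on a region, `background` elsewhere."""
    f = np.full(mesh.n_vertices, background)
    f[region.vertex_indices] = value
    return f


def generate_thickness(mesh: SurfaceMesh, cohort: pd.DataFrame,
                       spec: SimulationSpec) -> ThicknessDataset:
    """Simulate the thickness matrix for a cohort under the latent-seed model.

    Deterministic given spec.rng_seed (a stream independent of the one used
    for cohort sampling, so cohort and field noise never alias).
    """
    if spec.seed_region is not None:
        spec.seed_region.validate_against(mesh)
    n, v = len(cohort), mesh.n_vertices
    rng = np.random.default_rng([spec.rng_seed, 1])

    mu = _as_field(spec.baseline_mean, v)
    a_age = _as_field(spec.a_age, v)
    a_sex = _as_field(spec.a_sex, v)
    b0 = _as_field(spec.b0, v)
    db = _as_field(spec.delta_b, v)

    age = cohort["age"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float)
    group = cohort["group"].to_numpy(float)

    T = mu[None, :] + np.outer(age, a_age) + np.outer(sex, a_sex)
    if spec.seed_region is not None and spec.seed_signal_sd > 0:
        L = rng.normal(0.0, spec.seed_signal_sd, size=n)
        T[:, spec.seed_region.vertex_indices] += L[:, None]
        T += (b0[None, :] + np.outer(group, db)) * L[:, None]
    if spec.noise_sd > 0:
        eps = rng.normal(0.0, spec.noise_sd, size=(n, v))
        fwhm = default_noise_fwhm(mesh) if spec.noise_fwhm is None else spec.noise_fwhm
        if fwhm > 0:
            eps = smooth_field(mesh, eps, fwhm)
        T += eps
    return ThicknessDataset(matrix=T, mesh=mesh, cohort=cohort)


# -- I/O ---------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["subject_id", "group", "age", "sex", "psqi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    if df[required].isna().any().any():
        raise ValueError("cohort table has missing values")
    return df


def write_thickness(dataset: ThicknessDataset, path) -> None:
    """Thickness TSV: one row per subject, columns v0..v{V-1} (0-based)."""
    cols = [f"v{i}" for i in range(dataset.mesh.n_vertices)]
    df = pd.DataFrame(dataset.matrix, columns=cols)
    df.insert(0, "subject_id", dataset.cohort["subject_id"].to_numpy())
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_thickness(path, mesh: SurfaceMesh, cohort: pd.DataFrame) -> ThicknessDataset:
    df = pd.read_csv(path, sep="\t")
    if list(df["subject_id"]) != list(cohort["subject_id"]):
        raise ValueError("thickness row order does not match cohort")
    return ThicknessDataset(df.drop(columns="subject_id").to_numpy(float),
                            mesh, cohort)


def write_spec_sidecar(spec: SimulationSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_json_dict(), fh, indent=1, sort_keys=True)
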