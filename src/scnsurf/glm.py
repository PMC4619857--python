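"""Mass-univariate vertex-wise model fitting.

All maps share one vectorized ordinary-least-squares engine: the same
design matrix is fitted independently at every mesh vertex and the t
statistic of one contrast column is reported per vertex, along with the
residual matrix retained for random-field smoothness estimation.

The covariance models follow the seed-based structural covariance
convention. Per group, target thickness is regressed on the mean adjusted
seed thickness (T_i = b0 + b1*T_seed + e); group differences in coupling
are the t field of the product term in T_i = b0 + b1*T_seed + b2*G +
b3*T_seed*G + e, and sleep-quality modulation replaces the group indicator
with the PSQI score. With 0/1 group coding the interaction coefficient b3
is exactly the patient-minus-control difference of per-group slopes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import SeedRegion

# residual SD below this fraction of the data scale counts as exact fit
_ZERO_VAR_RTOL = 1e-10


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise invalid design matrices."""


@dataclass(frozen=True)
class DesignMatrix:
    """Named design matrix; intercept column must be present and the matrix
    full column rank (collinear columns are named in the error)."""

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", X)
        object.__setattr__(self, "names", tuple(self.names))
        if X.ndim != 2 or X.shape[1] != len(self.names):
            raise DesignError("matrix shape does not match column names")
        if "intercept" not in self.names:
            raise DesignError("design must contain an 'intercept' column")
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            # name the columns involved in the rank deficiency
            bad = []
            keep: list[int] = []
            for j in range(X.shape[1]):
                if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                    keep.append(j)
                else:
                    bad.append(self.names[j])
            raise DesignError(f"rank-deficient design; collinear columns: {bad}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> int:
        if name not in self.names:
            raise DesignError(f"no design column named {name!r}")
        return self.names.index(name)


def design(**columns: np.ndarray) -> DesignMatrix:
    """Build a DesignMatrix from keyword columns; an intercept is prepended."""
    names = ("intercept", *columns)
    arrays = [np.ones(len(next(iter(columns.values()))))]
    arrays += [np.asarray(v, dtype=float) for v in columns.values()]
    return DesignMatrix(names=names, matrix=np.column_stack(arrays))


@dataclass(frozen=True)
class StatMap:
    """Per-vertex effect size, t value and residual df for one contrast.

    `infinite` flags vertices with zero residual variance, where t is
    reported as signed infinity (0 when the effect is also exactly 0);
    these vertices are excluded from smoothness estimation downstream.
    """

    beta: np.ndarray
    t: np.ndarray
    df: int
    contrast: str
    residuals: np.ndarray = field(repr=False)
    infinite: np.ndarray = field(repr=False)
    model: str = ""
    extra: dict = field(default_factory=dict, repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.t)

    def uncorrected_p(self, tail: str = "positive") -> np.ndarray:
        """Per-vertex uncorrected tail p from the Student t distribution."""
        if tail == "positive":
            return stats.t.sf(self.t, self.df)
        if tail == "negative":
            return stats.t.cdf(self.t, self.df)
        if tail == "two-sided":
            return 2.0 * stats.t.sf(np.abs(self.t), self.df)
        raise ValueError(f"unknown tail {tail!r}")


def fit_glm(Y: np.ndarray, X: DesignMatrix, contrast: str,
            model: str = "") -> StatMap:
    """Vertex-wise OLS of Y (subjects x vertices) on X; t for one column.

    t = beta_hat / SE with SE^2 = sigma2_v * [(X'X)^-1]_cc and
    sigma2_v = RSS_v / (n - rank). Vertices with zero residual variance
    get a signed-infinity t and are flagged.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != X.n:
        raise ValueError("Y must be subjects x vertices, rows matching design")
    df = X.n - X.rank
    if df <= 0:
        raise DesignError("no residual degrees of freedom")
    c = X.column(contrast)
    xtx_inv = np.linalg.inv(X.matrix.T @ X.matrix)
    beta_all = xtx_inv @ (X.matrix.T @ Y)           # rank x vertices
    resid = Y - X.matrix @ beta_all
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    beta = beta_all[c]
    scale = max(1.0, float(np.abs(Y).max(initial=0.0)))
    zero_var = sigma2 <= X.n * (_ZERO_VAR_RTOL * scale) ** 2
    se = np.sqrt(np.where(zero_var, np.nan, sigma2) * xtx_inv[c, c])
    with np.errstate(invalid="ignore"):
        t = beta / se
    t = np.where(zero_var, np.sign(beta) * np.inf, t)
    t = np.where(zero_var & (beta == 0), 0.0, t)
    return StatMap(beta=beta, t=t, df=df, contrast=contrast,
                   residuals=resid, infinite=zero_var, model=model)


def residualize_covariates(Y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of Y on [intercept, covariates] per vertex (removes e.g.
    age and sex before covariance analysis). Output columns are mean-zero
    and orthogonal to every covariate."""
    cov = covariates.astype(float)
    if cov.isna().any().any():
        raise ValueError("covariates contain missing values")
    for name in cov.columns:
        if cov[name].nunique() <= 1:
            raise DesignError(f"constant covariate column {name!r}")
    X = design(**{name: cov[name].to_numpy() for name in cov.columns})
    beta = np.linalg.lstsq(X.matrix, np.asarray(Y, dtype=float), rcond=None)[0]
    return np.asarray(Y, dtype=float) - X.matrix @ beta


def seed_mean(Y: np.ndarray, seed: SeedRegion) -> np.ndarray:
    """Unweighted per-subject mean of (adjusted) thickness over seed vertices."""
    return np.asarray(Y, dtype=float)[:, seed.vertex_indices].mean(axis=1)


def scn_map(Y_group: np.ndarray, seed_values: np.ndarray) -> StatMap:
    """One group's structural covariance map: per-vertex simple regression
    of adjusted thickness on the seed mean; t of the slope, df = n - 2."""
    s = np.asarray(seed_values, dtype=float)
    if len(s) < 4:
        raise ValueError("need at least 4 subjects in the group")
    if np.ptp(s) == 0:
        raise ValueError("degenerate seed: zero variance across subjects")
    X = design(seed=s)
    return fit_glm(Y_group, X, "seed", model="scn: T ~ 1 + seed")


def interaction_map(Y: np.ndarray, seed_values: np.ndarray,
                    moderator: np.ndarray, moderator_name: str = "moderator",
                    covariates: pd.DataFrame | None = None) -> StatMap:
    """t field of the seed x moderator product term in
    T ~ 1 + seed + moderator + seed*moderator (df = n - 4).

    With a 0/1 group moderator this is the between-group covariance
    difference; with PSQI it is the sleep-quality modulation map. The
    default expects Y already residualized for nuisance covariates
    (the two-stage pipeline); passing `covariates` instead fits them
    jointly inside the model (df reduced accordingly).
    """
    s = np.asarray(seed_values, dtype=float)
    m = np.asarray(moderator, dtype=float)
    if np.ptp(m) == 0:
        raise ValueError("moderator is constant")
    term = f"seed_x_{moderator_name}"
    cols = {"seed": s, moderator_name: m, term: s * m}
    if covariates is not None:
        for name in covariates.columns:
            cols[str(name)] = covariates[name].to_numpy(float)
    X = design(**cols)
    return fit_glm(Y, X, term,
                   model=f"interaction: T ~ {' + '.join(('1',) + tuple(cols))}")


def global_mean_thickness(Y: np.ndarray) -> np.ndarray:
    """Per-subject mean thickness over all mesh vertices."""
    return np.asarray(Y, dtype=float).mean(axis=1)


def thickness_group_map(Y: np.ndarray, group: np.ndarray, age: np.ndarray,
                        sex: np.ndarray) -> StatMap:
    """Group difference (patient minus control with 0/1 coding) in raw
    thickness, controlling for age, sex and global mean thickness."""
    X = design(group=group, age=age, sex=sex,
               mean_ct=global_mean_thickness(Y))
    return fit_glm(Y, X, "group",
                   model="thickness: T ~ 1 + group + age + sex + mean_ct")


def thickness_psqi_map(Y: np.ndarray, psqi: np.ndarray, age: np.ndarray,
                       sex: np.ndarray) -> StatMap:
    """Partial correlation of thickness with PSQI removing age, sex and
    global mean thickness, via the GLM t for the PSQI term; the equivalent
    partial r = t / sqrt(t^2 + df) is stored in `extra['partial_r']`."""
    p = np.asarray(psqi, dtype=float)
    if np.ptp(p) == 0:
        raise ValueError("psqi is constant")
    X = design(psqi=p, age=age, sex=sex, mean_ct=global_mean_thickness(Y))
    sm = fit_glm(Y, X, "psqi",
                 model="psqi: T ~ 1 + psqi + age + sex + mean_ct")
    with np.errstate(invalid="ignore"):
        r = sm.t / np.sqrt(sm.t ** 2 + sm.df)
    r = np.where(sm.infinite, np.sign(sm.t), r)
    sm.extra["partial_r"] = r
    return sm


# -- summary-statistic tests (demographics table) ----------------------------

def two_sample_t(m1: float, sd1: float, n1: int, m2: float, sd2: float,
                 n2: int, tails: int = 2, variance: str = "pooled") -> dict:
    """Two-sample t test from summary statistics.

    Pooled variance is the default (the classical form; it reproduces the
    study's printed one-tailed PSQI p-value, which Welch does not).
    One-tailed p is for the alternative mean1 > mean2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    diff = m1 - m2
    if variance == "pooled":
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    elif variance == "welch":
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        raise ValueError("variance must be 'pooled' or 'welch'")
    t = diff / se
    p = stats.t.sf(t, df) if tails == 1 else 2 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def chi_square_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table
    [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return {"chi2": chi2, "df": 1, "p": float(stats.chi2.sf(chi2, 1))}


# -- StatMap I/O -------------------------------------------------------------

def write_statmap(sm: StatMap, tsv_path, json_path=None, extra_meta=None) -> None:
    """TSV `vertex_index beta t df` plus JSON header with model metadata."""
    df = pd.DataFrame({
        "vertex_index": np.arange(sm.n_vertices),
        "beta": sm.beta,
        "t": sm.t,
        "df": sm.df,
    })
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    if json_path is not None:
        meta = {"contrast": sm.contrast, "model": sm.model, "df": int(sm.df),
                "n_vertices": int(sm.n_vertices),
                "n_flagged_infinite": int(sm.infinite.sum())}
        meta.update(extra_meta or {})
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def write_statmap_gifti(sm: StatMap, path) -> None:
    """Optional GIFTI functional export of the t field."""
    import nibabel as nib
    arr = nib.gifti.GiftiDataArray(sm.t.astype(np.float32),
                                   intent="NIFTI_INTENT_TTEST")
    nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))
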