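"""Trial-level phenotype analysis for NCII populations.

Covers the phenotype side of the pipeline: the studentized-residual outlier
razor, the across-environment model y = mu + G + E + GxE + R(E) + eps
(BLUEs with genotype fixed, variance components with G, GxE and
replicate-within-environment random), broad-sense heritability

    H2 = sigma2_G / (sigma2_G + sigma2_GxE / N_E + sigma2_eps / (N_E N_R)),

within-environment BLUEs, midparent heterosis MPH = H - (P1 + P2)/2 and its
second-step mixed model, the GCA/SCA decomposition of hybrid performance,
and correlation/path analysis of component traits toward grain yield.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import factor_kernel, mixture_chi2_pvalue, reml_fit

__all__ = [
    "TrialModel",
    "TrialResults",
    "remove_outliers",
    "fit_trial_model",
    "broad_sense_heritability",
    "summarize_trait",
    "within_env_blue",
    "compute_mph",
    "mph_table",
    "mph_model",
    "MPHResults",
    "gca_sca_decompose",
    "GCASCAResult",
    "correlations_and_path",
    "PathResult",
]

RECORD_COLUMNS = ("genotype", "environment", "replicate", "trait", "value")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trial records are missing columns {missing}")
    return records


def _one_trait(records: pd.DataFrame, trait) -> pd.DataFrame:
    _check_records(records)
    traits = records["trait"].unique()
    if trait is None:
        if len(traits) != 1:
            raise ValueError(f"records hold several traits {list(traits)}; pick one")
        trait = traits[0]
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    return sub.reset_index(drop=True)


def _dummies(values, drop_first=False) -> np.ndarray:
    codes, _ = pd.factorize(values, sort=True)
    D = np.eye(codes.max() + 1)[codes]
    return D[:, 1:] if drop_first else D


# ---------------------------------------------------------------------------
# outlier razor

def remove_outliers(records: pd.DataFrame, threshold: float = 2.8):
    """Drop observations with |externally studentized residual| > threshold.

    The residuals come from the per-trait fixed-effect trial model with
    genotype, environment and replicate-within-environment terms; the
    threshold is strict (a residual exactly at the threshold is retained)
    and the pass is single-sweep.  Returns (clean_records, removal_log).
    """
    _check_records(records)
    records = records.reset_index(drop=True)
    keep_mask = np.ones(len(records), dtype=bool)
    log_rows = []
    for trait, sub in records.groupby("trait", sort=False):
        y = sub["value"].to_numpy(dtype=float)
        X = np.hstack(
            [
                np.ones((len(sub), 1)),
                _dummies(sub["genotype"], drop_first=True),
                _dummies(sub["environment"], drop_first=True),
                _dummies(
                    sub["environment"].astype(str) + ":" + sub["replicate"].astype(str),
                    drop_first=True,
                ),
            ]
        )
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        r = s > s[0] * max(X.shape) * np.finfo(float).eps
        Ur = U[:, r]
        rank = int(r.sum())
        fitted = Ur @ (Ur.T @ y)
        e = y - fitted
        h = np.sum(Ur**2, axis=1)
        dof = len(y) - rank
        if dof < 3:
            raise ValueError(f"trait {trait!r}: too few residual degrees of freedom")
        rss = float(e @ e)
        denom = rss * (1.0 - h) - e**2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = e * np.sqrt(np.maximum(dof - 1, 1) / np.where(denom > 0, denom, np.inf))
        out = np.abs(t) > threshold
        idx = sub.index[out]
        keep_mask[idx] = False
        for pos, i in enumerate(np.flatnonzero(out)):
            row = sub.iloc[i]
            log_rows.append(
                {
                    "trait": trait,
                    "genotype": row["genotype"],
                    "environment": row["environment"],
                    "replicate": row["replicate"],
                    "value": row["value"],
                    "studentized_residual": float(t[i]),
                }
            )
    clean = records.loc[keep_mask].reset_index(drop=True)
    log = pd.DataFrame(
        log_rows,
        columns=["trait", "genotype", "environment", "replicate", "value",
                 "studentized_residual"],
    )
    # genotypes that lost every observation cannot be analyzed downstream
    for trait, sub in records.groupby("trait", sort=False):
        before = set(sub["genotype"])
        after = set(clean[clean["trait"] == trait]["genotype"])
        gone = before - after
        if gone:
            warnings.warn(
                f"trait {trait!r}: genotypes fully removed by the outlier razor: "
                f"{sorted(map(str, gone))[:5]}"
            )
    return clean, log


# ---------------------------------------------------------------------------
# across-environment trial model

@dataclass
class TrialResults:
    """Variance components, significance flags and BLUEs of the trial model."""

    trait: str
    variances: dict           # 'genotype', 'gxe', 'rep', 'residual'
    significance: dict        # component -> {'lrt': ..., 'pvalue': ...}
    blues: pd.Series          # genotype -> across-environment BLUE
    n_env: int
    n_rep: int
    loglik: float
    gxe_estimable: bool = True

    def heritability(self) -> float:
        return broad_sense_heritability(
            self.variances["genotype"],
            self.variances.get("gxe", 0.0) if self.gxe_estimable else 0.0,
            self.variances["residual"],
            self.n_env,
            self.n_rep,
        )

    def summary(self) -> pd.Series:
        stats = summarize_trait(self.blues.to_numpy())
        stats.update(
            {
                "sigma2_G": self.variances["genotype"],
                "sigma2_GxE": self.variances.get("gxe", np.nan),
                "sigma2_e": self.variances["residual"],
                "N_E": self.n_env,
                "N_R": self.n_rep,
                "H2": self.heritability(),
            }
        )
        return pd.Series(stats, name=self.trait)


class TrialModel:
    """Across-environment model y = mu + G + E + GxE + R(E) + eps.

    Environments are fixed; genotype, genotype-by-environment and replicate
    nested in environment are random for variance estimation.  BLUEs are the
    GLS genotype estimates (genotype fixed) at the average environment.
    """

    def __init__(self, records: pd.DataFrame, trait=None):
        self.records = _one_trait(records, trait)
        self.trait = self.records["trait"].iloc[0]

    def fit(self) -> TrialResults:
        sub = self.records
        y = sub["value"].to_numpy(dtype=float)
        geno = sub["genotype"].to_numpy()
        env = sub["environment"].to_numpy()
        rep_in_env = sub["environment"].astype(str) + ":" + sub["replicate"].astype(str)
        n_env = len(np.unique(env))
        n_rep = int(round(sub.groupby(["genotype", "environment"]).size().median()))
        gxe_ok = n_env >= 2
        if not gxe_ok:
            warnings.warn("single environment: G x E variance is inestimable")

        X = np.hstack([np.ones((len(sub), 1)), _dummies(env, drop_first=True)])
        kernels = [factor_kernel(geno)]
        names = ["genotype"]
        if gxe_ok:
            kernels.append(factor_kernel(pd.Series(geno).astype(str) + "@" + pd.Series(env).astype(str)))
            names.append("gxe")
        kernels.append(factor_kernel(rep_in_env.to_numpy()))
        names.append("rep")
        res = reml_fit(y, X, kernels, names=names)

        significance = {}
        for comp in ("genotype", "gxe"):
            if comp not in names:
                continue
            reduced_idx = [i for i, nm in enumerate(names) if nm != comp]
            red = reml_fit(y, X, [kernels[i] for i in reduced_idx],
                           names=[names[i] for i in reduced_idx])
            lrt = max(0.0, 2.0 * (res.loglik - red.loglik))
            significance[comp] = {"lrt": lrt, "pvalue": mixture_chi2_pvalue(lrt)}

        blues = self._blues(sub, res)
        variances = {
            "genotype": res.variances["genotype"],
            "gxe": res.variances.get("gxe", np.nan),
            "rep": res.variances["rep"],
            "residual": res.variances["residual"],
        }
        return TrialResults(
            trait=self.trait,
            variances=variances,
            significance=significance,
            blues=blues,
            n_env=n_env,
            n_rep=max(n_rep, 1),
            loglik=res.loglik,
            gxe_estimable=gxe_ok,
        )

    def _blues(self, sub, varcomp) -> pd.Series:
        """GLS BLUEs with genotype fixed, averaging over environments."""
        y = sub["value"].to_numpy(dtype=float)
        geno_codes, geno_levels = pd.factorize(sub["genotype"], sort=True)
        G = np.eye(len(geno_levels))[geno_codes]
        E = _dummies(sub["environment"])
        E_centered = E - E.mean(axis=0, keepdims=True)
        X = np.hstack([G, E_centered[:, 1:]])
        V = varcomp.variances["residual"] * np.eye(len(y))
        if "gxe" in varcomp.variances:
            V += varcomp.variances["gxe"] * factor_kernel(
                sub["genotype"].astype(str) + "@" + sub["environment"].astype(str)
            )
        V += varcomp.variances["rep"] * factor_kernel(
            sub["environment"].astype(str) + ":" + sub["replicate"].astype(str)
        )
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
        return pd.Series(beta[: len(geno_levels)], index=geno_levels, name=self.trait)


def fit_trial_model(records: pd.DataFrame, trait=None) -> TrialResults:
    """Fit the across-environment trial model for one trait."""
    return TrialModel(records, trait).fit()


def broad_sense_heritability(sigma2_g, sigma2_gxe, sigma2_e, n_env, n_rep) -> float:
    """H2 on an entry-mean basis across environments and replicates."""
    if n_env < 1 or n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    denom = sigma2_g + sigma2_gxe / n_env + sigma2_e / (n_env * n_rep)
    if denom <= 0:
        warnings.warn("all variance components are zero: heritability undefined")
        return float("nan")
    return float(sigma2_g / denom)


def summarize_trait(values) -> dict:
    """Min, max, mean, SD and CV% of a trait vector (Table-1-style)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least two observations to summarize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0:
        warnings.warn("mean is zero: CV undefined")
        cv = float("nan")
    else:
        cv = 100.0 * sd / mean
    return {"min": float(v.min()), "max": float(v.max()), "mean": mean, "SD": sd, "CV": cv}


# ---------------------------------------------------------------------------
# within-environment BLUEs and midparent heterosis

def within_env_blue(records: pd.DataFrame, trait=None) -> pd.Series:
    """Per-genotype BLUE in a single environment (genotype fixed,
    replicate random).  With one replicate the BLUE is the observation."""
    sub = _one_trait(records, trait)
    envs = sub["environment"].unique()
    if len(envs) != 1:
        raise ValueError("within_env_blue expects records from one environment")
    y = sub["value"].to_numpy(dtype=float)
    geno_codes, geno_levels = pd.factorize(sub["genotype"], sort=True)
    G = np.eye(len(geno_levels))[geno_codes]
    reps = sub["replicate"].unique()
    if len(reps) == 1 or len(sub) == len(geno_levels):
        vals = pd.Series(y, index=sub["genotype"].to_numpy()).groupby(level=0).mean()
        return vals.rename(sub["trait"].iloc[0])
    res = reml_fit(y, G, [factor_kernel(sub["replicate"])], names=["rep"])
    V = res.variances["rep"] * factor_kernel(sub["replicate"]) + res.sigma2 * np.eye(len(y))
    Vi_G = np.linalg.solve(V, G)
    beta = np.linalg.solve(G.T @ Vi_G, Vi_G.T @ y)
    return pd.Series(beta, index=geno_levels, name=sub["trait"].iloc[0])


def compute_mph(hybrid, parent1, parent2):
    """Midparent heterosis MPH = H - (P1 + P2) / 2 (NaN propagates)."""
    return np.asarray(hybrid, dtype=float) - (
        np.asarray(parent1, dtype=float) + np.asarray(parent2, dtype=float)
    ) / 2.0


def mph_table(blues: pd.DataFrame, parent_of: dict) -> pd.DataFrame:
    """Per-hybrid, per-environment MPH from within-environment BLUEs.

    blues: long DataFrame (genotype, environment, value) holding hybrid and
    parent BLUEs; parent_of maps hybrid id -> (parent1 id, parent2 id).
    Hybrids with a missing parent BLUE in an environment get NaN there.
    """
    wide = blues.pivot_table(index="genotype", columns="environment", values="value", aggfunc="first")
    rows = []
    for hyb, (p1, p2) in parent_of.items():
        if hyb not in wide.index:
            continue
        for env in wide.columns:
            h = wide.at[hyb, env]
            v1 = wide.at[p1, env] if p1 in wide.index else np.nan
            v2 = wide.at[p2, env] if p2 in wide.index else np.nan
            rows.append(
                {"genotype": hyb, "environment": env,
                 "value": float(compute_mph(h, v1, v2))}
            )
    return pd.DataFrame(rows)


@dataclass
class MPHResults:
    """Second-step MPH mixed model: variance components and heritability."""

    variances: dict           # 'genotype', 'env', 'residual'
    heritability: float
    blues: pd.Series
    n_env: int
    loglik: float


def mph_model(mph_records: pd.DataFrame) -> MPHResults:
    """MPH_ij = mu + G_i + E_j + eps_ij with G and E random.

    The MPH heritability is sigma2_G / (sigma2_G + sigma2_eps / N_E):
    replicate variation is already absorbed by the first-step BLUEs.
    Genotype is refit as fixed for the MPH BLUEs.
    """
    req = {"genotype", "environment", "value"}
    if not req.issubset(mph_records.columns):
        raise ValueError(f"MPH records need columns {sorted(req)}")
    sub = mph_records.dropna(subset=["value"]).reset_index(drop=True)
    envs = sub["environment"].unique()
    if len(envs) < 2:
        raise ValueError("MPH model needs at least two environments")
    y = sub["value"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    Kg = factor_kernel(sub["genotype"])
    Ke = factor_kernel(sub["environment"])
    res = reml_fit(y, X, [Kg, Ke], names=["genotype", "env"])
    n_env = len(envs)
    h2 = res.variances["genotype"] / (
        res.variances["genotype"] + res.variances["residual"] / n_env
    ) if (res.variances["genotype"] + res.variances["residual"]) > 0 else float("nan")
    # BLUEs: genotype fixed, environment random
    geno_codes, geno_levels = pd.factorize(sub["genotype"], sort=True)
    G = np.eye(len(geno_levels))[geno_codes]
    V = res.variances["env"] * Ke + res.variances["residual"] * np.eye(len(y))
    Vi_G = np.linalg.solve(V, G)
    beta = np.linalg.solve(G.T @ Vi_G, Vi_G.T @ y)
    blues = pd.Series(beta, index=geno_levels, name="mph")
    return MPHResults(
        variances={
            "genotype": res.variances["genotype"],
            "env": res.variances["env"],
            "residual": res.variances["residual"],
        },
        heritability=float(h2),
        blues=blues,
        n_env=n_env,
        loglik=res.loglik,
    )


# ---------------------------------------------------------------------------
# GCA / SCA decomposition

@dataclass
class GCASCAResult:
    """Combining-ability variance components of hybrid performance."""

    variances: dict
    sca_gca_ratio: float
    sca_env_estimable: bool
    loglik: float

    def summary(self) -> pd.Series:
        s = pd.Series(self.variances)
        s["SCA/GCA"] = self.sca_gca_ratio
        return s


def gca_sca_decompose(hybrid_values: pd.DataFrame) -> GCASCAResult:
    """Random-effect decomposition y = mu + E + GCA_RIL + GCA_Tester + SCA
    + GCA_RIL x E + GCA_Tester x E + SCA x E + eps.

    hybrid_values: long DataFrame with columns ril, tester, environment,
    value (one row per hybrid x environment, typically within-environment
    BLUEs).  With a single observation per hybrid x environment cell the
    SCA x E variance is confounded with the residual and reported as NaN.
    The ratio is sigma2_SCA / (sigma2_GCA_RIL + sigma2_GCA_Tester).
    """
    req = {"ril", "tester", "environment", "value"}
    if not req.issubset(hybrid_values.columns):
        raise ValueError(f"need columns {sorted(req)}")
    sub = hybrid_values.dropna(subset=["value"]).reset_index(drop=True)
    if sub["tester"].nunique() < 2:
        raise ValueError("SCA is not identifiable with a single tester")
    y = sub["value"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    ril = sub["ril"].astype(str)
    tester = sub["tester"].astype(str)
    env = sub["environment"].astype(str)
    cell = ril + "x" + tester + "@" + env
    replicated = sub.groupby(["ril", "tester", "environment"]).size().max() > 1
    kernels = [
        factor_kernel(env),
        factor_kernel(ril),
        factor_kernel(tester),
        factor_kernel(ril + "x" + tester),
        factor_kernel(ril + "@" + env),
        factor_kernel(tester + "@" + env),
    ]
    names = ["env", "gca_ril", "gca_tester", "sca", "gca_ril_x_env", "gca_tester_x_env"]
    if replicated:
        kernels.append(factor_kernel(cell))
        names.append("sca_x_env")
    res = reml_fit(y, X, kernels, names=names)
    variances = {name: res.variances[name] for name in names}
    variances["residual"] = res.sigma2
    if not replicated:
        variances["sca_x_env"] = float("nan")
        warnings.warn("one observation per hybrid x environment: SCA x E is "
                      "confounded with the residual")
    gca_sum = variances["gca_ril"] + variances["gca_tester"]
    ratio = variances["sca"] / gca_sum if gca_sum > 0 else float("inf")
    return GCASCAResult(
        variances=variances,
        sca_gca_ratio=float(ratio),
        sca_env_estimable=bool(replicated),
        loglik=res.loglik,
    )


# ---------------------------------------------------------------------------
# correlations and path analysis

@dataclass
class PathResult:
    """Pairwise trait correlations and path coefficients toward a response.

    Path coefficients are standardized partial regression coefficients,
    p_i = b_i * s_Xi / s_Y; the display threshold (default 0.14) only
    affects formatted output, never the stored values.
    """

    correlations: pd.DataFrame
    path_coefficients: pd.Series
    response: str
    unstable: bool = False
    display_threshold: float = 0.14

    def display(self) -> pd.Series:
        p = self.path_coefficients
        return p[p.abs() >= self.display_threshold]


def correlations_and_path(trait_table: pd.DataFrame, response: str) -> PathResult:
    """Correlation matrix of all traits plus path coefficients of the
    response on the remaining traits (complete-case)."""
    if response not in trait_table.columns:
        raise ValueError(f"response {response!r} not among traits")
    df = trait_table.dropna()
    predictors = [c for c in df.columns if c != response]
    if len(df) < len(predictors) + 2:
        raise ValueError("not enough complete-case rows for path analysis")
    corr = df.corr()
    Xs = (df[predictors] - df[predictors].mean()) / df[predictors].std(ddof=1)
    ys = (df[response] - df[response].mean()) / df[response].std(ddof=1)
    A = Xs.to_numpy(dtype=float)
    cond = np.linalg.cond(A.T @ A)
    unstable = bool(cond > 1e8)
    if unstable:
        warnings.warn(f"collinear predictors (condition number {cond:.3g}); "
                      "path coefficients are unstable")
    coef, *_ = np.linalg.lstsq(A, ys.to_numpy(dtype=float), rcond=None)
    return PathResult(
        correlations=corr,
        path_coefficients=pd.Series(coef, index=predictors, name=f"path->{response}"),
        response=response,
        unstable=unstable,
    )
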