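"""Genomic prediction of hybrid performance with additive + dominance kernels.

GBLUP model: y = X beta + xi_a + xi_d + eps with xi_a ~ N(0, K_a sigma2_a),
xi_d ~ N(0, K_d sigma2_d).  Predictions for unphenotyped hybrids come from
the conditional expectation of their genetic values given the training
phenotypes.  Weighted GS (wGS) adds the peak markers of significant QTL —
re-mapped inside every training fold — as fixed-effect columns.

Three cross-validation schemes mimic hybrid-breeding scenarios with two
testers: CV1 trains on one tester population and predicts the other
(additive-only model); CV2 trains on the hybrids whose RIL parents appear
under both testers; CV3 trains on hybrids with disjoint RIL sets under the
two testers, so every test hybrid's RIL is phenotyped under the other
tester.  Accuracy is the plain correlation between predicted and observed
values over two-fold partitions repeated (by default) 200 times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import reml_fit

__all__ = [
    "CVPartition",
    "CVResult",
    "GBLUP",
    "gblup_fit_predict",
    "make_cv_partitions",
    "run_cross_validation",
]

SCHEMES = ("within", "CV1", "CV2", "CV3")


@dataclass
class CVPartition:
    scheme: str
    train: np.ndarray
    test: np.ndarray
    fold: int
    repeat: int
    seed: int | None = None

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets overlap")


@dataclass
class CVResult:
    """Per-partition prediction accuracies and their summary."""

    table: pd.DataFrame  # scheme, model, repeat, fold, accuracy
    fixed_snps: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["scheme", "model"])["accuracy"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


class GBLUP:
    """Additive(+dominance) GBLUP over a joint kinship of all individuals.

    Parameters
    ----------
    y : Series or array
        Phenotypes for all individuals (BLUEs); only training entries are
        used for fitting.
    kinships : mapping
        {'a': K_a} or {'a': K_a, 'd': K_d}, each over all individuals.
    X : array, optional
        Fixed-effect design over all individuals (default intercept).
        wGS fixed-marker columns are appended here.
    """

    def __init__(self, y, kinships, X=None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.shape[0]
        self.kernels = {k: np.asarray(v, dtype=float) for k, v in kinships.items()}
        for name, K in self.kernels.items():
            if K.shape != (n, n):
                raise ValueError(f"kernel {name} does not match n={n}")
        if X is None:
            X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("X rows do not match y")

    def fit_predict(self, train_idx, test_idx):
        """REML fit on the training rows; BLUP prediction for test rows."""
        tr = np.asarray(train_idx)
        te = np.asarray(test_idx)
        if np.ptp(self.y[tr]) == 0:
            # degenerate training response: predict its constant value
            return np.full(len(te), self.y[tr][0] if len(tr) else np.nan), None
        X_tr = self.X[tr]
        # drop constant columns (beyond the intercept) that carry no signal
        keep = [0] + [
            j for j in range(1, X_tr.shape[1]) if np.ptp(X_tr[:, j]) > 0
        ]
        if len(keep) < X_tr.shape[1]:
            warnings.warn("constant fixed-effect column(s) in training set dropped")
        # also drop collinear columns to keep the GLS solvable
        Xk = X_tr[:, keep]
        rank_cols = [0]
        for j in range(1, Xk.shape[1]):
            trial = Xk[:, rank_cols + [j]]
            if np.linalg.matrix_rank(trial) == len(rank_cols) + 1:
                rank_cols.append(j)
        cols = [keep[j] for j in rank_cols]
        X_tr = self.X[np.ix_(tr, cols)]
        X_te = self.X[np.ix_(te, cols)]
        names = list(self.kernels)
        res = reml_fit(
            self.y[tr], X_tr, [self.kernels[k][np.ix_(tr, tr)] for k in names],
            names=names,
        )
        V_tr = res.variances["residual"] * np.eye(len(tr))
        for k in names:
            V_tr += res.variances[k] * self.kernels[k][np.ix_(tr, tr)]
        r = self.y[tr] - X_tr @ res.beta
        alpha = np.linalg.solve(V_tr, r)
        g_te = np.zeros(len(te))
        for k in names:
            g_te += res.variances[k] * (self.kernels[k][np.ix_(te, tr)] @ alpha)
        return X_te @ res.beta + g_te, res


def gblup_fit_predict(y, kinships, train_idx, test_idx, X=None, fixed_snps=None):
    """Functional GBLUP: fit on train rows, predict test rows.

    fixed_snps: optional (n, q) matrix of marker columns entering as fixed
    effects (wGS); constant columns in the training portion are dropped with
    a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if fixed_snps is not None and np.size(fixed_snps):
        S = np.asarray(fixed_snps, dtype=float).reshape(n, -1)
        S = np.where(np.isnan(S), 0.0, S)
        X = np.hstack([X, S])
    model = GBLUP(y, kinships, X=X)
    pred, _ = model.fit_predict(train_idx, test_idx)
    return pred


def make_cv_partitions(
    hybrids: pd.DataFrame,
    scheme: str,
    nfolds: int = 2,
    repeats: int = 200,
    seed: int | None = None,
) -> list[CVPartition]:
    """Build cross-validation partitions over hybrid indices.

    hybrids: DataFrame with columns hybrid, ril, tester (row order defines
    the indices used by the partitions).

    within: random nfolds-fold split inside a single population.
    CV1: one tester population trains, the other tests (two fixed
    partitions; no randomness).
    CV2: the training fold is the hybrids whose RIL parents appear under
    both testers (the same random half of RILs in TC and TM); the rest test.
    CV3: the training fold pairs one half of the RILs with the first tester
    and the other half with the second tester, so train RIL sets are
    disjoint across testers and every test hybrid's RIL is in training
    under the other tester.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    req = {"hybrid", "ril", "tester"}
    if not req.issubset(hybrids.columns):
        raise ValueError(f"hybrid table needs columns {sorted(req)}")
    testers = sorted(hybrids["tester"].unique())
    rng = np.random.default_rng(seed)
    idx_all = np.arange(len(hybrids))
    parts: list[CVPartition] = []
    if scheme == "CV1":
        if len(testers) != 2:
            raise ValueError("CV1 requires exactly two tester populations")
        for fold, (tr_t, te_t) in enumerate([(testers[0], testers[1]), (testers[1], testers[0])]):
            tr = idx_all[hybrids["tester"] == tr_t]
            te = idx_all[hybrids["tester"] == te_t]
            parts.append(CVPartition("CV1", tr, te, fold=fold, repeat=0, seed=seed))
        return parts
    if scheme == "within":
        if len(testers) != 1:
            raise ValueError("'within' expects hybrids of a single population")
        for rep in range(repeats):
            perm = rng.permutation(idx_all)
            folds = np.array_split(perm, nfolds)
            for f in range(nfolds):
                te = np.sort(folds[f])
                tr = np.sort(np.setdiff1d(idx_all, te))
                parts.append(CVPartition("within", tr, te, fold=f, repeat=rep, seed=seed))
        return parts
    # CV2 / CV3 need the RIL-sharing structure across two testers
    if len(testers) != 2:
        raise ValueError(f"{scheme} requires exactly two tester populations")
    rils = np.array(sorted(hybrids["ril"].unique()))
    t0, t1 = testers
    for rep in range(repeats):
        perm = rng.permutation(rils)
        halves = np.array_split(perm, nfolds)
        for f in range(nfolds):
            half = set(halves[f])
            if scheme == "CV2":
                tr_mask = hybrids["ril"].isin(half)
            else:  # CV3
                other = set(perm) - half
                tr_mask = (
                    (hybrids["tester"] == t0) & hybrids["ril"].isin(half)
                ) | ((hybrids["tester"] == t1) & hybrids["ril"].isin(other))
            tr = idx_all[tr_mask.to_numpy()]
            te = np.sort(np.setdiff1d(idx_all, tr))
            parts.append(CVPartition(scheme, np.sort(tr), te, fold=f, repeat=rep, seed=seed))
    return parts


def run_cross_validation(
    y,
    kinships,
    hybrids: pd.DataFrame,
    scheme: str,
    model: str = "GS",
    X=None,
    partitions=None,
    nfolds: int = 2,
    repeats: int = 200,
    seed: int | None = None,
    fixed_snp_rule=None,
) -> CVResult:
    """Fit/predict/correlate over cross-validation partitions.

    For wGS, ``fixed_snp_rule(train_idx)`` must return the marker columns
    (an (n, q) matrix over all individuals) to use as fixed effects; it is
    called once per partition with the training indices only, so marker
    selection never sees test phenotypes.  CV1 uses an additive-only model;
    the other schemes use additive + dominance.
    """
    if model not in ("GS", "wGS"):
        raise ValueError("model must be 'GS' or 'wGS'")
    if model == "wGS" and fixed_snp_rule is None:
        raise ValueError("wGS needs a fixed_snp_rule")
    y = np.asarray(y, dtype=float).ravel()
    if partitions is None:
        partitions = make_cv_partitions(hybrids, scheme, nfolds=nfolds,
                                        repeats=repeats, seed=seed)
    use_kernels = {"a": kinships["a"]}
    if scheme != "CV1" and "d" in kinships:
        use_kernels["d"] = kinships["d"]
    rows = []
    snp_log = {}
    for part in partitions:
        fixed = None
        if model == "wGS":
            fixed = fixed_snp_rule(part.train)
            snp_log[(part.repeat, part.fold)] = (
                fixed.shape[1] if fixed is not None and np.size(fixed) else 0
            )
        pred = gblup_fit_predict(
            y, use_kernels, part.train, part.test, X=X, fixed_snps=fixed
        )
        obs = y[part.test]
        if np.std(pred) == 0 or np.std(obs) == 0:
            acc = np.nan
        else:
            acc = float(np.corrcoef(pred, obs)[0, 1])
        rows.append(
            {"scheme": part.scheme, "model": model, "repeat": part.repeat,
             "fold": part.fold, "accuracy": acc}
        )
    return CVResult(table=pd.DataFrame(rows), fixed_snps=snp_log)
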