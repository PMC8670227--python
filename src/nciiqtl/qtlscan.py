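"""Genome scans, QTL interval calling, pleiotropy grouping and favorable-QTL analysis.

Scans run on whitened data: per marker, the additive (Z_k) or dominance
(W_k) column is added to the null design and tested by the ML likelihood
ratio, reported as LOD = LRT / 4.61.  Epistatic scans test the whitened
element-wise product of two marker columns against the corresponding
two-main-effect null (the four interaction classes aa, ad, da, dd); the
product is formed in the original design space and then whitened, because
whitening does not commute with element-wise products.
Empirical LOD thresholds: 2.5 for main effects, 5.0 for epistasis, 2.0 for
the favorable-QTL analysis.  QTL intervals use greedy peak selection within
a 10 cM window followed by the 1.5-LOD drop; QTL of different traits are
grouped as pleiotropic when intervals overlap or peaks are within 0.65 cM.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import HybridCoding, MarkerMap
from .mixedmodel import LOD_SCALE, WhitenedData, ml_lrt

__all__ = [
    "scan_main_effects",
    "scan_epistasis",
    "call_qtl_intervals",
    "group_pleiotropic",
    "compute_pve",
    "favorable_qtl_analysis",
    "MAIN_LOD_THRESHOLD",
    "EPISTASIS_LOD_THRESHOLD",
    "FAVORABLE_LOD_THRESHOLD",
]

MAIN_LOD_THRESHOLD = 2.5
EPISTASIS_LOD_THRESHOLD = 5.0
FAVORABLE_LOD_THRESHOLD = 2.0

_EPI_NULLS = {
    # effect type -> (main-effect design for k, for k', interaction factors)
    "aa": ("Z", "Z", ("Z", "Z")),
    "ad": ("Z", "W", ("Z", "W")),
    "da": ("Z", "W", ("W", "Z")),
    "dd": ("W", "W", ("W", "W")),
}


def _design_columns(coding_or_ZW):
    if isinstance(coding_or_ZW, HybridCoding):
        return coding_or_ZW.Z, coding_or_ZW.W, coding_or_ZW.markers
    Z, W = coding_or_ZW
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    markers = np.array([f"m{k}" for k in range(Z.shape[1])], dtype=object)
    return Z, W, markers


def _background_from(wd: WhitenedData) -> np.ndarray:
    U, D = wd.eigenvectors, wd.eigenvalues
    return (U * D) @ U.T


def _subset_whiten(K, rows, y, X):
    """Local whitening of a row subset via Cholesky of (K+I)[rows, rows]."""
    H = K[np.ix_(rows, rows)] + np.eye(len(rows))
    L = np.linalg.cholesky(H)
    yw = np.linalg.solve(L, y[rows])
    Xw = np.linalg.solve(L, X[rows])
    return yw, Xw, L


def _residualize(A, Q0):
    return A - Q0 @ (Q0.T @ A)


def scan_main_effects(
    whitened: WhitenedData,
    coding_or_ZW,
    y=None,
    X=None,
    dominance_only: bool = False,
    marker_map: MarkerMap | None = None,
) -> pd.DataFrame:
    """Per-marker additive and dominance LOD scan on whitened data.

    Marker columns with missing codes are tested on the complete rows only,
    re-whitening the row subset against the same background (missing codes
    are never imputed for per-marker tests).  For midparent-heterosis
    datasets pass ``dominance_only=True``: additive effects do not
    contribute to MPH.  ``y``/``X`` are the untransformed response and
    fixed design, needed only when some codes are missing.

    Returns one row per marker with lrt/lod/effect/rss columns per effect
    type and map coordinates when a map is supplied.
    """
    Z, W, markers = _design_columns(coding_or_ZW)
    n = whitened.y_star.shape[0]
    effects = ("dom",) if dominance_only else ("add", "dom")
    Q0, _ = np.linalg.qr(whitened.X_star)
    y_r = _residualize(whitened.y_star, Q0)
    rss0 = float(y_r @ y_r)
    T = whitened.transform
    K_bg = None
    out = {"marker": markers}
    if marker_map is not None:
        pos = marker_map.table.set_index("marker")
        out["chromosome"] = pos.loc[markers, "chromosome"].to_numpy()
        out["cM"] = pos.loc[markers, "cM"].to_numpy(dtype=float)
        out["bp"] = pos.loc[markers, "bp"].to_numpy()
    for eff in effects:
        M = Z if eff == "add" else W
        miss = np.isnan(M)
        clean = ~miss.any(axis=0)
        lrt = np.zeros(M.shape[1])
        est = np.full(M.shape[1], np.nan)
        rss_full = np.full(M.shape[1], rss0)
        flags = np.zeros(M.shape[1], dtype=bool)
        if clean.any():
            C = T @ M[:, clean]
            Cr = _residualize(C, Q0)
            den = np.einsum("ij,ij->j", Cr, Cr)
            num = Cr.T @ y_r
            ok = den > 1e-10 * n
            beta = np.where(ok, num / np.where(den > 0, den, 1.0), np.nan)
            rss1 = np.where(ok, rss0 - np.where(ok, num, 0.0) * beta, rss0)
            rss1 = np.clip(rss1, 1e-300, None)
            lrt_c = np.where(ok, n * np.log(rss0 / rss1), 0.0)
            idx = np.flatnonzero(clean)
            lrt[idx] = np.maximum(lrt_c, 0.0)
            est[idx] = beta
            rss_full[idx] = rss1
            flags[idx] = ~ok
        for k in np.flatnonzero(~clean):
            if K_bg is None:
                K_bg = _background_from(whitened)
                if y is None or X is None:
                    raise ValueError(
                        "markers with missing codes need the untransformed y and X"
                    )
            rows = np.flatnonzero(~miss[:, k])
            if rows.size <= whitened.X_star.shape[1] + 1:
                flags[k] = True
                continue
            yw, Xw, L = _subset_whiten(K_bg, rows, np.asarray(y, float), np.asarray(X, float))
            cw = np.linalg.solve(L, M[rows, k])
            res = ml_lrt((yw, Xw), full_columns=cw[:, None])
            lrt[k] = res["lrt"]
            est[k] = res["effects"][0]
            rss_full[k] = res["rss_full"]
            flags[k] = not res["estimable"]
        out[f"lrt_{eff}"] = lrt
        out[f"lod_{eff}"] = lrt / LOD_SCALE
        out[f"effect_{eff}"] = est
        out[f"rss_null_{eff}"] = np.full(M.shape[1], rss0)
        out[f"rss_full_{eff}"] = rss_full
        out[f"inestimable_{eff}"] = flags
    return pd.DataFrame(out)


def scan_epistasis(
    whitened: WhitenedData,
    coding_or_ZW,
    effect_type: str,
    pairs=None,
    anchor=None,
    y=None,
    X=None,
    max_pairs: int | None = None,
) -> pd.DataFrame:
    """Pairwise interaction scan for one effect type in {aa, ad, da, dd}.

    For a pair (k, k') the null model carries the two main-effect columns of
    the type's parental roles and the full model adds the whitened
    element-wise product of the two marker columns (product first, then
    transform).  Modes: ``pairs`` (explicit list
    of index pairs), ``anchor`` (one marker index against all others, the
    anchor always taking the k role), or exhaustive over unordered pairs.
    Rows with a missing code at either marker are dropped for that pair.
    """
    if effect_type not in _EPI_NULLS:
        raise ValueError(f"effect_type must be one of {tuple(_EPI_NULLS)}")
    Z, W, markers = _design_columns(coding_or_ZW)
    m = Z.shape[1]
    if anchor is not None:
        pairs = [(anchor, k) for k in range(m) if k != anchor]
    elif pairs is None:
        pairs = list(combinations(range(m), 2))
    if max_pairs is not None:
        pairs = list(pairs)[:max_pairs]
    role_k, role_k2, (ia, ib) = _EPI_NULLS[effect_type]
    Mk = Z if role_k == "Z" else W
    Mk2 = Z if role_k2 == "Z" else W
    Ia = Z if ia == "Z" else W
    Ib = Z if ib == "Z" else W
    T = whitened.transform
    K_bg = None
    rows_out = []
    for k, k2 in pairs:
        if k == k2:
            continue
        cols = np.column_stack([Mk[:, k], Mk2[:, k2], Ia[:, k], Ib[:, k2]])
        miss = np.isnan(cols).any(axis=1)
        if miss.any():
            if K_bg is None:
                K_bg = _background_from(whitened)
                if y is None or X is None:
                    raise ValueError("pairs with missing codes need untransformed y, X")
            rows = np.flatnonzero(~miss)
            yw, Xw, L = _subset_whiten(K_bg, rows, np.asarray(y, float), np.asarray(X, float))
            main1 = np.linalg.solve(L, Mk[rows, k])
            main2 = np.linalg.solve(L, Mk2[rows, k2])
            inter = np.linalg.solve(L, Ia[rows, k] * Ib[rows, k2])
        else:
            yw, Xw = whitened.y_star, whitened.X_star
            main1 = T @ Mk[:, k]
            main2 = T @ Mk2[:, k2]
            inter = T @ (Ia[:, k] * Ib[:, k2])
        res = ml_lrt((yw, Xw), null_columns=np.column_stack([main1, main2]),
                     full_columns=inter[:, None])
        rows_out.append(
            {
                "marker_k": markers[k],
                "marker_k2": markers[k2],
                "k": k,
                "k2": k2,
                "effect_type": effect_type,
                "lrt": res["lrt"],
                "lod": res["lod"],
                "effect": res["effects"][0],
                "rss_null": res["rss_null"],
                "rss_full": res["rss_full"],
                "inestimable": not res["estimable"],
            }
        )
    return pd.DataFrame(rows_out)


def call_qtl_intervals(
    scan: pd.DataFrame,
    lod_column: str = "lod_add",
    lod_threshold: float = MAIN_LOD_THRESHOLD,
    window_cM: float = 10.0,
    drop: float = 1.5,
    trait: str | None = None,
    dataset: str | None = None,
) -> pd.DataFrame:
    """Greedy QTL peak calling with 1.5-LOD support intervals.

    Per chromosome: (1) markers passing the LOD threshold are candidates;
    (2) peaks are taken highest-LOD first (ties to the lower cM), removing
    other candidates within ``window_cM``; (3) each peak's interval is the
    contiguous marker run around it with LOD >= peak - ``drop``, snapped to
    marker positions.
    """
    required = {"marker", "chromosome", "cM", lod_column}
    if not required.issubset(scan.columns):
        raise ValueError(f"scan table needs columns {sorted(required)}")
    records = []
    eff_col = lod_column.replace("lod", "effect")
    rssn_col = lod_column.replace("lod", "rss_null")
    rssf_col = lod_column.replace("lod", "rss_full")
    for chrom, sub in scan.groupby("chromosome", sort=False):
        sub = sub.sort_values("cM").reset_index(drop=True)
        lod = sub[lod_column].to_numpy(dtype=float)
        cm = sub["cM"].to_numpy(dtype=float)
        candidates = set(np.flatnonzero(lod > lod_threshold))
        order = sorted(candidates, key=lambda i: (-lod[i], cm[i]))
        for i in order:
            if i not in candidates:
                continue
            candidates -= {j for j in candidates if abs(cm[j] - cm[i]) <= window_cM}
            lo = hi = i
            while lo > 0 and lod[lo - 1] >= lod[i] - drop:
                lo -= 1
            while hi < len(lod) - 1 and lod[hi + 1] >= lod[i] - drop:
                hi += 1
            rec = {
                "trait": trait,
                "dataset": dataset,
                "chromosome": chrom,
                "peak_marker": sub["marker"].iloc[i],
                "peak_cM": cm[i],
                "peak_lod": lod[i],
                "ci_lo_cM": cm[lo],
                "ci_hi_cM": cm[hi],
            }
            if "bp" in sub.columns:
                rec["peak_bp"] = sub["bp"].iloc[i]
                rec["ci_lo_bp"] = sub["bp"].iloc[lo]
                rec["ci_hi_bp"] = sub["bp"].iloc[hi]
            if eff_col in sub.columns:
                rec["effect"] = sub[eff_col].iloc[i]
            if rssn_col in sub.columns and rssf_col in sub.columns:
                rec["pve"] = compute_pve(sub[rssf_col].iloc[i], sub[rssn_col].iloc[i])
            records.append(rec)
    qtl = pd.DataFrame(records)
    if not qtl.empty:
        qtl = qtl.sort_values(["chromosome", "peak_cM"]).reset_index(drop=True)
        qtl["name"] = _qtl_names(qtl)
    return qtl


def _qtl_names(qtl: pd.DataFrame) -> list:
    """QTL names: q + trait + chromosome number, with a dataset prefix
    separated by a dash and a serial suffix for multiples per chromosome."""
    names = []
    seen = {}
    for _, row in qtl.iterrows():
        chrom = str(row["chromosome"])
        num = "".join(ch for ch in chrom if ch.isdigit()) or chrom
        trait = (row["trait"] or "trait").upper() if row["trait"] else "TRAIT"
        base = f"q{trait}{num}"
        if row["dataset"]:
            base = f"{row['dataset']}-{base}"
        count = seen.get((base,), 0) + 1
        seen[(base,)] = count
        names.append(base if count == 1 else f"{base}.{count}")
    return names


def group_pleiotropic(qtls: pd.DataFrame, proximity_cM: float = 0.65) -> pd.DataFrame:
    """Assign pleiotropy group ids: QTL on the same chromosome whose
    intervals overlap or whose peaks are within ``proximity_cM`` are merged
    (transitive closure)."""
    if qtls.empty:
        out = qtls.copy()
        out["pleiotropy_group"] = pd.Series(dtype=int)
        return out
    q = qtls.reset_index(drop=True)
    parent = list(range(len(q)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(q)):
        for j in range(i + 1, len(q)):
            if q.at[i, "chromosome"] != q.at[j, "chromosome"]:
                continue
            overlap = (
                q.at[i, "ci_lo_cM"] <= q.at[j, "ci_hi_cM"]
                and q.at[j, "ci_lo_cM"] <= q.at[i, "ci_hi_cM"]
            )
            close = abs(q.at[i, "peak_cM"] - q.at[j, "peak_cM"]) <= proximity_cM
            if overlap or close:
                union(i, j)
    roots = [find(i) for i in range(len(q))]
    ids = {r: g for g, r in enumerate(dict.fromkeys(roots))}
    q["pleiotropy_group"] = [ids[r] for r in roots]
    return q


def compute_pve(rss_full: float, rss_null: float) -> float:
    """Proportion of variance explained, 1 - RSS_full / RSS_null, in [0, 1]."""
    if rss_null <= 0:
        raise ValueError("rss_null must be positive")
    pve = 1.0 - rss_full / rss_null
    if pve < 0:
        warnings.warn("rss_full exceeds rss_null; PVE clipped to 0")
        return 0.0
    return float(min(pve, 1.0))


def favorable_qtl_analysis(
    qtls: pd.DataFrame,
    coding: HybridCoding,
    performance: pd.Series,
) -> dict:
    """Classify QTL as heterozygous- or homozygous-favorable and correlate
    per-hybrid favorable-QTL counts with hybrid performance.

    A QTL is heterozygous-favorable when the mean performance of the
    heterozygous class (W = 1) at its peak marker exceeds that of the
    homozygous class(es); otherwise the better homozygous class defines the
    favorable genotype.  Returns per-hybrid counts and the correlations
    r1 (homozygous count), r2 (heterozygous count), r3 (total) with
    performance, each with its p-value.
    """
    if qtls.empty:
        raise ValueError("favorable-QTL analysis needs at least one QTL")
    perf = performance.reindex(coding.hybrids).to_numpy(dtype=float)
    marker_index = {mk: i for i, mk in enumerate(coding.markers)}
    hom_count = np.zeros(coding.n_hybrids)
    het_count = np.zeros(coding.n_hybrids)
    classes = []
    for _, row in qtls.iterrows():
        k = marker_index[row["peak_marker"]]
        z = coding.Z[:, k]
        w = coding.W[:, k]
        het = w == 1
        hom = w == 0
        if not het.any() or not hom.any():
            warnings.warn(f"QTL {row.get('name', row['peak_marker'])}: a genotype "
                          "class is absent; skipped")
            continue
        het_mean = np.nanmean(perf[het])
        hom_mean = np.nanmean(perf[hom])
        if het_mean > hom_mean:
            classes.append("heterozygous")
            het_count += het.astype(float)
        else:
            classes.append("homozygous")
            hom_levels = np.unique(z[hom & ~np.isnan(z)])
            means = {lv: np.nanmean(perf[hom & (z == lv)]) for lv in hom_levels}
            best = max(means, key=means.get)
            hom_count += (hom & (z == best)).astype(float)
    if not classes:
        raise ValueError("every QTL was skipped: no genotype classes to compare")
    total = hom_count + het_count
    ok = ~np.isnan(perf)
    corr = {}
    for label, counts in (("r1", hom_count), ("r2", het_count), ("r3", total)):
        if np.std(counts[ok]) == 0:
            corr[label] = (float("nan"), float("nan"))
        else:
            corr[label] = tuple(map(float, stats.pearsonr(counts[ok], perf[ok])))
    return {
        "counts": pd.DataFrame(
            {
                "hybrid": coding.hybrids,
                "favorable_homozygous": hom_count,
                "favorable_heterozygous": het_count,
                "favorable_total": total,
            }
        ),
        "qtl_classes": classes,
        "r1": corr["r1"],
        "r2": corr["r2"],
        "r3": corr["r3"],
    }
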