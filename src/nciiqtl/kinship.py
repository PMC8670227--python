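"""Polygenic covariance kernels for hybrid populations.

Five kernels over individuals are built from the additive (Z) and dominance
(W) design matrices: first-order K_a and K_d, and the pairwise-epistatic
K_aa, K_ad and K_dd whose defining design vectors are element-wise products
of marker columns (Z_k*Z_k', Z_k*W_k', W_k*W_k').  The epistatic kernels are
computed with closed-form Hadamard identities instead of enumerating the
~m^2/2 pairs:

    K_aa ~ (G_a o G_a - D_a) / 2,   G_a = Z Z^T,  D_a = (ZoZ)(ZoZ)^T
    K_ad ~  G_a o G_d - (ZoW)(ZoW)^T          (ordered pairs k != k')
    K_dd ~ (G_d o G_d - D_d) / 2,   G_d = W W^T,  D_d = (WoW)(WoW)^T

where "o" is the element-wise product; the subtracted terms remove the
self-pairs k = k'.  Each kernel is normalized to mean diagonal 1 so the
variance ratios attached to different kernels are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import HybridCoding

__all__ = [
    "KinshipSet",
    "compute_first_order_kinships",
    "compute_epistatic_kinships",
    "build_kinships",
    "normalize_kernel",
]

GENETIC_COMPONENTS = ("a", "d", "aa", "ad", "dd")


@dataclass
class KinshipSet:
    """The five polygenic kernels and their normalization constants."""

    K_a: np.ndarray
    K_d: np.ndarray
    K_aa: np.ndarray
    K_ad: np.ndarray
    K_dd: np.ndarray
    norms: dict = field(default_factory=dict)
    n_markers: int = 0

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, f"K_{name}")

    def items(self):
        return [(name, self[name]) for name in GENETIC_COMPONENTS]

    @property
    def n(self) -> int:
        return self.K_a.shape[0]

    def check_psd(self, tol: float = 1e-8) -> bool:
        for name, K in self.items():
            w = np.linalg.eigvalsh(K)
            if w.min() < -tol * max(1.0, w.max()):
                return False
        return True


def normalize_kernel(K: np.ndarray, label: str = "kernel"):
    """Scale a kernel to mean diagonal 1; zero kernels pass through."""
    c = float(np.mean(np.diag(K)))
    if c <= 0:
        if not np.allclose(K, 0):
            raise ValueError(f"{label} has non-positive mean diagonal")
        warnings.warn(f"{label} is identically zero; left unnormalized")
        return K, 0.0
    return K / c, c


def compute_first_order_kinships(Z: np.ndarray, W: np.ndarray):
    """K_a from Z Z^T and K_d from W W^T, each mean-diagonal normalized."""
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.isnan(Z).any() or np.isnan(W).any():
        raise ValueError("Z/W contain missing values; impute columns first")
    for M, label in ((Z, "Z"), (W, "W")):
        if np.allclose(M - M[0], 0) and M.shape[0] > 1:
            warnings.warn(f"all rows of {label} identical; kernel is uninformative")
    Ka, ca = normalize_kernel(Z @ Z.T, "K_a")
    Kd, cd = normalize_kernel(W @ W.T, "K_d")
    return Ka, Kd, {"a": ca, "d": cd}


def compute_epistatic_kinships(Z: np.ndarray, W: np.ndarray):
    """K_aa, K_ad, K_dd via the closed-form Hadamard identities."""
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.isnan(Z).any() or np.isnan(W).any():
        raise ValueError("Z/W contain missing values; impute columns first")
    m = Z.shape[1]
    if m < 2:
        warnings.warn("fewer than 2 markers: epistatic kernels are zero")
        zero = np.zeros((Z.shape[0], Z.shape[0]))
        return zero, zero.copy(), zero.copy(), {"aa": 0.0, "ad": 0.0, "dd": 0.0}
    Ga = Z @ Z.T
    Gd = W @ W.T
    Da = (Z * Z) @ (Z * Z).T
    Dd = (W * W) @ (W * W).T
    ZW = Z * W
    raw_aa = (Ga * Ga - Da) / 2.0
    raw_ad = Ga * Gd - ZW @ ZW.T
    raw_dd = (Gd * Gd - Dd) / 2.0
    Kaa, caa = normalize_kernel(raw_aa, "K_aa")
    Kad, cad = normalize_kernel(raw_ad, "K_ad")
    Kdd, cdd = normalize_kernel(raw_dd, "K_dd")
    return Kaa, Kad, Kdd, {"aa": caa, "ad": cad, "dd": cdd}


def build_kinships(coding: HybridCoding, center: bool = True) -> KinshipSet:
    """All five kernels from a hybrid coding (mean-imputing missing codes).

    With ``center=True`` (the default) marker columns are mean-centered
    before the kernels are formed, so each kernel measures covariance of
    the centered genetic component and the attached variance component is
    on the same scale as the realized (centered) variance of that
    component.  The kernel algebra itself is centering-agnostic.
    """
    Z, W = coding.imputed()
    if center:
        Z = Z - Z.mean(axis=0, keepdims=True)
        W = W - W.mean(axis=0, keepdims=True)
    Ka, Kd, norms1 = compute_first_order_kinships(Z, W)
    Kaa, Kad, Kdd, norms2 = compute_epistatic_kinships(Z, W)
    return KinshipSet(
        K_a=Ka,
        K_d=Kd,
        K_aa=Kaa,
        K_ad=Kad,
        K_dd=Kdd,
        norms={**norms1, **norms2},
        n_markers=coding.n_markers,
    )


def save_kinships(ks: KinshipSet, directory):
    """Persist kernels as TSV matrices plus a JSON sidecar of constants."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, K in ks.items():
        np.savetxt(directory / f"K_{name}.tsv", K, delimiter="\t")
    (directory / "kinship_meta.json").write_text(
        json.dumps({"norms": ks.norms, "n_markers": ks.n_markers, "n": ks.n}, indent=2)
    )
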