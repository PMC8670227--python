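"""Genotype containers, hybrid additive/dominance coding and map arithmetic.

RIL genotypes are coded relative to the two parents of the cross:
+1 for the Ye478-type allele, -1 for the Qi319-type allele, NaN for missing.
Hybrids of a RIL and a tester are coded per locus into an additive score
Z in {1, 0, -1} (0 for the heterozygote) and a dominance indicator
W in {0, 1} (1 exactly at heterozygous loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "MarkerMap",
    "HybridCoding",
    "derive_hybrid_codes",
    "pool_populations",
    "genetic_distance",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
]

_ALPHABET = (-1.0, 1.0)


@dataclass
class GenotypeTable:
    """Parental-origin codes for a set of inbred individuals.

    codes[i, k] is +1 (Ye478-type), -1 (Qi319-type) or NaN (missing /
    residual heterozygote masked before coding) for individual i at marker k.
    Markers are stored in map order.
    """

    individuals: np.ndarray
    markers: np.ndarray
    codes: np.ndarray
    het_mask: np.ndarray | None = None

    def __post_init__(self):
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("codes shape does not match individuals x markers")
        vals = self.codes[~np.isnan(self.codes)]
        if vals.size and not np.isin(vals, _ALPHABET).all():
            bad = np.unique(vals[~np.isin(vals, _ALPHABET)])
            raise ValueError(f"genotype codes outside {{+1,-1,NaN}}: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.individuals, columns=self.markers)


@dataclass
class MarkerMap:
    """Genetic map: one row per marker with chromosome, cM and bp position.

    Within each chromosome the genetic positions must be non-decreasing;
    cM is the authoritative axis for interval arithmetic, bp is carried for
    reporting.
    """

    table: pd.DataFrame

    REQUIRED = ("marker", "chromosome", "cM", "bp")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"map is missing columns {missing}")
        for _, grp in t.groupby("chromosome", sort=False):
            if (np.diff(grp["cM"].to_numpy(dtype=float)) < 0).any():
                raise ValueError("genetic positions decrease within a chromosome")
        self.table = t.reset_index(drop=True)
        self._pos = {
            m: (c, float(x))
            for m, c, x in zip(t["marker"], t["chromosome"], t["cM"])
        }

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    def position(self, marker):
        try:
            return self._pos[marker]
        except KeyError:
            raise KeyError(f"marker {marker!r} not on map") from None


@dataclass
class HybridCoding:
    """Additive (Z) and dominance (W) design for a set of hybrids.

    W[j, k] == 1 exactly when Z[j, k] == 0 at successfully coded loci;
    population_indicator is 0 for the first tester population and 1 for the
    second (the X1 fixed covariate of the pooled analysis).
    """

    hybrids: np.ndarray
    markers: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    population_indicator: np.ndarray
    parent_links: list = field(default_factory=list)

    def __post_init__(self):
        self.hybrids = np.asarray(self.hybrids, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.Z = np.asarray(self.Z, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.population_indicator = np.asarray(self.population_indicator, dtype=float)
        ok = ~np.isnan(self.Z)
        if not np.array_equal(np.isnan(self.Z), np.isnan(self.W)):
            raise ValueError("Z and W missingness must coincide")
        if not np.array_equal((self.W[ok] == 1), (self.Z[ok] == 0)):
            raise ValueError("W must be 1 exactly where Z is 0")
        if not np.isin(self.population_indicator, (0.0, 1.0)).all():
            raise ValueError("population indicator must be 0/1")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def imputed(self):
        """Column-mean-imputed (Z, W) for kernel building.

        Per-marker scans must instead drop rows with missing codes; this
        imputation is only for the polygenic kernels.
        """
        Z = self.Z.copy()
        W = self.W.copy()
        for M in (Z, W):
            mu = np.nanmean(np.where(np.isnan(M), np.nan, M), axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            idx = np.where(np.isnan(M))
            M[idx] = mu[idx[1]]
        return Z, W


def derive_hybrid_codes(
    ril: GenotypeTable,
    tester,
    tester_id: str = "tester",
    population: int = 0,
) -> HybridCoding:
    """Infer hybrid Z/W codes from RIL and tester parental-origin codes.

    At each locus: equal parental alleles give a homozygote (Z = allele,
    W = 0); different alleles give the heterozygote (Z = 0, W = 1); a
    missing code in either parent propagates to a missing hybrid code.
    """
    t = _tester_vector(tester, ril.markers)
    R = ril.codes
    T = np.broadcast_to(t, R.shape)
    Z = np.where(R == T, R, 0.0)
    W = np.where(R == T, 0.0, 1.0)
    miss = np.isnan(R) | np.isnan(T)
    Z = np.where(miss, np.nan, Z)
    W = np.where(miss, np.nan, W)
    hybrids = np.array([f"{tester_id}:{ind}" for ind in ril.individuals], dtype=object)
    links = [(ind, tester_id) for ind in ril.individuals]
    return HybridCoding(
        hybrids=hybrids,
        markers=ril.markers.copy(),
        Z=Z,
        W=W,
        population_indicator=np.full(len(hybrids), float(population)),
        parent_links=links,
    )


def _tester_vector(tester, markers) -> np.ndarray:
    if isinstance(tester, GenotypeTable):
        if tester.n_individuals != 1:
            raise ValueError("tester GenotypeTable must hold exactly one individual")
        if not np.array_equal(tester.markers, markers):
            bad = sorted(set(map(str, tester.markers)) ^ set(map(str, markers)))
            raise ValueError(f"marker sets differ between RILs and tester: {bad[:10]}")
        return tester.codes[0]
    if isinstance(tester, pd.Series):
        if not np.array_equal(tester.index.to_numpy(dtype=object), markers):
            bad = sorted(set(map(str, tester.index)) ^ set(map(str, markers)))
            raise ValueError(f"marker sets differ between RILs and tester: {bad[:10]}")
        return tester.to_numpy(dtype=float)
    t = np.asarray(tester, dtype=float).ravel()
    if t.shape[0] != len(markers):
        raise ValueError("tester vector length does not match the marker set")
    return t


def pool_populations(coding_tc: HybridCoding, coding_tm: HybridCoding) -> HybridCoding:
    """Row-stack two tester populations into the pooled TC-TM coding.

    The population indicator is 0 for the first argument's rows and 1 for
    the second's.
    """
    if not np.array_equal(coding_tc.markers, coding_tm.markers):
        bad = sorted(set(map(str, coding_tc.markers)) ^ set(map(str, coding_tm.markers)))
        raise ValueError(f"marker sets differ between populations: {bad[:10]}")
    ids = np.concatenate([coding_tc.hybrids, coding_tm.hybrids])
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).loc[pd.Series(ids).duplicated()].unique()
        raise ValueError(f"duplicated hybrid ids when pooling: {list(dup[:10])}")
    return HybridCoding(
        hybrids=ids,
        markers=coding_tc.markers.copy(),
        Z=np.vstack([coding_tc.Z, coding_tm.Z]),
        W=np.vstack([coding_tc.W, coding_tm.W]),
        population_indicator=np.concatenate(
            [np.zeros(coding_tc.n_hybrids), np.ones(coding_tm.n_hybrids)]
        ),
        parent_links=list(coding_tc.parent_links) + list(coding_tm.parent_links),
    )


def genetic_distance(marker_map: MarkerMap, marker_a, marker_b) -> float:
    """|cM difference| if the markers share a chromosome, else +inf."""
    chrom_a, pos_a = marker_map.position(marker_a)
    chrom_b, pos_b = marker_map.position(marker_b)
    if chrom_a != chrom_b:
        return float("inf")
    return abs(pos_a - pos_b)


# ---------------------------------------------------------------------------
# TSV formats (individual x marker genotype table; long map table)

def write_genotypes(table: GenotypeTable, path):
    df = table.to_frame()
    df.index.name = "individual"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeTable(
        individuals=df.index.to_numpy(dtype=object),
        markers=df.columns.to_numpy(dtype=object),
        codes=df.to_numpy(dtype=float),
    )


def write_map(marker_map: MarkerMap, path):
    marker_map.table.to_csv(path, sep="\t", index=False)


def read_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def read_vcf_as_codes(path, parent_plus: str, parent_minus: str) -> GenotypeTable:
    """Convenience VCF import: biallelic calls converted to parental codes.

    parent_plus / parent_minus name the two sample columns whose alleles
    define the +1 / -1 codes.  Sites where the two parents are not opposite
    homozygotes are skipped; heterozygous or missing offspring calls become
    NaN.  Intended for small desk-scale files, not production VCF handling.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF import") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    i_plus = samples.index(parent_plus)
    i_minus = samples.index(parent_minus)
    offspring = [s for s in samples if s not in (parent_plus, parent_minus)]
    off_idx = [samples.index(s) for s in offspring]
    markers, rows = [], []
    for var in vcf:
        g = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if {g[i_plus], g[i_minus]} != {0, 3}:
            continue
        plus_is_ref = g[i_plus] == 0
        col = np.full(len(off_idx), np.nan)
        sub = g[off_idx]
        col[sub == 0] = 1.0 if plus_is_ref else -1.0
        col[sub == 3] = -1.0 if plus_is_ref else 1.0
        markers.append(var.ID or f"{var.CHROM}_{var.POS}")
        rows.append(col)
    codes = np.array(rows).T if rows else np.empty((len(offspring), 0))
    return GenotypeTable(
        individuals=np.array(offspring, dtype=object),
        markers=np.array(markers, dtype=object),
        codes=codes,
    )
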