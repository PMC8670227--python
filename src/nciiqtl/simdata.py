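"""Synthetic NCII studies with known ground truth.

Emulates the structure of a biparental maize RIL population crossed to two
near-identical testers: RIL genomes are parental mosaics generated by a
Haldane (no-interference) crossover process along a genetic map, the two
testers share a parental allele at a configurable fraction of loci, and
multi-environment replicated phenotypes are drawn from exactly the polygenic
model the pipeline fits (additive, dominance and pairwise-epistatic marker
effects plus genotype-by-environment, replicate and residual noise).

Effect sizes are calibrated so the realized variance of each genetic
component matches its target, and both the per-marker effects and the
realized component variances are recorded so recovery tests have an exact
reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, HybridCoding, MarkerMap, derive_hybrid_codes, pool_populations

__all__ = [
    "SimConfig",
    "TrueGenetics",
    "SimStudy",
    "haldane_recombination",
    "simulate_ril_population",
    "simulate_testers",
    "simulate_phenotypes",
    "simulate_study",
    "random_truth",
]

_EPI_TYPES = ("aa", "ad", "dd")


@dataclass
class SimConfig:
    """Dimensions and rates of a synthetic NCII study.

    Defaults mirror the study design this generator emulates: 339 F11 RILs,
    10 chromosomes of ~414 bin markers each (genome ~2,669 cM, i.e. the
    0.64 cM/bin average density), two testers identical at 95% of loci,
    4 environments x 2 replicates, and 0.5% residual heterozygosity masked
    to missing before coding.
    """

    n_ril: int = 339
    n_chromosomes: int = 10
    markers_per_chrom: int = 414
    map_length_cM: float = 266.9
    tester_similarity: float = 0.95
    n_env: int = 4
    n_rep: int = 2
    residual_het_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        for name in ("n_ril", "n_chromosomes", "markers_per_chrom", "n_env", "n_rep"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.tester_similarity <= 1.0:
            raise ValueError("tester_similarity must be in [0, 1]")
        if not 0.0 <= self.residual_het_rate <= 0.05:
            raise ValueError("residual_het_rate must be in [0, 0.05]")
        if self.map_length_cM <= 0 and self.markers_per_chrom > 1:
            raise ValueError("map_length_cM must be positive")


@dataclass
class TrueGenetics:
    """Ground-truth genetic architecture.

    additive_effects / dominance_effects are per-marker a_k and d_k;
    epistatic_pairs lists (k, k_prime, effect_type, effect) with effect_type
    in {'aa', 'ad', 'dd'}; variance_targets holds the intended component
    variances (keys among 'a', 'd', 'aa', 'ad', 'dd', 'gxe', 'rep',
    'residual').  Effects are rescaled at generation time so the realized
    variances hit the targets.
    """

    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    epistatic_pairs: list = field(default_factory=list)
    variance_targets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.additive_effects = np.asarray(self.additive_effects, dtype=float)
        self.dominance_effects = np.asarray(self.dominance_effects, dtype=float)
        for pair in self.epistatic_pairs:
            if pair[2] not in _EPI_TYPES:
                raise ValueError(f"epistatic effect type {pair[2]!r} not in {_EPI_TYPES}")
        for key, val in self.variance_targets.items():
            if val < 0:
                raise ValueError(f"variance target {key} is negative")

    def validate_markers(self, m: int):
        if self.additive_effects.shape[0] != m or self.dominance_effects.shape[0] != m:
            raise ValueError("effect vectors do not match the marker count")
        for k, k2, *_ in self.epistatic_pairs:
            if not (0 <= k < m and 0 <= k2 < m):
                raise ValueError(f"epistatic pair ({k}, {k2}) references a missing marker")


def haldane_recombination(d_cM) -> np.ndarray:
    """Haldane map function: recombination fraction at genetic distance d."""
    d = np.asarray(d_cM, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def _default_positions(config: SimConfig) -> dict:
    m = config.markers_per_chrom
    if m == 1:
        pos = np.array([0.0])
    else:
        pos = np.linspace(0.0, config.map_length_cM, m)
    return {f"chr{c + 1}": pos.copy() for c in range(config.n_chromosomes)}


def simulate_ril_population(config: SimConfig, rng=None, positions=None):
    """Simulate RIL parental mosaics along a genetic map.

    Each RIL chromosome is a two-state Markov chain over the parental
    origins, switching between adjacent markers with the Haldane
    recombination fraction of their cM distance, so the empirical
    recombinant fraction between any two markers matches the map function.
    Residual heterozygous calls (rate ``residual_het_rate``) are flagged and
    masked to missing, as F11 lines are treated as inbred.

    Returns (GenotypeTable, MarkerMap).
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if positions is None:
        positions = _default_positions(config)
    else:
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=float)
            if (np.diff(pos) < 0).any():
                raise ValueError(f"non-increasing map positions on {chrom}")
            positions[chrom] = pos
    rows_map = []
    blocks = []
    for chrom, pos in positions.items():
        m = len(pos)
        r = haldane_recombination(np.diff(pos))
        first = rng.choice([-1.0, 1.0], size=config.n_ril)
        chrom_codes = np.empty((config.n_ril, m))
        chrom_codes[:, 0] = first
        if m > 1:
            switch = rng.random((config.n_ril, m - 1)) < r[None, :]
            signs = np.where(switch, -1.0, 1.0)
            chrom_codes[:, 1:] = first[:, None] * np.cumprod(signs, axis=1)
        blocks.append(chrom_codes)
        for j, p in enumerate(pos):
            rows_map.append(
                {"marker": f"{chrom}_m{j + 1}", "chromosome": chrom,
                 "cM": float(p), "bp": int(round(p * 1e6))}
            )
    codes = np.hstack(blocks)
    het = rng.random(codes.shape) < config.residual_het_rate
    codes = np.where(het, np.nan, codes)
    marker_map = MarkerMap(pd.DataFrame(rows_map))
    table = GenotypeTable(
        individuals=np.array([f"RIL{i + 1:04d}" for i in range(config.n_ril)], dtype=object),
        markers=marker_map.markers.astype(object),
        codes=codes,
        het_mask=het,
    )
    return table, marker_map


def simulate_testers(config: SimConfig, marker_map: MarkerMap, rng=None):
    """Two tester genotype vectors sharing a parental allele at the
    configured fraction of loci.  Returns (tester1, tester2) arrays."""
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    m = len(marker_map.markers)
    t1 = rng.choice([-1.0, 1.0], size=m)
    same = rng.random(m) < config.tester_similarity
    t2 = np.where(same, t1, -t1)
    return t1, t2


def _component_vectors(Z, W, truth: TrueGenetics):
    """Raw (uncalibrated) genetic component vectors for a set of individuals."""
    out = {}
    out["a"] = Z @ truth.additive_effects
    out["d"] = W @ truth.dominance_effects
    for etype in _EPI_TYPES:
        pairs = [p for p in truth.epistatic_pairs if p[2] == etype]
        v = np.zeros(Z.shape[0])
        for k, k2, _, eff in pairs:
            if etype == "aa":
                v += Z[:, k] * Z[:, k2] * eff
            elif etype == "ad":
                v += Z[:, k] * W[:, k2] * eff
            else:
                v += W[:, k] * W[:, k2] * eff
        out[etype] = v
    return out


def _calibration_scales(Z, W, truth: TrueGenetics) -> dict:
    """Multipliers per component so realized variances hit the targets."""
    comps = _component_vectors(Z, W, truth)
    scales = {}
    for name in ("a", "d", "aa", "ad", "dd"):
        target = truth.variance_targets.get(name)
        if target is None:
            scales[name] = 1.0
            continue
        v = float(np.var(comps[name]))
        if v <= 0:
            if target > 0:
                raise ValueError(
                    f"component {name!r} has zero raw variance; cannot reach target {target}"
                )
            scales[name] = 0.0
        else:
            scales[name] = float(np.sqrt(target / v))
    return scales


def simulate_phenotypes(
    coding,
    truth: TrueGenetics,
    config: SimConfig,
    rng=None,
    trait: str = "trait1",
    scales: dict | None = None,
):
    """Multi-environment replicated phenotypes for a hybrid coding.

    observation = mu + sum Z_k a_k + sum W_k d_k + epistatic terms
                  + GxE draw + replicate-within-environment effect + residual

    Returns (records, realized) where records is a long-format TrialRecords
    DataFrame and realized maps each component to its realized variance
    (alongside the target).
    """
    rng = np.random.default_rng(config.seed + 2 if rng is None else rng)
    if isinstance(coding, HybridCoding):
        Z, W = coding.imputed()
        ids = coding.hybrids
    else:
        Z, W, ids = coding
        Z = np.where(np.isnan(Z), 0.0, np.asarray(Z, dtype=float))
        W = np.where(np.isnan(W), 0.0, np.asarray(W, dtype=float))
    truth.validate_markers(Z.shape[1])
    if scales is None:
        scales = _calibration_scales(Z, W, truth)
    comps = _component_vectors(Z, W, truth)
    genetic = np.zeros(Z.shape[0])
    realized = {}
    for name, vec in comps.items():
        vec = vec * scales.get(name, 1.0)
        genetic += vec
        realized[name] = {
            "target": truth.variance_targets.get(name),
            "realized": float(np.var(vec)),
        }
    s2_gxe = truth.variance_targets.get("gxe", 0.0)
    s2_rep = truth.variance_targets.get("rep", 0.0)
    s2_eps = truth.variance_targets.get("residual", 1.0)
    n = Z.shape[0]
    gxe = rng.normal(0.0, np.sqrt(s2_gxe), size=(n, config.n_env)) if s2_gxe > 0 else np.zeros((n, config.n_env))
    rep_eff = (
        rng.normal(0.0, np.sqrt(s2_rep), size=(config.n_env, config.n_rep))
        if s2_rep > 0
        else np.zeros((config.n_env, config.n_rep))
    )
    eps = rng.normal(0.0, np.sqrt(s2_eps), size=(n, config.n_env, config.n_rep))
    realized["gxe"] = {"target": s2_gxe, "realized": float(np.var(gxe))}
    realized["rep"] = {"target": s2_rep, "realized": float(np.var(rep_eff))}
    realized["residual"] = {"target": s2_eps, "realized": float(np.var(eps))}
    mu = 100.0
    values = (
        mu
        + genetic[:, None, None]
        + gxe[:, :, None]
        + rep_eff[None, :, :]
        + eps
    )
    env_ids = [f"env{j + 1}" for j in range(config.n_env)]
    rep_ids = [f"rep{k + 1}" for k in range(config.n_rep)]
    records = pd.DataFrame(
        {
            "genotype": np.repeat(ids, config.n_env * config.n_rep),
            "environment": np.tile(np.repeat(env_ids, config.n_rep), n),
            "replicate": np.tile(rep_ids, n * config.n_env),
            "trait": trait,
            "value": values.ravel(),
        }
    )
    return records, realized


def random_truth(
    config: SimConfig,
    n_qtl_add: int = 20,
    n_qtl_dom: int = 20,
    n_pairs: int = 10,
    variance_targets: dict | None = None,
    rng=None,
) -> TrueGenetics:
    """A polygenic architecture with effects at random markers.

    Default variance targets give a heritable, heterotic trait: additive
    1.0, dominance 0.5, each epistatic class 0.2, GxE 0.3, replicate 0.1,
    residual 1.0.
    """
    rng = np.random.default_rng(config.seed + 3 if rng is None else rng)
    m = config.n_chromosomes * config.markers_per_chrom
    a = np.zeros(m)
    d = np.zeros(m)
    a[rng.choice(m, size=min(n_qtl_add, m), replace=False)] = rng.normal(size=min(n_qtl_add, m))
    d[rng.choice(m, size=min(n_qtl_dom, m), replace=False)] = rng.normal(size=min(n_qtl_dom, m))
    pairs = []
    for _ in range(n_pairs):
        k, k2 = rng.choice(m, size=2, replace=False)
        pairs.append((int(k), int(k2), str(rng.choice(_EPI_TYPES)), float(rng.normal())))
    if variance_targets is None:
        variance_targets = {
            "a": 1.0, "d": 0.5, "aa": 0.2, "ad": 0.2, "dd": 0.2,
            "gxe": 0.3, "rep": 0.1, "residual": 1.0,
        }
    return TrueGenetics(
        additive_effects=a,
        dominance_effects=d,
        epistatic_pairs=pairs,
        variance_targets=dict(variance_targets),
    )


@dataclass
class SimStudy:
    """A complete synthetic NCII study bundle."""

    config: SimConfig
    truth: TrueGenetics
    ril: GenotypeTable
    marker_map: MarkerMap
    tester1: np.ndarray
    tester2: np.ndarray
    coding_tc: HybridCoding
    coding_tm: HybridCoding
    pooled: HybridCoding
    records: pd.DataFrame
    realized: dict
    tester_ids: tuple = ("T1", "T2")

    @property
    def parent_of(self) -> dict:
        """hybrid id -> (tester id, RIL id)."""
        out = {}
        for coding in (self.coding_tc, self.coding_tm):
            for hyb, (ril, tester) in zip(coding.hybrids, coding.parent_links):
                out[hyb] = (tester, ril)
        return out


def simulate_study(config: SimConfig, truth: TrueGenetics | None = None) -> SimStudy:
    """Generate a full synthetic study: RILs, testers, both hybrid
    populations, and phenotype records for hybrids, RILs and testers
    (inbred records enable the midparent-heterosis pipeline downstream).
    """
    master = np.random.default_rng(config.seed)
    ril, marker_map = simulate_ril_population(config, rng=master.spawn(1)[0])
    t1, t2 = simulate_testers(config, marker_map, rng=master.spawn(1)[0])
    if truth is None:
        truth = random_truth(config, rng=master.spawn(1)[0])
    coding_tc = derive_hybrid_codes(ril, t1, tester_id="T1", population=0)
    coding_tm = derive_hybrid_codes(ril, t2, tester_id="T2", population=1)
    pooled = pool_populations(coding_tc, coding_tm)
    # calibrate effect scales once, on the pooled hybrids (the dissection target)
    Zp, Wp = pooled.imputed()
    truth.validate_markers(Zp.shape[1])
    scales = _calibration_scales(Zp, Wp, truth)
    rng_pheno = master.spawn(1)[0]
    rec_h, realized = simulate_phenotypes(pooled, truth, config, rng=rng_pheno, scales=scales)
    # inbred phenotypes: Z = own codes, W = 0 (additive + aa terms only)
    codes = np.where(np.isnan(ril.codes), 0.0, ril.codes)
    rec_r, _ = simulate_phenotypes(
        (codes, np.zeros_like(codes), ril.individuals), truth, config,
        rng=master.spawn(1)[0], scales=scales,
    )
    testers = np.vstack([t1, t2])
    rec_t, _ = simulate_phenotypes(
        (testers, np.zeros_like(testers), np.array(["T1", "T2"], dtype=object)),
        truth, config, rng=master.spawn(1)[0], scales=scales,
    )
    records = pd.concat([rec_h, rec_r, rec_t], ignore_index=True)
    return SimStudy(
        config=config,
        truth=truth,
        ril=ril,
        marker_map=marker_map,
        tester1=t1,
        tester2=t2,
        coding_tc=coding_tc,
        coding_tm=coding_tm,
        pooled=pooled,
        records=records,
        realized=realized,
    )


def write_study(study: SimStudy, directory):
    """Persist a study as TSV tables plus a JSON provenance sidecar."""
    from .genotypes import write_genotypes, write_map

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_genotypes(study.ril, directory / "ril_genotypes.tsv")
    write_map(study.marker_map, directory / "map.tsv")
    pd.DataFrame(
        {"marker": study.marker_map.markers, "T1": study.tester1, "T2": study.tester2}
    ).to_csv(directory / "testers.tsv", sep="\t", index=False)
    study.records.to_csv(directory / "trial_records.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame(
        {
            "marker": study.marker_map.markers,
            "additive_effect": study.truth.additive_effects,
            "dominance_effect": study.truth.dominance_effects,
        }
    )
    truth_df.to_csv(directory / "truth_effects.tsv", sep="\t", index=False)
    (directory / "provenance.json").write_text(
        json.dumps(
            {
                "config": asdict(study.config),
                "variance_targets": study.truth.variance_targets,
                "epistatic_pairs": [list(p) for p in study.truth.epistatic_pairs],
                "realized": study.realized,
            },
            indent=2,
        )
    )
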