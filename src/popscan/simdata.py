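"""Synthetic data with ground truth for every analysis stage.

Population genotypes follow the Balding–Nichols model: each site draws an
ancestral frequency p uniformly between MAF bounds, each population draws
its own frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) — F being the expected
fixation index between populations — and diploid genotypes are binomial
(Hardy–Weinberg) draws with independent missingness.  Selective sweeps are
modeled as near-fixation of the alt allele in the target population inside a
stated interval: the swept frequency is 1 − 0.05·(1 − s) for intensity
s ∈ (0, 1], so s = 1 fixes the allele and drives interval diversity to zero
while inflating differentiation — the signal the sweep scan detects.
Homozygous tracts for the ROH detector are planted by overwriting one
sample's genotypes in an interval, and the F2 intercross generator produces
1:2:1 segregating genotypes with hatch/family fixed effects, an optional
slaughter-weight covariate and Gaussian noise.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genio import MISSING, GeneModel, GenotypeMatrix, PopulationPanel

logger = logging.getLogger(__name__)


@dataclass
class SweepSpec:
    population: str
    chrom: str
    start: int  # 0-based half-open interval
    end: int
    s: float = 1.0  # sweep intensity in (0, 1]

    def __post_init__(self) -> None:
        if not 0 < self.s <= 1:
            raise ValueError("sweep intensity s must be in (0, 1]")


@dataclass
class ROHSpec:
    sample: str
    chrom: str
    start: int
    end: int


@dataclass
class SimConfig:
    """Parameters of the structured-population genotype generator.

    Defaults mirror the desk-scale study conditions exercised throughout:
    two populations of 50 diploid samples diverged at F = 0.1 on a 5-Mb
    chromosome with 25,000 SNPs (one per 200 bp), 2% missing calls.
    """

    n_populations: int = 2
    samples_per_pop: int = 50
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1": 5_000_000})
    n_sites: int = 25_000
    divergence_f: float = 0.1
    maf_bounds: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.02
    sweeps: list[SweepSpec] = field(default_factory=list)
    rohs: list[ROHSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.divergence_f < 1:
            raise ValueError("divergence_f must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_bounds
        if not 0 < lo < hi < 1:
            raise ValueError("maf_bounds must satisfy 0 < lo < hi < 1")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths or not (
                0 <= sw.start < sw.end <= self.chrom_lengths[sw.chrom]
            ):
                raise ValueError(f"sweep interval outside chromosome: {sw}")
        for r in self.rohs:
            if r.chrom not in self.chrom_lengths or not (
                0 <= r.start < r.end <= self.chrom_lengths[r.chrom]
            ):
                raise ValueError(f"ROH interval outside chromosome: {r}")


def _positions(cfg: SimConfig, rng: np.random.Generator) -> tuple[list, list]:
    total = sum(cfg.chrom_lengths.values())
    chroms, pos = [], []
    remaining = cfg.n_sites
    items = list(cfg.chrom_lengths.items())
    for i, (c, length) in enumerate(items):
        n = remaining if i == len(items) - 1 else int(round(cfg.n_sites * length / total))
        n = min(n, remaining, length)
        remaining -= n
        p = np.sort(rng.choice(length, size=n, replace=False)) + 1
        chroms.append(np.full(n, c, dtype=object))
        pos.append(p.astype(np.int64))
    return chroms, pos


def simulate_populations(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, PopulationPanel, dict]:
    """Draw a structured-population genotype matrix with full ground truth.

    Returns (matrix, panel, truth); ``truth`` records the config, population
    allele frequencies per site, and sweep/ROH interval coordinates.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms_l, pos_l = _positions(cfg, rng)
    chrom = np.concatenate(chroms_l)
    pos = np.concatenate(pos_l)
    n_sites = pos.size
    lo, hi = cfg.maf_bounds
    p_anc = rng.uniform(lo, hi, size=n_sites)
    F = cfg.divergence_f
    pops = [f"pop{k + 1}" for k in range(cfg.n_populations)]
    # Balding–Nichols: per-population frequencies around the ancestral one
    pk = np.empty((cfg.n_populations, n_sites))
    shape = (1.0 - F) / F
    for k in range(cfg.n_populations):
        pk[k] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    # sweeps: near-fixation of the alt allele in the target population
    for sw in cfg.sweeps:
        k = pops.index(sw.population)
        in_iv = (chrom == sw.chrom) & (pos > sw.start) & (pos <= sw.end)
        pk[k, in_iv] = 1.0 - 0.05 * (1.0 - sw.s)
    sample_ids = [f"{p}_s{j + 1:03d}" for p in pops for j in range(cfg.samples_per_pop)]
    mapping = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    dosage = np.empty((len(sample_ids), n_sites), dtype=np.int8)
    row = 0
    for k in range(cfg.n_populations):
        for _ in range(cfg.samples_per_pop):
            dosage[row] = rng.binomial(2, pk[k]).astype(np.int8)
            row += 1
    if cfg.missing_rate > 0:
        drop = rng.random(dosage.shape) < cfg.missing_rate
        dosage[drop] = MISSING
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=chrom,
        pos=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        dosage=dosage,
    )
    planted_rohs = []
    for r in cfg.rohs:
        gm, tract = inject_roh(gm, r.sample, r.chrom, r.start, r.end)
        planted_rohs.append(tract)
    truth = {
        "config": _config_dict(cfg),
        "populations": pops,
        "pop_freqs": pk,
        "sweeps": [asdict(sw) for sw in cfg.sweeps],
        "rohs": planted_rohs,
    }
    return gm, PopulationPanel(mapping), truth


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["maf_bounds"] = list(cfg.maf_bounds)
    return d


def inject_roh(
    gm: GenotypeMatrix, sample: str, chrom: str, start: int, end: int
) -> tuple[GenotypeMatrix, dict]:
    """Plant a homozygous tract: the sample's non-missing genotypes in the
    0-based half-open interval become homozygous for the per-site major
    allele.  Other samples are untouched.  Returns (new matrix, tract record
    with the planted first/last SNP coordinates)."""
    idx = gm.sites_in(chrom, start, end)
    tract = {"sample": sample, "chrom": chrom, "start": start, "end": end,
             "n_snps": int(idx.size), "first_snp": None, "last_snp": None}
    if idx.size == 0:
        logger.warning("inject_roh: no SNPs in %s:%d-%d; no-op", chrom, start, end)
        return gm, tract
    row = gm.sample_index([sample])[0]
    dosage = gm.dosage.copy()
    called = dosage[:, idx] != MISSING
    alt = np.where(called, dosage[:, idx], 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    major_hom = np.where(alt * 2 > total, 2, 0).astype(np.int8)
    target = dosage[row, idx]
    dosage[row, idx] = np.where(target == MISSING, MISSING, major_hom)
    tract["first_snp"] = int(gm.pos[idx[0]])
    tract["last_snp"] = int(gm.pos[idx[-1]])
    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        dosage=dosage,
    )
    return out, tract


def simulate_genes(
    chrom_lengths: dict[str, int],
    n_genes: int,
    mean_length_bp: int = 20_000,
    seed: int = 0,
    with_exons: bool = True,
) -> list[GeneModel]:
    """Place non-overlapping gene intervals uniformly along the chromosomes."""
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    gid = 0
    for _ in range(n_genes):
        placed = False
        for _attempt in range(1000):
            u = rng.random() * total
            acc = 0
            for c, length in chrom_lengths.items():
                acc += length
                if u < acc:
                    break
            glen = max(1000, int(rng.exponential(mean_length_bp)))
            if glen >= length:
                continue
            start = int(rng.integers(1, length - glen + 1))
            end = start + glen - 1
            if any(s <= end and e >= start for s, e in occupied[c]):
                continue
            occupied[c].append((start, end))
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons: list[tuple[int, int]] = []
            if with_exons and glen >= 3000:
                n_ex = int(rng.integers(1, 5))
                cuts = np.sort(rng.choice(glen - 1, size=2 * n_ex, replace=False))
                for a, b in zip(cuts[::2], cuts[1::2]):
                    exons.append((start + int(a), start + int(b)))
            genes.append(GeneModel(f"gene{gid:04d}", c, start, end, strand, exons))
            placed = True
            break
        if not placed:
            raise RuntimeError("could not pack genes without overlap")
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


@dataclass
class F2SimConfig:
    """F2 intercross trait generator mirroring the association design:
    a biallelic QTL (additive a, dominance d), 2 hatches, 7 families, an
    optional slaughter-weight covariate, Gaussian residual noise."""

    n_individuals: int = 734
    mu: float = 1000.0
    additive: float = 0.0  # a, trait units per alt allele
    dominance: float = 0.0  # d, deviation of the het
    hatch_effects: tuple[float, float] = (0.0, 20.0)
    family_effects: tuple[float, ...] = (0.0, 10.0, -10.0, 25.0, -25.0, 5.0, -5.0)
    sigma: float = 50.0
    w_mean: float = 1500.0
    w_sd: float = 150.0
    beta_w: float = 0.0  # coefficient linking centered W to Y
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if len(self.hatch_effects) != 2 or len(self.family_effects) != 7:
            raise ValueError("design requires 2 hatch and 7 family levels")


def simulate_f2(cfg: F2SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate F2 phenotype records; returns (records, ground truth).

    Genotypes segregate 1:2:1; Y = mu + a(g−1) + d·1[g=1] + hatch + family
    + beta_w(W − W̄) + N(0, sigma²).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    g = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
    hatch = rng.integers(1, 3, size=n)
    family = rng.integers(1, 8, size=n)
    w = rng.normal(cfg.w_mean, cfg.w_sd, size=n)
    y = (
        cfg.mu
        + cfg.additive * (g - 1)
        + cfg.dominance * (g == 1)
        + np.asarray(cfg.hatch_effects)[hatch - 1]
        + np.asarray(cfg.family_effects)[family - 1]
        + cfg.beta_w * (w - w.mean())
        + rng.normal(0.0, cfg.sigma, size=n)
    )
    records = pd.DataFrame(
        {
            "id": [f"F2_{i + 1:04d}" for i in range(n)],
            "genotype": g,
            "hatch": hatch,
            "family": family,
            "W": w,
            "trait": y,
        }
    )
    truth = {
        "config": {**asdict(cfg), "hatch_effects": list(cfg.hatch_effects),
                   "family_effects": list(cfg.family_effects)},
        "genotype_counts": {int(k): int((g == k).sum()) for k in (0, 1, 2)},
    }
    return records, truth
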