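"""Genotype-dosage linkage disequilibrium: pairwise r², decay curves, pruning.

r² is the squared Pearson correlation of unphased alt-allele dosages
(composite LD) with pairwise deletion of missing calls — the convention of
genotype-based LD tools.  Decay curves bin all intra-chromosome pairs by
physical distance; pruning is the greedy 50-SNP/5-step windowed procedure
with an r² ceiling (the "--indep-pairwise 50 5 0.2" dialect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix, PopulationPanel


@dataclass
class LDDecayCurve:
    """Distance-binned mean r²: edges in bp, one mean and count per bin."""

    bin_edges: np.ndarray  # length n_bins + 1
    mean_r2: np.ndarray
    n_pairs: np.ndarray


def pair_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairs with either value missing are excluded; NaN if fewer than two
    complete pairs remain or either site is monomorphic among them.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING) & ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_one_vs_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """r² of column x against each column of Y with pairwise deletion."""
    mask = (x != MISSING)[:, None] & (Y != MISSING)
    xf = x.astype(float)
    Yf = Y.astype(float)
    n = mask.sum(axis=0).astype(float)
    sx = np.where(mask, xf[:, None], 0.0).sum(axis=0)
    sy = np.where(mask, Yf, 0.0).sum(axis=0)
    sxx = np.where(mask, xf[:, None] ** 2, 0.0).sum(axis=0)
    syy = np.where(mask, Yf**2, 0.0).sum(axis=0)
    sxy = np.where(mask, xf[:, None] * Yf, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (n * sxy - sx * sy) ** 2
        den = (n * sxx - sx**2) * (n * syy - sy**2)
        r2 = np.where((n >= 2) & (den > 0), num / den, np.nan)
    return r2


def ld_decay(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    max_dist_bp: int = 300_000,
    bin_bp: int = 1_000,
) -> LDDecayCurve:
    """Distance-binned mean r² over all intra-chromosome pairs of one population."""
    if not max_dist_bp > bin_bp > 0:
        raise ValueError("need max_dist_bp > bin_bp > 0")
    rows = gm.sample_index(panel.samples(population))
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in gm.chromosomes():
        on = np.flatnonzero(gm.chrom == c)
        p = gm.pos[on]
        D = gm.dosage[np.ix_(rows, on)]
        for i in range(on.size - 1):
            hi = np.searchsorted(p, p[i] + max_dist_bp, side="right")
            if hi <= i + 1:
                continue
            r2 = _r2_one_vs_many(D[:, i], D[:, i + 1 : hi])
            dist = p[i + 1 : hi] - p[i]
            fin = np.isfinite(r2)
            if fin.any():
                bins = np.minimum(dist[fin] // bin_bp, n_bins - 1)
                np.add.at(sums, bins, r2[fin])
                np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_bp
    return LDDecayCurve(bin_edges=edges, mean_r2=mean, n_pairs=counts)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns sorted retained site indices.

    Within each window of ``window_snps`` consecutive SNPs the later member
    of every retained pair with r² > ``r2_max`` is dropped; the window then
    advances by ``step_snps``.  The final set has no within-window pair above
    the ceiling.
    """
    retained = np.ones(gm.n_sites, dtype=bool)
    cache: dict[tuple[int, int], float] = {}

    def r2(i: int, j: int) -> float:
        key = (i, j)
        if key not in cache:
            cache[key] = pair_r2(gm.dosage[:, i], gm.dosage[:, j])
        return cache[key]

    for c in gm.chromosomes():
        on = np.flatnonzero(gm.chrom == c)
        m = on.size
        start = 0
        while True:
            window = on[start : start + window_snps]
            idx = [i for i in window if retained[i]]
            for ai in range(len(idx)):
                i = idx[ai]
                if not retained[i]:
                    continue
                for j in idx[ai + 1 :]:
                    if not retained[j]:
                        continue
                    v = r2(i, j)
                    if np.isfinite(v) and v > r2_max:
                        retained[j] = False
            if start + window_snps >= m:
                break
            start += step_snps
    return np.flatnonzero(retained)
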