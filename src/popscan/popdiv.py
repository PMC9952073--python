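"""Per-population diversity statistics: Ho, He and nucleotide diversity.

Observed heterozygosity is 1 minus the homozygous fraction of an
individual's non-missing genotypes; expected heterozygosity uses the
small-sample-unbiased per-site form 2*p*q*n/(n-1) with n non-missing allele
copies; per-site pi is the mean pairwise difference among allele copies,
2*j*(n-j)/(n*(n-1)) for j alt copies.  Windowed pi divides the summed
per-site pi by the window's physical length (per-bp reporting), so windows
with unequal SNP counts remain comparable and the reduction-of-diversity
ratio is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, PopulationPanel

logger = logging.getLogger(__name__)


@dataclass
class DiversitySummary:
    population: str
    ho: float
    he: float
    pi: float


def observed_het(
    gm: GenotypeMatrix, panel: PopulationPanel
) -> tuple[pd.Series, pd.Series]:
    """Per-individual and per-population observed heterozygosity.

    Individual Ho = 1 - (homozygous non-missing loci / non-missing loci);
    population Ho is the mean over its individuals.  Individuals with no
    non-missing genotypes are excluded with a warning.
    """
    called = gm.dosage != MISSING
    n_called = called.sum(axis=1)
    n_het = (gm.dosage == 1).sum(axis=1)
    ho = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    dropped = [s for s, n in zip(gm.sample_ids, n_called) if n == 0]
    if dropped:
        logger.warning("observed_het: excluding all-missing individuals %s", dropped)
    indiv = pd.Series(ho, index=gm.sample_ids, name="Ho")
    pop = {}
    for p in panel.populations:
        vals = indiv.reindex([s for s in panel.samples(p) if s in indiv.index])
        pop[p] = float(vals.dropna().mean())
    return indiv, pd.Series(pop, name="Ho")


def _pop_he(dosage: np.ndarray) -> float:
    """Mean over sites of unbiased expected heterozygosity for one pop."""
    called = dosage != MISSING
    n = 2 * called.sum(axis=0)
    j = np.where(called, dosage, 0).sum(axis=0)
    ok = n >= 2
    if not ok.any():
        return float("nan")
    n, j = n[ok].astype(float), j[ok].astype(float)
    p = j / n
    he = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(he.mean())


def expected_het(gm: GenotypeMatrix, panel: PopulationPanel) -> pd.Series:
    """Per-population expected heterozygosity (sites with n < 2 copies skipped)."""
    out = {}
    for p in panel.populations:
        rows = gm.sample_index(panel.samples(p))
        out[p] = _pop_he(gm.dosage[rows, :])
    return pd.Series(out, name="He")


def site_pi(alt_count, total_copies):
    """Per-site nucleotide diversity 2*j*(n-j)/(n*(n-1)).

    The mean pairwise difference among the n allele copies at the site;
    NaN where n < 2.  Accepts scalars or arrays.
    """
    j = np.asarray(alt_count, dtype=float)
    n = np.asarray(total_copies, dtype=float)
    if np.any(j < 0) or np.any(j > n):
        raise ValueError("need 0 <= alt_count <= total_copies")
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * j * (n - j) / (n * (n - 1.0)), np.nan)
    if np.isscalar(alt_count) and np.isscalar(total_copies):
        return float(pi)
    return pi


def per_site_pi(gm: GenotypeMatrix, sample_rows: np.ndarray) -> np.ndarray:
    """Per-site pi for the given sample rows; NaN where < 2 allele copies."""
    d = gm.dosage[sample_rows, :]
    called = d != MISSING
    n = 2 * called.sum(axis=0)
    j = np.where(called, d, 0).sum(axis=0)
    return site_pi(j, n)


def windowed_pi(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    windows,
    population: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window per-bp pi for one population.

    ``windows`` is a sequence of objects with ``chrom``/``start``/``end``
    (0-based half-open).  Window pi is the sum of per-site pi over genotyped
    sites in the window divided by window length in bp; windows without
    genotyped sites report 0 with n_snps = 0.  Returns (pi, n_snps) arrays
    aligned with ``windows``.
    """
    rows = gm.sample_index(panel.samples(population))
    pi_site = per_site_pi(gm, rows)
    usable = np.isfinite(pi_site)
    contrib = np.where(usable, pi_site, 0.0)
    # cumulative sums per chromosome allow O(1) per-window lookups
    csum: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in gm.chromosomes():
        on = np.flatnonzero(gm.chrom == c)
        csum[c] = (
            gm.pos[on],
            np.concatenate([[0.0], np.cumsum(contrib[on])]),
            np.concatenate([[0], np.cumsum(usable[on].astype(np.int64))]),
        )
    pi = np.zeros(len(windows))
    n_snps = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        if w.chrom not in csum:
            continue
        p, cs, cn = csum[w.chrom]
        lo = np.searchsorted(p, w.start + 1, side="left")
        hi = np.searchsorted(p, w.end, side="right")
        length = w.end - w.start
        pi[i] = (cs[hi] - cs[lo]) / length if length > 0 else 0.0
        n_snps[i] = cn[hi] - cn[lo]
    return pi, n_snps


def diversity_summary(gm: GenotypeMatrix, panel: PopulationPanel) -> pd.DataFrame:
    """Ho / He / genome-wide per-site-mean pi per population (Table-style)."""
    _, ho = observed_het(gm, panel)
    he = expected_het(gm, panel)
    pis = {}
    for p in panel.populations:
        rows = gm.sample_index(panel.samples(p))
        v = per_site_pi(gm, rows)
        pis[p] = float(np.nanmean(v)) if np.isfinite(v).any() else float("nan")
    df = pd.DataFrame({"Ho": ho, "He": he, "pi": pd.Series(pis)})
    df.index.name = "population"
    return df
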