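"""Windowed selective-sweep scan: Weir–Cockerham FST, π ratios, top-5% joint
candidate selection, window merging and gene annotation.

The scan slides 40-kb windows in 10-kb steps along each chromosome and, for
a target population against a control pool, computes (i) the Weir–Cockerham
(1984) two-population FST from genotype counts, combined across the sites of
a window as the ratio of summed variance components ("weighted" FST), (ii)
per-bp nucleotide diversity in both populations, (iii) the reduction of
diversity ROD = 1 − π_target/π_control and the rank-equivalent
log2(π_control/π_target), and (iv) a Z-transform of the window FST values.
Windows in the top 5% of both the FST statistic and the diversity-reduction
statistic are sweep candidates; consecutive candidate windows merge into
regions and genes intersecting candidate windows by ≥1 bp are reported per
statistic together with their intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import popdiv
from .genio import MISSING, GeneModel, GenotypeMatrix, PopulationPanel

logger = logging.getLogger(__name__)

WINDOW_BP = 40_000
STEP_BP = 10_000


@dataclass
class Window:
    """Genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    window_indices: list[int] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)


def make_windows(
    chrom_lengths: dict[str, int], size: int = WINDOW_BP, step: int = STEP_BP
) -> list[Window]:
    """Sliding windows at starts 0, step, 2*step, ... < chromosome length,
    truncated at the chromosome end."""
    if not size >= step > 0:
        raise ValueError("need size >= step > 0")
    windows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length), step):
            windows.append(Window(chrom, start, min(start + size, int(length))))
    return windows


def _pop_site_stats(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n called samples, alt freq, het freq) for one population."""
    called = dosage != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, dosage, 0).sum(axis=0)
    het = ((dosage == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def wc_site_components(
    gm: GenotypeMatrix, panel: PopulationPanel, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) variance components for two populations.

    Returns (a, a+b+c): the among-population component and the total.  Sites
    where either population has fewer than two genotyped samples, or that are
    monomorphic across both populations, get NaN components and are excluded
    from window ratios.
    """
    rows_a = gm.sample_index(panel.samples(pop_a))
    rows_b = gm.sample_index(panel.samples(pop_b))
    n1, p1, h1 = _pop_site_stats(gm.dosage[rows_a, :])
    n2, p2, h2 = _pop_site_stats(gm.dosage[rows_b, :])
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0
        total = a + b + c
    usable = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1)
    a = np.where(usable, a, np.nan)
    total = np.where(usable, total, np.nan)
    return a, total


def wc_fst(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    pop_a: str,
    pop_b: str,
    window: Window | None = None,
) -> float:
    """Ratio-of-sums ("weighted") Weir–Cockerham FST over a window, or the
    whole matrix if *window* is None.  NaN if no usable site."""
    a, total = wc_site_components(gm, panel, pop_a, pop_b)
    if window is not None:
        idx = gm.sites_in(window.chrom, window.start, window.end)
        a, total = a[idx], total[idx]
    fin = np.isfinite(a) & np.isfinite(total)
    if not fin.any() or total[fin].sum() == 0:
        return float("nan")
    return float(a[fin].sum() / total[fin].sum())


def rod(pi_target, pi_control):
    """Reduction of diversity: 1 − π_target/π_control (NaN if control π is 0)."""
    pi_t = np.asarray(pi_target, dtype=float)
    pi_c = np.asarray(pi_control, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(pi_c > 0, 1.0 - pi_t / pi_c, np.nan)
    return float(out) if out.ndim == 0 else out


def log2_pi_ratio(pi_control, pi_target):
    """log2(π_control/π_target); NaN where the control diversity is 0.

    A fully swept window (π_target = 0 with π_control > 0) maps to +inf, the
    limit of the transform, so the statistic stays defined — and
    rank-equivalent to ROD, which reports 1 there — exactly where the sweep
    signal is strongest."""
    pi_c = np.asarray(pi_control, dtype=float)
    pi_t = np.asarray(pi_target, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(pi_c > 0, np.log2(pi_c / np.maximum(pi_t, 0.0)), np.nan)
    return float(out) if out.ndim == 0 else out


def z_transform(values) -> np.ndarray:
    """Standardize to zero mean and unit sample SD (ddof=1) over finite
    entries; NaN entries propagate.  Raises on fewer than two finite values
    or zero spread."""
    x = np.asarray(values, dtype=float)
    fin = np.isfinite(x)
    if fin.sum() < 2:
        raise ValueError("need at least two finite values")
    sd = float(np.std(x[fin], ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation: Z-transform undefined")
    mu = float(np.mean(x[fin]))
    out = np.full_like(x, np.nan)
    out[fin] = (x[fin] - mu) / sd
    return out


def scan(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    target: str,
    control: str,
    windows: list[Window] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    size: int = WINDOW_BP,
    step: int = STEP_BP,
) -> pd.DataFrame:
    """Run the full windowed scan of *target* against *control*.

    Returns one row per window: CHROM, BIN_START, BIN_END, N_SNPS,
    WEIGHTED_FST, MEAN_FST, PI_TARGET, PI_CONTROL, ROD, LOG2_RATIO, Z_FST.
    """
    if windows is None:
        if chrom_lengths is None:
            chrom_lengths = {
                c: int(gm.pos[gm.chrom == c].max()) for c in gm.chromosomes()
            }
        windows = make_windows(chrom_lengths, size=size, step=step)
    a, total = wc_site_components(gm, panel, target, control)
    fin = np.isfinite(a) & np.isfinite(total)
    a_f = np.where(fin, a, 0.0)
    t_f = np.where(fin, total, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        site_fst = np.where(fin & (total != 0), a / total, np.nan)
    site_fst_f = np.where(np.isfinite(site_fst), site_fst, 0.0)
    site_fst_n = np.isfinite(site_fst).astype(np.int64)

    csum: dict[str, tuple] = {}
    for c in gm.chromosomes():
        on = np.flatnonzero(gm.chrom == c)
        csum[c] = (
            gm.pos[on],
            np.concatenate([[0.0], np.cumsum(a_f[on])]),
            np.concatenate([[0.0], np.cumsum(t_f[on])]),
            np.concatenate([[0], np.cumsum(fin[on].astype(np.int64))]),
            np.concatenate([[0.0], np.cumsum(site_fst_f[on])]),
            np.concatenate([[0], np.cumsum(site_fst_n[on])]),
        )
    n_w = len(windows)
    fst = np.full(n_w, np.nan)
    fst_mean = np.full(n_w, np.nan)
    n_snps = np.zeros(n_w, dtype=np.int64)
    for i, w in enumerate(windows):
        if w.chrom not in csum:
            continue
        p, ca, ct, cn, cf, cfn = csum[w.chrom]
        lo = np.searchsorted(p, w.start + 1, side="left")
        hi = np.searchsorted(p, w.end, side="right")
        n_use = cn[hi] - cn[lo]
        n_snps[i] = n_use
        w.n_snps = int(n_use)
        denom = ct[hi] - ct[lo]
        if n_use > 0 and denom != 0:
            fst[i] = (ca[hi] - ca[lo]) / denom
        nf = cfn[hi] - cfn[lo]
        if nf > 0:
            fst_mean[i] = (cf[hi] - cf[lo]) / nf
    pi_t, _ = popdiv.windowed_pi(gm, panel, windows, target)
    pi_c, _ = popdiv.windowed_pi(gm, panel, windows, control)
    df = pd.DataFrame(
        {
            "CHROM": [w.chrom for w in windows],
            "BIN_START": [w.start for w in windows],
            "BIN_END": [w.end for w in windows],
            "N_SNPS": n_snps,
            "WEIGHTED_FST": fst,
            "MEAN_FST": fst_mean,
            "PI_TARGET": pi_t,
            "PI_CONTROL": pi_c,
            "ROD": rod(pi_t, pi_c),
            "LOG2_RATIO": log2_pi_ratio(pi_c, pi_t),
        }
    )
    df["Z_FST"] = z_transform(df["WEIGHTED_FST"].to_numpy())
    return df


@dataclass
class CandidateSets:
    """Top-quantile window index sets under each statistic and their joint."""

    fst_windows: np.ndarray
    div_windows: np.ndarray
    joint_windows: np.ndarray
    fst_threshold: float
    div_threshold: float


def _top_quantile_mask(values: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    # NaN (undefined) windows are excluded; +inf (fully swept) rank on top
    defined = ~np.isnan(values)
    m = int(defined.sum())
    if m < int(np.ceil(1.0 / q)):
        raise ValueError(f"only {m} defined values; too few for q={q}")
    k = max(1, int(np.ceil(q * m)))
    thr = float(np.sort(values[defined])[-k])
    return defined & (values >= thr), thr


def select_candidates(
    scan_df: pd.DataFrame,
    q: float = 0.05,
    fst_stat: str = "Z_FST",
    div_stat: str = "ROD",
) -> CandidateSets:
    """Windows in the top-q tail of both statistics (ties all included).

    NaN windows are excluded from the quantile computation.  The joint set
    is the intersection of the two per-statistic candidate sets.
    """
    fst_mask, fst_thr = _top_quantile_mask(scan_df[fst_stat].to_numpy(float), q)
    div_mask, div_thr = _top_quantile_mask(scan_df[div_stat].to_numpy(float), q)
    return CandidateSets(
        fst_windows=np.flatnonzero(fst_mask),
        div_windows=np.flatnonzero(div_mask),
        joint_windows=np.flatnonzero(fst_mask & div_mask),
        fst_threshold=fst_thr,
        div_threshold=div_thr,
    )


def merge_windows(scan_df: pd.DataFrame, indices: np.ndarray) -> list[CandidateRegion]:
    """Merge overlapping or adjacent windows into maximal regions."""
    rows = scan_df.iloc[np.sort(indices)]
    regions: list[CandidateRegion] = []
    for idx, row in zip(np.sort(indices), rows.itertuples(index=False)):
        if (
            regions
            and regions[-1].chrom == row.CHROM
            and row.BIN_START <= regions[-1].end
        ):
            regions[-1].end = max(regions[-1].end, int(row.BIN_END))
            regions[-1].window_indices.append(int(idx))
        else:
            regions.append(
                CandidateRegion(
                    chrom=str(row.CHROM),
                    start=int(row.BIN_START),
                    end=int(row.BIN_END),
                    window_indices=[int(idx)],
                )
            )
    return regions


def genes_in_windows(
    scan_df: pd.DataFrame, indices: np.ndarray, genes: list[GeneModel]
) -> set[str]:
    """Gene ids whose span intersects any of the given windows by >= 1 bp."""
    hits: set[str] = set()
    win = scan_df.iloc[indices]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in win.itertuples(index=False):
        by_chrom.setdefault(str(row.CHROM), []).append(
            (int(row.BIN_START), int(row.BIN_END))
        )
    for g in genes:
        g0, g1 = g.start - 1, g.end  # to 0-based half-open
        for s, e in by_chrom.get(g.chrom, ()):
            if g0 < e and g1 > s:
                hits.add(g.gene_id)
                break
    return hits


def merge_and_annotate(
    scan_df: pd.DataFrame, cand: CandidateSets, genes: list[GeneModel]
) -> tuple[list[CandidateRegion], dict[str, set[str]]]:
    """Merge joint candidate windows into regions and map genes per statistic.

    Returns the merged regions (each annotated with overlapping genes) and a
    dict of gene sets: ``fst``, ``diversity``, and their ``joint``
    intersection.
    """
    regions = merge_windows(scan_df, cand.joint_windows)
    gene_sets = {
        "fst": genes_in_windows(scan_df, cand.fst_windows, genes),
        "diversity": genes_in_windows(scan_df, cand.div_windows, genes),
    }
    gene_sets["joint"] = gene_sets["fst"] & gene_sets["diversity"]
    for r in regions:
        r.gene_ids = sorted(
            g.gene_id
            for g in genes
            if g.chrom == r.chrom and g.start - 1 < r.end and g.end > r.start
        )
    return regions, gene_sets
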