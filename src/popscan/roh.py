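"""Runs-of-homozygosity detection and the F_ROH inbreeding coefficient.

The detector follows the two-stage windowed scan of the PLINK --homozyg
family: slide a fixed-size SNP window along each chromosome, call a window
"homozygous" if it holds at most ``max_het_per_window`` heterozygotes and
``max_missing_per_window`` missing calls, score each SNP by the fraction of
overlapping windows that are homozygous, and emit maximal runs of
consecutive high-scoring SNPs that satisfy the length, SNP-count, density
and gap constraints.  Segment boundaries are the first/last SNP positions
(the .hom output dialect).  F_ROH is total ROH length divided by the
autosomal genome length spanned by the SNPs (L_AUTO, 960,280 kb here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, PopulationPanel

logger = logging.getLogger(__name__)

#: autosomal genome length spanned by the SNP map, in bp
L_AUTO_BP = 960_280_000


@dataclass
class ROHParams:
    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_length_bp: int = 100_000
    min_density_bp_per_snp: int = 50_000  # at least one SNP per this many bp
    max_gap_bp: int = 1_000_000
    hit_rate_threshold: float = 0.05
    min_snps_in_segment: int = 100

    def __post_init__(self) -> None:
        for name in (
            "window_snps",
            "min_length_bp",
            "min_density_bp_per_snp",
            "max_gap_bp",
            "min_snps_in_segment",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hit_rate_threshold <= 1:
            raise ValueError("hit_rate_threshold must be in (0, 1]")


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int  # position of first SNP, 1-based
    end_bp: int  # position of last SNP, 1-based inclusive
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class InbreedingRecord:
    sample_id: str
    sum_roh_bp: int
    l_auto_bp: int = L_AUTO_BP
    f_roh: float = field(init=False)

    def __post_init__(self) -> None:
        if self.l_auto_bp <= 0:
            raise ValueError("l_auto_bp must be positive")
        self.f_roh = self.sum_roh_bp / self.l_auto_bp


def _eligible_snps(het: np.ndarray, miss: np.ndarray, params: ROHParams) -> np.ndarray:
    """Stage 1+2: per-SNP hit-rate eligibility for one chromosome."""
    m = het.size
    w = params.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    hc = np.concatenate([[0], np.cumsum(het.astype(np.int64))])
    mc = np.concatenate([[0], np.cumsum(miss.astype(np.int64))])
    n_win = m - w + 1
    win_het = hc[w:] - hc[:-w]
    win_miss = mc[w:] - mc[:-w]
    homo = (win_het <= params.max_het_per_window) & (
        win_miss <= params.max_missing_per_window
    )
    homo_c = np.concatenate([[0], np.cumsum(homo.astype(np.int64))])
    idx = np.arange(m)
    first = np.maximum(0, idx - w + 1)
    last = np.minimum(idx, n_win - 1)
    hits = homo_c[last + 1] - homo_c[first]
    covering = last - first + 1
    return hits / covering >= params.hit_rate_threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True in a boolean vector."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def detect_roh_individual(
    chrom: np.ndarray, pos: np.ndarray, dosage: np.ndarray, sample_id: str,
    params: ROHParams,
) -> list[ROHSegment]:
    """Scan one individual's dosage vector for ROH segments."""
    het = dosage == 1
    miss = dosage == MISSING
    segments: list[ROHSegment] = []
    seen: list[str] = []
    for c in pd.unique(chrom):
        seen.append(c)
        on = np.flatnonzero(chrom == c)
        if on.size < params.window_snps:
            logger.info(
                "detect_roh: chrom %s has %d < %d SNPs for %s; skipped",
                c, on.size, params.window_snps, sample_id,
            )
            continue
        p = pos[on]
        elig = _eligible_snps(het[on], miss[on], params)
        for lo, hi in _runs(elig):
            # split at inter-SNP gaps exceeding the permitted maximum
            gaps = np.diff(p[lo : hi + 1])
            cut = np.flatnonzero(gaps > params.max_gap_bp)
            bounds = [lo] + [lo + k + 1 for k in cut] + [hi + 1]
            for a, b in zip(bounds[:-1], bounds[1:]):
                n_snps = b - a
                start, end = int(p[a]), int(p[b - 1])
                length = end - start + 1
                if (
                    length >= params.min_length_bp
                    and n_snps >= params.min_snps_in_segment
                    and length <= n_snps * params.min_density_bp_per_snp
                ):
                    segments.append(
                        ROHSegment(sample_id, str(c), start, end, n_snps)
                    )
    return segments


def detect_roh(
    gm: GenotypeMatrix, params: ROHParams | None = None
) -> dict[str, list[ROHSegment]]:
    """Detect ROH for every individual; segments sorted, non-overlapping."""
    params = params or ROHParams()
    out: dict[str, list[ROHSegment]] = {}
    for i, s in enumerate(gm.sample_ids):
        out[s] = detect_roh_individual(gm.chrom, gm.pos, gm.dosage[i, :], s, params)
    return out


def f_roh(
    segments: list[ROHSegment], l_auto_bp: int = L_AUTO_BP, sample_id: str | None = None
) -> InbreedingRecord:
    """F_ROH = (sum of ROH lengths) / L_AUTO for one individual."""
    ids = {s.sample_id for s in segments}
    if len(ids) > 1:
        raise ValueError(f"segments from multiple individuals: {sorted(ids)}")
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in segments:
        if s.length_bp <= 0:
            raise ValueError("non-positive segment length")
        by_chrom.setdefault(s.chrom, []).append(s)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start_bp)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping segments on {a.chrom}: "
                    f"[{a.start_bp},{a.end_bp}] and [{b.start_bp},{b.end_bp}]"
                )
    total = sum(s.length_bp for s in segments)
    sid = sample_id or (next(iter(ids)) if ids else "")
    return InbreedingRecord(sample_id=sid, sum_roh_bp=total, l_auto_bp=l_auto_bp)


def summarize_roh(
    roh: dict[str, list[ROHSegment]],
    panel: PopulationPanel,
    l_auto_bp: int = L_AUTO_BP,
) -> pd.DataFrame:
    """Per-population ROH burden: segment count, mean length, mean F_ROH."""
    rows = []
    for p in panel.populations:
        samples = [s for s in panel.samples(p) if s in roh]
        segs = [seg for s in samples for seg in roh[s]]
        fs = [f_roh(roh[s], l_auto_bp, sample_id=s).f_roh for s in samples]
        rows.append(
            {
                "population": p,
                "n_individuals": len(samples),
                "n_segments": len(segs),
                "mean_length_bp": float(np.mean([s.length_bp for s in segs]))
                if segs
                else 0.0,
                "total_length_bp": int(sum(s.length_bp for s in segs)),
                "mean_f_roh": float(np.mean(fs)) if fs else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("population")


def roh_table(roh: dict[str, list[ROHSegment]]) -> pd.DataFrame:
    """Segments in PLINK .hom-style columns (IID, CHR, POS1, POS2, KB, NSNP)."""
    rows = [
        {
            "IID": seg.sample_id,
            "CHR": seg.chrom,
            "POS1": seg.start_bp,
            "POS2": seg.end_bp,
            "KB": seg.length_bp / 1000.0,
            "NSNP": seg.n_snps,
        }
        for segs in roh.values()
        for seg in segs
    ]
    return pd.DataFrame(rows, columns=["IID", "CHR", "POS1", "POS2", "KB", "NSNP"])
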