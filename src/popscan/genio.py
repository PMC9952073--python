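"""Genotype and interval I/O, site filtering, and simple site summaries.

The central container is :class:`GenotypeMatrix`: biallelic SNP genotypes
stored as alt-allele dosages (0/1/2, ``MISSING`` = -1) in a samples x sites
matrix, with 1-based coordinates sorted by (chrom, pos).  VCF is the exchange
format (read via cyvcf2, written as plain GT-only v4.2 text); gene intervals
come in as BED (0-based half-open) and are converted to 1-based inclusive
coordinates internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: sentinel for a missing diploid genotype in the dosage matrix
MISSING = -1

CATEGORIES = ("exon", "intron", "upstream", "downstream", "intergenic")


class VCFParseError(ValueError):
    """Malformed or unsorted VCF input."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP alt-allele dosage matrix with coordinates.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per dosage row.
    chrom, pos, ref, alt : ndarray
        Per-site chromosome name, 1-based position, and single-character
        reference/alternate alleles.
    dosage : ndarray of int8, shape (n_samples, n_sites)
        Count of alt alleles per genotype; ``MISSING`` (-1) for no-calls.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.pos)} sites"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set[str] = set()
        prev_chrom: str | None = None
        for i, c in enumerate(self.chrom):
            if c != prev_chrom:
                if c in seen:
                    raise VCFParseError(
                        f"sites not grouped by chromosome (chrom {c!r} "
                        f"recurs at site {i})"
                    )
                seen.add(c)
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise VCFParseError(
                    f"positions not strictly increasing on chrom {c!r} "
                    f"at site {i} (pos {self.pos[i]})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (must preserve sort order)."""
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[:, index],
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [lookup[s] for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[rows, :],
        )

    def sample_index(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=np.int64)

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites on *chrom* with 0-based half-open span [start, end)."""
        on = np.flatnonzero(self.chrom == chrom)
        if on.size == 0:
            return on
        p = self.pos[on]
        lo = np.searchsorted(p, start + 1, side="left")
        hi = np.searchsorted(p, end, side="right")
        return on[lo:hi]


@dataclass
class PopulationPanel:
    """Mapping from sample id to population label."""

    mapping: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.mapping.values():
            seen.setdefault(p)
        return list(seen)

    def samples(self, population: str) -> list[str]:
        out = [s for s, p in self.mapping.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} not in panel")
        return out

    @classmethod
    def read_tsv(cls, path) -> "PopulationPanel":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"panel line needs 2 columns: {line!r}")
                mapping[fields[0]] = fields[1]
        return cls(mapping)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.mapping.items():
                fh.write(f"{s}\t{p}\n")


@dataclass
class SiteFilterConfig:
    """Site-level QC thresholds: minimum MAF and minimum call rate."""

    maf_min: float = 0.05
    call_rate_min: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 1 and 0 <= self.call_rate_min <= 1):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class SiteFilterLog:
    n_input: int
    n_retained: int
    n_removed_maf: int
    n_removed_callrate: int
    n_removed_nocall: int


@dataclass
class GeneModel:
    """A gene interval with optional exon sub-intervals (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and indels are skipped (count logged); diploid GT
    fields map to alt-allele dosage, no-calls to ``MISSING``.  Raises
    :class:`VCFParseError` for malformed headers or unsorted records.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VCFParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    dosages: list[np.ndarray] = []
    n_skipped = 0
    for rec_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        gt = v.gt_types.astype(np.int8)  # 0/1/2 = dosage, 3 = unknown
        gt[gt == 3] = MISSING
        dosages.append(gt)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    dosage = (
        np.stack(dosages, axis=1)
        if dosages
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=dosage,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GT-only VCF v4.2 (MISSING encoded as ``./.``)."""
    gm._check_sorted()  # refuse to serialize an unsorted matrix
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popscan\n")
        for c in gm.chromosomes():
            length = int(gm.pos[gm.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STR[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def site_allele_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele copies, total called allele copies)."""
    called = gm.dosage != MISSING
    alt = np.where(called, gm.dosage, 0).sum(axis=0)
    return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)


def filter_sites(
    gm: GenotypeMatrix, cfg: SiteFilterConfig | None = None
) -> tuple[GenotypeMatrix, SiteFilterLog]:
    """Retain sites with MAF >= ``maf_min`` and call rate >= ``call_rate_min``.

    MAF is computed on non-missing allele copies.  Sites with zero
    non-missing calls are dropped and counted separately in the log.
    """
    cfg = cfg or SiteFilterConfig()
    alt, total = site_allele_counts(gm)
    nocall = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nocall, np.nan, alt / np.maximum(total, 1))
        maf = np.minimum(p, 1 - p)
    call_rate = (total / 2) / gm.n_samples
    ok_maf = maf >= cfg.maf_min
    ok_cr = call_rate >= cfg.call_rate_min
    keep = ~nocall & ok_maf & ok_cr
    log = SiteFilterLog(
        n_input=gm.n_sites,
        n_retained=int(keep.sum()),
        n_removed_maf=int((~nocall & ~ok_maf).sum()),
        n_removed_callrate=int((~nocall & ok_maf & ~ok_cr).sum()),
        n_removed_nocall=int(nocall.sum()),
    )
    logger.info(
        "filter_sites: retained %d/%d sites (maf<%g: %d, call rate<%g: %d, "
        "no calls: %d)",
        log.n_retained,
        log.n_input,
        cfg.maf_min,
        log.n_removed_maf,
        cfg.call_rate_min,
        log.n_removed_callrate,
        log.n_removed_nocall,
    )
    return gm.take_sites(np.flatnonzero(keep)), log


def snp_density(gm: GenotypeMatrix, bin_bp: int) -> dict[str, np.ndarray]:
    """Per-chromosome SNP counts over half-open bins of ``bin_bp`` bases.

    Bin k covers 0-based positions [k*bin_bp, (k+1)*bin_bp); a 1-based
    position p falls in bin (p-1)//bin_bp.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    out: dict[str, np.ndarray] = {}
    for c in gm.chromosomes():
        p = gm.pos[gm.chrom == c]
        bins = (p - 1) // bin_bp
        out[c] = np.bincount(bins)
    return out


_RANK = {"exon": 0, "intron": 1, "upstream": 2, "downstream": 2}


def classify_sites(
    gm: GenotypeMatrix, genes: list[GeneModel], flank_bp: int = 5000
) -> tuple[np.ndarray, dict[str, float]]:
    """Assign each site a functional category from gene intervals.

    Precedence exon > intron > upstream/downstream (strand-aware flanks of
    ``flank_bp``) > intergenic.  Returns the per-site category array and the
    category fractions (a probability vector over :data:`CATEGORIES`).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    cat = np.full(gm.n_sites, "intergenic", dtype=object)
    rank = np.full(gm.n_sites, 3, dtype=np.int8)
    n_ties = 0

    def assign(idx: np.ndarray, label: str) -> int:
        nonlocal n_ties
        r = _RANK[label]
        better = idx[rank[idx] > r]
        ties = idx[(rank[idx] == r) & (cat[idx] != label)]
        n_ties += ties.size
        cat[better] = label
        rank[better] = r
        return better.size

    for g in genes:
        on = np.flatnonzero(gm.chrom == g.chrom)
        if on.size == 0:
            continue
        p = gm.pos[on]
        inside = on[(p >= g.start) & (p <= g.end)]
        if g.exons:
            in_exon = np.zeros(inside.size, dtype=bool)
            for s, e in g.exons:
                in_exon |= (gm.pos[inside] >= s) & (gm.pos[inside] <= e)
            assign(inside[in_exon], "exon")
            assign(inside[~in_exon], "intron")
        else:
            assign(inside, "exon")
        before = on[(p >= g.start - flank_bp) & (p < g.start)]
        after = on[(p > g.end) & (p <= g.end + flank_bp)]
        if g.strand == "+":
            assign(before, "upstream")
            assign(after, "downstream")
        else:
            assign(before, "downstream")
            assign(after, "upstream")
    if n_ties:
        logger.info("classify_sites: %d flank-category ties resolved by precedence", n_ties)
    n = max(gm.n_sites, 1)
    fractions = {c: float((cat == c).sum()) / n for c in CATEGORIES}
    return cat, fractions


def read_bed_genes(path) -> list[GeneModel]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"BED line {i + 1}: need >= 3 columns")
            name = f[3] if len(f) > 3 else f"feature_{i + 1}"
            strand = f[5] if len(f) > 5 else "+"
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    strand=strand,
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def write_bed_genes(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
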