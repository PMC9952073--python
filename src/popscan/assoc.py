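"""Fixed-effect GLM genotype–trait association for an F2 intercross.

Model I:  Y = mu + G + H + f + e        (growth / meat-quality traits)
Model II: Y = mu + G + H + f + b(W − W̄) + e   (carcass traits)

G is the genotype class at the tested SNP (hom-ref / het / hom-alt), H the
hatch (2 levels), f the family (7 levels), W the slaughter weight covariate
centered at its sample mean.  Fits are ordinary least squares with
reference-cell coding; the genotype effect is tested by a partial (Type III)
F-test on the genotype dummies, least-squares means are evaluated at equal
weighting over the H and f levels (and W at its mean), and LSD pairwise
comparisons are unadjusted t-tests on LS-mean differences using the residual
mean square.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix, PopulationPanel

GENOTYPE_LABELS = {0: "hom_ref", 1: "het", 2: "hom_alt"}


@dataclass
class AssocResult:
    """Fit summary for one SNP x trait model."""

    trait: str
    model: str  # "I" or "II"
    ls_means: dict[int, float]
    f_stat: float
    p_value: float
    df_num: int
    df_resid: int
    mse: float
    b: float | None = None  # carcass-weight regression coefficient (Model II)
    genotype_levels: list[int] = field(default_factory=list)
    _params: np.ndarray | None = None
    _cov: np.ndarray | None = None
    _geno_cols: dict[int, int] | None = None


def _design(
    df: pd.DataFrame, covariate: bool
) -> tuple[np.ndarray, list[str], dict[int, int], list, list]:
    """Reference-coded design matrix: intercept, G, H, f dummies (+ centered W)."""
    g_levels = sorted(df["genotype"].unique())
    h_levels = sorted(df["hatch"].unique())
    f_levels = sorted(df["family"].unique())
    if len(g_levels) < 2:
        raise ValueError("no contrast: a single genotype class is present")
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    geno_cols: dict[int, int] = {g_levels[0]: -1}
    for lv in g_levels[1:]:
        geno_cols[lv] = len(cols)
        cols.append((df["genotype"] == lv).to_numpy(float))
        names.append(f"G[{lv}]")
    for lv in h_levels[1:]:
        cols.append((df["hatch"] == lv).to_numpy(float))
        names.append(f"H[{lv}]")
    for lv in f_levels[1:]:
        cols.append((df["family"] == lv).to_numpy(float))
        names.append(f"f[{lv}]")
    if covariate:
        w = df["W"].to_numpy(float)
        if np.ptp(w) == 0:
            raise ValueError("covariate degenerate: W is constant")
        cols.append(w - w.mean())
        names.append("W_centered")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: confounded factors among " + ", ".join(names[1:])
        )
    return X, names, geno_cols, h_levels, f_levels


def _fit(df: pd.DataFrame, trait: str, covariate: bool) -> AssocResult:
    y = df[trait].to_numpy(float)
    X, names, geno_cols, h_levels, f_levels = _design(df, covariate)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df_resid = n - k
    mse = float(resid @ resid) / df_resid if df_resid > 0 else float("nan")
    cov = XtX_inv * mse

    # partial F-test on the genotype dummy block (Type III with no interactions)
    g_idx = [c for g, c in geno_cols.items() if c >= 0]
    keep = [i for i in range(k) if i not in g_idx]
    Xr = X[:, keep]
    beta_r = np.linalg.lstsq(Xr, y, rcond=None)[0]
    rss_r = float(np.sum((y - Xr @ beta_r) ** 2))
    rss_f = float(resid @ resid)
    df_num = len(g_idx)
    if np.ptp(y) > 0 and mse > 0 and np.isfinite(mse):
        f_stat = ((rss_r - rss_f) / df_num) / mse
        p = float(stats.f.sf(f_stat, df_num, df_resid))
    else:  # zero residual variance: no stochastic contrast to test
        f_stat, p = float("nan"), 1.0

    # LS-means: prediction averaged over an equally weighted H x f grid,
    # covariate at its mean (centered term contributes zero)
    name_idx = {nm: i for i, nm in enumerate(names)}
    ls_means: dict[int, float] = {}
    for g, c in geno_cols.items():
        total = 0.0
        for h, f in itertools.product(h_levels, f_levels):
            v = beta[0]
            if c >= 0:
                v += beta[c]
            if f"H[{h}]" in name_idx:
                v += beta[name_idx[f"H[{h}]"]]
            if f"f[{f}]" in name_idx:
                v += beta[name_idx[f"f[{f}]"]]
            total += v
        ls_means[g] = float(total / (len(h_levels) * len(f_levels)))

    return AssocResult(
        trait=trait,
        model="II" if covariate else "I",
        ls_means=ls_means,
        f_stat=float(f_stat),
        p_value=p,
        df_num=df_num,
        df_resid=df_resid,
        mse=mse,
        b=float(beta[name_idx["W_centered"]]) if covariate else None,
        genotype_levels=sorted(geno_cols),
        _params=beta,
        _cov=cov,
        _geno_cols=geno_cols,
    )


def fit_model1(records: pd.DataFrame, trait: str) -> AssocResult:
    """Model I: Y ~ mu + genotype + hatch + family."""
    return _fit(records, trait, covariate=False)


def fit_model2(records: pd.DataFrame, trait: str) -> AssocResult:
    """Model II: Model I plus the centered slaughter-weight covariate b(W − W̄)."""
    return _fit(records, trait, covariate=True)


def lsd_pairwise(result: AssocResult) -> pd.DataFrame:
    """Unadjusted (LSD) pairwise t-comparisons of genotype LS-means.

    For each genotype pair the LS-mean difference reduces to a contrast on
    the genotype dummies, so SE(diff) comes from the fitted coefficient
    covariance; t has the model's residual df.
    """
    if result._params is None or result._cov is None or result._geno_cols is None:
        raise ValueError("result lacks fit internals")
    k = result._params.size
    rows = []
    for g1, g2 in itertools.combinations(result.genotype_levels, 2):
        c = np.zeros(k)
        c1, c2 = result._geno_cols[g1], result._geno_cols[g2]
        if c1 >= 0:
            c[c1] = 1.0
        if c2 >= 0:
            c[c2] -= 1.0
        diff = result.ls_means[g1] - result.ls_means[g2]
        se = float(np.sqrt(c @ result._cov @ c))
        if se > 0 and np.isfinite(se):
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), result.df_resid))
        else:
            t, p = float("nan"), 1.0
        rows.append(
            {
                "genotype_1": GENOTYPE_LABELS.get(g1, str(g1)),
                "genotype_2": GENOTYPE_LABELS.get(g2, str(g2)),
                "diff": diff,
                "se": se,
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def allele_freq_by_group(
    gm: GenotypeMatrix, panel: PopulationPanel, chrom: str, pos: int
) -> dict[str, float]:
    """Per-population alt-allele frequency at one SNP from non-missing calls."""
    idx = np.flatnonzero((gm.chrom == chrom) & (gm.pos == pos))
    if idx.size == 0:
        raise KeyError(f"SNP {chrom}:{pos} not present")
    d = gm.dosage[:, idx[0]]
    out: dict[str, float] = {}
    for p in panel.populations:
        rows = gm.sample_index(panel.samples(p))
        v = d[rows]
        called = v != MISSING
        n = 2 * int(called.sum())
        out[p] = float(v[called].sum()) / n if n else float("nan")
    return out


def association_table(
    records: pd.DataFrame, traits: list[str], model: str = "I"
) -> pd.DataFrame:
    """Fit one model per trait and tabulate F, p and LS-means, with BH-FDR."""
    fit = fit_model2 if model == "II" else fit_model1
    rows = []
    for t in traits:
        r = fit(records, t)
        row = {
            "trait": t,
            "model": r.model,
            "F": r.f_stat,
            "p": r.p_value,
            "df_resid": r.df_resid,
        }
        for g, m in r.ls_means.items():
            row[f"lsmean_{GENOTYPE_LABELS.get(g, g)}"] = m
        if r.b is not None:
            row["b"] = r.b
        rows.append(row)
    df = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
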