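"""cis-eQTL association mapping and summary-statistic utilities.

Associations are ordinary least squares of an expression unit on alt-allele
dosage (plus covariates), two-sided t test with df = n - 2 - n_covariates.
This mirrors MatrixeQTL-style linear-model mapping on residualized,
normalized expression; relatedness is assumed to have been regressed out
upstream.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AssocStat, CisWindow, ExpressionMatrix, GenotypePanel, SnpRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def hwe_test(hom_ref: int, het: int, hom_alt: int, method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium P-value from genotype counts.

    ``chisq`` is the conventional 1-df goodness-of-fit test used as a
    genotyping-quality filter; ``exact`` is the Wigginton-style exact test
    on the heterozygote count. Monomorphic sites return P = 1 by convention.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_alt = 2 * hom_alt + het
    n_ref = 2 * hom_ref + het
    if n_alt == 0 or n_ref == 0:
        return 1.0
    if method == "chisq":
        p = n_alt / (2 * n)
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.array([hom_ref, het, hom_alt], dtype=float)
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(het, min(n_alt, n_ref) // 1, n)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(het_obs: int, n_minor: int, n: int) -> float:
    """Exact HWE test: sum probabilities of heterozygote counts no more
    likely than the observed one, conditional on allele counts."""
    n_minor = int(n_minor)
    # heterozygote count shares parity with the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(het = h | n, n_minor) up to a constant (Levene-Haldane)
    n_major = 2 * n - n_minor
    hom_min = (n_minor - hets) // 2
    hom_maj = (n_major - hets) // 2
    logp = (
        hets * math.log(2)
        - _lgamma_arr(hom_min + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_maj + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == het_obs]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


def _lgamma_arr(x) -> np.ndarray:
    return np.vectorize(math.lgamma)(np.asarray(x, dtype=float))


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    info_min: float = 0.8,
    hwe_p_min: float = 1e-4,
) -> GenotypePanel:
    """Drop SNPs with MAF < maf_min, imputation info < info_min, or
    HWE P < hwe_p_min (all strict, matching the filter conventions)."""
    drops = {"maf": 0, "info": 0, "hwe": 0}
    keep: list[str] = []
    for rec in panel.snps:
        if rec.maf < maf_min:
            drops["maf"] += 1
        elif rec.info < info_min:
            drops["info"] += 1
        elif rec.hwe_p < hwe_p_min:
            drops["hwe"] += 1
        else:
            keep.append(rec.id)
    if not keep:
        raise ValueError("QC removed every SNP")
    if any(drops.values()):
        logger.info(
            "QC removed %d SNPs (maf=%d, info=%d, hwe=%d)",
            sum(drops.values()), drops["maf"], drops["info"], drops["hwe"],
        )
    return panel.subset(keep)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def _impute_missing(x: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages; log the imputed fraction."""
    mask = np.isnan(x)
    if mask.any():
        logger.info("mean-imputing %.3f of dosages", mask.mean())
        x = np.where(mask, np.nanmean(x), x)
    return x


def _design(n: int, covariates: Optional[np.ndarray]) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    return np.column_stack([np.ones(n), cov])


def associate(
    dosage: np.ndarray,
    expression: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    snp_id: str = "snp",
    feature_id: str = "feature",
) -> AssocStat:
    """OLS of expression on dosage (+ intercept and covariates).

    Returns beta, se, t and the two-sided P from a t distribution with
    df = n - 2 - n_covariates.
    """
    g = _impute_missing(np.asarray(dosage, dtype=float))
    y = np.asarray(expression, dtype=float)
    if g.shape != y.shape:
        raise ValueError("dosage and expression lengths differ")
    n = g.size
    if np.ptp(g) == 0:
        raise ValueError("monomorphic: constant dosage")
    base = _design(n, covariates)
    X = np.column_stack([base, g])
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError(f"not enough observations (n={n}) for df > 0")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = float(coef[-1])
    se = math.sqrt(sigma2 * xtx_inv[-1, -1])
    t = beta / se if se > 0 else 0.0
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AssocStat(snp_id, feature_id, beta, se, t, min(p, 1.0), df, n)


def bulk_associate(
    G: np.ndarray,
    Y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Vectorized simple regressions of every column of Y on every column of G.

    Both sides are first residualized on [1, covariates]; the resulting
    t statistics and P-values are identical to the full OLS with the
    covariates in the model (df = n - 2 - n_covariates). Returns arrays of
    shape (n_snps, n_features): beta, se, t, p, plus scalar df and n.

    Columns of Y containing NaN are handled pairwise-complete via a slower
    per-column path; NaN dosages are mean-imputed per SNP.
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = G.shape[0]
    if Y.shape[0] != n:
        raise ValueError("G and Y row counts differ")
    if np.isnan(G).any():
        G = np.apply_along_axis(_impute_missing, 0, G)
    n_cov = 0 if covariates is None else np.atleast_2d(np.asarray(covariates).T).shape[0]
    df = n - 2 - n_cov
    if df <= 0:
        raise ValueError("not enough observations for the model")

    nan_cols = np.isnan(Y).any(axis=0)
    base = _design(n, covariates)
    Q, _ = np.linalg.qr(base)

    def _resid(M: np.ndarray) -> np.ndarray:
        return M - Q @ (Q.T @ M)

    m, k = G.shape[1], Y.shape[1]
    beta = np.empty((m, k))
    se = np.empty((m, k))
    n_eff = np.full((m, k), n, dtype=int)

    Gr = _resid(G)
    gg = (Gr * Gr).sum(axis=0)
    if (gg <= 1e-12).any():
        raise ValueError("monomorphic (or covariate-collinear) dosage column")

    if (~nan_cols).any():
        Yc = _resid(Y[:, ~nan_cols])
        yy = (Yc * Yc).sum(axis=0)
        cross = Gr.T @ Yc
        b = cross / gg[:, None]
        rss = np.maximum(yy[None, :] - cross**2 / gg[:, None], 0.0)
        s2 = rss / df
        beta[:, ~nan_cols] = b
        se[:, ~nan_cols] = np.sqrt(s2 / gg[:, None])

    for j in np.flatnonzero(nan_cols):
        y = Y[:, j]
        ok = ~np.isnan(y)
        nj = int(ok.sum())
        base_j = _design(nj, None if covariates is None else np.asarray(covariates)[ok])
        Qj, _ = np.linalg.qr(base_j)
        yr = y[ok] - Qj @ (Qj.T @ y[ok])
        Gj = G[ok] - Qj @ (Qj.T @ G[ok])
        ggj = (Gj * Gj).sum(axis=0)
        ggj = np.where(ggj <= 1e-12, np.nan, ggj)
        cross = Gj.T @ yr
        b = cross / ggj
        rss = np.maximum(float(yr @ yr) - cross**2 / ggj, 0.0)
        dfj = nj - 2 - n_cov
        beta[:, j] = b
        se[:, j] = np.sqrt(rss / dfj / ggj)
        n_eff[:, j] = nj

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    dfs = n_eff - 2 - n_cov
    p = 2.0 * stats.t.sf(np.abs(t), dfs)
    return {"beta": beta, "se": se, "t": t, "p": p, "df": dfs, "n": n_eff}


def derive_from_p(p: float, beta: float, df: int) -> tuple[float, float]:
    """Reconstruct (t, se) from a two-sided P, a signed beta, and df.

    |t| is the upper-tail t quantile at p/2; t carries beta's sign;
    se = |beta| / |t|. p = 1 with beta = 0 returns (0, inf); p = 1 with a
    non-zero beta is inconsistent input.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    t_abs = float(stats.t.isf(p / 2.0, df))
    if t_abs == 0.0:
        if beta != 0.0:
            raise ValueError("p = 1 inconsistent with non-zero beta")
        return 0.0, math.inf
    if not math.isfinite(t_abs):
        # quantile overflow at extreme significance: clamp with a warning
        logger.warning("t quantile overflow at p=%g; clamping", p)
        t_abs = float(stats.t.isf(np.nextafter(0, 1) / 2.0, df))
    t = math.copysign(t_abs, beta) if beta != 0 else t_abs
    se = abs(beta) / t_abs if beta != 0 else math.inf
    return t, se


# ---------------------------------------------------------------------------
# cis scanning, FDR, proxies
# ---------------------------------------------------------------------------

def features_in_window(
    features: pd.DataFrame, chrom: str, center: int, half_width: int
) -> list[str]:
    """Feature ids whose [start, end] interval overlaps the inclusive window."""
    lo, hi = center - half_width, center + half_width
    sel = (
        (features["chrom"] == chrom)
        & (features["start"] <= hi)
        & (features["end"] >= lo)
    )
    return list(features.index[sel])


def cis_scan(
    gwas_snp: str,
    panel: GenotypePanel,
    expr: ExpressionMatrix,
    window: CisWindow = CisWindow(),
    covariates: Optional[np.ndarray] = None,
) -> list[AssocStat]:
    """Associate one SNP with every expression unit within the cis window.

    The window is anchored on the SNP position (discovery convention);
    a feature counts as inside if any part of its interval overlaps the
    inclusive +/- half_width window.
    """
    rec = panel.record(gwas_snp)
    feats = features_in_window(expr.features, rec.chrom, rec.pos, window.half_width)
    if not feats:
        logger.warning("no features within window of %s", gwas_snp)
        return []
    g = panel.dosage(gwas_snp)
    Y = expr.values[feats].to_numpy()
    res = bulk_associate(g, Y, covariates)
    return [
        AssocStat(
            gwas_snp, f,
            float(res["beta"][0, j]), float(res["se"][0, j]),
            float(res["t"][0, j]), float(res["p"][0, j]),
            int(res["df"][0, j]), int(res["n"][0, j]),
        )
        for j, f in enumerate(feats)
    ]


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q(stats_list: Iterable[AssocStat]) -> list[AssocStat]:
    """Fill the q field of a batch of associations with BH-adjusted values."""
    stats_list = list(stats_list)
    if not stats_list:
        return stats_list
    q = bh_fdr([s.p for s in stats_list])
    for s, qi in zip(stats_list, q):
        s.q = float(qi)
    return stats_list


def find_proxy(
    target_snp: str, panel: GenotypePanel, r2_min: float = 0.7
) -> Optional[SnpRecord]:
    """Best available tag SNP: maximal r^2 >= r2_min to the target, ties
    broken by distance then id; the target itself is excluded."""
    j = panel.index_of(target_snp)
    g = panel.dosages[:, j]
    if np.ptp(g) == 0:
        raise ValueError("target SNP is monomorphic")
    D = panel.dosages
    Dc = D - D.mean(axis=0)
    gc = g - g.mean()
    denom = np.sqrt((Dc**2).sum(axis=0) * (gc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, (Dc.T @ gc) / denom, 0.0) ** 2
    pos0 = panel.snps[j].pos
    best = None
    for k, rec in enumerate(panel.snps):
        if k == j or r2[k] < r2_min:
            continue
        key = (-r2[k], abs(rec.pos - pos0), rec.id)
        if best is None or key < best[0]:
            best = (key, rec)
    return None if best is None else best[1]


def power(n: int, r2: float, alpha: float = 0.05) -> float:
    """Power of the 1-df F test of a simple regression explaining a
    variance fraction r2 at sample size n: non-central F with
    ncp = n * r2 / (1 - r2)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    fcrit = stats.f.isf(alpha, 1, n - 2)
    if r2 == 0.0:
        return alpha
    ncp = n * r2 / (1.0 - r2)
    return float(stats.ncf.sf(fcrit, 1, n - 2, ncp))


def genotype_pca(panel: GenotypePanel, k: int) -> np.ndarray:
    """Top-k PC scores of the centred, variance-standardized dosage matrix.

    Sign convention: the largest-magnitude loading of each component is
    positive, so scores are deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= panel.n_individuals:
        raise ValueError("k must be smaller than the number of individuals")
    X = panel.dosages - panel.dosages.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    X = X[:, sd > 0] / sd[sd > 0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for c in range(min(k, Vt.shape[0])):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            scores[:, c] *= -1.0
    return scores
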