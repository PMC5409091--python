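"""Regulatory Trait Concordance (RTC) scoring.

For every SNP k in the interval containing the GWAS SNP, the phenotype is
residualized on SNP k and the best QTL is re-associated with those
residuals. If SNP k tags the functional variant, correcting for it
destroys the QTL signal, so the re-association P is large. SNPs are
ranked by how effectively they erase the signal (rank 1 = largest
residual P); the score is

    RTC = (N_SNPs - Rank_GWAS SNP) / N_SNPs,

so a perfectly concordant GWAS SNP scores (N-1)/N and RTC > 0.9 reads as
a shared functional effect.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .eqtl_map import associate
from .types import GenotypePanel, RtcResult

logger = logging.getLogger(__name__)


def residual_phenotype(
    expression: np.ndarray,
    best_qtl_dosage: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mean-zero OLS residuals of expression on a QTL dosage (+covariates)."""
    y = np.asarray(expression, dtype=float)
    g = np.asarray(best_qtl_dosage, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("constant dosage")
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cols.append(cov[:, None] if cov.ndim == 1 else cov)
    X = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def hotspot_interval(
    gwas_snp_pos: tuple[str, int],
    hotspot_bed: Optional[Sequence[tuple[str, int, int]]] = None,
    fallback_halfwidth: int = 250_000,
) -> tuple[str, int, int]:
    """Interval containing the SNP from a (recombination-hotspot) BED set,
    converted to 1-based inclusive; falls back to a symmetric window of
    ``fallback_halfwidth`` when no interval contains the SNP."""
    chrom, pos = gwas_snp_pos
    if hotspot_bed is not None:
        for c, s, e in hotspot_bed:  # 0-based half-open
            if c == chrom and s <= pos - 1 < e:
                return (c, s + 1, e)
        logger.warning("SNP %s:%d in no hotspot interval; using fallback", chrom, pos)
    return (chrom, max(1, pos - fallback_halfwidth), pos + fallback_halfwidth)


def score_from_rank(rank: int, n_snps: int) -> float:
    """(N_SNPs - rank) / N_SNPs."""
    if not (1 <= rank <= n_snps):
        raise ValueError("rank out of range")
    return (n_snps - rank) / n_snps


def rtc_score(
    gwas_snp: str,
    panel: GenotypePanel,
    expression: np.ndarray,
    best_qtl: str,
    interval: tuple[str, int, int],
    covariates: Optional[np.ndarray] = None,
    feature_id: str = "feature",
) -> RtcResult:
    """RTC of a GWAS SNP for one QTL within a 1-based inclusive interval.

    P-value ties are broken against the GWAS SNP (it takes the worst rank
    within its tie group), which is conservative for candidate-causal
    calls.
    """
    chrom, start, end = interval
    rec = panel.record(gwas_snp)
    if rec.chrom != chrom or not (start <= rec.pos <= end):
        raise ValueError(f"GWAS SNP {gwas_snp} outside interval {interval}")
    in_iv = [
        s.id for s in panel.snps
        if s.chrom == chrom and start <= s.pos <= end
    ]
    if len(in_iv) < 2:
        raise ValueError("need at least 2 SNPs in the interval")
    y = np.asarray(expression, dtype=float)
    g_best = panel.dosage(best_qtl)

    resid_p: dict[str, float] = {}
    for sid in in_iv:
        g_k = panel.dosage(sid)
        if np.ptp(g_k) == 0:
            resid_p[sid] = 0.0  # uninformative correction: least concordant
            continue
        resid = residual_phenotype(y, g_k, covariates)
        if np.corrcoef(g_best, g_k)[0, 1] ** 2 > 1 - 1e-10:
            # correcting for (a copy of) the best QTL removes it entirely
            resid_p[sid] = 1.0
            continue
        resid_p[sid] = associate(g_best, resid).p

    p_gwas = resid_p[gwas_snp]
    n = len(in_iv)
    # rank 1 = largest residual P (most concordant); GWAS SNP takes the
    # worst rank inside its tie group
    rank = sum(1 for v in resid_p.values() if v > p_gwas)
    rank += sum(1 for s, v in resid_p.items() if v == p_gwas)
    return RtcResult(
        gwas_snp=gwas_snp,
        feature_id=feature_id,
        interval=interval,
        n_snps=n,
        rank=rank,
        score=score_from_rank(rank, n),
    )
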