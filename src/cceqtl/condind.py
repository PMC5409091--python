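"""Conditional association of a GWAS SNP given the best cis-eQTL.

Summary mode reconstructs the two-SNP joint regression from marginal
summary statistics and an LD reference panel (the COJO idea): with
d_j = 2 p_j (1 - p_j) n and c = r sqrt(d_t d_c),

    X'X ~= [[d_t, c], [c, d_c]],   X'y ~= [d_t beta_t, d_c beta_c],

the joint coefficients solve the 2x2 system, the residual variance comes
from SSY ~= (n - 1) var_y minus the fitted sum of squares, and the target
coefficient's variance uses the full inverse of X'X (df = n - 3). When
individual-level data exist, ``exact_conditional`` is the oracle.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .eqtl_map import associate
from .types import AssocStat, ConditionalResult, GenotypePanel

logger = logging.getLogger(__name__)

COLLINEAR_R2 = 0.9  # GCTA convention for the summary-mode collinearity bound


def ld_r(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    """Pearson correlation of the two dosage columns."""
    a = panel.dosage(snp_a)
    b = panel.dosage(snp_b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant dosage column")
    return float(np.corrcoef(a, b)[0, 1])


def estimate_var_y(
    stats_list: Sequence[AssocStat], freqs: Sequence[float], n: int
) -> float:
    """Phenotypic variance recovered from marginal summary statistics.

    Inverts the simple-regression identity SSY = d_j beta_j^2 +
    (n - 2) d_j se_j^2 per SNP and takes the median across cis SNPs,
    which is robust to the occasional outlier SNP.
    """
    vals = []
    for s, p in zip(stats_list, freqs):
        d = 2.0 * p * (1.0 - p) * n
        vals.append(d * (s.se**2 * (n - 2) + s.beta**2) / (n - 1))
    if not vals:
        raise ValueError("no summary statistics to estimate var_y from")
    return float(np.median(vals))


def conditional_assoc(
    stat_target: AssocStat,
    stat_cond: AssocStat,
    r: float,
    freqs: tuple[float, float],
    n: int,
    var_y: Optional[float] = None,
) -> ConditionalResult:
    """Conditional effect of the target SNP given the conditioning SNP,
    from summary statistics alone.

    |r|^2 above the collinearity bound short-circuits to the collinear
    path: p_cond = 1, i.e. the target carries no signal beyond the
    conditioning SNP (downstream this reads as "shared").
    """
    if stat_target.feature_id != stat_cond.feature_id:
        raise ValueError("conditional_assoc requires stats on the same feature")
    p_t, p_c = freqs
    if r * r > COLLINEAR_R2:
        logger.info(
            "%s ~ %s collinear (r^2=%.3f): conditional P set to 1",
            stat_target.snp_id, stat_cond.snp_id, r * r,
        )
        return ConditionalResult(
            gwas_snp=stat_target.snp_id,
            best_eqtl=stat_cond.snp_id,
            feature_id=stat_target.feature_id,
            beta_cond=0.0,
            se_cond=math.inf,
            p_cond=1.0,
            mode="summary",
            collinear=True,
        )
    if var_y is None:
        var_y = estimate_var_y([stat_target, stat_cond], [p_t, p_c], n)
    ssy = (n - 1) * var_y
    # genotype sums of squares recovered from the simple-regression identity
    # SSY = d_j (beta_j^2 + (n-2) se_j^2); this equals the centred empirical
    # d_j exactly, whereas 2 p q n assumes Hardy-Weinberg proportions
    d_t = ssy / (stat_target.beta**2 + (n - 2) * stat_target.se**2)
    d_c = ssy / (stat_cond.beta**2 + (n - 2) * stat_cond.se**2)
    c = r * math.sqrt(d_t * d_c)

    xtx = np.array([[d_t, c], [c, d_c]])
    xty = np.array([d_t * stat_target.beta, d_c * stat_cond.beta])
    b = np.linalg.solve(xtx, xty)
    df = n - 3
    fitted_ss = float(b @ xty)
    sigma2 = max(ssy - fitted_ss, 0.0) / df
    if sigma2 == 0.0:
        logger.warning("non-positive residual variance; clamping")
        sigma2 = np.finfo(float).tiny
    cov = sigma2 * np.linalg.inv(xtx)
    se = math.sqrt(cov[0, 0])
    t = b[0] / se
    p = float(min(2.0 * stats.t.sf(abs(t), df), 1.0))
    return ConditionalResult(
        gwas_snp=stat_target.snp_id,
        best_eqtl=stat_cond.snp_id,
        feature_id=stat_target.feature_id,
        beta_cond=float(b[0]),
        se_cond=se,
        p_cond=p,
        mode="summary",
    )


def exact_conditional(
    dosage_target: np.ndarray,
    dosage_cond: np.ndarray,
    expression: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    gwas_snp: str = "target",
    best_eqtl: str = "cond",
    feature_id: str = "feature",
) -> ConditionalResult:
    """Joint OLS of expression on both SNPs; returns the target coefficient."""
    g_t = np.asarray(dosage_target, dtype=float)
    g_c = np.asarray(dosage_cond, dtype=float)
    r = np.corrcoef(g_t, g_c)[0, 1]
    if abs(r) > 1 - 1e-10:
        return ConditionalResult(
            gwas_snp=gwas_snp, best_eqtl=best_eqtl, feature_id=feature_id,
            beta_cond=0.0, se_cond=math.inf, p_cond=1.0,
            mode="exact", collinear=True,
        )
    cov = g_c if covariates is None else np.column_stack([g_c, covariates])
    st = associate(g_t, np.asarray(expression, dtype=float), covariates=cov)
    return ConditionalResult(
        gwas_snp=gwas_snp, best_eqtl=best_eqtl, feature_id=feature_id,
        beta_cond=st.beta, se_cond=st.se, p_cond=st.p, mode="exact",
    )


def is_independent(res: ConditionalResult, threshold: float = 0.05) -> bool:
    """Independent of the best cis-eQTL iff p_cond < threshold (strict)
    and the pair was not collinear."""
    return (not res.collinear) and res.p_cond < threshold
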