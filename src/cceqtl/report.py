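"""Candidate-causal classification and summary computations.

A GWAS SNP is a candidate-causal eQTL for an expression unit when the
association survives FDR (q < 0.05), is not independent of the best
cis-eQTL (P_cond > 0.05), and the colocalisation posterior favours a
shared variant (PP3 < PP4). The asQTL route replaces the last two
conditions with RTC > 0.9. The module also computes the eGene:eQTL
ratios, the relative-significance heatmap matrix, TAD co-membership of
multi-eGene eQTLs, and the qPCR delta-delta-Ct statistic.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ClassificationRecord, Status, TadIntervalSet

logger = logging.getLogger(__name__)

Q_SIG = 0.05
P_COND_SHARED = 0.05
RTC_MIN = 0.9


def classify_eqtl(rec: ClassificationRecord) -> Status:
    """Three-part rule: q < 0.05, P_cond > 0.05, PP3 < PP4."""
    if rec.q is None:
        raise ValueError("record has no q value")
    if rec.q >= Q_SIG:
        return "not_significant"
    if rec.p_cond is None or rec.pp3 is None or rec.pp4 is None:
        raise ValueError(
            f"significant record {rec.gwas_snp}x{rec.feature_id} missing "
            "conditional/colocalisation fields"
        )
    if rec.p_cond > P_COND_SHARED and rec.pp3 < rec.pp4:
        return "candidate_causal"
    return "significant_not_causal"


def classify_asqtl(rec: ClassificationRecord) -> Status:
    """asQTL rule: q < 0.05 and RTC > 0.9 (both strict)."""
    if rec.q is None or rec.rtc_score is None:
        raise ValueError("asQTL record needs q and rtc_score")
    if rec.q >= Q_SIG:
        return "not_significant"
    if rec.rtc_score > RTC_MIN:
        return "candidate_causal"
    return "significant_not_causal"


def classify_all(records: Sequence[ClassificationRecord]) -> list[ClassificationRecord]:
    """Fill the status field in place, routing junctions through the RTC rule."""
    for rec in records:
        rule = classify_asqtl if rec.quant_type == "junction" else classify_eqtl
        rec.status = rule(rec)
    return list(records)


def egene_eqtl_ratio(
    records: Sequence[ClassificationRecord], quant_type: str
) -> tuple[int, int, float]:
    """(n_eqtls, n_egenes, ratio) over the candidate-causal records of one
    quantification type.

    n_eqtls counts distinct GWAS SNPs with at least one candidate-causal
    record; n_egenes counts distinct genes across those records; the ratio
    is n_egenes / n_eqtls rounded half-even to 2 decimals. A gene counts
    once per quantification type however many of its exons are involved.
    """
    cc = [
        r for r in records
        if r.quant_type == quant_type and r.status == "candidate_causal"
    ]
    eqtls = {r.gwas_snp for r in cc}
    egenes = {r.gene_id for r in cc}
    if not eqtls:
        return 0, len(egenes), float("nan")
    return len(eqtls), len(egenes), round(len(egenes) / len(eqtls), 2)


def heatmap_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """Relative-significance matrix for the cross-quantification heatmap.

    Per column (quantification type), value = -log2(P / P_best) where
    P_best is the column's most significant (smallest) P, so the best
    association maps to 0 and weaker ones go negative, preserving the
    significance ordering. Rows are then sorted by decreasing cumulative
    significance (row sum). All-missing columns are skipped with a warning.
    """
    cols = {}
    for c in p.columns:
        col = p[c].astype(float)
        if col.isna().all():
            logger.warning("column %s all-missing; skipped", c)
            continue
        if ((col <= 0) | (col > 1)).any():
            raise ValueError(f"column {c} has P-values outside (0, 1]")
        cols[c] = -np.log2(col / col.min())
    out = pd.DataFrame(cols, index=p.index)
    order = out.sum(axis=1, skipna=True).sort_values(ascending=False).index
    return out.loc[order]


def tad_comembership(
    egene_tss: Sequence[tuple[str, int]],
    tads: TadIntervalSet,
) -> bool:
    """True iff every eGene TSS of one eQTL's candidate-causal set falls in
    a single TAD interval. A TSS outside every TAD counts as violating."""
    hits = []
    for chrom, pos in egene_tss:
        iv = tads.containing(chrom, pos)
        if iv is None:
            logger.warning("TSS %s:%d in no TAD; counted as crossing", chrom, pos)
            return False
        hits.append(iv)
    return len(set(hits)) <= 1


def delta_delta_ct(
    ct_target_case: Sequence[float],
    ct_ref_case: Sequence[float],
    ct_target_ctrl: Sequence[float],
    ct_ref_ctrl: Sequence[float],
) -> tuple[float, float]:
    """qPCR relative quantification against a reference gene.

    Delta-Ct = Ct_target - Ct_ref per sample; delta-delta-Ct is the case
    minus control mean difference; log2 fold change = -ddCt (one cycle =
    one doubling). P is a two-sample t test on the per-sample delta-Ct.
    """
    tc, rc = np.asarray(ct_target_case, float), np.asarray(ct_ref_case, float)
    tk, rk = np.asarray(ct_target_ctrl, float), np.asarray(ct_ref_ctrl, float)
    if tc.shape != rc.shape or tk.shape != rk.shape:
        raise ValueError("target/reference Ct vectors must pair up in length")
    if tc.size < 2 or tk.size < 2:
        raise ValueError("need at least 2 replicates per group")
    dct_case = tc - rc
    dct_ctrl = tk - rk
    ddct = float(dct_case.mean() - dct_ctrl.mean())
    if np.ptp(dct_case) == 0 and np.ptp(dct_ctrl) == 0:
        p = 1.0 if ddct == 0 else 0.0
    else:
        p = float(stats.ttest_ind(dct_case, dct_ctrl).pvalue)
    return -ddct, p
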