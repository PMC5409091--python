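"""End-to-end locus simulation and candidate-causal classification.

``simulate_locus`` draws one cis region under a causal layout (shared /
distinct / gwas_only / eqtl_only / null) — the data-generating regimes
behind the five colocalisation hypotheses — and ``classify_locus`` runs
the full integration: cis scan of the GWAS SNP, FDR, best-eQTL lookup,
summary-statistic conditional analysis, colocalisation, and the
three-part classification rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import coloc, condind, report, simgen
from .eqtl_map import CisWindow, attach_q, bulk_associate, cis_scan
from .types import (
    AssocStat,
    ClassificationRecord,
    ColocPriors,
    ExpressionMatrix,
    GeneModel,
    GenotypePanel,
    GwasSummary,
    SimulationConfig,
)


@dataclass
class LocusSim:
    """One simulated cis locus with its ground truth."""

    cfg: SimulationConfig
    panel: GenotypePanel
    genes: list[GeneModel]
    exon_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    gwas: GwasSummary
    gwas_snp: str
    eqtl_snp: Optional[str]
    target_gene: Optional[str]
    truth: pd.DataFrame


def _pick_snp_pair(
    panel: GenotypePanel, layout: str, rng: np.random.Generator
) -> tuple[str, Optional[str]]:
    """GWAS and eQTL causal SNPs honouring the layout's LD requirements."""
    m = panel.n_snps
    mid = panel.snp_ids[m // 2]
    if layout in ("shared", "gwas_only", "null", "eqtl_only"):
        return mid, mid
    # distinct: find a partner with r^2 < 0.2 to the GWAS SNP
    g = panel.dosage(mid)
    order = rng.permutation(m)
    for j in order:
        sid = panel.snp_ids[j]
        if sid == mid:
            continue
        r = np.corrcoef(g, panel.dosages[:, j])[0, 1]
        if r * r < 0.2:
            return mid, sid
    raise RuntimeError("no SNP pair with r^2 < 0.2 found for the distinct layout")


def simulate_locus(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> LocusSim:
    """Simulate genotypes, expression, and GWAS summaries for one locus.

    The first gene is the cis target. Under 'shared' the eQTL and GWAS
    causal variants coincide; 'distinct' separates them (r^2 < 0.2);
    'gwas_only' and 'eqtl_only' silence one side; 'null' both.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    panel = simgen.simulate_genotypes(cfg, rng=rng)
    genes = simgen.make_gene_models(cfg)
    gwas_snp, partner = _pick_snp_pair(panel, cfg.causal_layout, rng)

    eqtl_snp: Optional[str] = None
    causal: dict[str, str] = {}
    target_gene: Optional[str] = None
    if cfg.causal_layout in ("shared", "eqtl_only"):
        eqtl_snp = partner
    elif cfg.causal_layout == "distinct":
        eqtl_snp = partner
    if eqtl_snp is not None:
        target_gene = genes[0].gene_id
        causal[target_gene] = eqtl_snp

    exon_expr, truth = simgen.simulate_expression(
        panel, genes, cfg, causal=causal, layout="whole_gene", rng=rng
    )
    gene_expr = simgen.gene_from_exons(exon_expr)

    lam = cfg.gwas_lambda if cfg.causal_layout in ("shared", "distinct", "gwas_only") else 0.0
    gwas = simgen.simulate_gwas(
        panel, gwas_snp if lam > 0 else None, lam, cfg.n_gwas, rng=rng
    )
    return LocusSim(
        cfg=cfg, panel=panel, genes=genes, exon_expr=exon_expr,
        gene_expr=gene_expr, gwas=gwas, gwas_snp=gwas_snp,
        eqtl_snp=eqtl_snp, target_gene=target_gene, truth=truth,
    )


def eqtl_summary_for_feature(
    sim: LocusSim, feature_id: str, expr: Optional[ExpressionMatrix] = None
) -> pd.DataFrame:
    """Marginal summary statistics of every panel SNP against one feature."""
    expr = expr if expr is not None else sim.gene_expr
    y = expr.values[feature_id].to_numpy()
    res = bulk_associate(sim.panel.dosages, y)
    return pd.DataFrame(
        {
            "beta": res["beta"][:, 0],
            "se": res["se"][:, 0],
            "p": res["p"][:, 0],
            "n": res["n"][:, 0],
        },
        index=pd.Index(sim.panel.snp_ids, name="snp"),
    )


def classify_locus(
    sim: LocusSim,
    priors: ColocPriors = ColocPriors(),
    quant_type: str = "gene",
    window: CisWindow = CisWindow(),
) -> list[ClassificationRecord]:
    """Run the full integration for the locus's GWAS SNP at gene level.

    One record per expression unit in the cis window: BH-FDR over the
    scan; for significant units, the best cis-eQTL (smallest marginal P)
    conditions the GWAS SNP's effect through the summary-statistic joint
    model with the panel as LD reference, and colocalisation compares the
    GWAS and eQTL signals over all locus SNPs.
    """
    expr = sim.gene_expr if quant_type == "gene" else sim.exon_expr
    scan = attach_q(cis_scan(sim.gwas_snp, sim.panel, expr, window))
    freqs = dict(zip(sim.panel.snp_ids, sim.panel.alt_freqs()))
    n = sim.panel.n_individuals

    records: list[ClassificationRecord] = []
    for st in scan:
        gene_id = str(expr.features.loc[st.feature_id, "gene_id"]) \
            if "gene_id" in expr.features.columns else st.feature_id
        rec = ClassificationRecord(
            gwas_snp=sim.gwas_snp, feature_id=st.feature_id, gene_id=gene_id,
            quant_type=quant_type, q=float(st.q),
        )
        if st.q is not None and st.q < report.Q_SIG:
            esum = eqtl_summary_for_feature(sim, st.feature_id, expr)
            best = str(esum["p"].idxmin())
            t_stat = AssocStat(
                sim.gwas_snp, st.feature_id,
                float(esum.loc[sim.gwas_snp, "beta"]),
                float(esum.loc[sim.gwas_snp, "se"]), 0.0,
                float(esum.loc[sim.gwas_snp, "p"]), n - 2, n,
            )
            c_stat = AssocStat(
                best, st.feature_id,
                float(esum.loc[best, "beta"]), float(esum.loc[best, "se"]),
                0.0, float(esum.loc[best, "p"]), n - 2, n,
            )
            r = condind.ld_r(sim.panel, sim.gwas_snp, best) \
                if best != sim.gwas_snp else 1.0
            var_y = float(expr.values[st.feature_id].var(ddof=1))
            cond = condind.conditional_assoc(
                t_stat, c_stat, r,
                (freqs[sim.gwas_snp], freqs[best]), n, var_y=var_y,
            )
            cres = coloc.coloc_from_stats(
                sim.gwas.stats["beta"].to_numpy(),
                sim.gwas.stats["se"].to_numpy(),
                esum["beta"].to_numpy(),
                esum["se"].to_numpy(),
                priors,
            )
            rec.p_cond = cond.p_cond
            rec.pp3 = cres.pp3
            rec.pp4 = cres.pp4
        records.append(rec)
    for rec in records:
        if rec.q < report.Q_SIG and rec.p_cond is None:
            raise RuntimeError("significant record missing conditional fields")
        rec.status = report.classify_eqtl(rec)
    return records


def locus_is_candidate_causal(records: list[ClassificationRecord]) -> bool:
    return any(r.status == "candidate_causal" for r in records)
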