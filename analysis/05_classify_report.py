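#!/usr/bin/env python
"""Final classification and summary report.

Merges the per-stage outputs into classification records, applies the
candidate-causal rules (q < 0.05 & P_cond > 0.05 & PP3 < PP4 for
expression; q < 0.05 & RTC > 0.9 for junctions), computes eGene:eQTL
ratios and the relative-significance heatmap matrix, checks TAD
co-membership of multi-eGene eQTLs, and writes a summary JSON.
"""

import argparse
import json
import os

import numpy as np
import pandas as pd

from cceqtl import ClassificationRecord, TadIntervalSet, io, report

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--base", default=BASE)
    args = ap.parse_args()
    out_dir = os.path.join(args.base, "report")
    os.makedirs(out_dir, exist_ok=True)

    records = []
    pcols = {}
    for quant in ("gene", "exon"):
        scan = {s.feature_id: s for s in io.read_summary_tsv(
            os.path.join(args.base, "eqtl", f"summary_{quant}.tsv"))}
        cc = pd.read_csv(
            os.path.join(args.base, "integration",
                         f"conditional_coloc_{quant}.tsv"), sep="\t")
        cc = cc.set_index("feature") if len(cc) else cc
        pcols[quant] = {f: s.p for f, s in scan.items()}
        for f, s in scan.items():
            rec = ClassificationRecord(
                gwas_snp=s.snp_id, feature_id=f,
                gene_id=f.split(":")[0], quant_type=quant, q=s.q,
            )
            if len(cc) and f in cc.index:
                rec.p_cond = float(cc.loc[f, "p_cond"])
                rec.pp3 = float(cc.loc[f, "pp3"])
                rec.pp4 = float(cc.loc[f, "pp4"])
            records.append(rec)
    rtc_tab = pd.read_csv(os.path.join(args.base, "asqtl", "rtc.tsv"), sep="\t")
    asqtl_scan = io.read_summary_tsv(
        os.path.join(args.base, "asqtl", "asqtl_summary.tsv"))
    rtc_scores = dict(zip(rtc_tab.get("feature", []), rtc_tab.get("rtc_score", [])))
    for s in asqtl_scan:
        records.append(ClassificationRecord(
            gwas_snp=s.snp_id, feature_id=s.feature_id,
            gene_id=s.feature_id.split(":")[0], quant_type="junction",
            q=s.q, rtc_score=rtc_scores.get(s.feature_id, 0.0),
        ))
    report.classify_all(records)

    table = pd.DataFrame([{
        "gwas_snp": r.gwas_snp, "feature": r.feature_id, "gene": r.gene_id,
        "quant_type": r.quant_type, "q": r.q, "p_cond": r.p_cond,
        "pp3": r.pp3, "pp4": r.pp4, "rtc_score": r.rtc_score,
        "status": r.status,
    } for r in records])
    table.to_csv(os.path.join(out_dir, "classification.tsv"), sep="\t",
                 index=False)

    summary = {}
    for quant in ("gene", "exon", "junction"):
        n_eqtl, n_egene, ratio = report.egene_eqtl_ratio(records, quant)
        summary[quant] = {
            "n_candidate_causal_eqtls": n_eqtl,
            "n_candidate_causal_egenes": n_egene,
            "egene_eqtl_ratio": None if np.isnan(ratio) else ratio,
        }
        print(f"{quant}: {n_eqtl} candidate-causal eQTL(s), "
              f"{n_egene} eGene(s), ratio {ratio}")

    # cross-quantification heatmap input: GWAS-SNP association P per feature
    hm_in = pd.DataFrame(pcols)
    hm = report.heatmap_matrix(hm_in.dropna(how="all"))
    hm.to_csv(os.path.join(out_dir, "heatmap_matrix.tsv"), sep="\t")

    # TAD co-membership of the (single-locus) eGene set: the whole simulated
    # region sits in one domain, so multi-eGene calls must not cross it
    genes = io.read_gtf(os.path.join(args.base, "sim", "annotation.gtf"))
    span = (min(g.span()[0] for g in genes) - 1,
            max(g.span()[1] for g in genes) + 1)
    tads = TadIntervalSet(intervals=[(genes[0].chrom, span[0] - 1, span[1])],
                          source="synthetic")
    cc_genes = {r.gene_id for r in records if r.status == "candidate_causal"}
    tss = [(g.chrom, g.tss()) for g in genes if g.gene_id in cc_genes]
    summary["multi_egene_same_tad"] = report.tad_comembership(tss, tads) \
        if tss else None

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"wrote classification table ({len(table)} records), heatmap "
          f"matrix ({hm.shape[0]}x{hm.shape[1]}), and summary.json")


if __name__ == "__main__":
    main()
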