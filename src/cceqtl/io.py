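"""Readers and writers for the pipeline's standard formats.

Genotypes travel as VCF (DS dosage tag, read back through cyvcf2) or as a
plain dosage TSV; expression as features x samples TSV with a header row
of sample ids; annotation as GTF (read through gffutils); meta-exons as
0-based half-open BED; association results as a fixed-column summary TSV.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    AssocStat,
    ExpressionMatrix,
    GeneModel,
    GenotypePanel,
    GwasSummary,
    MetaExon,
    SnpRecord,
)

SUMMARY_COLUMNS = ["snp", "feature", "beta", "se", "t", "p", "df", "n", "q"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Plain-text VCF with GT (rounded) and DS (exact dosage) per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        chroms = sorted({s.chrom for s in panel.snps})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids) + "\n"
        )
        freqs = panel.alt_freqs()
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, rec in enumerate(panel.snps):
            d = panel.dosages[:, j]
            cells = [
                f"{gt_codes[int(round(x))]}:{x:g}" for x in d
            ]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref_allele}\t"
                f"{rec.alt_allele}\t.\tPASS\tAF={freqs[j]:.6g};INFO={rec.info:.4g}\t"
                "GT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str) -> GenotypePanel:
    """Load a panel from VCF via cyvcf2, preferring DS over GT dosages."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    from .eqtl_map import hwe_test

    for var in vcf:
        try:
            d = np.asarray(var.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError):
            gts = np.asarray(var.genotypes)[:, :2]
            d = gts.sum(axis=1).astype(float)
        p = float(np.clip(d.mean() / 2.0, 1e-9, 1 - 1e-9))
        ints = np.round(d).astype(int)
        info = var.INFO.get("INFO", 1.0)
        snps.append(
            SnpRecord(
                id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0] if var.ALT else "N",
                maf=min(p, 1 - p),
                info=float(info),
                hwe_p=hwe_test(
                    int((ints == 0).sum()), int((ints == 1).sum()),
                    int((ints == 2).sum()),
                ),
            )
        )
        cols.append(d)
    return GenotypePanel(
        snps=snps, dosages=np.column_stack(cols), sample_ids=sample_ids
    )


def write_dosage_tsv(panel: GenotypePanel, path: str) -> None:
    """Dosage TSV: SNP metadata columns then one column per sample."""
    meta = pd.DataFrame(
        {
            "id": panel.snp_ids,
            "chrom": [s.chrom for s in panel.snps],
            "pos": [s.pos for s in panel.snps],
            "ref": [s.ref_allele for s in panel.snps],
            "alt": [s.alt_allele for s in panel.snps],
            "maf": [s.maf for s in panel.snps],
            "info": [s.info for s in panel.snps],
            "hwe_p": [s.hwe_p for s in panel.snps],
        }
    )
    dos = pd.DataFrame(
        panel.dosages.T, columns=panel.sample_ids, index=meta.index
    )
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "ref", "alt", "maf", "info", "hwe_p"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    snps = [
        SnpRecord(
            id=str(r["id"]), chrom=str(r["chrom"]), pos=int(r["pos"]),
            ref_allele=str(r["ref"]), alt_allele=str(r["alt"]),
            maf=float(r["maf"]), info=float(r["info"]), hwe_p=float(r["hwe_p"]),
        )
        for _, r in df.iterrows()
    ]
    return GenotypePanel(
        snps=snps,
        dosages=df[sample_ids].to_numpy(dtype=float).T,
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path: str) -> None:
    """Features x samples TSV with feature coordinates, header = sample ids."""
    out = expr.features.copy()
    vals = expr.values.T
    vals.columns.name = None
    table = pd.concat([out, vals], axis=1)
    table.index.name = "feature_id"
    table.to_csv(path, sep="\t")


def read_expression_tsv(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    meta_cols = [c for c in ("gene_id", "chrom", "start", "end") if c in df.columns]
    features = df[meta_cols]
    values = df.drop(columns=meta_cols).T.astype(float)
    values.index.name = None
    return ExpressionMatrix(values=values, features=features)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def write_gtf(models: Sequence[GeneModel], path: str, source: str = "cceqtl") -> None:
    with open(path, "w") as fh:
        for g in models:
            s, e = g.span()
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx_id, exons in g.transcripts:
                ts, te = min(x for x, _ in exons), max(y for _, y in exons)
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}";'
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{ts}\t{te}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s_, e_ in exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s_}\t{e_}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def read_gtf(path: str) -> list[GeneModel]:
    """GENCODE-style GTF to GeneModels via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for tx in db.children(gene, featuretype="transcript", order_by="start"):
            exons = [
                (ex.start, ex.end)
                for ex in db.children(tx, featuretype="exon", order_by="start")
            ]
            transcripts.append((tx.attributes["transcript_id"][0], exons))
        models.append(
            GeneModel(
                gene_id=gene.attributes["gene_id"][0],
                chrom=gene.seqid,
                strand=gene.strand,
                transcripts=transcripts,
            )
        )
    return models


def write_meta_exon_bed(metas: Sequence[MetaExon], path: str) -> None:
    """Meta-exons as 0-based half-open BED (start-1, end)."""
    with open(path, "w") as fh:
        for me in metas:
            s, e = me.interval
            fh.write(
                f"chr\t{s - 1}\t{e}\t{me.feature_id}\t0\t+\t"
                + ",".join(me.member_transcripts) + "\n"
            )


def read_bed_intervals(path: str) -> list[tuple[str, int, int]]:
    """(chrom, start, end) tuples, 0-based half-open, from a BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def write_summary_tsv(stats_list: Sequence[AssocStat], path: str) -> None:
    rows = [
        {
            "snp": s.snp_id, "feature": s.feature_id, "beta": s.beta,
            "se": s.se, "t": s.t, "p": s.p, "df": s.df, "n": s.n,
            "q": s.q if s.q is not None else np.nan,
        }
        for s in stats_list
    ]
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_summary_tsv(path: str) -> list[AssocStat]:
    df = pd.read_csv(path, sep="\t")
    return [
        AssocStat(
            snp_id=str(r["snp"]), feature_id=str(r["feature"]),
            beta=float(r["beta"]), se=float(r["se"]), t=float(r["t"]),
            p=float(r["p"]), df=int(r["df"]), n=int(r["n"]),
            q=None if pd.isna(r["q"]) else float(r["q"]),
        )
        for _, r in df.iterrows()
    ]


def write_gwas_tsv(gwas: GwasSummary, path: str) -> None:
    out = gwas.stats.copy()
    out.insert(0, "trait", gwas.trait)
    out.to_csv(path, sep="\t")


def read_gwas_tsv(path: str) -> GwasSummary:
    df = pd.read_csv(path, sep="\t", index_col="snp")
    trait = str(df["trait"].iloc[0]) if "trait" in df.columns else "trait"
    return GwasSummary(stats=df[["beta", "se", "p", "n"]], trait=trait)
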