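"""Synthetic genotype, annotation, expression, and GWAS generators.

The generators reproduce the statistical structure the pipeline assumes:
LD-structured dosages (first-order Markov haplotypes), meta-exon expression
with per-exon or whole-gene causal eQTLs, GWAS summary statistics whose
z-scores follow the usual multivariate-normal-through-LD model, and
splice-junction link counts with a logistic usage shift. Everything is
deterministic given a seed; truth tables are returned for recovery tests.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import eqtl_map
from .types import (
    ExpressionMatrix,
    GeneModel,
    GenotypePanel,
    GwasSummary,
    LinkCountTable,
    MetaExon,
    SimulationConfig,
    SnpRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# annotation flattening
# ---------------------------------------------------------------------------

def flatten_annotation(
    models: Sequence[GeneModel], split_at_breakpoints: bool = True
) -> list[MetaExon]:
    """Collapse each gene's transcripts into non-redundant exonic units.

    With ``split_at_breakpoints`` (the exon-group convention) the exonic
    union is cut at every distinct exon start/end so transcript membership
    is exact per unit; without it, overlapping exons are merged into plain
    union-exons (the convention used for union-exon gene sums). Units are
    indexed 5'->3' in genomic coordinate order.
    """
    out: list[MetaExon] = []
    for gene in models:
        if not gene.transcripts:
            raise ValueError(f"gene {gene.gene_id} has no transcripts")
        exons = [
            (s, e, tx_id) for tx_id, exs in gene.transcripts for s, e in exs
        ]
        if not exons:
            raise ValueError(f"gene {gene.gene_id} has no exons")
        if split_at_breakpoints:
            units = _split_units(exons)
        else:
            units = _union_units(exons)
        for idx, (start, end, members) in enumerate(units, start=1):
            out.append(
                MetaExon(
                    gene_id=gene.gene_id,
                    index=idx,
                    interval=(start, end),
                    member_transcripts=sorted(members),
                )
            )
    return out


def _split_units(exons) -> list[tuple[int, int, set[str]]]:
    """Maximal disjoint segments between consecutive exon-boundary
    breakpoints, keeping only segments covered by at least one exon."""
    cuts = sorted({s for s, _, _ in exons} | {e + 1 for _, e, _ in exons})
    units = []
    for lo, hi in zip(cuts, cuts[1:]):
        seg = (lo, hi - 1)
        members = {tx for s, e, tx in exons if s <= seg[0] and seg[1] <= e}
        if members:
            units.append((seg[0], seg[1], members))
    return units


def _union_units(exons) -> list[tuple[int, int, set[str]]]:
    """Plain interval union of all exons (no breakpoint splitting)."""
    merged: list[list[int]] = []
    for s, e, _ in sorted(exons):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        members = {tx for es, ee, tx in exons if es <= e and ee >= s}
        out.append((s, e, members))
    return out


def gene_from_exons(exon_matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Union-exon gene quantification: per-individual sum of a gene's
    meta-exon values."""
    feats = exon_matrix.features
    if feats["gene_id"].isna().any():
        bad = feats.index[feats["gene_id"].isna()][0]
        raise ValueError(f"exon {bad} has no gene_id")
    gene_ids = feats["gene_id"].unique()
    values = pd.DataFrame(index=exon_matrix.values.index)
    rows = []
    for g in gene_ids:
        cols = feats.index[feats["gene_id"] == g]
        values[g] = exon_matrix.values[cols].sum(axis=1)
        rows.append(
            {
                "gene_id": g,
                "chrom": feats.loc[cols[0], "chrom"],
                "start": int(feats.loc[cols, "start"].min()),
                "end": int(feats.loc[cols, "end"].max()),
            }
        )
    features = pd.DataFrame(rows, index=pd.Index(gene_ids, name="feature_id"))
    return ExpressionMatrix(values=values, features=features)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GenotypePanel:
    """2n haplotypes from a first-order Markov chain over SNPs.

    Adjacent SNPs share a target haplotype correlation of ``cfg.ld_decay``
    (hence the same dosage correlation); allele frequencies are drawn from
    ``cfg.maf_range``. Dosages are the sums of two independent haplotypes,
    so genotype marginals are exactly binomial(2, p).
    """
    if cfg.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    m, n = cfg.n_snps, cfg.n_individuals
    rho = cfg.ld_decay

    # copy-with-innovation chain: each haplotype copies its previous allele
    # with probability rho, otherwise redraws from the SNP's innovation
    # frequency. Marginals follow p_j = rho p_{j-1} + (1-rho) p*_j exactly
    # (so they stay inside maf_range) and adjacent-pair correlation is
    # rho * sd_{j-1}/sd_j ~= rho, since high-LD neighbours end up with
    # similar frequencies -- as they do on real haplotypes.
    p_innov = rng.uniform(*cfg.maf_range, size=m)
    freqs = np.empty(m)
    freqs[0] = p_innov[0]
    for j in range(1, m):
        freqs[j] = rho * freqs[j - 1] + (1 - rho) * p_innov[j]

    H = np.empty((2 * n, m), dtype=np.int8)
    H[:, 0] = rng.random(2 * n) < freqs[0]
    for j in range(1, m):
        copy = rng.random(2 * n) < rho
        fresh = rng.random(2 * n) < p_innov[j]
        H[:, j] = np.where(copy, H[:, j - 1], fresh)

    dosages = (H[:n] + H[n:]).astype(float)

    snps = []
    for j in range(m):
        d = dosages[:, j]
        hom_alt = int((d == 2).sum())
        het = int((d == 1).sum())
        hom_ref = n - hom_alt - het
        snps.append(
            SnpRecord(
                id=f"rs{j + 1:05d}",
                chrom=cfg.chrom,
                pos=cfg.region_start + j * cfg.snp_spacing,
                ref_allele="A",
                alt_allele="G",
                maf=float(min(freqs[j], 1 - freqs[j])),
                info=float(rng.uniform(0.9, 1.0)),
                hwe_p=eqtl_map.hwe_test(hom_ref, het, hom_alt),
            )
        )
    sample_ids = [f"ind{i + 1:04d}" for i in range(n)]
    return GenotypePanel(snps=snps, dosages=dosages, sample_ids=sample_ids)


def add_tag_snp(
    panel: GenotypePanel,
    target: str,
    flip_prob: float = 0.02,
    rng: Optional[np.random.Generator] = None,
    snp_id: str = "rs_tag",
) -> GenotypePanel:
    """Append a tag SNP in tight LD with ``target``.

    The tag's haplotypes are the target's dosage halves with alleles
    flipped independently at ``flip_prob``, giving r^2 around
    (1 - 2*flip_prob)^... ~ 0.9+ for small flip probabilities — a
    convenience for shared-signal simulations that need a guaranteed
    high-LD proxy.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    j = panel.index_of(target)
    d = panel.dosages[:, j]
    # split dosage into two pseudo-haplotypes and flip each independently
    h1 = (d >= 1).astype(int)
    h2 = (d == 2).astype(int)
    flip1 = rng.random(d.size) < flip_prob
    flip2 = rng.random(d.size) < flip_prob
    tag = np.where(flip1, 1 - h1, h1) + np.where(flip2, 1 - h2, h2)
    rec = panel.snps[j]
    p = float(np.clip(tag.mean() / 2.0, 1e-6, 1 - 1e-6))
    hom_alt = int((tag == 2).sum())
    het = int((tag == 1).sum())
    new = SnpRecord(
        id=snp_id, chrom=rec.chrom, pos=rec.pos + 1,
        ref_allele=rec.ref_allele, alt_allele=rec.alt_allele,
        maf=min(p, 1 - p),
        info=rec.info,
        hwe_p=eqtl_map.hwe_test(d.size - hom_alt - het, het, hom_alt),
    )
    return GenotypePanel(
        snps=panel.snps + [new],
        dosages=np.column_stack([panel.dosages, tag.astype(float)]),
        sample_ids=list(panel.sample_ids),
    )


# ---------------------------------------------------------------------------
# gene models and expression
# ---------------------------------------------------------------------------

def make_gene_models(cfg: SimulationConfig, prefix: str = "G") -> list[GeneModel]:
    """Evenly spaced two-transcript genes across the simulated region.

    Each gene gets ``exons_per_gene`` exons of 200 bp spaced 1 kb apart;
    transcript 'a' contains all exons, transcript 'b' skips the second
    exon, so flattening yields units with distinct transcript membership
    and junction simulation has an alternative acceptor.
    """
    span = (cfg.n_snps - 1) * cfg.snp_spacing
    models = []
    for g in range(cfg.n_genes):
        gstart = cfg.region_start + int((g + 0.5) * span / max(cfg.n_genes, 1))
        exons = [
            (gstart + k * 1000, gstart + k * 1000 + 199)
            for k in range(cfg.exons_per_gene)
        ]
        tx_a = (f"{prefix}{g + 1}.a", list(exons))
        tx_b = (f"{prefix}{g + 1}.b", [e for k, e in enumerate(exons) if k != 1])
        models.append(
            GeneModel(
                gene_id=f"{prefix}{g + 1}",
                chrom=cfg.chrom,
                strand="+" if g % 2 == 0 else "-",
                transcripts=[tx_a, tx_b],
            )
        )
    return models


def simulate_expression(
    panel: GenotypePanel,
    genes: Sequence[GeneModel],
    cfg: SimulationConfig,
    causal: Optional[dict[str, str]] = None,
    layout: str = "whole_gene",
    target_exons: Optional[Sequence[int]] = None,
    covariate: Optional[np.ndarray] = None,
    covariate_beta: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Meta-exon expression on a continuous post-normalization scale.

    ``causal`` maps gene_id -> causal SNP id; affected meta-exons get
    value = mu + beta * dosage + covariate_beta * covariate + N(0, 1) with
    beta scaled so the genotype explains ``cfg.effect_size_r2`` of the
    variance. ``layout`` 'whole_gene' perturbs every meta-exon of the gene;
    'exon_specific' only those in ``target_exons`` (1-based indices).
    Returns the matrix and a truth table (feature, causal snp, beta, r2).
    """
    if cfg.effect_size_r2 >= 1.0:
        raise ValueError("effect_size_r2 must be < 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    causal = causal or {}
    metas = flatten_annotation(genes)
    n = panel.n_individuals

    cols, rows, truth = {}, [], []
    for me in metas:
        mu = rng.normal(0.0, 0.5)
        y = mu + rng.normal(0.0, 1.0, size=n)
        if covariate is not None and covariate_beta != 0.0:
            y = y + covariate_beta * np.asarray(covariate, dtype=float)
        snp = causal.get(me.gene_id)
        hit = snp is not None and (
            layout == "whole_gene"
            or (layout == "exon_specific" and me.index in set(target_exons or []))
        )
        if hit:
            g = panel.dosage(snp)
            sd_g = g.std()
            if sd_g == 0:
                raise ValueError(f"causal SNP {snp} is monomorphic")
            r2 = cfg.effect_size_r2
            beta = np.sqrt(r2 / (1.0 - r2)) / sd_g
            y = y + beta * g
            truth.append(
                {"feature_id": me.feature_id, "causal_snp": snp,
                 "beta": float(beta), "r2": r2}
            )
        cols[me.feature_id] = y
        rows.append(
            {"feature_id": me.feature_id, "gene_id": me.gene_id,
             "chrom": next(m.chrom for m in genes if m.gene_id == me.gene_id),
             "start": me.interval[0], "end": me.interval[1]}
        )
    values = pd.DataFrame(cols, index=panel.sample_ids)
    features = pd.DataFrame(rows).set_index("feature_id")
    truth_df = pd.DataFrame(truth, columns=["feature_id", "causal_snp", "beta", "r2"])
    return ExpressionMatrix(values=values, features=features), truth_df


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(
    panel: GenotypePanel,
    causal_snp: Optional[str],
    lambda_: float,
    n_gwas: int,
    rng: Optional[np.random.Generator] = None,
    trait: str = "disease",
    ridge_eps: float = 1e-6,
) -> GwasSummary:
    """GWAS summary statistics under the standard LD-propagation model.

    z ~ MVN(R @ lam * sqrt(n_gwas), R) with R the dosage correlation matrix
    of the panel and lam the standardized effect vector (lambda_ at the
    causal SNP, 0 elsewhere); se_j = 1/sqrt(2 p_j (1-p_j) n_gwas) and
    beta = z * se. A singular R is ridge-regularized with ``ridge_eps``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    D = panel.dosages
    R = np.corrcoef(D, rowvar=False)
    lam = np.zeros(panel.n_snps)
    if causal_snp is not None:
        lam[panel.index_of(causal_snp)] = lambda_
    mean = R @ lam * np.sqrt(n_gwas)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        logger.warning("singular LD matrix; ridge-regularizing with eps=%g", ridge_eps)
        L = np.linalg.cholesky(R + ridge_eps * np.eye(panel.n_snps))
    z = mean + L @ rng.standard_normal(panel.n_snps)
    freqs = panel.alt_freqs()
    se = 1.0 / np.sqrt(2.0 * freqs * (1.0 - freqs) * n_gwas)
    from scipy import stats as _st

    beta = z * se
    p = 2.0 * _st.norm.sf(np.abs(z))
    stats = pd.DataFrame(
        {"beta": beta, "se": se, "p": np.clip(p, np.nextafter(0, 1), 1.0),
         "n": n_gwas},
        index=pd.Index(panel.snp_ids, name="snp"),
    )
    return GwasSummary(stats=stats, trait=trait)


# ---------------------------------------------------------------------------
# splice junctions
# ---------------------------------------------------------------------------

def _alt_splice_event(gene: GeneModel, metas: Sequence[MetaExon]):
    """Find a donor unit whose transcripts continue to distinct acceptors.

    With the two-transcript gene models above, the first meta-exon is the
    shared donor; transcript 'a' proceeds to the skipped exon, 'b' to the
    next shared one.
    """
    mine = [m for m in metas if m.gene_id == gene.gene_id]
    if len(gene.transcripts) < 2:
        raise ValueError(f"gene {gene.gene_id} has a single transcript")
    shared = [m for m in mine if len(m.member_transcripts) == len(gene.transcripts)]
    partial = [m for m in mine if len(m.member_transcripts) < len(gene.transcripts)]
    if not shared or not partial:
        raise ValueError(
            f"gene {gene.gene_id} has no alternative acceptor structure"
        )
    donor = shared[0]
    acc_alt = partial[0]  # acceptor unique to a transcript subset
    after = [m for m in shared if m.index > acc_alt.index]
    if not after:
        raise ValueError(f"gene {gene.gene_id} lacks a downstream shared exon")
    acc_skip = after[0]
    return donor, acc_alt, acc_skip


def simulate_junctions(
    panel: GenotypePanel,
    gene: GeneModel,
    asqtl_snp: Optional[str],
    usage_shift: float,
    depth: float,
    rng: Optional[np.random.Generator] = None,
    pi0: float = 0.0,
    confounder: Optional[np.ndarray] = None,
    confounder_shift: float = 0.0,
) -> tuple[LinkCountTable, LinkCountTable, pd.DataFrame]:
    """Link counts for an alternative-acceptor event in both read directions.

    Per individual, the inclusion proportion of the alternative junction is
    pi = sigmoid(pi0 + usage_shift * dosage + confounder_shift * confounder);
    the optional confounder emulates a shared technical component (library
    batch) acting on usage across genes, which the PC normalization is
    meant to absorb. Counts are multinomial over the donor's outgoing
    junctions with a Poisson(depth) total. The reverse-direction table is
    an independent realization of the same donor-anchored proportions
    (opposite read orientation of the same junction family). Returns
    (forward, reverse, truth table).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    metas = flatten_annotation([gene])
    donor, acc_alt, acc_skip = _alt_splice_event(gene, metas)
    n = panel.n_individuals
    logit = np.full(n, pi0, dtype=float)
    if asqtl_snp is not None and usage_shift != 0.0:
        logit = logit + usage_shift * panel.dosage(asqtl_snp)
    if confounder is not None and confounder_shift != 0.0:
        logit = logit + confounder_shift * np.asarray(confounder, dtype=float)
    pi = expit(logit)

    def _draw(direction: str) -> LinkCountTable:
        total = rng.poisson(depth, size=n)
        alt = rng.binomial(total, pi)
        skip = total - alt
        link_ids = [
            f"{gene.gene_id}:me{donor.index}:me{acc_alt.index}:{direction}",
            f"{gene.gene_id}:me{donor.index}:me{acc_skip.index}:{direction}",
        ]
        links = pd.DataFrame(
            {
                "gene_id": gene.gene_id,
                "donor": [donor.feature_id] * 2,
                "acceptor": [acc_alt.feature_id, acc_skip.feature_id],
                "direction": direction,
                "anchor": [donor.feature_id] * 2,
                "chrom": gene.chrom,
                "pos": donor.interval[0],
            },
            index=pd.Index(link_ids, name="link_id"),
        )
        counts = pd.DataFrame(
            np.column_stack([alt, skip]), index=panel.sample_ids, columns=links.index
        )
        return LinkCountTable(links=links, counts=counts)

    fwd = _draw("5to3")
    rev = _draw("3to5")
    truth = pd.DataFrame(
        [{
            "gene_id": gene.gene_id,
            "alt_link": fwd.links.index[0],
            "asqtl_snp": asqtl_snp,
            "usage_shift": usage_shift,
        }]
    )
    return fwd, rev, truth
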