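"""Altrans-style splice-junction quantification and asQTL association.

Link counts (split/paired reads joining two exon boundaries) become link
fractions — each link's share of all links its anchor exon makes in that
individual — which are merged across read directions, rank-inverse-normal
transformed per link, residualized on sample-space principal components,
and tested against dosage with the ordinary linear model.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl_map import attach_q, bulk_associate
from .types import AssocStat, GenotypePanel, LinkCountTable, LinkFractionTable

logger = logging.getLogger(__name__)


def _anchor_groups(links: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    return links.groupby(["gene_id", "anchor", "direction"], sort=False)


def concat_link_tables(tables: list[LinkCountTable]) -> LinkCountTable:
    """Stack link tables of different genes over the same individuals."""
    if not tables:
        raise ValueError("no tables to concatenate")
    links = pd.concat([t.links for t in tables])
    counts = pd.concat([t.counts for t in tables], axis=1)
    return LinkCountTable(links=links, counts=counts)


def filter_boundaries(
    table: LinkCountTable, max_zero_frac: float = 0.10
) -> LinkCountTable:
    """Drop every link of an anchor exon-boundary whose total outgoing
    count is zero in more than ``max_zero_frac`` of individuals (strict)."""
    n = table.counts.shape[0]
    keep: list[str] = []
    for _, grp in _anchor_groups(table.links):
        totals = table.counts[grp.index].sum(axis=1)
        if (totals == 0).sum() / n > max_zero_frac:
            continue
        keep.extend(grp.index)
    if not keep:
        raise ValueError("all exon-boundaries removed by the zero-link filter")
    keep = [l for l in table.links.index if l in set(keep)]  # preserve order
    return LinkCountTable(
        links=table.links.loc[keep], counts=table.counts[keep].copy()
    )


def link_fractions(table: LinkCountTable) -> LinkFractionTable:
    """count / (anchor's total outgoing count); NaN where the total is 0."""
    fractions = pd.DataFrame(
        index=table.counts.index, columns=table.links.index, dtype=float
    )
    for _, grp in _anchor_groups(table.links):
        sub = table.counts[grp.index]
        totals = sub.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = sub.div(totals.where(totals > 0), axis=0)
        fractions[grp.index] = frac
    return LinkFractionTable(links=table.links.copy(), fractions=fractions)


def merge_directions(
    fwd: LinkFractionTable, rev: LinkFractionTable
) -> LinkFractionTable:
    """Average the 5'-3' and 3'-5' fraction estimates of each junction.

    Links are matched on (gene, donor, acceptor); where only one direction
    is defined for an individual, that value is kept. A provenance column
    records which directions contributed.
    """
    key = ["gene_id", "donor", "acceptor"]
    fk = fwd.links.reset_index().set_index(key)
    rk = rev.links.reset_index().set_index(key)
    common = fk.index.intersection(rk.index)
    if len(common) == 0:
        raise ValueError("forward and reverse tables share no links")

    merged_ids, rows, cols = [], [], {}
    for tup in common:
        fid = fk.loc[tup, "link_id"]
        rid = rk.loc[tup, "link_id"]
        f = fwd.fractions[fid]
        r = rev.fractions[rid]
        both = f.notna() & r.notna()
        merged = f.where(r.isna(), other=(f + r) / 2.0)
        merged = merged.where(f.notna(), other=r)
        gene, donor, acceptor = tup
        mid = f"{gene}:{donor.split(':')[-1]}:{acceptor.split(':')[-1]}:merged"
        merged_ids.append(mid)
        cols[mid] = merged
        row = fk.loc[tup].drop(labels=["link_id"]).to_dict()
        row.update(
            gene_id=gene, donor=donor, acceptor=acceptor, direction="merged",
            n_both=int(both.sum()),
        )
        rows.append(row)
    links = pd.DataFrame(rows, index=pd.Index(merged_ids, name="link_id"))
    fractions = pd.DataFrame(cols, index=fwd.fractions.index)
    return LinkFractionTable(links=links, fractions=fractions)


def inverse_normal_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Rank-based inverse-normal transform per column; NaNs pass through.

    Ranks are averaged over ties and mapped through the standard normal
    quantile at (rank - 0.5) / n_non_missing.
    """
    out = values.copy()
    for col in out.columns:
        v = out[col]
        ok = v.notna()
        n = int(ok.sum())
        if n == 0:
            continue
        ranks = v[ok].rank(method="average")
        out.loc[ok, col] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def pc_normalize(matrix: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """Residualize each column on the top sample-space principal components.

    Columns are centred first; ``n_pcs = 0`` returns the centred matrix.
    The PCs are the left singular vectors of the centred matrix, so they
    absorb shared technical structure (batch, depth) across links.
    Missing entries are mean-filled for the decomposition only and set
    back to NaN afterwards.
    """
    if n_pcs >= matrix.shape[0]:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    X = matrix.to_numpy(dtype=float)
    nan_mask = np.isnan(X)
    col_means = np.nanmean(np.where(nan_mask, np.nan, X), axis=0)
    Xc = np.where(nan_mask, col_means, X) - col_means
    if n_pcs == 0:
        out = Xc.copy()
    else:
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
        if n_pcs >= rank:
            raise ValueError(f"n_pcs={n_pcs} >= matrix rank {rank}")
        Uk = U[:, :n_pcs]
        out = Xc - Uk @ (Uk.T @ Xc)
    out[nan_mask] = np.nan
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_fractions(
    fractions: LinkFractionTable, n_pcs: int = 10
) -> LinkFractionTable:
    """Full normalization: inverse-normal transform per link, then PC
    residualization across the sample space."""
    int_frac = inverse_normal_transform(fractions.fractions)
    normed = pc_normalize(int_frac, n_pcs=n_pcs)
    return LinkFractionTable(links=fractions.links.copy(), fractions=normed)


def asqtl_scan(
    gwas_snp: str,
    panel: GenotypePanel,
    fractions: LinkFractionTable,
    half_width: int = 1_000_000,
    covariates: Optional[np.ndarray] = None,
) -> list[AssocStat]:
    """Associate one SNP with every normalized link fraction in cis.

    Missing fractions (anchor total 0) are excluded pairwise, with the
    per-link n recorded; q-values are BH-adjusted across all tests of the
    scan. The intended covariates are genotype PCs plus any binary batch
    indicators (e.g. imputation status).
    """
    rec = panel.record(gwas_snp)
    lo, hi = rec.pos - half_width, rec.pos + half_width
    links = fractions.links
    sel = (links["chrom"] == rec.chrom) & (links["pos"] >= lo) & (links["pos"] <= hi)
    ids = list(links.index[sel])
    if not ids:
        logger.warning("no links within the window of %s", gwas_snp)
        return []
    g = panel.dosage(gwas_snp)
    Y = fractions.fractions[ids].to_numpy(dtype=float)
    res = bulk_associate(g, Y, covariates)
    out = [
        AssocStat(
            gwas_snp, lid,
            float(res["beta"][0, j]), float(res["se"][0, j]),
            float(res["t"][0, j]), float(res["p"][0, j]),
            int(res["df"][0, j]), int(res["n"][0, j]),
        )
        for j, lid in enumerate(ids)
    ]
    return attach_q(out)
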