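"""Shared domain containers for the GWAS-eQTL integration pipeline.

Coordinates are 1-based inclusive throughout (GTF convention); BED I/O
converts to/from 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

Strand = Literal["+", "-"]


@dataclass
class SnpRecord:
    """One biallelic variant with the metadata the QC filters consume."""

    id: str
    chrom: str
    pos: int  # 1-based bp
    ref_allele: str
    alt_allele: str
    maf: float  # minor-allele frequency, in (0, 0.5] after folding
    info: float = 1.0  # imputation quality in [0, 1]
    hwe_p: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.id}: MAF {self.maf} outside (0, 0.5]")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position {self.pos} < 1")


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    ``dosages[i, j]`` is the alt-allele dosage of individual *i* at SNP *j*,
    in [0, 2]; SNP order in ``snps`` matches the columns.
    """

    snps: list[SnpRecord]
    dosages: np.ndarray  # (n_individuals, n_snps), float
    sample_ids: list[str]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("dosage matrix shape does not match snps/samples")
        self._index = {sid: j for j, sid in enumerate(ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(snp_id)]

    def record(self, snp_id: str) -> SnpRecord:
        return self.snps[self.index_of(snp_id)]

    def alt_freqs(self) -> np.ndarray:
        """Empirical alt-allele frequency per SNP (column mean / 2)."""
        return self.dosages.mean(axis=0) / 2.0

    def subset(self, snp_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.index_of(s) for s in snp_ids]
        return GenotypePanel(
            snps=[self.snps[j] for j in idx],
            dosages=self.dosages[:, idx].copy(),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class GeneModel:
    """A gene with its transcripts as ordered exon interval lists."""

    gene_id: str
    chrom: str
    strand: Strand
    # (transcript_id, [(start, end), ...]) with 1-based inclusive exons
    transcripts: list[tuple[str, list[tuple[int, int]]]]

    def __post_init__(self) -> None:
        for tx_id, exons in self.transcripts:
            ordered = sorted(exons)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"{self.gene_id}/{tx_id}: overlapping exons "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )

    @property
    def transcript_ids(self) -> list[str]:
        return [t for t, _ in self.transcripts]

    def tss(self) -> int:
        """Transcription start site: min start on '+', max end on '-'."""
        starts = [s for _, exons in self.transcripts for s, _ in exons]
        ends = [e for _, exons in self.transcripts for _, e in exons]
        return min(starts) if self.strand == "+" else max(ends)

    def span(self) -> tuple[int, int]:
        starts = [s for _, exons in self.transcripts for s, _ in exons]
        ends = [e for _, exons in self.transcripts for _, e in exons]
        return min(starts), max(ends)


@dataclass
class MetaExon:
    """A non-redundant exonic unit of one gene (1-based inclusive)."""

    gene_id: str
    index: int  # 1-based ordinal, 5'->3' in genomic coordinates
    interval: tuple[int, int]
    member_transcripts: list[str]

    @property
    def feature_id(self) -> str:
        return f"{self.gene_id}:me{self.index}"

    def __len__(self) -> int:
        return self.interval[1] - self.interval[0] + 1


CausalLayout = Literal["shared", "distinct", "gwas_only", "eqtl_only", "null"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; a seed is mandatory (no implicit RNG)."""

    seed: int
    n_individuals: int = 800
    n_snps: int = 200
    ld_decay: float = 0.9  # adjacent-pair haplotype correlation, [0, 1)
    maf_range: tuple[float, float] = (0.1, 0.5)
    causal_layout: CausalLayout = "shared"
    effect_size_r2: float = 0.05  # variance fraction per causal effect
    n_genes: int = 3
    exons_per_gene: int = 5
    junction_depth: float = 50.0  # mean link count per individual
    n_gwas: int = 5000
    gwas_lambda: float = 0.1  # standardized GWAS effect (z ~ lambda*sqrt(n))
    chrom: str = "chr1"
    region_start: int = 1_000_000
    snp_spacing: int = 5_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.effect_size_r2 < 1.0):
            raise ValueError("effect_size_r2 must be in [0, 1)")


@dataclass
class GwasSummary:
    """Per-SNP GWAS summary statistics for one trait.

    ``stats`` is indexed by SNP id with columns beta, se, p, n.
    """

    stats: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = {"beta", "se", "p", "n"} - set(self.stats.columns)
        if missing:
            raise ValueError(f"GwasSummary missing columns: {sorted(missing)}")


@dataclass
class ExpressionMatrix:
    """Individuals x features expression with feature coordinates.

    ``values``: DataFrame indexed by sample id, one column per feature.
    ``features``: DataFrame indexed by feature id with columns
    gene_id, chrom, start, end (1-based inclusive).
    """

    values: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.features.index):
            raise ValueError("feature table does not match value columns")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class AssocStat:
    """One SNP x feature linear-model association."""

    snp_id: str
    feature_id: str
    beta: float
    se: float
    t: float
    p: float
    df: int
    n: int
    q: Optional[float] = None  # BH-adjusted, filled after the scan


@dataclass
class CisWindow:
    """A symmetric cis window; anchor names what the window is centred on."""

    anchor: Literal["gwas_snp", "feature"] = "gwas_snp"
    half_width: int = 1_000_000

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


@dataclass
class ConditionalResult:
    """Conditional association of a target SNP given the best cis-eQTL."""

    gwas_snp: str
    best_eqtl: str
    feature_id: str
    beta_cond: float
    se_cond: float
    p_cond: float
    mode: Literal["summary", "exact"]
    collinear: bool = False


@dataclass
class ColocPriors:
    """Per-SNP priors and ABF effect-variance for colocalisation."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-6
    w1: float = 0.15**2  # prior effect variance, trait 1
    w2: float = 0.15**2

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2) < 1.0):
            raise ValueError("require 0 < p12 <= min(p1, p2) < 1")


@dataclass
class ColocResult:
    """Per-locus log-ABFs and posterior probabilities of H0..H4."""

    labf1: np.ndarray
    labf2: np.ndarray
    pp: np.ndarray  # (PP0, PP1, PP2, PP3, PP4)
    n_snps: int

    @property
    def pp3(self) -> float:
        return float(self.pp[3])

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


@dataclass
class RtcResult:
    """Regulatory Trait Concordance of a GWAS SNP within an interval."""

    gwas_snp: str
    feature_id: str
    interval: tuple[str, int, int]
    n_snps: int
    rank: int  # 1-based; 1 = most concordant
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.n_snps):
            raise ValueError("rank out of range")


@dataclass
class LinkCountTable:
    """Splice-junction link counts.

    ``links``: DataFrame indexed by link id with columns gene_id, donor,
    acceptor, direction ('5to3'|'3to5'), anchor (exon whose outgoing total
    normalizes the link), chrom, pos (anchor coordinate for cis windows).
    ``counts``: DataFrame indexed by sample id, one column per link id.
    """

    links: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.links.index):
            raise ValueError("count columns do not match link table")
        if (self.links["donor"] == self.links["acceptor"]).any():
            raise ValueError("link with donor == acceptor")


@dataclass
class LinkFractionTable:
    """Link fractions on the same link index; NaN where the anchor total is 0."""

    links: pd.DataFrame
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.fractions.columns.equals(self.links.index):
            raise ValueError("fraction columns do not match link table")


Status = Literal["candidate_causal", "significant_not_causal", "not_significant"]


@dataclass
class ClassificationRecord:
    """Per GWAS SNP x feature verdicts feeding the final classification."""

    gwas_snp: str
    feature_id: str
    gene_id: str
    quant_type: Literal["microarray", "gene", "exon", "junction"]
    q: float
    p_cond: Optional[float] = None
    pp3: Optional[float] = None
    pp4: Optional[float] = None
    rtc_score: Optional[float] = None
    status: Optional[Status] = None


@dataclass
class TadIntervalSet:
    """Topologically associated domains, 0-based half-open as read from BED."""

    intervals: list[tuple[str, int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in sorted(self.intervals):
            prev = by_chrom.setdefault(chrom, [])
            if prev and start < prev[-1][1]:
                raise ValueError(f"overlapping TADs on {chrom}")
            prev.append((start, end))
        self.intervals = [
            (c, s, e) for c in sorted(by_chrom) for s, e in by_chrom[c]
        ]

    def containing(self, chrom: str, pos: int) -> Optional[tuple[str, int, int]]:
        """Interval containing a 1-based position, or None."""
        for c, s, e in self.intervals:
            if c == chrom and s <= pos - 1 < e:
                return (c, s, e)
        return None
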