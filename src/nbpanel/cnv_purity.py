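"""Exon-coverage copy-number calling with tumor-purity adjustment.

Model: a tumor with purity ``p`` and per-gene copy number ``CN`` yields a
reference-normalized coverage ratio

    r = (p * CN + 2 * (1 - p)) / 2

and, at a heterozygous site whose minor allele is present in ``nB`` tumor
copies, an expected B-allele fraction

    BAF = (p * nB + (1 - p)) / (p * CN + 2 * (1 - p)).

Purity is recovered by a grid search that scores candidate purities by how
close the implied copy numbers are to integers and how well integer allele
splits explain the observed BAFs. Copy number is then inverted per gene and
classified with strict thresholds (loss: CN < 1, gain: CN > 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    """Per-exon mean sequencing depth for one sample."""

    sample_id: str
    coverage: pd.Series  # indexed by exon_id

    def __post_init__(self) -> None:
        if (self.coverage < 0).any():
            raise ValueError("coverage must be non-negative")


@dataclass
class ReferenceProfile:
    """Per-exon median of median-normalized coverage across normal samples.

    Non-positive exons are masked (NaN) and excluded downstream.
    """

    values: pd.Series

    def __post_init__(self) -> None:
        vals = self.values.astype(float).copy()
        vals[vals <= 0] = np.nan
        object.__setattr__(self, "values", vals)

    @property
    def masked_exons(self) -> list[str]:
        return list(self.values.index[self.values.isna()])


@dataclass(frozen=True)
class BafObservation:
    """Read counts at one heterozygous site."""

    chrom: str
    pos: int  # 1-based
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_count + self.alt_count == 0:
            raise ValueError("BAF site with zero total depth")

    @property
    def baf(self) -> float:
        return self.alt_count / (self.ref_count + self.alt_count)


@dataclass(frozen=True)
class PuritySolution:
    purity: float
    neutral_level: float
    residual: float
    identifiable: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")


@dataclass(frozen=True)
class CopyNumberCall:
    gene: str
    log2_ratio: float
    copy_number: float
    cn_class: str  # loss | neutral | gain


class SampleQCError(RuntimeError):
    """Sample-level failure (e.g. zero median coverage)."""


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_coverage(sample: CoverageProfile, reference: ReferenceProfile) -> pd.Series:
    """Per-exon log2 ratios of median-normalized sample over reference.

    The sample is first divided by its own median exon coverage, then by the
    reference per-exon value, then log2-transformed. Masked reference exons
    are dropped. Zero-coverage exons yield -inf (a hard deletion signal).
    """
    cov = sample.coverage
    med = float(np.median(cov.values))
    if med <= 0:
        raise SampleQCError(f"sample {sample.sample_id}: median exon coverage is zero")
    if reference.values.index.equals(cov.index):  # aligned fast path
        ref_vals = reference.values.values
        usable = ~np.isnan(ref_vals)
        with np.errstate(divide="ignore"):
            vals = np.log2((cov.values[usable] / med) / ref_vals[usable])
        return pd.Series(vals, index=cov.index[usable])
    ref = reference.values.reindex(cov.index)
    usable = ref.notna()
    with np.errstate(divide="ignore"):
        log2r = np.log2((cov[usable].astype(float) / med) / ref[usable])
    return log2r


def make_reference(profiles: list[CoverageProfile]) -> ReferenceProfile:
    """Median of median-normalized coverage across a set of normal samples."""
    if not profiles:
        raise ValueError("need at least one normal sample")
    normed = []
    for prof in profiles:
        med = float(np.median(prof.coverage.values))
        if med <= 0:
            raise SampleQCError(f"normal sample {prof.sample_id}: zero median coverage")
        normed.append(prof.coverage.astype(float) / med)
    return ReferenceProfile(values=pd.concat(normed, axis=1).median(axis=1))


# ---------------------------------------------------------------------------
# Purity estimation
# ---------------------------------------------------------------------------


def _kde_mode(values: np.ndarray) -> float:
    """Mode estimated as the data point with maximal kernel density.

    Evaluating at the data points keeps the dominant (copy-neutral) level
    exact when many exons share it.
    """
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return 0.0
    if len(values) < 3 or float(np.std(values)) < 1e-9:
        return float(np.median(values))
    kde = stats.gaussian_kde(values)
    uniq = np.unique(values)
    dens = kde(uniq)
    return float(uniq[int(np.argmax(dens))])


def _fold(x):
    return np.minimum(x, 1.0 - x)


def estimate_purity(
    log2_ratios: pd.Series,
    bafs: list[BafObservation],
    panel,
    grid: np.ndarray | None = None,
    baf_weight: float = 4.0,
    aberrant_log2_tol: float = 0.12,
    flat_baf_tol: float = 0.08,
) -> PuritySolution:
    """Grid-search tumor purity from coverage ratios and B-allele fractions.

    Only aberrant genes carry purity information: a copy-neutral gene inverts
    to CN 2 at every candidate purity, and its heterozygous sites are fit by
    the balanced allele split regardless of purity. The score therefore sums,
    over genes whose mean log2 ratio deviates from the copy-neutral level,
    the squared distance of the inverted gene CN from the nearest non-negative
    integer plus the squared deviation of each of the gene's observed BAFs
    from the best integer-allele-split prediction. A flat profile with all
    BAFs near 0.5 is unidentifiable: purity defaults to 1 with
    ``identifiable=False``.
    """
    if grid is None:
        grid = 0.05 + 0.01 * np.arange(96)
    if len(grid) == 0:
        raise ValueError("empty purity grid")
    raw = log2_ratios.to_numpy(dtype=float)
    keep = ~np.isnan(raw)
    if not keep.any():
        raise ValueError("no unmasked exons")
    values = raw[keep]
    kept_exons = log2_ratios.index[keep]

    level = _kde_mode(values)

    # gene-level mean log2 ratios (few exons per gene; no segmentation)
    gene_of_exon = dict(zip(panel.intervals["exon_id"], panel.intervals["gene"]))
    gene_sum: dict[str, float] = {}
    gene_n: dict[str, int] = {}
    gene_inf: dict[str, bool] = {}
    for exon, v in zip(kept_exons, values):
        g = gene_of_exon.get(exon)
        if g is None:
            continue
        gene_n[g] = gene_n.get(g, 0) + 1
        if np.isinf(v):
            gene_inf[g] = True
        else:
            gene_sum[g] = gene_sum.get(g, 0.0) + float(v)
    gene_l2 = {
        g: (-np.inf if gene_inf.get(g) else gene_sum.get(g, 0.0) / n)
        for g, n in gene_n.items()
    }
    aberrant = {g for g, l2 in gene_l2.items() if abs(l2 - level) > aberrant_log2_tol}

    folded_bafs = np.array([_fold(b.baf) for b in bafs]) if bafs else np.array([])
    if not aberrant and (
        len(folded_bafs) == 0 or np.all(np.abs(folded_bafs - 0.5) < flat_baf_tol)
    ):
        return PuritySolution(purity=1.0, neutral_level=level, residual=0.0, identifiable=False)

    with np.errstate(over="ignore"):
        gene_r = {g: float(2.0 ** (l2 - level)) for g, l2 in gene_l2.items()}
    ab_r = np.array([gene_r[g] for g in sorted(aberrant)])

    # BAF sites in aberrant genes, keyed to their gene-level ratio
    site_r, site_b = [], []
    for b in bafs:
        g = panel.gene_at(b.chrom, b.pos)
        if g not in aberrant or gene_r.get(g, 0.0) <= 0:
            continue
        site_r.append(gene_r[g])
        site_b.append(_fold(b.baf))
    site_r = np.asarray(site_r)
    site_b = np.asarray(site_b)

    p = np.asarray(grid, dtype=float)[:, None]  # grid x 1
    total = np.zeros(len(grid))
    if len(ab_r):
        cn = (2.0 * ab_r[None, :] - 2.0 * (1.0 - p)) / p  # grid x aberrant genes
        nearest = np.clip(np.round(cn), 0.0, None)
        total = np.sum((cn - nearest) ** 2, axis=1)
    if len(site_r):
        cn_site = (2.0 * site_r[None, :] - 2.0 * (1.0 - p)) / p  # grid x sites
        nb_cap = np.floor(np.clip(cn_site, 0.0, None) / 2.0)
        k_max = int(min(np.nanmax(nb_cap), 12.0))
        nb = np.arange(k_max + 1, dtype=float)[None, :, None]  # 1 x K x 1
        expected = (p[:, :, None] * nb + (1.0 - p[:, :, None])) / (
            2.0 * site_r[None, None, :]
        )  # grid x K x sites
        sq = (site_b[None, None, :] - _fold(expected)) ** 2
        sq[nb > nb_cap[:, None, :]] = np.inf  # invalid allele splits
        total = total + baf_weight * np.sum(np.min(sq, axis=1), axis=1)

    best = float(np.min(total))
    ties = np.flatnonzero(total <= best + 1e-12)
    idx = int(ties[-1])  # grid ascending: ties resolve to the largest purity
    return PuritySolution(
        purity=float(grid[idx]),
        neutral_level=level,
        residual=float(total[idx]),
        identifiable=True,
    )


# ---------------------------------------------------------------------------
# Copy-number calling
# ---------------------------------------------------------------------------


def invert_copy_number(ratio: float, purity: float) -> float:
    """CN = (2 r - 2 (1 - p)) / p — exact inverse of the mixture ratio."""
    return (2.0 * ratio - 2.0 * (1.0 - purity)) / purity


def classify_cn(cn: float, loss_below: float = 1.0, gain_above: float = 4.0) -> str:
    if cn < loss_below:
        return "loss"
    if cn > gain_above:
        return "gain"
    return "neutral"


def call_copy_number(
    log2_ratios: pd.Series,
    purity: PuritySolution,
    panel,
    loss_below: float = 1.0,
    gain_above: float = 4.0,
) -> list[CopyNumberCall]:
    """Per-gene purity-adjusted copy number with strict loss/gain thresholds.

    The gene-level ratio is the mean of its exon log2 ratios (no
    segmentation; panel genes have few exons). Genes whose exons are all
    masked are omitted with a warning.
    """
    if log2_ratios.index.equals(panel._exon_index):
        vals = log2_ratios.to_numpy(dtype=float)
    else:
        vals = log2_ratios.reindex(panel._exon_index).to_numpy(dtype=float)
    codes, genes = panel._gene_codes
    ok = ~np.isnan(vals)
    n_ok = np.bincount(codes[ok], minlength=len(genes))
    sums = np.bincount(codes[ok], weights=np.where(np.isinf(vals[ok]), 0.0, vals[ok]),
                       minlength=len(genes))
    has_inf = np.bincount(codes[ok & np.isinf(vals)], minlength=len(genes)) > 0

    p = purity.purity
    calls = []
    for i, gene in enumerate(genes):
        if n_ok[i] == 0:
            logger.warning("gene %s: all exons masked, no CN call", gene)
            continue
        l2 = -np.inf if has_inf[i] else float(sums[i] / n_ok[i])
        r = 0.0 if has_inf[i] else float(2.0 ** (l2 - purity.neutral_level))
        cn = invert_copy_number(r, p)
        calls.append(
            CopyNumberCall(
                gene=gene,
                log2_ratio=l2,
                copy_number=cn,
                cn_class=classify_cn(cn, loss_below, gain_above),
            )
        )
    return calls
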