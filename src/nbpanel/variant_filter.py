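"""Multi-caller merge plus artifact and germline filtering of SNV/indel calls.

The somatic call set is produced in four stages: per-caller calls are merged
by genomic identity, annotated with gene/effect, stripped of alignment
artifacts (strand-biased and clustered calls), and finally stripped of likely
germline variants using a high-VAF rule (with a hotspot exemption) and
population-frequency rules.
"""

from __future__ import annotations

import importlib.resources
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRUNCATING_EFFECTS = frozenset({"nonsense", "frameshift", "splice"})
EFFECT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "inframe_indel", "synonymous", "other"}
)


@dataclass
class VariantCall:
    """One candidate SNV/indel with per-caller support and filter status."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_fraction: float
    alt_forward: int | None = None
    alt_reverse: int | None = None
    callers: set[str] = field(default_factory=set)
    sample_id: str | None = None
    gene: str | None = None
    protein_change: str | None = None
    effect: str | None = None
    hotspot: bool = False
    exon_skip: bool = False
    filter_status: str = "pass"
    reason: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele_fraction outside [0, 1]: {self.allele_fraction}")

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def alt_depth(self) -> int | None:
        if self.alt_forward is None or self.alt_reverse is None:
            return None
        return self.alt_forward + self.alt_reverse

    @property
    def is_truncating(self) -> bool:
        return self.effect in TRUNCATING_EFFECTS

    def removed(self, reason: str) -> None:
        self.filter_status = "removed"
        self.reason = reason


@dataclass(frozen=True)
class PopulationResources:
    """Population allele frequencies, panel-of-normals counts and hotspots."""

    pop_af: dict
    pon_counts: dict
    pon_n: int = 480
    hotspots: frozenset = frozenset()

    def __post_init__(self) -> None:
        bad = [k for k, v in self.pon_counts.items() if v > self.pon_n]
        if bad:
            raise ValueError(f"panel-of-normals count exceeds pon_n for {bad[:3]}")


def _data_file(name: str):
    return importlib.resources.files("nbpanel.data").joinpath(name)


def load_default_resources(pon_n: int = 480) -> PopulationResources:
    with importlib.resources.as_file(_data_file("population_af.tsv")) as p:
        pop = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    with importlib.resources.as_file(_data_file("pon_counts.tsv")) as p:
        pon = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    with importlib.resources.as_file(_data_file("hotspots.tsv")) as p:
        hs = pd.read_csv(p, sep="\t")
    return PopulationResources(
        pop_af={(r.chrom, int(r.pos), r.ref, r.alt): float(r.af) for r in pop.itertuples()},
        pon_counts={(r.chrom, int(r.pos), r.ref, r.alt): int(r.count) for r in pon.itertuples()},
        pon_n=pon_n,
        hotspots=frozenset((r.gene, r.protein_change) for r in hs.itertuples()),
    )


def load_default_annotation() -> pd.DataFrame:
    with importlib.resources.as_file(_data_file("annotation.tsv")) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------


def merge_callers(call_lists: list[list[VariantCall]]) -> list[VariantCall]:
    """Collapse per-caller call lists into one record per distinct variant.

    Calls identical in (sample, chrom, pos, ref, alt) merge into a single
    record whose caller set is the union, whose allele fraction is the median
    across reporting callers and whose strand counts come from the caller
    with the deepest alt coverage.
    """
    by_key: dict[tuple, list[VariantCall]] = defaultdict(list)
    ref_at: dict[tuple, str] = {}
    for calls in call_lists:
        for c in calls:
            site = (c.sample_id, c.chrom, c.pos)
            if site in ref_at and ref_at[site] != c.ref and len(ref_at[site]) == len(c.ref):
                raise ValueError(
                    f"conflicting ref alleles at {c.chrom}:{c.pos}: "
                    f"{ref_at[site]!r} vs {c.ref!r}"
                )
            ref_at.setdefault(site, c.ref)
            by_key[c.key].append(c)

    merged = []
    for key in sorted(by_key, key=lambda k: (k[0] or "", k[1], k[2], k[3], k[4])):
        group = by_key[key]
        callers = set().union(*(c.callers for c in group))
        af = float(np.median([c.allele_fraction for c in group]))
        with_depth = [c for c in group if c.alt_depth is not None]
        donor = max(with_depth, key=lambda c: c.alt_depth) if with_depth else group[0]
        proto = group[0]
        merged.append(
            VariantCall(
                chrom=proto.chrom,
                pos=proto.pos,
                ref=proto.ref,
                alt=proto.alt,
                allele_fraction=af,
                alt_forward=donor.alt_forward,
                alt_reverse=donor.alt_reverse,
                callers=callers,
                sample_id=proto.sample_id,
                gene=proto.gene,
                protein_change=proto.protein_change,
                effect=proto.effect,
                hotspot=proto.hotspot,
                exon_skip=proto.exon_skip,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# Artifact filter
# ---------------------------------------------------------------------------


@lru_cache(maxsize=100_000)
def is_strand_biased(
    alt_forward: int, alt_reverse: int, p_cut: float = 0.001, frac_cut: float = 0.95
) -> bool:
    total = alt_forward + alt_reverse
    if total == 0:
        return False
    frac = max(alt_forward, alt_reverse) / total
    if frac < frac_cut:  # cannot fail both conditions; skip the exact test
        return False
    p = stats.binomtest(alt_forward, total, 0.5).pvalue
    return p < p_cut


def filter_artifacts(
    calls: list[VariantCall],
    p_cut: float = 0.001,
    frac_cut: float = 0.95,
    cluster_count: int = 3,
    cluster_window: int = 10,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Remove strand-biased and clustered calls.

    Strand bias: an exact two-sided binomial test of the alt-read strand
    split against 0.5 with p < ``p_cut`` and at least ``frac_cut`` of alt
    reads on one strand. Clustering: ``cluster_count`` or more distinct calls
    of one sample falling inside any ``cluster_window``-bp window. Returns
    (retained, removed); removed records carry their reason.
    """
    removed: list[VariantCall] = []
    survivors: list[VariantCall] = []
    for c in calls:
        if c.alt_forward is None or c.alt_reverse is None:
            logger.warning(
                "no strand counts for %s:%s %s>%s; strand-bias test skipped",
                c.chrom, c.pos, c.ref, c.alt,
            )
            survivors.append(c)
        elif is_strand_biased(c.alt_forward, c.alt_reverse, p_cut, frac_cut):
            c.removed("strand_bias")
            removed.append(c)
        else:
            survivors.append(c)

    clustered: set[int] = set()
    by_region: dict[tuple, list[VariantCall]] = defaultdict(list)
    for c in survivors:
        by_region[(c.sample_id, c.chrom)].append(c)
    for group in by_region.values():
        group.sort(key=lambda c: c.pos)
        positions = sorted({c.pos for c in group})
        flagged_pos = set()
        k = cluster_count
        for i in range(len(positions) - k + 1):
            if positions[i + k - 1] - positions[i] < cluster_window:
                flagged_pos.update(positions[i : i + k])
        for c in group:
            if c.pos in flagged_pos:
                clustered.add(id(c))

    retained = []
    for c in survivors:
        if id(c) in clustered:
            c.removed("cluster")
            removed.append(c)
        else:
            retained.append(c)
    return retained, removed


# ---------------------------------------------------------------------------
# Germline filter
# ---------------------------------------------------------------------------


def filter_germline(
    calls: list[VariantCall],
    resources: PopulationResources,
    vaf_germline_cut: float = 0.97,
    popdb_cut: float = 0.01,
    pon_cut: float = 0.03,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Remove likely germline variants; returns (somatic, removed).

    A call is removed iff its allele fraction is >= ``vaf_germline_cut`` and
    it is not a hotspot, or its population allele frequency is >=
    ``popdb_cut``, or its panel-of-normals occurrence fraction is >=
    ``pon_cut``. Absent lookup keys count as frequency zero. The hotspot
    exemption applies only to the VAF rule.
    """
    somatic, removed = [], []
    for c in calls:
        key = (c.chrom, c.pos, c.ref, c.alt)
        pop_af = resources.pop_af.get(key, 0.0)
        pon_frac = resources.pon_counts.get(key, 0) / resources.pon_n
        if c.allele_fraction >= vaf_germline_cut and not c.hotspot:
            c.removed("germline_vaf")
            removed.append(c)
        elif pop_af >= popdb_cut:
            c.removed("popdb")
            removed.append(c)
        elif pon_frac >= pon_cut:
            c.removed("pon")
            removed.append(c)
        else:
            somatic.append(c)
    return somatic, removed


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def classify_protein_change(change: str) -> str:
    """Heuristic effect class from a protein-change string."""
    if change.endswith("*") or change.endswith("Ter"):
        return "nonsense"
    if change.endswith("fs") or "fs" in change:
        return "frameshift"
    if "skip" in change or "splice" in change:
        return "splice"
    if change.endswith("=") or change.endswith("syn"):
        return "synonymous"
    if "del" in change or "ins" in change or "dup" in change:
        return "inframe_indel"
    s = change
    if len(s) >= 3 and s[0].isalpha() and s[-1].isalpha() and s[1:-1].isdigit():
        return "missense"
    return "other"


def annotation_lookup(annotation: pd.DataFrame) -> dict:
    """(gene, protein change) -> effect class mapping from the annotation table."""
    return {(r.gene, r.protein_change): r.effect for r in annotation.itertuples(index=False)}


def annotate_effects(
    calls: list[VariantCall],
    annotation,
    panel,
    hotspots: frozenset = frozenset(),
) -> list[VariantCall]:
    """Set gene, effect class and the hotspot flag on every call.

    Gene is assigned by panel position; effect comes from the annotation
    table (a DataFrame or a prebuilt :func:`annotation_lookup` dict) keyed by
    (gene, protein change) with a string-pattern fallback. Calls outside
    panel genes get effect "other" with a warning.
    """
    lookup = annotation if isinstance(annotation, dict) else annotation_lookup(annotation)
    for c in calls:
        gene = panel.gene_at(c.chrom, c.pos)
        if gene is None:
            logger.warning("variant %s:%s outside panel genes", c.chrom, c.pos)
            c.gene = None
            c.effect = "other"
            c.hotspot = False
            continue
        c.gene = gene
        if c.protein_change:
            c.effect = lookup.get((gene, c.protein_change)) or classify_protein_change(
                c.protein_change
            )
        elif c.effect not in EFFECT_CLASSES:
            c.effect = "other"
        c.hotspot = (gene, c.protein_change) in hotspots
        if c.protein_change and "skip" in c.protein_change:
            c.exon_skip = True
    return calls


def accounting_ok(n_input: int, retained: list, removed_lists: list[list]) -> bool:
    """Every input record is either retained or removed with a reason."""
    return n_input == len(retained) + sum(len(r) for r in removed_lists)
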