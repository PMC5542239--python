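"""Synthetic cohort generator with the statistical structure the analysis assumes.

Generates, per patient: truth alterations drawn independently per gene at
configured prevalences, negative-binomial exon depths scaled by the
purity-mixed copy-number ratio, binomial B-allele-fraction draws, per-caller
variant call lists with injected artifact false positives, Poisson FISH
signal counts, and stratum-specific exponential survival times with uniform
censoring.

All generators are pure functions of (config, seed): per-module child
streams are derived deterministically from the one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv_purity import BafObservation, CoverageProfile
from .cohort_survival import PatientRecord
from .fish_mycn import FishCount
from .panel_io import PanelDesign, default_panel
from .variant_filter import VariantCall

ALTERATION_KINDS = ("snv_missense", "snv_truncating", "indel", "cn_gain", "cn_loss")

# Prevalences calibrated so that, under independent per-gene draws, the
# closed-form cohort rates are exactly 63/72 patients with >= 1 alteration
# and 16/72 molecular target candidates.
_SINGLETON_PREV = 0.015852099246381646  # HRAS, MET, ERBB2, STK11
_BACKGROUND_PREV = 0.017556074678139688  # each of the 72 background genes


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AlterationSpec:
    """One way a gene can be altered, with its sampling weight."""

    kind: str
    weight: float
    protein_change: str | None = None
    effect: str | None = None
    hotspot: bool = False
    exon_skip: bool = False
    cn: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ALTERATION_KINDS:
            raise ConfigError(f"unknown alteration kind {self.kind!r}")
        if self.kind.startswith("cn_") and self.cn is None:
            raise ConfigError(f"{self.kind} spec needs a true copy number")


@dataclass(frozen=True)
class GeneModel:
    prevalence: float
    specs: tuple[AlterationSpec, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"prevalence outside [0, 1]: {self.prevalence}")
        if not self.specs:
            raise ConfigError("gene model needs at least one alteration spec")


@dataclass(frozen=True)
class CallerModel:
    sensitivity: float = 0.95
    fp_rate: float = 0.5  # expected artifact false positives per sample

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ConfigError("caller sensitivity must be in [0, 1]")
        if self.fp_rate < 0:
            raise ConfigError("caller fp_rate must be non-negative")


@dataclass
class CohortConfig:
    """Everything the simulator needs; defaults emulate the study cohort."""

    n_patients: int = 72
    genes: dict = field(default_factory=dict)  # gene -> GeneModel
    frac_high_risk: float = 31.0 / 72.0
    purity_range: tuple[float, float] = (0.3, 1.0)
    depth_mean: float = 500.0
    depth_dispersion: float | None = 0.1  # None -> noise-free expected depth
    baf_sites_per_gene: int = 1
    callers: dict = field(default_factory=dict)  # name -> CallerModel
    germline_rate: float = 0.0  # expected high-VAF germline leaks per sample
    vaf_range: tuple[float, float] = (0.05, 0.5)
    survival: dict = field(default_factory=dict)  # endpoint -> stratum -> S(H)
    censor_rate: float = 0.2
    admin_horizon: float = 120.0
    horizon: float = 36.0
    mycn_prevalence: float = 0.15
    exclusivity: bool = True
    arid1b_highrisk_frac: float = 0.8
    gain_minor_copies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("purity_range must satisfy 0 < low <= high <= 1")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        for endpoint, strata in self.survival.items():
            for stratum, s in strata.items():
                if not 0.0 < s <= 1.0:
                    raise ConfigError(
                        f"survival fraction for {endpoint}/{stratum} must be in (0, 1]"
                    )
        if not 0.0 <= self.mycn_prevalence <= 1.0:
            raise ConfigError("mycn_prevalence outside [0, 1]")

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes)


def _missense(weight: float, change: str | None = None, hotspot: bool = False) -> AlterationSpec:
    return AlterationSpec(
        kind="snv_missense", weight=weight, protein_change=change, effect="missense", hotspot=hotspot
    )


_BACKGROUND_GENES = [
    "ABL1", "AKT1", "AKT2", "APC", "AURKA", "BRAF", "BRCA2", "CCND1", "CCNE1", "CDK4",
    "CDK6", "CDKN1B", "CDKN2A", "CREBBP", "CTNNB1", "DDR2", "EGFR", "EP300", "ERBB3", "ERBB4",
    "ESR1", "EZH2", "FBXW7", "FGFR1", "FGFR2", "FGFR3", "FGFR4", "FLT3", "GNA11", "GNAQ",
    "GNAS", "IDH1", "IDH2", "IGF1R", "JAK1", "JAK2", "JAK3", "KDR", "KIT", "KRAS",
    "MAP2K1", "MAP2K2", "MDM2", "MDM4", "MLH1", "MPL", "MSH2", "MSH6", "MTOR", "NF1",
    "NF2", "NOTCH1", "NRAS", "PALB2", "PDGFRA", "PDGFRB", "PIK3CA", "PIK3R1", "PTEN", "PTPN11",
    "RAF1", "RB1", "RET", "ROS1", "SMAD4", "SMARCA4", "SMARCB1", "SMO", "TP53", "TSC1",
    "TSC2", "VHL",
]


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The packaged cohort configuration.

    Per-gene prevalences match the printed cohort fractions (ALK 12/72,
    BRCA1 10/72, ATM 9/72, PTCH1 8/72, ARID1B 5/72, ARID1A 3/72, ATRX 3/72);
    the four singleton actionable genes and the 72 background genes carry
    calibrated prevalences so the closed-form any-alteration and
    target-candidate rates equal 63/72 and 16/72.
    """
    genes: dict[str, GeneModel] = {
        "ALK": GeneModel(
            prevalence=12.0 / 72.0,
            specs=(
                _missense(3.0, "R1275Q", hotspot=True),
                _missense(1.5, "F1174I", hotspot=True),
                _missense(1.5, "R1192G", hotspot=True),
                AlterationSpec(kind="cn_gain", weight=1.0, cn=6.0),
                _missense(5.0),
            ),
        ),
        "BRCA1": GeneModel(
            prevalence=10.0 / 72.0,
            specs=(
                AlterationSpec(
                    kind="snv_truncating", weight=1.5, protein_change="Q1756fs", effect="frameshift"
                ),
                AlterationSpec(
                    kind="snv_truncating", weight=1.5, protein_change="R1751*", effect="nonsense"
                ),
                _missense(3.0),
                AlterationSpec(kind="cn_gain", weight=4.0, cn=6.0),
            ),
        ),
        "ATM": GeneModel(
            prevalence=9.0 / 72.0,
            specs=(
                AlterationSpec(kind="cn_loss", weight=3.0, cn=0.0),
                _missense(6.0),
            ),
        ),
        "PTCH1": GeneModel(prevalence=8.0 / 72.0, specs=(_missense(1.0),)),
        "ARID1B": GeneModel(
            prevalence=5.0 / 72.0,
            specs=(
                _missense(4.0),
                AlterationSpec(
                    kind="indel", weight=1.0, protein_change="S614del", effect="inframe_indel"
                ),
            ),
        ),
        "ARID1A": GeneModel(prevalence=3.0 / 72.0, specs=(_missense(1.0),)),
        "ATRX": GeneModel(
            prevalence=3.0 / 72.0,
            specs=(
                _missense(1.0, "A1988S"),
                _missense(1.0, "V2189A"),
                _missense(1.0, "R498G"),
            ),
        ),
        "HRAS": GeneModel(
            prevalence=_SINGLETON_PREV, specs=(_missense(1.0, "Q61R", hotspot=True),)
        ),
        "MET": GeneModel(
            prevalence=_SINGLETON_PREV,
            specs=(
                AlterationSpec(
                    kind="snv_truncating",
                    weight=1.0,
                    protein_change="exon14_skip",
                    effect="splice",
                    exon_skip=True,
                ),
            ),
        ),
        "ERBB2": GeneModel(
            prevalence=_SINGLETON_PREV, specs=(AlterationSpec(kind="cn_gain", weight=1.0, cn=6.0),)
        ),
        "STK11": GeneModel(
            prevalence=_SINGLETON_PREV, specs=(AlterationSpec(kind="cn_loss", weight=1.0, cn=0.0),)
        ),
    }
    for gene in _BACKGROUND_GENES:
        genes[gene] = GeneModel(prevalence=_BACKGROUND_PREV, specs=(_missense(1.0),))

    return CohortConfig(
        genes=genes,
        callers={
            "mutect": CallerModel(sensitivity=0.97, fp_rate=0.5),
            "lofreq": CallerModel(sensitivity=0.95, fp_rate=0.5),
            "snver": CallerModel(sensitivity=0.93, fp_rate=0.5),
        },
        survival={
            "rfs": {"arid1b": 0.375, "mycn": 0.905, "neither": 0.905},
            "os": {"arid1b": 0.333, "mycn": 0.300, "neither": 0.905},
        },
        seed=seed,
    )


def perfect_cohort_config(seed: int = 0) -> CohortConfig:
    """Default config with perfect callers and noise-free depth/BAF."""
    cfg = default_cohort_config(seed=seed)
    cfg.callers = {name: CallerModel(sensitivity=1.0, fp_rate=0.0) for name in cfg.callers}
    cfg.depth_dispersion = None
    cfg.germline_rate = 0.0
    return cfg


# ---------------------------------------------------------------------------
# Cohort truth
# ---------------------------------------------------------------------------

_ALTERATION_COLUMNS = [
    "patient_id", "gene", "kind", "chrom", "pos", "ref", "alt", "vaf",
    "protein_change", "effect", "hotspot", "exon_skip", "true_cn",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticCohort:
    config: CohortConfig
    seed: int
    patients: list[PatientRecord]
    alterations: pd.DataFrame  # truth table, one row per (patient, gene) alteration
    purity: dict  # patient_id -> truth purity

    def __post_init__(self) -> None:
        # per-patient indexes, built once (the pipeline queries per sample)
        self._variant_rows: dict[str, list] = {}
        self._cn_rows: dict[str, dict] = {}
        for row in self.alterations.itertuples(index=False):
            if row.kind in ("cn_gain", "cn_loss"):
                self._cn_rows.setdefault(row.patient_id, {})[row.gene] = float(row.true_cn)
            else:
                self._variant_rows.setdefault(row.patient_id, []).append(row)

    def cn_by_gene(self, patient_id: str) -> dict:
        return dict(self._cn_rows.get(patient_id, {}))

    def variant_rows(self, patient_id: str) -> list:
        """Truth SNV/indel rows for one patient (named-tuple records)."""
        return list(self._variant_rows.get(patient_id, []))

    def altered_genes(self, patient_id: str) -> set:
        genes = {r.gene for r in self._variant_rows.get(patient_id, [])}
        genes.update(self._cn_rows.get(patient_id, {}))
        return genes


def child_rng(seed: int, *salt: int) -> np.random.Generator:
    """Deterministic child stream: one root seed, integer salts per module."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=salt))


def simulate_survival(
    survival_fraction: float,
    horizon: float,
    censor_rate: float,
    rng: np.random.Generator,
    admin_horizon: float = 120.0,
) -> tuple[float, int]:
    """Exponential event time calibrated to S(horizon), uniform censoring.

    The event rate is lambda = -ln(s) / horizon; a ``censor_rate`` fraction
    of subjects get an independent uniform censoring time on (0, 2*horizon);
    everyone is administratively censored at ``admin_horizon``.
    """
    if survival_fraction <= 0:
        raise ConfigError("survival fraction must be > 0")
    lam = -np.log(survival_fraction) / horizon
    t_event = rng.exponential(1.0 / lam) if lam > 0 else np.inf
    c = rng.uniform(0.0, 2.0 * horizon) if rng.random() < censor_rate else np.inf
    end = min(c, admin_horizon)
    time = min(t_event, end)
    event = int(t_event <= end)
    return float(time), event


def _survival_stratum(arid1_altered: bool, mycn: bool) -> str:
    if arid1_altered:
        return "arid1b"
    if mycn:
        return "mycn"
    return "neither"


def generate_cohort(
    config: CohortConfig, seed: int | None = None, panel: PanelDesign | None = None
) -> SyntheticCohort:
    """Draw the full cohort truth: alterations, purity, risk, MYCN, survival.

    Per-gene alteration indicators are independent Bernoulli draws at the
    configured prevalence; each altered (patient, gene) pair receives one
    alteration drawn from the gene's spec weights. With the exclusivity flag
    set, no patient carries both an ARID1-family alteration and MYCN
    amplification.
    """
    if seed is None:
        seed = config.seed
    if panel is None:
        panel = default_panel()
    rng = child_rng(seed, 0)
    surv_rng = child_rng(seed, 1)

    gene_names = [g for g in config.genes if g in set(panel.genes)]
    skipped = set(config.genes) - set(gene_names)
    if skipped:
        raise ConfigError(f"configured genes not on panel: {sorted(skipped)}")
    prev = np.array([config.genes[g].prevalence for g in gene_names])
    n = config.n_patients
    altered = rng.random((n, len(gene_names))) < prev

    exon_map = panel._gene_exon_arrays  # per-gene exon rows for position assignment

    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    rows: list[dict] = []
    lo, hi = config.purity_range
    purity = {pid: float(rng.uniform(lo, hi)) for pid in patient_ids}

    spec_weights = {
        g: np.array([s.weight for s in config.genes[g].specs], dtype=float)
        for g in gene_names
    }
    spec_weights = {g: w / w.sum() for g, w in spec_weights.items()}
    for i, j in np.argwhere(altered):
        pid = patient_ids[i]
        gene = gene_names[j]
        model = config.genes[gene]
        spec = model.specs[rng.choice(len(model.specs), p=spec_weights[gene])]
        exons = exon_map[gene]
        chrom, start, end = exons[rng.integers(len(exons))]
        pos = int(rng.integers(int(start) + 1, int(end) + 1))  # 1-based within exon
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append(
            {
                "patient_id": pid,
                "gene": gene,
                "kind": spec.kind,
                "chrom": chrom,
                "pos": pos,
                "ref": _BASES[ref],
                "alt": _BASES[alt] if spec.kind != "indel" else "",
                "vaf": float(rng.uniform(*config.vaf_range)),
                "protein_change": spec.protein_change,
                "effect": spec.effect,
                "hotspot": spec.hotspot,
                "exon_skip": spec.exon_skip,
                "true_cn": spec.cn if spec.cn is not None else np.nan,
            }
        )
    alterations = pd.DataFrame(rows, columns=_ALTERATION_COLUMNS)

    arid1_patients = set(
        alterations.loc[alterations["gene"].isin(["ARID1A", "ARID1B"]), "patient_id"]
    )
    arid1b_patients = set(alterations.loc[alterations["gene"] == "ARID1B", "patient_id"])
    arid1 = {pid: pid in arid1_patients for pid in patient_ids}
    arid1b = {pid: pid in arid1b_patients for pid in patient_ids}

    patients = []
    for pid in patient_ids:
        mycn = bool(rng.random() < config.mycn_prevalence)
        if config.exclusivity and arid1[pid]:
            mycn = False
        if arid1b[pid]:
            high = rng.random() < config.arid1b_highrisk_frac
        else:
            high = rng.random() < config.frac_high_risk
        stratum = _survival_stratum(arid1b[pid], mycn)
        rfs_time, rfs_event = simulate_survival(
            config.survival["rfs"][stratum], config.horizon, config.censor_rate,
            surv_rng, config.admin_horizon,
        )
        os_time, os_event = simulate_survival(
            config.survival["os"][stratum], config.horizon, config.censor_rate,
            surv_rng, config.admin_horizon,
        )
        patients.append(
            PatientRecord(
                patient_id=pid,
                risk_group="high" if high else "non-high",
                mycn_amplified=mycn,
                rfs_time=rfs_time,
                rfs_event=rfs_event,
                os_time=os_time,
                os_event=os_event,
            )
        )
    return SyntheticCohort(
        config=config, seed=seed, patients=patients, alterations=alterations, purity=purity
    )


# ---------------------------------------------------------------------------
# Coverage + BAF
# ---------------------------------------------------------------------------


def _mixed_ratio(cn: np.ndarray, p: float) -> np.ndarray:
    return (p * cn + 2.0 * (1.0 - p)) / 2.0


def simulate_coverage(
    cn_by_gene: dict,
    purity: float,
    panel: PanelDesign,
    depth_mean: float,
    dispersion: float | None,
    rng: np.random.Generator,
    sample_id: str = "S1",
    baf_sites_per_gene: int = 1,
    gain_minor_copies: int = 2,
) -> tuple[CoverageProfile, list[BafObservation]]:
    """Exon depths and het-site BAFs for one sample under the mixture model.

    Expected exon depth is ``depth_mean * (p*CN + 2(1-p))/2``; dispersion
    ``None`` gives exactly the expectation (noise-free), 0 gives Poisson,
    and d > 0 gives a negative binomial (gamma-Poisson) with variance
    inflated to m * (1 + d) over the Poisson baseline. Het-site
    alt counts are binomial with success probability
    ``(p*nB + (1-p)) / (p*CN + 2(1-p))`` where the minor-allele copy count
    nB is 1 for CN=2, 0 for losses and ``gain_minor_copies`` for gains.
    """
    if not 0.0 < purity <= 1.0:
        raise ConfigError("purity must be in (0, 1]")
    if depth_mean <= 0:
        raise ConfigError("depth mean must be positive")
    if any(cn < 0 for cn in cn_by_gene.values()):
        raise ConfigError("copy numbers must be non-negative")

    df = panel.intervals
    gene_arr = df["gene"].to_numpy()
    chrom_arr = df["chrom"].to_numpy()
    start_arr = df["start"].to_numpy()
    cn = np.full(len(df), 2.0)
    for gene, value in cn_by_gene.items():
        cn[panel._gene_rows[gene]] = value
    r = _mixed_ratio(cn, purity)
    mean = depth_mean * r
    if dispersion is None:
        depth = mean
    elif dispersion == 0:
        depth = rng.poisson(mean).astype(float)
    else:
        lam = rng.gamma(shape=mean / dispersion, scale=dispersion)
        depth = rng.poisson(lam).astype(float)
    profile = CoverageProfile(
        sample_id=sample_id, coverage=pd.Series(depth, index=df["exon_id"].values)
    )

    bafs: list[BafObservation] = []
    for gene, rows in panel._gene_rows.items():
        g_cn = cn_by_gene.get(gene, 2.0)
        if g_cn == 2.0:
            nb = 1
        elif g_cn < 2.0:
            nb = 0
        else:
            nb = gain_minor_copies
        denom = purity * g_cn + 2.0 * (1.0 - purity)
        if denom <= 0:
            continue
        e = (purity * nb + (1.0 - purity)) / denom
        g_r = denom / 2.0
        for k in range(baf_sites_per_gene):
            row = rows[k % len(rows)]
            pos = int(start_arr[row]) + 15 + 7 * k  # deterministic in-exon site
            if dispersion is None:
                total = 10000
                alt = int(round(e * total))
            else:
                total = int(rng.poisson(depth_mean * g_r))
                if total == 0:
                    continue
                alt = int(rng.binomial(total, e))
            bafs.append(
                BafObservation(
                    chrom=str(chrom_arr[row]), pos=pos + 1, ref_count=total - alt, alt_count=alt
                )
            )
    return profile, bafs


def simulate_normals(
    panel: PanelDesign,
    depth_mean: float,
    dispersion: float | None,
    rng: np.random.Generator,
    n_samples: int = 20,
) -> list[CoverageProfile]:
    """Diploid normal samples for building a reference profile."""
    return [
        simulate_coverage({}, 1.0, panel, depth_mean, dispersion, rng,
                          sample_id=f"N{i + 1:02d}", baf_sites_per_gene=0)[0]
        for i in range(n_samples)
    ]


# ---------------------------------------------------------------------------
# Caller outputs
# ---------------------------------------------------------------------------

_EMPTY_FP_LOG = pd.DataFrame(columns=["sample_id", "chrom", "pos", "signature"])


def simulate_caller_outputs(
    truth_variants,
    caller_models: dict,
    panel: PanelDesign,
    rng: np.random.Generator,
    sample_id: str,
    depth_mean: float = 500.0,
    germline_rate: float = 0.0,
) -> tuple[dict, pd.DataFrame]:
    """Per-caller call lists plus a truth log of injected false positives.

    Each truth variant is detected independently per caller at its
    sensitivity. False positives carry an artifact signature — either a
    fully strand-skewed alt-read split or a cluster of three calls within a
    10-bp window — recorded in the log. Optional germline leaks are injected
    at allele fraction >= 0.97 into every caller.
    """
    df = panel.intervals
    calls: dict[str, list[VariantCall]] = {name: [] for name in caller_models}
    log_rows: list[dict] = []
    truth_rows = (
        list(truth_variants.itertuples(index=False))
        if isinstance(truth_variants, pd.DataFrame)
        else list(truth_variants)
    )

    def _strand_split(vaf: float) -> tuple[int, int]:
        n_alt = max(2, int(round(depth_mean * vaf)))
        fwd = int(rng.binomial(n_alt, 0.5))
        return fwd, n_alt - fwd

    for row in truth_rows:
        fwd, rev = _strand_split(row.vaf)
        for name, model in caller_models.items():
            if rng.random() >= model.sensitivity:
                continue
            calls[name].append(
                VariantCall(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt) if row.alt else "-",
                    allele_fraction=float(row.vaf),
                    alt_forward=fwd,
                    alt_reverse=rev,
                    callers={name},
                    sample_id=sample_id,
                    gene=row.gene,
                    protein_change=row.protein_change,
                    effect=row.effect,
                    exon_skip=bool(row.exon_skip),
                )
            )

    # germline leaks: high-VAF variants every caller sees
    n_germ = rng.poisson(germline_rate) if germline_rate > 0 else 0
    for _ in range(n_germ):
        row = df.iloc[int(rng.integers(len(df)))]
        pos = int(rng.integers(int(row["start"]) + 1, int(row["end"]) + 1))
        ref, alt = rng.choice(4, size=2, replace=False)
        vaf = float(rng.uniform(0.97, 1.0))
        fwd, rev = _strand_split(vaf)
        for name in caller_models:
            calls[name].append(
                VariantCall(
                    chrom=str(row["chrom"]), pos=pos, ref=_BASES[ref], alt=_BASES[alt],
                    allele_fraction=vaf, alt_forward=fwd, alt_reverse=rev,
                    callers={name}, sample_id=sample_id, effect="missense",
                )
            )
        log_rows.append(
            {"sample_id": sample_id, "chrom": str(row["chrom"]), "pos": pos,
             "signature": "germline"}
        )

    for name, model in caller_models.items():
        n_fp = rng.poisson(model.fp_rate) if model.fp_rate > 0 else 0
        for _ in range(n_fp):
            row = df.iloc[int(rng.integers(len(df)))]
            base_pos = int(rng.integers(int(row["start"]) + 1, int(row["end"]) - 8))
            vaf = float(rng.uniform(0.02, 0.10))
            if rng.random() < 0.5:  # strand-skewed artifact
                n_alt = max(30, int(round(depth_mean * vaf)))
                fwd, rev = (n_alt, 0) if rng.random() < 0.5 else (0, n_alt)
                ref, alt = rng.choice(4, size=2, replace=False)
                calls[name].append(
                    VariantCall(
                        chrom=str(row["chrom"]), pos=base_pos, ref=_BASES[ref], alt=_BASES[alt],
                        allele_fraction=vaf, alt_forward=fwd, alt_reverse=rev,
                        callers={name}, sample_id=sample_id, effect="missense",
                    )
                )
                log_rows.append(
                    {"sample_id": sample_id, "chrom": str(row["chrom"]), "pos": base_pos,
                     "signature": "strand_bias"}
                )
            else:  # clustered artifact: three calls inside a 10-bp window
                for offset in (0, 3, 6):
                    ref, alt = rng.choice(4, size=2, replace=False)
                    fwd, rev = _strand_split(vaf)
                    calls[name].append(
                        VariantCall(
                            chrom=str(row["chrom"]), pos=base_pos + offset,
                            ref=_BASES[ref], alt=_BASES[alt], allele_fraction=vaf,
                            alt_forward=fwd, alt_reverse=rev, callers={name},
                            sample_id=sample_id, effect="missense",
                        )
                    )
                    log_rows.append(
                        {"sample_id": sample_id, "chrom": str(row["chrom"]),
                         "pos": base_pos + offset, "signature": "cluster"}
                    )
    if log_rows:
        log = pd.DataFrame(log_rows, columns=["sample_id", "chrom", "pos", "signature"])
    else:
        log = _EMPTY_FP_LOG
    return calls, log


# ---------------------------------------------------------------------------
# FISH
# ---------------------------------------------------------------------------


def simulate_fish_counts(
    amplified: bool,
    rng: np.random.Generator,
    sample_id: str = "S1",
    n_nuclei: int = 50,
    ref_mean: float = 2.0,
    mycn_mean_normal: float = 2.0,
    mycn_mean_amplified: float = 40.0,
) -> FishCount:
    """Poisson signal counts over (by default) fifty non-overlapping nuclei."""
    mycn_mean = mycn_mean_amplified if amplified else mycn_mean_normal
    return FishCount(
        sample_id=sample_id,
        mycn_signals=rng.poisson(mycn_mean, size=n_nuclei),
        cep2_signals=rng.poisson(ref_mean, size=n_nuclei),
    )
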