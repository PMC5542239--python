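"""Readers/writers for panel, variant, coverage and report files, plus config.

Coordinate conventions used throughout the package:

* BED intervals are 0-based, half-open ``[start, end)``.
* Variant positions are 1-based (VCF convention); a 1-bp BED interval
  ``[s, s+1)`` therefore corresponds to variant position ``s + 1``.
"""

from __future__ import annotations

import dataclasses
import functools
import importlib.resources
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "allele_fraction",
    "alt_forward",
    "alt_reverse",
]


class PanelError(ValueError):
    """Malformed or inconsistent panel definition."""


class VariantTableError(ValueError):
    """Malformed variant table."""


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


@dataclass
class PanelDesign:
    """Exon interval set targeted by the capture panel.

    ``intervals`` has columns ``gene``, ``exon_id``, ``chrom``, ``start``,
    ``end`` sorted by (chrom, start); coordinates are 0-based half-open.
    Position lookups use per-chromosome sorted interval indexes built
    lazily, so they stay fast for cohort-scale simulations.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intervals
        if len(df) and not (df["end"] > df["start"]).all():
            raise PanelError("every exon must satisfy end > start")
        for gene, sub in df.groupby("gene", sort=False):
            sub = sub.sort_values(["chrom", "start"])
            same = sub["chrom"].values[:-1] == sub["chrom"].values[1:]
            overlap = sub["start"].values[1:] < sub["end"].values[:-1]
            if np.any(same & overlap):
                raise PanelError(f"overlapping exons within gene {gene!r}")

    @functools.cached_property
    def genes(self) -> list[str]:
        return sorted(self.intervals["gene"].unique())

    @property
    def exon_ids(self) -> list[str]:
        return list(self.intervals["exon_id"])

    @property
    def n_genes(self) -> int:
        return self.intervals["gene"].nunique()

    @property
    def total_length(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    @functools.cached_property
    def _gene_rows(self) -> dict:
        rows: dict[str, list[int]] = {}
        for i, g in enumerate(self.intervals["gene"].values):
            rows.setdefault(g, []).append(i)
        return {g: np.asarray(idx) for g, idx in rows.items()}

    @functools.cached_property
    def _exon_index(self) -> pd.Index:
        return pd.Index(self.intervals["exon_id"].values)

    @functools.cached_property
    def _gene_exon_arrays(self) -> dict:
        """gene -> ndarray of (chrom, start, end) rows, for fast sampling."""
        return {
            g: self.intervals.iloc[rows][["chrom", "start", "end"]].to_numpy()
            for g, rows in self._gene_rows.items()
        }

    @functools.cached_property
    def _gene_codes(self) -> tuple:
        """(codes array aligned with intervals rows, gene list in code order)."""
        genes = self.genes
        code_of = {g: i for i, g in enumerate(genes)}
        codes = np.array([code_of[g] for g in self.intervals["gene"].values])
        return codes, genes

    @functools.cached_property
    def _pos_index(self) -> dict:
        index = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            index[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["exon_id"].to_numpy(),
                sub["gene"].to_numpy(),
            )
        return index

    def exons_of(self, gene: str) -> pd.DataFrame:
        if gene not in self._gene_rows:
            return self.intervals.iloc[0:0]
        return self.intervals.iloc[self._gene_rows[gene]]

    def _locate(self, chrom: str, pos: int) -> int | None:
        if chrom not in self._pos_index:
            return None
        starts, ends, _, _ = self._pos_index[chrom]
        i = int(np.searchsorted(starts, pos, side="left")) - 1  # 1-based pos > start
        if i >= 0 and pos <= ends[i]:
            return i
        return None

    def exon_at(self, chrom: str, pos: int) -> str | None:
        """Exon id containing the 1-based position ``pos``, or None."""
        i = self._locate(chrom, pos)
        return None if i is None else str(self._pos_index[chrom][2][i])

    def gene_at(self, chrom: str, pos: int) -> str | None:
        i = self._locate(chrom, pos)
        return None if i is None else str(self._pos_index[chrom][3][i])

    def gene_of_exon(self, exon_id: str) -> str:
        df = self.intervals
        return str(df.loc[df["exon_id"] == exon_id, "gene"].iloc[0])


def _chrom_key(chrom: str) -> tuple[int, str]:
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (int(body), "") if body.isdigit() else (1000, body)


def read_panel(path: str | Path) -> PanelDesign:
    """Read a BED3+ file with a name column into a :class:`PanelDesign`.

    The name column is either ``GENE`` or ``GENE_exN``; the part before the
    last ``_ex`` suffix is the gene name.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise PanelError(f"{path}: line {lineno}: expected >= 4 BED columns")
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except ValueError as exc:
                raise PanelError(f"{path}: line {lineno}: {exc}") from None
            if end <= start:
                raise PanelError(f"{path}: line {lineno}: end <= start")
            gene = name.rsplit("_ex", 1)[0] if "_ex" in name else name
            rows.append((gene, name, chrom, start, end))
    if not rows:
        logger.warning("panel file %s is empty", path)
        return PanelDesign(
            pd.DataFrame(columns=["gene", "exon_id", "chrom", "start", "end"])
        )
    df = pd.DataFrame(rows, columns=["gene", "exon_id", "chrom", "start", "end"])
    df = df.sort_values(
        ["chrom", "start"], key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return PanelDesign(df)


def write_panel(panel: PanelDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in panel.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.exon_id}\n")


def _data_path(name: str):
    return importlib.resources.files("nbpanel.data").joinpath(name)


def default_panel() -> PanelDesign:
    """The packaged 83-gene panel (illustrative exon structures)."""
    with importlib.resources.as_file(_data_path("default_panel.bed")) as p:
        return read_panel(p)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All numeric thresholds of the analysis, with sensible defaults."""

    vaf_germline_cut: float = 0.97
    popdb_cut: float = 0.01
    pon_cut: float = 0.03
    pon_n: int = 480
    loss_below: float = 1.0
    gain_above: float = 4.0
    fish_fold: float = 10.0
    horizon_months: float = 36.0
    seed: int = 0
    min_callers: int = 1
    strand_bias_p: float = 0.001
    strand_bias_frac: float = 0.95
    cluster_count: int = 3
    cluster_window: int = 10
    purity_grid_start: float = 0.05
    purity_grid_stop: float = 1.0
    purity_grid_step: float = 0.01

    def __post_init__(self) -> None:
        for name in ("vaf_germline_cut", "popdb_cut", "pon_cut", "strand_bias_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.loss_below >= self.gain_above:
            raise ValueError("loss_below must be < gain_above")
        if self.pon_n <= 0:
            raise ValueError("pon_n must be positive")
        if self.fish_fold <= 0:
            raise ValueError("fish_fold must be positive")

    @property
    def purity_grid(self) -> np.ndarray:
        n = int(round((self.purity_grid_stop - self.purity_grid_start) / self.purity_grid_step))
        return self.purity_grid_start + self.purity_grid_step * np.arange(n + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def default(cls) -> "PipelineConfig":
        with importlib.resources.as_file(_data_path("default_config.yaml")) as p:
            return cls.from_yaml(p)


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------


def _variant_from_row(row: Mapping, caller_name: str, sample_id: str | None):
    from .variant_filter import VariantCall

    af = row.get("allele_fraction")
    if af is None or (isinstance(af, float) and np.isnan(af)):
        raise VariantTableError("missing allele fraction")

    def _int_or_none(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == ".":
            return None
        return int(v)

    def _str_or_none(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v in (".", ""):
            return None
        return str(v)

    return VariantCall(
        sample_id=sample_id,
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        allele_fraction=float(af),
        alt_forward=_int_or_none(row.get("alt_forward")),
        alt_reverse=_int_or_none(row.get("alt_reverse")),
        callers={caller_name},
        gene=_str_or_none(row.get("gene")),
        protein_change=_str_or_none(row.get("protein_change")),
        effect=_str_or_none(row.get("effect")),
    )


def read_variant_table(path: str | Path, caller_name: str) -> list:
    """Read a variant table (VCF 4.2 or TSV) into :class:`VariantCall` records.

    Records without an allele fraction are skipped with a logged error;
    positions stay 1-based.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path, caller_name)
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing columns {missing}")
    sample_col = "sample_id" if "sample_id" in df.columns else None
    calls, n_skipped = [], 0
    for _, row in df.iterrows():
        rec = row.to_dict()
        try:
            calls.append(
                _variant_from_row(rec, caller_name, rec.get(sample_col) if sample_col else None)
            )
        except VariantTableError as exc:
            n_skipped += 1
            logger.error("%s: skipped %s:%s %s", path, rec.get("chrom"), rec.get("pos"), exc)
    if n_skipped:
        logger.warning("%s: skipped %d record(s) with missing fields", path, n_skipped)
    return calls


def _read_vcf(path: Path, caller_name: str) -> list:
    calls, n_skipped = [], 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VariantTableError(f"{path}: VCF row with < 8 columns")
            chrom, pos, _, ref, alt, _, _, info = fields[:8]
            kv = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
            row = {
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
                "allele_fraction": float(kv["AF"]) if "AF" in kv else None,
                "alt_forward": kv.get("SAF"),
                "alt_reverse": kv.get("SAR"),
                "gene": kv.get("GENE"),
                "protein_change": kv.get("PCHANGE"),
                "sample_id": kv.get("SAMPLE"),
            }
            try:
                calls.append(_variant_from_row(row, caller_name, row.get("sample_id")))
            except VariantTableError as exc:
                n_skipped += 1
                logger.error("%s: skipped %s:%s %s", path, chrom, pos, exc)
    if n_skipped:
        logger.warning("%s: skipped %d record(s) with missing AF", path, n_skipped)
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">
##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alt reads on forward strand">
##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alt reads on reverse strand">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variant_table(calls: Iterable, path: str | Path) -> None:
    """Write calls as TSV or VCF 4.2 (chosen by file suffix)."""
    path = Path(path)
    calls = list(calls)
    if path.suffix.lower() == ".vcf":
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for c in calls:
                info = [f"AF={c.allele_fraction:.6g}"]
                if c.alt_forward is not None:
                    info.append(f"SAF={c.alt_forward}")
                if c.alt_reverse is not None:
                    info.append(f"SAR={c.alt_reverse}")
                if c.gene:
                    info.append(f"GENE={c.gene}")
                if c.protein_change:
                    info.append(f"PCHANGE={c.protein_change}")
                if c.sample_id:
                    info.append(f"SAMPLE={c.sample_id}")
                flt = c.reason if c.filter_status == "removed" else "PASS"
                fh.write(
                    f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{flt}\t{';'.join(info)}\n"
                )
        return
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id if c.sample_id else ".",
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "allele_fraction": f"{c.allele_fraction:.6g}",
                "alt_forward": c.alt_forward if c.alt_forward is not None else ".",
                "alt_reverse": c.alt_reverse if c.alt_reverse is not None else ".",
                "gene": c.gene or ".",
                "protein_change": c.protein_change or ".",
                "effect": c.effect or ".",
                "callers": ",".join(sorted(c.callers)),
                "filter_status": c.filter_status,
                "reason": c.reason or ".",
            }
        )
    pd.DataFrame(rows, columns=list(rows[0]) if rows else _VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Coverage / BAF / FISH / clinical tables
# ---------------------------------------------------------------------------


def read_coverage_table(path: str | Path):
    """TSV with columns exon_id, mean_coverage (one sample)."""
    from .cnv_purity import CoverageProfile

    df = pd.read_csv(path, sep="\t")
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else Path(path).stem
    cov = pd.Series(df["mean_coverage"].values, index=df["exon_id"].values, dtype=float)
    return CoverageProfile(sample_id=sample_id, coverage=cov)


def write_coverage_table(profile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": profile.sample_id,
            "exon_id": profile.coverage.index,
            "mean_coverage": profile.coverage.values,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_baf_table(path: str | Path) -> list:
    """TSV with columns chrom, pos, ref_count, alt_count."""
    from .cnv_purity import BafObservation

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        BafObservation(
            chrom=str(r.chrom), pos=int(r.pos), ref_count=int(r.ref_count), alt_count=int(r.alt_count)
        )
        for r in df.itertuples(index=False)
    ]


def write_baf_table(bafs: Iterable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": b.chrom, "pos": b.pos, "ref_count": b.ref_count, "alt_count": b.alt_count}
            for b in bafs
        ],
        columns=["chrom", "pos", "ref_count", "alt_count"],
    ).to_csv(path, sep="\t", index=False)


def read_reference_table(path: str | Path):
    from .cnv_purity import ReferenceProfile

    df = pd.read_csv(path, sep="\t")
    return ReferenceProfile(
        values=pd.Series(df["reference"].values, index=df["exon_id"].values, dtype=float)
    )


def write_reference_table(reference, path: str | Path) -> None:
    pd.DataFrame({"exon_id": reference.values.index, "reference": reference.values.values}).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_fish_table(path: str | Path) -> dict:
    """CSV: sample_id, nucleus_index, mycn_signals, cep2_signals -> FishCount per sample."""
    from .fish_mycn import FishCount

    df = pd.read_csv(path)
    out = {}
    for sample_id, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("nucleus_index")
        out[str(sample_id)] = FishCount(
            sample_id=str(sample_id),
            mycn_signals=sub["mycn_signals"].to_numpy(int),
            cep2_signals=sub["cep2_signals"].to_numpy(int),
        )
    return out


def write_fish_table(counts: Iterable, path: str | Path) -> None:
    rows = []
    for fc in counts:
        for i, (m, c) in enumerate(zip(fc.mycn_signals, fc.cep2_signals)):
            rows.append(
                {"sample_id": fc.sample_id, "nucleus_index": i, "mycn_signals": m, "cep2_signals": c}
            )
    pd.DataFrame(rows, columns=["sample_id", "nucleus_index", "mycn_signals", "cep2_signals"]).to_csv(
        path, index=False
    )


def read_clinical_table(path: str | Path) -> list:
    from .cohort_survival import PatientRecord

    df = pd.read_csv(path)
    return [
        PatientRecord(
            patient_id=str(r.patient_id),
            risk_group=str(r.risk_group),
            mycn_amplified=bool(r.mycn_amplified),
            rfs_time=float(r.rfs_time),
            rfs_event=int(r.rfs_event),
            os_time=float(r.os_time),
            os_event=int(r.os_event),
        )
        for r in df.itertuples(index=False)
    ]


def write_clinical_table(patients: Iterable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "risk_group": p.risk_group,
                "mycn_amplified": p.mycn_amplified,
                "rfs_time": f"{p.rfs_time:.6g}",
                "rfs_event": p.rfs_event,
                "os_time": f"{p.os_time:.6g}",
                "os_event": p.os_event,
            }
            for p in patients
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def write_report(results, out_dir: str | Path) -> None:
    """Write the cohort analysis report.

    Emits the alteration matrix, prevalence and actionability tables (TSV),
    a survival summary (JSON) and a run log echoing the config and seed.
    Output is deterministic: same inputs give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = results.matrix.sort_index()
    matrix = matrix[sorted(matrix.columns)]
    matrix.to_csv(out / "alteration_matrix.tsv", sep="\t", index_label="patient_id")

    results.prevalence.to_csv(out / "prevalence.tsv", sep="\t", index=False)

    act = results.actionability
    act = act.sort_values(list(act.columns)).reset_index(drop=True) if len(act) else act
    act.to_csv(out / "actionability.tsv", sep="\t", index=False)

    with open(out / "survival_summary.json", "w") as fh:
        json.dump(results.survival_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"seed: {results.seed}\n")
        fh.write("config:\n")
        for k, v in sorted(dataclasses.asdict(results.config).items()):
            fh.write(f"  {k}: {v}\n")
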