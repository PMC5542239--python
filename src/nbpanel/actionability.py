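"""Patient x gene alteration matrix and molecular-target classification."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd
import yaml

CELL_VALUES = ("none", "snv_indel", "cn_gain", "cn_loss", "both")


class CohortConsistencyError(ValueError):
    """Calls refer to a patient absent from the cohort."""


@dataclass(frozen=True)
class ActionabilityRule:
    """One drug-matching trigger for a gene."""

    gene: str
    trigger: str  # protein_change | truncating | cn_gain | cn_loss | exon_skip
    therapy_class: str
    changes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.trigger not in ("protein_change", "truncating", "cn_gain", "cn_loss", "exon_skip"):
            raise ValueError(f"unknown trigger {self.trigger!r}")
        if self.trigger == "protein_change" and not self.changes:
            raise ValueError("protein_change trigger needs a non-empty change list")


def load_rules(path=None) -> list[ActionabilityRule]:
    """Load the rule set (packaged default when no path is given)."""
    if path is None:
        res = importlib.resources.files("nbpanel.data").joinpath("actionability_rules.yaml")
        with importlib.resources.as_file(res) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [
        ActionabilityRule(
            gene=r["gene"],
            trigger=r["trigger"],
            therapy_class=r["therapy_class"],
            changes=tuple(r.get("changes", ())),
        )
        for r in raw["rules"]
    ]


def build_alteration_matrix(
    somatic_calls: list,
    cnv_calls: dict,
    patient_ids: list[str],
    synonymous_effects: tuple[str, ...] = ("synonymous",),
) -> pd.DataFrame:
    """One cell per (patient, gene): none | snv_indel | cn_gain | cn_loss | both.

    Synonymous variants are excluded; a cell is ``both`` when a patient has a
    sequence alteration and a copy-number change in the same gene. Multiple
    variants in one gene still occupy a single cell (prevalence counts
    patients, not variants).

    ``cnv_calls`` maps patient id -> list of CopyNumberCall.
    """
    genes: set[str] = set()
    snv: dict[tuple[str, str], bool] = {}
    cn: dict[tuple[str, str], str] = {}

    known = set(patient_ids)
    for call in somatic_calls:
        if call.sample_id not in known:
            raise CohortConsistencyError(f"call for unknown patient {call.sample_id!r}")
        if call.gene is None or call.effect in synonymous_effects:
            continue
        genes.add(call.gene)
        snv[(call.sample_id, call.gene)] = True
    for pid, calls in cnv_calls.items():
        if pid not in known:
            raise CohortConsistencyError(f"CNV calls for unknown patient {pid!r}")
        for c in calls:
            if c.cn_class in ("gain", "loss"):
                genes.add(c.gene)
                cn[(pid, c.gene)] = f"cn_{c.cn_class}"

    matrix = pd.DataFrame("none", index=list(patient_ids), columns=sorted(genes), dtype=object)
    for (pid, gene) in snv:
        matrix.loc[pid, gene] = "snv_indel"
    for (pid, gene), kind in cn.items():
        matrix.loc[pid, gene] = "both" if snv.get((pid, gene)) else kind
    return matrix


def classify_actionable(
    matrix: pd.DataFrame,
    somatic_calls: list,
    cnv_calls: dict,
    rules: list[ActionabilityRule],
) -> pd.DataFrame:
    """Apply the drug-matching rules; one row per fired (patient, gene, rule).

    Candidacy is deduplicated per (patient, therapy class): a patient whose
    alterations fire two rules with the same therapy class is listed once
    for that class (first firing gene kept, genes sorted).
    """
    calls_by_patient: dict[str, list] = {}
    for c in somatic_calls:
        calls_by_patient.setdefault(c.sample_id, []).append(c)

    fired: list[dict] = []
    for pid in matrix.index:
        seen_therapies: set[str] = set()
        p_calls = sorted(calls_by_patient.get(pid, []), key=lambda c: (c.gene or "", c.pos))
        p_cnv = {c.gene: c.cn_class for c in cnv_calls.get(pid, [])}
        for rule in rules:
            if rule.therapy_class in seen_therapies:
                continue
            hit = None
            if rule.trigger in ("cn_gain", "cn_loss"):
                if p_cnv.get(rule.gene) == rule.trigger.removeprefix("cn_"):
                    hit = rule.trigger
            else:
                for c in p_calls:
                    if c.gene != rule.gene or c.filter_status != "pass":
                        continue
                    if rule.trigger == "protein_change" and c.protein_change in rule.changes:
                        hit = c.protein_change
                    elif rule.trigger == "truncating" and c.is_truncating:
                        hit = f"truncating:{c.protein_change or c.effect}"
                    elif rule.trigger == "exon_skip" and c.exon_skip:
                        hit = "exon_skip"
                    if hit:
                        break
            if hit:
                seen_therapies.add(rule.therapy_class)
                fired.append(
                    {
                        "patient_id": pid,
                        "gene": rule.gene,
                        "trigger": hit,
                        "therapy_class": rule.therapy_class,
                    }
                )
    return pd.DataFrame(fired, columns=["patient_id", "gene", "trigger", "therapy_class"])


def candidate_fraction(actionable: pd.DataFrame, n_patients: int) -> float:
    if n_patients == 0:
        raise ValueError("empty cohort")
    return actionable["patient_id"].nunique() / n_patients
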