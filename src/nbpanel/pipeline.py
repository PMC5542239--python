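"""End-to-end orchestration: simulation -> filtering -> CNV -> cohort stats."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import actionability as act
from . import cohort_survival as surv
from .cnv_purity import (
    call_copy_number,
    estimate_purity,
    make_reference,
    normalize_coverage,
)
from .fish_mycn import score_mycn
from .panel_io import PanelDesign, PipelineConfig, default_panel
from .synthetic_cohort import (
    CohortConfig,
    child_rng,
    generate_cohort,
    simulate_caller_outputs,
    simulate_coverage,
    simulate_fish_counts,
    simulate_normals,
)
from .variant_filter import (
    annotate_effects,
    annotation_lookup,
    filter_artifacts,
    filter_germline,
    load_default_annotation,
    load_default_resources,
    merge_callers,
)


@dataclass
class CohortResult:
    config: PipelineConfig
    seed: int
    patients: list
    somatic_calls: list
    removed_calls: list
    cnv_calls: dict  # patient_id -> list[CopyNumberCall]
    purity: dict  # patient_id -> PuritySolution
    fish: dict  # patient_id -> (ratio, amplified)
    matrix: pd.DataFrame = field(default=None)
    prevalence: pd.DataFrame = field(default=None)
    actionability: pd.DataFrame = field(default=None)
    survival_summary: dict = field(default_factory=dict)


def run_synthetic_cohort(
    cohort_config: CohortConfig,
    pipeline_config: PipelineConfig | None = None,
    seed: int | None = None,
    panel: PanelDesign | None = None,
    reference=None,
    resources=None,
    annotation=None,
    rules=None,
    cnv_event_classes_only: bool = True,
    with_survival_summary: bool = True,
) -> CohortResult:
    """Simulate a cohort and push every sample through the full analysis.

    Variant route: per-caller call lists are merged, annotated, artifact- and
    germline-filtered. CNV route: simulated exon coverage and BAFs are
    reference-normalized, purity is grid-estimated per sample and per-gene
    copy numbers are classified. FISH counts give MYCN status (overriding
    the simulated clinical flag with the scored one).
    """
    if pipeline_config is None:
        pipeline_config = PipelineConfig.default()
    if panel is None:
        panel = default_panel()
    if seed is None:
        seed = cohort_config.seed

    cohort = generate_cohort(cohort_config, seed=seed, panel=panel)
    if resources is None:
        resources = load_default_resources(pon_n=pipeline_config.pon_n)
    if annotation is None:
        annotation = annotation_lookup(load_default_annotation())

    if reference is None:
        ref_rng = child_rng(seed, 100)
        reference = make_reference(
            simulate_normals(
                panel, cohort_config.depth_mean, cohort_config.depth_dispersion, ref_rng,
                n_samples=1 if cohort_config.depth_dispersion is None else 20,
            )
        )

    somatic_all, removed_all = [], []
    cnv_by_patient, purity_by_patient, fish_by_patient = {}, {}, {}
    grid = pipeline_config.purity_grid

    for k, patient in enumerate(cohort.patients):
        pid = patient.patient_id
        rng = child_rng(seed, 200, k)

        # --- variant route -------------------------------------------------
        truth_vars = cohort.variant_rows(pid)
        caller_calls, _ = simulate_caller_outputs(
            truth_vars,
            cohort_config.callers,
            panel,
            rng,
            sample_id=pid,
            depth_mean=cohort_config.depth_mean,
            germline_rate=cohort_config.germline_rate,
        )
        merged = merge_callers(list(caller_calls.values()))
        merged = [c for c in merged if len(c.callers) >= pipeline_config.min_callers]
        annotate_effects(merged, annotation, panel, resources.hotspots)
        kept, removed_artifacts = filter_artifacts(
            merged,
            p_cut=pipeline_config.strand_bias_p,
            frac_cut=pipeline_config.strand_bias_frac,
            cluster_count=pipeline_config.cluster_count,
            cluster_window=pipeline_config.cluster_window,
        )
        somatic, removed_germline = filter_germline(
            kept,
            resources,
            vaf_germline_cut=pipeline_config.vaf_germline_cut,
            popdb_cut=pipeline_config.popdb_cut,
            pon_cut=pipeline_config.pon_cut,
        )
        somatic_all.extend(somatic)
        removed_all.extend(removed_artifacts + removed_germline)

        # --- CNV route -----------------------------------------------------
        profile, bafs = simulate_coverage(
            cohort.cn_by_gene(pid),
            cohort.purity[pid],
            panel,
            cohort_config.depth_mean,
            cohort_config.depth_dispersion,
            rng,
            sample_id=pid,
            baf_sites_per_gene=cohort_config.baf_sites_per_gene,
            gain_minor_copies=cohort_config.gain_minor_copies,
        )
        log2r = normalize_coverage(profile, reference)
        purity = estimate_purity(log2r, bafs, panel, grid=grid)
        cnv = call_copy_number(
            log2r, purity, panel,
            loss_below=pipeline_config.loss_below,
            gain_above=pipeline_config.gain_above,
        )
        if cnv_event_classes_only:
            cnv = [c for c in cnv if c.cn_class != "neutral"]
        purity_by_patient[pid] = purity
        cnv_by_patient[pid] = cnv

        # --- FISH ----------------------------------------------------------
        counts = simulate_fish_counts(patient.mycn_amplified, rng, sample_id=pid)
        fish_by_patient[pid] = score_mycn(counts, fold_threshold=pipeline_config.fish_fold)

    patient_ids = [p.patient_id for p in cohort.patients]
    matrix = act.build_alteration_matrix(somatic_all, cnv_by_patient, patient_ids)
    if rules is None:
        rules = act.load_rules()
    actionable = act.classify_actionable(matrix, somatic_all, cnv_by_patient, rules)
    prevalence = surv.prevalence_table(matrix) if len(matrix.columns) else pd.DataFrame(
        columns=["gene", "n_altered", "n_patients", "fraction", "percent"]
    )

    scored_patients = [
        surv.PatientRecord(
            patient_id=p.patient_id,
            risk_group=p.risk_group,
            mycn_amplified=fish_by_patient[p.patient_id][1],
            rfs_time=p.rfs_time,
            rfs_event=p.rfs_event,
            os_time=p.os_time,
            os_event=p.os_event,
        )
        for p in cohort.patients
    ]
    summary = {}
    if with_survival_summary:
        summary = {
            "os_high_risk": surv.stratify_and_summarize(
                scored_patients, matrix, horizon=pipeline_config.horizon_months,
                endpoint="os", high_risk_only=True,
            ),
            "rfs_all": surv.stratify_and_summarize(
                scored_patients, matrix, horizon=pipeline_config.horizon_months,
                endpoint="rfs", high_risk_only=False,
            ),
        }

    return CohortResult(
        config=pipeline_config,
        seed=seed,
        patients=scored_patients,
        somatic_calls=somatic_all,
        removed_calls=removed_all,
        cnv_calls=cnv_by_patient,
        purity=purity_by_patient,
        fish=fish_by_patient,
        matrix=matrix,
        prevalence=prevalence,
        actionability=actionable,
        survival_summary=summary,
    )
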