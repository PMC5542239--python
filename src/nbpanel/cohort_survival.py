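"""Prevalence, Kaplan-Meier, log-rank and mutual-exclusivity statistics.

Conventions: times are in months; at tied times events precede censorings
(standard product-limit convention). The +/- reported with survival
estimates is the Greenwood standard error of the KM estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and survival endpoints for one patient."""

    patient_id: str
    risk_group: str  # "high" | "non-high"
    mycn_amplified: bool
    rfs_time: float
    rfs_event: int
    os_time: float
    os_event: int

    def __post_init__(self) -> None:
        for t in (self.rfs_time, self.os_time):
            if t < 0:
                raise ValueError("survival times must be non-negative")
        for e in (self.rfs_event, self.os_event):
            if e not in (0, 1):
                raise ValueError("event indicators must be 0/1")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with Greenwood standard errors."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) immediately after each event time
    se: np.ndarray  # Greenwood SE of S(t)
    n_risk: np.ndarray  # at risk just before each event time
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def se_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.se[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator with Greenwood variance.

    ``events`` are 0/1 indicators; at tied times events are processed before
    censorings, which the risk-set definition (at risk = time >= t) encodes.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative survival time")

    event_times = np.unique(times[events == 1])
    surv, se, n_risk, n_ev = [], [], [], []
    s = 1.0
    gw = 0.0  # running Greenwood sum d / (n (n - d))
    for t in event_times:
        n = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= (n - d) / n
        if n - d > 0:
            gw += d / (n * (n - d))
            se_t = s * np.sqrt(gw)
        else:
            se_t = 0.0  # S hit zero; variance degenerate
        surv.append(s)
        se.append(se_t)
        n_risk.append(n)
        n_ev.append(d)
    return SurvivalCurve(
        times=event_times,
        survival=np.asarray(surv),
        se=np.asarray(se),
        n_risk=np.asarray(n_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
    )


def logrank_test(groups, times, events) -> tuple[float, int, float]:
    """G-sample log-rank test; returns (chi-square, df, p).

    Observed-minus-expected event counts per group are compared using the
    hypergeometric covariance at each distinct event time; the statistic is
    the quadratic form over the first G-1 groups.
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.unique(groups)
    G = len(labels)
    if G < 2:
        raise ValueError("need at least two groups")
    for g in labels:
        if np.sum(groups == g) == 0:
            raise ValueError(f"empty group {g!r}")

    o_minus_e = np.zeros(G)
    cov = np.zeros((G, G))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int(((times == t) & (events == 1)).sum())
        n_g = np.array([int((at_risk & (groups == g)).sum()) for g in labels], dtype=float)
        d_g = np.array(
            [int(((times == t) & (events == 1) & (groups == g)).sum()) for g in labels],
            dtype=float,
        )
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        if n > 1:
            factor = d * (n - d) / (n - 1)
            cov += factor * (np.diag(n_g) / n - np.outer(n_g, n_g) / n**2)

    v = o_minus_e[:-1]
    V = cov[:-1, :-1]
    if np.allclose(v, 0.0):
        chi2 = 0.0
    else:
        chi2 = float(v @ np.linalg.pinv(V) @ v)
    df = G - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def prevalence_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene altered-patient counts and fractions from the cell matrix.

    A patient counts once per gene regardless of how many alterations they
    carry. Columns: gene, n_altered, n_patients, fraction, percent (one
    decimal, matching conventional reporting).
    """
    if len(matrix) == 0:
        raise ValueError("empty cohort")
    n = len(matrix)
    rows = []
    for gene in sorted(matrix.columns):
        altered = int((matrix[gene] != "none").sum())
        frac = altered / n
        rows.append(
            {
                "gene": gene,
                "n_altered": altered,
                "n_patients": n,
                "fraction": frac,
                "percent": round(100.0 * frac, 1),
            }
        )
    return pd.DataFrame(rows)


def mutual_exclusivity(
    matrix: pd.DataFrame, gene_set_a: list[str], status_b: pd.Series
) -> tuple[int, float]:
    """Overlap of A-altered and B-positive patients with a Fisher exact p.

    ``status_b`` is a boolean Series indexed by patient id (e.g. MYCN FISH
    amplification). The two-sided Fisher p is descriptive only.
    """
    present = [g for g in gene_set_a if g in matrix.columns]
    a_altered = (matrix[present] != "none").any(axis=1) if present else pd.Series(
        False, index=matrix.index
    )
    b = status_b.reindex(matrix.index).fillna(False).astype(bool)
    overlap = int((a_altered & b).sum())
    table = [
        [overlap, int((a_altered & ~b).sum())],
        [int((~a_altered & b).sum()), int((~a_altered & ~b).sum())],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return overlap, float(p)


def _stratum_of(patient: PatientRecord, arid1b_altered: bool) -> str:
    if arid1b_altered:
        return "arid1b"
    if patient.mycn_amplified:
        return "mycn"
    return "neither"


def stratify_and_summarize(
    patients: list[PatientRecord],
    matrix: pd.DataFrame,
    horizon: float = 36.0,
    endpoint: str = "os",
    high_risk_only: bool = False,
    gene: str = "ARID1B",
) -> dict:
    """Three-stratum survival summary: gene-altered, MYCN-amplified, neither.

    A gene-altered patient stays in the gene stratum even if also
    MYCN-amplified (gene takes precedence). Also reports the two-group
    altered-vs-wild-type comparison. Empty strata appear with n=0 and null
    estimates rather than raising.
    """
    if endpoint not in ("os", "rfs"):
        raise ValueError("endpoint must be 'os' or 'rfs'")
    if high_risk_only:
        patients = [p for p in patients if p.risk_group == "high"]

    altered = {
        pid: (gene in matrix.columns and matrix.loc[pid, gene] != "none")
        for pid in matrix.index
    }
    time_of = (lambda p: p.os_time) if endpoint == "os" else (lambda p: p.rfs_time)
    event_of = (lambda p: p.os_event) if endpoint == "os" else (lambda p: p.rfs_event)

    strata: dict[str, list[PatientRecord]] = {"arid1b": [], "mycn": [], "neither": []}
    for p in patients:
        strata[_stratum_of(p, altered.get(p.patient_id, False))].append(p)

    summary: dict = {"endpoint": endpoint, "horizon": horizon, "strata": {}, "gene": gene}
    for name, members in strata.items():
        entry: dict = {"n": len(members)}
        if members:
            curve = km_estimate([time_of(p) for p in members], [event_of(p) for p in members])
            entry["survival_at_horizon"] = curve.survival_at(horizon)
            entry["se_at_horizon"] = curve.se_at(horizon)
        else:
            entry["survival_at_horizon"] = None
            entry["se_at_horizon"] = None
        summary["strata"][name] = entry

    non_empty = [name for name, m in strata.items() if m]
    if len(non_empty) >= 2:
        labels, t, e = [], [], []
        for name in non_empty:
            for p in strata[name]:
                labels.append(name)
                t.append(time_of(p))
                e.append(event_of(p))
        chi2, df, pval = logrank_test(labels, t, e)
        summary["logrank"] = {"chi2": chi2, "df": df, "p": pval}
        pairwise = {}
        for i in range(len(non_empty)):
            for j in range(i + 1, len(non_empty)):
                a, b = non_empty[i], non_empty[j]
                lab, tt, ee = [], [], []
                for name in (a, b):
                    for p in strata[name]:
                        lab.append(name)
                        tt.append(time_of(p))
                        ee.append(event_of(p))
                c2, _, pv = logrank_test(lab, tt, ee)
                pairwise[f"{a}_vs_{b}"] = {"chi2": c2, "p": pv}
        summary["pairwise_logrank"] = pairwise
    else:
        summary["logrank"] = None
        summary["pairwise_logrank"] = {}

    # two-group altered vs wild-type split
    two = {"altered": [], "wildtype": []}
    for p in patients:
        two["altered" if altered.get(p.patient_id, False) else "wildtype"].append(p)
    two_summary = {}
    for name, members in two.items():
        entry = {"n": len(members)}
        if members:
            curve = km_estimate([time_of(p) for p in members], [event_of(p) for p in members])
            entry["survival_at_horizon"] = curve.survival_at(horizon)
            entry["se_at_horizon"] = curve.se_at(horizon)
        else:
            entry["survival_at_horizon"] = None
            entry["se_at_horizon"] = None
        two_summary[name] = entry
    if all(len(m) > 0 for m in two.values()):
        lab, tt, ee = [], [], []
        for name, members in two.items():
            for p in members:
                lab.append(name)
                tt.append(time_of(p))
                ee.append(event_of(p))
        c2, _, pv = logrank_test(lab, tt, ee)
        two_summary["logrank"] = {"chi2": c2, "p": pv}
    summary["two_group"] = two_summary
    return summary


def curve_table(curve: SurvivalCurve) -> pd.DataFrame:
    """Step-function table for plotting/export."""
    return pd.DataFrame(
        {
            "time": curve.times,
            "n_risk": curve.n_risk,
            "n_events": curve.n_events,
            "survival": curve.survival,
            "greenwood_se": curve.se,
        }
    )
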