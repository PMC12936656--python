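"""End-to-end orchestration: clean → classify → resolve → report → QC.

`run_resolve` ties the stages into the full workflow (registry-based
substance correction, optional refill-artifact suppression, small-group
policy, mode-table construction, per-record resolution) and produces the
per-group method-accounting report.  `run_adherence` derives supply events
from resolved prescriptions and computes yearly CMA5 plus the two-period
mean-DS and adherence-change summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .adherence import (AdherenceResult, PeriodSummary, events_from_results,
                        mean_ds_summary, period_change, yearly_adherence)
from .dose import FormClassifier, FormGroup, classify_form
from .model import (PackageRegistry, PrescriptionRecord,
                    correct_active_substance, flag_refill_ds_artifact)
from .resolve import (DSResult, FormRuleSet, Method, ModeTable,
                      build_mode_table, resolve_baseline, resolve_ds,
                      small_group_policy)


@dataclass
class RunReport:
    """Method accounting per form group: the audit trail of a resolve run."""

    counts: pd.DataFrame  # columns: form_group, method, count, group_percent
    n_input: int
    n_resolved: int
    n_unresolved: int
    warnings: list[str] = field(default_factory=list)

    @property
    def resolved_fraction(self) -> float:
        return self.n_resolved / self.n_input if self.n_input else 0.0

    def to_text(self) -> str:
        lines = [f"prescriptions: {self.n_input}  resolved: {self.n_resolved} "
                 f"({100 * self.resolved_fraction:.1f}%)  unresolved: {self.n_unresolved}"]
        for group, g in self.counts.groupby("form_group", sort=True):
            lines.append(f"\n{group} (n={int(g['count'].sum())})")
            for _, row in g.iterrows():
                lines.append(f"  {row['method']:<32} {int(row['count']):>8} "
                             f"({row['group_percent']:.2f}%)")
        if self.warnings:
            lines.append("\nwarnings:")
            lines.extend(f"  {w}" for w in self.warnings)
        return "\n".join(lines)


def build_run_report(results: Sequence[DSResult],
                     warnings: Iterable[str] = ()) -> RunReport:
    counter = Counter((r.form_group.value, r.method.value) for r in results)
    rows = []
    group_totals = Counter(r.form_group.value for r in results)
    for (group, method), n in sorted(counter.items()):
        rows.append({"form_group": group, "method": method, "count": n,
                     "group_percent": 100.0 * n / group_totals[group]})
    counts = pd.DataFrame(rows, columns=["form_group", "method", "count", "group_percent"])
    n_unresolved = sum(1 for r in results if not r.resolved)
    return RunReport(counts=counts, n_input=len(results),
                     n_resolved=len(results) - n_unresolved,
                     n_unresolved=n_unresolved, warnings=list(warnings))


def run_resolve(records: Sequence[PrescriptionRecord],
                registry: PackageRegistry | None = None,
                rules: FormRuleSet | None = None,
                classifier: FormClassifier | None = None,
                baseline: bool = False,
                refill_artifact_fix: bool = False,
                refill_artifact_days: int = 180,
                min_support: int = 1,
                small_group_threshold: int = 1000,
                rounding: str = "floor",
                dose_options: Mapping | None = None
                ) -> tuple[list[DSResult], RunReport]:
    """Resolve a batch of prescriptions and account for every record.

    Unresolved records are emitted and tagged, never dropped.
    """
    warnings: list[str] = []
    recs = list(records)
    if not recs:
        warnings.append("empty input: no prescriptions to resolve")

    if registry is not None:
        recs = [correct_active_substance(r, registry) for r in recs]
        n_fixed = sum(1 for r in recs
                      if any(n.startswith("SUBSTANCE_CORRECTED") for n in r.notes))
        if n_fixed:
            warnings.append(f"active substance corrected from package registry "
                            f"on {n_fixed} record(s)")

    if refill_artifact_fix:
        flags, recs = flag_refill_ds_artifact(
            recs, artifact_value=refill_artifact_days, suppress=True)
        n_flagged = sum(1 for f in flags if f.flagged)
        if n_flagged:
            warnings.append(f"refill-series DS artifact: provided DS suppressed "
                            f"on {n_flagged} record(s)")

    if baseline:
        results = [resolve_baseline(r, classifier=classifier, rounding=rounding,
                                    dose_options=dose_options) for r in recs]
        return results, build_run_report(results, warnings)

    provided_only = small_group_policy(recs, classifier, threshold=small_group_threshold)
    if provided_only:
        warnings.append("small-group policy (provided DS only) applied to: "
                        + ", ".join(sorted(g.value for g in provided_only)))

    single_dose = [r for r in recs
                   if classify_form(r, classifier).group is FormGroup.SINGLE_DOSE
                   and FormGroup.SINGLE_DOSE not in provided_only]
    table = build_mode_table(single_dose, min_support=min_support,
                             dose_options=dose_options)

    results = [resolve_ds(r, mode_table=table, rules=rules, classifier=classifier,
                          rounding=rounding, provided_only_groups=provided_only,
                          dose_options=dose_options)
               for r in recs]
    return results, build_run_report(results, warnings)


def results_to_frame(results: Sequence[DSResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "prescription_id": r.prescription_id,
        "form_group": r.form_group.value,
        "subgroup": r.subgroup.value if r.subgroup else "",
        "ds_days": r.ds_days if r.ds_days is not None else "",
        "method": r.method.value,
        "trace": r.detail,
    } for r in results])


def write_results(results: Sequence[DSResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


@dataclass
class AdherenceOutputs:
    adherence: list[AdherenceResult]
    mean_ds: list[PeriodSummary]
    change: pd.DataFrame

    def adherence_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "patient_id": a.patient_id, "medication_key": a.medication_key,
            "year": a.year, "cma5": a.cma5, "n_events": a.n_events,
            "window_start": a.window_start.isoformat(),
            "window_end": a.window_end.isoformat(),
        } for a in self.adherence])

    def mean_ds_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "atc_subgroup": s.atc_subgroup, "period": s.period,
            "mean_ds": s.mean_ds, "ci_low": s.ci_low, "ci_high": s.ci_high,
            "n": s.n, "band": s.band,
        } for s in self.mean_ds])


def run_adherence(records: Sequence[PrescriptionRecord],
                  results: Sequence[DSResult],
                  substances: Iterable[str],
                  periods: tuple[tuple[int, int], tuple[int, int]] = ((2012, 2015), (2017, 2019)),
                  exclude_years: Iterable[int] = (2016,)) -> AdherenceOutputs:
    """Yearly CMA5 plus the two-period QC summaries for chronic substances."""
    substances = list(substances)
    if not substances:
        raise ValueError("substances list must be non-empty")
    events = events_from_results(records, results, substances=substances)
    adherence = yearly_adherence(events)

    by_id = {r.prescription_id: r for r in records}
    rows = []
    for res in results:
        rec = by_id.get(res.prescription_id)
        if rec is None or res.ds_days is None:
            continue
        if rec.atc_code.strip().upper() not in {s.strip().upper() for s in substances}:
            continue
        rows.append({"atc_code": rec.atc_code, "year": rec.dispense_date.year,
                     "ds_days": res.ds_days})
    ds_table = pd.DataFrame(rows, columns=["atc_code", "year", "ds_days"])
    summaries = mean_ds_summary(ds_table, periods=periods, exclude_years=exclude_years)

    adherence_in_periods = [a for a in adherence
                            if a.year not in set(exclude_years)]
    change = period_change(adherence_in_periods, periods=periods)
    return AdherenceOutputs(adherence=adherence, mean_ds=summaries, change=change)


def read_substance_list(path: str | Path) -> list[str]:
    """Chronic-substance list: one ATC code per line; '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        code = line.split("#", 1)[0].strip()
        if code:
            out.append(code.upper())
    return out
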