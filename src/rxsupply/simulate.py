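"""Seeded synthetic prescription cohorts with known ground truth.

Real e-prescription extracts cannot be shared, so every pipeline stage is
exercised on generated cohorts that emulate their structure: refill streams
per patient and substance with inter-fill gaps drawn around the true days'
supply, heterogeneous dose-notation styles (unit counts, single-component
and summed-component substance amounts, volumes, drops), era-dependent
missingness (daily doses were largely absent before reporting became
mandatory in mid-2016, while prescriber-entered DS values grew more common
after), and the known error modes: same-day refill series stamped with the
combined 180-day course, and false active-substance entries recoverable
from the package registry.

The generator's defaults are the study conditions: 67.4% of pre-cutoff
quantitative-dose prescriptions lack the daily dose versus 0.4% after, and
15.2% versus 36.1% carry a provided DS.  Per-key daily-dose distributions
put 0.7 of the mass on the modal dose.  Fixed seed + fixed config give a
byte-identical cohort.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (DROPS, IU, MASS, UNIT, VOLUME, Component, PackageEntry,
                    PackageRegistry, PrescriptionRecord)
from .resolve import calculate_ds

WRONG_SUBSTANCE_NAME = "placebonium"


@dataclass(frozen=True)
class SubstanceSpec:
    """One synthetic substance: packaging, dosing distribution, usage style.

    ``dose_dist`` maps daily dose (in the substance's dosing unit: units,
    mL, or drops per day) to probability; ``None`` marks qualitative-dose
    forms where no quantitative daily dose is ever written.
    """

    name: str
    atc: str
    drug_form: str
    strengths: tuple[tuple[float, str], ...]  # (value, unit) per component
    units_per_package: int | None = None
    item_size: tuple[float, str] | None = None
    dose_dist: Mapping[float, float] | None = None
    dose_unit: str = UNIT  # unit | volume | drops
    imputed_ds: int | None = None  # ground-truth DS for qualitative forms
    chronic: bool = False
    weight: float = 1.0

    @property
    def package_id(self) -> str:
        return f"PKG-{self.name}"

    def components(self) -> tuple[Component, ...]:
        return tuple(Component(f"{self.name}", v, u) if len(self.strengths) == 1
                     else Component(f"{self.name}-{i}", v, u)
                     for i, (v, u) in enumerate(self.strengths, start=1))

    def modal_dose(self) -> float | None:
        if not self.dose_dist:
            return None
        return max(self.dose_dist.items(), key=lambda kv: (kv[1], -kv[0]))[0]


def _chronic_tablet(name: str, atc: str, strength: float,
                    dist: Mapping[float, float] | None = None) -> SubstanceSpec:
    return SubstanceSpec(name=name, atc=atc, drug_form="tablet",
                         strengths=((strength, MASS),), units_per_package=60,
                         dose_dist=dist or {1.0: 0.7, 2.0: 0.3},
                         chronic=True, weight=4.5)


DEFAULT_CATALOG: tuple[SubstanceSpec, ...] = (
    # chronic single-dose medications (the bulk of any dispensing dataset)
    _chronic_tablet("thyroxil", "H03AA01", 0.1),
    _chronic_tablet("cardiorel", "C01AA05", 0.25),
    _chronic_tablet("tensoprel", "C09AA02", 10.0),
    _chronic_tablet("betalolum", "C07AB02", 50.0),
    _chronic_tablet("lipidostat", "C10AA01", 20.0, {1.0: 0.7, 0.5: 0.3}),
    _chronic_tablet("glycephorm", "A10BA02", 500.0, {2.0: 0.7, 3.0: 0.3}),
    _chronic_tablet("neurontal", "N03AX12", 300.0, {3.0: 0.7, 2.0: 0.3}),
    _chronic_tablet("seroxil", "N06AB06", 20.0),
    _chronic_tablet("diurezid", "C03AA03", 25.0),
    # combination product: summed-mass notation becomes exercisable
    SubstanceSpec("duopril", "C09BA02", "tablet",
                  strengths=((5.0, MASS), (10.0, MASS)), units_per_package=60,
                  dose_dist={1.0: 0.7, 2.0: 0.3}, chronic=True, weight=4.5),
    # acute single-dose
    SubstanceSpec("amoxitab", "J01CA04", "tablet", ((500.0, MASS),),
                  units_per_package=20, dose_dist={2.0: 0.7, 3.0: 0.3}, weight=3.0),
    SubstanceSpec("analgin", "N02BE01", "tablet", ((500.0, MASS),),
                  units_per_package=20, dose_dist={3.0: 0.7, 2.0: 0.3}, weight=3.0),
    SubstanceSpec("suppofen", "M01AE01", "suppository", ((125.0, MASS),),
                  units_per_package=10, dose_dist={2.0: 0.7, 3.0: 0.3}, weight=2.0),
    # semisolid / qualitative-dose forms
    SubstanceSpec("dermacort", "D07AA02", "cream", ((10.0, MASS),),
                  item_size=(30.0, "g"), imputed_ds=30, weight=2.5),
    SubstanceSpec("dermagel", "M02AA15", "gel", ((50.0, MASS),),
                  item_size=(50.0, "g"), imputed_ds=30, weight=2.0),
    SubstanceSpec("onychix", "D01AE21", "medicinal nail polish", ((80.0, MASS),),
                  item_size=(3.0, "ml"), imputed_ds=210, weight=0.8),
    SubstanceSpec("otomycin", "S02AA01", "ear drops, solution", ((10.0, MASS),),
                  item_size=(10.0, "ml"), imputed_ds=7, weight=1.0),
    # eye drops: chronic multi-dose, anti-infective multi-dose, single-dose
    SubstanceSpec("timodrop", "S01ED01", "eye drops, solution", ((5.0, MASS),),
                  item_size=(5.0, "ml"), imputed_ds=30, chronic=True, weight=2.5),
    SubstanceSpec("ocumycin", "S01AA01", "eye drops, solution", ((3.0, MASS),),
                  item_size=(5.0, "ml"), imputed_ds=14, weight=1.5),
    SubstanceSpec("oculovis", "S01XA20", "eye drops, single-dose container",
                  ((0.5, MASS),), units_per_package=30,
                  dose_dist={3.0: 0.7, 4.0: 0.3}, weight=1.5),
    SubstanceSpec("pediadrop", "A07BA51", "oral drops, solution", ((15.0, MASS),),
                  item_size=(30.0, "ml"), dose_dist={20.0: 0.7, 40.0: 0.3},
                  dose_unit=DROPS, weight=1.5),
    SubstanceSpec("bronchodil", "R03AC02", "inhalation powder", ((0.2, MASS),),
                  units_per_package=60, dose_dist={2.0: 0.7, 1.0: 0.3},
                  chronic=True, weight=3.0),
    SubstanceSpec("rhinalin", "R01AA07", "nasal spray, solution", ((0.05, MASS),),
                  units_per_package=120, dose_dist={2.0: 0.7, 4.0: 0.3}, weight=1.5),
    SubstanceSpec("nasofungin", "R01AX91", "nasal spray, suspension", ((2.0, MASS),),
                  item_size=(10.0, "ml"), imputed_ds=7, weight=0.8),
    SubstanceSpec("tussinol", "R05CB02", "syrup", ((4.0, MASS),),
                  item_size=(200.0, "ml"), dose_dist={10.0: 0.7, 15.0: 0.3},
                  dose_unit=VOLUME, weight=1.5),
    SubstanceSpec("amoxisyrup", "J01CA91", "syrup", ((250.0, MASS),),
                  item_size=(100.0, "ml"), imputed_ds=14, weight=1.5),
    SubstanceSpec("estrapatch", "G03CA03", "transdermal patch", ((1.5, MASS),),
                  units_per_package=4, imputed_ds=7 * 4 + 7, weight=1.0),
    SubstanceSpec("fentapatch", "N02AB03", "transdermal patch", ((2.5, MASS),),
                  units_per_package=5, imputed_ds=3 * 5, weight=1.0),
    SubstanceSpec("nicoderm", "N07BA01", "transdermal patch", ((15.0, MASS),),
                  units_per_package=7, imputed_ds=7 * 7, weight=1.0),
    SubstanceSpec("vaginelle", "G02BB01", "vaginal delivery system", ((0.12, MASS),),
                  units_per_package=3, imputed_ds=90, weight=1.0),
    SubstanceSpec("gripavax", "J07BB02", "suspension for injection", ((15.0, MASS),),
                  units_per_package=1, imputed_ds=1, weight=1.2),
    SubstanceSpec("insupen", "A10AB05", "insulin injection pen", ((100.0, IU),),
                  units_per_package=5, item_size=(3.0, "ml"), imputed_ds=60,
                  chronic=True, weight=1.5),
    SubstanceSpec("miscellanium", "V03AB16", "solution for infusion", ((500.0, MASS),),
                  units_per_package=1, imputed_ds=10, weight=1.0),
)


@dataclass(frozen=True)
class Era:
    p_missing_daily_dose: float
    p_provided_ds: float


@dataclass
class CohortConfig:
    """Study conditions for a generated cohort."""

    n_patients: int = 200
    start_year: int = 2012
    end_year: int = 2019
    era_cutoff: dt.date = dt.date(2016, 7, 1)
    pre: Era = field(default_factory=lambda: Era(0.674, 0.152))
    post: Era = field(default_factory=lambda: Era(0.004, 0.361))
    notation_mix: dict[str, float] = field(default_factory=lambda: {
        "unit_count": 0.5, "single_mass": 0.25, "summed_mass": 0.25})
    p_week_notation: float = 0.1  # chance an integer daily frequency is written per week
    p_refill_artifact: float = 0.0
    p_wrong_substance: float = 0.0
    refill_artifact_days: int = 180
    drop_factor: float = 20.0
    seed: int = 0
    catalog: tuple[SubstanceSpec, ...] = DEFAULT_CATALOG
    max_substances_per_patient: int = 3

    def validate(self) -> None:
        for era in (self.pre, self.post):
            for p in (era.p_missing_daily_dose, era.p_provided_ds):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of range: {p}")
        for name, p in self.notation_mix.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"notation_mix[{name!r}] out of range: {p}")
        total = sum(self.notation_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"notation_mix must sum to 1, got {total}")
        for p in (self.p_refill_artifact, self.p_wrong_substance, self.p_week_notation):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range: {p}")
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")


@dataclass
class SimulatedCohort:
    records: list[PrescriptionRecord]
    registry: PackageRegistry
    ground_truth: pd.DataFrame  # indexed by prescription_id


def build_registry(catalog: Sequence[SubstanceSpec] = DEFAULT_CATALOG) -> PackageRegistry:
    reg = PackageRegistry()
    for spec in catalog:
        reg.add(PackageEntry(
            package_id=spec.package_id,
            components=spec.components(),
            drug_form=spec.drug_form,
            units_per_package=spec.units_per_package,
            item_size_value=spec.item_size[0] if spec.item_size else None,
            item_size_unit=spec.item_size[1] if spec.item_size else None,
        ))
    return reg


def _true_ds(spec: SubstanceSpec, daily_dose: float | None, n_packages: int,
             drop_factor: float) -> int:
    """Ground-truth DS consistent with the dispensed quantity (floor rule)."""
    if spec.dose_dist is None or daily_dose is None:
        base = spec.imputed_ds or 30
        # qualitative per-package conventions scale with the package count
        per_package = spec.imputed_ds is not None and spec.item_size is not None
        return base * n_packages if per_package else base
    if spec.dose_unit == UNIT:
        total = n_packages * (spec.units_per_package or 1)
        return calculate_ds(total, daily_dose)
    if spec.dose_unit == VOLUME:
        total = n_packages * spec.item_size[0]
        return calculate_ds(total, daily_dose)
    if spec.dose_unit == DROPS:
        total = n_packages * spec.item_size[0]
        return calculate_ds(total, daily_dose / drop_factor)
    raise ValueError(f"unknown dose unit {spec.dose_unit!r}")


def _dose_fields(spec: SubstanceSpec, daily_dose: float, notation: str,
                 weekly: bool) -> dict:
    """Express a true daily dose in one of the observed notation styles."""
    if spec.dose_unit == VOLUME:
        return dict(dose_times=1.0, dose_period="day",
                    dose_amount=daily_dose, dose_amount_unit=VOLUME)
    if spec.dose_unit == DROPS:
        return dict(dose_times=1.0, dose_period="day",
                    dose_amount=daily_dose, dose_amount_unit=DROPS)

    integral = float(daily_dose).is_integer() and daily_dose >= 1
    if notation in ("single_mass", "summed_mass") and integral:
        times = daily_dose
        if notation == "summed_mass" and len(spec.strengths) > 1:
            amount = sum(v for v, _ in spec.strengths)
        else:
            amount = max(v for v, _ in spec.strengths)
        unit = MASS
        per_dose = 1.0
    else:
        # unit-count: one administration of `daily_dose` units, or
        # `daily_dose` administrations of one unit
        times, per_dose = (daily_dose, 1.0) if integral else (1.0, daily_dose)
        amount = per_dose
        unit = UNIT
    if weekly and float(times).is_integer():
        return dict(dose_times=times * 7.0, dose_period="week",
                    dose_amount=amount, dose_amount_unit=unit)
    return dict(dose_times=times, dose_period="day",
                dose_amount=amount, dose_amount_unit=unit)


def generate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Generate a seeded cohort of refill streams with ground truth.

    Chronic substances produce continuous refill streams across the whole
    study window with inter-fill gaps drawn around the true DS; acute ones
    produce short bursts.  Era-dependent missingness is applied to the
    quantitative daily-dose fields and the provided DS.  Deterministic for
    a fixed seed and config.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    registry = build_registry(config.catalog)

    weights = np.array([s.weight for s in config.catalog], dtype=float)
    weights /= weights.sum()
    notations = list(config.notation_mix)
    notation_p = np.array([config.notation_mix[n] for n in notations])

    start = dt.date(config.start_year, 1, 1)
    end = dt.date(config.end_year, 12, 31)
    horizon = (end - start).days

    records: list[PrescriptionRecord] = []
    gt_rows: list[dict] = []
    rx_counter = 0

    for p_idx in range(config.n_patients):
        patient_id = f"P{p_idx:06d}"
        k = int(rng.integers(1, config.max_substances_per_patient + 1))
        spec_idx = rng.choice(len(config.catalog), size=k, replace=False, p=weights)
        for s_i in spec_idx:
            spec = config.catalog[int(s_i)]
            n_packages = 1

            def draw_dose() -> float | None:
                # the daily dose is drawn per dispensing (dose titration
                # between refills), so the per-record modal share of a key
                # equals the configured modal probability
                if spec.dose_dist is None:
                    return None
                doses = sorted(spec.dose_dist)
                probs = np.array([spec.dose_dist[d] for d in doses])
                return float(doses[int(rng.choice(len(doses), p=probs / probs.sum()))])

            typical_ds = _true_ds(spec, spec.modal_dose(), n_packages,
                                  config.drop_factor)
            fills: list[tuple[int, float | None, int]] = []  # (day, dose, ds)
            if spec.chronic:
                day = int(rng.integers(0, 180))
                while day <= horizon:
                    daily_dose = draw_dose()
                    true_ds = _true_ds(spec, daily_dose, n_packages, config.drop_factor)
                    fills.append((day, daily_dose, true_ds))
                    day += max(1, int(round(true_ds * rng.uniform(0.9, 1.2))))
            else:
                n_fills = int(rng.integers(1, 4))
                day = int(rng.integers(0, max(1, horizon - typical_ds * n_fills)))
                for _ in range(n_fills):
                    if day > horizon:
                        break
                    daily_dose = draw_dose()
                    true_ds = _true_ds(spec, daily_dose, n_packages, config.drop_factor)
                    fills.append((day, daily_dose, true_ds))
                    day += max(1, int(round(true_ds * rng.uniform(0.9, 1.5))))

            for day, daily_dose, true_ds in fills:
                issue = start + dt.timedelta(days=day)
                dispense = issue + dt.timedelta(days=int(rng.integers(0, 4)))
                era = config.pre if dispense < config.era_cutoff else config.post

                quantitative = spec.dose_dist is not None
                missing_dose = bool(rng.random() < era.p_missing_daily_dose)
                has_dose = quantitative and not missing_dose
                has_provided = bool(rng.random() < era.p_provided_ds)

                fields: dict = {}
                if has_dose:
                    notation = notations[int(rng.choice(len(notations), p=notation_p))]
                    weekly = bool(rng.random() < config.p_week_notation)
                    fields = _dose_fields(spec, daily_dose, notation, weekly)
                elif quantitative:
                    fields = dict(dose_free_text="use as directed")
                else:
                    fields = dict(dose_free_text="apply as directed")

                rx_counter += 1
                rx_id = f"RX{rx_counter:08d}"
                records.append(PrescriptionRecord(
                    patient_id=patient_id,
                    prescription_id=rx_id,
                    issue_date=issue,
                    dispense_date=dispense,
                    atc_code=spec.atc,
                    components=spec.components(),
                    drug_form=spec.drug_form,
                    package_id=spec.package_id,
                    n_packages=n_packages,
                    provided_ds=true_ds if has_provided else None,
                    units_per_package=spec.units_per_package,
                    item_size_value=spec.item_size[0] if spec.item_size else None,
                    item_size_unit=spec.item_size[1] if spec.item_size else None,
                    prescription_type="initial",
                    **fields,
                ))
                gt_rows.append(dict(
                    prescription_id=rx_id,
                    patient_id=patient_id,
                    substance=spec.name,
                    atc=spec.atc,
                    true_daily_dose=(daily_dose if quantitative else np.nan),
                    true_ds_days=true_ds,
                    is_modal=(quantitative and daily_dose == spec.modal_dose()),
                    dose_quantitative=quantitative,
                    missing_dose=(quantitative and not has_dose),
                    provided=has_provided,
                    era=("pre" if dispense < config.era_cutoff else "post"),
                    chronic=spec.chronic,
                    refill_artifact=False,
                    wrong_substance=False,
                ))

    ground_truth = pd.DataFrame(gt_rows).set_index("prescription_id")
    return SimulatedCohort(records=records, registry=registry, ground_truth=ground_truth)


def inject_errors(records: Sequence[PrescriptionRecord],
                  ground_truth: pd.DataFrame,
                  config: CohortConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[list[PrescriptionRecord], pd.DataFrame]:
    """Stamp known error modes onto a generated cohort.

    With probability ``p_refill_artifact``, a patient-substance stream with
    at least 3 fills gets its first three fills rewritten as a same-day
    refill series, each carrying the combined course length (provided DS =
    180 by default).  With probability ``p_wrong_substance`` a record's
    component names are falsified while the package registry keeps the
    truth, so :func:`rxsupply.model.correct_active_substance` can recover
    it.  Returns mutated copies; inputs are untouched.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    out = list(records)
    gt = ground_truth.copy()

    streams: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(out):
        streams.setdefault((r.patient_id, r.package_id), []).append(i)

    for key in sorted(streams):
        idx = streams[key]
        if len(idx) < 3:
            continue
        if rng.random() >= config.p_refill_artifact:
            continue
        trio = sorted(idx, key=lambda i: out[i].issue_date)[:3]
        anchor = out[trio[0]].issue_date
        for j in trio:
            r = out[j]
            out[j] = replace(
                r, issue_date=anchor,
                dispense_date=max(r.dispense_date, anchor),
                provided_ds=config.refill_artifact_days,
                prescription_type="refill")
            gt.loc[r.prescription_id, "refill_artifact"] = True

    for i, r in enumerate(out):
        if rng.random() >= config.p_wrong_substance:
            continue
        wrong = tuple(Component(WRONG_SUBSTANCE_NAME, c.strength_value, c.strength_unit)
                      for c in r.components)
        out[i] = replace(r, components=wrong)
        gt.loc[r.prescription_id, "wrong_substance"] = True

    return out, gt


# ---------------------------------------------------------------------------
# single-record construction helpers

_EXAMPLE_SPECS: dict[str, str] = {
    "tablet": "thyroxil",
    "combination_tablet": "duopril",
    "semisolid": "dermacort",
    "nail_polish": "onychix",
    "ear_drops": "otomycin",
    "eye_multi_dose": "timodrop",
    "eye_anti_infective": "ocumycin",
    "eye_single_dose": "oculovis",
    "oral_drops": "pediadrop",
    "inhalation": "bronchodil",
    "nasal_spray": "rhinalin",
    "nasal_antifungal": "nasofungin",
    "syrup": "tussinol",
    "syrup_antibiotic": "amoxisyrup",
    "patch_hormonal": "estrapatch",
    "patch_analgesic": "fentapatch",
    "patch_other": "nicoderm",
    "intravaginal": "vaginelle",
    "vaccine": "gripavax",
    "insulin": "insupen",
    "other": "miscellanium",
}


def example_prescription(kind: str,
                         issue_date: dt.date = dt.date(2018, 3, 1),
                         n_packages: int = 1,
                         units_per_package: int | None = None,
                         provided_ds: int | None = None,
                         dose_fields: Mapping | None = None,
                         prescription_id: str = "RX-EXAMPLE") -> PrescriptionRecord:
    """One minimal, fully-formed prescription of the requested kind.

    Daily-dose and provided-DS fields are absent unless supplied, which is
    the configuration the drug-form imputation rules are defined for.
    """
    spec_name = _EXAMPLE_SPECS[kind]
    spec = next(s for s in DEFAULT_CATALOG if s.name == spec_name)
    fields = dict(dose_fields or {})
    return PrescriptionRecord(
        patient_id="P-EXAMPLE",
        prescription_id=prescription_id,
        issue_date=issue_date,
        dispense_date=issue_date,
        atc_code=spec.atc,
        components=spec.components(),
        drug_form=spec.drug_form,
        package_id=spec.package_id,
        n_packages=n_packages,
        provided_ds=provided_ds,
        units_per_package=(units_per_package if units_per_package is not None
                           else spec.units_per_package),
        item_size_value=spec.item_size[0] if spec.item_size else None,
        item_size_unit=spec.item_size[1] if spec.item_size else None,
        **fields,
    )
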