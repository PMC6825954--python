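"""Body-size scaling of gait parameters.

Eleven walkway gait parameters (stride lengths, stand/swing/step-cycle
times, body speed and swing speeds) are scaled by dividing by a body-size
factor: silhouette length (cm), silhouette area (mm²), body weight (g) or
age (weeks).  Speed parameters additionally support dimensionless
Froude-style scaling, v / sqrt(g·l), with g = 981 cm/s² so that cm/s
speeds and cm lengths stay coherent.

Scaling is applied per run; run values are then averaged per animal and
age point (scaled-then-averaged, not averaged-then-scaled).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from statistics import fmean

import numpy as np
import pandas as pd

from .errors import AggregationError, MethodError, ParameterError, ScalingError, ValidationError

#: acceleration of gravity in cm/s² (9.81 m/s²), coherent with cm/s speeds
GRAVITY_CM_S2 = 981.0

#: the eleven gait parameters, in the order they are reported
PARAMETERS = (
    "stride_front",
    "stride_hind",
    "stand_front",
    "stand_hind",
    "swing_front",
    "swing_hind",
    "cycle_front",
    "cycle_hind",
    "body_speed",
    "swingspeed_front",
    "swingspeed_hind",
)

#: subset eligible for Froude-style scaling
SPEED_PARAMETERS = ("body_speed", "swingspeed_front", "swingspeed_hind")

SCALING_METHODS = ("length", "froude", "area", "weight", "age")

#: base units of the raw parameters
PARAMETER_UNITS = {
    "stride_front": "cm",
    "stride_hind": "cm",
    "stand_front": "s",
    "stand_hind": "s",
    "swing_front": "s",
    "swing_hind": "s",
    "cycle_front": "s",
    "cycle_hind": "s",
    "body_speed": "cm/s",
    "swingspeed_front": "cm/s",
    "swingspeed_hind": "cm/s",
}

_DENOM_UNIT = {"length": "cm", "area": "mm2", "weight": "g", "age": "week"}


def scaled_unit(parameter: str, method: str) -> str:
    """Unit bookkeeping, e.g. body speed scaled by length has unit 1/s."""
    base = PARAMETER_UNITS[parameter]
    if method == "froude":
        return "1"  # dimensionless
    denom = _DENOM_UNIT[method]
    if method == "length" and base == "cm":
        return "1"
    if method == "length" and base == "cm/s":
        return "1/s"
    return f"({base})/{denom}"


@dataclass(frozen=True)
class GaitRecord:
    """One run's gait parameters, left/right already averaged (body speed
    averaged over all four paws).  Units: cm, s, cm/s; weight in g."""

    animal_id: str
    genotype: str
    age: float
    run_id: str
    stride_front: float
    stride_hind: float
    stand_front: float
    stand_hind: float
    swing_front: float
    swing_hind: float
    cycle_front: float
    cycle_hind: float
    body_speed: float
    swingspeed_front: float
    swingspeed_hind: float
    weight: float | None = None


@dataclass(frozen=True)
class ScaledGaitRecord:
    """Gait parameters after scaling.  For the froude method only the speed
    slots are populated; the others are None."""

    animal_id: str
    genotype: str
    age: float
    run_id: str
    method: str
    denominator: float
    stride_front: float | None
    stride_hind: float | None
    stand_front: float | None
    stand_hind: float | None
    swing_front: float | None
    swing_hind: float | None
    cycle_front: float | None
    cycle_hind: float | None
    body_speed: float | None
    swingspeed_front: float | None
    swingspeed_hind: float | None
    gravity: float | None = None  # cm/s², set for froude


@dataclass(frozen=True)
class AnimalRecord:
    """Per-animal, per-age-point means over runs (raw or scaled)."""

    animal_id: str
    genotype: str
    age: float
    n_runs: int
    stride_front: float
    stride_hind: float
    stand_front: float
    stand_hind: float
    swing_front: float
    swing_hind: float
    cycle_front: float
    cycle_hind: float
    body_speed: float
    swingspeed_front: float
    swingspeed_hind: float
    l_sil_cm: float | None = None
    a_sil_mm2: float | None = None
    weight: float | None = None
    i_wsl: float | None = None
    scaling: str | None = None


def average_left_right(row) -> GaitRecord:
    """Collapse a raw gait-table row to one record: arithmetic mean of the
    left and right paw for each paired parameter, and of all four paws for
    body speed."""
    if hasattr(row, "to_dict"):
        row = row.to_dict()

    def get(col: str) -> float:
        if col not in row or pd.isna(row[col]):
            raise ValidationError(f"missing value for column {col!r}")
        return float(row[col])

    def pair(p: str, fh: str) -> float:
        return (get(f"{p}_{fh}_left") + get(f"{p}_{fh}_right")) / 2.0

    weight = row.get("weight")
    if weight is not None and pd.isna(weight):
        weight = None
    return GaitRecord(
        animal_id=str(row["animal_id"]),
        genotype=str(row["genotype"]),
        age=float(row["age"]),
        run_id=str(row["run_id"]),
        stride_front=pair("stride", "front"),
        stride_hind=pair("stride", "hind"),
        stand_front=pair("stand_time", "front"),
        stand_hind=pair("stand_time", "hind"),
        swing_front=pair("swing_time", "front"),
        swing_hind=pair("swing_time", "hind"),
        cycle_front=pair("step_cycle", "front"),
        cycle_hind=pair("step_cycle", "hind"),
        body_speed=fmean(get(f"body_speed_{p}") for p in ("rf", "lf", "rh", "lh")),
        swingspeed_front=pair("swing_speed", "front"),
        swingspeed_hind=pair("swing_speed", "hind"),
        weight=float(weight) if weight is not None else None,
    )


def scale_value(value: float, parameter: str, method: str, denominator: float) -> float:
    """Scale one parameter value.

    length/area/weight/age: value / denominator (denominator in cm, mm²,
    g or weeks respectively).  froude: value / sqrt(g·l) with the
    denominator interpreted as silhouette length in cm — valid only for
    speed parameters.
    """
    if method not in SCALING_METHODS:
        raise MethodError(f"unknown scaling method {method!r}")
    if not denominator > 0:
        raise ScalingError(f"scaling denominator must be > 0, got {denominator!r}")
    if method == "froude":
        if parameter not in SPEED_PARAMETERS:
            raise MethodError(
                f"froude scaling applies only to speed parameters, not {parameter!r}"
            )
        return value / np.sqrt(GRAVITY_CM_S2 * denominator)
    return value / denominator


def scale_record(rec: GaitRecord, method: str, denominator: float) -> ScaledGaitRecord:
    """Scale every applicable parameter of a run record by the given
    body-size denominator."""
    values: dict[str, float | None] = {}
    for p in PARAMETERS:
        if method == "froude" and p not in SPEED_PARAMETERS:
            values[p] = None
        else:
            values[p] = scale_value(getattr(rec, p), p, method, denominator)
    return ScaledGaitRecord(
        animal_id=rec.animal_id,
        genotype=rec.genotype,
        age=rec.age,
        run_id=rec.run_id,
        method=method,
        denominator=float(denominator),
        gravity=GRAVITY_CM_S2 if method == "froude" else None,
        **values,
    )


def weight_length_index(weight_g: float, l_sil_cm: float) -> float:
    """Body-condition index w / l², in g/cm² (BMI-like)."""
    if not weight_g > 0:
        raise ParameterError(f"weight must be > 0, got {weight_g!r}")
    if not l_sil_cm > 0:
        raise ParameterError(f"silhouette length must be > 0, got {l_sil_cm!r}")
    return weight_g / l_sil_cm**2


def _denominator_for(method: str, rec: GaitRecord, l_sil: float | None,
                     a_sil: float | None) -> float:
    if method in ("length", "froude"):
        if l_sil is None:
            raise ScalingError("silhouette length required for this method")
        return l_sil
    if method == "area":
        if a_sil is None:
            raise ScalingError("silhouette area required for area scaling")
        return a_sil
    if method == "weight":
        if rec.weight is None:
            raise ScalingError(f"run {rec.run_id}: weight required for weight scaling")
        return rec.weight
    if method == "age":
        return rec.age
    raise MethodError(f"unknown scaling method {method!r}")


def aggregate_animal(
    records: list[GaitRecord],
    lengths_cm: list[float] | None = None,
    areas_mm2: list[float] | None = None,
    scaling: str | None = None,
) -> AnimalRecord:
    """Average one animal's runs at one age point.

    With ``scaling`` set, each run is scaled first (by its own run-level
    denominator) and the scaled values are averaged — not the other way
    round.  Silhouette length/area and weight are averaged alongside, and
    the weight–silhouette-length index is derived from the animal means.
    """
    if not records:
        raise AggregationError("cannot aggregate zero runs")
    ids = {(r.animal_id, r.genotype, r.age) for r in records}
    if len(ids) > 1:
        raise AggregationError(f"records mix animals/age points: {sorted(ids)}")
    n = len(records)
    if lengths_cm is not None and len(lengths_cm) != n:
        raise AggregationError("lengths_cm must align with records")
    if areas_mm2 is not None and len(areas_mm2) != n:
        raise AggregationError("areas_mm2 must align with records")

    if scaling is None:
        per_run = [{p: getattr(r, p) for p in PARAMETERS} for r in records]
    else:
        per_run = []
        for i, r in enumerate(records):
            d = _denominator_for(
                scaling, r,
                lengths_cm[i] if lengths_cm is not None else None,
                areas_mm2[i] if areas_mm2 is not None else None,
            )
            sc = scale_record(r, scaling, d)
            per_run.append({p: getattr(sc, p) for p in PARAMETERS})

    means = {
        p: (fmean(run[p] for run in per_run)
            if per_run[0][p] is not None else float("nan"))
        for p in PARAMETERS
    }
    l_mean = fmean(lengths_cm) if lengths_cm is not None else None
    a_mean = fmean(areas_mm2) if areas_mm2 is not None else None
    weights = [r.weight for r in records if r.weight is not None]
    w_mean = fmean(weights) if weights else None
    i_wsl = (
        weight_length_index(w_mean, l_mean)
        if (w_mean is not None and l_mean is not None and w_mean > 0 and l_mean > 0)
        else None
    )
    r0 = records[0]
    return AnimalRecord(
        animal_id=r0.animal_id, genotype=r0.genotype, age=r0.age, n_runs=n,
        l_sil_cm=l_mean, a_sil_mm2=a_mean, weight=w_mean, i_wsl=i_wsl,
        scaling=scaling, **means,
    )


def build_animal_table(
    gait_df: pd.DataFrame,
    silhouettes: dict[str, dict] | None = None,
    scaling: str | None = None,
) -> pd.DataFrame:
    """Run-level raw gait table -> animal × age-point table.

    ``silhouettes`` maps run_id to a dict with ``silhouette_length_cm`` and
    optionally ``area_without_tail_mm2`` (the schema written by the
    extraction step); alternatively the gait table may carry ``l_sil_cm`` /
    ``a_sil_mm2`` columns directly.
    """
    rows = []
    for (animal, age), grp in gait_df.groupby(["animal_id", "age"], sort=True):
        records, lengths, areas = [], [], []
        for _, row in grp.iterrows():
            rec = average_left_right(row)
            records.append(rec)
            l = a = None
            if silhouettes is not None and str(row["run_id"]) in silhouettes:
                entry = silhouettes[str(row["run_id"])]
                l = entry.get("silhouette_length_cm")
                a = entry.get("area_without_tail_mm2")
            if l is None and "l_sil_cm" in row and not pd.isna(row["l_sil_cm"]):
                l = float(row["l_sil_cm"])
            if a is None and "a_sil_mm2" in row and not pd.isna(row["a_sil_mm2"]):
                a = float(row["a_sil_mm2"])
            lengths.append(l)
            areas.append(a)
        have_l = all(l is not None for l in lengths)
        have_a = all(a is not None for a in areas)
        if scaling in ("length", "froude") and not have_l:
            raise ScalingError(f"animal {animal} age {age}: missing silhouette length")
        if scaling == "area" and not have_a:
            raise ScalingError(f"animal {animal} age {age}: missing silhouette area")
        animal_rec = aggregate_animal(
            records,
            lengths_cm=lengths if have_l else None,
            areas_mm2=areas if have_a else None,
            scaling=scaling,
        )
        rows.append(animal_rec.__dict__ | {})
    df = pd.DataFrame(rows)
    return df.sort_values(["animal_id", "age"]).reset_index(drop=True)


def animal_record_fields() -> tuple[str, ...]:
    return tuple(f.name for f in fields(AnimalRecord))
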