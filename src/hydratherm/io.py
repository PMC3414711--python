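"""Plain-text (CSV) readers and writers for the pipeline's interchange formats.

ATD CSV:      species,temperature_K,water_pressure_mbar,time_us,counts
Series CSV:   temperature_K,K,sigma_K
Reduced CSV:  species,n,temperature_K,water_pressure_mbar,I_n,sigma_In,I_nm1,sigma_Inm1,eq_passed
Tautomer CSV: label,mia_kJmol,fraction
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .equilibrium import EquilibriumSeries, HydrationStepMeasurement
from .exceptions import DomainError
from .reduction import ATDRecord
from .tautomers import TautomerSet

ATD_HEADER = ["species", "temperature_K", "water_pressure_mbar", "time_us", "counts"]
SERIES_HEADER = ["temperature_K", "K", "sigma_K"]
REDUCED_HEADER = [
    "species", "n", "temperature_K", "water_pressure_mbar",
    "I_n", "sigma_In", "I_nm1", "sigma_Inm1", "eq_passed",
]
TAUTOMER_HEADER = ["label", "mia_kJmol", "fraction"]

_HYDRATION_RE = re.compile(r"\(H2O\)(\d+)\s*$")


def hydration_n_from_label(label: str) -> int:
    """Parse the trailing ``(H2O)n`` hydration count from a species label."""
    m = _HYDRATION_RE.search(label)
    return int(m.group(1)) if m else 0


def write_atd_csv(records: Iterable[ATDRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ATD_HEADER)
        for rec in records:
            for t, c in zip(rec.times, rec.counts):
                c_out = int(c) if float(c).is_integer() else repr(float(c))
                writer.writerow(
                    [rec.species_label, repr(rec.temperature),
                     repr(rec.water_pressure), repr(float(t)), c_out]
                )


def read_atd_csv(path: str | Path) -> list[ATDRecord]:
    """Read an ATD CSV, one record per (species, T, P) group, file order."""
    groups: dict[tuple[str, float, float], list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ATD_HEADER:
            raise DomainError(
                f"{path}: expected header {ATD_HEADER}, got {reader.fieldnames}"
            )
        for row in reader:
            key = (
                row["species"],
                float(row["temperature_K"]),
                float(row["water_pressure_mbar"]),
            )
            groups.setdefault(key, []).append(
                (float(row["time_us"]), float(row["counts"]))
            )
    records = []
    for (species, temp, pres), rows in groups.items():
        rows.sort(key=lambda r: r[0])
        arr = np.asarray(rows)
        records.append(
            ATDRecord(
                species_label=species,
                hydration_n=hydration_n_from_label(species),
                temperature=temp,
                water_pressure=pres,
                times=arr[:, 0],
                counts=arr[:, 1],
            )
        )
    return records


def write_series_csv(series: EquilibriumSeries, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SERIES_HEADER)
        for t, k, s in series.points:
            writer.writerow([repr(t), repr(k), repr(s)])


def read_series_csv(
    path: str | Path, species: str = "unknown", n: int = 1
) -> EquilibriumSeries:
    points = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SERIES_HEADER:
            raise DomainError(
                f"{path}: expected header {SERIES_HEADER}, got {reader.fieldnames}"
            )
        for row in reader:
            points.append(
                (float(row["temperature_K"]), float(row["K"]), float(row["sigma_K"]))
            )
    return EquilibriumSeries(species=species, n=n, points=tuple(points))


def write_reduced_csv(
    measurements: Sequence[HydrationStepMeasurement], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REDUCED_HEADER)
        for m in measurements:
            eq = "" if m.eq_passed is None else str(m.eq_passed)
            writer.writerow(
                [m.species, m.n, repr(m.temperature), repr(m.water_pressure),
                 repr(m.I_n), repr(m.sigma_In), repr(m.I_nm1),
                 repr(m.sigma_Inm1), eq]
            )


def read_reduced_csv(path: str | Path) -> list[HydrationStepMeasurement]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != REDUCED_HEADER:
            raise DomainError(
                f"{path}: expected header {REDUCED_HEADER}, got {reader.fieldnames}"
            )
        for row in reader:
            eq_raw = row["eq_passed"].strip()
            eq = None if eq_raw == "" else eq_raw == "True"
            out.append(
                HydrationStepMeasurement(
                    species=row["species"],
                    n=int(row["n"]),
                    I_n=float(row["I_n"]),
                    sigma_In=float(row["sigma_In"]),
                    I_nm1=float(row["I_nm1"]),
                    sigma_Inm1=float(row["sigma_Inm1"]),
                    water_pressure=float(row["water_pressure_mbar"]),
                    temperature=float(row["temperature_K"]),
                    eq_passed=eq,
                )
            )
    return out


def read_tautomer_csv(path: str | Path) -> TautomerSet:
    labels, mias, fractions = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != TAUTOMER_HEADER:
            raise DomainError(
                f"{path}: expected header {TAUTOMER_HEADER}, got {reader.fieldnames}"
            )
        for row in reader:
            labels.append(row["label"])
            mias.append(float(row["mia_kJmol"]))
            fractions.append(float(row["fraction"]))
    return TautomerSet(
        labels=tuple(labels), mias=tuple(mias), fractions=tuple(fractions)
    )


def write_tautomer_csv(t: TautomerSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TAUTOMER_HEADER)
        for label, mia, frac in zip(t.labels, t.mias, t.fractions):
            writer.writerow([label, repr(mia), repr(frac)])
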