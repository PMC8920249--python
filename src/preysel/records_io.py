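"""Domain types and I/O for feeding-trial records.

A feeding trial offers a predator a fixed assortment of prey (the
*treatment*: an offered-abundance vector over prey species, replaced
daily) and records how many individuals of each species it consumed in
each 24 h period.  This module defines the three containers the rest of
the pipeline consumes — :class:`TreatmentSpec`, :class:`FeedingRecord`
and :class:`DietProfile` — together with CSV readers/writers and a flat
key=value run-configuration format.

On disk the canonical record layout is long CSV, one row per
predator × day × species::

    predator_id,tank,compartment,treatment_id,day,species,count

A wide dialect (one column per species, named after the species) is
accepted on read.  Species order is always taken from the
:class:`TreatmentSpec`, never from file order, so that electivity and
niche-breadth vectors are stably ordered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentSpec",
    "FeedingRecord",
    "DietProfile",
    "FormatError",
    "ValidationError",
    "ReferenceError_",
    "read_treatments",
    "write_treatments",
    "study_treatments",
    "read_records",
    "write_records",
    "records_to_frame",
    "pooled_diet",
    "read_config",
    "write_config",
    "DEFAULT_CONFIG",
]

#: prey species of the assassin-snail study, in fixed order
STUDY_SPECIES = ("Ramshorn", "Trumpet", "Pond", "Quilted")

#: offered-count vectors of the study's five treatments (8 prey each)
STUDY_OFFERS = {
    "2:2:2:2": (2, 2, 2, 2),
    "1:2:1:4": (1, 2, 1, 4),
    "1:3:2:2": (1, 3, 2, 2),
    "2:1:4:1": (2, 1, 4, 1),
    "4:2:1:1": (4, 2, 1, 1),
}

#: run-configuration defaults (flat key=value file)
DEFAULT_CONFIG = {
    "seed": 0,
    "min_feedings": 3,
    "min_feedings_mode": "prey",  # or "days"
    "ci_level": 0.95,
    "ci_method": "t",  # or "bootstrap"
    "null_method": "monte_carlo",  # or "chi2"
    "mc_replicates": 10000,
}


class FormatError(ValueError):
    """A file is structurally malformed (missing columns, bad header)."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. count exceeds offer)."""


class ReferenceError_(KeyError):
    """A row references an unknown treatment."""


@dataclass(frozen=True)
class TreatmentSpec:
    """Offered prey abundances for one treatment.

    Parameters
    ----------
    treatment_id
        Label, conventionally the offer ratio such as ``"1:2:1:4"``.
    species
        Ordered prey-species labels; fixes the ordering of every vector
        downstream.
    offered_counts
        Individuals of each species placed in the compartment at the
        start of every 24 h period.
    """

    treatment_id: str
    species: tuple[str, ...]
    offered_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.species) != len(self.offered_counts):
            raise ValidationError("species and offered_counts length mismatch")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species labels")
        if any(c < 0 or int(c) != c for c in self.offered_counts):
            raise ValidationError("offered_counts must be non-negative integers")
        if sum(self.offered_counts) <= 0:
            raise ValidationError("offered_counts must sum to > 0")

    @property
    def m(self) -> int:
        return len(self.species)

    @property
    def offered_props(self) -> np.ndarray:
        """Relative offered abundances p_j (sum to 1)."""
        c = np.asarray(self.offered_counts, dtype=float)
        return c / c.sum()


@dataclass(frozen=True)
class FeedingRecord:
    """One predator-day: how many of each prey species were consumed.

    ``counts`` follows the species order of the owning treatment.  Prey
    are replaced every 24 h, so within-day consumption can never exceed
    the offer — this is enforced when a treatment table is available.
    """

    predator_id: str
    tank: str
    compartment: str
    treatment_id: str
    day: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"day must be >= 1, got {self.day}")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValidationError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def validate_against(self, spec: TreatmentSpec) -> None:
        if len(self.counts) != spec.m:
            raise ValidationError(
                f"predator {self.predator_id} day {self.day}: "
                f"{len(self.counts)} counts for {spec.m} species"
            )
        for sp, c, offer in zip(spec.species, self.counts, spec.offered_counts):
            if c > offer:
                raise ValidationError(
                    f"predator {self.predator_id} day {self.day}: consumed "
                    f"{c} {sp} but only {offer} offered"
                )


@dataclass(frozen=True)
class DietProfile:
    """Species-wise consumption totals for a subject.

    ``subject`` is a predator id, or ``"population"`` for pooled counts.
    When nothing was consumed the proportions are undefined and
    ``defined`` is False (never silently zero).
    """

    subject: str
    species: tuple[str, ...]
    x: tuple[int, ...]

    @property
    def n(self) -> int:
        return int(sum(self.x))

    @property
    def defined(self) -> bool:
        return self.n > 0

    @property
    def props(self) -> np.ndarray:
        if not self.defined:
            raise ValidationError(f"diet of {self.subject!r} is empty: proportions undefined")
        x = np.asarray(self.x, dtype=float)
        return x / x.sum()


# ---------------------------------------------------------------------------
# treatment table I/O


def read_treatments(path: str | Path) -> dict[str, TreatmentSpec]:
    """Read a treatment table CSV (treatment_id, species, offered_count)."""
    df = pd.read_csv(path, dtype={"treatment_id": str, "species": str})
    required = {"treatment_id", "species", "offered_count"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"treatment table missing columns: {sorted(required - set(df.columns))}"
        )
    specs: dict[str, TreatmentSpec] = {}
    for tid, grp in df.groupby("treatment_id", sort=False):
        specs[str(tid)] = TreatmentSpec(
            treatment_id=str(tid),
            species=tuple(grp["species"]),
            offered_counts=tuple(int(c) for c in grp["offered_count"]),
        )
    return specs


def write_treatments(specs: Mapping[str, TreatmentSpec], path: str | Path) -> None:
    rows = [
        {"treatment_id": s.treatment_id, "species": sp, "offered_count": c}
        for s in specs.values()
        for sp, c in zip(s.species, s.offered_counts)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def study_treatments() -> dict[str, TreatmentSpec]:
    """The five offered-abundance treatments of the assassin-snail design."""
    return {
        tid: TreatmentSpec(tid, STUDY_SPECIES, counts)
        for tid, counts in STUDY_OFFERS.items()
    }


# ---------------------------------------------------------------------------
# record I/O

_KEY_COLS = ["predator_id", "tank", "compartment", "treatment_id", "day"]


def read_records(
    path: str | Path,
    treatments: Mapping[str, TreatmentSpec],
    *,
    validate: bool = True,
) -> list[FeedingRecord]:
    """Read feeding records from long or wide CSV.

    Long form has ``species``/``count`` columns; wide form has one column
    per species named exactly as in the treatment table.  Rows violating
    an invariant raise :class:`ValidationError` naming the offending row;
    unknown treatments raise :class:`ReferenceError_`.

    Explicit zero rows and absent non-feeding days normalise to the same
    representation: a record exists for every predator-day present in the
    file, and days wholly absent simply yield no record.
    """
    df = pd.read_csv(path, dtype={c: str for c in _KEY_COLS if c != "day"})
    missing = [c for c in _KEY_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"record file missing columns: {missing}")

    long_form = {"species", "count"}.issubset(df.columns)
    records: list[FeedingRecord] = []
    errors: list[str] = []

    def build(key, counts_by_species: dict[str, int], rownum: int) -> None:
        pid, tank, comp, tid, day = key
        spec = treatments.get(tid)
        if spec is None:
            raise ReferenceError_(f"row {rownum}: unknown treatment_id {tid!r}")
        unknown = set(counts_by_species) - set(spec.species)
        if unknown:
            raise FormatError(
                f"row {rownum}: species {sorted(unknown)} not in treatment {tid!r}"
            )
        counts = tuple(int(counts_by_species.get(sp, 0)) for sp in spec.species)
        rec = FeedingRecord(pid, tank, comp, tid, int(day), counts)
        if validate:
            try:
                rec.validate_against(spec)
            except ValidationError as e:
                errors.append(f"row {rownum}: {e}")
                return
        records.append(rec)

    if long_form:
        grouped: dict[tuple, dict[str, int]] = {}
        first_row: dict[tuple, int] = {}
        for i, row in enumerate(df.itertuples(index=False), start=2):
            key = (row.predator_id, row.tank, row.compartment, row.treatment_id, row.day)
            grouped.setdefault(key, {})[row.species] = int(row.count)
            first_row.setdefault(key, i)
        for key, cbs in grouped.items():
            build(key, cbs, first_row[key])
    else:
        species_cols = [c for c in df.columns if c not in _KEY_COLS]
        if not species_cols:
            raise FormatError("wide record file has no species columns")
        for i, row in df.iterrows():
            key = tuple(row[c] for c in _KEY_COLS)
            cbs = {sp: int(row[sp]) for sp in species_cols}
            build(key, cbs, int(i) + 2)

    if errors:
        raise ValidationError(
            f"{len(errors)} invalid record(s):\n" + "\n".join(errors)
        )
    records.sort(key=lambda r: (r.treatment_id, r.predator_id, r.day))
    return records


def write_records(
    records: Iterable[FeedingRecord],
    treatments: Mapping[str, TreatmentSpec],
    path: str | Path,
) -> None:
    """Write records in the canonical long CSV form."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_KEY_COLS + ["species", "count"])
        for r in records:
            spec = treatments[r.treatment_id]
            for sp, c in zip(spec.species, r.counts):
                w.writerow(
                    [r.predator_id, r.tank, r.compartment, r.treatment_id, r.day, sp, c]
                )


def records_to_frame(
    records: Sequence[FeedingRecord], treatments: Mapping[str, TreatmentSpec]
) -> pd.DataFrame:
    """Long DataFrame view of records (one row per predator-day-species)."""
    rows = []
    for r in records:
        spec = treatments[r.treatment_id]
        for sp, c in zip(spec.species, r.counts):
            rows.append(
                {
                    "predator_id": r.predator_id,
                    "tank": r.tank,
                    "compartment": r.compartment,
                    "treatment_id": r.treatment_id,
                    "day": r.day,
                    "species": sp,
                    "count": c,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pooling


def pooled_diet(
    records: Sequence[FeedingRecord],
    spec: TreatmentSpec,
    *,
    subject: str = "population",
    exclude: str | None = None,
) -> DietProfile:
    """Pool consumption over all records of a treatment into one profile.

    ``exclude`` drops one predator (the exclude-self population variant
    used by the specialisation test).  An empty scope yields a profile
    flagged undefined rather than silent zeros.
    """
    x = np.zeros(spec.m, dtype=int)
    for r in records:
        if r.treatment_id != spec.treatment_id:
            continue
        if exclude is not None and r.predator_id == exclude:
            continue
        x += np.asarray(r.counts, dtype=int)
    return DietProfile(subject=subject, species=spec.species, x=tuple(int(v) for v in x))


def individual_diet(records: Sequence[FeedingRecord], spec: TreatmentSpec, predator_id: str) -> DietProfile:
    """Total diet of one predator over its trial."""
    x = np.zeros(spec.m, dtype=int)
    for r in records:
        if r.predator_id == predator_id and r.treatment_id == spec.treatment_id:
            x += np.asarray(r.counts, dtype=int)
    return DietProfile(subject=predator_id, species=spec.species, x=tuple(int(v) for v in x))


# ---------------------------------------------------------------------------
# run configuration (flat key=value text file)

_CONFIG_TYPES = {k: type(v) for k, v in DEFAULT_CONFIG.items()}


def read_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` run-configuration file.

    Unknown keys raise :class:`FormatError`; missing keys take defaults.
    """
    cfg = dict(DEFAULT_CONFIG)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"config line {lineno}: expected key = value, got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in DEFAULT_CONFIG:
            raise FormatError(f"config line {lineno}: unknown key {key!r}")
        typ = _CONFIG_TYPES[key]
        try:
            cfg[key] = typ(val) if typ is not bool else val.lower() in ("1", "true", "yes")
        except ValueError as e:
            raise FormatError(f"config line {lineno}: bad value for {key!r}: {e}") from e
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")
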