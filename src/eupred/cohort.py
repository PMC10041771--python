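"""Cohort data model, delimited-text I/O and inclusion filters.

A *cycle* is one fresh embryo transfer (single or double) for one couple;
the outcome is the number of gestational sacs seen on ultrasound at 12
weeks (0, 1 or 2).  Morphokinetic annotations are hours post
insemination / injection: pronuclear appearance and fading (tPNa, tPNf)
and the times of reaching the 2..8-cell stages (t2..t8).  Only t2 and
the intervals t3-t2 and t5-t4 enter the prediction models; the rest are
carried along untouched.

The exchange format is a flat CSV, one row per embryo, with cycle-level
columns repeated on every row of the cycle.  Missing annotations are
empty cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "EmbryoRecord",
    "CycleRecord",
    "Cohort",
    "MorphokineticFeatures",
    "FilterLog",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "cohort_from_frame",
    "apply_inclusion_filters",
    "extract_features",
]

_TIME_FIELDS = ("tPNa", "tPNf", "t2", "t3", "t4", "t5", "t6", "t7", "t8")

FERTILIZATION_METHODS = ("IVF", "ICSI")
TIME_ZERO_CONVENTIONS = ("insemination", "last_injection", "halfway_injection")


class CohortValidationError(ValueError):
    """Raised when a record violates the cohort invariants."""


@dataclass(frozen=True)
class EmbryoRecord:
    """One transferred (or sibling) embryo with its annotated timings."""

    embryo_id: str
    tPNa: Optional[float] = None
    tPNf: Optional[float] = None
    t2: Optional[float] = None
    t3: Optional[float] = None
    t4: Optional[float] = None
    t5: Optional[float] = None
    t6: Optional[float] = None
    t7: Optional[float] = None
    t8: Optional[float] = None
    transferred: bool = True

    def __post_init__(self) -> None:
        prev_name, prev = None, None
        for name in _TIME_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value) or value < 0:
                raise CohortValidationError(
                    f"embryo {self.embryo_id}: {name}={value!r} must be finite and >= 0"
                )
            if prev is not None and value < prev:
                raise CohortValidationError(
                    f"embryo {self.embryo_id}: {name}={value} precedes {prev_name}={prev}"
                )
            prev_name, prev = name, value

    def times(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in _TIME_FIELDS}

    @property
    def fertilized(self) -> bool:
        """Two-pronuclei evidence: pronuclear fading seen, or any cleavage time."""
        return self.tPNf is not None or any(
            getattr(self, t) is not None for t in ("t2", "t3", "t4", "t5", "t6", "t7", "t8")
        )

    def has_model_features(self) -> bool:
        return all(getattr(self, t) is not None for t in ("t2", "t3", "t4", "t5"))


@dataclass(frozen=True)
class CycleRecord:
    """One transfer cycle: covariates, 1-2 transferred embryos, sac count."""

    cycle_id: str
    female_age: float
    embryos: tuple[EmbryoRecord, ...]
    n_sacs: int
    clinic: str = ""
    couple_id: Optional[str] = None
    cycle_number: int = 1
    fertilization_method: str = "ICSI"
    time_zero_convention: str = "insemination"

    def __post_init__(self) -> None:
        object.__setattr__(self, "embryos", tuple(self.embryos))
        if not (self.female_age > 0 and math.isfinite(self.female_age)):
            raise CohortValidationError(f"cycle {self.cycle_id}: female_age must be > 0")
        if self.cycle_number < 1:
            raise CohortValidationError(f"cycle {self.cycle_id}: cycle_number must be >= 1")
        if self.fertilization_method not in FERTILIZATION_METHODS:
            raise CohortValidationError(
                f"cycle {self.cycle_id}: unknown fertilization_method "
                f"{self.fertilization_method!r}"
            )
        if self.time_zero_convention not in TIME_ZERO_CONVENTIONS:
            raise CohortValidationError(
                f"cycle {self.cycle_id}: unknown time_zero_convention "
                f"{self.time_zero_convention!r}"
            )
        n_transferred = sum(e.transferred for e in self.embryos)
        if n_transferred not in (1, 2):
            raise CohortValidationError(
                f"cycle {self.cycle_id}: {n_transferred} transferred embryos (need 1 or 2)"
            )
        if self.n_sacs not in (0, 1, 2):
            raise CohortValidationError(f"cycle {self.cycle_id}: n_sacs must be 0, 1 or 2")
        if self.n_sacs > n_transferred:
            raise CohortValidationError(
                f"cycle {self.cycle_id}: n_sacs={self.n_sacs} exceeds "
                f"{n_transferred} transferred embryo(s)"
            )

    @property
    def transferred_embryos(self) -> tuple[EmbryoRecord, ...]:
        return tuple(e for e in self.embryos if e.transferred)

    @property
    def n_transferred(self) -> int:
        return len(self.transferred_embryos)

    @property
    def is_det(self) -> bool:
        return self.n_transferred == 2

    @property
    def pregnant(self) -> bool:
        return self.n_sacs >= 1

    @property
    def effective_couple_id(self) -> str:
        """Couple identity: explicit column, else the cycle_id prefix before
        the last hyphen (whole id if there is none)."""
        if self.couple_id:
            return self.couple_id
        head, sep, _ = self.cycle_id.rpartition("-")
        return head if sep else self.cycle_id


@dataclass
class Cohort:
    """Ordered collection of cycles with provenance metadata."""

    cycles: list[CycleRecord] = field(default_factory=list)
    source: str = ""
    filter_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.cycles:
            if c.cycle_id in seen:
                raise CohortValidationError(f"duplicate cycle_id {c.cycle_id!r}")
            seen.add(c.cycle_id)

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    def __getitem__(self, i):
        return self.cycles[i]

    @property
    def n_embryos(self) -> int:
        return sum(c.n_transferred for c in self.cycles)

    @property
    def n_det(self) -> int:
        return sum(c.is_det for c in self.cycles)

    def subset(self, cycles: Sequence[CycleRecord], note: str = "") -> "Cohort":
        log = list(self.filter_log)
        if note:
            log.append(note)
        return Cohort(cycles=list(cycles), source=self.source, filter_log=log)


@dataclass(frozen=True)
class MorphokineticFeatures:
    """Per-embryo model inputs: t2, the 2->3 and 4->5 cell intervals, age."""

    t2: float
    int_t3_t2: float
    int_t5_t4: float
    female_age: float

    def __post_init__(self) -> None:
        if self.int_t3_t2 < 0 or self.int_t5_t4 < 0:
            raise CohortValidationError("cleavage intervals must be >= 0")


@dataclass
class FilterLog:
    """Counts of cycles removed per inclusion rule, in application order."""

    removed: dict[str, int] = field(default_factory=dict)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def record(self, rule: str, ids: list[str]) -> None:
        self.removed[rule] = len(ids)
        self.removed_ids[rule] = ids

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def lines(self) -> list[str]:
        return [f"{rule}: removed {n} cycle(s)" for rule, n in self.removed.items()]


# ---------------------------------------------------------------------------
# CSV exchange format

_CYCLE_COLUMNS = [
    "cycle_id",
    "clinic",
    "couple_id",
    "female_age",
    "cycle_number",
    "fertilization_method",
    "time_zero_convention",
    "n_sacs",
]
_EMBRYO_COLUMNS = ["embryo_id", *_TIME_FIELDS, "transferred"]
COLUMNS = _CYCLE_COLUMNS + _EMBRYO_COLUMNS


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for c in cohort:
        for e in c.embryos:
            row = {
                "cycle_id": c.cycle_id,
                "clinic": c.clinic,
                "couple_id": c.couple_id if c.couple_id is not None else "",
                "female_age": c.female_age,
                "cycle_number": c.cycle_number,
                "fertilization_method": c.fertilization_method,
                "time_zero_convention": c.time_zero_convention,
                "n_sacs": c.n_sacs,
                "embryo_id": e.embryo_id,
                "transferred": int(e.transferred),
            }
            row.update(e.times())
            rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def cohort_from_frame(frame: pd.DataFrame, source: str = "") -> Cohort:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {', '.join(missing)}")
    bad_rows: list[int] = []
    parsed: list[tuple[pd.Series, list[EmbryoRecord]]] = []
    # groupby(sort=False) keeps first-appearance order of cycles
    for _, group in frame.groupby("cycle_id", sort=False):
        embryos = []
        for idx, row in group.iterrows():
            try:
                embryos.append(
                    EmbryoRecord(
                        embryo_id=str(row["embryo_id"]),
                        transferred=bool(int(row["transferred"])),
                        **{t: _opt_float(row[t]) for t in _TIME_FIELDS},
                    )
                )
            except (ValueError, TypeError):
                bad_rows.append(int(idx) + 2)  # 1-based + header line
        parsed.append((group.iloc[0], embryos))
    if bad_rows:
        raise CohortValidationError(f"unparseable rows (1-based, incl. header): {bad_rows}")
    cycles: list[CycleRecord] = []
    for first, embryos in parsed:
        couple = first["couple_id"]
        if pd.isna(couple) or couple == "":
            couple = None
        cycles.append(
            CycleRecord(
                cycle_id=str(first["cycle_id"]),
                clinic=str(first["clinic"]) if not pd.isna(first["clinic"]) else "",
                couple_id=None if couple is None else str(couple),
                female_age=float(first["female_age"]),
                cycle_number=int(first["cycle_number"]),
                fertilization_method=str(first["fertilization_method"]),
                time_zero_convention=str(first["time_zero_convention"]),
                embryos=tuple(embryos),
                n_sacs=int(first["n_sacs"]),
            )
        )
    return Cohort(cycles=cycles, source=source)


def read_cohort(path, **read_csv_kwargs) -> Cohort:
    """Read a cohort from the flat one-row-per-embryo CSV format."""
    frame = pd.read_csv(path, **read_csv_kwargs)
    if frame.empty and not frame.columns.empty:
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {', '.join(missing)}")
        return Cohort(cycles=[], source=str(path))
    return cohort_from_frame(frame, source=str(path))


def write_cohort(cohort: Cohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inclusion filters

DEFAULT_DAY3_CUTOFF_H = 72.0


def apply_inclusion_filters(
    cohort: Cohort,
    day3_cutoff_h: float = DEFAULT_DAY3_CUTOFF_H,
    require_complete_features: bool = True,
) -> tuple[Cohort, FilterLog]:
    """Apply the study inclusion rules, in order, and log removals.

    Rules:
      a. at least one fertilized (2PN) embryo in the cycle;
      b. at least one embryo reaching the 5-cell stage by ``day3_cutoff_h``
         hours (default 72 h, the literal reading of "three days");
      c. first cycle per couple only (lowest cycle_number per couple);
      d. (optional, default on) every *transferred* embryo annotated with
         t2..t5, since the models need the full feature vector.

    Filters never error; they remove and log.
    """
    log = FilterLog()
    cycles = list(cohort.cycles)

    def drop(rule: str, keep_fn) -> None:
        nonlocal cycles
        kept, dropped = [], []
        for c in cycles:
            (kept if keep_fn(c) else dropped).append(c)
        log.record(rule, [c.cycle_id for c in dropped])
        cycles = kept

    drop("a_no_2pn_embryo", lambda c: any(e.fertilized for e in c.embryos))
    drop(
        "b_no_embryo_at_5cell_by_day3",
        lambda c: any(e.t5 is not None and e.t5 <= day3_cutoff_h for e in c.embryos),
    )

    # rule c: keep the lowest cycle_number per couple; ties keep first seen
    best: dict[str, CycleRecord] = {}
    for c in cycles:
        key = c.effective_couple_id
        if key not in best or c.cycle_number < best[key].cycle_number:
            best[key] = c
    keep_ids = {c.cycle_id for c in best.values()}
    drop("c_not_first_cycle_of_couple", lambda c: c.cycle_id in keep_ids)

    if require_complete_features:
        drop(
            "d_incomplete_model_features",
            lambda c: all(e.has_model_features() for e in c.transferred_embryos),
        )

    out = cohort.subset(cycles)
    out.filter_log.extend(log.lines())
    return out, log


def extract_features(cycle: CycleRecord) -> list[MorphokineticFeatures]:
    """Per-transferred-embryo model features; intervals are plain differences."""
    feats = []
    for e in cycle.transferred_embryos:
        for name in ("t2", "t3", "t4", "t5"):
            if getattr(e, name) is None:
                raise CohortValidationError(
                    f"cycle {cycle.cycle_id}, embryo {e.embryo_id}: {name} required"
                )
        feats.append(
            MorphokineticFeatures(
                t2=e.t2,
                int_t3_t2=e.t3 - e.t2,
                int_t5_t4=e.t5 - e.t4,
                female_age=cycle.female_age,
            )
        )
    return feats
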