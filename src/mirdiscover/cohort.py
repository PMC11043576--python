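"""Sample metadata: per-sample records, cohort tables, frequency matching and
the stratified 2:1 train/test split.

A cohort is a small, ordered table of case/control samples annotated with
exogenous hormone use at blood draw (the study's key effect modifier), age,
and — for cases — whether disease was pathology-confirmed.  Controls are
frequency matched to cases on age (binned) and hormone use, i.e. stratum
totals match, not individual pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
TRAIN = "train"
TEST = "test"

_TRUE_TOKENS = {"1", "yes", "true", "t", "y"}
_FALSE_TOKENS = {"0", "no", "false", "f", "n"}

SHEET_COLUMNS = (
    "sample_id",
    "group",
    "hormone_use",
    "age",
    "pathology_confirmed",
    "months_since_surgery",
)


class SchemaError(ValueError):
    """A sample sheet is missing a required column."""


class CohortValidationError(ValueError):
    """A record or table violates a cohort invariant."""


def parse_bool(token: object) -> bool:
    """Parse {0,1,yes,no,true,false,t,f,y,n} case-insensitively."""
    if isinstance(token, (bool, np.bool_)):
        return bool(token)
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise CohortValidationError(f"cannot parse boolean value {token!r}")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str
    hormone_use: bool
    age: float
    pathology_confirmed: bool | None = None
    months_since_surgery: float | None = None

    def __post_init__(self) -> None:
        if self.group not in (CASE, CONTROL):
            raise CohortValidationError(
                f"group must be {CASE!r} or {CONTROL!r}, got {self.group!r}"
            )
        if self.group == CONTROL and self.pathology_confirmed is not None:
            raise CohortValidationError(
                f"pathology_confirmed is defined only for cases ({self.sample_id})"
            )


@dataclass(frozen=True)
class CohortTable:
    """Ordered collection of :class:`SampleRecord` plus an optional split map."""

    records: tuple[SampleRecord, ...]
    phase: str = "replication"
    split: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.sample_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortValidationError(f"duplicate sample_id(s): {sorted(dupes)}")
        if self.split is not None:
            split = dict(self.split)
            if set(split) != set(ids):
                raise CohortValidationError(
                    "split must cover every record exactly once"
                )
            bad = {v for v in split.values() if v not in (TRAIN, TEST)}
            if bad:
                raise CohortValidationError(f"invalid split labels: {sorted(bad)}")
            object.__setattr__(self, "split", split)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.records)

    def ids(self, group: str | None = None, hormone_use: bool | None = None,
            split: str | None = None) -> tuple[str, ...]:
        """Sample ids filtered by any combination of group/hormone/split."""
        out = []
        for r in self.records:
            if group is not None and r.group != group:
                continue
            if hormone_use is not None and r.hormone_use != hormone_use:
                continue
            if split is not None:
                if self.split is None or self.split[r.sample_id] != split:
                    continue
            out.append(r.sample_id)
        return tuple(out)

    @property
    def case_ids(self) -> tuple[str, ...]:
        return self.ids(group=CASE)

    @property
    def control_ids(self) -> tuple[str, ...]:
        return self.ids(group=CONTROL)

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "CohortTable":
        keep = set(sample_ids)
        recs = tuple(r for r in self.records if r.sample_id in keep)
        split = (
            {r.sample_id: self.split[r.sample_id] for r in recs}
            if self.split is not None
            else None
        )
        return CohortTable(recs, phase=self.phase, split=split)

    def with_split(self, split: Mapping[str, str]) -> "CohortTable":
        return CohortTable(self.records, phase=self.phase, split=dict(split))

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "group": [r.group for r in self.records],
                "hormone_use": [r.hormone_use for r in self.records],
                "age": [r.age for r in self.records],
                "pathology_confirmed": [r.pathology_confirmed for r in self.records],
                "months_since_surgery": [r.months_since_surgery for r in self.records],
            }
        )
        if self.split is not None:
            df["split"] = [self.split[r.sample_id] for r in self.records]
        return df


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_sample_sheet(path: str | Path, dialect: str | None = None,
                      phase: str = "replication") -> CohortTable:
    """Read a CSV/TSV sample sheet into a :class:`CohortTable`.

    Required columns: ``sample_id, group, hormone_use, age``.  Optional:
    ``pathology_confirmed, months_since_surgery, split``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str)
    required = ("sample_id", "group", "hormone_use", "age")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"sample sheet is missing required column {col!r}")

    def _opt(row, col, conv):
        if col not in df.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return None
        return conv(v)

    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]).strip(),
                group=str(row["group"]).strip().lower(),
                hormone_use=parse_bool(row["hormone_use"]),
                age=float(row["age"]),
                pathology_confirmed=_opt(row, "pathology_confirmed", parse_bool),
                months_since_surgery=_opt(row, "months_since_surgery", float),
            )
        )
    split = None
    if "split" in df.columns and df["split"].notna().all():
        split = {
            str(r["sample_id"]).strip(): str(r["split"]).strip()
            for _, r in df.iterrows()
        }
    return CohortTable(tuple(records), phase=phase, split=split)


def write_sample_sheet(cohort: CohortTable, path: str | Path,
                       dialect: str | None = None) -> None:
    path = Path(path)
    df = cohort.frame.copy()
    for col in ("hormone_use", "pathology_confirmed"):
        df[col] = df[col].map(lambda v: "" if v is None else ("1" if v else "0"))
    df["months_since_surgery"] = df["months_since_surgery"].map(
        lambda v: "" if v is None else repr(float(v))
    )
    df.to_csv(path, sep=_sep_for(path, dialect), index=False)


# ---------------------------------------------------------------------------
# Frequency matching and splitting


@dataclass(frozen=True)
class MatchStratum:
    hormone_use: bool
    age_bin: int
    n_cases: int
    n_requested: int
    n_selected: int

    @property
    def shortfall(self) -> int:
        return self.n_requested - self.n_selected


def frequency_match(cases: CohortTable, control_pool: CohortTable, ratio: int = 2,
                    age_tolerance: float = 2.0, seed: int = 0
                    ) -> tuple[CohortTable, tuple[MatchStratum, ...]]:
    """Select ``ratio`` controls per case within (hormone use x age-bin) strata.

    Age bins have width ``2 * age_tolerance`` anchored at the youngest case.
    Selection within a stratum is uniform-random under ``seed``; a stratum
    with too few eligible controls is filled best-effort with a warning, and
    the per-stratum accounting is returned alongside the matched cohort.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if len(control_pool) == 0:
        raise ValueError("control pool is empty")
    case_records = [r for r in cases.records if r.group == CASE]
    if not case_records:
        raise ValueError("no cases to match")

    width = 2.0 * age_tolerance
    anchor = min(r.age for r in case_records)

    def age_bin(age: float) -> int:
        return int(np.floor((age - anchor) / width))

    rng = np.random.default_rng(seed)
    pool = [r for r in control_pool.records if r.group == CONTROL]

    strata: dict[tuple[bool, int], int] = {}
    for r in case_records:
        key = (r.hormone_use, age_bin(r.age))
        strata[key] = strata.get(key, 0) + 1

    chosen: list[SampleRecord] = []
    summary: list[MatchStratum] = []
    taken: set[str] = set()
    for key in sorted(strata):
        hormone, abin = key
        n_cases = strata[key]
        want = ratio * n_cases
        eligible = sorted(
            (
                r
                for r in pool
                if r.hormone_use == hormone
                and age_bin(r.age) == abin
                and r.sample_id not in taken
            ),
            key=lambda r: r.sample_id,
        )
        if len(eligible) < want:
            warnings.warn(
                f"stratum hormone={hormone} age_bin={abin}: "
                f"only {len(eligible)} of {want} controls available",
                stacklevel=2,
            )
            picked = eligible
        else:
            idx = rng.choice(len(eligible), size=want, replace=False)
            picked = [eligible[i] for i in sorted(idx)]
        taken.update(r.sample_id for r in picked)
        chosen.extend(picked)
        summary.append(MatchStratum(hormone, abin, n_cases, want, len(picked)))

    matched = CohortTable(tuple(case_records) + tuple(chosen), phase=cases.phase)
    return matched, tuple(summary)


def largest_remainder_quotas(sizes: Sequence[int], fraction: float) -> list[int]:
    """Integer allocation of ``round(sum(sizes) * fraction)`` across strata.

    Each stratum gets floor(n * fraction); leftover units go to the largest
    fractional remainders (ties broken by stratum order).
    """
    quotas = [n * fraction for n in sizes]
    base = [int(np.floor(q + 1e-9)) for q in quotas]
    total = int(round(sum(quotas)))
    remainders = [q - b for q, b in zip(quotas, base)]
    order = sorted(range(len(sizes)), key=lambda i: (-remainders[i], i))
    extra = total - sum(base)
    alloc = list(base)
    for i in order[:extra]:
        alloc[i] += 1
    return alloc


def stratified_split(cohort: CohortTable, train_fraction: float = 2.0 / 3.0,
                     strata: Sequence[str] = ("group", "hormone_use"),
                     seed: int = 0) -> CohortTable:
    """Assign each sample to train/test, stratified on ``strata`` fields.

    Within each stratum, largest-remainder rounding fixes the train count and
    membership is a seeded uniform draw.  A stratum with fewer than two
    samples goes entirely to the training set (with a warning).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    for f in strata:
        if not hasattr(SampleRecord, "__dataclass_fields__") or f not in SampleRecord.__dataclass_fields__:
            raise ValueError(f"unknown stratum field {f!r}")

    groups: dict[tuple, list[str]] = {}
    for r in cohort.records:
        key = tuple(getattr(r, f) for f in strata)
        groups.setdefault(key, []).append(r.sample_id)

    keys = sorted(groups)
    sizes = [len(groups[k]) for k in keys]
    quotas = largest_remainder_quotas(sizes, train_fraction)

    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    for key, n_train in zip(keys, quotas):
        members = sorted(groups[key])
        if len(members) < 2:
            warnings.warn(
                f"stratum {key} has {len(members)} sample(s); assigning all to train",
                stacklevel=2,
            )
            for sid in members:
                split[sid] = TRAIN
            continue
        perm = rng.permutation(len(members))
        for rank, idx in enumerate(perm):
            split[members[idx]] = TRAIN if rank < n_train else TEST
    return cohort.with_split(split)
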