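"""Synthetic two-phase cohort generator with planted, hormone-modified effects.

Every downstream stage of the pipeline is exercised against data from this
module: a discovery-phase qPCR Ct matrix (technical duplicates, a per-sample
loading shift that global normalization must remove, stable reference
miRNAs, missingness) and a replication-phase bead-panel MFI matrix (log-normal
fluorescence, blank and pooled-QC wells, occasional negative
background-corrected values).  Case/control effects are planted on the log
scale — cycles for Ct, log10 units for MFI — and can be restricted to the
hormone-user or non-user stratum, emulating the effect modification the
study design assumes.  All generators are pure functions of their parameters
and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, CohortTable, SampleRecord

HORMONE = "hormone"
NON_HORMONE = "non_hormone"
BOTH = "both"
_STRATA = (HORMONE, NON_HORMONE, BOTH)

LOG10_2 = float(np.log10(2.0))


@dataclass(frozen=True)
class EffectSpec:
    """A planted case-vs-control effect for one miRNA.

    ``log2_effect`` is the log2 fold change (case minus control) on the
    expression scale; positive means up-regulated in cases, which lowers Ct
    by ``log2_effect`` cycles and raises log10 MFI by
    ``log2_effect * log10(2)``.
    """

    mirna_id: str
    stratum: str
    log2_effect: float

    def __post_init__(self) -> None:
        if self.stratum not in _STRATA:
            raise ValueError(f"stratum must be one of {_STRATA}, got {self.stratum!r}")
        if self.log2_effect == 0:
            raise ValueError("planted effects must have |log2_effect| > 0")

    def applies_to(self, hormone_use: bool) -> bool:
        if self.stratum == BOTH:
            return True
        return hormone_use if self.stratum == HORMONE else not hormone_use


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth and noise model for a simulated two-phase study."""

    effects: tuple[EffectSpec, ...] = ()
    reference_mirnas: tuple[str, ...] = ()
    noise_sd_ct: float = 0.2          # cycles, per-sample biological/assay noise
    noise_sd_log10mfi: float = 0.15    # log10 units, assay + inter-individual spread
    missing_rate: float = 0.02        # per Ct measurement
    duplicate_sd: float = 0.2         # cycles, per technical replicate
    sample_shift_sd: float = 0.5      # cycles, per-sample loading artifact
    negative_rate: float = 0.002      # fraction of MFI values made negative
    background_mfi: float = 50.0      # blank-well raw fluorescence
    background_sd: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        object.__setattr__(self, "reference_mirnas", tuple(self.reference_mirnas))
        ids = [e.mirna_id for e in self.effects]
        if len(set(ids)) != len(ids):
            raise ValueError("effect mirna_ids must be unique")
        overlap = set(ids) & set(self.reference_mirnas)
        if overlap:
            raise ValueError(f"reference miRNAs overlap planted effects: {sorted(overlap)}")

    @property
    def planted_ids(self) -> tuple[str, ...]:
        return tuple(e.mirna_id for e in self.effects)

    def effect_for(self, mirna_id: str) -> EffectSpec | None:
        for e in self.effects:
            if e.mirna_id == mirna_id:
                return e
        return None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        d["effects"] = tuple(EffectSpec(**e) for e in d["effects"])
        d["reference_mirnas"] = tuple(d["reference_mirnas"])
        return cls(**d)


def default_truth(log2_effect: float = 1.0) -> SimulationTruth:
    """Study-condition default: five planted probes in the stratum pattern of
    the discovery-phase candidate table (two hormone-only, two non-user-only,
    one in both strata, signs mixed) plus five zero-variance references."""
    e = abs(log2_effect)
    return SimulationTruth(
        effects=(
            EffectSpec("syn-miR-101", HORMONE, +e),
            EffectSpec("syn-miR-102", HORMONE, -e),
            EffectSpec("syn-miR-103", NON_HORMONE, +e),
            EffectSpec("syn-miR-104", NON_HORMONE, -e),
            EffectSpec("syn-miR-105", BOTH, +e),
        ),
        reference_mirnas=tuple(f"syn-ref-{i:02d}" for i in range(1, 6)),
    )


@dataclass(frozen=True)
class CtMatrix:
    """miRNA x (sample-replicate) grid of Ct cycles; NaN marks missing.

    ``replicate_of`` maps a column to its sample id when technical
    duplicates are present; it is ``None`` after duplicate collapsing.
    """

    values: pd.DataFrame
    replicate_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 40):
            raise ValueError("Ct values must lie in [0, 40] or be missing")
        if self.replicate_of is not None:
            object.__setattr__(self, "replicate_of", dict(self.replicate_of))
            missing = set(self.values.columns) - set(self.replicate_of)
            if missing:
                raise ValueError(f"columns without replicate mapping: {sorted(missing)}")

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)


@dataclass(frozen=True)
class MfiMatrix:
    """probe x well grid of mean fluorescence intensity (raw scale).

    Values may be negative after background correction.  ``well_role`` labels
    each column as a study sample, blank (water) well or pooled-plasma QC well.
    """

    values: pd.DataFrame
    well_role: Mapping[str, str]

    _ROLES = ("study", "blank", "qc_pool")

    def __post_init__(self) -> None:
        object.__setattr__(self, "well_role", dict(self.well_role))
        if set(self.values.columns) != set(self.well_role):
            raise ValueError("well_role must label exactly the matrix columns")
        bad = {r for r in self.well_role.values() if r not in self._ROLES}
        if bad:
            raise ValueError(f"unknown well roles: {sorted(bad)}")

    def wells(self, role: str) -> list[str]:
        return [w for w in self.values.columns if self.well_role[w] == role]


# ---------------------------------------------------------------------------
# Generators


def simulate_cohort(n_cases: int, control_ratio: int = 2,
                    hormone_fraction: float = 0.78,
                    age_range: tuple[int, int] = (13, 25), seed: int = 0,
                    phase: str = "replication",
                    pathology_confirmed_fraction: float = 0.6) -> CohortTable:
    """Simulate a frequency-matched case/control cohort.

    Case hormone status is Bernoulli(``hormone_fraction``); each case's
    ``control_ratio`` matched controls copy its hormone status and age (plus
    or minus a year, clipped to range), so strata are matched by construction.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if control_ratio < 1:
        raise ValueError("control_ratio must be >= 1")
    lo, hi = age_range
    rng = np.random.default_rng(seed)
    case_h = rng.random(n_cases) < hormone_fraction
    case_age = rng.integers(lo, hi + 1, size=n_cases)
    confirmed = rng.random(n_cases) < pathology_confirmed_fraction
    months = rng.integers(7, 37, size=n_cases)

    records: list[SampleRecord] = []
    for i in range(n_cases):
        records.append(
            SampleRecord(
                sample_id=f"case-{i + 1:03d}",
                group=CASE,
                hormone_use=bool(case_h[i]),
                age=float(case_age[i]),
                pathology_confirmed=bool(confirmed[i]),
                months_since_surgery=float(months[i]),
            )
        )
    k = 0
    for i in range(n_cases):
        for _ in range(control_ratio):
            k += 1
            age = int(np.clip(case_age[i] + rng.integers(-1, 2), lo, hi))
            records.append(
                SampleRecord(
                    sample_id=f"ctrl-{k:03d}",
                    group=CONTROL,
                    hormone_use=bool(case_h[i]),
                    age=float(age),
                )
            )
    return CohortTable(tuple(records), phase=phase)


def _effect_delta(cohort: CohortTable, truth: SimulationTruth,
                  gene_ids: Sequence[str]) -> np.ndarray:
    """Planted log2 effect per (gene, sample); nonzero only for cases in the
    effect's stratum."""
    delta = np.zeros((len(gene_ids), len(cohort)))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for e in truth.effects:
        if e.mirna_id not in idx:
            continue
        gi = idx[e.mirna_id]
        for si, r in enumerate(cohort.records):
            if r.group == CASE and e.applies_to(r.hormone_use):
                delta[gi, si] = e.log2_effect
    return delta


def simulate_ct_matrix(cohort: CohortTable, truth: SimulationTruth,
                       n_mirnas: int = 754, seed: int = 0) -> CtMatrix:
    """Simulate a discovery-phase Ct matrix with technical duplicates.

    Per-miRNA baselines are Uniform(18, 33) cycles; every sample carries a
    shared Normal(0, ``sample_shift_sd``) loading shift; planted effects lower
    case Ct by ``log2_effect`` in their stratum; reference miRNAs carry no
    biological noise.  Values above 34 cycles are left in place — the QC
    filter owns that rule.
    """
    n_special = len(truth.effects) + len(truth.reference_mirnas)
    if n_mirnas < n_special:
        raise ValueError(
            f"n_mirnas={n_mirnas} < planted effects + references ({n_special})"
        )
    gene_ids = list(truth.planted_ids) + list(truth.reference_mirnas)
    gene_ids += [f"syn-miR-f{i:04d}" for i in range(1, n_mirnas - n_special + 1)]

    rng = np.random.default_rng(seed)
    G, S = len(gene_ids), len(cohort)
    base = rng.uniform(18.0, 33.0, size=G)
    shift = rng.normal(0.0, truth.sample_shift_sd, size=S)
    noise = rng.normal(0.0, truth.noise_sd_ct, size=(G, S))
    ref_rows = np.array([g in truth.reference_mirnas for g in gene_ids])
    noise[ref_rows, :] = 0.0

    ct = base[:, None] + shift[None, :] + noise - _effect_delta(cohort, truth, gene_ids)

    columns: list[str] = []
    replicate_of: dict[str, str] = {}
    data = np.empty((G, 2 * S))
    for si, sid in enumerate(cohort.sample_ids):
        for ri, tag in enumerate("AB"):
            col = f"{sid}_{tag}"
            columns.append(col)
            replicate_of[col] = sid
            data[:, 2 * si + ri] = ct[:, si] + rng.normal(
                0.0, truth.duplicate_sd, size=G
            )
    if truth.missing_rate > 0:
        mask = rng.random(data.shape) < truth.missing_rate
        data[mask] = np.nan
    data = np.clip(data, 0.0, 40.0)
    values = pd.DataFrame(data, index=gene_ids, columns=columns)
    return CtMatrix(values, replicate_of=replicate_of)


def simulate_mfi_matrix(cohort: CohortTable, truth: SimulationTruth,
                        panel: Sequence[str], blank_wells: int = 3,
                        qc_fraction: float = 0.05, seed: int = 0) -> MfiMatrix:
    """Simulate a replication-phase bead-panel MFI matrix.

    Study-well log10 MFI is Normal(per-probe baseline, ``noise_sd_log10mfi``)
    plus the planted stratum effect on the log10 scale; QC wells replicate
    one pooled profile; blank wells carry only background fluorescence.  A
    small fraction of study values is made negative to exercise the
    0.001-shift rule downstream.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be nonempty")
    rng = np.random.default_rng(seed)
    P, S = len(panel), len(cohort)
    base = rng.uniform(2.0, 4.0, size=P)

    log10v = base[:, None] + rng.normal(0.0, truth.noise_sd_log10mfi, size=(P, S))
    log10v += _effect_delta(cohort, truth, panel) * LOG10_2
    study = np.power(10.0, log10v)
    if truth.negative_rate > 0:
        # Background-corrected MFI dips below zero where true signal is
        # weakest, so the globally dimmest ``negative_rate`` fraction of
        # study values becomes negative (naturally concentrated in the
        # lower tail of the dimmest probe).
        thr = np.quantile(study, truth.negative_rate)
        mask = study <= thr
        study[mask] = rng.uniform(-10.0, -0.1, size=int(mask.sum()))

    n_qc = int(round(qc_fraction * S))
    qc = np.power(
        10.0, base[:, None] + rng.normal(0.0, truth.noise_sd_log10mfi, size=(P, n_qc))
    )
    blanks = rng.normal(truth.background_mfi, truth.background_sd, size=(P, blank_wells))

    columns = list(cohort.sample_ids)
    columns += [f"QC{i:02d}" for i in range(1, n_qc + 1)]
    columns += [f"BLANK{i:02d}" for i in range(1, blank_wells + 1)]
    values = pd.DataFrame(
        np.concatenate([study, qc, blanks], axis=1), index=panel, columns=columns
    )
    role = {sid: "study" for sid in cohort.sample_ids}
    role.update({f"QC{i:02d}": "qc_pool" for i in range(1, n_qc + 1)})
    role.update({f"BLANK{i:02d}": "blank" for i in range(1, blank_wells + 1)})
    return MfiMatrix(values, well_role=role)


# ---------------------------------------------------------------------------
# Truth recovery accounting


@dataclass(frozen=True)
class RecoveryReport:
    n_planted: int
    recovered: tuple[str, ...]
    false_selections: tuple[str, ...]

    @property
    def recall(self) -> float:
        return len(self.recovered) / self.n_planted if self.n_planted else float("nan")

    @property
    def n_false(self) -> int:
        return len(self.false_selections)


def recovery_report(selected: Sequence[str], truth: SimulationTruth,
                    ignore: Sequence[str] = ()) -> RecoveryReport:
    """Compare a selected miRNA list against the planted truth.

    ``ignore`` removes bookkeeping features (e.g. a forced covariate) from
    the false-selection count.
    """
    planted = set(truth.planted_ids)
    sel = [s for s in selected if s not in set(ignore)]
    recovered = tuple(sorted(planted & set(sel)))
    false = tuple(sorted(set(sel) - planted))
    return RecoveryReport(len(planted), recovered, false)


# ---------------------------------------------------------------------------
# Plain-text export (probes as rows, samples as columns)


def write_ct_tsv(ct: CtMatrix, path: str | Path) -> None:
    ct.values.to_csv(Path(path), sep="\t", index_label="mirna_id")


def read_ct_tsv(path: str | Path) -> CtMatrix:
    values = pd.read_csv(Path(path), sep="\t", index_col="mirna_id")
    values.index.name = None
    replicate_of = None
    if all(c.endswith(("_A", "_B")) for c in values.columns):
        replicate_of = {c: c[:-2] for c in values.columns}
    return CtMatrix(values, replicate_of=replicate_of)


def write_mfi_tsv(mfi: MfiMatrix, path: str | Path) -> None:
    path = Path(path)
    mfi.values.to_csv(path, sep="\t", index_label="probe_id")
    roles = pd.DataFrame(
        {"well": list(mfi.values.columns),
         "role": [mfi.well_role[w] for w in mfi.values.columns]}
    )
    roles.to_csv(path.with_suffix(".roles.tsv"), sep="\t", index=False)


def read_mfi_tsv(path: str | Path) -> MfiMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="probe_id")
    values.index.name = None
    roles = pd.read_csv(path.with_suffix(".roles.tsv"), sep="\t")
    return MfiMatrix(values, well_role=dict(zip(roles["well"], roles["role"])))
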