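"""Domain types, tabular I/O and configuration for the dosimetry pipeline.

All activity quantities are held internally as decay-corrected fractions of
injected activity (dimensionless for whole organs, per gram for VOI
concentrations).  Time is in hours post-injection throughout; readers
normalise minute-stamped files on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SOURCE_REGIONS",
    "REGION_VOCABULARY",
    "DEFAULT_ALIASES",
    "Participant",
    "Measurement",
    "UrineSample",
    "PhantomConstants",
    "NuclideConstants",
    "CU64",
    "MALE_PHANTOM",
    "FEMALE_PHANTOM",
    "phantom_for_sex",
    "normalize_region",
    "read_measurements",
    "write_measurements",
    "read_urine_samples",
    "read_participants",
    "write_dose_report",
    "load_config",
]

#: Source regions entering the residence-time accounting.
SOURCE_REGIONS = (
    "liver",
    "kidneys",
    "bladder_content",
    "spleen",
    "red_marrow",
    "heart_content",
)

#: Closed vocabulary of measurable VOI regions.
REGION_VOCABULARY = frozenset(
    {
        "liver",
        "spleen",
        "kidneys",
        "red_marrow",
        "blood_pool",
        "bladder_content",
        "lesion",
        "iliac_bone",
    }
)

#: Common spellings mapped onto the controlled vocabulary.
DEFAULT_ALIASES: Mapping[str, str] = {
    "kidney": "kidneys",
    "marrow": "red_marrow",
    "bone_marrow": "red_marrow",
    "blood": "blood_pool",
    "left_ventricle": "blood_pool",
    "bladder": "bladder_content",
    "urinary_bladder": "bladder_content",
    "tumor": "lesion",
    "iliac": "iliac_bone",
}


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class ValidationError(ValueError):
    """A row violates a domain invariant."""


@dataclass(frozen=True)
class Participant:
    """One imaged participant; sex selects the reference phantom."""

    id: str
    sex: str  # "male" | "female"
    body_mass: float  # kg
    injected_activity: float  # MBq

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"participant {self.id}: sex must be male/female, got {self.sex!r}")
        if not self.body_mass > 0:
            raise ValidationError(f"participant {self.id}: body_mass must be > 0")
        if not self.injected_activity > 0:
            raise ValidationError(f"participant {self.id}: injected_activity must be > 0")


@dataclass(frozen=True)
class Measurement:
    """A VOI activity-concentration sample at one time point.

    ``value`` is the decay-corrected fraction of injected activity per gram
    (blood pool: per mL, water density assumed).
    """

    participant_id: str
    region: str
    t: float  # hours post-injection
    value: float
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"{self.participant_id}/{self.region}: t must be >= 0, got {self.t}")
        if self.value < 0:
            raise ValidationError(f"{self.participant_id}/{self.region}: value must be >= 0, got {self.value}")
        if self.region not in REGION_VOCABULARY:
            raise ValidationError(f"unknown region {self.region!r}; known: {sorted(REGION_VOCABULARY)}")


@dataclass(frozen=True)
class UrineSample:
    """Cumulative decay-corrected urinary excretion at one collection time."""

    participant_id: str
    t: float  # hours
    cumulative_fraction: float  # of injected activity

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"{self.participant_id}: urine time must be >= 0")
        if not 0.0 <= self.cumulative_fraction <= 1.0:
            raise ValidationError(
                f"{self.participant_id}: cumulative fraction must be in [0, 1], got {self.cumulative_fraction}"
            )


@dataclass(frozen=True)
class PhantomConstants:
    """Reference-adult organ masses and blood volumes for one sex.

    Masses in grams, volumes in mL.  ``organ_masses`` covers every source
    region measured as a concentration; the heart chamber and total blood
    volumes convert the left-ventricle blood-pool concentration into
    whole-blood and heart-content activities.
    """

    sex: str
    organ_masses: Mapping[str, float]
    total_blood_volume: float
    heart_chamber_volume: float
    body_mass: float  # g

    def __post_init__(self) -> None:
        for region, m in self.organ_masses.items():
            if not m > 0:
                raise ValidationError(f"{self.sex} phantom: mass of {region} must be > 0")
        if not (0 < self.heart_chamber_volume < self.total_blood_volume):
            raise ValidationError("heart chamber volume must be positive and below total blood volume")


@dataclass(frozen=True)
class NuclideConstants:
    """Physical decay constants of the radionuclide."""

    name: str
    half_life: float  # hours

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValidationError("half-life must be > 0")

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant, 1/h."""
        return math.log(2.0) / self.half_life


#: Cu-64: positron emitter with a 12.7-h half-life.
CU64 = NuclideConstants("Cu-64", 12.7)

MALE_PHANTOM = PhantomConstants(
    sex="male",
    organ_masses={
        "liver": 1800.0,
        "spleen": 150.0,
        "kidneys": 310.0,
        "red_marrow": 1170.0,
        "bladder_content": 200.0,
    },
    total_blood_volume=5300.0,
    heart_chamber_volume=500.0,
    body_mass=73000.0,
)

FEMALE_PHANTOM = PhantomConstants(
    sex="female",
    organ_masses={
        "liver": 1400.0,
        "spleen": 130.0,
        "kidneys": 275.0,
        "red_marrow": 900.0,
        "bladder_content": 160.0,
    },
    total_blood_volume=3900.0,
    heart_chamber_volume=370.0,
    body_mass=60000.0,
)


def phantom_for_sex(sex: str) -> PhantomConstants:
    if sex == "male":
        return MALE_PHANTOM
    if sex == "female":
        return FEMALE_PHANTOM
    raise ValidationError(f"unknown sex {sex!r}")


def normalize_region(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Canonicalise a region label (case, whitespace, aliases)."""
    name = raw.strip().lower().replace(" ", "_").replace("-", "_")
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({normalize_region(k): v for k, v in aliases.items()})
    return table.get(name, name)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_measurements(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    nuclide: NuclideConstants = CU64,
    times_in_minutes: bool = False,
) -> list[Measurement]:
    """Read a VOI measurement table.

    Expected columns: ``participant_id, region, t, value`` and optionally
    ``decay_corrected`` (default true).  Values not decay corrected are
    corrected on read with exp(+lambda t), so downstream code always sees
    biological curves.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "region", "t", "value"], path)
    records: list[Measurement] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        t = float(row.t) / 60.0 if times_in_minutes else float(row.t)
        value = float(row.value)
        if t < 0:
            raise ValidationError(f"{path} row {idx}: negative time {t}")
        if value < 0:
            raise ValidationError(f"{path} row {idx}: negative value {value}")
        corrected = bool(getattr(row, "decay_corrected", True))
        if not corrected:
            value *= math.exp(nuclide.lambda_phys * t)
        region = normalize_region(str(row.region), aliases)
        try:
            records.append(
                Measurement(
                    participant_id=str(row.participant_id),
                    region=region,
                    t=t,
                    value=value,
                    decay_corrected=True,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path} row {idx}: {err}") from err
    return records


def write_measurements(records: Iterable[Measurement], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in records],
            "region": [m.region for m in records],
            "t": [m.t for m in records],
            "value": [m.value for m in records],
            "decay_corrected": [m.decay_corrected for m in records],
        }
    )
    df.to_csv(path, index=False)


def read_urine_samples(path: str | Path) -> list[UrineSample]:
    """Read a cumulative urine-collection table.

    Expected columns: ``participant_id, t, cumulative_fraction``.  Fractions
    must be decay corrected and non-decreasing per participant.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "t", "cumulative_fraction"], path)
    samples: list[UrineSample] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            samples.append(
                UrineSample(
                    participant_id=str(row.participant_id),
                    t=float(row.t),
                    cumulative_fraction=float(row.cumulative_fraction),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path} row {idx}: {err}") from err
    for pid in {s.participant_id for s in samples}:
        series = sorted((s.t, s.cumulative_fraction) for s in samples if s.participant_id == pid)
        fracs = [f for _, f in series]
        if any(b < a - 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValidationError(f"{path}: cumulative urine for {pid} is not non-decreasing")
    return samples


def read_participants(path: str | Path) -> list[Participant]:
    """Read demographics: ``participant_id, sex, body_mass, injected_activity``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "sex", "body_mass", "injected_activity"], path)
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        sex = str(row.sex).strip().lower()
        sex = {"m": "male", "f": "female"}.get(sex, sex)
        try:
            out.append(
                Participant(
                    id=str(row.participant_id),
                    sex=sex,
                    body_mass=float(row.body_mass),
                    injected_activity=float(row.injected_activity),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path} row {idx}: {err}") from err
    return out


def write_dose_report(
    per_participant: pd.DataFrame,
    sexes: Mapping[str, str],
    out_dir: str | Path,
    decimals: int = 3,
) -> pd.DataFrame:
    """Write the per-participant dose table plus an Average/M/F summary.

    ``per_participant`` is organs (rows) x participants (columns) in mSv/MBq.
    The summary carries mean and SD overall and stratified by sex, rounded to
    ``decimals`` as in standard dose reports.  Returns the summary frame.
    """
    if per_participant.empty:
        raise ValidationError("refusing to write an empty dose report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_participant.round(decimals).to_csv(out_dir / "doses_per_participant.csv")

    summary = summarize_table(per_participant, sexes)
    summary.round(decimals).to_csv(out_dir / "doses_summary.csv")
    return summary


def summarize_table(per_participant: pd.DataFrame, sexes: Mapping[str, str]) -> pd.DataFrame:
    """Average/M/F mean-and-SD summary of an organs x participants table.

    Blank cells (phantom organs absent for a sex) are ignored in the means,
    matching how sex-specific organs are averaged in dosimetry reports.
    With a single participant the SD columns are 0.
    """
    males = [c for c in per_participant.columns if sexes.get(c) == "male"]
    females = [c for c in per_participant.columns if sexes.get(c) == "female"]
    out = pd.DataFrame(index=per_participant.index)
    out["average"] = per_participant.mean(axis=1)
    out["sd"] = per_participant.std(axis=1, ddof=1).fillna(0.0)
    for label, cols in (("m", males), ("f", females)):
        if cols:
            sub = per_participant[cols]
            out[f"{label}_average"] = sub.mean(axis=1)
            out[f"{label}_sd"] = sub.std(axis=1, ddof=1).fillna(0.0)
    return out


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration (missing keys fall back to defaults)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: top level of config must be a mapping")
    return cfg
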