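"""Domain types and CSV ingestion for diet-diary datasets.

A dataset couples three tables: a participant roster (sex, age, survey
weight, number of diary days), a diary of consumption events (who ate how
many grams of which food on which day), and a food composition table giving
total dietary fibre per 100 g of each food as consumed.  Foods additionally
carry a reformulation category (``white_flour``, ``wholemeal`` or ``other``)
taken from a separate category-map file, which is what scenario scaling
keys on.

The fibre column is interpreted throughout as AOAC total dietary fibre
(the basis of the UK 30 g/day adult recommendation); the label is a
documented convention, not enforced — NSP values can be used as long as
the recommendation schedule is adjusted to match.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "Sex",
    "FoodItem",
    "Participant",
    "DiaryEntry",
    "Dataset",
    "Violation",
    "InputFormatError",
    "IntegrityError",
    "load_dataset",
    "validate_dataset",
    "write_dataset",
]


class InputFormatError(ValueError):
    """A CSV file could not be parsed against its documented schema."""


class IntegrityError(ValueError):
    """Referential integrity or uniqueness of a dataset is broken."""


class Category(str, enum.Enum):
    """Reformulation category of a food item."""

    WHITE_FLOUR = "white_flour"
    WHOLEMEAL = "wholemeal"
    OTHER = "other"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class FoodItem:
    """One row of the composition table.

    ``fibre_g_per_100g`` is grams of total dietary fibre per 100 g of the
    food as consumed.  ``custom_factor``, when set, overrides the
    category-level scaling factor for this food only.
    """

    food_code: str
    description: str
    category: Category
    fibre_g_per_100g: float
    custom_factor: float | None = None


@dataclass(frozen=True)
class Participant:
    participant_id: str
    sex: Sex
    age_years: float
    survey_weight: float = 1.0
    diary_days: int = 4


@dataclass(frozen=True)
class DiaryEntry:
    """One consumption event: ``amount_g`` grams of a food on one diary day."""

    participant_id: str
    day_index: int
    food_code: str
    amount_g: float


@dataclass
class Dataset:
    """A validated bundle of participants, diary entries and foods."""

    participants: list[Participant] = field(default_factory=list)
    entries: list[DiaryEntry] = field(default_factory=list)
    foods: list[FoodItem] = field(default_factory=list)

    def food_index(self) -> dict[str, FoodItem]:
        return {f.food_code: f for f in self.foods}

    def participant_index(self) -> dict[str, Participant]:
        return {p.participant_id: p for p in self.participants}

    def entries_frame(self) -> pd.DataFrame:
        """Diary entries as a DataFrame (column-wise build, fast for large diaries)."""
        return pd.DataFrame(
            {
                "participant_id": [e.participant_id for e in self.entries],
                "day_index": [e.day_index for e in self.entries],
                "food_code": [e.food_code for e in self.entries],
                "amount_g": [e.amount_g for e in self.entries],
            }
        )

    def participants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "sex": [p.sex.value for p in self.participants],
                "age_years": [p.age_years for p in self.participants],
                "survey_weight": [p.survey_weight for p in self.participants],
                "diary_days": [p.diary_days for p in self.participants],
            }
        )

    def foods_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "food_code": [f.food_code for f in self.foods],
                "description": [f.description for f in self.foods],
                "category": [f.category.value for f in self.foods],
                "fibre_g_per_100g": [f.fibre_g_per_100g for f in self.foods],
                "custom_factor": [f.custom_factor for f in self.foods],
            }
        )


@dataclass(frozen=True)
class Violation:
    """One broken invariant: which record, which rule, human-readable detail."""

    record: str
    rule: str
    message: str


_PARTICIPANT_COLS = ["participant_id", "sex", "age_years", "survey_weight", "diary_days"]
_ENTRY_COLS = ["participant_id", "day_index", "food_code", "amount_g"]
_FOOD_COLS = ["food_code", "description", "fibre_g_per_100g"]
_CATMAP_COLS = ["food_code", "category"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"{path}: file does not exist")
    try:
        frame = pd.read_csv(
            path,
            dtype={c: str for c in ("participant_id", "food_code")},
            float_precision="round_trip",
        )
    except Exception as exc:  # pandas raises several parser error types
        raise InputFormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required column(s) {missing}")
    return frame


def load_dataset(
    participants_path: str | Path,
    entries_path: str | Path,
    foods_path: str | Path,
    category_map_path: str | Path,
) -> Dataset:
    """Read the four CSV inputs, join categories onto foods, and validate.

    Foods absent from the category map default to ``other`` (logged).
    Duplicate identifiers or unresolved references raise :class:`IntegrityError`;
    malformed files raise :class:`InputFormatError` naming the file.
    """
    pframe = _read_csv(participants_path, _PARTICIPANT_COLS)
    eframe = _read_csv(entries_path, _ENTRY_COLS)
    fframe = _read_csv(foods_path, _FOOD_COLS)
    cframe = _read_csv(category_map_path, _CATMAP_COLS)

    try:
        participants = [
            Participant(
                participant_id=str(row.participant_id),
                sex=Sex(str(row.sex)),
                age_years=float(row.age_years),
                survey_weight=float(row.survey_weight),
                diary_days=int(row.diary_days),
            )
            for row in pframe.itertuples(index=False)
        ]
    except (ValueError, TypeError) as exc:
        raise InputFormatError(f"{participants_path}: bad field value ({exc})") from exc

    try:
        entries = [
            DiaryEntry(
                participant_id=str(row.participant_id),
                day_index=int(row.day_index),
                food_code=str(row.food_code),
                amount_g=float(row.amount_g),
            )
            for row in eframe.itertuples(index=False)
        ]
    except (ValueError, TypeError) as exc:
        raise InputFormatError(f"{entries_path}: bad field value ({exc})") from exc

    catmap: dict[str, Category] = {}
    custom: dict[str, float] = {}
    has_custom = "custom_factor" in cframe.columns
    for row in cframe.itertuples(index=False):
        code = str(row.food_code)
        try:
            catmap[code] = Category(str(row.category))
        except ValueError as exc:
            raise InputFormatError(
                f"{category_map_path}: unknown category {row.category!r} for food {code}"
            ) from exc
        if has_custom and pd.notna(row.custom_factor):
            custom[code] = float(row.custom_factor)

    foods = []
    for row in fframe.itertuples(index=False):
        code = str(row.food_code)
        if code not in catmap:
            logger.warning("food %s has no category-map entry; defaulting to 'other'", code)
        try:
            foods.append(
                FoodItem(
                    food_code=code,
                    description=str(row.description),
                    category=catmap.get(code, Category.OTHER),
                    fibre_g_per_100g=float(row.fibre_g_per_100g),
                    custom_factor=custom.get(code),
                )
            )
        except (ValueError, TypeError) as exc:
            raise InputFormatError(f"{foods_path}: bad field value ({exc})") from exc

    dataset = Dataset(participants=participants, entries=entries, foods=foods)
    violations = validate_dataset(dataset)
    if violations:
        detail = "; ".join(f"{v.record}: {v.message}" for v in violations[:10])
        raise IntegrityError(f"{len(violations)} integrity violation(s): {detail}")
    return dataset


def validate_dataset(d: Dataset) -> list[Violation]:
    """Check every dataset invariant; violations are returned, never raised.

    The function is pure: it inspects the dataset and builds a fresh list on
    every call.
    """
    out: list[Violation] = []

    seen_p: set[str] = set()
    for p in d.participants:
        rec = f"participant {p.participant_id}"
        if p.participant_id in seen_p:
            out.append(Violation(rec, "unique-participant-id", "duplicate participant_id"))
        seen_p.add(p.participant_id)
        if not (1.5 <= p.age_years <= 120):
            out.append(Violation(rec, "age-range", f"age_years {p.age_years} outside [1.5, 120]"))
        if not p.survey_weight > 0:
            out.append(Violation(rec, "positive-weight", f"survey_weight {p.survey_weight} must be > 0"))
        if p.diary_days < 1:
            out.append(Violation(rec, "diary-days", f"diary_days {p.diary_days} must be >= 1"))

    seen_f: set[str] = set()
    for f in d.foods:
        rec = f"food {f.food_code}"
        if f.food_code in seen_f:
            out.append(Violation(rec, "unique-food-code", "duplicate food_code"))
        seen_f.add(f.food_code)
        if f.fibre_g_per_100g < 0:
            out.append(Violation(rec, "non-negative-fibre", f"fibre_g_per_100g {f.fibre_g_per_100g} < 0"))
        if f.custom_factor is not None and f.custom_factor < 0:
            out.append(Violation(rec, "non-negative-factor", f"custom_factor {f.custom_factor} < 0"))

    pindex = d.participant_index()
    for i, e in enumerate(d.entries):
        rec = f"entry {i} (participant {e.participant_id}, day {e.day_index}, food {e.food_code})"
        participant = pindex.get(e.participant_id)
        if participant is None:
            out.append(Violation(rec, "participant-reference", f"unknown participant_id {e.participant_id!r}"))
        elif not (1 <= e.day_index <= participant.diary_days):
            out.append(
                Violation(
                    rec,
                    "day-range",
                    f"day_index {e.day_index} outside [1, diary_days={participant.diary_days}]",
                )
            )
        if e.food_code not in seen_f:
            out.append(Violation(rec, "food-reference", f"unknown food_code {e.food_code!r}"))
        if e.amount_g < 0:
            out.append(Violation(rec, "non-negative-amount", f"amount_g {e.amount_g} < 0"))

    return out


def write_dataset(d: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four CSV files of the input schema; returns name → path.

    Output is deterministic for a given dataset, so identical datasets
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out_dir / "participants.csv",
        "entries": out_dir / "entries.csv",
        "foods": out_dir / "foods.csv",
        "category_map": out_dir / "category_map.csv",
    }
    # shortest round-trip float repr so written values re-load bit-identically
    fmt = {"float_format": lambda v: repr(float(v))}
    d.participants_frame().to_csv(paths["participants"], index=False, **fmt)
    d.entries_frame().to_csv(paths["entries"], index=False, **fmt)
    foods = d.foods_frame()
    foods[["food_code", "description", "fibre_g_per_100g"]].to_csv(paths["foods"], index=False, **fmt)
    foods[["food_code", "category", "custom_factor"]].to_csv(paths["category_map"], index=False, **fmt)
    return paths
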