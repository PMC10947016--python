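from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from fibrescen.data_model import (
    Category,
    Dataset,
    DiaryEntry,
    FoodItem,
    Participant,
    Sex,
)

FOODS = [
    FoodItem("WB01", "white bread", Category.WHITE_FLOUR, 4.0),
    FoodItem("WM01", "wholemeal bread", Category.WHOLEMEAL, 7.0),
    FoodItem("OT01", "baked beans", Category.OTHER, 5.1),
]


def small_dataset() -> Dataset:
    """Hand-written 2-participant, 3-food, 6-entry dataset."""
    participants = [
        Participant("p1", Sex.MALE, 35.0, survey_weight=1.2, diary_days=4),
        Participant("p2", Sex.FEMALE, 8.0, survey_weight=0.8, diary_days=3),
    ]
    entries = [
        DiaryEntry("p1", 1, "WB01", 150.0),
        DiaryEntry("p1", 2, "WB01", 100.0),
        DiaryEntry("p1", 2, "WM01", 80.0),
        DiaryEntry("p1", 4, "OT01", 200.0),
        DiaryEntry("p2", 1, "WB01", 60.0),
        DiaryEntry("p2", 3, "OT01", 130.0),
    ]
    return Dataset(participants=participants, entries=entries, foods=list(FOODS))


@pytest.fixture
def dataset() -> Dataset:
    return small_dataset()


def random_dataset(
    rng: np.random.Generator,
    n_participants: int = 10,
    n_entries: int = 50,
    with_custom: bool = False,
) -> Dataset:
    """Randomised dataset for oracle comparisons (no structure beyond validity)."""
    foods = [
        FoodItem(
            f"F{i:02d}",
            f"food {i}",
            list(Category)[i % 3],
            float(rng.uniform(0.5, 10.0)),
            custom_factor=float(rng.uniform(0.5, 2.0)) if with_custom and i % 4 == 0 else None,
        )
        for i in range(6)
    ]
    participants = [
        Participant(
            f"p{i}",
            Sex.MALE if i % 2 else Sex.FEMALE,
            float(rng.uniform(2.0, 90.0)),
            survey_weight=float(rng.uniform(0.3, 3.0)),
            diary_days=int(rng.integers(1, 5)),
        )
        for i in range(n_participants)
    ]
    entries = [
        DiaryEntry(
            participants[int(rng.integers(n_participants))].participant_id,
            1,
            foods[int(rng.integers(len(foods)))].food_code,
            float(rng.uniform(0.0, 400.0)),
        )
        for _ in range(n_entries)
    ]
    # keep day_index within each participant's diary
    fixed = []
    by_id = {p.participant_id: p for p in participants}
    for e in entries:
        days = by_id[e.participant_id].diary_days
        fixed.append(DiaryEntry(e.participant_id, int(rng.integers(1, days + 1)), e.food_code, e.amount_g))
    return Dataset(participants=participants, entries=fixed, foods=foods)


def write_csvs(dataset: Dataset, out_dir: Path) -> dict[str, Path]:
    from fibrescen.data_model import write_dataset

    return write_dataset(dataset, out_dir)
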