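"""Overall-tract apparent digestibility from lignin as an indigestible marker."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class DigestibilityError(ValueError):
    """Raised on invalid marker inputs."""


@dataclass(frozen=True)
class MarkerInputs:
    """Nutrient:lignin ratios plus dry-matter intakes (kg/d) for one diet."""

    feces_ratio: float
    forage_ratio: float
    supplement_ratio: float = 0.0
    forage_dmi: float = 1.0
    supplement_dmi: float = 0.0

    def __post_init__(self) -> None:
        if self.forage_dmi < 0 or self.supplement_dmi < 0:
            raise DigestibilityError("intakes must be non-negative")
        if self.forage_dmi + self.supplement_dmi <= 0:
            raise DigestibilityError("total dry-matter intake must be positive")
        if self.feces_ratio < 0:
            raise DigestibilityError("feces ratio must be non-negative")


def diet_ratio(inputs: MarkerInputs) -> float:
    """Intake-weighted nutrient:lignin ratio of the whole diet.

    The forage and supplement ratios are averaged with weights equal to their
    dry-matter consumptions, so the result always lies between the two
    component ratios.
    """
    total = inputs.forage_dmi + inputs.supplement_dmi
    return (
        inputs.forage_ratio * inputs.forage_dmi
        + inputs.supplement_ratio * inputs.supplement_dmi
    ) / total


def apparent_digestibility(feces_ratio: float, diet_ratio: float) -> tuple[float, bool]:
    """Apparent digestibility (kg/kg) as ``1 - feces_ratio / diet_ratio``.

    Returns ``(digestibility, negative_flag)``.  Negative values (feces ratio
    above the diet ratio) are reported, not clipped: marker methods can
    legitimately produce them and clipping would hide data problems.
    """
    if diet_ratio <= 0:
        raise DigestibilityError("diet ratio must be positive")
    if feces_ratio < 0:
        raise DigestibilityError("feces ratio must be non-negative")
    value = 1.0 - feces_ratio / diet_ratio
    return value, value < 0


def digestibility_table(
    feed: pd.DataFrame, feces: pd.DataFrame, intakes: pd.DataFrame
) -> pd.DataFrame:
    """Apparent digestibility per (animal, season, diet, nutrient).

    ``feed`` needs columns diet, component (forage/supplement), nutrient,
    ratio; ``feces`` needs animal, season, diet, nutrient, ratio; ``intakes``
    needs animal, season, diet, forage_dmi, supplement_dmi.
    """
    records = []
    feed_idx = feed.set_index(["diet", "component", "nutrient"])["ratio"]
    intake_idx = intakes.set_index(["animal", "season", "diet"])
    for _, row in feces.iterrows():
        key = (row["animal"], row["season"], row["diet"])
        try:
            intake = intake_idx.loc[key]
        except KeyError as exc:
            raise DigestibilityError(f"no intake record for {key}") from exc
        r_for = feed_idx.get((row["diet"], "forage", row["nutrient"]))
        if r_for is None:
            raise DigestibilityError(
                f"no forage ratio for diet {row['diet']!r}/{row['nutrient']!r}"
            )
        r_sup = feed_idx.get((row["diet"], "supplement", row["nutrient"]), 0.0)
        mi = MarkerInputs(
            feces_ratio=row["ratio"],
            forage_ratio=r_for,
            supplement_ratio=r_sup,
            forage_dmi=float(intake["forage_dmi"]),
            supplement_dmi=float(intake["supplement_dmi"]),
        )
        dr = diet_ratio(mi)
        value, negative = apparent_digestibility(mi.feces_ratio, dr)
        records.append(
            {
                "animal": row["animal"],
                "season": row["season"],
                "diet": row["diet"],
                "nutrient": row["nutrient"],
                "diet_ratio": dr,
                "feces_ratio": mi.feces_ratio,
                "digestibility": value,
                "negative_flag": negative,
            }
        )
    return pd.DataFrame.from_records(records)
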