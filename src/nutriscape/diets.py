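"""Diet grid construction for two-nutrient (protein, carbohydrate) designs.

A diet is described by its P:C ratio in parts and by the fraction of diet
mass that is nutritional (protein + carbohydrate); the remainder is inert
bulk.  The landscape coordinates used everywhere downstream are the protein
and carbohydrate percentages of total diet mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError

#: The ten P:C ratios of the reference experimental design.
DEFAULT_RATIOS: tuple[tuple[float, float], ...] = (
    (3, 1),
    (2, 1),
    (1.5, 1),
    (1, 1),
    (1, 1.5),
    (1, 2),
    (1, 3),
    (1, 5),
    (1, 8),
    (1, 16),
)

#: The four total-nutrition dilutions (fraction of diet mass that is P + C).
DEFAULT_TOTALS: tuple[float, ...] = (0.12, 0.36, 0.60, 0.80)


def _fmt_part(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class DietSpec:
    """One diet: a P:C ratio in parts plus a total-nutrition dilution.

    ``protein_pct`` and ``carbohydrate_pct`` are percentages of total diet
    mass and sum to ``100 * total_nutrition``.
    """

    diet_id: str
    p_parts: float
    c_parts: float
    total_nutrition: float

    def __post_init__(self) -> None:
        if self.p_parts < 0 or self.c_parts < 0:
            raise ValidationError("ratio parts must be nonnegative")
        if self.p_parts == 0 and self.c_parts == 0:
            raise ValidationError("ratio parts cannot both be zero")
        if not 0 < self.total_nutrition <= 1:
            raise ValidationError("total_nutrition must lie in (0, 1]")

    @property
    def protein_pct(self) -> float:
        return 100.0 * self.total_nutrition * self.p_parts / (self.p_parts + self.c_parts)

    @property
    def carbohydrate_pct(self) -> float:
        return 100.0 * self.total_nutrition * self.c_parts / (self.p_parts + self.c_parts)

    @classmethod
    def from_parts(
        cls, p_parts: float, c_parts: float, total_nutrition: float
    ) -> "DietSpec":
        diet_id = (
            f"{_fmt_part(p_parts)}:{_fmt_part(c_parts)}"
            f"@{_fmt_part(total_nutrition * 100)}"
        )
        return cls(diet_id, float(p_parts), float(c_parts), float(total_nutrition))


def build_diet_grid(
    ratios: Sequence[tuple[float, float]] = DEFAULT_RATIOS,
    totals: Iterable[float] = DEFAULT_TOTALS,
) -> list[DietSpec]:
    """Construct the full factorial ratio x dilution diet grid.

    Parameters
    ----------
    ratios:
        (p_parts, c_parts) pairs; parts must be nonnegative and not both zero.
    totals:
        Total-nutrition fractions in (0, 1].

    Returns
    -------
    list of :class:`DietSpec`, one per ratio x total combination, with
    unique ``diet_id`` labels of the form ``"<p>:<c>@<total%>"``.
    """
    ratios = list(ratios)
    totals = list(totals)
    if not ratios:
        raise ValidationError("at least one P:C ratio is required")
    if not totals:
        raise ValidationError("at least one total-nutrition level is required")
    grid = [
        DietSpec.from_parts(p, c, t) for (p, c) in ratios for t in totals
    ]
    ids = [d.diet_id for d in grid]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate diets in the requested grid")
    return grid
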