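"""Classification and tallying of excision-screen PCR band patterns.

Each plant in the screen is genotyped with two PCR reactions: a target-locus
reaction whose product size reveals whether the att-flanked segment is still
present (unexcised band) or has been excised (excision band), and a
recombinase-gene reaction.  The three boolean band calls per plant are
classified into the category columns used by the screening tables for the
retransformant (TR1), backcross/self (BC1/S1), and manual-cross (MC1)
generations, tallied per family, and aggregated into the headline
percentages (e.g. fraction of target-carrying progeny showing excision).

Band calling from gel images is out of scope: booleans are the input
contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

GENERATIONS = ("TR1", "BC1", "S1", "MC1")


@dataclass(frozen=True)
class PlantRecord:
    """One plant's generation/family plus its three PCR band calls."""

    family: str
    generation: str
    band_excision: bool
    band_unexcised: bool
    band_recombinase: bool

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise ValueError(f"unknown generation {self.generation!r}")


@dataclass(frozen=True)
class CategoryFlags:
    """Derived category memberships for one plant.

    ``target_positive``     — either target-locus band present
    ``excision_positive``   — excision band present
    ``excised_only``        — excision band without the unexcised band
    ``recombinase_positive``— recombinase band present
    ``excision_no_recombinase`` — excision band without the recombinase band
    ``recombinase_no_target``   — recombinase band without any target band
    """

    target_positive: bool
    excision_positive: bool
    excised_only: bool
    recombinase_positive: bool
    excision_no_recombinase: bool
    recombinase_no_target: bool


def classify(record: PlantRecord) -> CategoryFlags:
    """Deterministic boolean mapping from band calls to screen categories."""
    target = record.band_excision or record.band_unexcised
    return CategoryFlags(
        target_positive=target,
        excision_positive=record.band_excision,
        excised_only=record.band_excision and not record.band_unexcised,
        recombinase_positive=record.band_recombinase,
        excision_no_recombinase=record.band_excision and not record.band_recombinase,
        recombinase_no_target=record.band_recombinase and not target,
    )


# Column scheme of each screening table, as (column, membership test).
SCHEMAS: dict[str, list[str]] = {
    "TR1": ["recombinase_and_target", "excision_positive", "excision_no_unexcised"],
    "BC1": [
        "target_positive",
        "excision_positive",
        "excision_no_recombinase",
        "recombinase_no_target",
    ],
    "MC1": [
        "target_positive",
        "recombinase_positive",
        "excision_and_recombinase",
        "excision_no_unexcised",
    ],
}
# S1 plants are scored with the BC1 column scheme
SCHEMAS["S1"] = SCHEMAS["BC1"]


def _category_value(record: PlantRecord, flags: CategoryFlags, column: str) -> bool:
    if column == "recombinase_and_target":
        return flags.recombinase_positive and flags.target_positive
    if column == "excision_and_recombinase":
        return flags.excision_positive and flags.recombinase_positive
    if column == "excision_no_unexcised":
        return flags.excised_only
    return getattr(flags, column)


def tally(records: Iterable[PlantRecord], schema: str) -> pd.DataFrame:
    """Tally per-plant records into one row of category counts per family.

    Column scheme is selected by ``schema`` (one of TR1, BC1, S1, MC1).
    Families appear in first-seen order; an empty record list yields an empty
    table with the schema's columns.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {list(SCHEMAS)}")
    columns = SCHEMAS[schema]
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        flags = classify(rec)
        row = rows.setdefault(
            rec.family, {"plants_tested": 0, **{c: 0 for c in columns}}
        )
        row["plants_tested"] += 1
        for col in columns:
            row[col] += int(_category_value(rec, flags, col))
    df = pd.DataFrame(
        [{"family": fam, **counts} for fam, counts in rows.items()],
        columns=["family", "plants_tested", *columns],
    )
    return df.astype({c: int for c in ["plants_tested", *columns]} if len(df) else {})


@dataclass(frozen=True)
class AggregateResult:
    fraction: Fraction
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return float(self.fraction)

    def percent(self, decimals: int = 0) -> float:
        return round(100 * self.numerator / self.denominator, decimals)

    def formatted(self, decimals: int = 0) -> str:
        return f"{self.percent(decimals):.{decimals}f}%"


def aggregate(
    rows: pd.DataFrame, numerator: str, denominator: str
) -> AggregateResult:
    """Ratio of two column sums over a tally table, as an exact rational.

    ``denominator`` may be any table column including ``plants_tested``.
    The result is invariant under row order and family partitioning, since it
    sums counts before dividing.
    """
    num = int(rows[numerator].sum())
    den = int(rows[denominator].sum())
    if den == 0:
        raise ZeroDivisionError(f"denominator column {denominator!r} sums to zero")
    return AggregateResult(Fraction(num, den), num, den)


def lines_with_positive(rows: pd.DataFrame, column: str) -> int:
    """Number of families with at least one plant in a category."""
    return int((rows[column] > 0).sum())


def read_records_tsv(path) -> list[PlantRecord]:
    """Read per-plant records from TSV (family, generation, three band calls)."""
    df = pd.read_csv(path, sep="\t")
    return [
        PlantRecord(
            family=str(r.family),
            generation=str(r.generation),
            band_excision=bool(int(r.band_excision)),
            band_unexcised=bool(int(r.band_unexcised)),
            band_recombinase=bool(int(r.band_recombinase)),
        )
        for r in df.itertuples()
    ]


def load_table(name: str, family_prefix: Optional[str] = None) -> pd.DataFrame:
    """Load one of the packaged screening-count tables.

    ``name`` is ``tr1``, ``bc1`` or ``mc1``.  These are pre-tallied family
    count tables (the published screen), in the same column scheme
    :func:`tally` emits, usable directly with :func:`aggregate`.  An optional
    ``family_prefix`` filters rows (e.g. ``"Bxb1.9."`` for one parent line).
    """
    fname = {"tr1": "table_tr1.tsv", "bc1": "table_bc1.tsv", "mc1": "table_mc1.tsv"}[
        name.lower()
    ]
    with resources.files("attkit.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if family_prefix is not None:
        df = df[df["family"].str.startswith(family_prefix)].reset_index(drop=True)
    return df
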