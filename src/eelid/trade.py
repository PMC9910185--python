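"""Trade-ledger consistency check.

European eels are CITES Appendix-II listed: every lawful export to the US
needs a permit.  The mass fraction of permitted European-eel imports among
all freshwater-eel imports is therefore the frequency of European eels one
would expect to see at retail if all trade were lawful.  Comparing that
fraction with the market-survey confidence interval asks whether the
observed retail frequency is consistent with legal trade alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError
from .survey import FrequencyEstimate

#: USDA-reported freshwater-eel import mass and CITES-permitted
#: European-eel mass over the 2019-2021 study period, in kg.
STUDY_YEARS = (2019, 2021)
STUDY_IMPORTS_KG = 16_795_248.0
STUDY_PERMITS_KG = 265_500.0


def study_ledger() -> "TradeLedger":
    """Totals-only ledger holding the 2019-2021 study-period aggregates."""
    return TradeLedger.from_totals(
        STUDY_IMPORTS_KG, STUDY_PERMITS_KG, years=STUDY_YEARS
    )


@dataclass(frozen=True)
class ImportRow:
    year: int
    country: str
    district: str
    mass_kg: float


@dataclass(frozen=True)
class PermitRow:
    year: int
    mass_kg: float


@dataclass
class TradeLedger:
    """Freshwater-eel import masses and CITES-permitted export masses."""

    import_rows: list[ImportRow]
    permit_rows: list[PermitRow]

    def __post_init__(self) -> None:
        for row in [*self.import_rows, *self.permit_rows]:
            if row.mass_kg < 0:
                raise InputError("trade masses must be non-negative")

    @classmethod
    def from_totals(
        cls,
        imports_kg: float,
        permits_kg: float,
        years: tuple[int, int] = (2019, 2021),
    ) -> "TradeLedger":
        """Totals-only shortcut: one aggregate row per ledger."""
        y = years[0]
        return cls(
            import_rows=[ImportRow(y, "all", "all", imports_kg)],
            permit_rows=[PermitRow(y, permits_kg)],
        )

    @classmethod
    def from_csv(cls, imports_path: str | Path, permits_path: str | Path) -> "TradeLedger":
        """Read the two ledger CSVs.

        Imports: columns ``year, country, district, mass_kg``.
        Permits: columns ``year, mass_kg``.
        """
        imports: list[ImportRow] = []
        with open(imports_path, newline="") as fh:
            for row in csv.DictReader(fh):
                imports.append(
                    ImportRow(
                        year=int(row["year"]),
                        country=row.get("country", ""),
                        district=row.get("district", ""),
                        mass_kg=float(row["mass_kg"]),
                    )
                )
        permits: list[PermitRow] = []
        with open(permits_path, newline="") as fh:
            for row in csv.DictReader(fh):
                permits.append(
                    PermitRow(year=int(row["year"]), mass_kg=float(row["mass_kg"]))
                )
        if not imports:
            raise InputError(f"no import rows in {imports_path}")
        return cls(import_rows=imports, permit_rows=permits)


@dataclass(frozen=True)
class ConsistencyReport:
    legal_fraction: float
    observed: FrequencyEstimate
    inside_ci: bool


def legal_fraction(
    ledger: TradeLedger, years: tuple[int, int] | None = None
) -> float:
    """Percent of imported freshwater-eel mass covered by CITES permits,
    over an optional inclusive year range, rounded to one decimal."""
    def in_range(year: int) -> bool:
        return years is None or years[0] <= year <= years[1]

    total = sum(r.mass_kg for r in ledger.import_rows if in_range(r.year))
    permitted = sum(r.mass_kg for r in ledger.permit_rows if in_range(r.year))
    if total <= 0:
        raise InputError("zero import mass in the selected year range")
    return round(100.0 * permitted / total, 1)


def consistency_check(
    estimate: FrequencyEstimate, expected: float
) -> ConsistencyReport:
    """Is the legally-expected frequency inside the survey's CI?

    The interval is treated as closed: an expected value equal to an
    endpoint counts as inside.
    """
    low, high = estimate.ci
    return ConsistencyReport(
        legal_fraction=expected,
        observed=estimate,
        inside_ci=bool(low <= expected <= high),
    )
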