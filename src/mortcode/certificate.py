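"""Death-certificate data model, CSV I/O, demographic binning and the grid encoding.

A certificate carries Part I (up to 4 lines listing the chain of events in
inverse causal order: immediate cause on line 1, underlying cause on the
last used line) and Part II (up to 2 lines of other significant
conditions).  Each line is a sequence of ICD-10 codes.  For modelling, the
six lines are laid out as a padded ``L x W`` integer grid (default 6 x 20),
Part I on rows 0-3 and Part II on rows 4-5.

Demographics are factorized: gender (2 states), year of death (default 16
states, 2000-2015) and age in 25 bins — two classes under one year (the
neonatal period under 28 days, then 28 days to one year), 1-4 years, then
5-year intervals up to 105-109, and 110+.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .vocabulary import CodeError, Vocabulary, parse_code

__all__ = [
    "Demographics",
    "Certificate",
    "bin_age",
    "encode_grid",
    "decode_grid",
    "read_certificates",
    "write_certificates",
    "DEFAULT_BASE_YEAR",
    "DEFAULT_N_YEARS",
    "N_AGE_BINS",
]

DEFAULT_BASE_YEAR = 2000
DEFAULT_N_YEARS = 16
N_AGE_BINS = 25
DAYS_PER_YEAR = 365.25

MAX_PART1_LINES = 4
MAX_PART2_LINES = 2


def bin_age(age_value: float, age_unit: str) -> int:
    """Factorize an age at death into one of the 25 bins.

    Bin 0 is the neonatal period (0-27 days), bin 1 the rest of the first
    year, bin 2 ages 1-4, bins 3-23 the 5-year intervals 5-9 ... 105-109,
    and bin 24 ages 110 and over.  The bins tile [0, inf) exactly.
    """
    if age_unit not in ("days", "years"):
        raise ValueError(f"age_unit must be 'days' or 'years', got {age_unit!r}")
    if age_value < 0:
        raise ValueError(f"negative age: {age_value}")
    days = age_value if age_unit == "days" else age_value * DAYS_PER_YEAR
    if days < 28:
        return 0
    if days < DAYS_PER_YEAR:
        return 1
    years = days / DAYS_PER_YEAR
    if years < 5:
        return 2
    if years >= 110:
        return 24
    return 3 + int((years - 5) // 5)


@dataclass(frozen=True)
class Demographics:
    """Factorized covariates: age bin (0-24), gender (0=male, 1=female),
    year index (0..n_years-1, calendar year minus the base year)."""

    age_bin: int
    gender: int
    year_index: int
    n_years: int = DEFAULT_N_YEARS

    def __post_init__(self) -> None:
        if not 0 <= self.age_bin < N_AGE_BINS:
            raise ValueError(f"age_bin {self.age_bin} outside 0..{N_AGE_BINS - 1}")
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 or 1, got {self.gender}")
        if not 0 <= self.year_index < self.n_years:
            raise ValueError(
                f"year_index {self.year_index} outside 0..{self.n_years - 1}"
            )


@dataclass(frozen=True)
class Certificate:
    """One death record: cause lines, raw demographics, optional gold UCD.

    ``part1``/``part2`` are lists of code lines (lists of normalized ICD-10
    tokens) preserving written order.  Raw age and calendar year are kept so
    certificates round-trip through CSV; the factorized
    :class:`Demographics` is derived once at construction.
    """

    id: str
    part1: tuple[tuple[str, ...], ...]
    part2: tuple[tuple[str, ...], ...]
    year: int
    sex: int
    age_value: float
    age_unit: str
    gold_ucd: str | None = None
    rejected: bool | None = None
    base_year: int = DEFAULT_BASE_YEAR
    n_years: int = DEFAULT_N_YEARS

    @staticmethod
    def build(
        id: str,
        part1: Iterable[Iterable[str]],
        part2: Iterable[Iterable[str]],
        year: int,
        sex: int,
        age_value: float,
        age_unit: str,
        gold_ucd: str | None = None,
        rejected: bool | None = None,
        base_year: int = DEFAULT_BASE_YEAR,
        n_years: int = DEFAULT_N_YEARS,
    ) -> "Certificate":
        p1 = tuple(tuple(parse_code(c) for c in line) for line in part1)
        p2 = tuple(tuple(parse_code(c) for c in line) for line in part2)
        if len(p1) > MAX_PART1_LINES:
            raise ValueError(f"certificate {id}: Part I has more than {MAX_PART1_LINES} lines")
        if len(p2) > MAX_PART2_LINES:
            raise ValueError(f"certificate {id}: Part II has more than {MAX_PART2_LINES} lines")
        if not any(p1) and not any(p2):
            raise ValueError(f"certificate {id}: no coded line")
        return Certificate(
            id=id,
            part1=p1,
            part2=p2,
            year=int(year),
            sex=int(sex),
            age_value=float(age_value),
            age_unit=age_unit,
            gold_ucd=parse_code(gold_ucd) if gold_ucd else None,
            rejected=rejected,
            base_year=base_year,
            n_years=n_years,
        )

    @property
    def demographics(self) -> Demographics:
        year_index = self.year - self.base_year
        if not 0 <= year_index < self.n_years:
            raise ValueError(
                f"certificate {self.id}: year {self.year} outside "
                f"{self.base_year}..{self.base_year + self.n_years - 1}"
            )
        return Demographics(
            age_bin=bin_age(self.age_value, self.age_unit),
            gender=self.sex,
            year_index=year_index,
            n_years=self.n_years,
        )

    def all_codes(self) -> tuple[str, ...]:
        return tuple(c for line in self.part1 + self.part2 for c in line)

    def with_gold(self, gold_ucd: str | None, rejected: bool | None) -> "Certificate":
        return replace(self, gold_ucd=gold_ucd, rejected=rejected)


def encode_grid(
    cert: Certificate, vocab: Vocabulary, L: int = 6, W: int = 20
) -> np.ndarray:
    """Encode the cause lines as an ``L x W`` integer index grid.

    Part I lines occupy rows 0-3 and Part II lines rows 4-5, each
    left-justified in written order; remaining cells hold ``pad_index``
    and codes absent from the vocabulary map to ``unknown_index``.
    """
    if L < MAX_PART1_LINES + MAX_PART2_LINES:
        raise ValueError(f"grid height L={L} cannot hold 4 Part I + 2 Part II lines")
    grid = np.full((L, W), vocab.pad_index, dtype=np.int64)
    for rows, part in ((range(0, 4), cert.part1), (range(4, 6), cert.part2)):
        for row, line in zip(rows, part):
            if len(line) > W:
                raise ValueError(
                    f"certificate {cert.id}: line with {len(line)} codes exceeds "
                    f"grid width W={W}; bigger certificates can be processed with "
                    "an appropriately larger code matrix encoding"
                )
            for col, code in enumerate(line):
                grid[row, col] = vocab.index_of(code)
    return grid


def decode_grid(grid: np.ndarray, vocab: Vocabulary) -> tuple[list[list[str]], list[list[str]]]:
    """Row-wise scan recovering the Part I / Part II code lines of a grid."""
    lines: list[list[str]] = []
    for row in grid:
        codes = []
        for idx in row:
            if idx == vocab.pad_index:
                break
            codes.append(
                "?" if idx == vocab.unknown_index else vocab.code_at(int(idx))
            )
        lines.append(codes)
    part1 = [l for l in lines[:4]]
    part2 = [l for l in lines[4:6]]
    while part1 and not part1[-1]:
        part1.pop()
    while part2 and not part2[-1]:
        part2.pop()
    return part1, part2


CSV_COLUMNS = [
    "id", "year", "sex", "age_value", "age_unit",
    "l1", "l2", "l3", "l4", "p2l1", "p2l2", "ucd", "rejected",
]

_SEX_TOKENS = {"M": 0, "1": 0, "F": 1, "2": 1}


def _parse_line_cell(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(parse_code(tok) for tok in cell.split())


def read_certificates(
    path,
    base_year: int = DEFAULT_BASE_YEAR,
    n_years: int = DEFAULT_N_YEARS,
) -> list[Certificate]:
    """Read certificates from the package CSV dialect.

    Required columns: id, year, sex, age_value, age_unit and the six line
    columns l1-l4, p2l1, p2l2 (space-separated ICD-10 codes, empty cell =
    empty line).  Optional: ucd (gold label) and rejected (0/1).  Errors
    carry the 1-based data row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = set(CSV_COLUMNS) - {"ucd", "rejected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    certs = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        try:
            year = int(row.year)
            if not base_year <= year < base_year + n_years:
                raise ValueError(
                    f"year {year} outside configured range "
                    f"{base_year}..{base_year + n_years - 1}"
                )
            sex_tok = row.sex.strip().upper()
            if sex_tok not in _SEX_TOKENS:
                raise ValueError(f"unrecognized sex token {row.sex!r}")
            part1 = [_parse_line_cell(getattr(row, c)) for c in ("l1", "l2", "l3", "l4")]
            part2 = [_parse_line_cell(getattr(row, c)) for c in ("p2l1", "p2l2")]
            while part1 and not part1[-1]:
                part1.pop()
            while part2 and not part2[-1]:
                part2.pop()
            ucd = getattr(row, "ucd", "").strip() if hasattr(row, "ucd") else ""
            rej_cell = getattr(row, "rejected", "").strip() if hasattr(row, "rejected") else ""
            rejected = None if rej_cell == "" else rej_cell in ("1", "true", "True")
            cert = Certificate.build(
                id=row.id,
                part1=part1,
                part2=part2,
                year=year,
                sex=_SEX_TOKENS[sex_tok],
                age_value=float(row.age_value),
                age_unit=row.age_unit.strip(),
                gold_ucd=ucd or None,
                rejected=rejected,
                base_year=base_year,
                n_years=n_years,
            )
            cert.demographics  # validate bins eagerly
        except (ValueError, CodeError) as exc:
            raise ValueError(f"{path}, data row {pos}: {exc}") from exc
        certs.append(cert)
    return certs


def write_certificates(certs: list[Certificate], path) -> None:
    """Write certificates in the CSV dialect (stable column order)."""
    rows = []
    for c in certs:
        p1 = list(c.part1) + [()] * (4 - len(c.part1))
        p2 = list(c.part2) + [()] * (2 - len(c.part2))
        age = c.age_value
        rows.append({
            "id": c.id,
            "year": c.year,
            "sex": "M" if c.sex == 0 else "F",
            "age_value": int(age) if float(age).is_integer() else age,
            "age_unit": c.age_unit,
            "l1": " ".join(p1[0]), "l2": " ".join(p1[1]),
            "l3": " ".join(p1[2]), "l4": " ".join(p1[3]),
            "p2l1": " ".join(p2[0]), "p2l2": " ".join(p2[1]),
            "ucd": c.gold_ucd or "",
            "rejected": "" if c.rejected is None else int(c.rejected),
        })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
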