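"""Year-harmonized recoding and cause-group time series.

Coding rules drift over calendar years, which leaves discontinuities in
cause-specific mortality time series.  Because the coder conditions on
the year of coding, an entire corpus can be re-predicted with the year
covariate fixed to one reference year, removing rule drift; the
per-year, per-cause-group death counts before and after recoding are
then compared through their maximum year-over-year jump (a smoothness
surrogate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .certificate import Certificate
from .coder import TrainedCoder, predict_proba_batch
from .vocabulary import Vocabulary, parse_code

__all__ = [
    "CauseGroup",
    "TimeSeriesTable",
    "overdose_groups",
    "recode",
    "count_by_group",
    "trajectory_comparison",
]


@dataclass(frozen=True)
class CauseGroup:
    """A named set of ICD-10 code prefixes; a code belongs to the group when
    its normalized token starts with any prefix (so "F11" covers F110-F119)."""

    name: str
    prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise ValueError(f"cause group {self.name!r} needs at least one prefix")

    def matches(self, code: str) -> bool:
        tok = parse_code(code)
        return any(tok.startswith(p) for p in self.prefixes)


def overdose_groups() -> list[CauseGroup]:
    """The six overdose-related underlying-cause groupings.

    Opioid/cannabis disorders (F11, F12); cocaine, hallucinogen and other
    stimulant disorders (F14-F16, deliberately skipping F13); other
    psychoactive-substance disorders (F19); and accidental (X42),
    intentional (X62) and undetermined-intent (Y12) poisoning by narcotics
    and psychodysleptics.
    """
    return [
        CauseGroup("opioid_cannabis", ("F11", "F12")),
        CauseGroup("cocaine_stimulants", ("F14", "F15", "F16")),
        CauseGroup("other_psychoactive", ("F19",)),
        CauseGroup("accidental_poisoning", ("X42",)),
        CauseGroup("intentional_poisoning", ("X62",)),
        CauseGroup("undetermined_poisoning", ("Y12",)),
    ]


@dataclass(frozen=True)
class TimeSeriesTable:
    """Group x year death counts from one coding source."""

    years: tuple[int, ...]
    groups: tuple[str, ...]
    counts: np.ndarray  # (n_groups, n_years) int
    source: str
    total_counts: np.ndarray | None = None

    def total(self) -> np.ndarray:
        """Per-year count of certificates matching at least one group
        (deduplicated at certificate level); falls back to the column sum
        when the deduplicated total was not recorded."""
        if self.total_counts is not None:
            return self.total_counts
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "group": g, "source": self.source,
             "count": int(self.counts[i, j])}
            for i, g in enumerate(self.groups)
            for j, y in enumerate(self.years)
        ]
        return pd.DataFrame(rows, columns=["year", "group", "source", "count"])


def recode(
    coder: TrainedCoder,
    certs: list[Certificate],
    vocab: Vocabulary,
    fixed_year: int,
) -> list[str]:
    """Predict a UCD for every certificate with the year covariate
    overridden to ``fixed_year`` (certificates are not modified).

    ``fixed_year`` is a calendar year; it is converted through each
    certificate's configured base year and must fall inside the model's
    year range.
    """
    if not certs:
        return []
    base_year = certs[0].base_year
    year_index = fixed_year - base_year
    if not 0 <= year_index < coder.config.Y:
        raise ValueError(
            f"fixed_year {fixed_year} outside the model's range "
            f"{base_year}..{base_year + coder.config.Y - 1}"
        )
    probs = predict_proba_batch(coder, certs, vocab, fixed_year_index=year_index)
    order = np.lexsort(
        (np.broadcast_to(np.arange(probs.shape[1]), probs.shape), -probs), axis=1
    )
    return [vocab.code_at(int(i)) for i in order[:, 0]]


def count_by_group(
    ucds: list[str],
    years: list[int],
    groups: list[CauseGroup],
    source: str = "original",
) -> TimeSeriesTable:
    """Per-year, per-group death counts by prefix match.

    A UCD matching several groups counts once in each, but only once in
    the certificate-level total.
    """
    if len(ucds) != len(years):
        raise ValueError("ucds and years must be aligned")
    year_axis = tuple(sorted(set(years)))
    yidx = {y: j for j, y in enumerate(year_axis)}
    counts = np.zeros((len(groups), len(year_axis)), dtype=np.int64)
    total = np.zeros(len(year_axis), dtype=np.int64)
    for ucd, year in zip(ucds, years):
        hit = False
        for i, g in enumerate(groups):
            if g.matches(ucd):
                counts[i, yidx[year]] += 1
                hit = True
        if hit:
            total[yidx[year]] += 1
    return TimeSeriesTable(
        years=year_axis,
        groups=tuple(g.name for g in groups),
        counts=counts,
        source=source,
        total_counts=total,
    )


def trajectory_comparison(
    original: TimeSeriesTable, recoded: TimeSeriesTable
) -> pd.DataFrame:
    """Per-year difference table plus the maximum absolute year-over-year
    jump of each source's grouped total (the smoothness surrogate).

    Jump statistics are attached as ``DataFrame.attrs``:
    ``max_jump_original``, ``max_jump_recoded`` and per-year jumps
    ``jumps_original`` / ``jumps_recoded`` (keyed by the later year of
    each consecutive pair).
    """
    if original.years != recoded.years or original.groups != recoded.groups:
        raise ValueError("time series tables must share years and groups")
    delta = recoded.counts - original.counts
    rows = [
        {"year": y, "group": g, "delta": int(delta[i, j])}
        for i, g in enumerate(original.groups)
        for j, y in enumerate(original.years)
    ]
    out = pd.DataFrame(rows, columns=["year", "group", "delta"])
    for label, table in (("original", original), ("recoded", recoded)):
        tot = table.total().astype(np.int64)
        jumps = {
            int(table.years[j]): int(abs(tot[j] - tot[j - 1]))
            for j in range(1, len(table.years))
        }
        out.attrs[f"jumps_{label}"] = jumps
        out.attrs[f"max_jump_{label}"] = max(jumps.values()) if jumps else 0
    return out
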