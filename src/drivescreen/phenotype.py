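"""Progeny phenotype summaries and the sex-ratio test.

Per-female cross records (eggs laid, larvae hatched, male and female
adults) are summarized the way distortion experiments report them:
per-female percentages averaged with their SEM, alongside pooled
totals.  Sex-ratio distortion is tested on the pooled male/female
counts with a 1-df chi-square goodness-of-fit against the Mendelian
50% male expectation (no continuity correction by default — counts in
this design are large).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrossRecord",
    "StrainSummary",
    "SexRatioTest",
    "records_from_dataframe",
    "summarize_strain",
    "test_sex_ratio",
]


@dataclass(frozen=True)
class CrossRecord:
    """One female's progeny counts."""

    female_id: str
    strain: str
    eggs: int
    larvae: int
    males: int
    females: int

    def __post_init__(self) -> None:
        if min(self.eggs, self.larvae, self.males, self.females) < 0:
            raise ValueError(f"{self.female_id}: counts must be non-negative")
        if self.larvae > self.eggs:
            raise ValueError(f"{self.female_id}: larvae ({self.larvae}) exceed eggs ({self.eggs})")
        if self.males + self.females > self.larvae:
            raise ValueError(f"{self.female_id}: sexed adults exceed larvae")


def records_from_dataframe(df: pd.DataFrame) -> list[CrossRecord]:
    return [
        CrossRecord(str(r.female_id), str(r.strain), int(r.eggs), int(r.larvae),
                    int(r.males), int(r.females))
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class StrainSummary:
    strain: str
    n_females: int
    mean_eggs: float
    sem_eggs: float
    mean_hatch_pct: float
    sem_hatch_pct: float
    mean_male_pct: float
    sem_male_pct: float
    total_eggs: int
    total_larvae: int
    total_males: int
    total_females: int


def _mean_sem(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(len(arr)))


def summarize_strain(records: Iterable[CrossRecord]) -> StrainSummary:
    """Average per-female egg counts, hatch % and male % (each ±SEM).

    Percentages are computed per female and then averaged, matching how
    distortion figures report "average percentage of males from n
    females"; pooled totals are carried alongside because the sex-ratio
    test operates on pooled counts.  Females with zero eggs (or zero
    sexed adults) are excluded from the corresponding percentage only.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need >= 2 cross records for SEM")
    strains = {r.strain for r in records}
    if len(strains) != 1:
        raise ValueError(f"records span multiple strains: {sorted(strains)}")

    hatch = [100.0 * r.larvae / r.eggs for r in records if r.eggs > 0]
    male = [100.0 * r.males / (r.males + r.females) for r in records if r.males + r.females > 0]
    mean_eggs, sem_eggs = _mean_sem([float(r.eggs) for r in records])
    mean_hatch, sem_hatch = _mean_sem(hatch) if len(hatch) >= 2 else (float("nan"), float("nan"))
    mean_male, sem_male = _mean_sem(male) if len(male) >= 2 else (float("nan"), float("nan"))

    return StrainSummary(
        strain=records[0].strain,
        n_females=len(records),
        mean_eggs=mean_eggs,
        sem_eggs=sem_eggs,
        mean_hatch_pct=mean_hatch,
        sem_hatch_pct=sem_hatch,
        mean_male_pct=mean_male,
        sem_male_pct=sem_male,
        total_eggs=sum(r.eggs for r in records),
        total_larvae=sum(r.larvae for r in records),
        total_males=sum(r.males for r in records),
        total_females=sum(r.females for r in records),
    )


@dataclass(frozen=True)
class SexRatioTest:
    strain: str
    males: int
    females: int
    chi_square: float
    df: int
    p_value: float
    expected_male_fraction: float


def test_sex_ratio(
    males: int,
    females: int,
    expected: float = 0.5,
    strain: str = "strain",
    continuity: bool = False,
) -> SexRatioTest:
    """1-df goodness-of-fit of pooled counts against an expected male fraction.

    statistic = sum over the two sex classes of (obs - exp)^2 / exp;
    the p-value is the upper tail of the chi-square distribution with
    one degree of freedom.  A Yates continuity correction is available
    but off by default.
    """
    n = males + females
    if n < 1:
        raise ValueError("need at least one offspring")
    if not 0.0 < expected < 1.0:
        raise ValueError("expected male fraction must lie in (0, 1)")
    exp_m, exp_f = n * expected, n * (1.0 - expected)
    if continuity:
        chi2 = (abs(males - exp_m) - 0.5) ** 2 / exp_m + (abs(females - exp_f) - 0.5) ** 2 / exp_f
    else:
        chi2 = (males - exp_m) ** 2 / exp_m + (females - exp_f) ** 2 / exp_f
    p = float(stats.chi2.sf(chi2, df=1))
    return SexRatioTest(strain, males, females, float(chi2), 1, p, expected)
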