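"""Old-vs-new reference-database comparison.

Given per-sample species-level detections under a conventional (old) and an
augmented (new) reference database, this module computes the improvement
summary: total/shared/unique OTU counts, per-sample means, percent increases
(rounded to the nearest integer), the per-sample delta-OTU series
(new minus old), seasonal delta summaries, and two-sided Wilcoxon rank-sum
p-values.  The rank-sum test enumerates the exact permutation null for small
pooled samples and uses the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import datetime as dt
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: month -> season (winter is December-February)
DEFAULT_SEASON_MAP: dict[int, str] = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}

SEASON_ORDER = ("spring", "summer", "autumn", "winter")


@dataclass
class DetectionTable:
    """Per-sample species-resolved OTU detections under one database."""

    database_label: str
    detected: dict[str, set[str]]  # sample_id -> otu ids
    species: dict[str, str] = field(default_factory=dict)  # otu -> binomial
    similarity: dict[str, float] = field(default_factory=dict)

    def sample_ids(self) -> set[str]:
        return set(self.detected)

    def all_otus(self) -> set[str]:
        out: set[str] = set()
        for s in self.detected.values():
            out |= s
        return out

    def per_sample_counts(self) -> pd.Series:
        return pd.Series({s: len(v) for s, v in sorted(self.detected.items())},
                         name=self.database_label)


def detection_table(assignments, table: pd.DataFrame,
                    label: str) -> DetectionTable:
    """Build a DetectionTable from assignments and an OTU count table.

    An OTU counts as detected in a sample when it is species-resolved and
    has a positive count there.
    """
    species_otus = {a.otu_id: a for a in assignments
                    if a.resolution == "species"}
    detected: dict[str, set[str]] = {s: set() for s in table.columns}
    for otu_id, a in species_otus.items():
        if otu_id not in table.index:
            continue
        row = table.loc[otu_id]
        for sample in table.columns[row.values > 0]:
            detected[sample].add(otu_id)
    return DetectionTable(
        database_label=label, detected=detected,
        species={o: a.species_name for o, a in species_otus.items()},
        similarity={o: a.similarity for o, a in species_otus.items()},
    )


def delta_otus(new_table: DetectionTable,
               old_table: DetectionTable) -> pd.Series:
    """Per-sample delta = |new detections| - |old detections|."""
    if new_table.sample_ids() != old_table.sample_ids():
        diff = sorted(new_table.sample_ids() ^ old_table.sample_ids())
        raise ValueError(f"sample sets differ; symmetric difference: {diff}")
    new_counts = new_table.per_sample_counts()
    old_counts = old_table.per_sample_counts()
    out = (new_counts - old_counts).astype(float)
    out.name = "delta_otus"
    return out


# ---------------------------------------------------------------------------
# rank-sum test

def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (handles ties)."""
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * ny / 2.0
    combos = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(nx + ny), nx)),
        dtype=np.intp).reshape(-1, nx)
    u_all = ranks[combos].sum(axis=1) - nx * (nx + 1) / 2
    dev = np.abs(u_all - mu)
    return float(np.mean(dev >= abs(u_obs - mu) - 1e-9))


def rank_sum_test(x, y, exact_max_pooled: int = 20,
                  paired: bool = False) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact full enumeration when the pooled sample size is at most
    ``exact_max_pooled``; tie-corrected normal approximation with continuity
    correction otherwise.  ``paired=True`` switches to the Wilcoxon
    signed-rank test on the paired differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if paired:
        d = x - y
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
    if x.size + y.size <= exact_max_pooled:
        return _exact_rank_sum_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue)


# ---------------------------------------------------------------------------
# seasonal summaries

def season_of(date: dt.date, season_map: dict[int, str] | None = None) -> str:
    season_map = season_map or DEFAULT_SEASON_MAP
    return season_map[date.month]


def seasonal_summary(delta_series: pd.Series,
                     dates: dict[str, dt.date],
                     season_map: dict[int, str] | None = None) -> dict:
    """Per-season mean +- SD of deltas and pairwise rank-sum p-values.

    ``delta_series`` is indexed by sample id; ``dates`` maps sample ids to
    calendar dates.  Empty seasons are reported absent.
    """
    season_map = season_map or DEFAULT_SEASON_MAP
    groups: dict[str, list[float]] = {}
    for sample, value in delta_series.items():
        season = season_of(dates[sample], season_map)
        groups.setdefault(season, []).append(float(value))
    summary = {
        season: {
            "n": len(v),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }
        for season, v in groups.items()
    }
    pairwise = {}
    present = [s for s in SEASON_ORDER if s in groups]
    for a, b in itertools.combinations(present, 2):
        pairwise[f"{a}_vs_{b}"] = rank_sum_test(groups[a], groups[b])
    return {"seasons": summary, "pairwise_p": pairwise}


# ---------------------------------------------------------------------------
# the comparison report

def _pct(numerator: float, denominator: float) -> int | None:
    if denominator == 0:
        return None
    return int(round(100.0 * numerator / denominator))


@dataclass
class ComparisonReport:
    total_old: int
    total_new: int
    shared: int
    unique_new: int
    unique_old: int
    difference: int
    pct_increase_total: int | None
    mean_per_sample_old: float
    mean_per_sample_new: float
    sd_per_sample_old: float
    sd_per_sample_new: float
    min_per_sample_old: int
    min_per_sample_new: int
    max_per_sample_old: int
    max_per_sample_new: int
    pct_increase_per_sample: int | None
    mean_delta: float
    sd_delta: float
    delta_series: dict[str, float] = field(default_factory=dict)
    seasonal: dict | None = None
    p_old_vs_new: float | None = None

    @classmethod
    def from_counts(cls, shared: int, unique_new: int, unique_old: int,
                    mean_per_sample_old: float, mean_per_sample_new: float,
                    sd_per_sample_old: float = float("nan"),
                    sd_per_sample_new: float = float("nan"),
                    min_per_sample_old: int = 0, min_per_sample_new: int = 0,
                    max_per_sample_old: int = 0, max_per_sample_new: int = 0
                    ) -> "ComparisonReport":
        """Report arithmetic from summary counts alone (no per-sample data)."""
        total_new = shared + unique_new
        total_old = shared + unique_old
        difference = total_new - total_old
        mean_delta = mean_per_sample_new - mean_per_sample_old
        return cls(
            total_old=total_old, total_new=total_new, shared=shared,
            unique_new=unique_new, unique_old=unique_old,
            difference=difference,
            pct_increase_total=_pct(difference, total_old),
            mean_per_sample_old=mean_per_sample_old,
            mean_per_sample_new=mean_per_sample_new,
            sd_per_sample_old=sd_per_sample_old,
            sd_per_sample_new=sd_per_sample_new,
            min_per_sample_old=min_per_sample_old,
            min_per_sample_new=min_per_sample_new,
            max_per_sample_old=max_per_sample_old,
            max_per_sample_new=max_per_sample_new,
            pct_increase_per_sample=_pct(mean_delta, mean_per_sample_old),
            mean_delta=mean_delta, sd_delta=float("nan"),
        )

    def as_dict(self) -> dict:
        out = dict(self.__dict__)
        out["delta_series"] = dict(self.delta_series)
        return out


def summarize(old: DetectionTable, new: DetectionTable,
              dates: dict[str, dt.date] | None = None,
              season_map: dict[int, str] | None = None) -> ComparisonReport:
    """Full comparison of two detection tables over the same samples."""
    if old.sample_ids() != new.sample_ids():
        diff = sorted(old.sample_ids() ^ new.sample_ids())
        raise ValueError(f"sample sets differ; symmetric difference: {diff}")
    old_otus, new_otus = old.all_otus(), new.all_otus()
    shared = len(old_otus & new_otus)
    unique_new = len(new_otus - old_otus)
    unique_old = len(old_otus - new_otus)
    old_counts = old.per_sample_counts()
    new_counts = new.per_sample_counts()
    deltas = delta_otus(new, old)
    total_old, total_new = len(old_otus), len(new_otus)
    difference = total_new - total_old
    mean_old = float(old_counts.mean())
    mean_new = float(new_counts.mean())
    report = ComparisonReport(
        total_old=total_old, total_new=total_new, shared=shared,
        unique_new=unique_new, unique_old=unique_old, difference=difference,
        pct_increase_total=_pct(difference, total_old),
        mean_per_sample_old=mean_old, mean_per_sample_new=mean_new,
        sd_per_sample_old=float(old_counts.std(ddof=1)) if len(old_counts) > 1 else 0.0,
        sd_per_sample_new=float(new_counts.std(ddof=1)) if len(new_counts) > 1 else 0.0,
        min_per_sample_old=int(old_counts.min()),
        min_per_sample_new=int(new_counts.min()),
        max_per_sample_old=int(old_counts.max()),
        max_per_sample_new=int(new_counts.max()),
        pct_increase_per_sample=_pct(mean_new - mean_old, mean_old),
        mean_delta=float(deltas.mean()),
        sd_delta=float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0,
        delta_series={s: float(v) for s, v in deltas.items()},
    )
    if len(old_counts) > 1:
        report.p_old_vs_new = rank_sum_test(old_counts.values,
                                            new_counts.values)
    if dates is not None:
        report.seasonal = seasonal_summary(deltas, dates, season_map)
    return report
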