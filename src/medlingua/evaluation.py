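"""Precision/coverage evaluation protocol and its statistics.

Each strategy is evaluated on a set of queries by recording the first 20
ranked PMIDs and the total hit count (coverage), then judging every ranked
citation on a 3-level scale (relevant / partially relevant / not relevant).
Two precision readings follow: *strict* counts only fully relevant citations
as true positives, *relaxed* also counts the partially relevant ones.
Per-strategy precision is pooled by micro-averaging — total relevant over
total retrieved across queries — which is what the aggregate rows of the
study tables report.

Statistics: Pearson correlation with a Fisher-z 95% CI (response time vs
hit count), an unpaired two-sided Mann-Whitney rank test for coverage
comparisons (exact by enumeration for small samples, tie-corrected normal
approximation otherwise), and a two-sided Fisher exact test on pooled 2×2
relevant/irrelevant counts.
"""

from __future__ import annotations

import csv
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LEVELS",
    "QueryRun",
    "Judgment",
    "PrecisionCell",
    "precision_at_k",
    "pooled_precision",
    "coverage_total",
    "pearson_with_ci",
    "mann_whitney",
    "fisher_exact",
    "sensitivity_reanalysis",
    "read_runs",
    "read_judgments",
    "write_runs",
    "write_judgments",
    "cells_from_runs",
    "write_report",
]

LEVELS = ("relevant", "partially_relevant", "not_relevant")


@dataclass
class QueryRun:
    """Per-query output of one strategy: ranked top PMIDs plus coverage."""

    query: str
    strategy: str
    pmids: list[str]
    total_hits: int

    def __post_init__(self) -> None:
        if len(self.pmids) > 20:
            raise ValueError("a run records at most the first 20 PMIDs")
        if len(self.pmids) > self.total_hits:
            raise ValueError("ranked list longer than total hit count")


@dataclass(frozen=True)
class Judgment:
    pmid: str
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown relevance level {self.level!r}")


@dataclass(frozen=True)
class PrecisionCell:
    """Counts behind one (query, strategy) precision entry."""

    query: str
    strategy: str
    retrieved: int
    relevant_strict: int
    relevant_relaxed: int

    def __post_init__(self) -> None:
        if not (0 <= self.relevant_strict <= self.relevant_relaxed <= self.retrieved <= 20):
            raise ValueError(
                f"inconsistent counts for ({self.query}, {self.strategy}): "
                f"{self.relevant_strict} <= {self.relevant_relaxed} <= "
                f"{self.retrieved} <= 20 violated"
            )

    def precision(self, mode: str) -> float | None:
        if self.retrieved == 0:
            return None
        numer = self.relevant_strict if mode == "strict" else self.relevant_relaxed
        return numer / self.retrieved


def _check_mode(mode: str) -> None:
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be 'strict' or 'relaxed', got {mode!r}")


def precision_at_k(
    run: QueryRun, judgments: Mapping[str, str], mode: str = "strict"
) -> tuple[float, PrecisionCell]:
    """Precision over the ranked list of one run (denominator = number
    retrieved, at most 20).  Every ranked PMID must be judged."""
    _check_mode(mode)
    unjudged = [p for p in run.pmids if p not in judgments]
    if unjudged:
        raise ValueError(
            f"unjudged PMIDs for query {run.query!r}: {', '.join(unjudged)}"
        )
    strict = sum(1 for p in run.pmids if judgments[p] == "relevant")
    relaxed = strict + sum(
        1 for p in run.pmids if judgments[p] == "partially_relevant"
    )
    cell = PrecisionCell(
        query=run.query,
        strategy=run.strategy,
        retrieved=len(run.pmids),
        relevant_strict=strict,
        relevant_relaxed=relaxed,
    )
    if not run.pmids:
        raise ValueError(f"query {run.query!r}: no citations retrieved")
    return (strict if mode == "strict" else relaxed) / len(run.pmids), cell


def pooled_precision(cells: Iterable[PrecisionCell], mode: str = "strict") -> float:
    """Micro-averaged precision: Σ relevant / Σ retrieved over the cells of
    one strategy.  Queries that retrieved nothing contribute to neither sum.
    Raises if nothing at all was retrieved."""
    _check_mode(mode)
    retrieved = relevant = 0
    for cell in cells:
        retrieved += cell.retrieved
        relevant += (
            cell.relevant_strict if mode == "strict" else cell.relevant_relaxed
        )
    if retrieved == 0:
        raise ValueError("pooled precision undefined: no citations retrieved")
    return relevant / retrieved


def coverage_total(per_query_totals: Sequence[int]) -> int:
    """Total coverage of a strategy: the exact sum of per-query hit counts."""
    if any(t < 0 for t in per_query_totals):
        raise ValueError("negative hit count")
    return int(sum(per_query_totals))


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with a Fisher z-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(len(x) - 3)
    zcrit = float(stats.norm.ppf(0.5 + confidence / 2.0))
    lo, hi = math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
    return r, (lo, hi)


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], two_sided: bool = True
) -> tuple[float, float]:
    """Mann-Whitney rank-sum test (unpaired), mid-ranks for ties.

    Returns (U, p) where U is the statistic of the first sample.  For
    n+m ≤ 16 the p-value is exact, by enumerating every assignment of the
    pooled mid-ranks to the first sample; otherwise a normal approximation
    with tie correction and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks
    u_obs = _u_statistic(ranks[:n], n)
    mu = n * m / 2.0

    if n + m <= 16:
        dev_obs = abs(u_obs - mu)
        if not two_sided:
            dev_obs = u_obs - mu
        hits = total = 0
        for idx in combinations(range(n + m), n):
            u = _u_statistic(ranks[list(idx)], n)
            total += 1
            if two_sided:
                if abs(u - mu) >= dev_obs - 1e-12:
                    hits += 1
            else:
                if (u - mu) >= dev_obs - 1e-12:
                    hits += 1
        return u_obs, hits / total

    # normal approximation with tie correction
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        return u_obs, 1.0  # all values tied
    dev = abs(u_obs - mu)
    z = max(0.0, dev - 0.5) / math.sqrt(sigma2)
    p = 2.0 * float(stats.norm.sf(z)) if two_sided else float(stats.norm.sf(z))
    return u_obs, min(1.0, p)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2×2 table: the total hypergeometric
    probability of tables (with the same margins) no more probable than the
    observed one.  A zero margin makes the test vacuous: p = 1 with a
    warning."""
    ((a, b), (c, d)) = ((int(table[0][0]), int(table[0][1])),
                        (int(table[1][0]), int(table[1][1])))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if 0 in (a + b, c + d, a + c, b + d):
        warnings.warn("fisher_exact: zero margin, test is vacuous (p=1)")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def sensitivity_reanalysis(
    cells: Iterable[PrecisionCell],
    scenario: str,
    query: str,
    mode: str = "strict",
    strategies: Sequence[str] | None = None,
) -> dict[str, float]:
    """Recompute pooled precision per strategy under a bias scenario for one
    query: ``exclude_query`` drops it; ``zero_results`` sets its retrieved
    count to 0 for the named strategies (default: all); ``assume_relevant``
    sets its relevant counts equal to its retrieved count."""
    cells = list(cells)
    if scenario not in ("exclude_query", "zero_results", "assume_relevant"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if not any(c.query == query for c in cells):
        raise ValueError(f"unknown query {query!r}")
    affected = set(strategies) if strategies is not None else None

    adjusted: list[PrecisionCell] = []
    for cell in cells:
        if cell.query == query and (affected is None or cell.strategy in affected):
            if scenario == "exclude_query":
                continue
            if scenario == "zero_results":
                cell = PrecisionCell(cell.query, cell.strategy, 0, 0, 0)
            else:  # assume_relevant
                cell = PrecisionCell(
                    cell.query, cell.strategy,
                    cell.retrieved, cell.retrieved, cell.retrieved,
                )
        adjusted.append(cell)

    out: dict[str, float] = {}
    by_strategy: dict[str, list[PrecisionCell]] = defaultdict(list)
    for cell in adjusted:
        by_strategy[cell.strategy].append(cell)
    for strategy, strategy_cells in sorted(by_strategy.items()):
        out[strategy] = pooled_precision(strategy_cells, mode)
    return out


# -- run / judgment file I/O ----------------------------------------------
#
# Run files: TSV with columns (query, strategy, total_hits, rank, pmid);
# one row per ranked citation, rank 1-based.  A query that retrieved
# nothing is a single row with rank 0 and an empty pmid.
# Judgment files: TSV with columns (query, pmid, level).


def write_runs(runs: Iterable[QueryRun], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["query", "strategy", "total_hits", "rank", "pmid"])
        for run in runs:
            if not run.pmids:
                writer.writerow([run.query, run.strategy, run.total_hits, 0, ""])
            for rank, pmid in enumerate(run.pmids, start=1):
                writer.writerow([run.query, run.strategy, run.total_hits, rank, pmid])


def read_runs(path: str | Path) -> list[QueryRun]:
    grouped: dict[tuple[str, str], QueryRun] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["query"], row["strategy"])
            run = grouped.get(key)
            if run is None:
                run = grouped[key] = QueryRun(
                    query=row["query"],
                    strategy=row["strategy"],
                    pmids=[],
                    total_hits=int(row["total_hits"]),
                )
            if row["pmid"]:
                run.pmids.append(row["pmid"])
    return list(grouped.values())


def write_judgments(
    judgments: Mapping[str, Mapping[str, str]], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["query", "pmid", "level"])
        for query in sorted(judgments):
            for pmid, level in sorted(judgments[query].items()):
                writer.writerow([query, pmid, level])


def read_judgments(path: str | Path) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = defaultdict(dict)
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["level"] not in LEVELS:
                raise ValueError(f"unknown relevance level {row['level']!r}")
            out[row["query"]][row["pmid"]] = row["level"]
    return dict(out)


def cells_from_runs(
    runs: Iterable[QueryRun], judgments: Mapping[str, Mapping[str, str]]
) -> list[PrecisionCell]:
    """Judge every run; unplanted/unlisted PMIDs count as not relevant only
    if the judgment file says so — an unjudged ranked PMID is an error."""
    cells = []
    for run in runs:
        if not run.pmids:
            cells.append(PrecisionCell(run.query, run.strategy, 0, 0, 0))
            continue
        _, cell = precision_at_k(run, judgments.get(run.query, {}), "strict")
        cells.append(cell)
    return cells


def write_report(
    cells: Iterable[PrecisionCell],
    coverage: Mapping[str, Mapping[str, int]],
    out_dir: str | Path,
) -> None:
    """Emit the coverage matrix (query × strategy hit counts, with a Total
    row) and the precision matrix (strict-relaxed pairs, with the pooled
    Total row) as TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = list(cells)
    strategies = sorted({c.strategy for c in cells})
    queries = sorted({c.query for c in cells})

    with (out_dir / "coverage.tsv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["query"] + strategies)
        for query in sorted(coverage):
            writer.writerow(
                [query] + [coverage[query].get(s, 0) for s in strategies]
            )
        writer.writerow(
            ["Total"]
            + [
                coverage_total([coverage[q].get(s, 0) for q in coverage])
                for s in strategies
            ]
        )

    by_cell = {(c.query, c.strategy): c for c in cells}
    with (out_dir / "precision.tsv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["query"] + [f"{s} (strict-relaxed)" for s in strategies])
        for query in queries:
            row = [query]
            for s in strategies:
                cell = by_cell.get((query, s))
                if cell is None or cell.retrieved == 0:
                    row.append("-")
                else:
                    row.append(
                        f"{cell.precision('strict'):.2f}-{cell.precision('relaxed'):.2f}"
                    )
            writer.writerow(row)
        totals = ["Total"]
        for s in strategies:
            strategy_cells = [c for c in cells if c.strategy == s]
            totals.append(
                f"{pooled_precision(strategy_cells, 'strict'):.2f}-"
                f"{pooled_precision(strategy_cells, 'relaxed'):.2f}"
            )
        writer.writerow(totals)
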