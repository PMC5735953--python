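"""Class-enrichment statistics for motif presence calls.

Presence/absence of each motif is compared between two promoter classes via
a 2x2 contingency table and the two-sided Fisher exact test. The two-sided
p-value uses the point-probability criterion (sum of hypergeometric
probabilities of all tables with the same margins whose probability does
not exceed that of the observed table), the convention of R's
``fisher.test`` and SciPy's ``fisher_exact``. Probabilities are computed in
log space from exact log-factorials so tables with a 500-promoter control
margin do not overflow, and point-probability ties are included with a
relative tolerance of 1e-7 to keep the sum platform-independent.

Raw p-values are reported; no multiple-testing correction is applied. The
report carries the number of rows so users can correct downstream.
"""

from __future__ import annotations

import json
import math
import numbers
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .motifs import MotifCatalog

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_exact",
    "fisher_exact_two_sided",
    "odds_ratio",
    "enrich",
    "enrichment_report",
    "DEFAULT_COMPARISONS",
    "REPORT_COLUMNS",
    "write_report",
    "read_report",
]

#: The three class comparisons of the promoter study.
DEFAULT_COMPARISONS: list[tuple[str, str]] = [
    ("class_I", "class_II"),
    ("class_I", "background"),
    ("class_II", "background"),
]

REPORT_COLUMNS = [
    "motif", "comparison", "n_A", "hits_A", "frac_A",
    "n_B", "hits_B", "frac_B", "odds_ratio", "p_two_sided",
]

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (a, b) = with/without motif in set A, (c, d) in set B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 0:
                raise ValueError(f"count {name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


_logfact: list[float] = [0.0]


def _log_factorial(n: int) -> float:
    # exact log-factorials, extended lazily and cached
    while len(_logfact) <= n:
        _logfact.append(_logfact[-1] + math.log(len(_logfact)))
    return _logfact[n]


def _log_hypergeom(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(A = a) for the hypergeometric with margins (row1, row2, col1)."""
    n = row1 + row2
    return (
        _log_factorial(row1) + _log_factorial(row2)
        + _log_factorial(col1) + _log_factorial(n - col1)
        - _log_factorial(n)
        - _log_factorial(a) - _log_factorial(row1 - a)
        - _log_factorial(col1 - a) - _log_factorial(row2 - col1 + a)
    )


def fisher_exact(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher exact p-value on a 2x2 table.

    ``alternative`` is ``"two-sided"`` (point-probability criterion),
    ``"greater"`` (set A enriched: P(A >= a)) or ``"less"``. A degenerate
    margin (an empty row, or an all-zero / all-one column) makes every
    table with those margins equally likely, so p = 1.
    """
    row1, row2 = table.a + table.b, table.c + table.d
    col1 = table.a + table.c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    if alternative == "greater":
        support = range(table.a, hi + 1)
    elif alternative == "less":
        support = range(lo, table.a + 1)
    elif alternative == "two-sided":
        log_obs = _log_hypergeom(table.a, row1, row2, col1)
        cutoff = log_obs + math.log1p(_TIE_RTOL)
        support = [a for a in range(lo, hi + 1)
                   if _log_hypergeom(a, row1, row2, col1) <= cutoff]
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    total = math.fsum(
        math.exp(_log_hypergeom(a, row1, row2, col1)) for a in support
    )
    return min(total, 1.0)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (point-probability criterion)."""
    return fisher_exact(table, "two-sided")


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio (a*d)/(b*c); inf for a zero denominator with a
    positive numerator, 1.0 when both products are zero."""
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        return math.inf if num > 0 else 1.0
    return num / den


@dataclass(frozen=True)
class EnrichmentResult:
    """One motif x one class comparison."""

    motif_name: str
    set_a: str
    set_b: str
    table: ContingencyTable
    odds_ratio: float
    p_two_sided: float

    @property
    def frac_a(self) -> float:
        return self.table.a / (self.table.a + self.table.b)

    @property
    def frac_b(self) -> float:
        return self.table.c / (self.table.c + self.table.d)


def _class_genes(classes: Mapping[str, str], label: str,
                 genes: Iterable[str]) -> list[str]:
    return [g for g in genes if classes.get(g) == label]


def enrich(presence: pd.DataFrame, classes: Mapping[str, str],
           motif_name: str, set_a: str, set_b: str) -> EnrichmentResult:
    """Test one motif for differential presence between two classes.

    ``presence`` is the boolean gene x motif matrix from
    :func:`dyadscan.scan.build_presence`; ``classes`` maps gene ids to class
    labels. Both classes must be non-empty among the matrix's genes.
    """
    if motif_name not in presence.columns:
        raise KeyError(f"motif not in presence matrix: {motif_name!r}")
    genes_a = _class_genes(classes, set_a, presence.index)
    genes_b = _class_genes(classes, set_b, presence.index)
    for label, genes in ((set_a, genes_a), (set_b, genes_b)):
        if not genes:
            raise ValueError(f"class {label!r} has no genes in the presence matrix")
    col = presence[motif_name]
    a = int(col.loc[genes_a].sum())
    c = int(col.loc[genes_b].sum())
    table = ContingencyTable(a, len(genes_a) - a, c, len(genes_b) - c)
    return EnrichmentResult(
        motif_name, set_a, set_b, table,
        odds_ratio(table), fisher_exact_two_sided(table),
    )


def enrichment_report(presence: pd.DataFrame, classes: Mapping[str, str],
                      catalog: MotifCatalog,
                      comparisons: Sequence[tuple[str, str]] = tuple(DEFAULT_COMPARISONS),
                      ) -> pd.DataFrame:
    """One row per (motif, comparison), in catalog then comparison order."""
    rows = []
    for motif in catalog:
        for set_a, set_b in comparisons:
            r = enrich(presence, classes, motif.name, set_a, set_b)
            t = r.table
            rows.append({
                "motif": motif.name,
                "comparison": f"{set_a}_vs_{set_b}",
                "n_A": t.a + t.b, "hits_A": t.a, "frac_A": r.frac_a,
                "n_B": t.c + t.d, "hits_B": t.c, "frac_B": r.frac_b,
                "odds_ratio": r.odds_ratio, "p_two_sided": r.p_two_sided,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(report: pd.DataFrame, path: Union[str, Path],
                 fmt: str = "tsv") -> None:
    if fmt == "tsv":
        report.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        records = report.to_dict(orient="records")
        for rec in records:
            if isinstance(rec.get("odds_ratio"), float) and math.isinf(rec["odds_ratio"]):
                rec["odds_ratio"] = "inf"
        payload = {"n_tests": len(report), "results": records}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, allow_nan=False)
    else:
        raise ValueError(f"unknown report format: {fmt!r}")


def read_report(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
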