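"""Overrepresentation analysis.

Entities are selected by an AND-combined criterion (or an explicit id list),
each annotation term yields a 2x2 contingency table against the whole
information table as background, a one-sided ("greater") exact p-value is
computed by summing hypergeometric point probabilities over all more
extreme tables, and p-values are corrected with Bonferroni or
Benjamini-Hochberg.  The hypergeometric pmf is implemented here from first
principles (log-gamma), because this exact test is the analytical core of
the engine rather than plumbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from gxp.errors import ValidationError
from gxp.tables_io import InfoTable, _atomic_write_text

NUMERIC_COMPARATORS = {"<", "<=", ">", ">=", "="}
COMPARATORS = NUMERIC_COMPARATORS | {"contains"}
ADJUST_METHODS = ("bonferroni", "benjamini_hochberg")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Clause:
    column: str
    comparator: str  # <, <=, >, >=, =, contains
    value: object  # float for numeric comparators on numeric columns, else str


@dataclass
class SelectionCriterion:
    """Either a conjunction of clauses or an explicit identifier list."""

    clauses: list[Clause] = field(default_factory=list)
    id_list: list[str] | None = None

    def __post_init__(self) -> None:
        if (self.id_list is None) == (not self.clauses):
            raise ValidationError("criterion needs clauses or an id list (not both/neither)")

    def to_dict(self) -> dict:
        return {
            "clauses": [
                {"column": c.column, "comparator": c.comparator, "value": c.value}
                for c in self.clauses
            ],
            "id_list": self.id_list,
        }


_NUM_OPS = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
    "=": lambda v, t: v == t,
}


def _clause_hits(info: InfoTable, clause: Clause) -> set[str]:
    col = info.column(clause.column)
    hits: set[str] = set()
    if clause.comparator in NUMERIC_COMPARATORS and col.kind == "numeric":
        try:
            threshold = float(clause.value)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ValidationError(
                f"clause on numeric column {clause.column!r} needs a numeric value, "
                f"got {clause.value!r}"
            ) from None
        op = _NUM_OPS[clause.comparator]
        for eid, cell in zip(info.entity_ids, col.cells):
            if cell is None:  # missing never satisfies a numeric clause
                continue
            if op(cell, threshold):
                hits.add(eid)
        return hits
    if clause.comparator == "contains":
        needle = str(clause.value).lower()
        for eid, cell in zip(info.entity_ids, col.cells):
            if cell is not None and needle in str(cell).lower():
                hits.add(eid)
        return hits
    if clause.comparator == "=":
        for i, eid in enumerate(info.entity_ids):
            if str(clause.value) in col.split_cell(i) or str(col.cells[i]) == str(clause.value):
                hits.add(eid)
        return hits
    raise ValidationError(
        f"comparator {clause.comparator!r} is not applicable to "
        f"{col.kind} column {clause.column!r}"
    )


def select_entities(info: InfoTable, criterion: SelectionCriterion) -> set[str]:
    """Ids satisfying ALL clauses, or the validated explicit id list.

    Unknown ids in an explicit list are dropped after emitting a warning.
    """
    if criterion.id_list is not None:
        known = set(info.entity_ids)
        wanted = list(criterion.id_list)
        missing = [i for i in wanted if i not in known]
        if missing:
            import warnings

            warnings.warn(f"ids not in the information table ignored: {missing}", stacklevel=2)
        return {i for i in wanted if i in known}
    result: set[str] | None = None
    for clause in criterion.clauses:
        hits = _clause_hits(info, clause)
        result = hits if result is None else (result & hits)
    return result if result is not None else set()


# ---------------------------------------------------------------------------
# term index
# ---------------------------------------------------------------------------


@dataclass
class TermIndex:
    column: str
    terms: dict[str, set[str]]  # term -> entity ids

    def sizes(self) -> dict[str, int]:
        return {t: len(s) for t, s in self.terms.items()}


def build_term_index(
    info: InfoTable, column: str, delimiter: str | None = None
) -> TermIndex:
    """Map every annotation term of ``column`` to its entity set.

    Multi-valued cells are split on ``delimiter`` (default: the column's
    own multivalue delimiter).  Empty cells contribute nothing.
    """
    col = info.column(column)
    if col.kind == "numeric":
        raise ValidationError(f"cannot index numeric column {column!r} as terms")
    delim = delimiter if delimiter is not None else col.multivalue_delimiter
    terms: dict[str, set[str]] = {}
    for i, eid in enumerate(info.entity_ids):
        cell = col.cells[i]
        if cell is None or cell == "":
            continue
        if delim:
            values = [v.strip() for v in str(cell).split(delim) if v.strip()]
        else:
            values = [str(cell)]
        for v in values:
            terms.setdefault(v, set()).add(eid)
    return TermIndex(column=column, terms=terms)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: selection status x annotation status."""

    a: int  # selected and annotated
    b: int  # selected, not annotated
    c: int  # not selected, annotated
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def selection_size(self) -> int:
        return self.a + self.b

    @property
    def term_size(self) -> int:
        return self.a + self.c


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P[X = k] for X ~ Hypergeometric(N, K, n): k successes in a draw of n
    from a population of N containing K successes.

    Computed as C(K,k) C(N-K, n-k) / C(N,n) through log-gamma for numeric
    stability.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters K={K}, n={n}, N={N}")
    if k < max(0, n - (N - K)) or k > min(K, n):
        if 0 <= k <= n:
            return 0.0
        raise ValidationError(f"k={k} outside [0, n={n}]")
    if N == 0:
        return 1.0
    return math.exp(_log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n))


def fisher_exact_greater(t: ContingencyTable) -> float:
    """One-sided exact p-value for enrichment.

    Sums hypergeometric point probabilities over the observed table and all
    more extreme ones (larger ``a`` with margins fixed) until a cell hits
    zero; accumulation happens in plain floating point on values produced
    in log space, and the result is clipped into (0, 1].
    """
    K, n, N = t.term_size, t.selection_size, t.N
    upper = min(n, K)
    total = 0.0
    for x in range(t.a, upper + 1):
        total += hypergeom_pmf(x, K, n, N)
    total = min(total, 1.0)
    return max(total, math.ulp(0.0))  # never report exactly zero


# ---------------------------------------------------------------------------
# multiple-testing correction
# ---------------------------------------------------------------------------


def adjust_pvalues(pvalues: list[float], method: str = "benjamini_hochberg") -> list[float]:
    """Bonferroni or Benjamini-Hochberg step-up adjustment.

    Output order matches input order; adjusted values are monotone within
    the ranking and capped at 1.
    """
    if method not in ADJUST_METHODS:
        raise ValidationError(f"unknown adjustment method {method!r}")
    m = len(pvalues)
    if m == 0:
        return []
    for p in pvalues:
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p!r} outside (0, 1]")
    if method == "bonferroni":
        return [min(1.0, m * p) for p in pvalues]
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------


@dataclass
class OraRow:
    term: str
    a: int
    term_size: int
    selection_size: int
    N: int
    p_raw: float
    p_adj: float


@dataclass
class OraResult:
    rows: list[OraRow]  # sorted by p_adj, ties by term name
    method: str
    alpha: float
    column: str

    def significant(self) -> list[OraRow]:
        return [r for r in self.rows if r.p_adj < self.alpha]

    def to_dict(self) -> dict:
        return {
            "kind": "ora",
            "method": self.method,
            "alpha": self.alpha,
            "column": self.column,
            "rows": [
                {
                    "term": r.term,
                    "a": r.a,
                    "term_size": r.term_size,
                    "selection_size": r.selection_size,
                    "N": r.N,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                }
                for r in self.rows
            ],
        }

    def to_tsv(self, path: str | None = None) -> str | None:
        lines = ["term\ta\tterm_size\tselection_size\tN\tp_raw\tp_adj"]
        for r in self.rows:
            lines.append(
                f"{r.term}\t{r.a}\t{r.term_size}\t{r.selection_size}\t{r.N}"
                f"\t{r.p_raw:.6g}\t{r.p_adj:.6g}"
            )
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        _atomic_write_text(path, text)
        return None


def run_ora(
    info: InfoTable,
    criterion: SelectionCriterion,
    column: str,
    method: str = "benjamini_hochberg",
    alpha: float = 0.05,
) -> OraResult:
    """Test every term of ``column`` for overrepresentation in the selection.

    The background is the whole information table: N = number of entities,
    including those without any term in the tested column.  Terms with no
    selected member (a = 0) are still reported so the full table remains
    available.
    """
    selected = select_entities(info, criterion)
    if not selected:
        raise ValidationError("empty selection: no overrepresentation test possible")
    index = build_term_index(info, column)
    if not index.terms:
        raise ValidationError(f"column {column!r} holds no annotation terms")
    N = len(info.entity_ids)
    n_sel = len(selected)
    terms = sorted(index.terms)
    raws = []
    tables = []
    for term in terms:
        members = index.terms[term]
        a = len(selected & members)
        table = ContingencyTable(
            a=a, b=n_sel - a, c=len(members) - a, d=N - n_sel - (len(members) - a)
        )
        tables.append(table)
        raws.append(fisher_exact_greater(table))
    adjusted = adjust_pvalues(raws, method)
    rows = [
        OraRow(
            term=term,
            a=t.a,
            term_size=t.term_size,
            selection_size=t.selection_size,
            N=t.N,
            p_raw=p,
            p_adj=q,
        )
        for term, t, p, q in zip(terms, tables, raws, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_adj, r.term))
    return OraResult(rows=rows, method=method, alpha=alpha, column=column)
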