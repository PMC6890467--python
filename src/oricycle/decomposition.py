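"""Model selection by independence of cell-cycle variable decompositions.

A *decomposition* is a minimal set of cell-cycle variables from which all
others follow through the algebraic relations tying them together (sums,
growth ratios, and the exponential-growth link ``log(ratio) = rate *
duration``).  If the cell cycle is driven by independent control
processes, the variables of the true decomposition fluctuate
independently across cells; the determinant of their Pearson correlation
matrix,

    I = det(R),

equals 1 for fully independent fluctuations and approaches 0 as any
linear dependence appears (it is the squared volume of the unit-variance
data cloud).  Ranking all sufficient decompositions by ``I`` therefore
ranks candidate control models by how well they describe the data.

Three variable pools are provided: the 6-variable division cycle alone
(3 degrees of freedom), and the full 10-variable division-centric and
replication-centric views (4 degrees of freedom each).  Sufficiency of a
subset is decided by constraint propagation: a relation with all but one
member known is solved for the remainder, iterated to a fixed point.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Relation",
    "VariablePool",
    "Decomposition",
    "CorrelationResult",
    "IndependenceReport",
    "InconsistencyError",
    "POOL_MODES",
    "get_pool",
    "close_variables",
    "is_sufficient",
    "enumerate_decompositions",
    "correlation_matrix",
    "independence",
    "rank_decompositions",
]

_REL_TOL = 1e-6  # relative tolerance for consistency of known relations


class InconsistencyError(ValueError):
    """Over-determined inputs violate one of the pool relations."""


@dataclass(frozen=True)
class Relation:
    """One algebraic relation between pool variables.

    forms:
        ``sum``:      members (c, a, b) with c = a + b
        ``ratio``:    members (q, num, den) with q = num / den
        ``loglink``:  members (c, a, b) with log(c) = a * b

    All quantities are assumed strictly positive (rates, durations,
    sizes, ratios of a growing cell), which makes every relation
    invertible in each argument.
    """

    form: str
    members: tuple[str, str, str]

    def solve(self, known: dict[str, float]) -> tuple[str, float] | None:
        """Solve for the single unknown member, if exactly one."""
        unknown = [m for m in self.members if m not in known]
        if len(unknown) != 1:
            return None
        target = unknown[0]
        c, a, b = self.members
        if self.form == "sum":  # c = a + b
            if target == c:
                value = known[a] + known[b]
            elif target == a:
                value = known[c] - known[b]
            else:
                value = known[c] - known[a]
        elif self.form == "ratio":  # c = a / b
            if target == c:
                value = known[a] / known[b]
            elif target == a:
                value = known[c] * known[b]
            else:
                value = known[a] / known[c]
        elif self.form == "loglink":  # log(c) = a * b
            if target == c:
                value = math.exp(known[a] * known[b])
            elif target == a:
                value = math.log(known[c]) / known[b]
            else:
                value = math.log(known[c]) / known[a]
        else:
            raise ValueError(f"unknown relation form {self.form!r}")
        return target, value

    def check(self, known: dict[str, float]) -> bool:
        """True if the fully known relation is satisfied."""
        c, a, b = self.members
        if any(m not in known for m in self.members):
            return True
        if self.form == "sum":
            lhs, rhs = known[c], known[a] + known[b]
        elif self.form == "ratio":
            lhs, rhs = known[c], known[a] / known[b]
        else:
            lhs, rhs = math.log(known[c]), known[a] * known[b]
        scale = max(abs(lhs), abs(rhs), 1e-300)
        return abs(lhs - rhs) <= _REL_TOL * scale


@dataclass(frozen=True)
class VariablePool:
    """A variable set, its relations, and its degrees of freedom."""

    mode: str
    variables: tuple[str, ...]
    relations: tuple[Relation, ...]
    dof: int
    free_variables: tuple[str, ...]  # one canonical sufficient subset

    def generic_assignment(self, rng: np.random.Generator) -> dict[str, float]:
        """A random, fully consistent assignment of all pool variables."""
        known = {
            "Lb": rng.uniform(0.8, 2.0),
            "dL": rng.uniform(0.5, 1.5),
            "dLbi": rng.uniform(0.2, 0.4),
            "lambda": rng.uniform(0.005, 0.02),
            "Lambda_i": rng.uniform(0.8, 1.5),
            "dLif": rng.uniform(0.5, 1.5),
            "dLib": rng.uniform(0.2, 0.8),
            "alpha": rng.uniform(0.005, 0.02),
        }
        seed_values = {v: known[v] for v in self.free_variables}
        return close_variables(seed_values, self)


_DIVISION_CORE = (
    Relation("sum", ("Ld", "Lb", "dL")),
    Relation("ratio", ("Rbd", "Ld", "Lb")),
    Relation("loglink", ("Rbd", "lambda", "Tbd")),
)
_DIVISION_INIT = (
    Relation("sum", ("Li", "Lb", "dLbi")),
    Relation("ratio", ("Rbi", "Li", "Lb")),
    Relation("loglink", ("Rbi", "lambda", "Tbi")),
)
_REPLICATION = (
    Relation("sum", ("Lambda_f", "Lambda_i", "dLif")),
    Relation("ratio", ("Rif", "Lambda_f", "Lambda_i")),
    Relation("loglink", ("Rif", "alpha", "Tif")),
    Relation("sum", ("Lambda_b", "Lambda_i", "dLib")),
    Relation("ratio", ("Rib", "Lambda_b", "Lambda_i")),
    Relation("loglink", ("Rib", "alpha", "Tib")),
)

_POOLS = {
    "division_cycle_only": VariablePool(
        mode="division_cycle_only",
        variables=("Lb", "Ld", "Tbd", "lambda", "dL", "Rbd"),
        relations=_DIVISION_CORE,
        dof=3,
        free_variables=("Lb", "dL", "lambda"),
    ),
    "division_centric_full": VariablePool(
        mode="division_centric_full",
        variables=(
            "Lb",
            "Ld",
            "Tbd",
            "Li",
            "Tbi",
            "lambda",
            "dL",
            "dLbi",
            "Rbd",
            "Rbi",
        ),
        relations=_DIVISION_CORE + _DIVISION_INIT,
        dof=4,
        free_variables=("Lb", "dL", "dLbi", "lambda"),
    ),
    "replication_centric_full": VariablePool(
        mode="replication_centric_full",
        variables=(
            "Lambda_i",
            "Lambda_f",
            "Lambda_b",
            "Tif",
            "Tib",
            "alpha",
            "dLif",
            "dLib",
            "Rif",
            "Rib",
        ),
        relations=_REPLICATION,
        dof=4,
        free_variables=("Lambda_i", "dLif", "dLib", "alpha"),
    ),
}

POOL_MODES = tuple(_POOLS)


def get_pool(mode: str) -> VariablePool:
    try:
        return _POOLS[mode]
    except KeyError:
        raise ValueError(
            f"unknown pool mode {mode!r}; expected one of {POOL_MODES}"
        ) from None


# ---------------------------------------------------------------------------
# Constraint propagation
# ---------------------------------------------------------------------------


def close_variables(
    known: dict[str, float], pool: VariablePool
) -> dict[str, float]:
    """Propagate the pool relations from ``known`` to a fixed point.

    Any relation with all but one member known is solved for the
    remainder.  Fully known relations are checked for consistency; a
    violation beyond the relative tolerance raises
    :class:`InconsistencyError`.
    """
    extra = set(known) - set(pool.variables)
    if extra:
        raise ValueError(f"unknown variable(s) for pool {pool.mode}: {extra}")
    values = dict(known)
    changed = True
    while changed:
        changed = False
        for rel in pool.relations:
            solved = rel.solve(values)
            if solved is not None:
                values[solved[0]] = solved[1]
                changed = True
    for rel in pool.relations:
        if not rel.check(values):
            raise InconsistencyError(
                f"relation {rel.form}{rel.members} violated by inputs"
            )
    return values


def is_sufficient(subset, pool: VariablePool) -> bool:
    """True iff closure from the subset reaches every pool variable.

    Decided on numeric assignments at generic positive values (two
    independent random consistent points), so internally dependent
    subsets fail automatically: they cannot reach the rest of the pool.
    """
    subset = tuple(subset)
    if len(subset) != pool.dof:
        return False
    rng = np.random.default_rng(171717)
    for _ in range(2):
        full = pool.generic_assignment(rng)
        seed_values = {v: full[v] for v in subset}
        closed = close_variables(seed_values, pool)
        if set(closed) != set(pool.variables):
            return False
    return True


# ---------------------------------------------------------------------------
# Independence
# ---------------------------------------------------------------------------


@dataclass
class Decomposition:
    variables: tuple[str, ...]
    sufficient: bool
    R: np.ndarray | None = None
    independence: float | None = None
    n_used: int = 0
    degenerate: bool = False


@dataclass
class CorrelationResult:
    variables: tuple[str, ...]
    R: np.ndarray
    p_values: np.ndarray
    n_used: int
    small_sample: bool  # n_used < 100


def enumerate_decompositions(pool: VariablePool) -> list[Decomposition]:
    """All dof-sized subsets of the pool, tested for sufficiency.

    Insufficient subsets are retained (``sufficient=False``) for audit;
    the order is the deterministic lexicographic order of the pool's
    variable tuple.
    """
    return [
        Decomposition(variables=subset, sufficient=is_sufficient(subset, pool))
        for subset in itertools.combinations(pool.variables, pool.dof)
    ]


def correlation_matrix(
    table: pd.DataFrame, variables
) -> CorrelationResult:
    """Pearson correlations on complete-case raw variables.

    Two-sided p-values come from the exact t-distribution of the sample
    correlation under the null.
    """
    variables = tuple(variables)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing variable column(s): {missing}")
    data = table.loc[:, list(variables)].dropna().to_numpy(dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    sd = data.std(axis=0)
    zero = [v for v, s in zip(variables, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    r = np.corrcoef(data, rowvar=False)
    # two-sided p-values from the t-transform of r
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return CorrelationResult(
        variables=variables,
        R=r,
        p_values=p,
        n_used=n,
        small_sample=n < 100,
    )


def independence(R: np.ndarray) -> float:
    """Independence ``I = det(R)`` of a correlation matrix, clipped to [0, 1]."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have unit diagonal")
    det = float(np.linalg.det(R))
    if det < 0:
        det = 0.0  # sample correlation matrices are PSD up to rounding
    return min(det, 1.0)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


@dataclass
class IndependenceReport:
    """Sufficient decompositions ranked by independence."""

    pool_mode: str
    ranking: pd.DataFrame  # columns: rank, variables, independence, n_used
    decompositions: list[Decomposition] = field(default_factory=list)

    def top(self, k: int = 5) -> pd.DataFrame:
        return self.ranking.head(k).reset_index(drop=True)

    def to_text(self, k: int = 5) -> str:
        lines = [
            f"Decomposition ranking — pool: {self.pool_mode}",
            f"{'rank':>4}  {'independence':>12}  {'n':>6}  variables",
        ]
        for _, row in self.top(k).iterrows():
            lines.append(
                f"{int(row['rank']):>4}  {row['independence']:>12.4f}  "
                f"{int(row['n_used']):>6}  {row['variables']}"
            )
        lines.append(
            "note: pairwise p-values are reported per correlation; no "
            "multiple-testing correction is applied to the ranking."
        )
        return "\n".join(lines)


def rank_decompositions(
    table: pd.DataFrame, pool: VariablePool
) -> IndependenceReport:
    """Rank all sufficient decompositions of ``pool`` on a cycle table.

    Sorted by independence descending; ties broken lexicographically by
    the variable tuple.  Degenerate subsets (zero-variance columns after
    complete-case filtering) are flagged and excluded from the ranking.
    """
    missing = [v for v in pool.variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing variable column(s): {missing}")
    decomps = enumerate_decompositions(pool)
    rows = []
    for d in decomps:
        if not d.sufficient:
            continue
        try:
            corr = correlation_matrix(table, d.variables)
        except ValueError:
            d.degenerate = True
            continue
        d.R = corr.R
        d.independence = independence(corr.R)
        d.n_used = corr.n_used
        rows.append(
            {
                "variables": "+".join(d.variables),
                "independence": d.independence,
                "n_used": d.n_used,
            }
        )
    ranking = pd.DataFrame(rows, columns=["variables", "independence", "n_used"])
    ranking = ranking.sort_values(
        ["independence", "variables"], ascending=[False, True]
    ).reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    return IndependenceReport(
        pool_mode=pool.mode, ranking=ranking, decompositions=decomps
    )
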