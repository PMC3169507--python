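"""Linear-programming estimation of complex copy numbers.

In the ideal case every copy of every protein is consumed by complex
formation: p_i = Σ_j S_ij c_j, where p_i is the abundance of protein i,
c_j the copy number of complex j, and S_ij the stoichiometric count of
protein i in complex j (restricted to *core* memberships — the skeleton
of each complex — so that promiscuous attachments do not inflate the
estimate). With more proteins than complexes the system is
over-determined, so we instead require availability,
Σ_j S_ij c_j ≤ p_i, and minimize the total leftover

    DA = Σ_{i∈K} (p_i − Σ_j S_ij c_j),

summed over the set K of proteins with known positive abundance. Under
the availability constraint this equals the L1 deviation from the ideal
balance. The minimizer gives copy numbers for complexes; substituting
them back into the ideal balance imputes abundances for proteins whose
abundance was unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .datatypes import AbundanceTable, ComplexomeDataset, Role

logger = logging.getLogger(__name__)

_FEAS_TOL = 1e-8


@dataclass
class AbundanceProblem:
    """LP data: core stoichiometry S restricted to proteins in K."""

    complexes: tuple[str, ...]  # column order
    proteins: tuple[str, ...]  # row order: all core proteins (known or not)
    S: sparse.csr_matrix  # (n_proteins, n_complexes), core memberships only
    p: dict[str, float]  # known positive abundances (the set K)
    condition: str

    @property
    def known_proteins(self) -> tuple[str, ...]:
        return tuple(pid for pid in self.proteins if pid in self.p)


@dataclass
class AbundanceSolution:
    """Optimal copy numbers with leftovers, flags and imputations."""

    condition: str
    c: dict[str, float]
    objective: float  # DA, total leftover over K
    slack: dict[str, float]  # p_i − Σ_j S_ij c_j for i in K
    undetermined: frozenset[str]  # complexes constrained by no known protein
    imputed: dict[str, float] = field(default_factory=dict)
    imputed_flags: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": "abundance",
            "condition": self.condition,
            "c": {k: float(v) for k, v in self.c.items()},
            "objective": float(self.objective),
            "slack": {k: float(v) for k, v in self.slack.items()},
            "undetermined": sorted(self.undetermined),
            "imputed": {k: float(v) for k, v in self.imputed.items()},
            "imputed_flags": dict(self.imputed_flags),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AbundanceSolution":
        return cls(
            condition=d["condition"],
            c=dict(d["c"]),
            objective=d["objective"],
            slack=dict(d["slack"]),
            undetermined=frozenset(d["undetermined"]),
            imputed=dict(d.get("imputed", {})),
            imputed_flags=dict(d.get("imputed_flags", {})),
            metadata=dict(d.get("metadata", {})),
        )


def build_abundance_problem(
    dataset: ComplexomeDataset, abundance: AbundanceTable, condition: str
) -> AbundanceProblem:
    """Assemble the LP from core memberships and one condition's abundances.

    Proteins with unknown (or zero) abundance stay in the row space of S
    — they will receive imputations — but impose no constraint and do
    not enter the objective.
    """
    if condition not in abundance.conditions:
        raise ValueError(
            f"condition {condition!r} not in table (has {abundance.conditions})"
        )
    core = [m for m in dataset.memberships if m.role is Role.CORE]
    if not core:
        raise ValueError("nothing to estimate: dataset has no core memberships")
    complexes = tuple(sorted({m.complex_id for m in core}))
    proteins = tuple(sorted({m.protein_id for m in core}))
    ci = {c: j for j, c in enumerate(complexes)}
    pi = {p: i for i, p in enumerate(proteins)}
    rows, cols, vals = [], [], []
    for m in core:
        rows.append(pi[m.protein_id])
        cols.append(ci[m.complex_id])
        vals.append(float(m.copies))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(proteins), len(complexes))
    )
    known = abundance.known(condition)
    p = {pid: known[pid] for pid in proteins if pid in known}
    return AbundanceProblem(
        complexes=complexes, proteins=proteins, S=S, p=p, condition=condition
    )


def solve_abundance(
    problem: AbundanceProblem, compute_intervals: bool = False
) -> AbundanceSolution:
    """Minimize the total leftover DA subject to availability.

    Minimizing DA = Σ_{i∈K}(p_i − (Sc)_i) is equivalent to maximizing
    Σ_{i∈K}(Sc)_i, a plain LP solved with HiGHS. Complexes appearing in
    no constraint (no core member with known abundance) are flagged
    undetermined and conservatively assigned c = 0.

    With ``compute_intervals`` the optimal face is probed: per complex,
    c_j is re-minimized and re-maximized at fixed optimal DA, yielding
    the interval [min c_j, max c_j] over all optimal solutions (stored
    in ``metadata['intervals']``).
    """
    known_idx = [i for i, pid in enumerate(problem.proteins) if pid in problem.p]
    if not known_idx:
        c = {cid: 0.0 for cid in problem.complexes}
        return AbundanceSolution(
            condition=problem.condition,
            c=c,
            objective=0.0,
            slack={},
            undetermined=frozenset(problem.complexes),
            metadata={"objective_form": "L1-leftover"},
        )
    S_K = problem.S[known_idx, :]
    p_K = np.array([problem.p[problem.proteins[i]] for i in known_idx])
    col_active = np.asarray(S_K.sum(axis=0)).ravel() > 0
    undetermined = frozenset(
        cid for j, cid in enumerate(problem.complexes) if not col_active[j]
    )
    # max Σ_i (S_K c)_i  ⇔  min −(1ᵀ S_K) c   s.t.  S_K c ≤ p_K, c ≥ 0
    obj = -np.asarray(S_K.sum(axis=0)).ravel()
    res = linprog(obj, A_ub=S_K, b_ub=p_K, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - c=0 is always feasible
        raise RuntimeError(
            f"LP solver failed: {res.message}\n"
            f"shape={S_K.shape} p range=({p_K.min()}, {p_K.max()})"
        )
    c_vec = np.where(col_active, res.x, 0.0)
    used = S_K @ c_vec
    slack_vec = p_K - used
    if slack_vec.min() < -_FEAS_TOL:
        raise RuntimeError(f"availability violated: min slack {slack_vec.min()}")
    DA = float(slack_vec.sum())
    sol = AbundanceSolution(
        condition=problem.condition,
        c={cid: float(c_vec[j]) for j, cid in enumerate(problem.complexes)},
        objective=DA,
        slack={
            problem.proteins[i]: float(s) for i, s in zip(known_idx, slack_vec)
        },
        undetermined=undetermined,
        metadata={"objective_form": "L1-leftover"},
    )
    if compute_intervals:
        sol.metadata["intervals"] = _optimal_intervals(
            S_K, p_K, obj, -DA + float(p_K.sum()), problem.complexes, col_active
        )
    return sol


def _optimal_intervals(S_K, p_K, obj, opt_usage, complexes, col_active):
    """[min c_j, max c_j] over the optimal face, per complex."""
    n = len(complexes)
    A_eq = obj.reshape(1, -1)
    b_eq = np.array([-opt_usage])
    intervals = {}
    for j, cid in enumerate(complexes):
        if not col_active[j]:
            intervals[cid] = (0.0, 0.0)
            continue
        lohi = []
        for sign in (1.0, -1.0):
            e = np.zeros(n)
            e[j] = sign
            r = linprog(
                e, A_ub=S_K, b_ub=p_K, A_eq=A_eq, b_eq=b_eq,
                bounds=(0, None), method="highs",
            )
            lohi.append(sign * r.fun if r.success else np.nan)
        intervals[cid] = (float(lohi[0]), float(lohi[1]))
    return intervals


def impute_abundance(
    solution: AbundanceSolution, dataset: ComplexomeDataset
) -> dict[str, float]:
    """Impute p̂_i = Σ_j S_ij c_j for proteins outside K.

    Uses the ideal balance with the solved copy numbers, over core
    memberships. A protein whose complexes are all undetermined gets
    p̂ = 0 with an ``undetermined`` provenance flag; proteins in K or in
    no complex are skipped. Updates ``solution.imputed`` in place and
    returns it.
    """
    core = [m for m in dataset.memberships if m.role is Role.CORE]
    by_protein: dict[str, list] = {}
    for m in core:
        by_protein.setdefault(m.protein_id, []).append(m)
    known = set(solution.slack)
    for pid, ms in by_protein.items():
        if pid in known:
            continue
        value = sum(m.copies * solution.c.get(m.complex_id, 0.0) for m in ms)
        solution.imputed[pid] = float(value)
        if all(m.complex_id in solution.undetermined for m in ms):
            solution.imputed_flags[pid] = "undetermined"
        else:
            solution.imputed_flags[pid] = "estimated"
    return solution.imputed


def abundance_ratio_by_category(
    sol_num: AbundanceSolution,
    sol_den: AbundanceSolution,
    function_solution,
    level: int = 1,
    hc_only: bool = True,
    eps: float = 1e-9,
) -> dict[str, dict]:
    """Condition-dependent abundance ratios grouped by functional category.

    Per complex, ratio = c_num / c_den (conventionally SD over YEPD:
    minimal over rich media). Complexes with c_den < ``eps`` are
    excluded and counted. Categories are function codes truncated to
    ``level`` dotted fields; a complex with functions in several
    categories contributes to each. Each contributing complex is also
    classified by ratio: ``up`` (> 1.2), ``down`` (< 0.8), or ``mid``
    (inclusive bounds).
    """
    from .functions import FunctionSolution  # local import to avoid cycle

    assert isinstance(function_solution, FunctionSolution)
    ratios: dict[str, float] = {}
    excluded = 0
    for cid in sol_num.c:
        den = sol_den.c.get(cid, 0.0)
        if den < eps:
            excluded += 1
            continue
        ratios[cid] = sol_num.c[cid] / den
    by_cat: dict[str, set[str]] = {}
    for (cid, code), conf in function_solution.confidence.items():
        if hc_only and conf != "HC":
            continue
        if cid not in ratios:
            continue
        cat = ".".join(code.split(".")[:level])
        by_cat.setdefault(cat, set()).add(cid)
    out: dict[str, dict] = {}
    for cat, cids in sorted(by_cat.items()):
        vals = sorted(ratios[cid] for cid in cids)
        classes = {
            "up": sum(v > 1.2 for v in vals),
            "down": sum(v < 0.8 for v in vals),
            "mid": sum(0.8 <= v <= 1.2 for v in vals),
        }
        out[cat] = {
            "mean_ratio": float(np.mean(vals)),
            "n_complexes": len(vals),
            "classes": classes,
            "excluded_zero_denominator": excluded,
        }
    return out
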