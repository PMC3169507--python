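"""Functional annotation of complexes by minimum set cover.

The covering constraint says that every function carried by a protein
must be carried by at least one of the complexes the protein belongs to:

    Σ_j U_ij Fc_jk ≥ 1   whenever Fp_ik = 1,

where U_ij is the binary membership indicator over *all* roles (core and
attachment — allowing every alternative assignment makes the surviving
ones more certain), Fp_ik annotates protein i with function k, and
Fc_jk is the sought complex annotation. In the spirit of parsimony we
minimize, independently for each function k, the number of complexes
assigned that function (Σ_j Fc_jk) — a minimum set cover per function,
solved exactly as a small MILP. An alternative objective instead
minimizes the number of *newly annotated core proteins* the chosen
complexes drag in, with ties broken by fewer complexes.

Minimum covers are rarely unique. An assignment (j, k) is labelled
high-confidence (HC) when complex j appears in *every* optimal cover of
function k, decided exactly by re-solving with Fc_jk forced to 0 and
checking whether the optimum degrades. After annotation, functions are
re-substituted down to proteins: protein i is predicted to carry k when
it is a *core* member of an assigned complex and lacked the annotation
— and each such prediction can be traced to the donor proteins whose
annotations forced the cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .datatypes import ComplexomeDataset, FunctionTable, Role

logger = logging.getLogger(__name__)

VARIANTS = ("min_complexes", "min_proteins")


@dataclass
class FunctionProblem:
    """Covering data: memberships over all roles plus protein annotations."""

    complexes: tuple[str, ...]
    proteins: tuple[str, ...]
    membership: dict[str, frozenset[str]]  # protein -> complexes (all roles)
    core_membership: dict[str, frozenset[str]]  # protein -> complexes (core)
    complex_members: dict[str, frozenset[str]]  # complex -> proteins (all roles)
    complex_cores: dict[str, frozenset[str]]  # complex -> proteins (core)
    annotations: dict[str, frozenset[str]]  # function code -> annotated proteins
    excluded_proteins: tuple[str, ...]  # annotated but in no complex

    @property
    def universe(self) -> tuple[str, ...]:
        return tuple(sorted(self.annotations))


@dataclass
class FunctionSolution:
    """Per-function minimum covers with confidence and provenance."""

    variant: str
    confidence: dict[tuple[str, str], str]  # (complex, code) -> "raw" | "HC"
    m_star: dict[str, int]  # code -> minimum cover size (min_complexes count)
    provenance: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def assignments(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.confidence)

    def hc_assignments(self) -> frozenset[tuple[str, str]]:
        return frozenset(k for k, v in self.confidence.items() if v == "HC")

    def complexes_for(self, code: str, hc_only: bool = False) -> frozenset[str]:
        return frozenset(
            cid
            for (cid, c), conf in self.confidence.items()
            if c == code and (not hc_only or conf == "HC")
        )

    def to_dict(self) -> dict:
        return {
            "kind": "functions",
            "variant": self.variant,
            "assignments": [
                {
                    "complex": cid,
                    "function": code,
                    "confidence": conf,
                    "source_proteins": sorted(
                        self.provenance.get((cid, code), frozenset())
                    ),
                }
                for (cid, code), conf in sorted(self.confidence.items())
            ],
            "m_star": dict(sorted(self.m_star.items())),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunctionSolution":
        confidence = {}
        provenance = {}
        for a in d["assignments"]:
            key = (a["complex"], a["function"])
            confidence[key] = a["confidence"]
            provenance[key] = frozenset(a["source_proteins"])
        return cls(
            variant=d["variant"],
            confidence=confidence,
            m_star={k: int(v) for k, v in d["m_star"].items()},
            provenance=provenance,
            metadata=dict(d.get("metadata", {})),
        )


def build_function_problem(
    dataset: ComplexomeDataset, functions: FunctionTable
) -> FunctionProblem:
    """Assemble U (all roles) and Fp; report annotated proteins outside
    every complex (they cannot constrain any cover)."""
    membership: dict[str, set[str]] = {}
    core_membership: dict[str, set[str]] = {}
    complex_members: dict[str, set[str]] = {}
    complex_cores: dict[str, set[str]] = {}
    for m in dataset.memberships:
        membership.setdefault(m.protein_id, set()).add(m.complex_id)
        complex_members.setdefault(m.complex_id, set()).add(m.protein_id)
        if m.role is Role.CORE:
            core_membership.setdefault(m.protein_id, set()).add(m.complex_id)
            complex_cores.setdefault(m.complex_id, set()).add(m.protein_id)
    annotations: dict[str, set[str]] = {}
    excluded: set[str] = set()
    for pid, codes in functions.entries.items():
        if pid not in membership:
            excluded.add(pid)
            continue
        for code in codes:
            annotations.setdefault(code, set()).add(pid)
    if excluded:
        logger.info(
            "%d annotated protein(s) are in no complex and are excluded "
            "from covering constraints",
            len(excluded),
        )
    return FunctionProblem(
        complexes=dataset.complexes,
        proteins=dataset.proteins,
        membership={p: frozenset(s) for p, s in membership.items()},
        core_membership={p: frozenset(s) for p, s in core_membership.items()},
        complex_members={c: frozenset(s) for c, s in complex_members.items()},
        complex_cores={c: frozenset(s) for c, s in complex_cores.items()},
        annotations={k: frozenset(s) for k, s in annotations.items()},
        excluded_proteins=tuple(sorted(excluded)),
    )


def _instance(problem: FunctionProblem, code: str):
    """Candidate complexes and proteins-to-cover of one function's cover."""
    covered = sorted(problem.annotations[code])
    candidates = sorted(set().union(*(problem.membership[p] for p in covered)))
    return candidates, covered


def _solve_cover(
    problem: FunctionProblem,
    code: str,
    variant: str,
    forbidden: str | None = None,
) -> tuple[float, dict[str, int] | None, int]:
    """Solve one per-function cover instance exactly with HiGHS.

    Returns (objective value, chosen complexes or None if infeasible,
    number of chosen complexes). For ``min_proteins`` the objective is
    the lexicographic combination (M+1)·(new core proteins) + complexes.
    """
    candidates, covered = _instance(problem, code)
    n = len(candidates)
    cidx = {c: j for j, c in enumerate(candidates)}
    if variant == "min_complexes":
        n_var = n
        obj = np.ones(n)
    else:
        # extra binary y_i per potentially newly annotated core protein
        annotated = problem.annotations[code]
        new_core: list[str] = sorted(
            {
                p
                for c in candidates
                for p in problem.complex_cores.get(c, frozenset())
                if p not in annotated
            }
        )
        yidx = {p: n + i for i, p in enumerate(new_core)}
        n_var = n + len(new_core)
        obj = np.zeros(n_var)
        obj[:n] = 1.0
        obj[n:] = n + 1  # one new protein outweighs any number of complexes
    rows, cols, vals, lb = [], [], [], []
    r = 0
    for p in covered:
        for c in problem.membership[p] & set(candidates):
            rows.append(r)
            cols.append(cidx[c])
            vals.append(1.0)
        lb.append(1.0)
        r += 1
    if variant == "min_proteins":
        # y_i >= x_j  ⇔  y_i − x_j ≥ 0 for each core membership of a new protein
        for p in new_core:
            for c in problem.core_membership.get(p, frozenset()) & set(candidates):
                rows.append(r)
                cols.append(yidx[p])
                vals.append(1.0)
                rows.append(r)
                cols.append(cidx[c])
                vals.append(-1.0)
                lb.append(0.0)
                r += 1
    A = csr_matrix((vals, (rows, cols)), shape=(r, n_var))
    ub_var = np.ones(n_var)
    if forbidden is not None:
        if forbidden not in cidx:
            # forbidding an irrelevant complex changes nothing
            forbidden = None
        else:
            ub_var[cidx[forbidden]] = 0.0
    res = milp(
        c=obj,
        constraints=LinearConstraint(A, lb, np.inf),
        integrality=np.ones(n_var),
        bounds=Bounds(np.zeros(n_var), ub_var),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0 or res.x is None:
        return np.inf, None, 0
    chosen = {c: 1 for c in candidates if res.x[cidx[c]] > 0.5}
    # post-hoc covering check: never trust the solver blindly
    for p in covered:
        if not problem.membership[p] & set(chosen):
            raise RuntimeError(f"cover for {code!r} leaves protein {p!r} uncovered")
    return float(round(res.fun)), chosen, len(chosen)


def solve_function_assignment(
    problem: FunctionProblem, variant: str = "min_complexes"
) -> FunctionSolution:
    """Solve all per-function covers; returns raw assignments.

    The global problem decomposes into one independent minimum-set-cover
    instance per function; each is solved to proven optimality.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    confidence: dict[tuple[str, str], str] = {}
    m_star: dict[str, int] = {}
    provenance: dict[tuple[str, str], frozenset[str]] = {}
    objectives: dict[str, float] = {}
    for code in sorted(problem.annotations):
        opt, chosen, n_complexes = _solve_cover(problem, code, variant)
        if chosen is None:  # pragma: no cover - covers always feasible
            raise RuntimeError(f"cover instance for function {code!r} infeasible")
        m_star[code] = n_complexes
        objectives[code] = opt
        for cid in chosen:
            confidence[(cid, code)] = "raw"
            provenance[(cid, code)] = frozenset(
                problem.complex_members[cid] & problem.annotations[code]
            )
    return FunctionSolution(
        variant=variant,
        confidence=confidence,
        m_star=m_star,
        provenance=provenance,
        metadata={"objectives": objectives},
    )


def hc_filter(problem: FunctionProblem, solution: FunctionSolution) -> FunctionSolution:
    """Label assignments present in every optimal cover as HC.

    (j, k) is HC iff forbidding complex j makes function k's instance
    infeasible or strictly worse than its optimum — the exact
    characterization of membership in all optima.
    """
    objectives = solution.metadata.get("objectives", {})
    for (cid, code) in sorted(solution.confidence):
        opt = objectives[code]
        forced, _, _ = _solve_cover(problem, code, solution.variant, forbidden=cid)
        if forced > opt + 0.5:  # integer objectives: strictly worse or infeasible
            solution.confidence[(cid, code)] = "HC"
    return solution


def resubstitute_protein_functions(
    solution: FunctionSolution,
    dataset: ComplexomeDataset,
    functions: FunctionTable,
    hc_only: bool = True,
) -> dict[tuple[str, str], frozenset[str]]:
    """Predict new protein functions from assigned complexes.

    (i, k) is predicted when protein i is a *core* member of a complex
    assigned k (HC-only if requested) and i lacked annotation k. Returns
    predictions mapped to their source complexes.
    """
    core_of: dict[str, set[str]] = {}
    for m in dataset.memberships:
        if m.role is Role.CORE:
            core_of.setdefault(m.complex_id, set()).add(m.protein_id)
    predictions: dict[tuple[str, str], set[str]] = {}
    for (cid, code), conf in solution.confidence.items():
        if hc_only and conf != "HC":
            continue
        for pid in core_of.get(cid, set()):
            if code in functions.functions_of(pid):
                continue
            predictions.setdefault((pid, code), set()).add(cid)
    return {k: frozenset(v) for k, v in predictions.items()}


def trace_function_source(
    solution: FunctionSolution,
    dataset: ComplexomeDataset,
    functions: FunctionTable,
    complex_id: str,
    code: str,
) -> dict[str, str]:
    """Donor proteins of an assignment: members of the complex already
    annotated with the function. Returns {protein: role}; roles are
    comma-joined when a protein is both core and attachment."""
    matching = [k for k in solution.confidence if k == (complex_id, code)]
    if not matching:
        raise KeyError(f"function {code!r} is not assigned to complex {complex_id!r}")
    donors: dict[str, set[str]] = {}
    for m in dataset.memberships:
        if m.complex_id == complex_id and code in functions.functions_of(m.protein_id):
            donors.setdefault(m.protein_id, set()).add(m.role.value)
    if not donors:
        raise RuntimeError(
            f"assignment ({complex_id!r}, {code!r}) has no donor protein; "
            "covering invariant violated"
        )
    return {p: ",".join(sorted(roles)) for p, roles in donors.items()}
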