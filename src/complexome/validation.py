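"""Hold-out validation of abundance imputation and function assignment.

Abundance: proteins with known abundance are split into training and
test sets; the LP is solved on training abundances only; imputed test
abundances p̂ are compared with the held-out truth through the relative
deviation α = |p̂ − p| / p, and the ranked α curve is compared with a
random-pairing null in which the imputed values are permuted across the
test proteins.

Functions: annotated proteins are split the same way; test annotations
are masked, the set-cover pipeline runs on training annotations, and
re-substituted predictions for test proteins are scored by two
complementary fractions — of predicted protein-function pairs present
in the held-out truth (specificity-like) and of predicted-for proteins
with at least one correct function (sensitivity-like) — for both raw
and high-confidence outcomes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .abundance import build_abundance_problem, impute_abundance, solve_abundance
from .datatypes import AbundanceTable, ComplexomeDataset, FunctionTable, Role
from .functions import (
    build_function_problem,
    hc_filter,
    resubstitute_protein_functions,
    solve_function_assignment,
)


@dataclass(frozen=True)
class SplitSpec:
    """Training fraction and seed of one protein-level split."""

    training_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.training_fraction < 1.0):
            raise ValueError("training fraction must lie strictly in (0, 1)")


@dataclass
class Fraction:
    """A metric with its counts, rendered like ``33.5% (641/1912)``."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    def __str__(self) -> str:
        if self.denominator == 0:
            return f"undefined ({self.numerator}/{self.denominator})"
        return f"{100 * self.value:.1f}% ({self.numerator}/{self.denominator})"


@dataclass
class ValidationReport:
    kind: str  # "abundance" | "functions"
    spec: SplitSpec
    n_train: int
    n_test: int
    alphas: dict[str, float] = field(default_factory=dict)  # protein -> α
    ranked_alpha: list[float] = field(default_factory=list)
    null_mean: list[float] = field(default_factory=list)
    null_lo: list[float] = field(default_factory=list)  # central 95% band
    null_hi: list[float] = field(default_factory=list)
    function_metrics: dict[str, dict[str, Fraction]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def ranked_table(self) -> list[tuple[int, float, float, float, float]]:
        """(rank, α, null mean, null 2.5%, null 97.5%) rows."""
        return [
            (r + 1, a, m, lo, hi)
            for r, (a, m, lo, hi) in enumerate(
                zip(self.ranked_alpha, self.null_mean, self.null_lo, self.null_hi)
            )
        ]


def split(eligible, spec: SplitSpec) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Uniform random partition with |training| = round(p·n).

    Rounding is half-away-from-zero; deterministic given the seed.
    Raises if the training set would be empty or exhaust the proteins.
    """
    items = tuple(sorted(eligible))
    n = len(items)
    if n == 0:
        raise ValueError("eligible set is empty")
    n_train = int(math.floor(spec.training_fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"training fraction {spec.training_fraction} with n={n} leaves an "
            f"empty training or test set"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    train = tuple(sorted(items[i] for i in order[:n_train]))
    test = tuple(sorted(items[i] for i in order[n_train:]))
    return train, test


def _table_hash(entries: dict) -> str:
    payload = json.dumps(sorted((str(k), str(v)) for k, v in entries.items()))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_abundance(
    dataset: ComplexomeDataset,
    abundance: AbundanceTable,
    condition: str,
    spec: SplitSpec,
    n_null: int = 200,
) -> ValidationReport:
    """Mask test abundances, re-impute them, and rank α against a
    random-pairing null of ``n_null`` replicates."""
    core_proteins = {
        m.protein_id for m in dataset.memberships if m.role is Role.CORE
    }
    known = abundance.known(condition)
    eligible = sorted(set(known) & core_proteins)
    train, test = split(eligible, spec)
    masked_entries = {
        (pid, cond): v
        for (pid, cond), v in abundance.entries.items()
        if not (cond == condition and pid in set(test))
    }
    masked = AbundanceTable.from_entries(masked_entries, proteins=abundance.proteins)
    problem = build_abundance_problem(dataset, masked, condition)
    solution = solve_abundance(problem)
    impute_abundance(solution, dataset)
    report = ValidationReport(
        kind="abundance",
        spec=spec,
        n_train=len(train),
        n_test=len(test),
        metadata={
            "condition": condition,
            "alpha_form": "|estimated - real| / real",
            "n_null": n_null,
            "training_input_hash": _table_hash(masked_entries),
        },
    )
    estimable = [
        pid
        for pid in test
        if solution.imputed_flags.get(pid) == "estimated" and known[pid] > 0
    ]
    if not estimable:
        report.warnings.append(
            "no imputable test protein lies in a determined complex"
        )
        return report
    estimates = np.array([solution.imputed[pid] for pid in estimable])
    truths = np.array([known[pid] for pid in estimable])
    alpha = np.abs(estimates - truths) / truths
    report.alphas = {pid: float(a) for pid, a in zip(estimable, alpha)}
    report.ranked_alpha = [float(a) for a in np.sort(alpha)]
    rng = np.random.default_rng(spec.seed + 1)
    null_curves = np.empty((n_null, len(estimable)))
    for r in range(n_null):
        perm = rng.permutation(len(estimable))
        null_alpha = np.abs(estimates[perm] - truths) / truths
        null_curves[r] = np.sort(null_alpha)
    report.null_mean = [float(x) for x in null_curves.mean(axis=0)]
    report.null_lo = [float(x) for x in np.quantile(null_curves, 0.025, axis=0)]
    report.null_hi = [float(x) for x in np.quantile(null_curves, 0.975, axis=0)]
    return report


def validate_functions(
    dataset: ComplexomeDataset,
    functions: FunctionTable,
    spec: SplitSpec,
    variant: str = "min_complexes",
) -> ValidationReport:
    """Mask test annotations, rerun the cover pipeline on training
    annotations, and score re-substituted predictions for test proteins.

    ``fraction_of_functions``: predicted (protein, function) pairs over
    test proteins that are in the held-out truth, over all such
    predicted pairs. ``fraction_of_proteins``: test proteins with ≥ 1
    correct predicted function, over test proteins with ≥ 1 predicted
    function. Both are reported for raw and HC outcomes.
    """
    in_complex = {m.protein_id for m in dataset.memberships}
    eligible = sorted(p for p in functions.entries if p in in_complex)
    train, test = split(eligible, spec)
    test_set = set(test)
    masked = FunctionTable.from_entries(
        {p: codes for p, codes in functions.entries.items() if p not in test_set}
    )
    problem = build_function_problem(dataset, masked)
    solution = hc_filter(problem, solve_function_assignment(problem, variant))
    report = ValidationReport(
        kind="functions",
        spec=spec,
        n_train=len(train),
        n_test=len(test),
        metadata={
            "variant": variant,
            "training_input_hash": _table_hash(
                {p: ";".join(sorted(c)) for p, c in masked.entries.items()}
            ),
        },
    )
    for label, hc_only in (("raw", False), ("HC", True)):
        preds = resubstitute_protein_functions(
            solution, dataset, masked, hc_only=hc_only
        )
        test_preds = {(p, k) for (p, k) in preds if p in test_set}
        correct = {
            (p, k) for (p, k) in test_preds if k in functions.functions_of(p)
        }
        proteins_with_pred = {p for (p, _) in test_preds}
        proteins_correct = {p for (p, _) in correct}
        report.function_metrics[label] = {
            "fraction_of_functions": Fraction(len(correct), len(test_preds)),
            "fraction_of_proteins": Fraction(
                len(proteins_correct), len(proteins_with_pred)
            ),
        }
        if not test_preds:
            report.warnings.append(f"{label}: no predictions for test proteins")
    return report
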