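import itertools

import numpy as np
import pytest

from complexome.datatypes import (
    ComplexomeDataset,
    FunctionTable,
    Membership,
    Role,
)
from complexome.functions import (
    build_function_problem,
    hc_filter,
    resubstitute_protein_functions,
    solve_function_assignment,
    trace_function_source,
)


def build(memberships, annotations):
    ds = ComplexomeDataset.from_memberships(memberships)
    table = FunctionTable.from_entries(annotations)
    return ds, table, build_function_problem(ds, table)


def core(c, p):
    return Membership(c, p, Role.CORE)


def attach(c, p):
    return Membership(c, p, Role.ATTACHMENT)


def enumerate_min_covers(membership, covered):
    """All minimum covers by subset enumeration (independent oracle)."""
    candidates = sorted(set().union(*(membership[p] for p in covered)))
    best, covers = len(candidates) + 1, []
    for r in range(1, len(candidates) + 1):
        if r > best:
            break
        for combo in itertools.combinations(candidates, r):
            chosen = set(combo)
            if all(membership[p] & chosen for p in covered):
                best = r
                covers.append(chosen)
        if covers:
            break
    return best, covers


class TestBuildProblem:
    def test_toy_counts(self, toy):
        table = FunctionTable.from_entries({"b": ["10.01"]})
        prob = build_function_problem(toy, table)
        assert sum(len(v) for v in prob.membership.values()) == 8
        assert prob.annotations == {"10.01": frozenset({"b"})}

    def test_annotated_protein_outside_complexes_reported(self, toy):
        table = FunctionTable.from_entries({"b": ["10.01"], "zz": ["10.01"]})
        prob = build_function_problem(toy, table)
        assert prob.excluded_proteins == ("zz",)
        assert prob.annotations["10.01"] == frozenset({"b"})

    def test_empty_function_table(self, toy):
        prob = build_function_problem(toy, FunctionTable.from_entries({}))
        assert prob.universe == ()
        sol = solve_function_assignment(prob)
        assert sol.assignments == frozenset()


class TestMinimumCovers:
    def test_unique_cover_single_complex(self):
        # i1 only in A, i2 in A and B: A alone covers both
        ds, table, prob = build(
            [core("A", "i1"), core("A", "i2"), core("B", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = solve_function_assignment(prob)
        assert sol.complexes_for("10.01") == {"A"}
        assert sol.m_star["10.01"] == 1

    def test_disjoint_forced_cover(self):
        ds, table, prob = build(
            [core("A", "i1"), core("C", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = solve_function_assignment(prob)
        assert sol.complexes_for("10.01") == {"A", "C"}
        assert sol.m_star["10.01"] == 2

    def test_tie_instance_optimum(self):
        ds, table, prob = build(
            [core("A", "i1"), core("B", "i1"), core("A", "i2"), core("B", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = solve_function_assignment(prob)
        assert sol.m_star["10.01"] == 1
        assert sol.complexes_for("10.01") in ({"A"}, {"B"})

    def test_covering_invariant_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n_c, n_p = int(rng.integers(2, 8)), int(rng.integers(2, 10))
            memberships = []
            for i in range(n_p):
                for j in rng.choice(
                    n_c, size=int(rng.integers(1, n_c + 1)), replace=False
                ):
                    memberships.append(core(f"C{j}", f"P{i}"))
            annotated = rng.choice(n_p, size=max(1, n_p // 2), replace=False)
            ds, table, prob = build(
                memberships, {f"P{i}": ["10.01"] for i in annotated}
            )
            sol = solve_function_assignment(prob)
            chosen = sol.complexes_for("10.01")
            for pid in prob.annotations["10.01"]:
                assert prob.membership[pid] & chosen


class TestHighConfidence:
    def test_forced_cover_is_hc(self):
        ds, table, prob = build(
            [core("A", "i1"), core("A", "i2"), core("B", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = hc_filter(prob, solve_function_assignment(prob))
        assert sol.confidence[("A", "10.01")] == "HC"

    def test_tie_instance_has_no_hc(self):
        ds, table, prob = build(
            [core("A", "i1"), core("B", "i1"), core("A", "i2"), core("B", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = hc_filter(prob, solve_function_assignment(prob))
        assert sol.hc_assignments() == frozenset()
        assert len(sol.assignments) == 1  # raw assignment still reported

    def test_disjoint_instance_both_hc(self):
        ds, table, prob = build(
            [core("A", "i1"), core("C", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = hc_filter(prob, solve_function_assignment(prob))
        assert sol.hc_assignments() == {("A", "10.01"), ("C", "10.01")}

    def test_hc_invariant_under_complex_relabelling(self):
        # HC membership is a property of the instance, not of solver
        # variable order; relabelling complexes permutes variables
        rng = np.random.default_rng(41)
        memberships, annotations = [], {}
        for i in range(10):
            for j in rng.choice(6, size=int(rng.integers(1, 4)), replace=False):
                memberships.append(core(f"C{j}", f"P{i}"))
            if rng.random() < 0.6:
                annotations[f"P{i}"] = ["10.01"]
        ds, table, prob = build(memberships, annotations)
        base_hc = hc_filter(prob, solve_function_assignment(prob)).hc_assignments()
        for trial in range(4):
            perm = rng.permutation(6)
            relabel = {f"C{j}": f"C{perm[j]}" for j in range(6)}
            ms2 = [
                Membership(relabel[m.complex_id], m.protein_id, m.role)
                for m in memberships
            ]
            ds2, t2, prob2 = build(ms2, annotations)
            hc2 = hc_filter(prob2, solve_function_assignment(prob2)).hc_assignments()
            assert {(relabel[c], k) for (c, k) in base_hc} == hc2


class TestOracleEquivalence:
    def test_m_star_and_hc_match_enumeration(self):
        rng = np.random.default_rng(53)
        for _ in range(25):
            n_c = int(rng.integers(2, 11))
            n_p = int(rng.integers(2, 9))
            memberships = []
            membership_map = {}
            for i in range(n_p):
                js = rng.choice(
                    n_c, size=min(n_c, int(rng.integers(1, 4))), replace=False
                )
                membership_map[f"P{i}"] = {f"C{j}" for j in js}
                memberships.extend(core(f"C{j}", f"P{i}") for j in js)
            annotated = [f"P{i}" for i in range(n_p) if rng.random() < 0.7]
            if not annotated:
                annotated = ["P0"]
            ds, table, prob = build(
                memberships, {p: ["10.01"] for p in annotated}
            )
            sol = hc_filter(prob, solve_function_assignment(prob))
            best, covers = enumerate_min_covers(membership_map, annotated)
            assert sol.m_star["10.01"] == best
            expected_hc = frozenset(
                (c, "10.01") for c in frozenset.intersection(
                    *map(frozenset, covers)
                )
            )
            assert sol.hc_assignments() == expected_hc

    def test_min_proteins_matches_lexicographic_enumeration(self):
        rng = np.random.default_rng(59)
        for _ in range(12):
            n_c, n_p = int(rng.integers(2, 7)), int(rng.integers(3, 8))
            membership_map = {}
            memberships = []
            for i in range(n_p):
                js = rng.choice(n_c, size=int(rng.integers(1, 3)), replace=False)
                membership_map[f"P{i}"] = {f"C{j}" for j in js}
                memberships.extend(core(f"C{j}", f"P{i}") for j in js)
            annotated = {f"P{i}" for i in range(n_p) if rng.random() < 0.5}
            if not annotated:
                annotated = {"P0"}
            ds, table, prob = build(
                memberships, {p: ["10.01"] for p in annotated}
            )
            sol = solve_function_assignment(prob, "min_proteins")
            candidates = sorted(
                set().union(*(membership_map[p] for p in annotated))
            )
            best = None
            for r in range(1, len(candidates) + 1):
                for combo in itertools.combinations(candidates, r):
                    chosen = set(combo)
                    if not all(membership_map[p] & chosen for p in annotated):
                        continue
                    new = {
                        p
                        for p, cs in membership_map.items()
                        if p not in annotated and cs & chosen
                    }
                    key = (len(new), len(chosen))
                    if best is None or key < best:
                        best = key
            got = sol.complexes_for("10.01")
            new_got = {
                p
                for p, cs in membership_map.items()
                if p not in annotated and cs & got
            }
            assert (len(new_got), len(got)) == best

    def test_monotonicity_under_deletion_and_annotation(self):
        ds, table, prob = build(
            [core("A", "i1"), core("A", "i2"), core("B", "i2"), core("B", "i3")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        base = solve_function_assignment(prob).m_star["10.01"]
        # deleting a complex can only shrink the candidate pool
        ds2, t2, prob2 = build(
            [core("A", "i1"), core("A", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        assert solve_function_assignment(prob2).m_star["10.01"] >= base
        # annotating one more protein adds a covering constraint
        ds3, t3, prob3 = build(
            [core("A", "i1"), core("A", "i2"), core("B", "i2"), core("B", "i3")],
            {"i1": ["10.01"], "i2": ["10.01"], "i3": ["10.01"]},
        )
        assert solve_function_assignment(prob3).m_star["10.01"] >= base


class TestResubstitution:
    def _world(self):
        return build(
            [
                core("A", "i1"),
                core("A", "i2"),
                core("A", "i3"),
                attach("A", "i4"),
                core("B", "i2"),
            ],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )

    def test_core_member_gains_function(self):
        ds, table, prob = self._world()
        sol = hc_filter(prob, solve_function_assignment(prob))
        preds = resubstitute_protein_functions(sol, ds, table, hc_only=True)
        assert preds[("i3", "10.01")] == {"A"}

    def test_attachment_member_excluded(self):
        ds, table, prob = self._world()
        sol = hc_filter(prob, solve_function_assignment(prob))
        preds = resubstitute_protein_functions(sol, ds, table, hc_only=True)
        assert ("i4", "10.01") not in preds

    def test_already_annotated_excluded(self):
        ds, table, prob = self._world()
        sol = hc_filter(prob, solve_function_assignment(prob))
        preds = resubstitute_protein_functions(sol, ds, table, hc_only=True)
        assert ("i1", "10.01") not in preds and ("i2", "10.01") not in preds

    def test_hc_predictions_subset_of_raw(self):
        rng = np.random.default_rng(61)
        memberships, annotations = [], {}
        for i in range(12):
            for j in rng.choice(5, size=int(rng.integers(1, 4)), replace=False):
                memberships.append(core(f"C{j}", f"P{i}"))
            if rng.random() < 0.5:
                annotations[f"P{i}"] = ["10.01", "02.01"][: int(rng.integers(1, 3))]
        ds, table, prob = build(memberships, annotations)
        sol = hc_filter(prob, solve_function_assignment(prob))
        raw = set(resubstitute_protein_functions(sol, ds, table, hc_only=False))
        hc = set(resubstitute_protein_functions(sol, ds, table, hc_only=True))
        assert hc <= raw


class TestProvenance:
    def test_trace_lists_all_donors(self):
        ds, table, prob = build(
            [core("A", "i1"), core("A", "i2"), core("B", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = solve_function_assignment(prob)
        donors = trace_function_source(sol, ds, table, "A", "10.01")
        assert set(donors) == {"i1", "i2"}

    def test_trace_reports_attachment_role(self):
        ds, table, prob = build(
            [core("A", "i1"), attach("A", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = solve_function_assignment(prob)
        donors = trace_function_source(sol, ds, table, "A", "10.01")
        assert donors == {"i1": "core", "i2": "attachment"}

    def test_trace_unassigned_errors(self):
        ds, table, prob = build([core("A", "i1")], {"i1": ["10.01"]})
        sol = solve_function_assignment(prob)
        with pytest.raises(KeyError):
            trace_function_source(sol, ds, table, "A", "99.99")

    def test_provenance_stored_on_solution(self):
        ds, table, prob = build(
            [core("A", "i1"), core("A", "i2")],
            {"i1": ["10.01"], "i2": ["10.01"]},
        )
        sol = solve_function_assignment(prob)
        assert sol.provenance[("A", "10.01")] == {"i1", "i2"}


class TestPlantedRecovery:
    def test_unique_structure_recovered_as_hc(self):
        # each function planted on one complex, expressed by >= 2 core
        # proteins that co-occur nowhere else
        memberships, annotations = [], {}
        for j in range(6):
            for t in range(3):
                pid = f"P{j}_{t}"
                memberships.append(core(f"C{j}", pid))
                annotations.setdefault(pid, []).append(f"{j + 1:02d}.01")
        ds, table, prob = build(memberships, annotations)
        sol = hc_filter(prob, solve_function_assignment(prob))
        for j in range(6):
            assert sol.confidence[(f"C{j}", f"{j + 1:02d}.01")] == "HC"
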