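"""Synthetic complexomes with known ground truth.

The generator emulates the structure of the yeast complexome data the
package is designed for: exponential-like (truncated geometric) complex
sizes and protein membership counts wired by a bipartite configuration
model, role labels with at least one core protein per complex,
log-normal planted complex copy numbers with nonnegative exponential
surplus on protein abundances (so the planted truth always satisfies
the LP availability constraint), and hierarchical dotted function codes
planted on complexes, copied to their core proteins, and thinned by a
dropout rate to create "unknown" annotations.

Defaults mirror the published yeast statistics: 491 complexes and 1,491
proteins with mean complex size 13.41 and mean protein membership 4.42,
and 325 distinct function codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    AbundanceTable,
    ComplexomeDataset,
    FunctionTable,
    Membership,
    Role,
)

_MAX_REWIRE_TRIES = 200


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic complexome."""

    n_complexes: int = 491
    n_proteins: int = 1491
    mean_complex_size: float = 13.41
    mean_membership: float = 4.42
    min_complex_size: int = 2
    core_fraction: float = 0.25
    abundance_mu: float = 7.0  # log of typical complex copy number
    abundance_sigma: float = 1.2
    surplus_noise: float = 0.1  # exponential surplus, as fraction of ideal abundance
    condition_effect_sigma: float = 0.3  # lognormal spread of SD/YEPD ratio
    conditions: tuple[str, str] = ("YEPD", "SD")
    n_functions: int = 325
    complexes_per_function: int = 2
    dropout: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_complexes, self.n_proteins, self.n_functions + 1) < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.core_fraction <= 1.0 and 0.0 <= self.dropout <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.mean_membership < 1 or self.mean_complex_size < self.min_complex_size:
            raise ValueError("degree means below their minimum support")
        if self.surplus_noise < 0:
            raise ValueError("surplus noise must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    c_star: dict[str, dict[str, float]]  # condition -> complex -> copy number
    ideal_abundance: dict[str, dict[str, float]]  # condition -> protein -> Σ S c*
    full_annotations: dict[str, frozenset[str]]  # pre-dropout protein functions
    planted_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)


def _truncated_geometric(rng, mean: float, minimum: int, maximum: int, size: int):
    """Geometric draws shifted to start at ``minimum``, clipped at ``maximum``."""
    if mean <= minimum:
        return np.full(size, minimum, dtype=int)
    p = 1.0 / (mean - minimum + 1.0)
    draws = minimum - 1 + rng.geometric(p, size=size)
    return np.clip(draws, minimum, maximum)


def _balance(stubs: np.ndarray, target: int, minimum: int, rng) -> np.ndarray:
    """Adjust a degree sequence so it sums to ``target`` (units of 1)."""
    stubs = stubs.copy()
    diff = int(target - stubs.sum())
    guard = 0
    while diff != 0:
        i = int(rng.integers(len(stubs)))
        if diff > 0:
            stubs[i] += 1
            diff -= 1
        elif stubs[i] > minimum:
            stubs[i] -= 1
            diff += 1
        guard += 1
        if guard > 100 * len(stubs) + abs(diff) * 10 + 1000:
            raise RuntimeError(
                "cannot balance stub sequence; adjust size/membership means"
            )
    return stubs


def wire_configuration_model(
    complex_sizes: np.ndarray, protein_degrees: np.ndarray, rng
) -> list[set[int]]:
    """Bipartite configuration-model wiring without parallel edges.

    Protein stubs are shuffled and dealt to complex slots; duplicates
    inside a complex are repaired by random swaps with slots of other
    complexes. Raises after bounded retries (advising a parameter
    change) if a simple graph cannot be reached.
    """
    sizes = np.asarray(complex_sizes, dtype=int)
    degrees = np.asarray(protein_degrees, dtype=int)
    assert sizes.sum() == degrees.sum(), "stub totals must match"
    if np.any(sizes > len(degrees)):
        raise ValueError("a complex larger than the protein set cannot be simple")
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    rng.shuffle(stubs)
    slot_complex = np.repeat(np.arange(len(sizes)), sizes)
    total = len(stubs)
    # multiset of proteins per complex; counts > 1 are parallel edges
    counts: list[dict[int, int]] = [dict() for _ in sizes]
    for slot in range(total):
        j = int(slot_complex[slot])
        p = int(stubs[slot])
        counts[j][p] = counts[j].get(p, 0) + 1
    dup_slots = [
        slot
        for slot in range(total)
        if counts[int(slot_complex[slot])][int(stubs[slot])] > 1
    ]
    tries = 0
    while dup_slots:
        slot = dup_slots[-1]
        j = int(slot_complex[slot])
        p = int(stubs[slot])
        if counts[j].get(p, 0) <= 1:  # resolved by an earlier swap
            dup_slots.pop()
            continue
        tries += 1
        if tries > _MAX_REWIRE_TRIES * total:
            raise RuntimeError(
                "configuration-model rewiring failed; lower the mean complex "
                "size or raise the number of proteins"
            )
        other = int(rng.integers(total))
        oj = int(slot_complex[other])
        q = int(stubs[other])
        # swap p<->q iff it creates no new parallel edge on either side
        if oj == j or q == p or counts[j].get(q, 0) > 0 or counts[oj].get(p, 0) > 0:
            continue
        stubs[slot], stubs[other] = q, p
        counts[j][p] -= 1
        counts[j][q] = 1
        counts[oj][q] -= 1
        if counts[oj][q] == 0:
            del counts[oj][q]
        counts[oj][p] = 1
    return [set(c) for c in counts]


def generate(
    spec: SyntheticSpec,
) -> tuple[ComplexomeDataset, AbundanceTable, FunctionTable, GroundTruth]:
    """Generate one synthetic complexome; deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    M, N = spec.n_complexes, spec.n_proteins
    sizes = _truncated_geometric(
        rng, spec.mean_complex_size, spec.min_complex_size, N, M
    )
    degrees = _truncated_geometric(rng, spec.mean_membership, 1, M, N)
    degrees = _balance(degrees, int(sizes.sum()), 1, rng)
    members = wire_configuration_model(sizes, degrees, rng)

    cw = max(len(str(M)), 3)
    pw = max(len(str(N)), 3)
    cids = [f"C{j:0{cw}d}" for j in range(M)]
    pids = [f"P{i:0{pw}d}" for i in range(N)]

    memberships: list[Membership] = []
    complex_cores: list[list[int]] = []
    for j, mem in enumerate(members):
        mem_list = sorted(mem)
        order = rng.permutation(len(mem_list))
        n_core = max(1, int(round(spec.core_fraction * len(mem_list))))
        cores = sorted(mem_list[k] for k in order[:n_core])
        complex_cores.append(cores)
        core_set = set(cores)
        for i in mem_list:
            role = Role.CORE if i in core_set else Role.ATTACHMENT
            memberships.append(Membership(cids[j], pids[i], role))
    dataset = ComplexomeDataset.from_memberships(memberships)

    # planted copy numbers: log-normal baseline, per-complex condition ratio
    base = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, size=M)
    ratio = rng.lognormal(0.0, spec.condition_effect_sigma, size=M)
    c_star = {
        spec.conditions[0]: {cids[j]: float(base[j]) for j in range(M)},
        spec.conditions[1]: {cids[j]: float(base[j] * ratio[j]) for j in range(M)},
    }
    ideal: dict[str, dict[str, float]] = {cond: {} for cond in spec.conditions}
    entries: dict[tuple[str, str], float] = {}
    core_of_protein: dict[int, list[int]] = {}
    for j, cores in enumerate(complex_cores):
        for i in cores:
            core_of_protein.setdefault(i, []).append(j)
    for cond in spec.conditions:
        for i in range(N):
            value = sum(c_star[cond][cids[j]] for j in core_of_protein.get(i, []))
            ideal[cond][pids[i]] = float(value)
            if value > 0:
                eps = (
                    rng.exponential(spec.surplus_noise * value)
                    if spec.surplus_noise > 0
                    else 0.0
                )
            else:
                # attachment-only protein: free abundance, unconstrained
                eps = float(rng.lognormal(spec.abundance_mu, spec.abundance_sigma))
            entries[(pids[i], cond)] = float(value + eps)
    abundance = AbundanceTable.from_entries(entries)

    # planted functions: hierarchical dotted codes on complexes -> core proteins
    codes = _function_codes(spec.n_functions)
    planted: set[tuple[str, str]] = set()
    full: dict[str, set[str]] = {}
    for code in codes:
        chosen = rng.choice(M, size=min(spec.complexes_per_function, M), replace=False)
        for j in chosen:
            planted.add((cids[int(j)], code))
            for i in complex_cores[int(j)]:
                full.setdefault(pids[i], set()).add(code)
    kept: dict[str, set[str]] = {}
    for pid in sorted(full):
        for code in sorted(full[pid]):
            if rng.random() >= spec.dropout:
                kept.setdefault(pid, set()).add(code)
    functions = FunctionTable.from_entries(kept)
    truth = GroundTruth(
        c_star=c_star,
        ideal_abundance=ideal,
        full_annotations={p: frozenset(s) for p, s in full.items()},
        planted_pairs=frozenset(planted),
    )
    return dataset, abundance, functions, truth


def _function_codes(n: int) -> list[str]:
    """First ``n`` codes of a synthetic three-level dotted hierarchy."""
    codes: list[str] = []
    top = 1
    while len(codes) < n:
        for mid in range(1, 6):
            for leaf in range(1, 6):
                codes.append(f"{top:02d}.{mid:02d}.{leaf:02d}")
                if len(codes) == n:
                    return codes
        top += 1
    return codes


def sample_degrees(pmf, size: int, rng) -> np.ndarray:
    """Draw ``size`` degrees from a pmf indexed by 0..k_max."""
    p = np.asarray(pmf, dtype=float)
    p = p / p.sum()
    return rng.choice(len(p), size=size, p=p)


def expected_counts(pmf, n: int) -> np.ndarray:
    """Largest-remainder rounding of ``n * pmf`` to integer counts."""
    raw = np.asarray(pmf, dtype=float)
    raw = raw / raw.sum() * n
    base = np.floor(raw).astype(int)
    rem = n - int(base.sum())
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def configuration_model_from_pmfs(
    p_protein,
    p_complex,
    n_proteins: int,
    seed: int,
    degree_sequence: str = "expected",
) -> ComplexomeDataset:
    """Configuration-model complexome with degree sequences from given pmfs.

    A configuration model prescribes a degree sequence; by default the
    sequence realizes the expected counts of each degree (largest-
    remainder rounding of N·p(k)), so the only randomness is the wiring
    — the sharpest single-graph check of the generating-function
    prediction. With ``degree_sequence="sampled"`` the sequences are
    instead drawn i.i.d. from the pmfs. Protein memberships have min 1;
    complex sizes min 2; the complex count is set so slots match stubs,
    with the size sequence balanced to close the rounding remainder.
    """
    if degree_sequence not in ("expected", "sampled"):
        raise ValueError(f"unknown degree_sequence {degree_sequence!r}")
    rng = np.random.default_rng(seed)
    pp = np.asarray(p_protein, dtype=float).copy()
    pp[0] = 0.0  # a protein in no complex never appears in the projection
    pp /= pp.sum()
    pc = np.asarray(p_complex, dtype=float).copy()
    pc[: min(2, len(pc))] = 0.0  # size-0/1 complexes project nothing
    pc /= pc.sum()
    mean_size = float(np.arange(len(pc)) @ pc)
    if degree_sequence == "expected":
        degrees = np.repeat(np.arange(len(pp)), expected_counts(pp, n_proteins))
        target = int(degrees.sum())
        n_complexes = int(round(target / mean_size))
        sizes = np.repeat(np.arange(len(pc)), expected_counts(pc, n_complexes))
        sizes = _balance(sizes, target, 2, rng)
    else:
        degrees = sample_degrees(pp, n_proteins, rng)
        target = int(degrees.sum())
        size_list: list[int] = []
        total = 0
        while total < target - mean_size:
            s = int(sample_degrees(pc, 1, rng)[0])
            size_list.append(s)
            total += s
        sizes = np.array(size_list, dtype=int)
        degrees = _balance(degrees, total, 1, rng)
    members = wire_configuration_model(np.asarray(sizes), degrees, rng)
    cw = max(len(str(len(sizes))), 3)
    pw = max(len(str(n_proteins)), 3)
    memberships = [
        Membership(f"C{j:0{cw}d}", f"P{i:0{pw}d}", Role.CORE)
        for j, mem in enumerate(members)
        for i in mem
    ]
    return ComplexomeDataset.from_memberships(memberships)


def figure1_toy() -> ComplexomeDataset:
    """The canonical three-complex worked example.

    Complex A = {a, b, c}, B = {b, d, e}, C = {b, e}; all roles core.
    In the protein projection, the pair (b, e) has weight 2 (shared
    complexes B and C); in the complex projection every pair is linked
    through b, and (B, C) has weight 2 (shared proteins b and e).
    """
    rows = [("A", "a"), ("A", "b"), ("A", "c"),
            ("B", "b"), ("B", "d"), ("B", "e"),
            ("C", "b"), ("C", "e")]
    return ComplexomeDataset.from_memberships(
        Membership(c, p, Role.CORE) for c, p in rows
    )
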