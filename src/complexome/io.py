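"""Readers and writers for the tabular complexome formats.

All inputs are headered TSV with configurable column names (the source
supplements are spreadsheet exports with inconsistent headers). Ids are
whitespace-stripped but case-sensitive. Multi-code function cells split
on ``;`` or ``|``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .datatypes import (
    AbundanceTable,
    ComplexomeDataset,
    FunctionTable,
    FUNCTION_CODE_RE,
    Membership,
    Role,
)

if TYPE_CHECKING:  # pragma: no cover
    from .abundance import AbundanceSolution
    from .functions import FunctionSolution

logger = logging.getLogger(__name__)

MULTI_CODE_SPLIT = re.compile(r"[;|]")


class ConfigurationError(Exception):
    """A required column cannot be resolved from the dialect."""


class ParseError(Exception):
    """A cell value violates the format contract; names the line number."""


@dataclass
class Dialect:
    """Column-name mapping for the TSV inputs."""

    complex_col: str = "complex"
    protein_col: str = "protein"
    role_col: str = "role"
    copies_col: str = "copies"  # optional; absent means copies = 1
    condition_col: str = "condition"
    abundance_col: str = "abundance"
    functions_col: str = "functions"
    strict_codes: bool = True
    extra: dict = field(default_factory=dict)


DEFAULT_DIALECT = Dialect()


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_complexes(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> ComplexomeDataset:
    """Read a membership table into a validated :class:`ComplexomeDataset`.

    Duplicate (complex, protein, role) rows are collapsed with a logged
    warning. A malformed role raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require(df, [dialect.complex_col, dialect.protein_col, dialect.role_col], path)
    has_copies = dialect.copies_col in df.columns
    memberships: list[Membership] = []
    seen: set[tuple[str, str, str]] = set()
    n_dup = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        cid = str(r[dialect.complex_col]).strip()
        pid = str(r[dialect.protein_col]).strip()
        role_raw = str(r[dialect.role_col]).strip().lower()
        try:
            role = Role(role_raw)
        except ValueError:
            raise ParseError(
                f"{path}:{idx}: invalid role {role_raw!r} (expected 'core' or 'attachment')"
            ) from None
        copies = 1
        if has_copies:
            raw = str(r[dialect.copies_col]).strip()
            if raw:
                try:
                    copies = int(raw)
                except ValueError:
                    raise ParseError(f"{path}:{idx}: non-integer copies {raw!r}") from None
        key = (cid, pid, role.value)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        memberships.append(Membership(cid, pid, role, copies))
    if n_dup:
        logger.warning("%s: collapsed %d duplicate membership row(s)", path, n_dup)
    ds = ComplexomeDataset.from_memberships(memberships)
    logger.info(
        "%s: %d complexes, %d proteins, %d memberships (%d core, %d attachment)",
        path,
        ds.n_complexes,
        ds.n_proteins,
        len(ds.memberships),
        sum(m.role is Role.CORE for m in ds.memberships),
        sum(m.role is Role.ATTACHMENT for m in ds.memberships),
    )
    return ds


def read_abundance(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> AbundanceTable:
    """Read a (protein, condition, abundance) table.

    Blank abundance cells mean "unknown" (the protein is retained);
    negative or non-numeric values raise :class:`ParseError`.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require(df, [dialect.protein_col, dialect.condition_col, dialect.abundance_col], path)
    entries: dict[tuple[str, str], float] = {}
    proteins: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pid = str(r[dialect.protein_col]).strip()
        cond = str(r[dialect.condition_col]).strip()
        raw = str(r[dialect.abundance_col]).strip()
        proteins.add(pid)
        if raw == "":
            continue  # unknown
        try:
            value = float(raw)
        except ValueError:
            raise ParseError(f"{path}:{idx}: non-numeric abundance {raw!r}") from None
        if value < 0:
            raise ParseError(f"{path}:{idx}: negative abundance {value}")
        entries[(pid, cond)] = value
    return AbundanceTable.from_entries(entries, proteins=proteins)


def read_functions(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> FunctionTable:
    """Read per-protein function codes; cells split on ``;`` or ``|``.

    In strict mode a code failing the dotted-numeric pattern raises
    :class:`ParseError`; in lenient mode it is skipped with a warning.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require(df, [dialect.protein_col, dialect.functions_col], path)
    entries: dict[str, set[str]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pid = str(r[dialect.protein_col]).strip()
        cell = str(r[dialect.functions_col]).strip()
        for code in MULTI_CODE_SPLIT.split(cell):
            code = code.strip()
            if not code:
                continue
            if not FUNCTION_CODE_RE.match(code):
                if dialect.strict_codes:
                    raise ParseError(f"{path}:{idx}: malformed function code {code!r}")
                logger.warning("%s:%d: skipping malformed code %r", path, idx, code)
                continue
            entries.setdefault(pid, set()).add(code)
    return FunctionTable.from_entries(entries)


# ---------------------------------------------------------------------------
# Solution writers / readers


def write_solution(
    solution: "AbundanceSolution | FunctionSolution",
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write a solved abundance or function solution to TSV or JSON.

    Round-trip safe: :func:`read_solution` on the written JSON, or the
    TSV re-read, reproduces the assignment content exactly.
    """
    from .abundance import AbundanceSolution
    from .functions import FunctionSolution

    path = Path(path)
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown format {format!r}")
    if isinstance(solution, AbundanceSolution):
        payload = solution.to_dict()
        if format == "json":
            path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        else:
            rows = [
                "\t".join(["complex", "copy_number", "flag"]),
                *(
                    f"{cid}\t{solution.c[cid]:.10g}\t"
                    + ("undetermined" if cid in solution.undetermined else "ok")
                    for cid in sorted(solution.c)
                ),
            ]
            path.write_text("\n".join(rows) + "\n")
    elif isinstance(solution, FunctionSolution):
        payload = solution.to_dict()
        if format == "json":
            path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        else:
            rows = ["\t".join(["complex", "function", "confidence", "source_proteins"])]
            for (cid, code) in sorted(solution.assignments):
                conf = solution.confidence[(cid, code)]
                src = ";".join(sorted(solution.provenance.get((cid, code), frozenset())))
                rows.append(f"{cid}\t{code}\t{conf}\t{src}")
            path.write_text("\n".join(rows) + "\n")
    else:  # pragma: no cover
        raise TypeError(f"unsupported solution type {type(solution)!r}")


def read_solution(path: str | Path) -> "AbundanceSolution | FunctionSolution":
    """Read back a JSON solution written by :func:`write_solution`."""
    from .abundance import AbundanceSolution
    from .functions import FunctionSolution

    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind == "abundance":
        return AbundanceSolution.from_dict(payload)
    if kind == "functions":
        return FunctionSolution.from_dict(payload)
    raise ParseError(f"{path}: unknown solution kind {kind!r}")


def write_dataset(dataset: ComplexomeDataset, path: str | Path) -> None:
    """Write a membership TSV (inverse of :func:`read_complexes`)."""
    rows = ["complex\tprotein\trole\tcopies"]
    for m in dataset.memberships:
        rows.append(f"{m.complex_id}\t{m.protein_id}\t{m.role.value}\t{m.copies}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    """Write an abundance TSV (inverse of :func:`read_abundance`)."""
    rows = ["protein\tcondition\tabundance"]
    for (pid, cond) in sorted(table.entries):
        rows.append(f"{pid}\t{cond}\t{table.entries[(pid, cond)]:.10g}")
    known = {p for (p, _) in table.entries}
    for pid in table.proteins:
        if pid not in known:
            cond = table.conditions[0] if table.conditions else "NA"
            rows.append(f"{pid}\t{cond}\t")
    Path(path).write_text("\n".join(rows) + "\n")


def write_function_table(table: FunctionTable, path: str | Path) -> None:
    """Write a function TSV (inverse of :func:`read_functions`)."""
    rows = ["protein\tfunctions"]
    for pid in sorted(table.entries):
        rows.append(f"{pid}\t{';'.join(sorted(table.entries[pid]))}")
    Path(path).write_text("\n".join(rows) + "\n")
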