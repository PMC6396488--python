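"""Reading the class-annotated genotype table and writing result tables.

The input format is a headerless, tab-delimited text file: column 1 is the
individual ID, column 2 a class key assigning the individual's role(s) in the
analysis, and columns 3+ hold one bi-allelic SNP genotype per column written
as ``X/Y`` with missing calls coded ``-/-``.  The five class keys are:

====  ==========================================================
Mo    considered only as a potential mother
Fa    considered only as a potential father
Off   considered only as a potential offspring
Pa    considered as a potential parent of either sex
All   considered as potential mother, father, and offspring
====  ==========================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import GenotypeFormatError

VALID_CLASS_KEYS = frozenset({"Mo", "Fa", "Off", "Pa", "All"})
MISSING_TOKEN = "-/-"


@dataclass
class RawGenotypeTable:
    """Parsed but not-yet-encoded genotype table.

    ``rows`` is a list of ``(id, class_key, genotype_tokens)`` triples, one
    per individual, all with the same number of genotype tokens.
    """

    rows: list[tuple[str, str, list[str]]]

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    @property
    def class_keys(self) -> list[str]:
        return [r[1] for r in self.rows]

    @property
    def n_individuals(self) -> int:
        return len(self.rows)

    @property
    def n_loci(self) -> int:
        return len(self.rows[0][2]) if self.rows else 0


def _check_token(token: str, line_no: int) -> None:
    parts = token.split("/")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise GenotypeFormatError(
            f"line {line_no}: malformed genotype token {token!r} "
            "(expected 'X/Y' or '-/-')"
        )


def read_genotype_table(path: str | Path) -> RawGenotypeTable:
    """Read a headerless, tab-delimited genotype table.

    Raises :class:`GenotypeFormatError` on ragged rows (unequal locus
    counts), unknown class keys, duplicate IDs, or malformed tokens; the
    message names the offending line.
    """
    path = Path(path)
    rows: list[tuple[str, str, list[str]]] = []
    seen: set[str] = set()
    n_loci: int | None = None
    with path.open() as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenotypeFormatError(
                    f"line {line_no}: expected at least 3 tab-delimited "
                    f"columns, got {len(fields)}"
                )
            ind_id, class_key, tokens = fields[0], fields[1], fields[2:]
            if class_key not in VALID_CLASS_KEYS:
                raise GenotypeFormatError(
                    f"line {line_no}: unknown class key {class_key!r} for "
                    f"individual {ind_id!r} (expected one of "
                    f"{sorted(VALID_CLASS_KEYS)})"
                )
            if ind_id in seen:
                raise GenotypeFormatError(
                    f"line {line_no}: duplicate individual ID {ind_id!r}"
                )
            if n_loci is None:
                n_loci = len(tokens)
            elif len(tokens) != n_loci:
                raise GenotypeFormatError(
                    f"line {line_no}: ragged row — {len(tokens)} genotype "
                    f"columns, expected {n_loci}"
                )
            for tok in tokens:
                if tok != MISSING_TOKEN:
                    _check_token(tok, line_no)
            seen.add(ind_id)
            rows.append((ind_id, class_key, tokens))
    return RawGenotypeTable(rows=rows)


def write_genotype_table(table: RawGenotypeTable, path: str | Path) -> None:
    """Write a table in the same headerless tab-delimited format."""
    with Path(path).open("w") as handle:
        for ind_id, class_key, tokens in table.rows:
            handle.write("\t".join([ind_id, class_key, *tokens]) + "\n")


def _fmt(value: float | None) -> str:
    """Six significant digits; empty string for missing values."""
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    return f"{value:.6g}"


TRIAD_COLUMNS = ["Mother", "Father", "Offspring", "GD", "UsableLoci", "p"]


def write_triad_table(records: Iterable, which: str, path: str | Path) -> None:
    """Write a tab-delimited triad table sorted ascending by GD.

    ``which`` is ``"all"`` (every enumerated triad; p left empty for
    undeclared triads) or ``"significant"`` (declared triads only).
    Triads with undefined GD (no comparable loci) sort last with GD empty.
    """
    if which not in ("all", "significant"):
        raise ValueError(f"which must be 'all' or 'significant', got {which!r}")
    recs = list(records)
    if which == "significant":
        recs = [r for r in recs if r.declared]
    recs.sort(key=lambda r: (math.isnan(r.gd), r.gd if not math.isnan(r.gd) else 0.0))
    frame = pd.DataFrame(
        {
            "Mother": [r.mother_id for r in recs],
            "Father": [r.father_id for r in recs],
            "Offspring": [r.offspring_id for r in recs],
            "GD": [_fmt(r.gd) for r in recs],
            "UsableLoci": [r.usable_loci for r in recs],
            "p": [_fmt(r.p_value) if r.declared else "" for r in recs],
        },
        columns=TRIAD_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


DYAD_COLUMNS = [
    "Parent", "Offspring", "GDM", "GDM.zscore", "GDCV", "GDCV.zscore", "p",
]


def write_dyad_table(records: Iterable, path: str | Path) -> None:
    """Write the significant dyad pairs (both test stages passed)."""
    recs = [r for r in records if r.stage1_flag and r.stage2_flag]
    recs.sort(key=lambda r: (r.cumulative_p, r.offspring_id, r.parent_id))
    frame = pd.DataFrame(
        {
            "Parent": [r.parent_id for r in recs],
            "Offspring": [r.offspring_id for r in recs],
            "GDM": [_fmt(r.gdm) for r in recs],
            "GDM.zscore": [_fmt(r.gdm_z) for r in recs],
            "GDCV": [_fmt(r.gdcv) for r in recs],
            "GDCV.zscore": [_fmt(r.gdcv_z) for r in recs],
            "p": [_fmt(r.cumulative_p) for r in recs],
        },
        columns=DYAD_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
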