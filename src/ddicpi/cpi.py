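"""Chemical-protein interactome (CPI) matrices.

The central object of the package is the CPI matrix: a dense table of docking
scores (kcal/mol, predominantly negative, more negative = stronger predicted
binding) for a library of drugs against a panel of protein structures.  This
module provides the data model, delimited-text I/O, assembly of a matrix from
AutoDock-Vina-style docking result files, and per-target rank percentiles used
to explain predictions ("this drug ranks target X in the top 20% of its score
vector").
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    DuplicateIdentifierError,
    MissingDataError,
    ParseError,
    UnknownIdentifierError,
    UnparseableResultError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: accepted spellings of a missing cell in CPI files
NA_TOKENS = frozenset({"", "NA", "na", "NaN", "nan"})

TARGET_CLASSES = ("PK", "PD", "unknown")


@dataclass(frozen=True)
class TargetRecord:
    """One protein structure in the docking panel (e.g. a PDB entry)."""

    target_id: str
    target_class: str = "unknown"
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValidationError("target_id must be non-empty")
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(
                f"target_class must be one of {TARGET_CLASSES}, "
                f"got {self.target_class!r}"
            )


@dataclass(frozen=True)
class DrugRecord:
    """One small molecule in the drug library."""

    drug_id: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")


@dataclass(frozen=True)
class DockingResult:
    """Best (lowest-energy) docking outcome of one ligand against one target."""

    ligand_id: str
    target_id: str
    best_score: float
    n_poses: int

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValidationError("n_poses must be >= 1")
        if not math.isfinite(self.best_score):
            raise ValidationError("best_score must be finite")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdentifierError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


class CPIMatrix:
    """Dense drugs x targets table of docking scores with explicit missingness.

    Scores are stored as a float array with NaN marking missing cells; the
    drug/target order given at construction is preserved and defines the
    feature order used downstream, so it must be reproducible across runs.
    """

    def __init__(
        self,
        drugs: Sequence[DrugRecord],
        targets: Sequence[TargetRecord],
        scores: np.ndarray,
    ) -> None:
        drugs = list(drugs)
        targets = list(targets)
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(drugs), len(targets)):
            raise ValidationError(
                f"scores shape {scores.shape} does not match "
                f"{len(drugs)} drugs x {len(targets)} targets"
            )
        _check_unique([d.drug_id for d in drugs], "drug")
        _check_unique([t.target_id for t in targets], "target")
        present = scores[~np.isnan(scores)]
        if present.size and not np.all(np.isfinite(present)):
            raise ValidationError("non-missing scores must be finite")
        self.drugs = drugs
        self.targets = targets
        self.scores = scores
        self._drug_index = {d.drug_id: i for i, d in enumerate(drugs)}
        self._target_index = {t.target_id: j for j, t in enumerate(targets)}

    # -- basic introspection -------------------------------------------------

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    @property
    def target_ids(self) -> list[str]:
        return [t.target_id for t in self.targets]

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape  # type: ignore[return-value]

    def n_missing(self) -> int:
        return int(np.isnan(self.scores).sum())

    def drug_row(self, drug_id: str) -> np.ndarray:
        """Score vector of one drug across the whole panel (NaN = missing)."""
        try:
            return self.scores[self._drug_index[drug_id]]
        except KeyError:
            raise UnknownIdentifierError(f"unknown drug id: {drug_id!r}") from None

    def has_drug(self, drug_id: str) -> bool:
        return drug_id in self._drug_index

    def target_position(self, target_id: str) -> int:
        try:
            return self._target_index[target_id]
        except KeyError:
            raise UnknownIdentifierError(f"unknown target id: {target_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.drug_ids, columns=self.target_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CPIMatrix):
            return NotImplemented
        return (
            self.drug_ids == other.drug_ids
            and self.target_ids == other.target_ids
            and np.array_equal(self.scores, other.scores, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"CPIMatrix({len(self.drugs)} drugs x {len(self.targets)} targets)"


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cpi(path: str | Path, dialect: str | None = None) -> CPIMatrix:
    """Read a CPI matrix from a delimited text file.

    Layout: header row of target ids (first header cell ignored/blank), one
    row per drug with the drug id in the first column.  Missing scores are
    empty cells or "NA".  ``dialect`` may be ``"tsv"``, ``"csv"`` or a literal
    delimiter; by default it is inferred from the file suffix.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file, expected a header row")
    header = lines[0].split(sep)
    target_ids = [c.strip() for c in header[1:]]
    if any(not t for t in target_ids):
        raise ParseError(f"{path}: malformed header (empty target id)")
    try:
        _check_unique(target_ids, "target")
    except DuplicateIdentifierError as e:
        raise DuplicateIdentifierError(f"{path}: {e}") from None

    drug_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        if len(cells) != len(target_ids) + 1:
            raise ParseError(
                f"{path}, line {lineno}: expected {len(target_ids) + 1} "
                f"columns, found {len(cells)}"
            )
        drug_ids.append(cells[0].strip())
        row: list[float] = []
        for col, cell in zip(target_ids, cells[1:]):
            cell = cell.strip()
            if cell in NA_TOKENS:
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}, target {col!r}: "
                        f"non-numeric cell {cell!r}"
                    ) from None
        rows.append(row)
    try:
        _check_unique(drug_ids, "drug")
    except DuplicateIdentifierError as e:
        raise DuplicateIdentifierError(f"{path}: {e}") from None
    scores = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(target_ids)), dtype=float)
    )
    return CPIMatrix(
        [DrugRecord(d) for d in drug_ids],
        [TargetRecord(t) for t in target_ids],
        scores,
    )


def write_cpi(matrix: CPIMatrix, path: str | Path, dialect: str | None = None) -> None:
    """Write a CPI matrix in the layout :func:`read_cpi` accepts.

    Scores are written with ``repr`` so a read/write round trip preserves them
    to full float64 precision; missing cells are written as ``NA``.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["drug_id", *matrix.target_ids]) + "\n")
        for drug_id, row in zip(matrix.drug_ids, matrix.scores):
            cells = [drug_id] + [
                "NA" if np.isnan(v) else repr(float(v)) for v in row
            ]
            fh.write(sep.join(cells) + "\n")


def read_target_panel(path: str | Path) -> list[TargetRecord]:
    """Read a two-column TSV panel file (target_id, class in {PK, PD})."""
    records: list[TargetRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}, line {lineno}: expected 2 columns")
            tid, cls = parts[0].strip(), parts[1].strip()
            if cls not in ("PK", "PD"):
                raise ParseError(
                    f"{path}, line {lineno}: class must be PK or PD, got {cls!r}"
                )
            records.append(TargetRecord(tid, cls))
    _check_unique([r.target_id for r in records], "target")
    return records


# ---------------------------------------------------------------------------
# Vina result parsing
# ---------------------------------------------------------------------------

# stdout table rows look like "   1        -7.5      0.000      0.000"
_TABLE_ROW = re.compile(r"^\s*\d+\s+(-?\d+(?:\.\d+)?)\s+\S+\s+\S+\s*$")
# per-model remark lines in output structure files
_REMARK_ROW = re.compile(
    r"^REMARK VINA RESULT:\s+(-?\d+(?:\.\d+)?)\s+\S+\s+\S+\s*$"
)


def parse_vina_result(
    path: str | Path, ligand_id: str, target_id: str
) -> DockingResult:
    """Extract the best docking score from an AutoDock-Vina result file.

    Accepts either a stdout log containing the mode/affinity table or an
    output structure file with per-model ``REMARK VINA RESULT`` lines; in both
    dialects the representative score is the minimum (lowest-energy) affinity
    over all reported binding modes.
    """
    path = Path(path)
    with open(path, encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()

    affinities = [float(m.group(1)) for line in lines if (m := _REMARK_ROW.match(line))]
    if not affinities:
        # stdout dialect: only trust table rows after the affinity header
        in_table = False
        for line in lines:
            if "affinity" in line.lower() and "mode" in line.lower():
                in_table = True
                continue
            if in_table and (m := _TABLE_ROW.match(line)):
                affinities.append(float(m.group(1)))
    if not affinities:
        raise UnparseableResultError(
            f"{path}: no affinity line found; the docking run failed or a "
            "wrong file was supplied"
        )
    return DockingResult(
        ligand_id=ligand_id,
        target_id=target_id,
        best_score=min(affinities),
        n_poses=len(affinities),
    )


def assemble_cpi(
    results: Iterable[DockingResult],
    drugs: Sequence[DrugRecord],
    targets: Sequence[TargetRecord],
) -> CPIMatrix:
    """Fill a CPI matrix from docking results.

    Cells with no result stay missing; duplicate results for the same
    (ligand, target) cell keep the minimum score and log a warning.
    """
    drugs = list(drugs)
    targets = list(targets)
    drug_index = {d.drug_id: i for i, d in enumerate(drugs)}
    target_index = {t.target_id: j for j, t in enumerate(targets)}
    scores = np.full((len(drugs), len(targets)), np.nan)
    for res in results:
        if res.ligand_id not in drug_index:
            raise UnknownIdentifierError(
                f"result references undeclared drug {res.ligand_id!r}"
            )
        if res.target_id not in target_index:
            raise UnknownIdentifierError(
                f"result references undeclared target {res.target_id!r}"
            )
        i, j = drug_index[res.ligand_id], target_index[res.target_id]
        if not np.isnan(scores[i, j]):
            logger.warning(
                "duplicate result for (%s, %s): keeping minimum of %s and %s",
                res.ligand_id, res.target_id, scores[i, j], res.best_score,
            )
            scores[i, j] = min(scores[i, j], res.best_score)
        else:
            scores[i, j] = res.best_score
    return CPIMatrix(drugs, targets, scores)


def rank_percentile(matrix: CPIMatrix, drug_id: str, target_id: str) -> float:
    """Rank of a target within one drug's score vector, as a fraction.

    Rank 1 is the most negative (strongest) score among the drug's non-missing
    targets; ties share the mean rank.  The returned value is rank/N in
    (0, 1]; values <= 0.20 correspond to the "top 20%" readout used to flag
    targets plausibly mediating a predicted interaction.
    """
    row = matrix.drug_row(drug_id)
    j = matrix.target_position(target_id)
    if np.isnan(row[j]):
        raise MissingDataError(
            f"drug {drug_id!r} has no score for target {target_id!r}"
        )
    present = ~np.isnan(row)
    ranks = rankdata(row[present], method="average")
    # position of target j among the non-missing entries
    pos = int(present[:j].sum())
    return float(ranks[pos] / present.sum())
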