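"""Symmetric pair featurization and labeled pair sets.

An unordered drug pair is represented, per target j, by the sum S_j and the
absolute difference AD_j of the two drugs' docking scores against j; with T
targets this yields a 2T-dimensional feature vector that is invariant to the
order of the two drugs.  This module also builds labeled training sets:
a positive list of known interacting pairs plus uniformly sampled negatives,
and the design matrix over a CPI panel (pairs touching any missing docking
score are dropped -- only pairs with complete CPI annotations are trainable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .cpi import CPIMatrix
from .errors import (
    CapacityError,
    MissingDataError,
    PanelMismatchError,
    ParseError,
    UnknownIdentifierError,
    ValidationError,
)

PROVENANCES = ("positive_list", "sampled_negative")


@dataclass(frozen=True)
class DrugPair:
    """Unordered pair of distinct drugs; identity uses the sorted-id form."""

    drug_a: str
    drug_b: str

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValidationError(f"self-pair not allowed: {self.drug_a!r}")
        if not self.drug_a or not self.drug_b:
            raise ValidationError("drug ids must be non-empty")

    @property
    def canonical(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b) if self.drug_a <= self.drug_b else (
            self.drug_b,
            self.drug_a,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DrugPair):
            return NotImplemented
        return self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)


class LabeledPairSet:
    """Drug pairs with 0/1 labels (1 = known interaction) and provenance."""

    def __init__(
        self,
        pairs: Sequence[DrugPair],
        labels: Sequence[int],
        provenance: Sequence[str] | str = "positive_list",
    ) -> None:
        pairs = list(pairs)
        labels_arr = np.asarray(labels, dtype=int)
        if labels_arr.shape != (len(pairs),):
            raise ValidationError("labels must have one entry per pair")
        if labels_arr.size and not np.isin(labels_arr, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")
        if isinstance(provenance, str):
            prov = [provenance] * len(pairs)
        else:
            prov = list(provenance)
        if len(prov) != len(pairs):
            raise ValidationError("provenance must have one entry per pair")
        for p in prov:
            if p not in PROVENANCES:
                raise ValidationError(f"unknown provenance {p!r}")
        seen: dict[tuple[str, str], int] = {}
        for pair, lab in zip(pairs, labels_arr):
            key = pair.canonical
            if key in seen:
                if seen[key] != lab:
                    raise ValidationError(
                        f"pair {key} appears with both labels"
                    )
                raise ValidationError(f"duplicate pair {key}")
            seen[key] = int(lab)
        self.pairs = pairs
        self.labels = labels_arr
        self.provenance = prov

    def __len__(self) -> int:
        return len(self.pairs)

    def canonical_set(self) -> set[tuple[str, str]]:
        return {p.canonical for p in self.pairs}

    def positives(self) -> list[DrugPair]:
        return [p for p, y in zip(self.pairs, self.labels) if y == 1]

    def concat(self, other: "LabeledPairSet") -> "LabeledPairSet":
        return LabeledPairSet(
            self.pairs + other.pairs,
            np.concatenate([self.labels, other.labels]),
            self.provenance + other.provenance,
        )

    def drug_ids(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.drug_a)
            out.add(p.drug_b)
        return out


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------


def feature_names(target_ids: Sequence[str]) -> list[str]:
    """Interleaved feature layout: [S:T1, AD:T1, S:T2, AD:T2, ...]."""
    names: list[str] = []
    for t in target_ids:
        names.append(f"S:{t}")
        names.append(f"AD:{t}")
    return names


def featurize_pair(row_a: np.ndarray, row_b: np.ndarray) -> np.ndarray:
    """Sum and absolute-difference features for one drug pair.

    Both rows must come from the same panel (same target order) and be free of
    missing values; the output has length 2T, interleaved as
    [S_1, AD_1, S_2, AD_2, ...], and is symmetric in the two drugs.
    """
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PanelMismatchError(
            f"score vectors have different lengths: {a.shape} vs {b.shape}"
        )
    if np.isnan(a).any() or np.isnan(b).any():
        raise MissingDataError("score vector contains missing entries")
    out = np.empty(2 * a.size)
    out[0::2] = a + b
    out[1::2] = np.abs(a - b)
    return out


class DesignMatrix(NamedTuple):
    """Feature table for a list of pairs over one CPI panel."""

    X: np.ndarray
    y: np.ndarray | None
    kept_pairs: list[DrugPair]
    dropped_pairs: list[DrugPair]
    feature_names: list[str]


def assemble_design_matrix(
    pairs: LabeledPairSet | Sequence[DrugPair],
    cpi: CPIMatrix,
) -> DesignMatrix:
    """Build the pairs x 2T feature matrix over a CPI panel.

    Rows follow the order of ``pairs``; pairs in which either drug has any
    missing docking score are dropped and reported in ``dropped_pairs``.
    """
    if isinstance(pairs, LabeledPairSet):
        pair_list = pairs.pairs
        labels: np.ndarray | None = pairs.labels
    else:
        pair_list = list(pairs)
        labels = None

    drug_index = {d.drug_id: i for i, d in enumerate(cpi.drugs)}
    idx_a = np.empty(len(pair_list), dtype=int)
    idx_b = np.empty(len(pair_list), dtype=int)
    for k, p in enumerate(pair_list):
        for which, did in ((idx_a, p.drug_a), (idx_b, p.drug_b)):
            if did not in drug_index:
                raise UnknownIdentifierError(f"unknown drug id: {did!r}")
            which[k] = drug_index[did]

    complete_row = ~np.isnan(cpi.scores).any(axis=1)
    keep = complete_row[idx_a] & complete_row[idx_b]

    A = cpi.scores[idx_a[keep]]
    B = cpi.scores[idx_b[keep]]
    X = np.empty((A.shape[0], 2 * A.shape[1]))
    X[:, 0::2] = A + B
    X[:, 1::2] = np.abs(A - B)

    kept = [p for p, k in zip(pair_list, keep) if k]
    dropped = [p for p, k in zip(pair_list, keep) if not k]
    y = labels[keep] if labels is not None else None
    return DesignMatrix(X, y, kept, dropped, feature_names(cpi.target_ids))


# ---------------------------------------------------------------------------
# negative sampling and query enumeration
# ---------------------------------------------------------------------------


def _pair_from_index(idx: int, drugs: Sequence[str]) -> tuple[int, int]:
    """Map a flat index in [0, C(n,2)) to the (i, j) of the i<j pair."""
    # invert k = i*n - i*(i+1)/2 + (j - i - 1)
    n = len(drugs)
    i = int(n - 2 - math.floor(math.sqrt(-8 * idx + 4 * n * (n - 1) - 7) / 2 - 0.5))
    j = int(idx + i + 1 - i * n + i * (i + 1) // 2)
    return i, j


def sample_negatives(
    positives: LabeledPairSet,
    drugs: Sequence[str],
    n: int,
    seed: int,
) -> LabeledPairSet:
    """Sample n unordered non-interacting pairs uniformly without replacement.

    Candidates are all C(|drugs|, 2) unordered pairs minus the positive set
    and self-pairs; the draw is deterministic for a fixed seed.
    """
    drugs = list(drugs)
    if len(set(drugs)) != len(drugs):
        raise ValidationError("drug library contains duplicates")
    total = len(drugs) * (len(drugs) - 1) // 2
    forbidden = positives.canonical_set()
    # positives may mention drugs outside the library; only those inside
    # reduce capacity
    in_library = set(drugs)
    n_forbidden_inside = sum(
        1 for a, b in forbidden if a in in_library and b in in_library
    )
    capacity = total - n_forbidden_inside
    if n > capacity:
        raise CapacityError(
            f"requested {n} negatives but only {capacity} candidate pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen: list[DrugPair] = []
    if n > capacity // 2 or total <= 1_000_000:
        # small library or dense request: enumerate and draw exactly
        candidates = [
            (drugs[i], drugs[j])
            for i in range(len(drugs))
            for j in range(i + 1, len(drugs))
            if (tuple(sorted((drugs[i], drugs[j]))) not in forbidden)
        ]
        picks = rng.choice(len(candidates), size=n, replace=False)
        chosen = [DrugPair(*candidates[k]) for k in sorted(picks)]
    else:
        # sparse request: rejection sampling over flat pair indices
        taken: set[tuple[str, str]] = set()
        while len(chosen) < n:
            batch = rng.integers(0, total, size=2 * (n - len(chosen)) + 16)
            for idx in batch:
                i, j = _pair_from_index(int(idx), drugs)
                key = tuple(sorted((drugs[i], drugs[j])))
                if key in forbidden or key in taken:
                    continue
                taken.add(key)
                chosen.append(DrugPair(drugs[i], drugs[j]))
                if len(chosen) == n:
                    break
    return LabeledPairSet(chosen, [0] * n, "sampled_negative")


def enumerate_query_pairs(
    query_id: str, library: Sequence[str]
) -> list[DrugPair]:
    """Pair a query drug with every library drug (self-pair skipped)."""
    if not library:
        raise ValidationError("library must be non-empty")
    return [DrugPair(query_id, d) for d in library if d != query_id]


# ---------------------------------------------------------------------------
# pair-list file I/O
# ---------------------------------------------------------------------------


def read_pair_list(path: str | Path, default_label: int = 1) -> LabeledPairSet:
    """Read a TSV pair list: drug_a, drug_b, optional 0/1 label.

    Lines starting with '#' are comments.  Rows without a label column get
    ``default_label``.
    """
    pairs: list[DrugPair] = []
    labels: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}, line {lineno}: expected >= 2 columns")
            a, b = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip():
                try:
                    lab = int(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: label must be 0 or 1"
                    ) from None
            else:
                lab = default_label
            pairs.append(DrugPair(a, b))
            labels.append(lab)
    provenance = [
        "positive_list" if y == 1 else "sampled_negative" for y in labels
    ]
    return LabeledPairSet(pairs, labels, provenance)


def write_pair_list(pairs: LabeledPairSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_a\tdrug_b\tlabel\n")
        for p, y in zip(pairs.pairs, pairs.labels):
            fh.write(f"{p.drug_a}\t{p.drug_b}\t{int(y)}\n")


def write_design_matrix(dm: DesignMatrix, path: str | Path) -> None:
    """Export a design matrix as TSV with the feature-name header."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["drug_a", "drug_b", *dm.feature_names]
        if dm.y is not None:
            cols.append("label")
        fh.write("\t".join(cols) + "\n")
        for k, p in enumerate(dm.kept_pairs):
            row = [p.drug_a, p.drug_b] + [repr(float(v)) for v in dm.X[k]]
            if dm.y is not None:
                row.append(str(int(dm.y[k])))
            fh.write("\t".join(row) + "\n")
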