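"""Tanimoto similarity on binary fingerprints and the redundancy filter.

Used to test robustness of a trained interaction model to structural
redundancy in the drug library: every molecule whose fingerprint has Tanimoto
coefficient above the cutoff (default 0.75) to ANY other library molecule is
removed -- both members of an over-threshold pair are dropped -- and the
training pairs touching removed drugs are discarded before re-evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .pairs import LabeledPairSet


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary molecular fingerprint."""

    drug_id: str
    bits: np.ndarray  # bool vector

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1:
            raise ValidationError("bits must be a 1-D vector")
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")

    @property
    def n_bits(self) -> int:
        return self.bits.size


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two all-zero fingerprints give 0 by convention."""
    if a.n_bits != b.n_bits:
        raise ValidationError(
            f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}"
        )
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 0.0
    return float(np.sum(a.bits & b.bits) / union)


def redundancy_filter(
    fps: Sequence[Fingerprint], cutoff: float = 0.75
) -> list[str]:
    """Drug ids kept after removing every molecule similar to any other.

    A molecule is removed when its Tanimoto coefficient to ANY other input
    molecule exceeds ``cutoff``; the removal is symmetric (both members of an
    over-threshold pair go) and the input order of the survivors is preserved.
    """
    fps = list(fps)
    if not fps:
        raise ValidationError("need at least one fingerprint")
    lengths = {f.n_bits for f in fps}
    if len(lengths) > 1:
        raise ValidationError("all fingerprints must share one bit length")
    B = np.stack([f.bits for f in fps]).astype(np.float64)
    inter = B @ B.T
    popcount = B.sum(axis=1)
    union = popcount[:, None] + popcount[None, :] - inter
    with np.errstate(invalid="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(tc, 0.0)
    drop = (tc > cutoff).any(axis=1)
    return [f.drug_id for f, d in zip(fps, drop) if not d]


def filter_pairs(
    pairs: LabeledPairSet, kept_drugs: Sequence[str]
) -> LabeledPairSet:
    """Drop every pair touching a drug not in ``kept_drugs``."""
    kept = set(kept_drugs)
    mask = [p.drug_a in kept and p.drug_b in kept for p in pairs.pairs]
    return LabeledPairSet(
        [p for p, m in zip(pairs.pairs, mask) if m],
        pairs.labels[np.asarray(mask, dtype=bool)],
        [v for v, m in zip(pairs.provenance, mask) if m],
    )


# ---------------------------------------------------------------------------
# fingerprint file I/O (TSV, hex-encoded bitstrings)
# ---------------------------------------------------------------------------


def _hex_to_bits(hexstr: str, n_bits: int) -> np.ndarray:
    raw = bytes.fromhex(hexstr)
    bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8))
    if bits.size < n_bits:
        raise ParseError("hex string shorter than declared bit length")
    return bits[:n_bits].astype(bool)


def _bits_to_hex(bits: np.ndarray) -> str:
    padded = np.zeros(-(-bits.size // 8) * 8, dtype=np.uint8)
    padded[: bits.size] = bits.astype(np.uint8)
    return np.packbits(padded).tobytes().hex()


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Read a fingerprint TSV: a '#bits=N' header then drug_id<TAB>hex rows."""
    path = Path(path)
    fps: list[Fingerprint] = []
    n_bits: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#bits="):
                    n_bits = int(line[len("#bits=") :])
                continue
            if n_bits is None:
                raise ParseError(f"{path}: missing '#bits=N' header line")
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}, line {lineno}: expected 2 columns")
            try:
                bits = _hex_to_bits(parts[1].strip(), n_bits)
            except (ValueError, ParseError) as e:
                raise ParseError(f"{path}, line {lineno}: {e}") from None
            fps.append(Fingerprint(parts[0].strip(), bits))
    if not fps:
        raise ParseError(f"{path}: no fingerprints found")
    return fps


def write_fingerprints(fps: Sequence[Fingerprint], path: str | Path) -> None:
    fps = list(fps)
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(f"#bits={fps[0].n_bits}\n")
        for f in fps:
            fh.write(f"{f.drug_id}\t{_bits_to_hex(f.bits)}\n")


def fingerprints_from_smiles(
    entries: Sequence[tuple[str, str]], n_bits: int = 1024, radius: int = 2
) -> list[Fingerprint]:
    """Optional adapter: hashed Morgan fingerprints from (drug_id, SMILES).

    Requires rdkit; the core similarity operations work on any supplied
    binary fingerprints and do not depend on this adapter.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out: list[Fingerprint] = []
    for drug_id, smiles in entries:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(f"unparseable SMILES for {drug_id!r}: {smiles!r}")
        fp = gen.GetFingerprint(mol)
        bits = np.zeros(n_bits, dtype=bool)
        bits[list(fp.GetOnBits())] = True
        out.append(Fingerprint(drug_id, bits))
    return out
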