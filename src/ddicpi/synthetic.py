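"""Synthetic fixtures: CPI matrices, planted-truth pair labels, Vina files.

The real inputs of an interactome-based interaction classifier (a docked drug
library, curated positive pairs) cannot ship with a package, so tests and
examples run on generated stand-ins: docking scores drawn i.i.d. normal on
the kcal/mol scale Vina produces, and labels drawn from a *planted* logistic
model over the pair features.  Because the generating model is known, the
planted world carries its own oracle AUROC and the pipeline can be judged by
how closely it recovers it.  Real docking scores correlate across similar
binding pockets; the independence assumption here is a documented limitation
that keeps the oracle analytic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cpi import CPIMatrix, DrugRecord, TargetRecord
from .errors import CapacityError, ValidationError
from .evaluation import auroc
from .model import _sigmoid
from .pairs import DrugPair, LabeledPairSet, assemble_design_matrix

DEFAULT_SCORE_MEAN = -7.0  # kcal/mol, typical Vina best-pose affinity
DEFAULT_SCORE_SD = 1.5


def gen_cpi(
    n_drugs: int,
    n_targets: int,
    seed: int,
    score_mean: float = DEFAULT_SCORE_MEAN,
    score_sd: float = DEFAULT_SCORE_SD,
    missing_rate: float = 0.0,
) -> CPIMatrix:
    """Random CPI matrix with i.i.d. normal docking scores.

    Drug ids are D0001... and target ids T0001...; missing cells (if any) are
    placed uniformly at random.  Deterministic per seed.
    """
    if n_drugs <= 0 or n_targets <= 0:
        raise ValidationError("dimensions must be positive")
    if not 0 <= missing_rate < 1:
        raise ValidationError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    scores = rng.normal(score_mean, score_sd, size=(n_drugs, n_targets))
    if missing_rate > 0:
        mask = rng.random(size=scores.shape) < missing_rate
        scores[mask] = np.nan
    width_d = max(4, len(str(n_drugs)))
    width_t = max(4, len(str(n_targets)))
    drugs = [DrugRecord(f"D{i + 1:0{width_d}d}") for i in range(n_drugs)]
    # alternate PK/PD so panel-class plumbing is exercised
    targets = [
        TargetRecord(f"T{j + 1:0{width_t}d}", "PK" if j % 2 == 0 else "PD")
        for j in range(n_targets)
    ]
    return CPIMatrix(drugs, targets, scores)


def _sample_distinct_pairs(
    drug_ids: Sequence[str], n: int, rng: np.random.Generator
) -> list[DrugPair]:
    n_drugs = len(drug_ids)
    total = n_drugs * (n_drugs - 1) // 2
    if n > total:
        raise CapacityError(f"requested {n} pairs but only {total} exist")
    flat = rng.choice(total, size=n, replace=False)
    pairs = []
    for idx in flat:
        # invert the row-major upper-triangle index
        i = int(
            n_drugs
            - 2
            - np.floor(
                np.sqrt(-8 * idx + 4 * n_drugs * (n_drugs - 1) - 7) / 2 - 0.5
            )
        )
        j = int(idx + i + 1 - i * n_drugs + i * (i + 1) // 2)
        pairs.append(DrugPair(drug_ids[i], drug_ids[j]))
    return pairs


@dataclass
class PlantedWorld:
    """A synthetic dataset whose labels come from a known logistic model."""

    cpi: CPIMatrix
    pairs: LabeledPairSet
    true_weights: np.ndarray  # on standardized pair features
    true_intercept: float
    oracle_auroc: float
    seed: int
    X: np.ndarray  # raw pair features, rows aligned with pairs
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    linear_scores: np.ndarray  # true_intercept + Z @ true_weights


def _solve_intercept(
    zw: np.ndarray, u: np.ndarray, target_frac: float, tol: float = 0.02
) -> float:
    """Intercept whose realized positive fraction is within tol of target.

    First solves E[p] = target analytically by bisection, then (if the
    realized Bernoulli draw with uniforms ``u`` lands outside the band)
    bisects on the realized fraction itself, which is monotone in b.
    """
    def realized(b: float) -> float:
        return float(np.mean(u < _sigmoid(b + zw)))

    def expected(b: float) -> float:
        return float(np.mean(_sigmoid(b + zw)))

    lo, hi = -30.0, 30.0
    for fn in (expected, realized):
        a, c = lo, hi
        for _ in range(200):
            mid = 0.5 * (a + c)
            if fn(mid) < target_frac:
                a = mid
            else:
                c = mid
        b = 0.5 * (a + c)
        if abs(realized(b) - target_frac) <= tol:
            return b
    raise ValidationError(
        "could not calibrate intercept to the requested positive fraction"
    )


def gen_planted_world(
    n_drugs: int = 150,
    n_targets: int = 20,
    n_pos: int = 1000,
    n_neg: int = 1000,
    sparsity: float = 0.3,
    effect_scale: float | None = None,
    seed: int = 0,
    auroc_band: tuple[float, float] = (0.85, 0.88),
    missing_rate: float = 0.0,
) -> PlantedWorld:
    """Generate a CPI matrix plus pair labels from a planted logistic model.

    ``sparsity`` is the fraction of the 2T pair features with nonzero planted
    weight.  When ``effect_scale`` is None, the weight magnitude is calibrated
    by bisection so the oracle AUROC of the planted linear score lands inside
    ``auroc_band`` (the operating regime of a well-performing interaction
    classifier); a fixed value skips calibration.  ``n_pos``/``n_neg`` are
    target class counts: labels are Bernoulli draws from the planted model
    with the intercept tuned so the realized positive fraction is within 2%
    of n_pos / (n_pos + n_neg).  Fully deterministic per seed.
    """
    n_pairs = n_pos + n_neg
    if n_pairs > n_drugs * (n_drugs - 1) // 2:
        raise CapacityError("n_pos + n_neg exceeds the number of drug pairs")
    rng = np.random.default_rng(seed)
    cpi = gen_cpi(
        n_drugs, n_targets, seed=int(rng.integers(2**31)),
        missing_rate=missing_rate,
    )
    pair_rng = np.random.default_rng(int(rng.integers(2**31)))
    pairs = _sample_distinct_pairs(cpi.drug_ids, n_pairs, pair_rng)
    dm = assemble_design_matrix(pairs, cpi)
    X = dm.X
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd

    p_feat = Z.shape[1]
    k = max(1, round(sparsity * p_feat))
    w_rng = np.random.default_rng(int(rng.integers(2**31)))
    support = w_rng.choice(p_feat, size=k, replace=False)
    base_w = np.zeros(p_feat)
    base_w[support] = w_rng.normal(0.0, 1.0, size=k)
    u = np.random.default_rng(int(rng.integers(2**31))).random(n_pairs)
    target_frac = n_pos / n_pairs

    def world_at(scale: float):
        w = scale * base_w
        zw = Z @ w
        b = _solve_intercept(zw, u, target_frac)
        scores = b + zw
        labels = (u < _sigmoid(scores)).astype(int)
        if labels.min() == labels.max():  # degenerate draw, no signal to rank
            return w, b, scores, labels, 0.5
        return w, b, scores, labels, auroc(scores, labels)

    if effect_scale is not None:
        w, b, scores, labels, roc = world_at(effect_scale)
    else:
        lo_band, hi_band = auroc_band
        lo_s, hi_s = 1e-3, 1.0
        # expand until the band is bracketed
        for _ in range(60):
            if world_at(hi_s)[4] >= lo_band:
                break
            hi_s *= 2
        for _ in range(80):
            mid = 0.5 * (lo_s + hi_s)
            roc = world_at(mid)[4]
            if lo_band <= roc <= hi_band:
                break
            if roc < lo_band:
                lo_s = mid
            else:
                hi_s = mid
        else:
            raise ValidationError("could not calibrate oracle AUROC into band")
        w, b, scores, labels, roc = world_at(mid)

    labeled = LabeledPairSet(
        pairs,
        labels,
        ["positive_list" if y else "sampled_negative" for y in labels],
    )
    return PlantedWorld(
        cpi=cpi,
        pairs=labeled,
        true_weights=w,
        true_intercept=b,
        oracle_auroc=roc,
        seed=seed,
        X=X,
        feature_names=dm.feature_names,
        scaler_mean=mean,
        scaler_sd=sd,
        linear_scores=scores,
    )


# ---------------------------------------------------------------------------
# Vina-style result files
# ---------------------------------------------------------------------------

VINA_DIALECTS = ("log", "pdbqt")


def gen_vina_log(
    path: str | Path,
    ligand_id: str,
    target_id: str,
    scores: Sequence[float],
    dialect: str = "log",
) -> Path:
    """Write a parseable docking-result fixture whose best score is min(scores).

    ``dialect`` is "log" (stdout mode/affinity table) or "pdbqt" (per-model
    result remark lines in an output structure file).
    """
    scores = list(scores)
    if not scores:
        raise ValidationError("score list must be non-empty")
    if dialect not in VINA_DIALECTS:
        raise ValidationError(f"dialect must be one of {VINA_DIALECTS}")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "log":
            fh.write(f"# synthetic docking log: {ligand_id} vs {target_id}\n")
            fh.write("mode |   affinity | dist from best mode\n")
            fh.write("     | (kcal/mol) | rmsd l.b.| rmsd u.b.\n")
            fh.write("-----+------------+----------+----------\n")
            for i, s in enumerate(scores, start=1):
                fh.write(f"{i:>4} {s:>12.3f} {0.0:>10.3f} {0.0:>10.3f}\n")
        else:
            for i, s in enumerate(scores, start=1):
                fh.write(f"MODEL {i}\n")
                fh.write(
                    f"REMARK VINA RESULT: {s:>10.3f} {0.0:>10.3f} {0.0:>10.3f}\n"
                )
                fh.write(f"ATOM      1  C   LIG A   1       0.000   0.000   0.000\n")
                fh.write("ENDMDL\n")
    return path
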