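"""Collider-bias guards applied before stratification.

Stratifying on a variable influenced by the instruments would induce spurious
instrument-outcome association (collider bias). Continuous stratifiers (BMI,
polygenic score) are made independent of the instruments by regressing out the
instrument dosages; binary stratifiers (family history) by decile-matched
subsampling of the unexposed group at a fixed exposed:unexposed ratio within
deciles of the instrument-predicted exposure probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._utils import bin_by_rank, round_half_away, substream
from ._glm import _logistic_irls
from .simulate import GenotypeMatrix


def _instrument_design(
    genotypes: GenotypeMatrix, instrument_ids: Optional[Sequence[str]]
) -> Tuple[np.ndarray, List[str]]:
    """Mean-imputed dosage block for the requested instruments, rank-checked."""
    imputed = genotypes.mean_imputed()
    if instrument_ids is None:
        ids = list(genotypes.variant_ids)
        block = imputed
    else:
        ids = list(instrument_ids)
        missing = set(ids) - set(genotypes.variant_ids)
        if missing:
            raise ValueError(f"instruments absent from genotypes: {sorted(missing)}")
        cols = [genotypes.variant_ids.index(v) for v in ids]
        block = imputed[:, cols]
    X = np.column_stack([np.ones(block.shape[0]), block])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                collinear.append(ids[j - 1])
        raise ValueError(f"instrument dosage matrix is rank-deficient; collinear: {collinear}")
    return X, ids


def residualize(
    values,
    genotypes: GenotypeMatrix,
    instrument_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Remove the instruments' contribution from a continuous variable.

    Fits a multilinear regression of ``values`` on the instrument dosages
    (missing dosages mean-imputed for this fit), mean-centers the predictions
    and subtracts them. The output keeps the input's mean and is orthogonal to
    every (imputed) instrument in sample. Idempotent.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) != genotypes.n_individuals:
        raise ValueError("values must align with genotype rows")
    X, _ = _instrument_design(genotypes, instrument_ids)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    return y - (pred - pred.mean())


@dataclass
class MatchReport:
    """Bookkeeping of a ratio-matched subsampling run."""

    n_exposed_kept: int
    n_unexposed_kept: int
    n_excluded: int
    per_bin: List[Tuple[int, int, int]] = field(default_factory=list)  # (bin, n_exposed, n_unexposed_kept)
    shortfall_bins: List[int] = field(default_factory=list)


def match_binary(
    exposed,
    genotypes: GenotypeMatrix,
    instrument_ids: Optional[Sequence[str]] = None,
    ratio: float = 4.5,
    n_bins: int = 10,
    seed: int = 0,
) -> Tuple[np.ndarray, MatchReport]:
    """Ratio-matched subsampling of the unexposed group within prediction deciles.

    A logistic regression predicts the binary stratifier from the instrument
    dosages; individuals are binned into ``n_bins`` deciles of the prediction
    (ties broken by stable rank). Within each bin every exposed individual is
    kept and the unexposed are randomly subsampled without replacement to
    round(ratio x n_exposed) -- rounding half away from zero. Bins with too
    few unexposed keep all of them and record the shortfall.

    Returns (sorted kept row indices, MatchReport). The subsample uses a
    dedicated named random stream so other pipeline draws are unaffected.
    """
    e = np.asarray(exposed, dtype=bool)
    if len(e) != genotypes.n_individuals:
        raise ValueError("exposed must align with genotype rows")
    if not (e.any() and (~e).any()):
        raise ValueError("both exposed and unexposed individuals are required")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    X, _ = _instrument_design(genotypes, instrument_ids)
    beta, _, ok = _logistic_irls(X, e.astype(float))
    if not ok:
        raise RuntimeError("logistic regression for matching did not converge")
    pred = X @ beta  # monotone in predicted probability
    bins = bin_by_rank(pred, n_bins)
    rng = substream(seed, 7)
    keep_mask = np.zeros(len(e), dtype=bool)
    keep_mask[e] = True
    report = MatchReport(int(e.sum()), 0, 0)
    for b in range(n_bins):
        in_bin = bins == b
        n_exp = int((in_bin & e).sum())
        unexp_idx = np.flatnonzero(in_bin & ~e)
        raw_target = ratio * n_exp
        if not np.isfinite(raw_target):
            target = len(unexp_idx)  # infinite ratio keeps everyone
        else:
            target = int(round_half_away(raw_target))
        if len(unexp_idx) <= target:
            chosen = unexp_idx
            if len(unexp_idx) < target:
                report.shortfall_bins.append(b)
        else:
            chosen = rng.choice(unexp_idx, size=target, replace=False)
        keep_mask[chosen] = True
        report.per_bin.append((b, n_exp, len(chosen)))
        report.n_unexposed_kept += len(chosen)
    report.n_excluded = int(len(e) - keep_mask.sum())
    return np.flatnonzero(keep_mask), report
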