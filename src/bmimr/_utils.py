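"""Shared numeric helpers: deterministic rounding, rank-based binning, RNG streams."""

from __future__ import annotations

import numpy as np


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention used for all rendered tables).

    numpy/python round half to even, which would make rendered cells depend on
    the parity of the digit before the tie; tables here need the arithmetic
    convention (0.5 -> 1, 2.5 -> 3, -0.5 -> -1).
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def equal_bin_sizes(n: int, n_bins: int) -> np.ndarray:
    """Sizes of ``n_bins`` contiguous bins partitioning ``n`` items.

    Sizes differ by at most one; the larger bins are placed last so that the
    remainder lands in the highest bins (deterministic).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n < n_bins:
        raise ValueError(f"cannot split {n} items into {n_bins} non-empty bins; use fewer bins")
    base, rem = divmod(n, n_bins)
    return np.array([base] * (n_bins - rem) + [base + 1] * rem, dtype=int)


def bin_by_rank(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each element to one of ``n_bins`` equal-size bins by rank.

    Ties are broken by stable rank (original order), so the assignment is
    deterministic and bins partition the input with sizes differing by <= 1.
    Returns an integer bin index (0-based) per input element.
    """
    values = np.asarray(values)
    order = np.argsort(values, kind="stable")
    sizes = equal_bin_sizes(len(values), n_bins)
    bins = np.empty(len(values), dtype=int)
    bins[order] = np.repeat(np.arange(n_bins), sizes)
    return bins


def substream(seed: int, stream: int) -> np.random.Generator:
    """A named, independent random stream derived from the master seed."""
    return np.random.default_rng([int(seed) % (2**31), int(stream)])
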