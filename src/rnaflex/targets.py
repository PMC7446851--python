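"""Regression targets: per-chain B-factor outlier removal and normalization.

Raw crystallographic B-factors are not comparable across chains (different
refinement protocols, chain sizes, resolutions), so each chain is treated
separately: extreme values are first removed with a median-based rule, then
the retained values are z-normalized to zero mean and unit *population*
variance.  The resulting unitless values are the quantities the models
predict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TargetVector",
    "MODIFIED_Z_THRESHOLD",
    "remove_outliers_median",
    "normalize_bfactors",
    "make_target_vector",
]

#: Iglewicz–Hoaglin cutoff on the modified z-score
MODIFIED_Z_THRESHOLD = 3.5


@dataclass(frozen=True)
class TargetVector:
    """Normalized B-factors of one chain plus the outlier mask.

    ``values`` has zero mean and unit population variance; ``kept_mask``
    aligns with the chain's sample atoms (False = removed as outlier).
    """

    values: np.ndarray
    kept_mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.kept_mask, dtype=bool)
        if v.size != int(m.sum()):
            raise ValueError("values must align with the kept entries of the mask")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "kept_mask", m)


def remove_outliers_median(
    raw, threshold: float = MODIFIED_Z_THRESHOLD
) -> np.ndarray:
    """Boolean keep-mask from the modified z-score outlier rule.

    The modified z-score of entry ``x_i`` is ``0.6745 * (x_i - median) / MAD``
    with ``MAD = median(|x_i - median|)``; entries with ``|M_i| > threshold``
    are masked out.  When the MAD is zero (at least half the values
    identical) no entry is removed.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need at least 3 values for median-based outlier removal")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return np.ones(x.size, dtype=bool)
    m = 0.6745 * (x - med) / mad
    return np.abs(m) <= threshold


def normalize_bfactors(raw_kept) -> np.ndarray:
    """Z-normalize retained B-factors: zero mean, unit population variance."""
    x = np.asarray(raw_kept, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 retained values to normalize")
    mean = x.mean()
    sd = x.std()  # population convention: divide by n
    if sd == 0.0:
        raise ValueError("zero-variance B-factors: cannot normalize chain")
    return (x - mean) / sd


def make_target_vector(raw, threshold: float = MODIFIED_Z_THRESHOLD) -> TargetVector:
    """Outlier removal followed by normalization, as one step."""
    mask = remove_outliers_median(raw, threshold)
    values = normalize_bfactors(np.asarray(raw, dtype=float)[mask])
    lo, hi = values.min(), values.max()
    if lo < -3.5 or hi > 4.5:
        # diagnostic only: typical normalized B-factors span roughly [-3, 4]
        import logging
        logging.getLogger(__name__).info(
            "normalized B-factors span [%.2f, %.2f], wider than typical", lo, hi
        )
    return TargetVector(values, mask)
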