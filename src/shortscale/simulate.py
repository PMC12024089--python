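"""Synthetic Likert response generators with controlled latent structure.

Two generators are provided:

* :func:`generate_responses` draws from a bifactor-style Gaussian latent model
  (one general distress factor plus correlated subscale group factors) and
  discretizes each latent score through fixed standard-normal thresholds into
  categories 1..5.  With positively shifted thresholds the marginals are
  positively skewed, the shape typical of general-population symptom
  checklists.
* :func:`generate_block_responses` plants an exchangeable block correlation
  structure (``within_r`` inside blocks, ``between_r`` across), the natural
  fixture for testing variable clustering.

Both are deterministic under a seed (NumPy PCG64 via ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import ResponseMatrix, ValidationError

#: Default standard-normal cutpoints.  Cutting well to the right of zero
#: makes category 1 modal and the item means < 2 (positive skew).
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.5, 1.2, 1.8, 2.3)


@dataclass(frozen=True)
class LatentModelSpec:
    """General + correlated-group-factor model for Likert items.

    Item i's latent score is ``a_i*G + b_i*g_s(i) + sqrt(1-a_i^2-b_i^2)*e_i``
    where G is the general factor and g_s the item's subscale group factor.
    Group factors share a single second-order factor so that any two of them
    correlate at ``group_factor_corr``; they are orthogonal to G.
    """

    subscale_of: Mapping  # item_id -> subscale label
    general_loadings: Sequence[float]
    group_loadings: Sequence[float]
    group_factor_corr: float = 0.0
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        a = np.asarray(self.general_loadings, dtype=float)
        b = np.asarray(self.group_loadings, dtype=float)
        p = len(self.subscale_of)
        if a.shape != (p,) or b.shape != (p,):
            raise ValidationError(
                "general_loadings and group_loadings must each have one entry per item"
            )
        if np.any(a < 0) or np.any(a >= 1) or np.any(b < 0) or np.any(b >= 1):
            raise ValidationError("loadings must lie in [0, 1)")
        if np.any(a**2 + b**2 >= 1):
            j = int(np.argmax(a**2 + b**2))
            raise ValidationError(
                f"general^2 + group^2 must be < 1 (violated at item index {j})"
            )
        if not 0 <= self.group_factor_corr < 1:
            raise ValidationError("group_factor_corr must be in [0, 1)")
        t = np.asarray(self.thresholds, dtype=float)
        if t.shape != (4,) or np.any(np.diff(t) <= 0):
            raise ValidationError("thresholds must be 4 strictly ascending reals")

    @property
    def n_items(self) -> int:
        return len(self.subscale_of)

    @property
    def item_ids(self) -> list:
        return list(self.subscale_of.keys())


@dataclass(frozen=True)
class BlockSpec:
    """Planted block correlation structure for clustering fixtures."""

    block_sizes: Sequence[int]
    within_r: float
    between_r: float = 0.0
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        sizes = list(self.block_sizes)
        if not sizes or any(int(s) < 1 for s in sizes):
            raise ValidationError("block_sizes must be positive counts")
        if not 0 < self.within_r < 1:
            raise ValidationError("within_r must be in (0, 1)")
        if not 0 <= self.between_r <= self.within_r:
            raise ValidationError("between_r must satisfy 0 <= between_r <= within_r")
        t = np.asarray(self.thresholds, dtype=float)
        if t.shape != (4,) or np.any(np.diff(t) <= 0):
            raise ValidationError("thresholds must be 4 strictly ascending reals")
        # PSD check of the implied matrix (exchangeable blocks are PSD for
        # these parameter ranges, but a degenerate spec should still fail loud)
        C = _block_correlation(sizes, self.within_r, self.between_r)
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValidationError("implied block correlation matrix is not PSD")

    @property
    def n_items(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def assignment(self) -> np.ndarray:
        """Planted block index per item."""
        return np.repeat(np.arange(len(self.block_sizes)), list(self.block_sizes))


def _block_correlation(sizes, within_r, between_r) -> np.ndarray:
    p = int(sum(sizes))
    blocks = np.repeat(np.arange(len(sizes)), sizes)
    same = blocks[:, None] == blocks[None, :]
    C = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(C, 1.0)
    return C


def expected_latent_correlation(spec) -> np.ndarray:
    """Population correlation matrix of the latent (pre-discretization) scores."""
    if isinstance(spec, BlockSpec):
        return _block_correlation(list(spec.block_sizes), spec.within_r, spec.between_r)
    if isinstance(spec, LatentModelSpec):
        a = np.asarray(spec.general_loadings, dtype=float)
        b = np.asarray(spec.group_loadings, dtype=float)
        subs = np.asarray([spec.subscale_of[i] for i in spec.item_ids])
        same = subs[:, None] == subs[None, :]
        group_part = np.where(same, 1.0, spec.group_factor_corr)
        C = np.outer(a, a) + np.outer(b, b) * group_part
        np.fill_diagonal(C, 1.0)
        return C
    raise ValidationError(f"unsupported spec type: {type(spec).__name__}")


def _discretize(z: np.ndarray, thresholds) -> np.ndarray:
    """Map latent scores to categories 1..5 by counting crossed thresholds."""
    t = np.asarray(thresholds, dtype=float)
    return (1 + (z[..., None] > t).sum(axis=-1)).astype(np.int64)


def generate_responses(spec: LatentModelSpec, n: int, seed: int) -> ResponseMatrix:
    """Draw ``n`` respondents from the latent factor model and discretize."""
    if not isinstance(spec, LatentModelSpec):
        raise ValidationError("spec must be a LatentModelSpec")
    if n < 2:
        raise ValidationError("n must be >= 2")
    rng = np.random.default_rng(seed)
    a = np.asarray(spec.general_loadings, dtype=float)
    b = np.asarray(spec.group_loadings, dtype=float)
    item_ids = spec.item_ids
    subscales = [spec.subscale_of[i] for i in item_ids]
    labels = sorted(set(subscales))
    sub_index = np.array([labels.index(s) for s in subscales])

    general = rng.standard_normal(n)
    c = spec.group_factor_corr
    second_order = rng.standard_normal(n)
    unique_group = rng.standard_normal((n, len(labels)))
    group = np.sqrt(c) * second_order[:, None] + np.sqrt(1.0 - c) * unique_group
    noise = rng.standard_normal((n, len(item_ids)))
    resid = np.sqrt(1.0 - a**2 - b**2)
    z = general[:, None] * a + group[:, sub_index] * b + noise * resid
    return ResponseMatrix(_discretize(z, spec.thresholds), item_ids)


def generate_block_responses(spec: BlockSpec, n: int, seed: int) -> ResponseMatrix:
    """Draw ``n`` respondents from the planted-block latent model and discretize."""
    if not isinstance(spec, BlockSpec):
        raise ValidationError("spec must be a BlockSpec")
    if n < 2:
        raise ValidationError("n must be >= 2")
    rng = np.random.default_rng(seed)
    C = expected_latent_correlation(spec)
    # Exchangeable blocks factor exactly: eigendecomposition is robust for the
    # marginally-PSD corner cases (e.g. within_r == between_r).
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    z = rng.standard_normal((n, spec.n_items)) @ L.T
    item_ids = [f"v{j + 1}" for j in range(spec.n_items)]
    return ResponseMatrix(_discretize(z, spec.thresholds), item_ids)


def scl90_like_spec(
    general_range: tuple[float, float] = (0.62, 0.80),
    group_range: tuple[float, float] = (0.28, 0.40),
    group_factor_corr: float = 0.30,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    bank=None,
) -> LatentModelSpec:
    """A 90-item bifactor spec emulating the statistical shape of SCL-90 data.

    SCL-90 responses carry one dominant general-distress factor (full-scale
    alpha around 0.97 implies mean inter-item correlations near 0.45-0.5) plus
    ten mutually correlated subscale group factors and positively skewed
    marginals.  Loadings vary deterministically across items inside the given
    ranges so items are not exchangeable.
    """
    if bank is None:
        from .fixtures import scl90_bank

        bank = scl90_bank()
    item_ids = bank.item_ids
    p = len(item_ids)
    # deterministic low-discrepancy spread of loadings across items
    frac = (np.arange(p) * 0.6180339887498949) % 1.0
    a = general_range[0] + frac * (general_range[1] - general_range[0])
    frac2 = (np.arange(p) * 0.4142135623730951 + 0.25) % 1.0
    b = group_range[0] + frac2 * (group_range[1] - group_range[0])
    subscale_of = {i: bank.subscale_of(i) for i in item_ids}
    return LatentModelSpec(
        subscale_of=subscale_of,
        general_loadings=a,
        group_loadings=b,
        group_factor_corr=group_factor_corr,
        thresholds=tuple(thresholds),
    )
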