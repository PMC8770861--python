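"""Synthetic imaging-genetics data with known sparse canonical structure.

A shared latent variable z ~ N(0, 1) drives both views through sparse
ground-truth loading vectors:

    X = z u*' + E_X,   Y = z v*' + E_Y,   E entries iid N(0, delta^2)

so the cross-covariance of X and Y is rank one and (u*, v*) is the
population canonical pair.  The truth vectors are piecewise-constant
signed blocks (contiguous runs of equal magnitude), mimicking genomic
regions and spatially coherent imaging signatures; the noise scale delta
degrades the attainable canonical correlation, which for the
unstandardized projections has the closed form 1 / (1 + delta^2) when
||u*|| = ||v*|| = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import DataMatrix

# Default problem size: 800 genomic features, 100 imaging features.
DEFAULT_P = 800
DEFAULT_Q = 100
DEFAULT_N = 200
DEFAULT_BLOCKS_U = [(100, 15, +1), (400, 10, -1)]
DEFAULT_BLOCKS_V = [(20, 10, +1), (70, 6, -1)]
DEFAULT_NOISE_GRID = (0.5, 1.0, 2.0, 4.0)


class TruthError(ValueError):
    """Raised for invalid ground-truth block specifications."""


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``u_star`` / ``v_star`` are unit-norm sparse loading vectors with at
    least one contiguous nonzero block and a majority of zeros; ``z`` is
    the realized latent variable (populated by :func:`simulate` when
    requested), ``delta`` the noise scale.
    """

    u_star: np.ndarray
    v_star: np.ndarray
    z: np.ndarray | None = None
    delta: float | None = None
    seed: int | None = None

    @property
    def p(self) -> int:
        return self.u_star.size

    @property
    def q(self) -> int:
        return self.v_star.size


def _block_vector(d: int, blocks: list[tuple[int, int, int]]) -> np.ndarray:
    if not blocks:
        raise TruthError("at least one nonzero block is required")
    w = np.zeros(d)
    covered: set[int] = set()
    total = 0
    for start, length, sign in blocks:
        if length < 1:
            raise TruthError(f"block length must be >= 1, got {length}")
        if sign not in (-1, 1):
            raise TruthError(f"block sign must be +1 or -1, got {sign}")
        if start < 0 or start + length > d:
            raise TruthError(
                f"block ({start},{length}) out of range for {d} features"
            )
        idx = set(range(start, start + length))
        if idx & covered:
            raise TruthError(f"block ({start},{length}) overlaps another block")
        covered |= idx
        w[start : start + length] = sign
        total += length
    if total > d // 2:
        raise TruthError("blocks must leave at least 50% of entries zero")
    return w / np.linalg.norm(w)


def make_truth(
    p: int = DEFAULT_P,
    q: int = DEFAULT_Q,
    blocks_u: list[tuple[int, int, int]] | None = None,
    blocks_v: list[tuple[int, int, int]] | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Build unit-norm block-sparse ground-truth loadings.

    Each block is (start, length, sign); blocks must be disjoint and leave
    a majority of entries zero.  Defaults reproduce the package's standard
    simulation layout at p=800, q=100.
    """
    if blocks_u is None:
        blocks_u = DEFAULT_BLOCKS_U if p == DEFAULT_P else _auto_blocks(p)
    if blocks_v is None:
        blocks_v = DEFAULT_BLOCKS_V if q == DEFAULT_Q else _auto_blocks(q)
    return SyntheticTruth(
        u_star=_block_vector(p, blocks_u),
        v_star=_block_vector(q, blocks_v),
        seed=seed,
    )


def _auto_blocks(d: int) -> list[tuple[int, int, int]]:
    """Scale the default two-block layout to an arbitrary dimension.

    Block width grows slowly with d so each active feature keeps a
    non-negligible share of the signal variance.
    """
    if d >= 12:
        length = min(max(2, round(d * 0.03)), d // 4)
        return [(d // 8, length, +1), (d // 2, length, -1)]
    return [(d // 8, max(1, d // 4), +1)]


def simulate(
    n: int,
    truth: SyntheticTruth,
    noise_level: float,
    seed: int = 0,
    standardize: bool = True,
    return_latent: bool = False,
):
    """Draw one dataset from the rank-one latent model.

    z_i ~ N(0,1) iid; X = z u*' + E_X and Y = z v*' + E_Y with all noise
    entries iid N(0, noise_level^2).  Columns are z-scored unless
    ``standardize=False``.  Deterministic given ``seed``.

    Returns ``(X, Y)``, or ``(X, Y, truth_with_latent)`` when
    ``return_latent=True``.
    """
    if n < 10:
        raise ValueError("need n >= 10 samples")
    if noise_level < 0:
        raise ValueError("noise_level must be nonnegative")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    Xraw = np.outer(z, truth.u_star)
    Yraw = np.outer(z, truth.v_star)
    if noise_level > 0:
        Xraw = Xraw + noise_level * rng.standard_normal((n, truth.p))
        Yraw = Yraw + noise_level * rng.standard_normal((n, truth.q))
    feat_x = [f"g{i + 1:04d}" for i in range(truth.p)]
    feat_y = [f"roi{i + 1:03d}" for i in range(truth.q)]
    samples = [f"s{i + 1:04d}" for i in range(n)]
    X = DataMatrix.from_values(Xraw, feat_x, samples, standardize=standardize)
    Y = DataMatrix.from_values(Yraw, feat_y, samples, standardize=standardize)
    if return_latent:
        full = replace(truth, z=z, delta=float(noise_level), seed=seed)
        return X, Y, full
    return X, Y


def simulate_null(
    n: int, p: int, q: int, seed: int = 0, standardize: bool = True
) -> tuple[DataMatrix, DataMatrix]:
    """Independent Gaussian views with no shared latent (the null model)."""
    rng = np.random.default_rng(seed)
    X = DataMatrix.from_values(
        rng.standard_normal((n, p)), standardize=standardize
    )
    Y = DataMatrix.from_values(
        rng.standard_normal((n, q)), standardize=standardize
    )
    return X, Y
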