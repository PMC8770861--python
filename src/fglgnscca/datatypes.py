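"""Core data container: a standardized samples-by-features matrix.

Both data views (genomic features X and imaging features Y) are held as
:class:`DataMatrix` instances whose columns are z-scored.  Columns that are
constant before standardization carry no information for a correlation
analysis; they are set to all-zero and flagged rather than dropped, so that
feature indexing stays aligned with any user-supplied structure graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataError(ValueError):
    """Raised when an input matrix violates a structural precondition."""


@dataclass
class DataMatrix:
    """An n-samples x d-features numeric matrix with z-scored columns.

    Parameters
    ----------
    values
        Real matrix of shape (n, d).  After :meth:`standardize` each
        non-constant column has mean 0 and unit variance.
    feature_names
        Length-d column labels.
    sample_ids
        Length-n row labels.
    constant_mask
        Boolean length-d vector flagging columns that were constant before
        standardization (these are all-zero in ``values``).
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    constant_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise DataError(f"need n >= 2 samples and d >= 2 features, got {n}x{d}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("matrix contains non-finite entries")
        if len(self.feature_names) != d:
            raise DataError("feature_names length does not match number of columns")
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length does not match number of rows")
        if self.constant_mask is None:
            self.constant_mask = np.zeros(d, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        feature_names: list[str] | None = None,
        sample_ids: list[str] | None = None,
        standardize: bool = True,
    ) -> "DataMatrix":
        """Build a DataMatrix, z-scoring columns unless ``standardize=False``."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n, d = values.shape
        if feature_names is None:
            feature_names = [f"f{i + 1:04d}" for i in range(d)]
        if sample_ids is None:
            sample_ids = [f"s{i + 1:04d}" for i in range(n)]
        dm = cls(values, list(feature_names), list(sample_ids))
        if standardize:
            dm = dm.standardize()
        return dm

    def standardize(self) -> "DataMatrix":
        """Return a copy with z-scored columns (sample sd, ddof=1).

        Constant columns become all-zero and are flagged in
        ``constant_mask``.
        """
        v = self.values
        mean = v.mean(axis=0)
        sd = v.std(axis=0, ddof=1)
        const = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
        safe_sd = np.where(const, 1.0, sd)
        z = (v - mean) / safe_sd
        z[:, const] = 0.0
        return DataMatrix(z, list(self.feature_names), list(self.sample_ids), const)


def standardize_train_test(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both arrays with the training fold's column mean and sd.

    Constant training columns are zeroed in both arrays (no information and
    an undefined scale).  Used for cross-validation so the held-out fold
    never influences the scaling.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    const = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    safe_sd = np.where(const, 1.0, sd)
    tr = (train - mean) / safe_sd
    te = (test - mean) / safe_sd
    tr[:, const] = 0.0
    te[:, const] = 0.0
    return tr, te
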