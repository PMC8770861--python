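"""Evaluation protocol: repeated k-fold CV, grid search, noise sweeps,
top-feature tables and pairwise correlation tests.

The central quantity is the test-fold canonical correlation (CC): the
Pearson correlation of the held-out projections X_test u and Y_test v for
loadings fitted on the training folds.  Repeated five-fold CV stacks every
fitted loading vector into a stability matrix (repeats x folds rows), from
which feature-selection tables are built by averaging absolute weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .datatypes import DataMatrix, standardize_train_test
from .solver import (
    CanonicalSolution,
    HyperParams,
    fit_fglgnscca,
    fit_fglscca,
    fit_l1scca,
)
from .structures import default_structures
from .synthetic import SyntheticTruth, make_truth, simulate

logger = logging.getLogger(__name__)

DEFAULT_GAMMA_GRID = (0.1, 1.0, 10.0, 100.0)


@dataclass
class ModelConfig:
    """Which solver to run and how to build its structural priors."""

    model: str = "fglgnscca"  # fglgnscca | fglscca | l1scca
    hp: HyperParams = field(default_factory=HyperParams)
    chain_scheme: str = "unit"
    graph_scheme: str = "chain_plus_corr"
    graph_threshold: float = 0.5
    conn_scheme: str = "abs_corr"
    conn_threshold: float = 0.0
    graph_edges: list[tuple[int, int, float]] | None = None
    c1: float | None = None  # l1scca budgets; default sqrt(p)/2, sqrt(q)/2
    c2: float | None = None

    def fit(self, X: DataMatrix, Y: DataMatrix, seed: int | None = None) -> CanonicalSolution:
        """Build structures on (X, Y) and fit the configured model."""
        hp = self.hp if seed is None else replace(self.hp, seed=seed)
        if self.model == "l1scca":
            c1 = self.c1 if self.c1 is not None else max(1.0, np.sqrt(X.n_features) / 2)
            c2 = self.c2 if self.c2 is not None else max(1.0, np.sqrt(Y.n_features) / 2)
            return fit_l1scca(
                X, Y, c1, c2, tol=hp.tol, max_iter=hp.max_iter, seed=hp.seed
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-graph warning at CV scale
            sx, sy = default_structures(
                X,
                Y,
                chain_scheme=self.chain_scheme,
                graph_scheme=self.graph_scheme,
                graph_threshold=self.graph_threshold,
                conn_scheme=self.conn_scheme,
                conn_threshold=self.conn_threshold,
                graph_edges=self.graph_edges,
            )
        if self.model == "fglgnscca":
            return fit_fglgnscca(X, Y, sx, sy, hp)
        if self.model == "fglscca":
            return fit_fglscca(X, Y, sx, sy, hp)
        raise ValueError(f"unknown model {self.model!r}")


@dataclass
class CVResult:
    """Repeated-CV output: per-fold CCs and the loading stability matrices."""

    fold_cc: np.ndarray
    mean_cc: float
    sd_cc: float
    loadings_u: np.ndarray  # (repeats*folds, p)
    loadings_v: np.ndarray  # (repeats*folds, q)
    train_cc: np.ndarray = None  # type: ignore[assignment]


@dataclass
class GridSearchResult:
    """Gamma grid-search table and the selected pair."""

    grid: list[tuple[float, float, float, float]]  # (g1, g2, mean_cc, sd_cc)
    best: tuple[float, float]


def test_cc(
    X_test: np.ndarray | DataMatrix,
    Y_test: np.ndarray | DataMatrix,
    u: np.ndarray,
    v: np.ndarray,
    absolute: bool = False,
) -> float:
    """Pearson correlation of the held-out projections X u and Y v.

    A zero-variance projection yields 0 with a warning.  By default the
    signed correlation is returned; set ``absolute=True`` to fold the sign.
    """
    Xv = X_test.values if isinstance(X_test, DataMatrix) else np.asarray(X_test)
    Yv = Y_test.values if isinstance(Y_test, DataMatrix) else np.asarray(Y_test)
    xu = Xv @ np.asarray(u, dtype=float)
    yv = Yv @ np.asarray(v, dtype=float)
    if xu.std() <= 1e-14 or yv.std() <= 1e-14:
        warnings.warn("zero-variance projection; CC defined as 0", stacklevel=2)
        return 0.0
    r = float(np.corrcoef(xu, yv)[0, 1])
    return abs(r) if absolute else r


test_cc.__test__ = False  # not a pytest case despite the field's naming


def _align_rows(rows: np.ndarray) -> np.ndarray:
    """Flip each row to positive inner product with the running mean so
    sign-ambiguous loadings do not cancel when averaged."""
    out = rows.copy()
    mean = out[0].copy()
    for i in range(1, out.shape[0]):
        if out[i] @ mean < 0:
            out[i] = -out[i]
        mean += (out[i] - mean) / (i + 1)
    return out


def repeated_cv(
    X: DataMatrix,
    Y: DataMatrix,
    model_config: ModelConfig,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    absolute: bool = False,
) -> CVResult:
    """Repeated k-fold cross-validation of one model configuration.

    Each repeat reshuffles the samples into k folds; for every fold the
    model is fitted on the training part (re-standardized, structures
    rebuilt) and its test-fold CC recorded.  All fitted loadings are
    stacked (sign-aligned) into the stability matrices with exactly
    repeats*k rows.
    """
    n = X.n_samples
    if Y.n_samples != n:
        raise ValueError("X and Y must share samples")
    if n < 2 * k:
        raise ValueError(f"n={n} too small for {k}-fold CV")
    ss = np.random.SeedSequence(seed)
    fold_cc: list[float] = []
    train_cc: list[float] = []
    rows_u: list[np.ndarray] = []
    rows_v: list[np.ndarray] = []
    for rep, child in enumerate(ss.spawn(repeats)):
        state = child.generate_state(2)
        kf = KFold(n_splits=k, shuffle=True, random_state=int(state[0]) % (2**32 - 1))
        for fold, (tr, te) in enumerate(kf.split(X.values)):
            if tr.size < 3 or te.size < 3:
                raise ValueError("fold too small to standardize")
            Xtr, Xte = standardize_train_test(X.values[tr], X.values[te])
            Ytr, Yte = standardize_train_test(Y.values[tr], Y.values[te])
            Xdm = DataMatrix.from_values(
                Xtr, X.feature_names, [X.sample_ids[i] for i in tr], standardize=False
            )
            Ydm = DataMatrix.from_values(
                Ytr, Y.feature_names, [Y.sample_ids[i] for i in tr], standardize=False
            )
            fit_seed = int(state[1]) % (2**31 - 1) + fold
            sol = model_config.fit(Xdm, Ydm, seed=fit_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cc = test_cc(Xte, Yte, sol.u, sol.v, absolute=absolute)
            fold_cc.append(cc)
            train_cc.append(sol.cc_train)
            rows_u.append(sol.u)
            rows_v.append(sol.v)
    fold_arr = np.asarray(fold_cc)
    return CVResult(
        fold_cc=fold_arr,
        mean_cc=float(fold_arr.mean()),
        sd_cc=float(fold_arr.std(ddof=1)) if fold_arr.size > 1 else 0.0,
        loadings_u=_align_rows(np.vstack(rows_u)),
        loadings_v=_align_rows(np.vstack(rows_v)),
        train_cc=np.asarray(train_cc),
    )


def grid_search(
    X: DataMatrix,
    Y: DataMatrix,
    base_config: ModelConfig,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive search over the (gamma1, gamma2) grid by repeated CV.

    The sparsity coefficients stay fixed at their configured values (the
    protocol fixes lambda1 = lambda2 = 1 and tunes only the gammas).  A
    failing cell is recorded as NaN, not fatal, unless every cell fails.
    Ties on mean CC break to the lexicographically smallest pair.
    """
    if not gamma_grid:
        raise ValueError("gamma grid must be nonempty")
    table: list[tuple[float, float, float, float]] = []
    for g1 in gamma_grid:
        for g2 in gamma_grid:
            cfg = replace(base_config, hp=replace(base_config.hp, gamma1=g1, gamma2=g2))
            try:
                cv = repeated_cv(X, Y, cfg, k=k, repeats=repeats, seed=seed)
                table.append((float(g1), float(g2), cv.mean_cc, cv.sd_cc))
            except Exception as exc:  # noqa: BLE001 - cell failure is data
                logger.warning("grid cell (%s, %s) failed: %s", g1, g2, exc)
                table.append((float(g1), float(g2), float("nan"), float("nan")))
    finite = [row for row in table if np.isfinite(row[2])]
    if not finite:
        raise RuntimeError("every grid cell failed")
    best_cc = max(row[2] for row in finite)
    candidates = sorted(
        (row[0], row[1]) for row in finite if row[2] == best_cc
    )
    return GridSearchResult(grid=table, best=candidates[0])


def noise_experiment(
    models: list[ModelConfig],
    noise_levels: list[float],
    n: int = 200,
    truth_config: SyntheticTruth | dict | None = None,
    repeats: int = 4,
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """Mean test-fold CC per (model, noise level) on simulated data.

    For each noise level, ``repeats`` independent datasets are drawn (shared
    across models so comparisons are paired) and each is scored by one
    k-fold CV, pooling repeats*k test-fold CCs per cell.  Independent
    datasets, rather than repeated shuffles of one, keep the dataset-draw
    variance from dominating the cell means.  Returns a long-format table
    (model, noise_level, mean_cc, sd_cc).
    """
    if not models:
        raise ValueError("need at least one model")
    if len(noise_levels) < 2:
        raise ValueError("need at least two noise levels")
    if isinstance(truth_config, SyntheticTruth):
        truth = truth_config
    elif isinstance(truth_config, dict):
        truth = make_truth(**truth_config)
    else:
        truth = make_truth()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(noise_levels))
    rows = []
    for level, child in zip(noise_levels, children):
        rep_seeds = [
            int(g.generate_state(1)[0] % (2**31 - 1)) for g in child.spawn(repeats)
        ]
        per_model: dict[str, list[float]] = {cfg.model: [] for cfg in models}
        for rep_seed in rep_seeds:
            X, Y = simulate(n, truth, noise_level=level, seed=rep_seed)
            for cfg in models:
                cv = repeated_cv(X, Y, cfg, k=k, repeats=1, seed=rep_seed)
                per_model[cfg.model].extend(cv.fold_cc.tolist())
        for cfg in models:
            ccs = np.asarray(per_model[cfg.model])
            rows.append(
                {
                    "model": cfg.model,
                    "noise_level": float(level),
                    "mean_cc": float(ccs.mean()),
                    "sd_cc": float(ccs.std(ddof=1)) if ccs.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def top_k_features(
    loadings: np.ndarray, feature_names: list[str], k: int
) -> list[tuple[str, float]]:
    """Rank features by mean absolute weight across stability-matrix rows.

    Ties break deterministically by feature index.  Returns the top k
    (name, mean_abs_weight) pairs, sorted descending.
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if k <= 0:
        raise ValueError("k must be positive")
    if k > loadings.shape[1]:
        raise ValueError(f"k={k} exceeds number of features {loadings.shape[1]}")
    if loadings.shape[1] != len(feature_names):
        raise ValueError("feature_names length mismatch")
    mean_abs = np.mean(np.abs(loadings), axis=0)
    order = np.argsort(-mean_abs, kind="stable")  # stable => index tie-break
    return [(feature_names[i], float(mean_abs[i])) for i in order[:k]]


def pairwise_correlation_tests(
    X: DataMatrix,
    Y: DataMatrix,
    top_genes: list[int],
    top_rois: list[int],
) -> pd.DataFrame:
    """Pearson r and Fisher-z p-value for every (gene, ROI) column pair.

    p-values come from the two-sided normal test on sqrt(n-3) atanh(r);
    Benjamini-Hochberg q-values are appended as a convenience.  Constant
    columns give an undefined r and are flagged.  Rows are sorted by
    ascending p-value (flagged rows last).
    """
    n = X.n_samples
    if Y.n_samples != n:
        raise ValueError("X and Y must share samples")
    if n < 4:
        raise ValueError("need n >= 4 for the Fisher z test")
    rows = []
    for g in top_genes:
        xg = X.values[:, g]
        sx_ = xg.std()
        for r_idx in top_rois:
            yr = Y.values[:, r_idx]
            sy_ = yr.std()
            if sx_ <= 1e-14 or sy_ <= 1e-14:
                rows.append(
                    {
                        "gene": X.feature_names[g],
                        "roi": Y.feature_names[r_idx],
                        "r": np.nan,
                        "p_value": np.nan,
                        "flag": "constant_column",
                    }
                )
                continue
            r = float(np.corrcoef(xg, yr)[0, 1])
            r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
            zstat = np.sqrt(n - 3) * np.arctanh(r_c)
            p = float(2 * scipy.stats.norm.sf(abs(zstat)))
            rows.append(
                {
                    "gene": X.feature_names[g],
                    "roi": Y.feature_names[r_idx],
                    "r": r,
                    "p_value": p,
                    "flag": "",
                }
            )
    df = pd.DataFrame(rows)
    ok = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["q_value"] = q
    df = df.sort_values("p_value", na_position="last", kind="stable").reset_index(
        drop=True
    )
    return df
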