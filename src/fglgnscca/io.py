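"""File ingestion and result emission.

Matrices travel as delimited text: the labeled dialect has feature names in
the first row and sample IDs in the first column; the raw dialect is a
headerless numeric table for which labels are synthesized.  Graphs are
3-column edge lists.  Fitted solutions are written as per-side loading
tables plus a JSON run report that suffices to reproduce the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import DataError, DataMatrix
from .evaluation import CVResult, top_k_features
from .solver import CanonicalSolution

FLOAT_FMT = "%.17g"


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    dialect: str = "labeled_tsv",
    standardize: bool = True,
    sep: str | None = None,
) -> DataMatrix:
    """Read a delimited matrix file into a (by default standardized)
    :class:`DataMatrix`.

    ``labeled_tsv``: first row feature names, first column sample IDs.
    ``raw``: headerless numbers; labels f0001..., s0001... are synthesized.
    Non-numeric cells raise an error naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise DataError(f"empty file: {path}")
    s = _sep_for(path, sep)
    if dialect == "labeled_tsv":
        df = pd.read_csv(path, sep=s, index_col=0, comment="#")
        feature_names = [str(c) for c in df.columns]
        sample_ids = [str(i) for i in df.index]
    elif dialect == "raw":
        df = pd.read_csv(path, sep=s, header=None, comment="#")
        feature_names = [f"f{i + 1:04d}" for i in range(df.shape[1])]
        sample_ids = [f"s{i + 1:04d}" for i in range(df.shape[0])]
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-numeric cell at row {i + 1}, column {j + 1} "
                f"(value {df[col].iloc[i]!r}) in {path}"
            )
        if converted.isna().any():
            i = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise DataError(f"missing value at row {i + 1}, column {j + 1} in {path}")
        values[:, j] = converted.to_numpy(dtype=float)
    return DataMatrix.from_values(values, feature_names, sample_ids, standardize)


def write_matrix(dm: DataMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a DataMatrix in the labeled dialect at full precision."""
    df = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.feature_names)
    df.to_csv(Path(path), sep=sep, float_format=FLOAT_FMT)


def read_graph(
    path: str | Path, feature_names: list[str]
) -> list[tuple[int, int, float]]:
    """Read a 3-column edge list (name-or-index, name-or-index, weight).

    Lines starting with '#' are comments.  Feature names are resolved
    against ``feature_names``; bare integers are taken as 0-based indices.
    """
    path = Path(path)
    index = {name: i for i, name in enumerate(feature_names)}
    edges: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise DataError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            ij = []
            for token in parts[:2]:
                if token in index:
                    ij.append(index[token])
                else:
                    try:
                        ij.append(int(token))
                    except ValueError:
                        raise DataError(
                            f"{path}:{lineno}: unknown feature {token!r}"
                        ) from None
            try:
                w = float(parts[2])
            except ValueError:
                raise DataError(f"{path}:{lineno}: bad weight {parts[2]!r}") from None
            edges.append((ij[0], ij[1], w))
    return edges


def _loadings_frame(
    w: np.ndarray, names: list[str]
) -> pd.DataFrame:
    ranked = top_k_features(w.reshape(1, -1), names, k=len(names))
    rank_of = {name: r + 1 for r, (name, _) in enumerate(ranked)}
    return pd.DataFrame(
        {
            "feature": names,
            "weight": w,
            "rank": [rank_of[n] for n in names],
        }
    )


def write_solution(
    solution: CanonicalSolution,
    cv: CVResult | None,
    outdir: str | Path,
    feature_names_x: list[str],
    feature_names_y: list[str],
    config: dict | None = None,
) -> dict[str, Path]:
    """Write u.tsv, v.tsv, report.json (and stability matrices if CV ran).

    The loading tables carry (feature, weight, rank-by-|weight|); the
    report embeds the resolved configuration, convergence information and
    the canonical correlations, so a run is reproducible from the report
    alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    for side, w, names in (
        ("u", solution.u, feature_names_x),
        ("v", solution.v, feature_names_y),
    ):
        p = outdir / f"{side}.tsv"
        _loadings_frame(np.asarray(w), names).to_csv(
            p, sep="\t", index=False, float_format=FLOAT_FMT
        )
        files[side] = p

    report = {
        "tool": "fglgnscca",
        "version": __version__,
        "config": config or {},
        "n_iter": int(solution.n_iter),
        "converged": bool(solution.converged),
        "cc_train": float(solution.cc_train),
        "objective_trace": [float(x) for x in solution.objective_trace],
        "diagnostics": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in solution.diagnostics.items()
        },
    }
    if cv is not None:
        report["cv"] = {
            "mean_cc": float(cv.mean_cc),
            "sd_cc": float(cv.sd_cc),
            "fold_cc": [float(x) for x in cv.fold_cc],
        }
        for side, mat, names in (
            ("loadings_u", cv.loadings_u, feature_names_x),
            ("loadings_v", cv.loadings_v, feature_names_y),
        ):
            p = outdir / f"{side}.tsv"
            pd.DataFrame(mat, columns=names).to_csv(
                p, sep="\t", index=False, float_format=FLOAT_FMT
            )
            files[side] = p
    rp = outdir / "report.json"
    rp.write_text(json.dumps(report, indent=2))
    files["report"] = rp
    return files
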