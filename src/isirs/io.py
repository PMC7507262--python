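"""Readers and writers for the plain-text tabular formats the tool consumes.

Feature matrices are TSV/CSV with sample IDs in the first column and a header
of feature names; responses are two-column tables (sample ID, value).  Sample
alignment between the two is always by ID intersection, never by row order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CVReport,
    FeatureMatrix,
    OLSModel,
    RedundancyReport,
    ResponseVector,
    SelectionTrace,
    ValidationError,
)

log = logging.getLogger("isirs")

_SEPS = {"tsv": "\t", "csv": ","}


def _sep_for(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _SEPS:
            raise ValidationError(f"format must be tsv or csv, got {fmt!r}")
        return _SEPS[fmt]
    return "," if str(path).endswith(".csv") else "\t"


def read_feature_matrix(
    path: str | Path,
    fmt: str | None = None,
    omics_path: str | Path | None = None,
    impute_missing: bool = False,
) -> FeatureMatrix:
    """Read a samples x features table.

    Missing cells are rejected unless ``impute_missing`` is set, in which case
    they are filled with the column mean (logged).  ``omics_path`` optionally
    names a two-column sidecar table mapping feature ID -> omics type.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = _sep_for(path, fmt)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        seen: set[str] = set()
        dupes = sorted({h for h in header if h in seen or seen.add(h)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate feature columns: {dupes[:10]}")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate sample ids: {dupes[:10]}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        col = non_numeric[0]
        row = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()].index
        raise ValidationError(
            f"non-numeric cells in column {col!r}"
            + (f" (e.g. sample {row[0]!r})" if len(row) else "")
        )
    if df.isna().any().any():
        if not impute_missing:
            cell = np.argwhere(df.isna().values)[0]
            raise ValidationError(
                f"missing value at sample {df.index[cell[0]]!r}, "
                f"feature {df.columns[cell[1]]!r} (use impute_missing to fill "
                "with column means)"
            )
        n_missing = int(df.isna().sum().sum())
        df = df.fillna(df.mean())
        log.warning("imputed %d missing cells with column means", n_missing)

    omics = None
    if omics_path is not None:
        side = pd.read_csv(omics_path, sep=_sep_for(omics_path, None), index_col=0)
        mapping = side.iloc[:, 0].to_dict()
        missing = [c for c in df.columns if c not in mapping]
        if missing:
            raise ValidationError(f"omics sidecar missing features: {missing[:10]}")
        omics = [str(mapping[c]) for c in df.columns]

    return FeatureMatrix(
        values=df.to_numpy(dtype=float),
        feature_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
        omics_type=omics,
    )


def read_response(path: str | Path, fmt: str | None = None) -> ResponseVector:
    """Read a two-column (sample ID, value) response table."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path, fmt), index_col=0,
                     float_precision="round_trip")
    if df.shape[1] != 1:
        raise ValidationError(f"response table must have exactly 2 columns, got {df.shape[1] + 1}")
    col = df.columns[0]
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.values)[0]) + 2  # +1 header, +1 1-based
        raise ValidationError(f"non-numeric response value at line {line}")
    if coerced.isna().any():
        i = df.index[coerced.isna()][0]
        raise ValidationError(f"missing response for sample {i!r}")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate sample ids in response: {dupes[:10]}")
    return ResponseVector(
        coerced.to_numpy(dtype=float), [str(i) for i in df.index], label=str(col)
    )


def align(X: FeatureMatrix, Y: ResponseVector) -> tuple[FeatureMatrix, ResponseVector]:
    """Align a feature matrix and response by sample-ID intersection.

    Samples present on only one side are dropped with a logged report; no
    overlap at all is an error.
    """
    common = [s for s in X.sample_ids if s in set(Y.sample_ids)]
    if not common:
        raise ValidationError("no overlapping sample ids between features and response")
    dropped = (len(X.sample_ids) - len(common)) + (len(Y.sample_ids) - len(common))
    if dropped:
        log.warning("dropped %d unmatched samples during alignment", dropped)
    xpos = {s: i for i, s in enumerate(X.sample_ids)}
    ypos = {s: i for i, s in enumerate(Y.sample_ids)}
    return (
        X.select_samples([xpos[s] for s in common]),
        Y.select_samples([ypos[s] for s in common]),
    )


def write_feature_matrix(X: FeatureMatrix, path: str | Path, fmt: str | None = None) -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_ids)
    df.to_csv(Path(path), sep=_sep_for(path, fmt), float_format="%.17g", index_label="sample_id")


def write_response(Y: ResponseVector, path: str | Path, fmt: str | None = None) -> None:
    df = pd.DataFrame({Y.label: Y.values}, index=Y.sample_ids)
    df.to_csv(Path(path), sep=_sep_for(path, fmt), float_format="%.17g", index_label="sample_id")


def write_results(
    output_dir: str | Path,
    X: FeatureMatrix,
    trace: SelectionTrace | None = None,
    model: OLSModel | None = None,
    omega: np.ndarray | None = None,
    report: CVReport | None = None,
    redundancy: RedundancyReport | None = None,
    Y: ResponseVector | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the result bundle of a run to ``output_dir``.

    Emits whichever pieces are provided: ``selected_features.tsv`` (feature,
    omics type, omega, OLS coefficient, t, p, significance flag),
    ``iterations.tsv`` (per-pass screened/retained sets), ``cv_predictions.tsv``
    (per-sample out-of-fold predictions), and ``summary.json`` (metrics, d,
    seed, config echo).  Returns the mapping of artifact name -> path.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if model is not None and trace is not None:
        rows = []
        for k in trace.final_set:
            rows.append({
                "feature_id": X.feature_ids[k],
                "omics_type": X.omics_type[k] if X.omics_type else "",
                "omega": float(omega[k]) if omega is not None else float("nan"),
                "coefficient": model.coefficients[k],
                "t_stat": model.t_stats[k],
                "p_value": model.p_values[k],
                "significant_at_001": k in model.significant_at_001,
            })
        p = out / "selected_features.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.17g")
        written["selected_features"] = p

    if trace is not None:
        rows = [
            {
                "iteration": s + 1,
                "n_screened": len(rec.screened),
                "n_retained": len(rec.retained),
                "screened": ",".join(X.feature_ids[i] for i in rec.screened),
                "retained": ",".join(X.feature_ids[i] for i in rec.retained),
                "residual_norm": rec.residual_norm,
            }
            for s, rec in enumerate(trace.iterations)
        ]
        p = out / "iterations.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.17g")
        written["iterations"] = p

    if report is not None and Y is not None:
        p = out / "cv_predictions.tsv"
        pd.DataFrame({
            "sample_id": Y.sample_ids,
            "observed": Y.values,
            "predicted": report.per_sample_prediction,
        }).to_csv(p, sep="\t", index=False, float_format="%.17g")
        written["cv_predictions"] = p

    summary: dict = {"n": X.n, "p": X.p}
    if trace is not None:
        summary.update(
            d=trace.d, k1=trace.k1, n_selected=len(trace.final_set),
            stop_reason=trace.stop_reason, n_iterations=len(trace.iterations),
            events=trace.events,
        )
    if model is not None:
        summary["r_squared"] = model.r_squared
        summary["n_significant_at_001"] = len(model.significant_at_001)
    if report is not None:
        summary.update(
            cv_method=report.method, cv_pcc=report.pcc, cv_mse=report.mse,
            cv_folds=report.folds, cv_repeats=report.repeats, cv_seed=report.seed,
        )
    if redundancy is not None:
        summary.update(
            mrs_pcc=redundancy.mrs_pcc, mrs_mi=redundancy.mrs_mi,
            mrs_n_features=redundancy.n_features, mi_bins=redundancy.bins,
        )
    if config is not None:
        summary["config"] = config
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written["summary"] = p
    return written
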