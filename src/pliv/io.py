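"""Tabular ingestion and report serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult
from .inference import VarianceEstimate
from .model import Dataset

__all__ = ["read_table", "build_report", "format_report", "write_report"]


def read_table(
    path: str | Path,
    y: str,
    x: str,
    z: str,
    log_y: bool = False,
    log_x: bool = False,
    log_z: bool = False,
) -> Dataset:
    """Read a CSV/TSV file into a Dataset.

    The delimiter is inferred from the extension (.tsv/.tab -> tab, else
    comma).  Rows with a missing value in any of the three columns are dropped
    and counted; requested log transforms are validated (all values strictly
    positive) before being applied.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    for col in (y, x, z):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    sub = frame[[y, x, z]].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)

    arrays = {}
    for name, col, do_log in (("y", y, log_y), ("x", x, log_x), ("z", z, log_z)):
        vals = kept[col].to_numpy(dtype=float)
        if do_log:
            bad = np.nonzero(vals <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"log transform of column {col!r} requires strictly positive values; "
                    f"first offending row index {int(kept.index[bad[0]])}"
                )
            vals = np.log(vals)
        arrays[name] = vals
    return Dataset(
        y=arrays["y"], x=arrays["x"], z=arrays["z"],
        transform_log_y=log_y, transform_log_x=log_x, transform_log_z=log_z,
        n_dropped=n_dropped,
    )


def build_report(fit: FitResult, vc: VarianceEstimate, summary: pd.DataFrame, meta: dict) -> dict:
    """Machine-readable fit report (JSON-serializable)."""
    return {
        "software": {"package": "pliv", "version": _version()},
        "meta": meta,
        "counts": {"K": fit.space.counts.K, "J": fit.space.counts.J},
        "loglik": fit.model_loglik,
        "aic": fit.aic(),
        "bic": fit.bic(),
        "first_stage_F": fit.first_stage_F,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "n_obs": fit.n_obs,
        "inference_mode": vc.mode,
        "parameters": summary.replace({np.nan: None}).to_dict(orient="records"),
    }


def format_report(report: dict) -> str:
    """Human-readable summary mirroring the standard Wald-table layout."""
    lines = [
        f"PLIV fit (K={report['counts']['K']}, J={report['counts']['J']}, "
        f"n={report['n_obs']}, mode={report['inference_mode']})",
        f"log-likelihood {report['loglik']:.3f}   AIC {report['aic']:.2f}   "
        f"BIC {report['bic']:.2f}   first-stage F {report['first_stage_F']:.1f}",
        f"converged: {report['converged']} ({report['n_iter']} iterations)",
        "",
        f"{'Parameter':<10}{'Estimate':>10}{'Std.Err':>10}{'z':>8}{'95% CI':>22}{'p':>10}",
    ]
    for row in report["parameters"]:
        p = row["p"]
        p_str = "-" if p is None else ("<1e-4" if p < 1e-4 else f"{p:.4f}")
        ci = "({:.3f}, {:.3f})".format(row["ci_low"], row["ci_high"])
        lines.append(
            f"{row['parameter']:<10}{row['estimate']:>10.4f}{row['se']:>10.4f}"
            f"{row['z']:>8.2f}{ci:>22}{p_str:>10}"
        )
    return "\n".join(lines)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("pliv")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
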