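"""Resolution-vs-length regression and run-level report assembly.

Species-level resolution is regressed on the natural log of the mean
metabarcode length by ordinary least squares (R², F and p are invariant to
the log base, so the choice is cosmetic). For a simple regression the F
statistic satisfies F = R²(n-2)/(1-R²) with df = (1, n-2), which is asserted
as an internal consistency check.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import EvaluationReport


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS of species-level resolution on log mean amplicon length."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int

    def __post_init__(self):
        if self.r_squared >= 1.0 - 1e-12:
            return  # perfect fit: F is unbounded, the identity degenerates
        expected_f = self.r_squared * self.df[1] / (1.0 - self.r_squared)
        if not math.isclose(self.f_stat, expected_f, rel_tol=1e-9,
                            abs_tol=1e-9):
            raise ValueError(
                "inconsistent regression result: F != R^2 (n-2)/(1-R^2)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["df"] = list(self.df)
        return d


def _extract_points(reports) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(reports, pd.DataFrame):
        frame = reports
        pairs = [
            (row["mean_len"], row["resolution_species"])
            for _, row in frame.iterrows()
        ]
    else:
        pairs = [(rep.mean_len, rep.resolution_species) for rep in reports]
    pairs = [
        (ml, rs) for ml, rs in pairs
        if ml is not None and rs is not None
        and np.isfinite(ml) and np.isfinite(rs) and ml > 0
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"regression requires >= 3 usable points, got {len(pairs)}"
        )
    x = np.log([ml for ml, _ in pairs])
    y = np.array([rs for _, rs in pairs], dtype=float)
    return x, y


def resolution_length_regression(
        reports: Sequence[EvaluationReport] | pd.DataFrame
) -> RegressionResult:
    """OLS of species-level resolution on log(mean metabarcode length).

    Accepts a list of :class:`EvaluationReport` or a DataFrame with columns
    ``mean_len`` and ``resolution_species``. Reports lacking either quantity
    (e.g. zero amplification) are dropped; fewer than 3 usable points raise.
    """
    x, y = _extract_points(reports)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(x)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        df=(1, n - 2),
        p_value=float(model.f_pvalue),
        n=n,
    )


def load_reference_panel_metrics() -> pd.DataFrame:
    """The packaged per-primer evaluation metrics of the 15-pair 18S panel
    (coverage, length summary, per-rank resolution), as reported for a
    curated nematode reference database; lets the regression be exercised
    without any database download."""
    from importlib.resources import files

    source = files("primerval.data").joinpath("panel_metrics_18s.tsv")
    with source.open() as handle:
        return pd.read_csv(handle, sep="\t")


# ---------------------------------------------------------------------------
# run bundle

def file_checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def build_manifest(parameters: Mapping, inputs: Mapping[str, str | Path] = (),
                   seeds: Mapping[str, int] = ()) -> dict:
    """Run manifest: version, parameters, seeds and input checksums —
    sufficient to reproduce every output bit-identically (the timestamp is
    informational and excluded from reproducibility comparisons)."""
    from . import __version__

    return {
        "tool": "primerval",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": dict(parameters),
        "seeds": dict(seeds),
        "input_checksums": {
            name: file_checksum(path) for name, path in dict(inputs).items()
        },
    }


def assemble_run_report(reports: Sequence[EvaluationReport],
                        specificities: Iterable[tuple[str, float | None, int]],
                        regression: RegressionResult | None,
                        manifest: Mapping,
                        out_dir: str | Path) -> Path:
    """Write the run bundle: report.tsv, specificity.tsv, regression.json,
    manifest.json under ``out_dir``. Returns the bundle directory."""
    from .metrics import write_report_tsv, write_specificity_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_report_tsv(reports, out / "report.tsv")
    write_specificity_tsv(specificities, out / "specificity.tsv")
    with open(out / "regression.json", "w") as handle:
        json.dump(regression.to_dict() if regression else None, handle,
                  indent=2)
        handle.write("\n")
    with open(out / "manifest.json", "w") as handle:
        json.dump(dict(manifest), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return out


def load_run_report(bundle_dir: str | Path) -> dict:
    """Read a run bundle back into DataFrames / dicts."""
    bundle = Path(bundle_dir)
    with open(bundle / "regression.json") as handle:
        regression = json.load(handle)
    with open(bundle / "manifest.json") as handle:
        manifest = json.load(handle)
    return {
        "report": pd.read_csv(bundle / "report.tsv", sep="\t"),
        "specificity": pd.read_csv(bundle / "specificity.tsv", sep="\t"),
        "regression": regression,
        "manifest": manifest,
    }
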