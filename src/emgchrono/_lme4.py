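"""Subprocess bridge to lme4 (via Rscript) for mixed-model fitting.

The numerical engine for LME/GLME fits is lme4, driven through a small R
runner shipped with the package; data travel as a temporary CSV and results
come back as JSON.  Only the columns referenced by the model are sent.
"""

from __future__ import annotations

import json
import re
import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

_RUNNER = Path(__file__).with_name("lme4_runner.R")


class Lme4Error(RuntimeError):
    pass


def rscript_path() -> str:
    path = shutil.which("Rscript")
    if path is None:
        raise Lme4Error(
            "Rscript not found on PATH; mixed-model fitting requires R with lme4"
        )
    return path


def _formula_columns(formula: str, data: pd.DataFrame) -> list[str]:
    tokens = set(re.findall(r"[A-Za-z_][A-Za-z0-9_.]*", formula))
    return [c for c in data.columns if c in tokens]


def run_lme4(
    formula: str,
    data: pd.DataFrame,
    family: str = "gaussian",
    reml: bool = True,
    factors: dict[str, list[str]] | None = None,
    optimizer: str = "bobyqa",
    maxfun: int = 200_000,
    timeout: float = 1800.0,
) -> dict:
    """Fit one model with lmer/glmer and return the parsed JSON summary."""
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unsupported family {family!r}")
    cols = _formula_columns(formula, data)
    if not cols:
        raise ValueError("formula references no column of the data")
    with tempfile.TemporaryDirectory(prefix="emgchrono_lme4_") as tmp:
        tmp = Path(tmp)
        data_path, out_path, job_path = tmp / "data.csv", tmp / "out.json", tmp / "job.json"
        data[cols].to_csv(data_path, index=False)
        job = {
            "data": str(data_path),
            "out": str(out_path),
            "formula": formula,
            "family": family,
            "reml": reml,
            "optimizer": optimizer,
            "maxfun": maxfun,
            "factors": factors or {},
        }
        job_path.write_text(json.dumps(job))
        proc = subprocess.run(
            [rscript_path(), "--vanilla", str(_RUNNER), str(job_path)],
            capture_output=True, text=True, timeout=timeout,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise Lme4Error(
                f"lme4 fit failed (exit {proc.returncode}).\n"
                f"formula: {formula}\nstderr:\n{proc.stderr[-4000:]}"
            )
        return json.loads(out_path.read_text())
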