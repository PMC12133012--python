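"""Reading and writing the package's delimited-text formats.

Two input formats are understood:

* batch-estimate CSV — header columns ``sbar_mu_hat, lambda_hat``, one row
  per batch in time order (the sufficient input to every chart);
* raw-batch CSV — one row per batch, the m observed failure times ascending,
  no header; the life-test design comes from a sidecar YAML/JSON config
  with keys ``n``, ``m``, ``r`` (and optionally ``baseline``).

Outputs are chart-trace CSVs (step, statistic, signal) and JSON summaries.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .baselines import BaselineSurvival, get_baseline
from .charts import ChartRun, ChartSpec
from .model import BatchEstimate, CensoringScheme, ICSpec, ProgressiveSample, mle

PathLike = Union[str, Path]


def read_batch_estimates(path: PathLike) -> List[BatchEstimate]:
    """Read a batch-estimate CSV (columns sbar_mu_hat, lambda_hat)."""
    df = pd.read_csv(path)
    missing = {"sbar_mu_hat", "lambda_hat"} - set(df.columns)
    if missing:
        raise ValueError(f"batch-estimate CSV lacks columns {sorted(missing)}")
    return [
        BatchEstimate(float(a), float(b))
        for a, b in zip(df["sbar_mu_hat"], df["lambda_hat"])
    ]


def write_batch_estimates(path: PathLike, batches: Sequence[BatchEstimate]) -> None:
    pd.DataFrame(
        {
            "sbar_mu_hat": [b.sbar_mu_hat for b in batches],
            "lambda_hat": [b.lambda_hat for b in batches],
        }
    ).to_csv(path, index=False)


def read_raw_batches(path: PathLike, m: int) -> List[ProgressiveSample]:
    """Read a raw-batch CSV: one row per batch, m ascending failure times."""
    df = pd.read_csv(path, header=None)
    if df.shape[1] != m:
        raise ValueError(f"expected {m} failure times per row, got {df.shape[1]}")
    return [ProgressiveSample(tuple(row)) for row in df.to_numpy(dtype=float)]


def read_scheme_config(path: PathLike) -> Dict:
    """Parse a YAML/JSON sidecar config; must contain keys n, m, r."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    for key in ("n", "m", "r"):
        if key not in cfg:
            raise ValueError(f"scheme config missing key {key!r}")
    cfg["scheme"] = CensoringScheme(int(cfg["n"]), int(cfg["m"]), tuple(cfg["r"]))
    return cfg


def baseline_from_config(cfg: Dict) -> BaselineSurvival:
    """Resolve the baseline named in a config (default exponential)."""
    spec = cfg.get("baseline", "exponential")
    if isinstance(spec, str):
        return get_baseline(spec)
    name = spec.pop("name")
    return get_baseline(name, **spec)


def estimates_from_raw(
    samples: Sequence[ProgressiveSample],
    scheme: CensoringScheme,
    baseline: BaselineSurvival,
) -> List[BatchEstimate]:
    """Per-batch MLEs for a sequence of raw censored batches."""
    return [mle(s, scheme, baseline) for s in samples]


def write_chart_run(path: PathLike, run: ChartRun) -> None:
    """Write a chart trace CSV with columns step, statistic, signal (0/1)."""
    stats = np.asarray(run.statistics)
    pd.DataFrame(
        {
            "step": np.arange(1, stats.size + 1),
            "statistic": stats,
            "signal": (stats > run.h).astype(int),
        }
    ).to_csv(path, index=False)


def chart_run_summary(run: ChartRun, spec: ChartSpec) -> Dict:
    """JSON-ready summary of one chart run."""
    return {
        "kind": run.kind,
        "gamma": spec.gamma,
        "h": run.h,
        "start": None if spec.kind == "WL" else spec.start,
        "n_batches": len(run.statistics),
        "first_signal": run.first_signal,
    }


def write_json(path: PathLike, obj: Dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_ic(cfg: Dict) -> ICSpec:
    """ICSpec from a config mapping with keys sbar_mu0, lambda0."""
    ic = cfg["ic"] if "ic" in cfg else cfg
    return ICSpec(float(ic["sbar_mu0"]), float(ic["lambda0"]))
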