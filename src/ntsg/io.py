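"""File I/O and fixture generation.

Lifetime data comes as one numeric column in CSV/TSV/whitespace text with an
optional header; results are written as JSON and flat CSV.  The 128 published
survival times (in months) that anchor the worked examples ship with the
package as ``data/survival_times.csv``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .chart import SubgroupCounts, make_design, ChartConfig, p_fail
from .fitting import FitResult, LifetimeSample
from .weibull import NtsWeibullParams, ntsw_sample

__all__ = [
    "read_lifetimes",
    "load_survival_times",
    "make_fixture",
    "write_fit_result",
    "read_counts",
    "write_counts",
]

_FIXTURES = ("table4", "ntsw_sample", "incontrol_counts", "shifted_counts")


def read_lifetimes(path, label: Optional[str] = None) -> LifetimeSample:
    """Read a one-column lifetime sample from CSV/TSV/whitespace text.

    A single leading non-numeric line is treated as a header.  Non-numeric
    rows and nonpositive values are rejected with their line numbers.
    """
    path = Path(path)
    values = []
    bad_lines = []
    nonpos_lines = []
    with path.open() as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        first_tokens = lines[0].replace(",", " ").replace("\t", " ").split()
        if first_tokens and not _all_numeric(first_tokens):
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        tokens = line.replace(",", " ").replace("\t", " ").split()
        if not tokens:
            continue
        if not _all_numeric(tokens):
            bad_lines.append(lineno)
            continue
        for tok in tokens:
            v = float(tok)
            if v <= 0.0:
                nonpos_lines.append(lineno)
            values.append(v)
    if bad_lines:
        raise ValueError(f"non-numeric rows at lines {bad_lines} in {path}")
    if nonpos_lines:
        raise ValueError(f"nonpositive lifetimes at lines {nonpos_lines} in {path}")
    if not values:
        raise ValueError(f"no numeric data found in {path}")
    return LifetimeSample(np.array(values), label=label or path.stem)


def _all_numeric(tokens) -> bool:
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            return False
    return True


def load_survival_times() -> LifetimeSample:
    """The bundled 128 published survival times (months)."""
    with resources.files("ntsg.data").joinpath("survival_times.csv").open() as fh:
        values = [float(line) for line in fh.readlines()[1:] if line.strip()]
    return LifetimeSample(np.array(values), label="survival_times")


def write_fit_result(fit: FitResult, json_path=None, csv_path=None) -> None:
    """Persist a fit as JSON (full precision) and/or one-row flat CSV."""
    if json_path is not None:
        Path(json_path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
    if csv_path is not None:
        row: Dict[str, object] = {"model": fit.model, "loglik": fit.loglik,
                                  "converged": fit.converged}
        row.update(fit.estimates)
        pd.DataFrame([row]).to_csv(csv_path, index=False)


def read_counts(path) -> pd.DataFrame:
    """Read a subgroup failure-count series (columns: subgroup_id, D)."""
    df = pd.read_csv(path)
    if df.shape[1] == 1:
        df.columns = ["D"]
        df.insert(0, "subgroup_id", np.arange(1, len(df) + 1))
    else:
        df = df.iloc[:, :2]
        df.columns = ["subgroup_id", "D"]
    return df


def write_counts(counts: SubgroupCounts, path) -> None:
    pd.DataFrame(
        {"subgroup_id": np.arange(1, counts.counts.size + 1), "D": counts.counts}
    ).to_csv(path, index=False)


def make_fixture(name: str, seed: int, outdir, **options) -> Path:
    """Write a named data fixture and return its path.

    * ``table4`` — the bundled 128 survival times, verbatim.
    * ``ntsw_sample`` — seeded draws from the amplified Weibull
      (options: ``delta``, ``alpha``, ``lambda_``, ``m``; defaults
      2.5, 2.2, 1.5, 200).
    * ``incontrol_counts`` — seeded binomial subgroup failure counts under an
      in-control chart design (options: ``n``, ``delta``, ``lambda_``, ``q``,
      ``k``, ``tau``, ``n_subgroups``; defaults are the n=30 design with
      k=2.981, tau=0.948).
    * ``shifted_counts`` — same, with a life-scale shift ``c`` (default 2.0).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "table4":
        path = outdir / "table4.csv"
        sample = load_survival_times()
        pd.DataFrame({"time": sample.values}).to_csv(path, index=False)
        return path
    if name == "ntsw_sample":
        p = NtsWeibullParams(
            delta=options.get("delta", 2.5),
            alpha=options.get("alpha", 2.2),
            lambda_=options.get("lambda_", 1.5),
        )
        m = int(options.get("m", 200))
        path = outdir / "ntsw_sample.csv"
        pd.DataFrame({"time": ntsw_sample(m, p, seed)}).to_csv(path, index=False)
        return path
    if name in ("incontrol_counts", "shifted_counts"):
        n = int(options.get("n", 30))
        cfg = ChartConfig(
            n=n,
            delta=options.get("delta", 2.5),
            lambda_=options.get("lambda_", 1.5),
            r0=options.get("r0", 370.0),
            q=options.get("q", 0.5),
        )
        design = make_design(cfg, k=options.get("k", 2.981), tau=options.get("tau", 0.948))
        c = float(options.get("c", 2.0)) if name == "shifted_counts" else 1.0
        p = p_fail(design.tau, cfg.delta, cfg.lambda_, cfg.q, c=c)
        n_sub = int(options.get("n_subgroups", 50))
        rng = np.random.default_rng(seed)
        counts = SubgroupCounts(counts=rng.binomial(n, p, size=n_sub), n=n)
        path = outdir / f"{name}.csv"
        write_counts(counts, path)
        return path
    raise ValueError(f"unknown fixture {name!r}; choose from {_FIXTURES}")
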