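"""Benchmark statistics: Pearson correlation and mean unsigned error between
experimental and predicted ddG tables, plus tabular report rendering."""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BenchmarkReport", "pearson_r", "mue", "benchmark_report",
           "render_text", "render_csv", "parse_csv"]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; requires n >= 3 and nonzero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(x, y).statistic)


def mue(exp, pred) -> float:
    """Mean unsigned error |pred - exp| in kcal/mol."""
    exp = np.asarray(exp, float)
    pred = np.asarray(pred, float)
    if exp.shape != pred.shape:
        raise ValueError("length mismatch")
    if len(exp) == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(pred - exp)))


@dataclass
class BenchmarkReport:
    method: str
    n: int
    pearson_r: float
    mue: float
    table: pd.DataFrame      # columns exp, pred, abs_error


def benchmark_report(tables: dict) -> list[BenchmarkReport]:
    """One report per method from ``{method: (exp, pred)}`` tables."""
    if not tables:
        raise ValueError("need at least one method table")
    out = []
    for method, (exp, pred) in tables.items():
        exp = np.asarray(exp, float)
        pred = np.asarray(pred, float)
        df = pd.DataFrame({"exp": exp, "pred": pred,
                           "abs_error": np.abs(pred - exp)})
        out.append(BenchmarkReport(method=method, n=len(exp),
                                   pearson_r=pearson_r(exp, pred),
                                   mue=mue(exp, pred), table=df))
    return out


def render_text(reports: list[BenchmarkReport]) -> str:
    lines = [f"{'method':<24s} {'n':>4s} {'pearson_r':>10s} {'MUE (kcal/mol)':>15s}"]
    for r in reports:
        lines.append(f"{r.method:<24s} {r.n:>4d} {r.pearson_r:>10.4f} {r.mue:>15.4f}")
    return "\n".join(lines) + "\n"


def render_csv(reports: list[BenchmarkReport]) -> str:
    df = pd.DataFrame([{"method": r.method, "n": r.n,
                        "pearson_r": r.pearson_r, "mue": r.mue}
                       for r in reports])
    return df.to_csv(index=False, float_format="%.10g")


def parse_csv(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text))
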