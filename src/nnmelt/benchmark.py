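"""Benchmark harness: compare predictions against experimental tables.

Reads a tab-separated table with a header line; required columns are
``sequence`` and ``tm_exp`` (deg C).  Optional columns override the shared
environment per row: ``seq2``, ``Na``, ``K``, ``Tris``, ``Mg``, ``dNTP``,
``CT``.  Each row is run through the full computation pipeline and the
relative error (Tm_computed - Tm_exp) / Tm_exp is reported, so published
accuracy tables can be reproduced by whoever holds the experimental data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

from .corrections import Environment, error_margin
from .sequences import build_duplex
from .tm_engines import Options, compute

_ENV_COLUMNS = ("Na", "K", "Tris", "Mg", "dNTP", "CT")


@dataclass(frozen=True)
class BenchmarkRow:
    sequence: str
    tm_experimental: float
    tm_computed: float
    error: float    # fractional, per the harness definition


def evaluate(table: str | Path, env: Environment,
             options: Options | None = None) -> list[BenchmarkRow]:
    """Run every row of a benchmark table; returns per-row errors."""
    rows: list[BenchmarkRow] = []
    with open(table, newline="") as fh:
        for record in csv.DictReader(fh, delimiter="\t"):
            overrides = {c: float(record[c]) for c in _ENV_COLUMNS
                         if record.get(c)}
            row_env = replace(env, **overrides) if overrides else env
            duplex = build_duplex(record["sequence"], record.get("seq2") or None,
                                  row_env.hybridization)
            result = compute(duplex, row_env, options)
            tm_exp = float(record["tm_exp"])
            rows.append(BenchmarkRow(
                sequence=record["sequence"],
                tm_experimental=tm_exp,
                tm_computed=result.tm,
                error=error_margin(result.tm, tm_exp),
            ))
    return rows


def mean_absolute_error_percent(rows: list[BenchmarkRow]) -> float:
    """Mean |relative error| as a percentage, the usual summary figure."""
    if not rows:
        raise ValueError("no benchmark rows")
    return 100.0 * sum(abs(r.error) for r in rows) / len(rows)
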