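"""Tabular input/output for per-locus allele frequency data.

The on-disk format is a CSV/TSV with a header and the columns
``population, locus, allele, N`` plus either ``frequency`` (sample allele
frequencies) or ``count`` (allele copy counts).  N is the number of
sampled diploid individuals and must be constant within a population.
Frequencies are converted to integer copy counts ``round(2N * f)``
(round-half-to-even); published tables are often rounded, so per-locus
frequency sums may miss 1 by up to 1e-6 * 2N in count units, which is
tolerated and logged, whereas copy counts must sum to exactly 2N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError, TableSumError

__all__ = ["FrequencyTable", "read_frequency_table", "write_frequency_table"]

log = logging.getLogger(__name__)

_KEY_COLS = ["population", "locus", "allele", "N"]
_SUM_TOL = 1e-6


@dataclass(frozen=True)
class FrequencyTable:
    """Validated long-format allele count table.

    ``data`` has columns population, locus, allele, N, count, frequency
    (frequency = count / (2N), recomputed after validation).
    """

    data: pd.DataFrame

    def counts(self, population: str, locus: str) -> dict[str, int]:
        sub = self.data[
            (self.data["population"] == population) & (self.data["locus"] == locus)
        ]
        return dict(zip(sub["allele"], sub["count"]))

    def frequencies(self, population: str, locus: str) -> dict[str, float]:
        sub = self.data[
            (self.data["population"] == population) & (self.data["locus"] == locus)
        ]
        return dict(zip(sub["allele"], sub["frequency"]))

    def sample_size(self, population: str) -> int:
        sub = self.data[self.data["population"] == population]
        return int(sub["N"].iloc[0])

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.data["population"]))


def _sniff_sep(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", "tsv"):
        return "," if dialect == "csv" else "\t"
    if dialect is not None:
        raise TableFormatError(f"unknown dialect {dialect!r} (use 'csv' or 'tsv')")
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_frequency_table(path: str | Path, dialect: str | None = None) -> FrequencyTable:
    """Read and validate a frequency/count table from CSV or TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, dialect))
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("population", "locus", "allele", "n") if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required columns: {missing}")
    df = df.rename(columns={"n": "N"})
    has_freq = "frequency" in df.columns
    has_count = "count" in df.columns
    if not has_freq and not has_count:
        raise TableFormatError("need a 'frequency' or 'count' column")

    for col in ["N"] + (["frequency"] if has_freq else []) + (
        ["count"] if has_count else []
    ):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), col].iloc[0]
            raise TableFormatError(f"non-numeric value {bad!r} in column {col!r}")
        df[col] = vals

    for pop, sub in df.groupby("population"):
        if sub["N"].nunique() != 1:
            raise TableFormatError(f"sample size N varies within population {pop!r}")

    rows = []
    for (pop, locus), sub in df.groupby(["population", "locus"], sort=False):
        N = int(sub["N"].iloc[0])
        if sub["allele"].duplicated().any():
            raise TableFormatError(f"duplicate allele rows for {pop!r}/{locus!r}")
        if has_count:
            counts = sub["count"].to_numpy()
            if np.any(counts != np.round(counts)) or counts.min() < 0:
                raise TableFormatError(f"counts must be non-negative integers ({pop!r}/{locus!r})")
            counts = counts.astype(int)
            if counts.sum() != 2 * N:
                raise TableSumError(
                    f"{pop!r}/{locus!r}: counts sum to {counts.sum()}, expected {2 * N}"
                )
        else:
            freqs = sub["frequency"].to_numpy(dtype=float)
            if freqs.min() < 0:
                raise TableFormatError(f"negative frequency in {pop!r}/{locus!r}")
            if abs(freqs.sum() - 1.0) > _SUM_TOL * max(1.0, 2 * N):
                raise TableSumError(
                    f"{pop!r}/{locus!r}: frequencies sum to {freqs.sum():.6f}, not 1"
                )
            if abs(freqs.sum() - 1.0) > 1e-9:
                log.warning(
                    "%s/%s: frequencies sum to %.6f; accepting within tolerance",
                    pop, locus, freqs.sum(),
                )
            # published frequencies are rounded; snap to the copy-count lattice
            counts = np.round(2 * N * freqs).astype(int)  # round-half-to-even
            delta = counts - 2 * N * freqs
            if np.abs(delta).max() > 0:
                log.info(
                    "%s/%s: rounded copy counts by at most %.4g",
                    pop, locus, float(np.abs(delta).max()),
                )
            drift = int(2 * N - counts.sum())
            if drift != 0:
                # attribute residual rounding drift to the largest class
                counts[int(np.argmax(counts))] += drift
                log.info("%s/%s: adjusted largest count by %d to restore sum 2N",
                         pop, locus, drift)
        for allele, count in zip(sub["allele"], counts):
            rows.append((pop, locus, allele, N, int(count), count / (2 * N)))

    out = pd.DataFrame(
        rows, columns=["population", "locus", "allele", "N", "count", "frequency"]
    )
    return FrequencyTable(out)


def write_frequency_table(
    table: FrequencyTable, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a validated table; round-trips through the reader exactly."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise TableFormatError(f"unknown dialect {dialect!r}")
    table.data.to_csv(path, sep=sep, index=False)
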