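"""Two-year GC-MS volatiles table: data model, I/O, class profiling and
retention-index arithmetic.

The packaged dataset covers the volatile fraction of *Marrubium vulgare*
sampled in two consecutive growing seasons (2019, 2020).  Each record holds
the compound name, its compound-class code, the train/test/validation cycle
used for retention-index modeling, the experimental retention index (RI) and
relative FID percentage for each year, and a SMILES string for identified
structures.  Relative amounts reported below the chromatographic
quantitation limit are stored as a *trace* flag rather than a number.

Retention indices follow the linear (van den Dool) convention relative to a
C8-C32 n-alkane ladder, the appropriate form for temperature-programmed GC.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TRACE_TOKEN",
    "CLASS_CODES",
    "CYCLES",
    "CompoundRecord",
    "VolatilesTable",
    "AlkaneLadder",
    "load_table",
    "write_table",
    "packaged_table_path",
    "class_profile",
    "top_compounds",
    "kovats_ri",
    "area_normalize",
]

#: reserved token for sub-quantitation-limit percentages in the CSV fixture
TRACE_TOKEN = "trace"

#: compound-class codes: oxygenated monoterpenes, sesquiterpene hydrocarbons,
#: oxygenated sesquiterpenes, oxygenated diterpenes, triterpenes, aromatics,
#: alkanes, other aliphatics/miscellaneous, and not-identified peaks
CLASS_CODES = ("OMN", "ST", "OST", "OD", "T", "AR", "A", "O", "NI")

CYCLES = ("Train", "Test", "Validation")

YEARS = (2019, 2020)

_FIXTURE_COLUMNS = [
    "row_index", "name", "class", "cycle", "ri_pred",
    "ri_2019", "pct_2019", "ri_2020", "pct_2020", "smiles",
]


def _round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed table precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompoundRecord:
    """One chromatographic peak of the two-year table."""

    row_index: int
    name: str
    compound_class: str
    cycle: str | None = None
    ri_pred: float | None = None
    ri_2019: float | None = None
    pct_2019: float | None = None
    trace_2019: bool = False
    ri_2020: float | None = None
    pct_2020: float | None = None
    trace_2020: bool = False
    smiles: str | None = None

    def __post_init__(self) -> None:
        loc = f"row {self.row_index} ({self.name!r})"
        if self.compound_class not in CLASS_CODES:
            raise ValueError(f"{loc}: unknown class code {self.compound_class!r}")
        if self.cycle is not None and self.cycle not in CYCLES:
            raise ValueError(f"{loc}: unknown cycle {self.cycle!r}")
        for pct in (self.pct_2019, self.pct_2020):
            if pct is not None and pct < 0:
                raise ValueError(f"{loc}: negative percentage {pct}")
        if not (self.observed(2019) or self.observed(2020)):
            raise ValueError(f"{loc}: no observation in either year")
        if self.compound_class == "NI" and (self.smiles or self.ri_pred is not None):
            raise ValueError(f"{loc}: NI records carry no structure or predicted RI")

    def observed(self, year: int) -> bool:
        """Whether the compound was detected at all in ``year``."""
        if year == 2019:
            return self.ri_2019 is not None or self.pct_2019 is not None or self.trace_2019
        if year == 2020:
            return self.ri_2020 is not None or self.pct_2020 is not None or self.trace_2020
        raise ValueError(f"unknown year {year}")

    def ri(self, year: int) -> float | None:
        return self.ri_2019 if year == 2019 else self.ri_2020

    def percent(self, year: int, trace_policy: str = "zero") -> float | None:
        """Relative percentage for ``year``.

        ``trace_policy`` controls trace-flagged cells: ``"zero"`` counts them
        as 0.0 (the convention consistent with the table's printed totals),
        ``"exclude"`` returns None for them.
        """
        if year == 2019:
            pct, trace = self.pct_2019, self.trace_2019
        elif year == 2020:
            pct, trace = self.pct_2020, self.trace_2020
        else:
            raise ValueError(f"unknown year {year}")
        if pct is not None:
            return pct
        if trace:
            return 0.0 if trace_policy == "zero" else None
        return None

    @property
    def identified(self) -> bool:
        return self.compound_class != "NI"


@dataclass(frozen=True)
class VolatilesTable:
    """Ordered collection of :class:`CompoundRecord` covering both years."""

    records: tuple[CompoundRecord, ...]
    years: tuple[int, ...] = YEARS

    def __post_init__(self) -> None:
        idx = [r.row_index for r in self.records]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise ValueError(f"duplicate row_index values: {dupes}")
        if idx and idx != list(range(1, len(idx) + 1)):
            raise ValueError("row_index values must be contiguous starting at 1")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, row_index: int) -> CompoundRecord:
        return self.records[row_index - 1]

    def identified(self) -> tuple[CompoundRecord, ...]:
        return tuple(r for r in self.records if r.identified)

    def modeled(self, year: int) -> tuple[CompoundRecord, ...]:
        """Identified compounds with an experimental RI and a structure in
        ``year`` -- the subset entering QSRR modeling."""
        return tuple(
            r for r in self.records
            if r.identified and r.smiles and r.ri(year) is not None
        )


def packaged_table_path() -> Path:
    """Path of the packaged two-year volatiles CSV."""
    return Path(__file__).parent / "data" / "marrubium_table1.csv"


def _parse_cell(raw: str, row_id: str, col: str) -> tuple[float | None, bool]:
    raw = raw.strip()
    if not raw:
        return None, False
    if raw.lower() == TRACE_TOKEN:
        return None, True
    try:
        return float(raw), False
    except ValueError:
        raise ValueError(f"{row_id}: cannot parse {col}={raw!r}") from None


def load_table(path: str | Path | None = None) -> VolatilesTable:
    """Read a volatiles table CSV; defaults to the packaged dataset.

    Raises :class:`ValueError` naming the offending row for duplicate row
    indices, unknown class codes or negative percentages.
    """
    path = packaged_table_path() if path is None else Path(path)
    records: list[CompoundRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_FIXTURE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            row_id = f"{path.name} line {lineno}"
            idx = int(row["row_index"])
            pct19, tr19 = _parse_cell(row["pct_2019"], row_id, "pct_2019")
            pct20, tr20 = _parse_cell(row["pct_2020"], row_id, "pct_2020")
            ri19, _ = _parse_cell(row["ri_2019"], row_id, "ri_2019")
            ri20, _ = _parse_cell(row["ri_2020"], row_id, "ri_2020")
            rip, _ = _parse_cell(row["ri_pred"], row_id, "ri_pred")
            records.append(CompoundRecord(
                row_index=idx,
                name=row["name"],
                compound_class=row["class"].strip(),
                cycle=row["cycle"].strip() or None,
                ri_pred=rip,
                ri_2019=ri19, pct_2019=pct19, trace_2019=tr19,
                ri_2020=ri20, pct_2020=pct20, trace_2020=tr20,
                smiles=row["smiles"].strip() or None,
            ))
    return VolatilesTable(records=tuple(records))


def write_table(table: VolatilesTable, path: str | Path) -> None:
    """Write a table back to CSV; inverse of :func:`load_table` on the
    packaged fixture (lossless round trip)."""
    def fmt_pred(x):
        return "" if x is None else f"{x:.3f}"

    def fmt_ri(x):
        return "" if x is None else (f"{int(x)}" if float(x).is_integer() else f"{x:g}")

    def fmt_pct(p, trace):
        if trace:
            return TRACE_TOKEN
        return "" if p is None else f"{p:.1f}"

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_FIXTURE_COLUMNS)
        for r in table:
            w.writerow([
                r.row_index, r.name, r.compound_class, r.cycle or "",
                fmt_pred(r.ri_pred),
                fmt_ri(r.ri_2019), fmt_pct(r.pct_2019, r.trace_2019),
                fmt_ri(r.ri_2020), fmt_pct(r.pct_2020, r.trace_2020),
                r.smiles or "",
            ])


def class_profile(
    table: VolatilesTable, year: int, trace_policy: str = "zero"
) -> dict[str, float]:
    """Per-class sums of the printed relative percentages for ``year``.

    Every class code maps to a value (0.0 when absent); sums are rounded
    half-up to one decimal, the table's display precision.
    """
    if year not in table.years:
        raise ValueError(f"year {year} not covered by table")
    sums = {c: 0.0 for c in CLASS_CODES}
    for r in table:
        pct = r.percent(year, trace_policy=trace_policy)
        if pct is not None:
            sums[r.compound_class] += pct
    return {c: _round_half_up(v, 1) for c, v in sums.items()}


def top_compounds(
    table: VolatilesTable, year: int, n: int
) -> list[tuple[str, float]]:
    """The ``n`` most abundant peaks in ``year`` as (name, percent), ranked
    by percent descending with ties broken by row order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    entries = []
    for r in table:
        pct = r.percent(year, trace_policy="zero")
        if pct is not None:
            entries.append((r.name, pct, r.row_index))
    entries.sort(key=lambda t: (-t[1], t[2]))
    return [(name, pct) for name, pct, _ in entries[:n]]


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times (minutes) of the C8-C32 n-alkane reference series."""

    carbon_numbers: tuple[int, ...]
    retention_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.carbon_numbers) != len(self.retention_times):
            raise ValueError("carbon_numbers and retention_times length mismatch")
        if len(self.carbon_numbers) < 2:
            raise ValueError("a ladder needs at least two alkanes")
        cs = self.carbon_numbers
        if any(c < 8 or c > 32 for c in cs):
            raise ValueError("carbon numbers must lie in 8..32")
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        ts = self.retention_times
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("retention times must increase strictly with carbon number")

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "AlkaneLadder":
        items = sorted(mapping.items())
        return cls(tuple(c for c, _ in items), tuple(t for _, t in items))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlkaneLadder":
        """Two-column CSV: carbon_number, rt_min (header optional)."""
        mapping: dict[int, float] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or not row[0].strip():
                    continue
                try:
                    c = int(row[0])
                except ValueError:
                    continue  # header line
                mapping[c] = float(row[1])
        return cls.from_mapping(mapping)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["carbon_number", "rt_min"])
            for c, t in zip(self.carbon_numbers, self.retention_times):
                w.writerow([c, f"{t:g}"])

    @property
    def span(self) -> tuple[float, float]:
        return self.retention_times[0], self.retention_times[-1]


def kovats_ri(rt: float, ladder: AlkaneLadder) -> float:
    """Linear (van den Dool) retention index of a peak at ``rt`` minutes.

    RI = 100 * (n + (rt - t_n) / (t_{n+1} - t_n)) with t_n <= rt <= t_{n+1};
    no extrapolation outside the ladder span.
    """
    lo, hi = ladder.span
    if not (lo <= rt <= hi):
        raise ValueError(
            f"retention time {rt} min outside ladder span [{lo}, {hi}]")
    ts = ladder.retention_times
    cs = ladder.carbon_numbers
    i = bisect_right(ts, rt) - 1
    if i == len(ts) - 1:  # exactly the last rung
        return 100.0 * cs[-1]
    c_lo, c_hi = cs[i], cs[i + 1]
    t_lo, t_hi = ts[i], ts[i + 1]
    return 100.0 * (c_lo + (c_hi - c_lo) * (rt - t_lo) / (t_hi - t_lo))


def area_normalize(areas: Sequence[float] | np.ndarray) -> np.ndarray:
    """FID peak-area normalization: each area as a percent of the total."""
    a = np.asarray(areas, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("areas must be a non-empty 1-D sequence")
    if np.any(a < 0):
        raise ValueError("peak areas must be non-negative")
    total = a.sum()
    if total == 0:
        raise ValueError("all peak areas are zero")
    return a * (100.0 / total)
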