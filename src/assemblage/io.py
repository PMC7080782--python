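"""Domain containers and delimited-text readers/writers.

The canonical on-disk format for abundances is a long (tidy) TSV with
columns ``microcosm_id, treatment, day, asv_id, count``; wide
timepoint-by-ASV matrices exist only in memory.  Function (substrate-use),
CO2 and enzyme-activity tables are plain CSV.  All writers emit a
``# assemblage-schema: <name> v1`` comment line so files are
self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("filtered", "unfiltered")

SCHEMA_PREFIX = "# assemblage-schema:"


class ParseError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass
class MicrocosmSeries:
    """One microcosm's ASV abundance matrix over ordered timepoints.

    ``counts`` has shape (n_timepoints, n_asvs); ``rel_abundance`` is the
    row-normalized version (rows with zero total stay all-zero and are
    flagged in :meth:`zero_read_timepoints`).
    """

    microcosm_id: str
    inoculum_id: str
    treatment: str
    days: np.ndarray
    asv_ids: list[str]
    counts: np.ndarray
    rel_abundance: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.counts = np.asarray(self.counts)
        self.asv_ids = list(self.asv_ids)
        if self.rel_abundance is None:
            self.rel_abundance = relative_abundance(self.counts)
        else:
            self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)

    @property
    def label(self) -> str:
        """Short unique sample label, e.g. ``M03-F``; keys function/CO2 rows."""
        return f"{self.microcosm_id}-{self.treatment[0].upper()}"

    @property
    def n_timepoints(self) -> int:
        return len(self.days)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def zero_read_timepoints(self) -> np.ndarray:
        """Indices of retained-but-flagged timepoints with zero total reads."""
        return np.flatnonzero(self.counts.sum(axis=1) == 0)

    def transfer_indices(self, interval: int = 3) -> np.ndarray:
        """Transfer index per timepoint (day 0 -> 0, the pre-transfer inoculum)."""
        return self.days // interval


@dataclass
class Experiment:
    """A collection of microcosm series sharing one transfer design."""

    series: list[MicrocosmSeries]
    transfer_interval_days: int = 3
    n_transfers: int = 21

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    def get(self, microcosm_id: str, treatment: str) -> MicrocosmSeries:
        for s in self.series:
            if s.microcosm_id == microcosm_id and s.treatment == treatment:
                return s
        raise KeyError((microcosm_id, treatment))

    def day_for_transfer(self, t: int) -> int:
        return t * self.transfer_interval_days


@dataclass
class FunctionProfileTable:
    """Water-subtracted substrate responses, one row per (microcosm, day)."""

    index: list[tuple[str, int]]
    substrate_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def row(self, microcosm_id: str, day: int) -> np.ndarray:
        return self.values[self.index.index((microcosm_id, day))]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.index, names=["microcosm_id", "day"])
        return pd.DataFrame(self.values, index=idx, columns=self.substrate_ids)


@dataclass
class Co2Table:
    """Percent CO2 respiration, one row per (microcosm, day)."""

    index: list[tuple[str, int]]
    percent_co2: np.ndarray

    def __post_init__(self) -> None:
        self.percent_co2 = np.asarray(self.percent_co2, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.index, names=["microcosm_id", "day"])
        return pd.DataFrame({"percent_co2": self.percent_co2}, index=idx)


@dataclass
class ActivityTable:
    """Per-ASV enzyme activities (units/mL), strain replicates pre-averaged."""

    asv_ids: list[str]
    activities: pd.DataFrame  # columns: enzyme classes

    ENZYMES = ("endochitinase", "protease", "lipase")

    def activity(self, asv_id: str, enzyme: str) -> float:
        if asv_id not in self.activities.index:
            return 0.0
        return float(self.activities.loc[asv_id, enzyme])


def relative_abundance(counts: np.ndarray) -> np.ndarray:
    """Total-sum scaling per row; all-zero rows remain all-zero."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, counts / np.where(totals == 0, 1.0, totals), 0.0)
    return rel


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, sep) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str)


def read_abundance_long(path) -> Experiment:
    """Read the long-format abundance TSV into an :class:`Experiment`.

    Missing (day, asv) cells are zero.  Duplicated
    (microcosm, treatment, day, asv) rows or negative counts raise
    :class:`ParseError` naming the offending row.
    """
    df = _read_table(path, "\t")
    required = ["microcosm_id", "treatment", "day", "asv_id", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"malformed header: missing columns {missing}")
    inoculum_col = "inoculum_id" if "inoculum_id" in df.columns else None
    df["day"] = df["day"].astype(int)
    df["count"] = df["count"].astype(float)
    if (df["count"] < 0).any():
        row = int(df.index[df["count"] < 0][0])
        raise ParseError(f"negative count at data row {row}")
    if not np.allclose(df["count"], np.round(df["count"])):
        row = int(df.index[df["count"] != np.round(df["count"])][0])
        raise ParseError(f"non-integer count at data row {row}")
    df["count"] = df["count"].astype(int)
    dup = df.duplicated(subset=["microcosm_id", "treatment", "day", "asv_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ParseError(f"duplicate (microcosm, treatment, day, asv) at data row {row}")
    bad_tr = ~df["treatment"].isin(TREATMENTS)
    if bad_tr.any():
        row = int(df.index[bad_tr][0])
        raise ParseError(f"unknown treatment {df.loc[row, 'treatment']!r} at data row {row}")

    series = []
    for (mid, tr), grp in df.groupby(["microcosm_id", "treatment"], sort=True):
        days = sorted(grp["day"].unique())
        asvs = sorted(grp["asv_id"].unique())
        wide = (
            grp.pivot(index="day", columns="asv_id", values="count")
            .reindex(index=days, columns=asvs)
            .fillna(0)
            .to_numpy(dtype=int)
        )
        inoc = grp[inoculum_col].iloc[0] if inoculum_col else mid
        series.append(
            MicrocosmSeries(
                microcosm_id=mid,
                inoculum_id=inoc,
                treatment=tr,
                days=np.array(days),
                asv_ids=asvs,
                counts=wide,
            )
        )
    return Experiment(series=series)


def write_abundance_long(exp: Experiment, path) -> None:
    """Write an Experiment to long TSV; ``read(write(exp))`` reproduces counts.

    Zero cells are omitted (the reader restores them), except that a
    sampled timepoint with zero total reads is preserved via a single
    explicit zero row so round-trips keep the timepoint.
    """
    rows = []
    for s in exp.series:
        for i, day in enumerate(s.days):
            nz = np.flatnonzero(s.counts[i])
            if len(nz) == 0 and s.n_asvs > 0:
                rows.append((s.microcosm_id, s.inoculum_id, s.treatment, day, s.asv_ids[0], 0))
                continue
            for j in nz:
                rows.append(
                    (s.microcosm_id, s.inoculum_id, s.treatment, day, s.asv_ids[j], int(s.counts[i, j]))
                )
    df = pd.DataFrame(
        rows, columns=["microcosm_id", "inoculum_id", "treatment", "day", "asv_id", "count"]
    )
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} abundance-long v1\n")
        df.to_csv(fh, sep="\t", index=False)


def write_function_table(table: FunctionProfileTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} function-profiles v1\n")
        table.to_frame().to_csv(fh)


def read_function_table(path) -> FunctionProfileTable:
    df = pd.read_csv(path, comment="#")
    df["day"] = df["day"].astype(int)
    index = list(zip(df["microcosm_id"], df["day"]))
    substrates = [c for c in df.columns if c not in ("microcosm_id", "day")]
    return FunctionProfileTable(index=index, substrate_ids=substrates,
                                values=df[substrates].to_numpy(float))


def write_co2_table(table: Co2Table, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} co2 v1\n")
        table.to_frame().to_csv(fh)


def read_co2_table(path) -> Co2Table:
    df = pd.read_csv(path, comment="#")
    df["day"] = df["day"].astype(int)
    return Co2Table(index=list(zip(df["microcosm_id"], df["day"])),
                    percent_co2=df["percent_co2"].to_numpy(float))


def write_activity_table(table: ActivityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} activities v1\n")
        table.activities.rename_axis("asv_id").to_csv(fh)


def read_activity_table(path) -> ActivityTable:
    df = pd.read_csv(path, comment="#", index_col="asv_id")
    return ActivityTable(asv_ids=list(df.index), activities=df)


# ---------------------------------------------------------------------------
# validation


def validate_experiment(exp: Experiment) -> list[str]:
    """Check type invariants; returns human-readable violations (not errors)."""
    violations: list[str] = []
    seen = set()
    for s in exp.series:
        key = (s.microcosm_id, s.treatment)
        if key in seen:
            violations.append(f"{key}: duplicate (microcosm_id, treatment) pair")
        seen.add(key)
        if not np.all(np.diff(s.days) > 0):
            violations.append(f"{key}: days not strictly increasing")
        if s.counts.shape != (len(s.days), len(s.asv_ids)):
            violations.append(f"{key}: counts shape inconsistent with days/asv_ids")
            continue
        if s.rel_abundance.shape != s.counts.shape:
            violations.append(f"{key}: rel_abundance shape inconsistent")
            continue
        if (s.counts < 0).any():
            violations.append(f"{key}: negative counts")
        totals = s.counts.sum(axis=1)
        for i in np.flatnonzero(totals > 0):
            rowsum = s.rel_abundance[i].sum()
            if abs(rowsum - 1.0) > 1e-9:
                violations.append(
                    f"{key}: rel_abundance row {i} (day {s.days[i]}) sums to {rowsum:.6g}, not 1"
                )
            expected = s.counts[i] / totals[i]
            if not np.allclose(s.rel_abundance[i], expected, atol=1e-9):
                violations.append(
                    f"{key}: rel_abundance row {i} (day {s.days[i]}) inconsistent with counts"
                )
    return violations
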