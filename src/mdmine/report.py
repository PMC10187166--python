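"""Aggregation and statistics over a harvest index.

This layer turns an index of datasets and files — plus per-file parse
summaries — into the corpus-level views a curator asks for: per-repository
totals, deposition counts by year, engine distributions, cumulative
distributions of system sizes and frame counts, thermostat x barostat
cross-tabulations, temperature histograms, the production-run time/
resolution split, and a filterable search with TSV export.

Every aggregation is a plain recount over the index tables; sizes are
summed in bytes and converted to decimal gigabytes (1 GB = 10^9 bytes)
once, at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gmx_formats import MdpSummary
from .harvester import HarvestIndex
from .inference import (BAROSTATS, THERMOSTATS, InferenceConfig,
                        default_config, infer_resolution, infer_run_type)

__all__ = [
    "RepositorySummaryRow",
    "Ecdf",
    "CrossTab",
    "tabulate_by_repository",
    "files_per_year",
    "engine_distribution",
    "unknown_extension_top",
    "ecdf",
    "crosstab_thermo_baro",
    "trajectory_share",
    "temperature_histogram",
    "production_time_split",
    "search",
    "export_tsv",
    "round_half_away",
]

GB = 10 ** 9

TRAJECTORY_EXTENSIONS = ("xtc", "trr")

TIME_BANDS = ("<=50 ns", "50 ns - 1 us", ">1 us")
TIME_BAND_EDGES_NS = (50.0, 1000.0)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Table-style repository summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepositorySummaryRow:
    """Per-repository corpus statistics.

    ``loose_file_count`` counts files directly deposited in datasets
    (zip archives included); ``in_zip_file_count`` counts archive members
    recovered from previews; their sum is ``total_file_count``.
    """

    repository: str
    dataset_count: int
    first_date: Optional[str]
    last_date: Optional[str]
    loose_file_count: int
    total_size_gb: float
    zip_file_count: int
    in_zip_file_count: int
    total_file_count: int


def tabulate_by_repository(index: HarvestIndex) -> list[RepositorySummaryRow]:
    """One summary row per repository plus a ``total`` row of column sums.

    Sizes are summed in bytes per repository and converted to decimal GB;
    the totals row sums bytes across repositories before converting, so
    integer columns add up exactly.
    """
    datasets = index.dataset_frame()
    files = index.file_frame()
    repos = sorted(set(datasets["repository"]).union(files["repository"]))
    rows: list[RepositorySummaryRow] = []
    tot = dict.fromkeys(
        ("datasets", "loose", "bytes", "zips", "in_zip", "total"), 0)
    for repo in repos:
        d = datasets[datasets["repository"] == repo]
        f = files[files["repository"] == repo]
        loose = f[~f["from_zip"]]
        in_zip = f[f["from_zip"]]
        n_bytes = int(loose["size_bytes"].fillna(0).sum())
        dates = sorted(x for x in d["created_date"] if x)
        row = RepositorySummaryRow(
            repository=repo,
            dataset_count=len(d),
            first_date=dates[0] if dates else None,
            last_date=dates[-1] if dates else None,
            loose_file_count=len(loose),
            total_size_gb=n_bytes / GB,
            zip_file_count=int((loose["extension"] == "zip").sum()),
            in_zip_file_count=len(in_zip),
            total_file_count=len(f),
        )
        rows.append(row)
        tot["datasets"] += row.dataset_count
        tot["loose"] += row.loose_file_count
        tot["bytes"] += n_bytes
        tot["zips"] += row.zip_file_count
        tot["in_zip"] += row.in_zip_file_count
        tot["total"] += row.total_file_count
    rows.append(RepositorySummaryRow(
        repository="total",
        dataset_count=tot["datasets"],
        first_date=None,
        last_date=None,
        loose_file_count=tot["loose"],
        total_size_gb=tot["bytes"] / GB,
        zip_file_count=tot["zips"],
        in_zip_file_count=tot["in_zip"],
        total_file_count=tot["total"],
    ))
    return rows


def repository_summary_frame(index: HarvestIndex) -> pd.DataFrame:
    """:func:`tabulate_by_repository` as a DataFrame (for export)."""
    return pd.DataFrame([vars(r) for r in tabulate_by_repository(index)])


# ---------------------------------------------------------------------------
# deposition and engine views
# ---------------------------------------------------------------------------

def files_per_year(index: HarvestIndex,
                   by_repository: bool = True) -> pd.Series:
    """Count indexed files under their dataset's deposition year.

    Archive members count the same as loose files.  Returns a Series
    indexed by (year, repository), or by year alone.
    """
    datasets = index.dataset_frame()
    files = index.file_frame()
    if files.empty or datasets.empty:
        return pd.Series(dtype=int)
    dates = datasets.set_index(["repository", "dataset_id"])["created_date"]
    years = files.set_index(["repository", "dataset_id"]).index.map(dates)
    years = pd.Series([int(str(d)[:4]) if d else None for d in years],
                      name="year")
    df = pd.DataFrame({"year": years, "repository": files["repository"].values})
    df = df.dropna(subset=["year"])
    df["year"] = df["year"].astype(int)
    keys = ["year", "repository"] if by_repository else ["year"]
    return df.groupby(keys).size().sort_index()


def _keyword_flags(index: HarvestIndex, config: InferenceConfig) -> dict[tuple[str, str], bool]:
    return {
        (d.repository, d.dataset_id): config.has_md_keyword(d.title, d.description)
        for d in index.datasets
    }


def engine_distribution(index: HarvestIndex,
                        config: Optional[InferenceConfig] = None) -> dict[str, int]:
    """Count files per assigned MD engine, ``"unknown"`` included.

    Counts sum to the total number of indexed files.
    """
    from .inference import assign_engine

    if config is None:
        config = default_config()
    flags = _keyword_flags(index, config)
    counts: dict[str, int] = {}
    for f in index.files:
        engine = assign_engine(f.extension,
                               flags.get((f.repository, f.dataset_id), False),
                               config.engine_rules)
        counts[engine] = counts.get(engine, 0) + 1
    return counts


def unknown_extension_top(index: HarvestIndex, n: int,
                          config: Optional[InferenceConfig] = None
                          ) -> list[tuple[str, int]]:
    """The n most common extensions among engine-unknown files.

    Ties break lexicographically; ``"none"`` (dotless names) is a valid
    bucket.
    """
    from .inference import assign_engine

    if n < 1:
        raise ValueError("n must be >= 1")
    if config is None:
        config = default_config()
    flags = _keyword_flags(index, config)
    counts: dict[str, int] = {}
    for f in index.files:
        engine = assign_engine(f.extension,
                               flags.get((f.repository, f.dataset_id), False),
                               config.engine_rules)
        if engine == "unknown":
            counts[f.extension] = counts.get(f.extension, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass
class Ecdf:
    """Empirical CDF on distinct sorted values."""

    values: np.ndarray
    fractions: np.ndarray

    def __call__(self, x: float) -> float:
        """P(X <= x) under the empirical distribution."""
        idx = np.searchsorted(self.values, x, side="right")
        return 0.0 if idx == 0 else float(self.fractions[idx - 1])


def ecdf(values: Iterable[float]) -> Ecdf:
    """Standard empirical CDF; ties collapse onto distinct values."""
    arr = np.asarray(sorted(values), dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("ecdf() requires finite values")
    if arr.size == 0:
        return Ecdf(values=np.array([]), fractions=np.array([]))
    distinct, counts = np.unique(arr, return_counts=True)
    fractions = np.cumsum(counts) / arr.size
    return Ecdf(values=distinct, fractions=fractions)


@dataclass
class CrossTab:
    """Thermostat x barostat contingency table.

    The ``undefined`` x ``undefined`` cell is the no-coupling group —
    setups that would not be used for production — and is reported
    separately by :attr:`no_coupling_count`.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def no_coupling_count(self) -> int:
        try:
            i = self.row_labels.index("undefined")
            j = self.col_labels.index("undefined")
        except ValueError:
            return 0
        return int(self.counts[i, j])

    def cell(self, thermostat: str, barostat: str) -> int:
        return int(self.counts[self.row_labels.index(thermostat),
                               self.col_labels.index(barostat)])


def crosstab_thermo_baro(summaries: Iterable[MdpSummary]) -> CrossTab:
    """Count (thermostat, barostat) pairs over normalised summaries."""
    rows = tuple(THERMOSTATS) + ("undefined", "unrecognized")
    cols = tuple(BAROSTATS) + ("undefined", "unrecognized")
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    r_idx = {lbl: i for i, lbl in enumerate(rows)}
    c_idx = {lbl: j for j, lbl in enumerate(cols)}
    for s in summaries:
        counts[r_idx[s.thermostat], c_idx[s.barostat]] += 1
    return CrossTab(row_labels=rows, col_labels=cols, counts=counts)


def temperature_histogram(summaries: Iterable[MdpSummary],
                          bin_width_K: float = 2.0) -> dict[float, int]:
    """Histogram of reference temperatures, bins left-closed right-open.

    Bin keys are left edges, multiples of the bin width; files without a
    readable temperature are excluded.
    """
    if bin_width_K <= 0:
        raise ValueError("bin width must be positive")
    hist: dict[float, int] = {}
    for s in summaries:
        if s.ref_t_K is None:
            continue
        left = math.floor(s.ref_t_K / bin_width_K) * bin_width_K
        hist[left] = hist.get(left, 0) + 1
    return dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# headline shares and splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryShare:
    trajectory_count: int
    gromacs_count: int
    fraction: float
    percent: int


def trajectory_share(index: HarvestIndex,
                     config: Optional[InferenceConfig] = None) -> TrajectoryShare:
    """Fraction of Gromacs-assigned files that are trajectories (.xtc/.trr).

    Raises
    ------
    ZeroDivisionError
        When the index holds no Gromacs-assigned file.
    """
    from .inference import assign_engine

    if config is None:
        config = default_config()
    flags = _keyword_flags(index, config)
    gromacs = trajectories = 0
    for f in index.files:
        engine = assign_engine(f.extension,
                               flags.get((f.repository, f.dataset_id), False),
                               config.engine_rules)
        if engine == "gromacs":
            gromacs += 1
            if f.extension in TRAJECTORY_EXTENSIONS:
                trajectories += 1
    if gromacs == 0:
        raise ZeroDivisionError("no Gromacs-assigned files; share undefined")
    fraction = trajectories / gromacs
    return TrajectoryShare(trajectory_count=trajectories, gromacs_count=gromacs,
                           fraction=fraction,
                           percent=round_half_away(100.0 * fraction))


def production_time_split(summaries: Iterable[MdpSummary]
                          ) -> pd.DataFrame:
    """Count production setups by resolution and planned-time band.

    Bands: <=50 ns (closed at 50), 50 ns - 1 us (closed at 1000), >1 us.
    Only files labelled production (md/sd integrator, time above 1 ns)
    contribute; resolution comes from the time-step cutoff.
    """
    resolutions = ("all-atom", "coarse-grain", "unknown")
    table = pd.DataFrame(0, index=list(resolutions), columns=list(TIME_BANDS))
    for s in summaries:
        if infer_run_type(s) != "production":
            continue
        t = s.sim_time_ns
        if t <= TIME_BAND_EDGES_NS[0]:
            band = TIME_BANDS[0]
        elif t <= TIME_BAND_EDGES_NS[1]:
            band = TIME_BANDS[1]
        else:
            band = TIME_BANDS[2]
        table.loc[infer_resolution(s.dt_ps), band] += 1
    return table


# ---------------------------------------------------------------------------
# search / filter / export
# ---------------------------------------------------------------------------

def search(index: HarvestIndex,
           text_query: Optional[str] = None,
           repository: Optional[str] = None,
           engine: Optional[str] = None,
           extension: Optional[str] = None,
           date_range: Optional[tuple[Optional[str], Optional[str]]] = None,
           n_particles_range: Optional[tuple[Optional[float], Optional[float]]] = None,
           sim_time_range_ns: Optional[tuple[Optional[float], Optional[float]]] = None,
           gro_summaries: Optional[pd.DataFrame] = None,
           mdp_summaries: Optional[pd.DataFrame] = None,
           config: Optional[InferenceConfig] = None) -> pd.DataFrame:
    """Conjunctive keyword-and-filter search over the index.

    ``text_query`` matches case-insensitively over dataset title and
    description.  Numeric range filters need the corresponding summary
    table (``n_particles`` per .gro file, ``sim_time_ns`` per .mdp file)
    keyed by (repository, dataset_id, file_name).  With no predicates the
    whole file table is returned.  Ordering is deterministic:
    (repository, dataset_id, file_name).
    """
    from .inference import assign_engine

    if config is None:
        config = default_config()
    files = index.file_frame()
    datasets = index.dataset_frame()
    merged = files.merge(
        datasets[["repository", "dataset_id", "title", "description",
                  "created_date"]],
        on=["repository", "dataset_id"], how="left")

    mask = pd.Series(True, index=merged.index)
    if text_query:
        blob = (merged["title"].fillna("") + " "
                + merged["description"].fillna("")).str.lower()
        for token in text_query.lower().split():
            mask &= blob.str.contains(token, regex=False)
    if repository is not None:
        mask &= merged["repository"] == repository
    if extension is not None:
        mask &= merged["extension"] == extension.lower().lstrip(".")
    if engine is not None:
        flags = _keyword_flags(index, config)
        engines = [
            assign_engine(ext, flags.get((repo, ds), False), config.engine_rules)
            for repo, ds, ext in zip(merged["repository"], merged["dataset_id"],
                                     merged["extension"])
        ]
        mask &= pd.Series(engines, index=merged.index) == engine
    if date_range is not None:
        lo, hi = date_range
        if lo is not None:
            mask &= merged["created_date"] >= lo
        if hi is not None:
            mask &= merged["created_date"] <= hi

    key = ["repository", "dataset_id", "file_name"]
    for spec, table, column in ((n_particles_range, gro_summaries, "n_particles"),
                                (sim_time_range_ns, mdp_summaries, "sim_time_ns")):
        if spec is None:
            continue
        if table is None:
            raise ValueError(f"a summary table with {column!r} is required "
                             f"for this range filter")
        lo, hi = spec
        sub = merged.merge(table[key + [column]], on=key, how="left")
        value = sub[column]
        cond = value.notna()
        if lo is not None:
            cond &= value >= lo
        if hi is not None:
            cond &= value <= hi
        mask &= cond.values

    result = merged[mask].sort_values(key).reset_index(drop=True)
    return result


def export_tsv(table: pd.DataFrame, destination: Union[str, Path]) -> Path:
    """Write a rectangular table as UTF-8 TSV with a header row.

    Embedded tabs and newlines in free-text cells are replaced by single
    spaces so the file stays strictly rectangular.
    """
    destination = Path(destination)
    sanitized = table.copy()
    for col in sanitized.columns:
        if sanitized[col].dtype == object:
            sanitized[col] = sanitized[col].map(
                lambda v: " ".join(str(v).split("\t")) .replace("\r\n", " ")
                .replace("\n", " ").replace("\r", " ")
                if isinstance(v, str) else v)
    sanitized.to_csv(destination, sep="\t", index=False, encoding="utf-8",
                     lineterminator="\n")
    return destination
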