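"""Containers, IO, validation, filtering and species resolution for
circle-based winter count-survey data.

The unit of observation is one species category counted on one circle in
one year.  A circle-year with no records at all is a *missing survey* and
is semantically distinct from a recorded zero count: missing surveys are
simply absent from the table and are later treated as unobserved by the
model, while zeros enter the Poisson likelihood.

Species categories are ``WEST`` (western grebe), ``CLARK`` (Clark's
grebe) and ``UNID`` (birds reported only to genus, *Aechmophorus* spp.).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import regions as _regions
from .errors import (AllocationWarning, EmptyDatasetError, ParseError,
                     ValidationError)

SPECIES = ("WEST", "CLARK", "UNID")

RECORD_COLUMNS = ["circle_id", "year", "species", "count", "effort_hours",
                  "boat_used"]
CIRCLE_COLUMNS = ["circle_id", "latitude", "longitude", "coast_distance_km",
                  "region"]
CSV_COLUMNS = ["circle_id", "latitude", "longitude", "coast_distance_km",
               "year", "species", "count", "effort_hours", "boat_used"]

# Coverage bins: number of missing survey years per circle.
COVERAGE_BINS = [(0, 0, "complete"), (1, 5, "1-5 missing"),
                 (6, 10, "6-10 missing"), (11, 18, "11-18 missing"),
                 (19, None, ">18 missing")]


@dataclass(frozen=True)
class CountRecord:
    """One survey observation: a species category counted on a circle-year."""

    circle_id: str
    year: int
    species: str
    count: float
    effort_hours: float
    boat_used: int

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species category {self.species!r}")
        if self.count < 0:
            raise ValidationError(
                f"negative count {self.count} for circle {self.circle_id}, "
                f"year {self.year}")
        if not self.effort_hours > 0:
            raise ValidationError(
                f"effort_hours must be positive for circle {self.circle_id}, "
                f"year {self.year}")


@dataclass(frozen=True)
class CircleMeta:
    """Location, coast distance and region assignment of one survey circle."""

    circle_id: str
    latitude: float
    longitude: float
    coast_distance_km: float | None = None
    region: str | None = None

    def __post_init__(self):
        if not -90 <= self.latitude <= 90:
            raise ValidationError(
                f"latitude {self.latitude} out of range for {self.circle_id}")
        d = self.coast_distance_km
        if d is not None and not np.isnan(d) and d < 0:
            raise ValidationError(
                f"negative coast distance for {self.circle_id}")


@dataclass
class SurveyDataset:
    """A validated table of count records plus circle metadata.

    Parameters
    ----------
    records : DataFrame
        Columns ``circle_id, year, species, count, effort_hours, boat_used``;
        at most one row per (circle, year, species).
    circles : DataFrame
        Columns ``circle_id, latitude, longitude, coast_distance_km, region``;
        exactly one row per circle referenced by ``records``.
    year_range : (int, int)
        Inclusive span of survey years the dataset covers.  Circle-years
        inside the span with no records are missing surveys.
    """

    records: pd.DataFrame
    circles: pd.DataFrame
    year_range: tuple[int, int] = None

    def __post_init__(self):
        self.records = self.records.reset_index(drop=True)
        self.circles = self.circles.reset_index(drop=True)
        if self.year_range is None:
            if len(self.records) == 0:
                raise ValidationError("empty dataset needs an explicit year_range")
            self.year_range = (int(self.records.year.min()),
                               int(self.records.year.max()))
        self.year_range = (int(self.year_range[0]), int(self.year_range[1]))
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        rec, circ = self.records, self.circles
        missing = [c for c in RECORD_COLUMNS if c not in rec.columns]
        if missing:
            raise ValidationError(f"records table lacks columns {missing}")
        missing = [c for c in CIRCLE_COLUMNS if c not in circ.columns]
        if missing:
            raise ValidationError(f"circles table lacks columns {missing}")
        if (rec["count"] < 0).any():
            bad = rec.index[rec["count"] < 0].tolist()
            raise ValidationError(f"negative counts at record rows {bad}")
        if not (rec["effort_hours"] > 0).all():
            bad = rec.index[~(rec["effort_hours"] > 0)].tolist()
            raise ValidationError(f"non-positive effort at record rows {bad}")
        if not rec["species"].isin(SPECIES).all():
            bad = sorted(set(rec["species"]) - set(SPECIES))
            raise ValidationError(f"unknown species categories {bad}")
        dup = rec.duplicated(subset=["circle_id", "year", "species"])
        if dup.any():
            raise ValidationError(
                f"duplicate (circle, year, species) rows at {rec.index[dup].tolist()}")
        if circ["circle_id"].duplicated().any():
            raise ValidationError("duplicate circle metadata rows")
        if not (circ["latitude"].between(-90, 90)).all():
            raise ValidationError("circle latitude out of [-90, 90]")
        d = circ["coast_distance_km"]
        if (d.dropna() < 0).any():
            raise ValidationError("negative coast distance")
        unknown = set(rec["circle_id"]) - set(circ["circle_id"])
        if unknown:
            raise ValidationError(f"records reference circles without metadata: "
                                  f"{sorted(unknown)}")
        # Effort and boat flag describe the survey, so they must agree
        # across the species rows of one circle-year.
        per_cy = rec.groupby(["circle_id", "year"])[["effort_hours", "boat_used"]]
        if (per_cy.nunique() > 1).any().any():
            raise ValidationError(
                "inconsistent effort_hours/boat_used within a circle-year")

    # -- basic accessors ------------------------------------------------
    @property
    def n_circles(self) -> int:
        return len(self.circles)

    @property
    def n_years(self) -> int:
        return self.year_range[1] - self.year_range[0] + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)

    def surveyed_years(self) -> pd.Series:
        """Number of distinct years each circle was surveyed."""
        n = self.records.groupby("circle_id")["year"].nunique()
        return n.reindex(self.circles["circle_id"], fill_value=0)

    def total_counts(self) -> pd.Series:
        """Lifetime total count (all species categories) per circle."""
        tot = self.records.groupby("circle_id")["count"].sum()
        return tot.reindex(self.circles["circle_id"], fill_value=0.0)

    # -- model-facing aggregation ---------------------------------------
    def aggregate(self) -> pd.DataFrame:
        """Collapse species rows to one row per surveyed circle-year.

        Counts are summed over species and rounded half-to-even so the
        Poisson likelihood receives integers even after fractional
        species allocation.  Effort and boat flag are carried through.
        """
        g = (self.records.groupby(["circle_id", "year"], as_index=False)
             .agg(count=("count", "sum"),
                  effort_hours=("effort_hours", "first"),
                  boat_used=("boat_used", "first")))
        g["count"] = np.round(g["count"].to_numpy()).astype(np.int64)
        meta = self.circles.set_index("circle_id")
        g["region"] = g["circle_id"].map(meta["region"]).to_numpy()
        g["latitude"] = g["circle_id"].map(meta["latitude"]).to_numpy()
        return g

    # -- IO --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Denormalized single-table view (the CSV dialect)."""
        meta = self.circles.set_index("circle_id")
        out = self.records.copy()
        out.insert(1, "latitude", out["circle_id"].map(meta["latitude"]))
        out.insert(2, "longitude", out["circle_id"].map(meta["longitude"]))
        out.insert(3, "coast_distance_km",
                   out["circle_id"].map(meta["coast_distance_km"]))
        return out[CSV_COLUMNS]

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _to_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based plus header line
        raise ParseError(f"{path}: cannot parse {col}={raw[bad].iloc[0]!r} "
                         f"at line {row}")
    return out


def read_count_table(path, year_range=None, rules=None) -> SurveyDataset:
    """Read and validate a denormalized count-survey CSV.

    The file has one row per (circle, year, species) with columns
    ``circle_id, latitude, longitude, coast_distance_km, year, species,
    count, effort_hours, boat_used``.  Zero counts are preserved as
    zeros; circle-years with no rows are missing surveys.  Circles whose
    ``region`` column is absent are assigned from the rule table.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "region"]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in ["latitude", "longitude", "coast_distance_km", "year",
                "count", "effort_hours", "boat_used"]:
        df[col] = _to_numeric(df, col, path)
    if df["count"].isna().any() or df["year"].isna().any():
        row = int(df.index[df["count"].isna() | df["year"].isna()][0]) + 2
        raise ParseError(f"{path}: blank count or year at line {row}")
    if (df["count"] < 0).any():
        row = int(df.index[df["count"] < 0][0]) + 2
        raise ValidationError(f"{path}: negative count at line {row}")
    if not (df["effort_hours"] > 0).all():
        row = int(df.index[~(df["effort_hours"] > 0)][0]) + 2
        raise ValidationError(
            f"{path}: missing or non-positive effort_hours at line {row} "
            "(surveys with unknown effort are rejected)")
    df["year"] = df["year"].astype(int)
    df["boat_used"] = df["boat_used"].fillna(0).astype(int)
    df["species"] = df["species"].str.strip().str.upper()

    records = df[RECORD_COLUMNS].copy()
    circles = (df.groupby("circle_id", as_index=False)
               .agg(latitude=("latitude", "first"),
                    longitude=("longitude", "first"),
                    coast_distance_km=("coast_distance_km", "first")))
    if "region" in df.columns:
        circles["region"] = df.groupby("circle_id")["region"].first().to_numpy()
    else:
        circles["region"] = [
            _regions.assign_region(lat, lon, cd, rules=rules, circle_id=cid)
            for cid, lat, lon, cd in circles.itertuples(index=False)]
    return SurveyDataset(records, circles, year_range)


def assign_regions(dataset: SurveyDataset, rules=None) -> SurveyDataset:
    """Return a copy with every circle's region (re)assigned from the rules."""
    circles = dataset.circles.copy()
    circles["region"] = [
        _regions.assign_region(row.latitude, row.longitude,
                               row.coast_distance_km, rules=rules,
                               circle_id=row.circle_id)
        for row in circles.itertuples(index=False)]
    return SurveyDataset(dataset.records.copy(), circles, dataset.year_range)


def filter_circles(dataset: SurveyDataset, min_total: int = 10,
                   min_coverage: float = 0.5):
    """Retain circles with enough birds and enough survey coverage.

    A circle is kept when its lifetime total count is at least
    ``min_total`` *and* it was surveyed in at least ``min_coverage`` of
    the years in ``year_range`` (boundaries inclusive on both rules).

    Returns
    -------
    (SurveyDataset, DataFrame)
        The filtered dataset and an exclusion report with one row per
        dropped circle (``circle_id, total_count, years_surveyed, reason``).

    Raises
    ------
    EmptyDatasetError
        If no circle survives.
    """
    totals = dataset.total_counts()
    surveyed = dataset.surveyed_years()
    need_years = min_coverage * dataset.n_years
    reasons = []
    for cid in dataset.circles["circle_id"]:
        why = []
        if totals[cid] < min_total:
            why.append(f"total count {totals[cid]:g} < {min_total}")
        if surveyed[cid] < need_years:
            why.append(f"surveyed {surveyed[cid]} of {dataset.n_years} years "
                       f"(< {min_coverage:.0%})")
        if why:
            reasons.append((cid, totals[cid], surveyed[cid], "; ".join(why)))
    report = pd.DataFrame(reasons, columns=["circle_id", "total_count",
                                            "years_surveyed", "reason"])
    drop = set(report["circle_id"])
    keep_circles = dataset.circles[~dataset.circles["circle_id"].isin(drop)]
    keep_records = dataset.records[~dataset.records["circle_id"].isin(drop)]
    if len(keep_circles) == 0:
        raise EmptyDatasetError(
            f"all {dataset.n_circles} circles excluded by filtering "
            f"(min_total={min_total}, min_coverage={min_coverage})")
    return (SurveyDataset(keep_records.copy(), keep_circles.copy(),
                          dataset.year_range), report)


def _identified_ratio(w: float, c: float):
    tot = w + c
    return (w / tot) if tot > 0 else None


def allocate_unidentified(dataset: SurveyDataset) -> SurveyDataset:
    """Apportion genus-level (UNID) counts to WEST and CLARK.

    On each count the UNID birds are split in the ratio of the western
    and Clark's grebes identified on that same count.  When nothing was
    identified there, the fallback chain is: the pooled identified ratio
    of the circle's region in that year, then the region's all-years
    pooled ratio; if that also has no identified birds the UNID record
    is left in place and a warning is issued.  Allocation is fractional
    and conserves the circle-year total exactly.
    """
    rec = dataset.records
    meta = dataset.circles.set_index("circle_id")["region"]
    wide = (rec.pivot_table(index=["circle_id", "year"], columns="species",
                            values="count", aggfunc="first")
            .reindex(columns=["WEST", "CLARK", "UNID"]))
    had = wide.notna()
    wide = wide.fillna(0.0)
    wide["region"] = meta.reindex(wide.index.get_level_values(0)).to_numpy()

    ident = wide.reset_index()
    ry = ident.groupby(["region", "year"])[["WEST", "CLARK"]].sum()
    rall = ident.groupby("region")[["WEST", "CLARK"]].sum()

    new_west = wide["WEST"].to_numpy(dtype=float).copy()
    new_clark = wide["CLARK"].to_numpy(dtype=float).copy()
    unid = wide["UNID"].to_numpy(dtype=float)
    leftover = np.zeros_like(unid)

    for k, ((cid, year), u) in enumerate(zip(wide.index, unid)):
        if u <= 0:
            continue
        region = wide["region"].iloc[k]
        ratio = _identified_ratio(new_west[k], new_clark[k])
        if ratio is None and (region, year) in ry.index:
            ratio = _identified_ratio(*ry.loc[(region, year)])
        if ratio is None and region in rall.index:
            ratio = _identified_ratio(*rall.loc[region])
        if ratio is None:
            warnings.warn(
                f"circle {cid}, year {year}: no identified grebes anywhere in "
                "the fallback chain; UNID count left unresolved",
                AllocationWarning)
            leftover[k] = u
            continue
        new_west[k] += u * ratio
        new_clark[k] += u * (1.0 - ratio)

    # Rebuild the long table, preserving which species rows existed and
    # materialising rows that gained an allocation.
    effb = rec.groupby(["circle_id", "year"])[["effort_hours", "boat_used"]].first()
    rows = []
    for k, (cid, year) in enumerate(wide.index):
        eff, boat = effb.loc[(cid, year)]
        for sp, val, existed in (
                ("WEST", new_west[k], had["WEST"].iloc[k]),
                ("CLARK", new_clark[k], had["CLARK"].iloc[k]),
                ("UNID", leftover[k], leftover[k] > 0)):
            if existed or val > 0:
                rows.append((cid, int(year), sp, float(val), float(eff),
                             int(boat)))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records = records[~((records.species == "UNID") & (records["count"] == 0))]
    return SurveyDataset(records, dataset.circles.copy(), dataset.year_range)


def coverage_summary(dataset: SurveyDataset) -> pd.DataFrame:
    """Tabulate circles by how many survey years they are missing.

    Bins follow the reporting convention 0 / 1-5 / 6-10 / 11-18 / >18
    missing years; percentages sum to 100 up to rounding.
    """
    if dataset.n_circles:
        surveyed = dataset.surveyed_years()
        missing = dataset.n_years - surveyed
    else:
        missing = pd.Series(dtype=int)
    rows = []
    for lo, hi, label in COVERAGE_BINS:
        if hi is None:
            n = int((missing > lo - 1).sum()) if len(missing) else 0
        else:
            n = int(missing.between(lo, hi).sum()) if len(missing) else 0
        pct = 100.0 * n / dataset.n_circles if dataset.n_circles else 0.0
        rows.append((label, n, pct))
    return pd.DataFrame(rows, columns=["bin", "n_circles", "percent"])
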