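"""Data model and CSV I/O for continuous-fermentation stability analysis.

Two tabular formats are handled here:

* a *steady-state summary table* with one row per fermentation
  (:class:`SteadyStateRecord`), of which the packaged reference dataset of
  33 chemostat runs of citramalate-producing *E. coli* is an instance, and
* a *fermentation time series* (:class:`FermentationTimeSeries`) holding
  sampled concentrations and the plasmid-bearing fraction of the culture.

Units follow bioprocess convention throughout: concentrations in g L^-1,
rates in h^-1, specific rates in g per g dry cell weight (DCW) per hour.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

__all__ = [
    "ADDICTION_SYSTEMS",
    "OD600_TO_DCW",
    "SteadyStateRecord",
    "FermentationTimeSeries",
    "SteadyStateWindow",
    "ValidationIssue",
    "od_to_dcw",
    "read_steady_state_table",
    "write_steady_state_table",
    "records_to_json",
    "load_paper_dataset",
    "validate_record",
    "validate_records",
    "read_timeseries",
    "write_timeseries",
]

#: Recognised plasmid-maintenance strategies.  ``none`` marks the
#: unstabilized benchmark, ``tet`` antibiotic selection; the rest are
#: plasmid addiction systems based on essential-gene complementation.
ADDICTION_SYSTEMS = ("none", "tet", "infA", "ssb", "proBA", "proC", "dapD")

#: Dry-cell-weight calibration: g DCW per litre per unit of OD600.
OD600_TO_DCW = 0.34


def od_to_dcw(od600):
    """Convert an optical density at 600 nm to dry cell weight (g L^-1).

    Uses the linear spectrophotometric calibration of 0.34 g L^-1 DCW per
    OD600 unit.  Accepts scalars or arrays; negative input is rejected.
    """
    od600 = np.asarray(od600, dtype=float)
    if np.any(od600 < 0):
        raise ValueError("OD600 must be non-negative")
    out = OD600_TO_DCW * od600
    return float(out) if out.ndim == 0 else out


@dataclass
class SteadyStateRecord:
    """One fermentation's design factors and steady-state performance.

    The performance metrics are averages over the stable production
    period of the run.  ``stability_duration`` is the total fermentation
    time minus the time taken to reach steady state (hours).
    """

    ferm_id: str
    strain: str
    addiction_system: str
    plasmid_size: int          # bp; 0 permitted for constructs without one
    dilution_rate: float       # h^-1
    temperature: float         # degC
    total_duration: float      # h
    stability_duration: float  # h
    cma_titer: float           # g_CMA L^-1
    specific_productivity: float  # g_CMA g_DCW^-1 h^-1
    specific_uptake: float        # g_Glu g_DCW^-1 h^-1
    yield_ps: float            # g_CMA g_Glu^-1
    yield_px: float            # g_CMA g_DCW^-1
    yield_xs: float            # g_DCW g_Glu^-1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.addiction_system not in ADDICTION_SYSTEMS:
            raise ValueError(
                f"{self.ferm_id}: unknown addiction system "
                f"{self.addiction_system!r}; expected one of {ADDICTION_SYSTEMS}"
            )


@dataclass
class SteadyStateWindow:
    """A detected stable stretch of a fermentation time series."""

    start_time: float  # h
    end_time: float    # h
    mean_dcw: float = float("nan")
    mean_cma: float = float("nan")
    mean_glucose_residual: float = float("nan")
    cv_dcw: float = float("nan")
    cv_cma: float = float("nan")

    def __post_init__(self):
        if not self.start_time < self.end_time:
            raise ValueError("window start must precede its end")


@dataclass
class FermentationTimeSeries:
    """A sampled chemostat trajectory with its operating conditions.

    ``plasmid_fraction`` may be sparse: time points without a patch-plating
    observation carry NaN.
    """

    times: np.ndarray              # h, strictly increasing
    dcw: np.ndarray                # g L^-1
    cma: np.ndarray                # g L^-1
    glucose_residual: np.ndarray   # g L^-1
    glucose_feed: float            # g L^-1 in the feed
    plasmid_fraction: np.ndarray   # in [0, 1], NaN where unobserved
    dilution_rate: float           # h^-1
    temperature: float             # degC
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ("dcw", "cma", "glucose_residual", "plasmid_fraction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must have the same length as times")
            setattr(self, name, arr)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        pf = self.plasmid_fraction
        obs = pf[~np.isnan(pf)]
        if np.any((obs < 0) | (obs > 1)):
            raise ValueError("plasmid_fraction must lie in [0, 1]")

    @property
    def residence_time(self) -> float:
        """Mean hydraulic residence time 1/D in hours."""
        return 1.0 / self.dilution_rate

    def feed_exceedances(self) -> np.ndarray:
        """Indices where residual glucose exceeds the feed concentration.

        Transient exceedances can occur around start-up or sampling noise;
        they are flagged rather than rejected.
        """
        return np.flatnonzero(self.glucose_residual > self.glucose_feed)


@dataclass
class ValidationIssue:
    ferm_id: str
    field: str
    message: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.ferm_id}.{self.field}: {self.message}"


# ---------------------------------------------------------------------------
# summary-table I/O

#: Map from common column spellings (lower-case, stripped) to field names.
COLUMN_ALIASES = {
    "ferm_id": "ferm_id", "ferm ref": "ferm_id", "id": "ferm_id",
    "strain": "strain",
    "addiction_system": "addiction_system", "addiction system": "addiction_system",
    "plasmid_size": "plasmid_size", "plasmid size": "plasmid_size",
    "plasmid size (bp)": "plasmid_size",
    "dilution_rate": "dilution_rate", "dilution rate": "dilution_rate", "d": "dilution_rate",
    "temperature": "temperature", "t": "temperature",
    "total_duration": "total_duration", "total duration": "total_duration",
    "stability_duration": "stability_duration", "stability duration": "stability_duration",
    "cma_titer": "cma_titer", "[cma]": "cma_titer", "cma": "cma_titer", "titer": "cma_titer",
    "specific_productivity": "specific_productivity",
    "specific productivity": "specific_productivity",
    "specific_uptake": "specific_uptake", "specific uptake": "specific_uptake",
    "yield_ps": "yield_ps", "yield (p/s)": "yield_ps", "yield(p/s)": "yield_ps",
    "yield_px": "yield_px", "yield (p/x)": "yield_px", "yield(p/x)": "yield_px",
    "yield_xs": "yield_xs", "yield (x/s)": "yield_xs", "yield(x/s)": "yield_xs",
}

_TEXT_FIELDS = {"ferm_id", "strain", "addiction_system"}
_MANDATORY = (
    "ferm_id", "strain", "addiction_system", "plasmid_size", "dilution_rate",
    "temperature", "total_duration", "stability_duration", "cma_titer",
    "specific_productivity", "specific_uptake", "yield_ps", "yield_px", "yield_xs",
)


class TableFormatError(ValueError):
    """A summary-table CSV is structurally unusable (missing columns...)."""


def read_steady_state_table(path) -> list[SteadyStateRecord]:
    """Read a steady-state summary table CSV into records.

    Column names are matched case-insensitively against a documented alias
    map (e.g. ``Yield (P/S)`` -> ``yield_ps``).  Unknown extra columns are
    preserved in each record's ``metadata`` rather than treated as errors.
    Per-row invariant violations raise :class:`ValueError` naming the row;
    use :func:`validate_records` for a non-raising report.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_summary(fh, str(path))


def _read_summary(fh, label) -> list[SteadyStateRecord]:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise TableFormatError(f"{label}: empty file, no header")
    colmap, extra = {}, []
    for col in reader.fieldnames:
        key = col.strip().lower()
        if key in COLUMN_ALIASES:
            colmap[col] = COLUMN_ALIASES[key]
        else:
            extra.append(col)
    missing = [m for m in _MANDATORY if m not in colmap.values()]
    if missing:
        raise TableFormatError(f"{label}: missing mandatory column(s) {missing}")

    records = []
    for i, row in enumerate(reader, start=2):
        kwargs, meta = {}, {}
        for col, fieldname in colmap.items():
            raw = (row.get(col) or "").strip()
            if fieldname in _TEXT_FIELDS:
                kwargs[fieldname] = raw
                continue
            try:
                val = float(raw)
            except ValueError:
                raise ValueError(
                    f"{label} line {i}: non-numeric value {raw!r} in column {col!r}"
                ) from None
            kwargs[fieldname] = int(val) if fieldname == "plasmid_size" else val
        for col in extra:
            meta[col] = row.get(col)
        rec = SteadyStateRecord(metadata=meta, **kwargs)
        hard = [iss for iss in validate_record(rec) if iss.field != "consistency"]
        if hard:
            raise ValueError(f"{label} line {i}: " + "; ".join(map(str, hard)))
        records.append(rec)
    return records


def write_steady_state_table(records, path):
    """Write records as a summary-table CSV (RFC-4180, UTF-8)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANDATORY)
        for r in records:
            writer.writerow([getattr(r, f) for f in _MANDATORY])


def records_to_json(records) -> str:
    """Serialise a record collection to a JSON array."""
    return json.dumps([asdict(r) for r in records], indent=1)


def load_paper_dataset() -> list[SteadyStateRecord]:
    """Load the packaged 33-fermentation reference dataset (F1..F33).

    Rows carry the published steady-state metrics for seven strains of
    citramalate-producing *E. coli* run at three operating conditions.
    Plasmid sizes are per-construct totals; the two benchmark strains carry
    their full vector sizes (3205 and 3646 bp).
    """
    text = resources.files("fermstab").joinpath("data/table2.csv").read_text("utf-8")
    return _read_summary(io.StringIO(text), "table2.csv")


# ---------------------------------------------------------------------------
# validation

def validate_record(rec: SteadyStateRecord, ratio_decimals: int = 2) -> list[ValidationIssue]:
    """Check a record's invariants and internal metric consistency.

    Hard invariants (non-negative metrics, stability within total duration,
    positive rates) yield issues with the offending field name.  In
    addition, two redundancy checks exploit the metric definitions:

    * specific productivity should equal Yield(P/X) x D, and
    * Yield(P/S) should equal specific productivity / specific uptake,

    evaluated *at the table's printed precision*: a row passes if values
    rounded to ``ratio_decimals`` decimals could have produced the printed
    entries.  Failures are reported under the pseudo-field ``consistency``
    so that anomalous source rows are flagged, never silently corrected.
    """
    issues = []

    def bad(fieldname, msg):
        issues.append(ValidationIssue(rec.ferm_id, fieldname, msg))

    if rec.dilution_rate <= 0:
        bad("dilution_rate", "must be positive")
    if rec.temperature <= 0:
        bad("temperature", "must be positive")
    if rec.plasmid_size < 0:
        bad("plasmid_size", "must be >= 0")
    if not 0 <= rec.stability_duration <= rec.total_duration:
        bad("stability_duration", "must lie in [0, total_duration]")
    for f in ("cma_titer", "specific_productivity", "specific_uptake",
              "yield_ps", "yield_px", "yield_xs"):
        if getattr(rec, f) < 0:
            bad(f, "must be non-negative")
    if issues:
        return issues

    half = 0.5 * 10.0 ** (-ratio_decimals)
    # productivity = Yield(P/X) * D, allowing +-half a printed unit on each side
    qp = rec.yield_px * rec.dilution_rate
    lo = (rec.yield_px - half) * rec.dilution_rate
    hi = (rec.yield_px + half) * rec.dilution_rate
    if not (lo - half <= rec.specific_productivity <= hi + half):
        bad("consistency",
            f"specific_productivity {rec.specific_productivity} inconsistent "
            f"with yield_px x D = {qp:.3f}")
    # Yield(P/S) = productivity / uptake, interval-propagating printed rounding
    if rec.specific_uptake > 0:
        r_lo = (rec.specific_productivity - half) / (rec.specific_uptake + half)
        r_hi = (rec.specific_productivity + half) / max(rec.specific_uptake - half, 1e-9)
        if not (r_lo - half <= rec.yield_ps <= r_hi + half):
            bad("consistency",
                f"yield_ps {rec.yield_ps} inconsistent with productivity/uptake "
                f"= {rec.specific_productivity / rec.specific_uptake:.3f}")
    return issues


def validate_records(records) -> dict[str, list[ValidationIssue]]:
    """Validate a collection; returns ``{ferm_id: issues}`` for flagged rows."""
    report = {}
    for rec in records:
        issues = validate_record(rec)
        if issues:
            report[rec.ferm_id] = issues
    return report


# ---------------------------------------------------------------------------
# time-series I/O
#
# Format: '#'-prefixed header lines carry scalar fields as `# key = value`,
# followed by an RFC-4180 CSV body with columns
# time,dcw,cma,glucose_residual,plasmid_fraction.  Unobserved plasmid
# fractions are empty cells.

def write_timeseries(ts: FermentationTimeSeries, path):
    """Write a time series; :func:`read_timeseries` round-trips it losslessly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# dilution_rate = {ts.dilution_rate!r}\n")
        fh.write(f"# temperature = {ts.temperature!r}\n")
        fh.write(f"# glucose_feed = {ts.glucose_feed!r}\n")
        for k, v in ts.metadata.items():
            fh.write(f"# meta:{k} = {v}\n")
        writer = csv.writer(fh)
        writer.writerow(["time", "dcw", "cma", "glucose_residual", "plasmid_fraction"])
        for i in range(len(ts.times)):
            pf = ts.plasmid_fraction[i]
            writer.writerow([
                repr(float(ts.times[i])), repr(float(ts.dcw[i])),
                repr(float(ts.cma[i])), repr(float(ts.glucose_residual[i])),
                "" if np.isnan(pf) else repr(float(pf)),
            ])


def read_timeseries(path) -> FermentationTimeSeries:
    """Read a time-series CSV written by :func:`write_timeseries`."""
    scalars, meta, rows = {}, {}, []
    with open(path, newline="", encoding="utf-8") as fh:
        body = []
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                key = key.strip()
                if key.startswith("meta:"):
                    meta[key[5:]] = val.strip()
                else:
                    scalars[key] = float(val)
            else:
                body.append(line)
    for key in ("dilution_rate", "temperature", "glucose_feed"):
        if key not in scalars:
            raise TableFormatError(f"{path}: missing '# {key} = ...' header")
    reader = csv.DictReader(body)
    for row in reader:
        rows.append(row)
    times = np.array([float(r["time"]) for r in rows])
    if len(times) and np.any(np.diff(times) <= 0):
        raise TableFormatError(f"{path}: time stamps not strictly increasing")
    pf = np.array([float(r["plasmid_fraction"]) if r["plasmid_fraction"] else np.nan
                   for r in rows])
    return FermentationTimeSeries(
        times=times,
        dcw=np.array([float(r["dcw"]) for r in rows]),
        cma=np.array([float(r["cma"]) for r in rows]),
        glucose_residual=np.array([float(r["glucose_residual"]) for r in rows]),
        plasmid_fraction=pf,
        glucose_feed=scalars["glucose_feed"],
        dilution_rate=scalars["dilution_rate"],
        temperature=scalars["temperature"],
        metadata=meta,
    )
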