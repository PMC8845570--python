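"""Quantification of kinetic growth curves from anaerobic carbohydrate arrays.

Each well of a growth array yields a time series of A600 absorbance readings
recorded every 10-20 minutes for up to 4 days.  This module turns those
curves into two phenotype parameters per strain x substrate assay:

* total growth  G = A600(max) - A600(min), after subtracting the strain's
  mean no-carbohydrate (negative control) growth, and
* growth rate   r = G / (t_max - t_min)  in absorbance units per minute,

applies the no-growth threshold (G <= 0.1 -> scored 0) and the
discordant-replicate rule (one positive, one negative -> both zeroed), and
performs the two-stage normalization: first within each strain (its best
substrate set to 1.0), then within each substrate (the best strain set to
1.0), yielding values in [0, 1] throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

NEGATIVE_CONTROL = "NONE"

__all__ = [
    "NEGATIVE_CONTROL",
    "KineticCurve",
    "GrowthWindow",
    "GrowthMetrics",
    "GrowthParams",
    "PhenotypeMatrix",
    "call_growth_window",
    "subtract_negative_control",
    "compute_metrics",
    "apply_growth_calls",
    "normalize_within_strain",
    "normalize_within_substrate",
    "process_plate",
]


@dataclass(frozen=True)
class KineticCurve:
    """One well's A600 time series.

    ``times`` are minutes since inoculation and must be strictly increasing;
    at least 10 readings are required, all finite and non-negative.
    """

    well_id: str
    strain_id: str
    substrate_id: str
    replicate: int
    times: np.ndarray
    a600: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        a600 = np.asarray(self.a600, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "a600", a600)
        if times.ndim != 1 or times.shape != a600.shape:
            raise ValueError("times and a600 must be 1-D and equal length")
        if len(times) < 10:
            raise ValueError("kinetic series must contain at least 10 readings")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a600)) or np.any(a600 < 0):
            raise ValueError("a600 values must be finite and >= 0")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    @property
    def is_negative_control(self) -> bool:
        return self.substrate_id == NEGATIVE_CONTROL


@dataclass(frozen=True)
class GrowthWindow:
    """Called growth onset ("min") and endpoint ("max") on one curve."""

    t_min: float
    t_max: float
    a_min: float
    a_max: float
    flagged_manual_review: bool = False

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError("t_min must be <= t_max")
        if self.a_min > self.a_max:
            raise ValueError("a_min must be <= a_max")


@dataclass(frozen=True)
class GrowthMetrics:
    total_growth: float
    growth_rate: float
    is_growth: bool = True


@dataclass(frozen=True)
class GrowthParams:
    """Tunable parameters for window calling and thresholding.

    ``no_growth_threshold`` (0.1 absorbance units) is the published cutoff
    below which an assay is scored "no growth".  The remaining three control
    the automated min/max caller: curves are median-smoothed over
    ``smoothing_window`` points (suppressing single-reading bubble spikes),
    growth onset requires the forward slope to exceed ``slope_epsilon`` for
    two consecutive intervals, and the curve must subsequently rise at least
    ``rise_delta`` above the onset value.
    """

    no_growth_threshold: float = 0.1
    smoothing_window: int = 5
    slope_epsilon: float = 1e-4
    rise_delta: float = 0.02

    def __post_init__(self) -> None:
        if self.no_growth_threshold <= 0:
            raise ValueError("no_growth_threshold must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


def smooth_curve(a600: np.ndarray, window: int) -> np.ndarray:
    """Median-smooth a trace; robust to isolated bubble/precipitation spikes."""
    if window <= 1:
        return np.asarray(a600, dtype=float)
    return median_filter(np.asarray(a600, dtype=float), size=window, mode="nearest")


def call_growth_window(curve: KineticCurve, params: GrowthParams | None = None) -> GrowthWindow:
    """Call the growth onset (min) and endpoint (max) points of a curve.

    The min point is the first time, on the median-smoothed curve, where the
    forward slope exceeds ``slope_epsilon`` for at least two consecutive
    intervals and the smoothed curve later rises >= ``rise_delta`` above the
    value there.  The max point is the (first) global maximum of the smoothed
    curve at or after the min point.  When no onset is found the degenerate
    window anchored at the first reading is returned; it is flagged for
    manual review if the raw curve nevertheless spans more than the
    no-growth threshold.
    """
    params = params or GrowthParams()
    if len(curve.times) < params.smoothing_window:
        raise ValueError("kinetic series shorter than smoothing window")
    t = curve.times
    s = smooth_curve(curve.a600, params.smoothing_window)
    slopes = np.diff(s) / np.diff(t)

    onset = None
    for i in range(len(slopes) - 1):
        if slopes[i] > params.slope_epsilon and slopes[i + 1] > params.slope_epsilon:
            if np.max(s[i:]) - s[i] >= params.rise_delta:
                onset = i
                break
    if onset is None:
        raw_span = float(np.max(curve.a600) - np.min(curve.a600))
        return GrowthWindow(
            t_min=float(t[0]),
            t_max=float(t[0]),
            a_min=float(curve.a600[0]),
            a_max=float(curve.a600[0]),
            flagged_manual_review=raw_span > params.no_growth_threshold,
        )
    j = onset + int(np.argmax(s[onset:]))
    return GrowthWindow(
        t_min=float(t[onset]),
        t_max=float(t[j]),
        a_min=float(s[onset]),
        a_max=float(s[j]),
    )


def subtract_negative_control(total_growth: float, neg_controls: list[float]) -> float:
    """Subtract the mean no-carbohydrate control growth, clamping at zero."""
    if len(neg_controls) == 0:
        raise ValueError("no negative-control measurements supplied")
    return max(0.0, float(total_growth) - float(np.mean(neg_controls)))


def compute_metrics(window: GrowthWindow) -> GrowthMetrics:
    """Total growth G = a_max - a_min and rate r = G / (t_max - t_min)."""
    g = window.a_max - window.a_min
    dt = window.t_max - window.t_min
    rate = g / dt if dt > 0 else 0.0
    return GrowthMetrics(total_growth=float(g), growth_rate=float(rate))


def apply_growth_calls(
    rep1: GrowthMetrics, rep2: GrowthMetrics, params: GrowthParams | None = None
) -> tuple[GrowthMetrics, GrowthMetrics]:
    """Apply the no-growth threshold and the discordant-replicate rule.

    A replicate with total growth <= the threshold is scored no-growth; if
    either replicate is no-growth (including discordant pairs), both are
    converted to zero.
    """
    params = params or GrowthParams()
    ok1 = rep1.total_growth > params.no_growth_threshold
    ok2 = rep2.total_growth > params.no_growth_threshold
    if ok1 and ok2:
        return (replace(rep1, is_growth=True), replace(rep2, is_growth=True))
    zero = GrowthMetrics(total_growth=0.0, growth_rate=0.0, is_growth=False)
    return (zero, zero)


STAGES = ("raw", "called", "strain_normalized", "substrate_normalized")


@dataclass
class PhenotypeMatrix:
    """Strains x substrates total-growth and growth-rate tables.

    ``stage`` records how far the values have been processed: ``raw`` (window
    metrics), ``called`` (thresholded, control-subtracted, replicate-averaged),
    ``strain_normalized`` or ``substrate_normalized`` (values in [0, 1]).
    ``is_growth`` is the boolean call table, available from the called stage.
    """

    growth: pd.DataFrame
    rate: pd.DataFrame
    stage: str = "raw"
    is_growth: pd.DataFrame | None = None
    strain_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.growth.index.equals(self.rate.index) or not self.growth.columns.equals(
            self.rate.columns
        ):
            raise ValueError("growth and rate tables must share strains and substrates")
        if self.stage in ("strain_normalized", "substrate_normalized"):
            for df in (self.growth, self.rate):
                vals = df.to_numpy(dtype=float)
                if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
                    raise ValueError("normalized values must lie in [0, 1]")

    @property
    def strains(self) -> list[str]:
        return list(self.growth.index)

    @property
    def substrates(self) -> list[str]:
        return list(self.growth.columns)


def _normalize_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    maxima = df.max(axis=1)
    zero_rows = [str(i) for i in df.index[maxima <= 0]]
    safe = maxima.replace(0, 1.0)
    return df.div(safe, axis=0), zero_rows


def normalize_within_strain(m: PhenotypeMatrix) -> tuple[PhenotypeMatrix, list[str]]:
    """Scale each strain so its best substrate equals 1.0.

    Growth and rate are normalized independently.  All-zero strain rows are
    left at zero and their ids returned (and warned) rather than erroring —
    some poorly growing strains legitimately produce near-empty rows.
    """
    if m.stage != "called":
        raise ValueError("normalize_within_strain expects a called-stage matrix")
    g, zg = _normalize_rows(m.growth)
    r, zr = _normalize_rows(m.rate)
    zero_rows = sorted(set(zg) | set(zr))
    if zero_rows:
        warnings.warn(f"all-zero strain rows left unnormalized: {', '.join(zero_rows)}")
    out = PhenotypeMatrix(
        growth=g, rate=r, stage="strain_normalized", is_growth=m.is_growth, strain_meta=m.strain_meta
    )
    return out, zero_rows


def normalize_within_substrate(m: PhenotypeMatrix) -> PhenotypeMatrix:
    """Scale each substrate column so the best strain equals 1.0."""
    if m.stage not in ("strain_normalized", "substrate_normalized"):
        raise ValueError("normalize_within_substrate expects a strain-normalized matrix")

    def norm_cols(df: pd.DataFrame) -> pd.DataFrame:
        maxima = df.max(axis=0).replace(0, 1.0)
        return df.div(maxima, axis=1)

    return PhenotypeMatrix(
        growth=norm_cols(m.growth),
        rate=norm_cols(m.rate),
        stage="substrate_normalized",
        is_growth=m.is_growth,
        strain_meta=m.strain_meta,
    )


def process_plate(
    curves: list[KineticCurve], params: GrowthParams | None = None
) -> tuple[PhenotypeMatrix, pd.DataFrame]:
    """Run the full per-well pipeline on a set of curves.

    Calls windows, computes raw metrics, subtracts each strain's mean
    negative-control growth, applies the no-growth threshold and the
    discordant-replicate rule, and averages the two called replicates into a
    called-stage :class:`PhenotypeMatrix`.  Also returns the tidy per-assay
    table (one row per strain x substrate).
    """
    params = params or GrowthParams()
    records = []
    for c in curves:
        w = call_growth_window(c, params)
        met = compute_metrics(w)
        records.append(
            {
                "well_id": c.well_id,
                "strain_id": c.strain_id,
                "substrate_id": c.substrate_id,
                "replicate": c.replicate,
                "total_growth_raw": met.total_growth,
                "growth_rate_raw": met.growth_rate,
                "flagged_manual_review": w.flagged_manual_review,
            }
        )
    wells = pd.DataFrame.from_records(records)

    neg = (
        wells[wells.substrate_id == NEGATIVE_CONTROL]
        .groupby("strain_id")["total_growth_raw"]
        .apply(list)
        .to_dict()
    )
    assays = wells[wells.substrate_id != NEGATIVE_CONTROL]

    rows = []
    for (strain, substrate), grp in assays.groupby(["strain_id", "substrate_id"], sort=True):
        reps = grp.sort_values("replicate")
        mets = []
        for _, r in reps.iterrows():
            g = r.total_growth_raw
            if strain in neg:
                g = subtract_negative_control(g, neg[strain])
            mets.append(GrowthMetrics(total_growth=g, growth_rate=r.growth_rate_raw))
        if len(mets) >= 2:
            m1, m2 = apply_growth_calls(mets[0], mets[1], params)
            called = [m1, m2] + mets[2:]
        else:  # a lone replicate is thresholded on its own
            m = mets[0]
            if m.total_growth <= params.no_growth_threshold:
                m = GrowthMetrics(0.0, 0.0, is_growth=False)
            called = [m]
        rows.append(
            {
                "strain_id": strain,
                "substrate_id": substrate,
                "total_growth_raw": float(np.mean([m.total_growth for m in mets])),
                "total_growth_called": float(np.mean([m.total_growth for m in called])),
                "growth_rate": float(np.mean([m.growth_rate for m in called])),
                "is_growth": all(m.is_growth for m in called),
            }
        )
    tidy = pd.DataFrame(rows)
    growth = tidy.pivot(index="strain_id", columns="substrate_id", values="total_growth_called")
    rate = tidy.pivot(index="strain_id", columns="substrate_id", values="growth_rate")
    is_growth = tidy.pivot(index="strain_id", columns="substrate_id", values="is_growth")
    matrix = PhenotypeMatrix(
        growth=growth.fillna(0.0),
        rate=rate.fillna(0.0),
        stage="called",
        is_growth=is_growth.fillna(False).astype(bool),
    )
    return matrix, tidy
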