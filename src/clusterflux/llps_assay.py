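"""Analysis of the phase-separated droplet enzyme assay.

The in vitro experiment follows product (2-oxoglutarate) formation by an
enzyme (ICD) inside protein droplets while titrating its clustering partner
(MDH) over a ladder of MDH:ICD molar ratios.  At each time point the reaction
mix is split into droplet and supernatant phases and the product amount in
each is quantified against a linear calibration curve.  This module turns
those per-phase time courses into initial-rate velocities, percent rate
enhancements relative to the no-partner baseline, and droplet/supernatant
partition ratios, and fits an empirical monotone map from the molar ratio to
the cluster excess ratio gamma of the reaction-diffusion model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_model import ValidationError

__all__ = [
    "AssayTimeCourse",
    "EnhancementCurve",
    "LinearCalibration",
    "GammaCalibration",
    "fit_linear_calibration",
    "velocity_from_timecourse",
    "percent_enhancement",
    "partition_ratio",
    "enhancement_curve",
    "calibrate_gamma",
    "read_assay_table",
    "courses_to_table",
]

#: assay aliquot volumes (mL); equal aliquots of each phase are sampled
DEFAULT_PHASE_VOLUMES = {"droplet": 0.010, "supernatant": 0.010}


@dataclass
class AssayTimeCourse:
    """Product time course for one MDH:ICD condition and replicate.

    ``condition_ratio`` is the MDH:ICD molar ratio (0 = no MDH) and
    ``mdh_source`` distinguishes the endogenous enzyme from orthologs.
    Amounts are nmol of product measured in the droplet and supernatant
    aliquots at common times (min); ``enzyme_nmol`` is the amount of ICD.
    """

    condition_ratio: float
    mdh_source: str
    replicate: int
    times_min: np.ndarray
    droplet_nmol: np.ndarray
    supernatant_nmol: np.ndarray
    enzyme_nmol: float
    phase_volumes_ml: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_VOLUMES))

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.droplet_nmol = np.asarray(self.droplet_nmol, dtype=float)
        self.supernatant_nmol = np.asarray(self.supernatant_nmol, dtype=float)
        if not (len(self.times_min) == len(self.droplet_nmol) == len(self.supernatant_nmol)):
            raise ValidationError("phases must be measured at identical times")
        if np.any(np.diff(self.times_min) < 0):
            raise ValidationError("times must be non-decreasing")
        if np.any(self.droplet_nmol < 0) or np.any(self.supernatant_nmol < 0):
            raise ValidationError("product amounts must be >= 0")

    @property
    def total_nmol(self) -> np.ndarray:
        return self.droplet_nmol + self.supernatant_nmol


@dataclass(frozen=True)
class LinearCalibration:
    """Absorbance -> nmol product calibration line."""

    slope: float
    intercept: float
    r_squared: float

    def to_nmol(self, absorbance) -> np.ndarray:
        return self.slope * np.asarray(absorbance, dtype=float) + self.intercept


def fit_linear_calibration(
    absorbance: Sequence[float], nmol: Sequence[float]
) -> LinearCalibration:
    """Least-squares calibration line over the standard series (>= 3 points)."""
    x = np.asarray(absorbance, dtype=float)
    y = np.asarray(nmol, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("calibration needs >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in absorbance; cannot calibrate")
    res = stats.linregress(x, y)
    cal = LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
    if cal.slope <= 0:
        raise ValidationError(f"calibration slope must be > 0, got {cal.slope}")
    return cal


def velocity_from_timecourse(
    course: AssayTimeCourse,
    window: tuple[float, float] | None = None,
    n_initial: int = 3,
) -> float:
    """Initial-rate velocity per enzyme (1/s) from the total-product slope.

    Only the sum of droplet and supernatant product enters: the velocity is
    the slope of total nmol vs time over the window (default: the first
    ``n_initial`` time points), divided by the enzyme amount and converted
    from 1/min to 1/s.
    """
    if course.enzyme_nmol <= 0:
        raise ValidationError("enzyme_nmol must be > 0")
    t = course.times_min
    y = course.total_nmol
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    else:
        t, y = t[:n_initial], y[:n_initial]
    if len(t) < 2:
        raise ValidationError("velocity window must contain >= 2 points")
    slope = np.polyfit(t, y, 1)[0]  # nmol/min
    if slope < 0:
        import warnings

        warnings.warn("decreasing product; velocity <= 0", RuntimeWarning, stacklevel=2)
    return float(slope / course.enzyme_nmol / 60.0)


def percent_enhancement(
    v: float, v_baseline: float, convention: str = "enhancement"
) -> float:
    """Percent rate change vs baseline.

    ``convention='enhancement'`` (default) reports the increment
    100*(v - v0)/v0, so a 1.1x rate reads as 10% and a 2.8x rate as 180%.
    ``convention='percent_of_activity'`` reports 100*v/v0 instead.
    """
    if v_baseline <= 0:
        raise ValidationError("baseline velocity must be > 0")
    if convention == "enhancement":
        return 100.0 * (v - v_baseline) / v_baseline
    if convention == "percent_of_activity":
        return 100.0 * v / v_baseline
    raise ValidationError(f"unknown convention {convention!r}")


def partition_ratio(course: AssayTimeCourse, t_min: float) -> float:
    """Droplet/supernatant product concentration ratio at a measured time."""
    idx = np.flatnonzero(np.isclose(course.times_min, t_min))
    if len(idx) == 0:
        raise ValidationError(f"t={t_min} min is not a measured time point")
    i = int(idx[0])
    v = course.phase_volumes_ml
    c_drop = course.droplet_nmol[i] / v["droplet"]
    c_sup = course.supernatant_nmol[i] / v["supernatant"]
    if c_sup == 0:
        return math.nan
    return float(c_drop / c_sup)


@dataclass(frozen=True)
class EnhancementCurve:
    """Mean percent enhancement per MDH:ICD condition with dispersion."""

    conditions: np.ndarray
    mean_enhancement: np.ndarray
    sd_enhancement: np.ndarray
    se_enhancement: np.ndarray
    n_replicates: np.ndarray
    baseline_velocity: float
    mdh_source: str

    def at(self, ratio: float) -> float:
        idx = np.flatnonzero(np.isclose(self.conditions, ratio))
        if len(idx) == 0:
            raise ValidationError(f"condition {ratio} not in curve")
        return float(self.mean_enhancement[int(idx[0])])


def enhancement_curve(
    courses: Iterable[AssayTimeCourse],
    mdh_source: str,
    convention: str = "enhancement",
    **velocity_options,
) -> EnhancementCurve:
    """Build the enhancement-vs-ratio curve for one MDH source.

    The baseline is the mean velocity across replicates of the ratio-0 (no
    MDH) condition; per-replicate velocities at each condition are converted
    to percent enhancement against that common baseline.
    """
    by_cond: dict[float, list[float]] = {}
    for course in courses:
        if course.mdh_source != mdh_source and course.condition_ratio != 0:
            continue
        by_cond.setdefault(course.condition_ratio, []).append(
            velocity_from_timecourse(course, **velocity_options)
        )
    if 0.0 not in by_cond:
        raise ValidationError("baseline (ratio 0) condition missing")
    v0_reps = np.asarray(by_cond[0.0], dtype=float)
    v0 = float(np.mean(v0_reps))
    var_v0 = float(np.var(v0_reps, ddof=1)) / len(v0_reps) if len(v0_reps) > 1 else 0.0
    conds = np.array(sorted(by_cond))
    means, sds, ses, ns = [], [], [], []
    for c in conds:
        vs = np.asarray(by_cond[c], dtype=float)
        e = np.array([percent_enhancement(v, v0, convention) for v in vs])
        if c == 0.0:
            # baseline enhancement is 0 by construction (its mean defines v0)
            e = e - float(np.mean(e)) if convention == "enhancement" else e
        vbar = float(np.mean(vs))
        var_v = float(np.var(vs, ddof=1)) / len(vs) if len(vs) > 1 else 0.0
        # delta-method SE of 100*(vbar/v0 - 1): the shared baseline estimate
        # shifts every condition coherently, so its variance must propagate
        se = 100.0 * math.sqrt(var_v / v0**2 + vbar**2 * var_v0 / v0**4)
        means.append(float(np.mean(e)))
        sds.append(float(np.std(e, ddof=1)) if len(e) > 1 else 0.0)
        ses.append(se)
        ns.append(len(e))
    return EnhancementCurve(
        conditions=conds,
        mean_enhancement=np.asarray(means),
        sd_enhancement=np.asarray(sds),
        se_enhancement=np.asarray(ses),
        n_replicates=np.asarray(ns),
        baseline_velocity=v0,
        mdh_source=mdh_source,
    )


@dataclass(frozen=True)
class GammaCalibration:
    """Monotone empirical map MDH:ICD molar ratio -> cluster excess gamma.

    Piecewise linear in log10(1 + ratio) between anchor points; ratio 0 maps
    to gamma 0 always.  The model itself does not predict this map (it ties
    partner abundance to cluster occupancy), so it is calibrated from data or
    supplied anchors and serialized with its provenance.
    """

    anchor_ratios: np.ndarray
    anchor_gammas: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        r = np.asarray(self.anchor_ratios, dtype=float)
        g = np.asarray(self.anchor_gammas, dtype=float)
        if len(r) != len(g) or len(r) < 2:
            raise ValidationError("need >= 2 anchor points")
        if np.any(np.diff(r) <= 0) or np.any(np.diff(g) < 0):
            raise ValidationError("anchors must be increasing in ratio, non-decreasing in gamma")
        if r[0] != 0.0 or g[0] != 0.0:
            raise ValidationError("the map must anchor ratio 0 -> gamma 0")
        object.__setattr__(self, "anchor_ratios", r)
        object.__setattr__(self, "anchor_gammas", g)

    def __call__(self, ratio) -> np.ndarray:
        x = np.log10(1.0 + np.asarray(ratio, dtype=float))
        xa = np.log10(1.0 + self.anchor_ratios)
        return np.interp(x, xa, self.anchor_gammas)

    def to_dict(self) -> dict:
        return {
            "anchor_ratios": self.anchor_ratios.tolist(),
            "anchor_gammas": self.anchor_gammas.tolist(),
            "provenance": self.provenance,
        }


def calibrate_gamma(
    curve: EnhancementCurve,
    anchors: Sequence[tuple[float, float]] | None = None,
    gamma_max: float = 50.0,
    monotone_tolerance_sd: float = 2.0,
) -> GammaCalibration:
    """Fit the empirical ratio -> gamma map from an enhancement curve.

    With explicit ``anchors`` [(ratio, gamma), ...] the map simply
    interpolates them.  Otherwise anchor gammas are assigned proportionally
    to the normalized enhancement at each condition, scaled to ``gamma_max``
    at the strongest condition -- an ordering-preserving empirical anchoring,
    not a mechanistic fit.  A curve that decreases by more than
    ``monotone_tolerance_sd`` standard errors between consecutive conditions
    is rejected.
    """
    if anchors is not None:
        anchors = sorted((float(r), float(g)) for r, g in anchors)
        r = np.array([a[0] for a in anchors])
        g = np.array([a[1] for a in anchors])
        if r[0] != 0.0:
            r = np.insert(r, 0, 0.0)
            g = np.insert(g, 0, 0.0)
        return GammaCalibration(r, g, provenance="explicit anchors")

    e = curve.mean_enhancement
    se = curve.se_enhancement
    drops = np.diff(e)
    tol = monotone_tolerance_sd * np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
    if np.any(drops < -np.maximum(tol, 1e-12)):
        raise ValidationError("enhancement curve not monotone within noise")
    e_max = float(e.max())
    if e_max <= 0:
        raise ValidationError("no positive enhancement to anchor gamma against")
    gam = gamma_max * np.maximum.accumulate(np.clip(e, 0.0, None)) / e_max
    r = curve.conditions.copy()
    if r[0] != 0.0:
        r = np.insert(r, 0, 0.0)
        gam = np.insert(gam, 0, 0.0)
    gam[r == 0.0] = 0.0
    return GammaCalibration(
        r, gam, provenance=f"proportional anchoring, gamma_max={gamma_max}"
    )


# ---------------------------------------------------------------------------
# delimited-table round trip


def courses_to_table(courses: Iterable[AssayTimeCourse]) -> pd.DataFrame:
    """Long-format table: condition_ratio, mdh_source, replicate, time_min, phase, amount_nmol."""
    rows = []
    for c in courses:
        for phase, amounts in (
            ("droplet", c.droplet_nmol),
            ("supernatant", c.supernatant_nmol),
        ):
            for t, a in zip(c.times_min, amounts):
                rows.append(
                    {
                        "condition_ratio": c.condition_ratio,
                        "mdh_source": c.mdh_source,
                        "replicate": c.replicate,
                        "time_min": t,
                        "phase": phase,
                        "amount_nmol": a,
                        "enzyme_nmol": c.enzyme_nmol,
                    }
                )
    return pd.DataFrame(rows)


def read_assay_table(path: str | Path, sep: str = ",") -> list[AssayTimeCourse]:
    """Parse a long-format assay table back into time-course objects."""
    df = pd.read_csv(path, sep=sep)
    required = {
        "condition_ratio", "mdh_source", "replicate", "time_min", "phase",
        "amount_nmol", "enzyme_nmol",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"assay table missing columns: {sorted(missing)}")
    out = []
    for (ratio, source, rep), grp in df.groupby(
        ["condition_ratio", "mdh_source", "replicate"], sort=True
    ):
        wide = grp.pivot_table(
            index="time_min", columns="phase", values="amount_nmol"
        ).sort_index()
        out.append(
            AssayTimeCourse(
                condition_ratio=float(ratio),
                mdh_source=str(source),
                replicate=int(rep),
                times_min=wide.index.to_numpy(),
                droplet_nmol=wide["droplet"].to_numpy(),
                supernatant_nmol=wide["supernatant"].to_numpy(),
                enzyme_nmol=float(grp["enzyme_nmol"].iloc[0]),
            )
        )
    return out
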