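"""13C labeling-dynamics computations.

Cells fed a mixture of fully 13C-labeled and unlabeled glucose incorporate
label into downstream metabolites; GC-MS reports the abundance of each
isotopologue M+0 ... M+n per metabolite.  This module normalizes those
abundances into mass distribution vectors (MDV), computes the fractional
contribution FC = sum_i i*s(i)/n of the tracer to each metabolite's carbon,
summarizes unlabeled-fraction (M+0) decay curves, detects the metabolic
steady-state window, and fits the glucose uptake rate from medium-glucose vs
cell-dry-weight data.

No natural-isotope-abundance correction is applied (see
:func:`natural_abundance_correction`): labeling dynamics are compared between
strains measured on the same instrument, where the correction cancels to
first order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_model import ValidationError

__all__ = [
    "TIMEPOINT_HOURS",
    "IsotopologueSeries",
    "MDVec",
    "UptakeFit",
    "SteadyStateWindow",
    "compute_mdv",
    "fractional_contribution",
    "m0_curve",
    "fc_curve",
    "fit_labeling_kinetics",
    "detect_steady_state",
    "fit_glucose_uptake",
    "natural_abundance_correction",
    "read_isotopologue_table",
    "series_to_table",
]

#: collection labels -> hours after dilution (T0 is the pre-dilution sample)
TIMEPOINT_HOURS = {"T0": 0.0, "T1": 3.0, "T2": 4.0, "T3": 5.0, "T4": 6.0, "T5": 7.0}

MDVec = np.ndarray


def compute_mdv(raw: Sequence[float]) -> MDVec:
    """Mass distribution vector: isotopologue abundances normalized to sum 1."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or len(raw) < 2:
        raise ValidationError("need a 1-D vector of >= 2 isotopologue abundances")
    if np.any(raw < 0):
        raise ValidationError("abundances must be >= 0")
    total = raw.sum()
    if total == 0:
        raise ValidationError("all-zero isotopologue vector")
    return raw / total


def fractional_contribution(mdv: MDVec, n: int) -> float:
    """FC = sum_i i*s(i)/n: fraction of the metabolite's carbon from tracer."""
    mdv = np.asarray(mdv, dtype=float)
    if len(mdv) != n + 1:
        raise ValidationError(f"MDV of a {n}-carbon metabolite must have {n + 1} entries")
    return float(np.arange(n + 1) @ mdv / n)


def natural_abundance_correction(mdv: MDVec) -> MDVec:
    """No-op hook for natural 13C abundance correction.

    The analysis compares labeling dynamics between strains rather than
    absolute fluxes, so the correction is deliberately not applied; the hook
    exists so a correction matrix can be slotted in without touching callers.
    """
    return np.asarray(mdv, dtype=float)


@dataclass
class IsotopologueSeries:
    """Raw isotopologue abundances over time for one metabolite and strain.

    ``abundances`` has shape (n_times, n_replicates, n_carbons + 1).
    """

    metabolite: str
    strain: str
    n_carbons: int
    time_labels: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.n_carbons < 1:
            raise ValidationError("n_carbons must be >= 1")
        if self.abundances.ndim != 3 or self.abundances.shape[2] != self.n_carbons + 1:
            raise ValidationError(
                "abundances must have shape (times, replicates, n_carbons + 1)"
            )
        if self.abundances.shape[0] != len(self.time_labels):
            raise ValidationError("one abundance block per time label required")
        if np.any(self.abundances < 0):
            raise ValidationError("abundances must be >= 0")

    @property
    def times_h(self) -> np.ndarray:
        return np.array([TIMEPOINT_HOURS[t] for t in self.time_labels])

    def mdvs(self) -> np.ndarray:
        """Replicate-wise MDVs, same shape as abundances."""
        out = np.empty_like(self.abundances)
        for i in range(self.abundances.shape[0]):
            for j in range(self.abundances.shape[1]):
                out[i, j] = compute_mdv(self.abundances[i, j])
        return out


def m0_curve(series: IsotopologueSeries) -> pd.DataFrame:
    """Per-time mean and SD of the unlabeled fraction s(0)."""
    s0 = series.mdvs()[:, :, 0]
    return pd.DataFrame(
        {
            "time_label": series.time_labels,
            "time_h": series.times_h,
            "mean_m0": s0.mean(axis=1),
            "sd_m0": s0.std(axis=1, ddof=1) if s0.shape[1] > 1 else 0.0,
        }
    )


def fc_curve(series: IsotopologueSeries) -> pd.DataFrame:
    """Per-time mean and SD of the fractional contribution."""
    mdvs = series.mdvs()
    fc = np.array(
        [
            [fractional_contribution(mdvs[i, j], series.n_carbons)
             for j in range(mdvs.shape[1])]
            for i in range(mdvs.shape[0])
        ]
    )
    return pd.DataFrame(
        {
            "time_label": series.time_labels,
            "time_h": series.times_h,
            "mean_fc": fc.mean(axis=1),
            "sd_fc": fc.std(axis=1, ddof=1) if fc.shape[1] > 1 else 0.0,
            "se_fc": (fc.std(axis=1, ddof=1) / np.sqrt(fc.shape[1]))
            if fc.shape[1] > 1
            else 0.0,
        }
    )


def fit_labeling_kinetics(series: IsotopologueSeries) -> tuple[float, float, float]:
    """Fit FC(t) = p*(1 - exp(-lambda*t)); returns (plateau p, rate lambda, plateau SE).

    The plateau equals the labeled fraction of the feed at isotopic steady
    state; the rate orders strains by how fast their pools turn over.
    """
    from scipy.optimize import curve_fit

    curve = fc_curve(series)
    t = curve["time_h"].to_numpy()
    y = curve["mean_fc"].to_numpy()

    def model(t, p, lam):
        return p * (1.0 - np.exp(-lam * t))

    p0 = (max(y.max(), 0.1), 0.5)
    popt, pcov = curve_fit(
        model, t, y, p0=p0, bounds=([0.0, 1e-6], [1.0, 50.0]), maxfev=10000
    )
    return float(popt[0]), float(popt[1]), float(np.sqrt(pcov[0, 0]))


@dataclass(frozen=True)
class SteadyStateWindow:
    """Contiguous trailing block of time points at metabolic steady state."""

    labels: tuple[str, ...]
    level_slope_pvalues: dict
    uptake_relative_spread: float
    alpha: float
    uptake_tolerance: float

    @property
    def empty(self) -> bool:
        return len(self.labels) == 0


def detect_steady_state(
    levels: pd.DataFrame,
    uptake_rates: Sequence[float],
    alpha: float = 0.05,
    uptake_tolerance: float = 0.20,
) -> SteadyStateWindow:
    """Largest trailing window with flat metabolite levels and steady uptake.

    ``levels`` is a tidy frame with columns time_label, metabolite, intensity
    (replicates as repeated rows).  A window qualifies when (a) no metabolite
    shows a regression slope of intensity on time significantly different
    from zero at ``alpha`` (two-sided), and (b) the per-interval uptake rates
    inside the window stay within ``uptake_tolerance`` relative spread of
    their mean.  Windows are trailing blocks of >= 3 time points, largest
    first.
    """
    for col in ("time_label", "metabolite", "intensity"):
        if col not in levels.columns:
            raise ValidationError(f"levels frame missing column {col!r}")
    labels = sorted(levels["time_label"].unique(), key=lambda t: TIMEPOINT_HOURS[t])
    if len(labels) < 3:
        raise ValidationError("need >= 3 candidate time points")
    uptake_rates = np.asarray(uptake_rates, dtype=float)

    def window_ok(window: list[str]) -> tuple[bool, dict, float]:
        sub = levels[levels["time_label"].isin(window)]
        hours = sub["time_label"].map(TIMEPOINT_HOURS)
        pvals = {}
        ok = True
        for metab, grp in sub.groupby("metabolite"):
            t = hours.loc[grp.index].to_numpy(dtype=float)
            y = grp["intensity"].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                pvals[metab] = 1.0
                continue
            res = stats.linregress(t, y)
            pvals[metab] = float(res.pvalue)
            if res.pvalue < alpha:
                ok = False
        # intervals whose right endpoint lies in the window
        first = labels.index(window[0])
        rates = uptake_rates[max(first - 1, 0): len(labels) - 1]
        rates = rates[: len(window)]
        spread = 0.0
        if len(rates) > 1 and np.mean(rates) != 0:
            spread = float(np.ptp(rates) / abs(np.mean(rates)))
            if spread > uptake_tolerance:
                ok = False
        return ok, pvals, spread

    for size in range(len(labels), 2, -1):
        window = labels[-size:]
        ok, pvals, spread = window_ok(window)
        if ok:
            return SteadyStateWindow(
                labels=tuple(window),
                level_slope_pvalues=pvals,
                uptake_relative_spread=spread,
                alpha=alpha,
                uptake_tolerance=uptake_tolerance,
            )
    return SteadyStateWindow(
        labels=(),
        level_slope_pvalues={},
        uptake_relative_spread=float("nan"),
        alpha=alpha,
        uptake_tolerance=uptake_tolerance,
    )


@dataclass(frozen=True)
class UptakeFit:
    """Glucose uptake rate from dS = (-q/m) dC regression."""

    q: float
    m: float
    slope: float
    r_squared: float


def fit_glucose_uptake(
    glucose_g_per_L: Sequence[float],
    cdw_g: Sequence[float],
    growth_rate: float,
) -> UptakeFit:
    """Uptake rate q (g gCDW^-1 h^-1) from glucose depletion vs biomass gain.

    Regresses the change in medium glucose on the change in cell dry weight
    (both relative to the first observation, line through the origin); the
    slope is -q/m with m the growth rate.
    """
    S = np.asarray(glucose_g_per_L, dtype=float)
    C = np.asarray(cdw_g, dtype=float)
    if len(S) != len(C) or len(S) < 3:
        raise ValidationError("need >= 3 paired (glucose, CDW) observations")
    if growth_rate <= 0:
        raise ValidationError("growth_rate must be > 0")
    dS = S[1:] - S[0]
    dC = C[1:] - C[0]
    denom = float(dC @ dC)
    if denom == 0:
        raise ValidationError("zero variance in cell dry weight")
    slope = float(dS @ dC) / denom
    fitted = slope * dC
    ss_res = float(np.sum((dS - fitted) ** 2))
    ss_tot = float(np.sum((dS - dS.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return UptakeFit(q=-slope * growth_rate, m=growth_rate, slope=slope, r_squared=r2)


# ---------------------------------------------------------------------------
# delimited-table round trip


def series_to_table(series_list: Sequence[IsotopologueSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for i, label in enumerate(s.time_labels):
            for j in range(s.abundances.shape[1]):
                for m in range(s.n_carbons + 1):
                    rows.append(
                        {
                            "metabolite": s.metabolite,
                            "strain": s.strain,
                            "n_carbons": s.n_carbons,
                            "time_label": label,
                            "replicate": j + 1,
                            "isotopologue": f"M+{m}",
                            "abundance": s.abundances[i, j, m],
                        }
                    )
    return pd.DataFrame(rows)


def read_isotopologue_table(path, sep: str = ",") -> list[IsotopologueSeries]:
    df = pd.read_csv(path, sep=sep)
    required = {
        "metabolite", "strain", "n_carbons", "time_label", "replicate",
        "isotopologue", "abundance",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"isotopologue table missing columns: {sorted(missing)}")
    out = []
    for (metab, strain), grp in df.groupby(["metabolite", "strain"], sort=True):
        n = int(grp["n_carbons"].iloc[0])
        labels = sorted(grp["time_label"].unique(), key=lambda t: TIMEPOINT_HOURS[t])
        reps = sorted(grp["replicate"].unique())
        abund = np.zeros((len(labels), len(reps), n + 1))
        iso_order = [f"M+{m}" for m in range(n + 1)]
        for (label, rep), sub in grp.groupby(["time_label", "replicate"]):
            vec = sub.set_index("isotopologue")["abundance"].reindex(iso_order)
            if vec.isna().any():
                raise ValidationError(
                    f"{metab}/{strain}/{label}: every isotopologue M+0..M+{n} required"
                )
            abund[labels.index(label), reps.index(rep)] = vec.to_numpy()
        out.append(
            IsotopologueSeries(
                metabolite=str(metab),
                strain=str(strain),
                n_carbons=n,
                time_labels=labels,
                abundances=abund,
            )
        )
    return out
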