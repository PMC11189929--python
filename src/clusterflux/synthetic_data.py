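"""Seeded generators for every input the analysis stages consume.

Each generator emulates one experiment family of the study:

* :func:`gen_llps_assay` -- droplet/supernatant product time courses over the
  MDH:ICD molar-ratio ladder (1:1 ... 500:1), for the endogenous enzyme and
  two orthologs.  Truth enhancements rise from ~10% at 10:1 to 180% at and
  above 250:1 for the endogenous enzyme and are 0 for orthologs; the truth
  droplet/supernatant concentration ratio at 40 min is 2 at 500:1 endogenous
  and 1 otherwise.  These anchors are the printed experimental outcomes, not
  model output: the abundance-to-clustering map is empirical (see
  :mod:`clusterflux.llps_assay`).
* :func:`gen_tracer_dataset` -- 13C isotopologue time series for TCA/anabolic
  metabolites under a 55%/45% labeled/unlabeled glucose feed, with labeling
  kinetics FC(t) = p(1 - exp(-lambda t)), plateau p = 0.55, and lambda reduced
  in MDH-overexpression strains (the flux-delay truth), plus a glucose
  uptake table with constant truth uptake rate.
* :func:`gen_intensity_table` -- GC-MS-style metabolite intensity tables with
  strain/replicate/OD metadata; endogenous-MDH strains carry a 3.5x
  2-oxoglutarate increase and 2-5x drops across the glutamate-derived amino
  acid pool; ortholog and control strains are null.

All noise is multiplicative log-normal with a configured CV (positivity
preserving, mean preserving), drawn from one seeded generator in a fixed
order, so identical configs give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .cluster_model import ValidationError
from .isotope_tracer import TIMEPOINT_HOURS, IsotopologueSeries
from .llps_assay import AssayTimeCourse

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "gen_llps_assay",
    "gen_tracer_dataset",
    "gen_intensity_table",
    "write_dataset",
]

#: MDH:ICD molar-ratio ladder of the droplet assay (0 = no MDH baseline)
ASSAY_RATIOS = (0.0, 1.0, 10.0, 50.0, 100.0, 250.0, 500.0)

#: truth percent enhancement per ratio, endogenous MDH (printed anchors at
#: 10:1 -> ~10% and >= 250:1 -> 180%; intermediate points interpolate the
#: saturating dose response of the published assay figure)
ENDOGENOUS_ENHANCEMENT = {
    0.0: 0.0, 1.0: 2.0, 10.0: 10.0, 50.0: 60.0,
    100.0: 120.0, 250.0: 180.0, 500.0: 180.0,
}

#: truth droplet/supernatant concentration ratio at 40 min, endogenous MDH
ENDOGENOUS_PARTITION_40MIN = {
    0.0: 1.0, 1.0: 1.05, 10.0: 1.1, 50.0: 1.3,
    100.0: 1.5, 250.0: 1.8, 500.0: 2.0,
}

ASSAY_TIMES_MIN = (0.0, 10.0, 20.0, 30.0, 40.0, 60.0)
ORTHOLOG_SOURCES = ("StMDH", "OceMDH")

TRACER_METABOLITES = {"succinate": 4, "fumarate": 4, "ornithine": 5, "valine": 5}
#: labeling rate truths (1/h): overexpression strains are delayed
TRACER_LAMBDA = {"control": 1.0, "BsMDH": 0.45, "inactBsMDH": 0.5}
LABEL_PLATEAU = 0.55  # fraction of labeled glucose in the feed
ISOTOPE_BLUR_EPS = 0.02

METABOLITE_EFFECTS_ENDOGENOUS = {
    # carbon-nitrogen branchpoint jam: product accumulates ...
    "2-oxoglutarate": 3.5,
    # ... while the glutamate-derived pool drops 2-5x
    "glutamine": 1 / 3.5, "aspartate": 1 / 2.5, "valine": 1 / 3.0,
    "leucine": 1 / 4.0, "isoleucine": 1 / 5.0, "ornithine": 1 / 3.0,
    "citrulline": 1 / 2.0, "arginine": 1 / 2.0, "glutamate": 1 / 1.25,
    # downstream TCA intermediates drop moderately
    "succinate": 1 / 1.6, "fumarate": 1 / 1.6, "malate": 1 / 1.4,
    "oxaloacetate": 1 / 1.5,
    # glycolysis/anaplerosis crossroad
    "pyruvate": 1.8, "phosphoenolpyruvate": 1.5, "fructose-1,6-diphosphate": 1 / 1.3,
}

INTENSITY_METABOLITES = tuple(
    list(METABOLITE_EFFECTS_ENDOGENOUS)
    + ["citrate", "isocitrate", "glucose-6-phosphate", "alanine", "serine"]
)

INTENSITY_STRAINS = (
    "control", "BsMDH", "inactBsMDH", "StMDH", "inactStMDH", "OceMDH", "inactOceMDH"
)
ENDOGENOUS_STRAINS = ("BsMDH", "inactBsMDH")


@dataclass(frozen=True)
class SyntheticConfig:
    """Seeded generator configuration.

    ``cv`` is the multiplicative noise coefficient of variation applied to
    every measured quantity; replicate counts default to the study's (3 for
    assay/tracer, 4 for metabolomics).
    """

    seed: int = 0
    cv: float = 0.05
    preset: str = "endogenous"
    replicates_assay: int = 3
    replicates_tracer: int = 3
    replicates_metab: int = 4

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if min(self.replicates_assay, self.replicates_tracer) < 1:
            raise ValidationError("replicate counts must be >= 1")
        if self.replicates_metab < 2:
            raise ValidationError("metabolomics needs >= 2 replicates")


@dataclass
class TruthRecord:
    """Ground-truth parameters serialized alongside each generated dataset."""

    kind: str
    config: dict
    truth: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-preserving log-normal multipliers with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def gen_llps_assay(
    config: SyntheticConfig,
    enzyme_nmol: float = 0.1,
    baseline_velocity_per_s: float = 0.1,
) -> tuple[list[AssayTimeCourse], TruthRecord]:
    """Droplet-assay product time courses for the full condition ladder.

    Product accumulates linearly at the condition's truth velocity; the
    droplet/supernatant split follows a partition ratio growing linearly in
    time to its 40-minute truth value.  The ratio-0 baseline is generated
    once (source ``none``); ortholog conditions have zero truth enhancement
    and no preferential partitioning.
    """
    if config.preset not in ("endogenous", "null"):
        raise ValidationError(f"unknown assay preset {config.preset!r}")
    rng = np.random.default_rng(config.seed)
    times = np.asarray(ASSAY_TIMES_MIN)
    courses: list[AssayTimeCourse] = []

    def truth_for(source: str, ratio: float) -> tuple[float, float]:
        if config.preset == "null" or source in ORTHOLOG_SOURCES or ratio == 0.0:
            enh = 0.0
            part = 1.0
        else:
            enh = ENDOGENOUS_ENHANCEMENT[ratio]
            part = ENDOGENOUS_PARTITION_40MIN[ratio]
        return enh, part

    conditions = [("none", 0.0)]
    conditions += [("BsMDH", r) for r in ASSAY_RATIOS if r > 0]
    conditions += [(s, r) for s in ORTHOLOG_SOURCES for r in ASSAY_RATIOS if r > 0]

    truth = {}
    for source, ratio in conditions:
        enh, part40 = truth_for(source, ratio)
        truth[f"{source}:{ratio:g}"] = {"enhancement_pct": enh, "partition_40min": part40}
        v = baseline_velocity_per_s * (1.0 + enh / 100.0)  # 1/s per enzyme
        total = v * enzyme_nmol * times * 60.0  # nmol
        part_t = 1.0 + (part40 - 1.0) * times / 40.0
        droplet = total * part_t / (1.0 + part_t)
        supernatant = total / (1.0 + part_t)
        for rep in range(1, config.replicates_assay + 1):
            d = droplet * _noise(rng, config.cv, droplet.shape)
            s = supernatant * _noise(rng, config.cv, supernatant.shape)
            courses.append(
                AssayTimeCourse(
                    condition_ratio=ratio,
                    mdh_source=source,
                    replicate=rep,
                    times_min=times,
                    droplet_nmol=d,
                    supernatant_nmol=s,
                    enzyme_nmol=enzyme_nmol,
                )
            )
    record = TruthRecord(
        kind="llps_assay",
        config=asdict(config),
        truth={
            "baseline_velocity_per_s": baseline_velocity_per_s,
            "enzyme_nmol": enzyme_nmol,
            "conditions": truth,
        },
    )
    return courses, record


def _mixture_mdv(n: int, f: float) -> np.ndarray:
    """Expected MDV of a two-pool mixture with a blurred labeled pool.

    The unlabeled pool is pure M+0 (so an unlabeled culture shows s(0) = 1
    exactly); the labeled pool is binomially blurred, Binomial(n, 1 - eps),
    to populate intermediate isotopologues.
    """
    labeled = binom.pmf(np.arange(n + 1), n, 1.0 - ISOTOPE_BLUR_EPS)
    unlabeled = np.zeros(n + 1)
    unlabeled[0] = 1.0
    return (1.0 - f) * unlabeled + f * labeled


def gen_tracer_dataset(
    config: SyntheticConfig,
    intensity_scale: float = 1e5,
    uptake_q: float = 0.9,
    growth_rate: float = 0.6,
) -> tuple[list[IsotopologueSeries], pd.DataFrame, TruthRecord]:
    """13C labeling time series plus a glucose-uptake table.

    FC(t) follows p*(1 - exp(-lambda t)) with plateau p = 0.55 (the labeled
    fraction of the feed) for every strain; lambda is reduced in the
    MDH-overexpression strains.  The labeled-pool mixture fraction is scaled
    by 1/(1 - eps) so the realized FC plateau equals p exactly despite the
    binomial blur.  Total intensities drift in the first two collection
    points and are flat afterwards (the metabolic steady-state window).
    """
    rng = np.random.default_rng(config.seed + 1)
    labels = list(TIMEPOINT_HOURS)
    hours = np.array([TIMEPOINT_HOURS[t] for t in labels])
    level_drift = {"T0": 1.6, "T1": 1.15}  # pre-steady-state drift factors

    series_list = []
    for strain, lam in TRACER_LAMBDA.items():
        for metab, n in TRACER_METABOLITES.items():
            abund = np.zeros((len(labels), config.replicates_tracer, n + 1))
            for i, label in enumerate(labels):
                fc = LABEL_PLATEAU * (1.0 - np.exp(-lam * hours[i]))
                f = fc / (1.0 - ISOTOPE_BLUR_EPS)
                mdv = _mixture_mdv(n, f)
                scale = intensity_scale * level_drift.get(label, 1.0)
                for j in range(config.replicates_tracer):
                    abund[i, j] = scale * mdv * _noise(rng, config.cv, n + 1)
            series_list.append(
                IsotopologueSeries(
                    metabolite=metab,
                    strain=strain,
                    n_carbons=n,
                    time_labels=labels,
                    abundances=abund,
                )
            )

    # glucose uptake: dS = (-q/m) dC along exponential growth, 0.4% glucose
    t_u = np.array([3.0, 4.0, 5.0, 6.0])
    C0 = 0.05
    C = C0 * np.exp(growth_rate * (t_u - t_u[0]))
    S = 4.0 - (uptake_q / growth_rate) * (C - C0)
    uptake = pd.DataFrame(
        {
            "time_h": t_u,
            "glucose_g_per_L": S * _noise(rng, config.cv / 5.0, S.shape),
            "cdw_g": C * _noise(rng, config.cv / 5.0, C.shape),
        }
    )
    record = TruthRecord(
        kind="tracer",
        config=asdict(config),
        truth={
            "plateau": LABEL_PLATEAU,
            "lambda_per_h": dict(TRACER_LAMBDA),
            "uptake_q": uptake_q,
            "growth_rate": growth_rate,
            "steady_state_labels": ["T2", "T3", "T4", "T5"],
        },
    )
    return series_list, uptake, record


def gen_intensity_table(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Strain x replicate metabolite intensity table with OD metadata.

    Endogenous-MDH strains (active and inactive) carry the truth fold
    changes; ortholog and control strains are null.  The ``null`` preset
    switches all effects off.
    """
    if config.preset not in ("endogenous", "null"):
        raise ValidationError(f"unknown intensity preset {config.preset!r}")
    rng = np.random.default_rng(config.seed + 2)
    base = {
        m: float(10 ** rng.uniform(4.0, 6.0)) for m in INTENSITY_METABOLITES
    }
    rows = []
    for strain in INTENSITY_STRAINS:
        effected = config.preset == "endogenous" and strain in ENDOGENOUS_STRAINS
        for rep in range(1, config.replicates_metab + 1):
            od = 0.4 * float(_noise(rng, 0.03, ()))
            row = {"strain": strain, "replicate": rep, "od": od}
            for m in INTENSITY_METABOLITES:
                fold = METABOLITE_EFFECTS_ENDOGENOUS.get(m, 1.0) if effected else 1.0
                row[m] = base[m] * fold * od * float(_noise(rng, config.cv, ()))
            rows.append(row)
    table = pd.DataFrame(rows)
    record = TruthRecord(
        kind="intensity",
        config=asdict(config),
        truth={
            "base_intensity": base,
            "fold_changes_endogenous": (
                dict(METABOLITE_EFFECTS_ENDOGENOUS)
                if config.preset == "endogenous"
                else {}
            ),
            "endogenous_strains": list(ENDOGENOUS_STRAINS),
        },
    )
    return table, record


def write_dataset(outdir: str | Path, name: str, frame: pd.DataFrame, record: TruthRecord) -> None:
    """Write a generated table plus its truth record with fixed formatting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    record.to_json(outdir / f"{name}.truth.json")
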