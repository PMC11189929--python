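"""Metabolite-intensity processing: normalization, fold changes, branchpoint
ratios, exact rank-sum testing, and PCA scores.

Input tables are tidy sample x metabolite intensity matrices with ``strain``,
``replicate`` and ``od`` metadata columns (one row per harvested culture).
Intensities are normalized to the culture's optical density, compared to a
control strain as (signed-log) fold changes, and summarized as branchpoint
metabolite ratios normalized so the control ratio is 1.  Group comparisons at
the small sample sizes typical of such experiments (3-4 replicates) use a
two-tailed Mann-Whitney test whose p-value is computed exactly from the full
permutation distribution of the rank-sum statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cluster_model import ValidationError

__all__ = [
    "META_COLUMNS",
    "TestResult",
    "normalize_by_od",
    "relative_to_control",
    "metabolite_ratio",
    "mann_whitney_exact",
    "pca_scores",
    "metabolite_columns",
]

META_COLUMNS = ("strain", "replicate", "od")

#: largest per-group size for which the exact permutation distribution is used
EXACT_MAX_GROUP = 8


def metabolite_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _check_table(table: pd.DataFrame) -> None:
    missing = set(META_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"intensity table missing columns: {sorted(missing)}")
    mets = metabolite_columns(table)
    if not mets:
        raise ValidationError("intensity table has no metabolite columns")
    if (table[mets] < 0).any().any():
        raise ValidationError("intensities must be non-negative")


def normalize_by_od(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's intensities by its OD at harvest."""
    _check_table(table)
    if table["od"].isna().any() or (table["od"] <= 0).any():
        raise ValidationError("every sample needs OD > 0")
    out = table.copy()
    mets = metabolite_columns(table)
    out[mets] = out[mets].div(out["od"], axis=0)
    return out


def relative_to_control(
    table: pd.DataFrame, control_label: str = "control", log_base: int = 2
) -> pd.DataFrame:
    """Signed log fold-change matrix (strains x metabolites) vs the control.

    Values are log_base(strain mean / control mean); the control row is
    exactly zero.  Published heat maps render the negated matrix (-log2 or
    -log10); that sign flip is presentation, so the stored convention is the
    plain strain-over-control log ratio.  Metabolites with a zero control
    mean are dropped with a warning.
    """
    _check_table(table)
    if log_base not in (2, 10):
        raise ValidationError("log_base must be 2 or 10")
    strains = table["strain"].unique()
    if control_label not in strains:
        raise ValidationError(f"control strain {control_label!r} not in table")
    mets = metabolite_columns(table)
    means = table.groupby("strain")[mets].mean()
    ctrl = means.loc[control_label]
    bad = ctrl[ctrl == 0].index.tolist()
    if bad:
        import warnings

        warnings.warn(
            f"dropping metabolites with zero control mean: {bad}", RuntimeWarning,
            stacklevel=2,
        )
        means = means.drop(columns=bad)
        ctrl = ctrl.drop(index=bad)
    log = np.log2 if log_base == 2 else np.log10
    fc = means.divide(ctrl, axis=1)
    out = pd.DataFrame(log(fc), index=means.index, columns=means.columns)
    out.loc[control_label] = 0.0
    return out


def mann_whitney_exact(x, y) -> "TestResult":
    """Two-tailed Mann-Whitney U test, exact at small group sizes.

    U is computed by average-rank summation.  When both groups have at most
    8 observations the two-tailed p comes from the full permutation
    distribution of U over all C(n1+n2, n1) group assignments of the pooled
    value multiset (ties therefore handled exactly), doubling the smaller
    tail and capping at 1.  Larger groups fall back to the tie-corrected
    normal approximation and are tagged as such.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        total = math.comb(n1 + n2, n1)
        le = ge = 0
        base = n1 * (n1 + 1) / 2.0
        eps = 1e-9
        for idx in combinations(range(n1 + n2), n1):
            u = float(ranks[list(idx)].sum() - base)
            if u <= u1 + eps:
                le += 1
            if u >= u1 - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        method = "exact"
    else:
        # normal approximation with tie correction
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            from scipy.stats import norm

            z = (u1 - mu) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "normal-approximation"
    return TestResult(statistic=u1, pvalue=float(max(p, np.nextafter(0, 1))),
                      method=method, n1=n1, n2=n2)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n1: int
    n2: int


def metabolite_ratio(
    table: pd.DataFrame,
    numerator: str,
    denominator: str,
    control_label: str = "control",
) -> pd.DataFrame:
    """Branchpoint metabolite ratio per strain, normalized so control = 1.

    The per-strain point estimate is (mean numerator)/(mean denominator)
    divided by the control strain's same quantity.  Each strain's
    replicate-wise numerator/denominator ratios are compared with the
    control's by the exact two-tailed Mann-Whitney test; dispersion is the
    SD of replicate ratios on the control-normalized scale.
    """
    _check_table(table)
    mets = metabolite_columns(table)
    for m in (numerator, denominator):
        if m not in mets:
            raise ValidationError(f"metabolite {m!r} not in table")
    if control_label not in table["strain"].unique():
        raise ValidationError(f"control strain {control_label!r} not in table")

    cols = [numerator] if numerator == denominator else [numerator, denominator]
    means = table.groupby("strain")[cols].mean()
    if (means[denominator] == 0).any():
        raise ValidationError(f"zero mean denominator {denominator!r} for some strain")
    raw_ratio = means[numerator] / means[denominator]
    ctrl_ratio = raw_ratio.loc[control_label]
    if ctrl_ratio == 0:
        raise ValidationError("control ratio is zero; cannot normalize")

    rep_ratio = {}
    for strain, grp in table.groupby("strain"):
        den = grp[denominator].to_numpy(dtype=float)
        if np.any(den == 0):
            raise ValidationError(f"zero denominator replicate in strain {strain!r}")
        rep_ratio[strain] = grp[numerator].to_numpy(dtype=float) / den

    rows = []
    ctrl_reps = rep_ratio[control_label]
    for strain in means.index:
        reps = rep_ratio[strain] / ctrl_ratio
        if strain == control_label:
            p = 1.0
            stat = math.nan
        else:
            res = mann_whitney_exact(rep_ratio[strain], ctrl_reps)
            p, stat = res.pvalue, res.statistic
        rows.append(
            {
                "strain": strain,
                "numerator": numerator,
                "denominator": denominator,
                "ratio": float(raw_ratio.loc[strain] / ctrl_ratio),
                "sd": float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0,
                "n": len(reps),
                "U": stat,
                "pvalue": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("strain")


def pca_scores(
    table: pd.DataFrame, scaling: str = "unit", n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and explained-variance fractions of the intensity matrix.

    ``scaling='unit'`` autoscales each metabolite to unit variance before the
    singular decomposition (constant metabolites are dropped);
    ``scaling='center'`` only centers.  Returns (scores frame with strain and
    replicate metadata, explained-variance fractions).
    """
    _check_table(table)
    mets = metabolite_columns(table)
    X = table[mets].to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need >= 2 samples and >= 2 metabolites")
    X = X - X.mean(axis=0)
    if scaling == "unit":
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise ValidationError("constant matrix; PCA undefined")
        X = X[:, keep] / sd[keep]
    elif scaling == "center":
        if np.allclose(X, 0):
            raise ValidationError("constant matrix; PCA undefined")
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")

    from sklearn.decomposition import PCA

    k = min(X.shape) if n_components is None else n_components
    k = min(k, min(X.shape))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        index=table.index,
    )
    frame.insert(0, "strain", table["strain"].to_numpy())
    frame.insert(1, "replicate", table["replicate"].to_numpy())
    return frame, pca.explained_variance_ratio_
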