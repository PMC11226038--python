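"""Two-factor ANOVA decomposition and effect-size biomarker ranking.

The ranked quantity is the treatment × time interaction ("the effect").
Three effect sizes are computed from the decomposition:

    eta² = SS_effect / SS_total
    partial eta² = SS_effect / (SS_total + SS_error)
    omega² = (SS_effect − DF_effect · MS_error) / (SS_total + MS_error)

The partial eta² denominator above follows the source protocol verbatim
(its reported values sit *below* eta², which the textbook definition
``SS_effect / (SS_effect + SS_error)`` cannot produce); the textbook form
is also computed as ``partial_eta2_classic``.  omega² is reported raw and
may be negative.

An effect is flagged "large" above 0.138 (configurable).

Outlier flagging approximates a Q-targeted robust procedure with a
median/MAD z-score and Benjamini-Hochberg control at the Q level; it is
documented as NOT bit-compatible with the proprietary original.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaDecomposition",
    "EffectSizes",
    "two_way_anova",
    "effect_sizes",
    "rank_biomarkers",
    "flag_outliers",
    "LARGE_EFFECT_THRESHOLD",
]

#: Default "large effect" cutoff (the dashed-line convention).
LARGE_EFFECT_THRESHOLD = 0.138


@dataclass
class AnovaDecomposition:
    """Cell-means sums of squares for a two-factor layout with interaction."""

    ss_a: float
    ss_b: float
    ss_effect: float  # A × B interaction
    ss_error: float
    ss_total: float
    df_a: int
    df_b: int
    df_effect: int
    df_error: int
    n_obs: int
    balanced: bool

    @property
    def ms_error(self) -> float:
        if self.df_error <= 0:
            return float("nan")
        return self.ss_error / self.df_error


def two_way_anova(
    design_table: pd.DataFrame,
    factor_a: str = "group",
    factor_b: str = "timepoint",
    response: str = "value",
) -> AnovaDecomposition:
    """Cell-means decomposition of a two-factor design.

    Balanced designs partition exactly: SS_total = SS_A + SS_B +
    SS_effect + SS_error.  Unbalanced designs (deaths, exclusions) use the
    unweighted-cell-means analysis with the harmonic mean cell size; the
    partition is then approximate and ``balanced`` is False.

    Raises on empty cells.  A design with a single replicate everywhere is
    allowed but yields SS_error = 0 and DF_error = 0 (MS_error = NaN).
    """
    df = design_table[[factor_a, factor_b, response]].dropna()
    a_levels = sorted(df[factor_a].unique(), key=str)
    b_levels = sorted(df[factor_b].unique(), key=str)
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError(
            f"need ≥2 levels per factor, got {a} × {b} ({factor_a} × {factor_b})"
        )
    y = df[response].to_numpy(dtype=float)
    n_obs = len(y)

    cells: dict[tuple, np.ndarray] = {}
    for (la, lb), sub in df.groupby([factor_a, factor_b]):
        cells[(la, lb)] = sub[response].to_numpy(dtype=float)
    for la in a_levels:
        for lb in b_levels:
            if (la, lb) not in cells:
                raise ValueError(f"empty cell: {factor_a}={la!r}, {factor_b}={lb!r}")

    ns = np.array([[len(cells[(la, lb)]) for lb in b_levels] for la in a_levels], float)
    means = np.array(
        [[cells[(la, lb)].mean() for lb in b_levels] for la in a_levels], float
    )
    balanced = bool(np.all(ns == ns.flat[0]))

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = float(
        sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    )

    if balanced:
        n = ns.flat[0]
        mu = means.mean()
        mu_a = means.mean(axis=1)
        mu_b = means.mean(axis=0)
        ss_a = float(b * n * ((mu_a - mu) ** 2).sum())
        ss_b = float(a * n * ((mu_b - mu) ** 2).sum())
        inter = means - mu_a[:, None] - mu_b[None, :] + mu
        ss_effect = float(n * (inter**2).sum())
    else:
        # unweighted means with harmonic cell size
        n_h = a * b / float((1.0 / ns).sum())
        mu = means.mean()
        mu_a = means.mean(axis=1)
        mu_b = means.mean(axis=0)
        ss_a = float(b * n_h * ((mu_a - mu) ** 2).sum())
        ss_b = float(a * n_h * ((mu_b - mu) ** 2).sum())
        inter = means - mu_a[:, None] - mu_b[None, :] + mu
        ss_effect = float(n_h * (inter**2).sum())

    df_error = n_obs - a * b
    if df_error == 0:
        warnings.warn(
            "single replicate per cell: SS_error = 0, MS_error undefined",
            stacklevel=2,
        )
    return AnovaDecomposition(
        ss_a=ss_a,
        ss_b=ss_b,
        ss_effect=ss_effect,
        ss_error=ss_error,
        ss_total=ss_total,
        df_a=a - 1,
        df_b=b - 1,
        df_effect=(a - 1) * (b - 1),
        df_error=df_error,
        n_obs=n_obs,
        balanced=balanced,
    )


@dataclass
class EffectSizes:
    eta2: float
    partial_eta2: float  # SS_effect / (SS_total + SS_error), per protocol
    partial_eta2_classic: float  # SS_effect / (SS_effect + SS_error)
    omega2: float  # raw, may be negative
    large_effect_threshold: float
    large_eta2: bool
    large_partial_eta2: bool
    large_omega2: bool


def effect_sizes(
    decomposition: AnovaDecomposition,
    large_effect_threshold: float = LARGE_EFFECT_THRESHOLD,
) -> EffectSizes:
    """Apply the three effect-size formulas to a decomposition."""
    d = decomposition
    if d.ss_total <= 0:
        raise ValueError("SS_total must be > 0 to define effect sizes")
    eta2 = d.ss_effect / d.ss_total
    partial = d.ss_effect / (d.ss_total + d.ss_error)
    if d.ss_effect + d.ss_error > 0:
        classic = d.ss_effect / (d.ss_effect + d.ss_error)
    else:
        classic = 0.0
    ms_error = d.ms_error
    if np.isnan(ms_error):
        omega2 = float("nan")
    else:
        omega2 = (d.ss_effect - d.df_effect * ms_error) / (d.ss_total + ms_error)
    return EffectSizes(
        eta2=float(eta2),
        partial_eta2=float(partial),
        partial_eta2_classic=float(classic),
        omega2=float(omega2),
        large_effect_threshold=large_effect_threshold,
        large_eta2=bool(eta2 > large_effect_threshold),
        large_partial_eta2=bool(partial > large_effect_threshold),
        large_omega2=bool(not np.isnan(omega2) and omega2 > large_effect_threshold),
    )


def rank_biomarkers(
    volume_table: pd.DataFrame,
    factor_a: str = "group",
    factor_b: str = "timepoint",
    response: str = "volume_mm3",
    unit_column: str = "bone_id",
    bone_order: list[str] | None = None,
    large_effect_threshold: float = LARGE_EFFECT_THRESHOLD,
) -> pd.DataFrame:
    """Per-bone ANOVA + effect sizes, ranked by descending eta².

    Ties are broken by catalog order (``bone_order``) when supplied, else
    by bone id.  partial eta² and omega² are carried as validation columns.
    """
    bones = list(volume_table[unit_column].unique())
    if len(bones) < 2:
        raise ValueError("ranking needs ≥2 bones")
    order = {u: i for i, u in enumerate(bone_order)} if bone_order else None
    rows = []
    for bone in bones:
        sub = volume_table[volume_table[unit_column] == bone]
        dec = two_way_anova(sub, factor_a, factor_b, response)
        es = effect_sizes(dec, large_effect_threshold)
        rows.append(
            {
                unit_column: bone,
                "eta2": es.eta2,
                "partial_eta2": es.partial_eta2,
                "partial_eta2_classic": es.partial_eta2_classic,
                "omega2": es.omega2,
                "large_eta2": es.large_eta2,
                "large_partial_eta2": es.large_partial_eta2,
                "large_omega2": es.large_omega2,
                "ss_effect": dec.ss_effect,
                "ss_error": dec.ss_error,
                "ss_total": dec.ss_total,
                "df_effect": dec.df_effect,
                "df_error": dec.df_error,
                "balanced": dec.balanced,
            }
        )
    out = pd.DataFrame(rows)
    tiebreak = (
        out[unit_column].map(order) if order is not None else out[unit_column]
    )
    out = (
        out.assign(_tb=tiebreak)
        .sort_values(["eta2", "_tb"], ascending=[False, True], kind="mergesort")
        .drop(columns="_tb")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def flag_outliers(values, q_target: float = 0.01) -> pd.DataFrame:
    """Median/MAD robust outlier flags with an FDR-style Q target.

    Robust z = (x − median) / (1.4826 · MAD); two-sided normal p-values are
    Benjamini-Hochberg adjusted and flagged below ``q_target``.  This is a
    documented stand-in for the proprietary robust-regression procedure,
    not a bit-compatible reimplementation.

    Requires ≥4 observations.  MAD = 0 yields no flags with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-dimensional")
    if len(x) < 4:
        raise ValueError(f"need ≥4 observations, got {len(x)}")
    if not 0 < q_target < 1:
        raise ValueError("q_target must be in (0, 1)")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers can be flagged", stacklevel=2)
        z = np.zeros_like(x)
        p = np.ones_like(x)
        flags = np.zeros(len(x), dtype=bool)
    else:
        z = (x - med) / (1.4826 * mad)
        p = 2.0 * sps.norm.sf(np.abs(z))
        flags = _benjamini_hochberg(p) < q_target
    return pd.DataFrame(
        {
            "value": x,
            "robust_z": z,
            "p_value": p,
            "outlier": flags,
            "method": "median-MAD robust z + BH (ROUT-like approximation)",
        }
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
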