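"""Replicated quantitative stage: moderated two-group tests on log2 data.

The quantitative design measures subcutaneous fat in four groups — FC, FF,
LC, LF (Fat/Lean line x control/high-fat diet) — with >=2 replicates per
group. Four pairwise contrasts are tested (FC vs LC, FF vs LF, FF vs FC,
LF vs LC) with an empirical-Bayes moderated t-statistic:

* per-probe residual (pooled two-group) variance ``s_g^2`` with
  ``df = n1 + n2 - 2`` residual degrees of freedom;
* a scaled inverse-chi-square prior ``(d0, s0^2)`` estimated from all
  probes by method-of-moments matching on ``log s_g^2``;
* shrunken variance ``s~^2 = (d0 s0^2 + df s_g^2) / (d0 + df)``;
* ``t = dmean / sqrt(s~^2 (1/n1 + 1/n2))`` referred to a t distribution
  on ``d0 + df`` degrees of freedom.

``d0 = 0`` reduces exactly to the ordinary pooled two-sample t test;
``d0 = inf`` pools all probes to a single common variance. P-values are
adjusted per contrast with the Benjamini-Hochberg step-up FDR procedure.

Significance is computed on the log2 scale; fold changes and the AU
expression floor are computed from group means of the linear intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import DEFAULT_EPSILON, ExpressionStudy, ValidationError

#: the four contrasts of the 2-line x 2-diet design, as
#: (group1, group2) pairs of (line, diet); log2_fold = group1 - group2
CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "FCvsLC": (("F", "control"), ("L", "control")),
    "FFvsLF": (("F", "highfat"), ("L", "highfat")),
    "FFvsFC": (("F", "highfat"), ("F", "control")),
    "LFvsLC": (("L", "highfat"), ("L", "control")),
}

DIET_RESPONSE_LABELS = (
    "line_only",
    "diet_only",
    "diet_amplified",
    "interaction_opposing",
    "null",
)


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior on per-probe residual variance."""

    d0: float  # prior degrees of freedom; may be math.inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValidationError("prior degrees of freedom d0 must be positive")
        if not self.s0_sq > 0:
            raise ValidationError("prior variance s0_sq must be positive")


#: sentinel prior meaning "no shrinkage": ordinary pooled two-sample t
NO_SHRINKAGE = VariancePrior.__new__(VariancePrior)
object.__setattr__(NO_SHRINKAGE, "d0", 0.0)
object.__setattr__(NO_SHRINKAGE, "s0_sq", 1.0)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic start x ~ 1/y (valid for small y) and the fact
    that trigamma is decreasing and convex.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 as x -> 0
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_variance_prior(variances: np.ndarray, df: int) -> VariancePrior:
    """Estimate (d0, s0^2) from per-probe residual variances.

    Method of moments on ``z = log s_g^2``: under the scaled
    inverse-chi-square model, ``z`` has variance
    ``trigamma(df/2) + trigamma(d0/2)``; the excess of the observed
    variance of ``z`` over ``trigamma(df/2)`` identifies ``d0``, and the
    mean of ``z`` then identifies ``s0^2`` through digamma corrections.
    When the observed spread does not exceed the theoretical minimum,
    ``d0 = inf`` (fully pooled variance) is returned.
    """
    s2 = np.asarray(variances, dtype=float)
    if s2.ndim != 1 or len(s2) < 10:
        raise ValidationError(
            f"need >=10 residual variances to estimate a prior, got {s2.size}"
        )
    if (s2 <= 0).any():
        raise ValidationError("residual variances must be positive")
    if df < 1:
        raise ValidationError("residual degrees of freedom must be >= 1")

    if np.ptp(s2) == 0.0:
        # exactly degenerate input: no spread at all
        return VariancePrior(d0=math.inf, s0_sq=float(s2[0]))

    half_df = df / 2.0
    z = np.log(s2)
    e = z - float(special.digamma(half_df)) + math.log(half_df)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1))
    excess = var_e - float(special.polygamma(1, half_df))
    if excess <= 0:
        return VariancePrior(d0=math.inf, s0_sq=float(math.exp(mean_e)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(mean_e + float(special.digamma(half_d0)) - math.log(half_d0))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Equivalent to sorting ascending, taking ``q_i = min_{j>=i} p_j m / j``
    capped at 1, and restoring the input order; ties receive equal
    adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("bh_adjust needs a non-empty p-value list")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_matrix(study: ExpressionStudy, line: str, diet: str) -> pd.DataFrame:
    ids = study.sample_ids(line=line, diet=diet)
    if len(ids) < 2:
        raise ValidationError(
            f"group (line={line}, diet={diet}) has {len(ids)} replicates; need >=2"
        )
    return study.intensities[ids]


def moderated_t_test(
    study: ExpressionStudy,
    contrast: str,
    prior: VariancePrior | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Moderated two-group t test for one contrast, all probes at once.

    Parameters
    ----------
    study
        A quantitative study (>=2 replicates per group).
    contrast
        One of :data:`CONTRASTS`.
    prior
        Variance prior; if None, estimated from this contrast's residual
        variances via :func:`estimate_variance_prior`. Pass
        :data:`NO_SHRINKAGE` (d0=0) for the ordinary pooled t.

    Returns
    -------
    DataFrame indexed by probe_id with columns ``log2_fold`` (group1 -
    group2 of log2 means), ``mean1_au``/``mean2_au`` (linear group
    means), ``s2`` (pooled residual variance), ``t``, ``df``, ``p`` and
    BH-adjusted ``padj``.
    """
    if contrast not in CONTRASTS:
        raise ValidationError(f"unknown contrast {contrast!r}; use one of {list(CONTRASTS)}")
    (l1, d1), (l2, d2) = CONTRASTS[contrast]
    g1 = _group_matrix(study, l1, d1)
    g2 = _group_matrix(study, l2, d2)
    n1, n2 = g1.shape[1], g2.shape[1]
    df_resid = n1 + n2 - 2

    x1 = np.log2(g1.clip(lower=epsilon).to_numpy(float))
    x2 = np.log2(g2.clip(lower=epsilon).to_numpy(float))
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    if prior is None:
        prior = estimate_variance_prior(np.maximum(s2, 1e-12), df_resid)

    if prior.d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    elif math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
        df_total = prior.d0 + df_resid

    delta = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "contrast": contrast,
            "log2_fold": delta,
            "mean1_au": g1.to_numpy(float).mean(axis=1),
            "mean2_au": g2.to_numpy(float).mean(axis=1),
            "s2": s2,
            "t": t,
            "df": df_total,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=study.probe_ids,
    )
    out.index.name = "probe_id"
    return out


def run_all_contrasts(
    study: ExpressionStudy,
    prior: VariancePrior | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> dict[str, pd.DataFrame]:
    """Moderated t for all four contrasts, sharing one variance prior.

    If ``prior`` is None it is estimated once from the FC-vs-LC residual
    variances and reused, so every contrast is shrunk toward the same
    prior (all contrasts share the probe-level variance structure).
    """
    if prior is None:
        (l1, d1), (l2, d2) = CONTRASTS["FCvsLC"]
        g1 = _group_matrix(study, l1, d1)
        g2 = _group_matrix(study, l2, d2)
        n1, n2 = g1.shape[1], g2.shape[1]
        x1 = np.log2(g1.clip(lower=epsilon).to_numpy(float))
        x2 = np.log2(g2.clip(lower=epsilon).to_numpy(float))
        ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
        s2 = np.maximum(ss / (n1 + n2 - 2), 1e-12)
        prior = estimate_variance_prior(s2, n1 + n2 - 2)
    return {c: moderated_t_test(study, c, prior=prior, epsilon=epsilon) for c in CONTRASTS}


def quantitative_filter(
    results: dict[str, pd.DataFrame],
    fold: float = 2.0,
    alpha: float = 0.05,
    floor: float = 100.0,
) -> dict[str, dict[str, list[str]]]:
    """Quantitative candidate filter per contrast.

    A probe is retained for a contrast iff its linear fold change between
    the group means exceeds ``fold`` (ratio of higher over lower mean),
    its BH-adjusted p is below ``alpha``, and the mean AU intensity of the
    higher group exceeds ``floor``.

    Returns ``{contrast: {"up": [...], "down": [...]}}`` where "up" means
    higher in the contrast's first group.
    """
    out: dict[str, dict[str, list[str]]] = {}
    for contrast, res in results.items():
        m1 = res["mean1_au"].to_numpy(float)
        m2 = res["mean2_au"].to_numpy(float)
        hi = np.maximum(m1, m2)
        lo = np.maximum(np.minimum(m1, m2), 1e-12)
        ratio = hi / lo
        keep = (ratio > fold) & (res["padj"].to_numpy() < alpha) & (hi > floor)
        up = keep & (m1 > m2)
        down = keep & (m2 > m1)
        probes = res.index
        out[contrast] = {"up": list(probes[up]), "down": list(probes[down])}
    return out


def classify_diet_response(
    means: dict[str, float],
    log2_folds: dict[str, float],
    significant: dict[str, bool],
) -> str:
    """Classify one probe's line-by-diet response pattern.

    Parameters
    ----------
    means
        Linear-AU group means keyed FC, FF, LC, LF (all four required).
    log2_folds
        log2 fold change per contrast (group1 - group2).
    significant
        Per-contrast significance flag (e.g. membership in the
        quantitative candidate filter, either direction).

    Labels
    ------
    ``interaction_opposing``
        Line contrast significant on both diets with opposite signs.
    ``line_only``
        Line contrast significant on both diets, same sign, and neither
        within-line diet contrast significant.
    ``diet_amplified``
        Line contrast significant on both diets, same sign, and the
        high-fat line difference strictly larger in magnitude than the
        control one (baseline divergence amplified by diet).
    ``diet_only``
        A within-line diet contrast significant while neither line
        contrast is.
    ``null``
        Anything else.
    """
    for g in ("FC", "FF", "LC", "LF"):
        if g not in means:
            raise ValidationError(f"missing group mean {g!r}")
    line_c = significant.get("FCvsLC", False)
    line_f = significant.get("FFvsLF", False)
    diet_sig = significant.get("FFvsFC", False) or significant.get("LFvsLC", False)
    lfc_c = log2_folds.get("FCvsLC", 0.0)
    lfc_f = log2_folds.get("FFvsLF", 0.0)

    if line_c and line_f:
        if lfc_c * lfc_f < 0:
            return "interaction_opposing"
        if diet_sig and abs(lfc_f) > abs(lfc_c):
            return "diet_amplified"
        if not diet_sig:
            return "line_only"
        return "null"
    if diet_sig and not line_c and not line_f:
        return "diet_only"
    return "null"


def classify_all(
    results: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    significant: dict[str, set[str]] | None = None,
) -> pd.Series:
    """Vector of diet-response labels for every probe.

    By default a probe is "significant" for a contrast when its
    BH-adjusted p is below ``alpha``; significance for classification is
    purely statistical (no fold or AU floor), so a contrast whose true
    fold sits exactly at a reporting threshold is still classified
    stably. Pass explicit per-contrast probe sets to override.
    """
    probes = results["FCvsLC"].index
    if significant is None:
        significant = {
            c: set(res.index[res["padj"].to_numpy() < alpha])
            for c, res in results.items()
        }
    group_of = {"FCvsLC": ("FC", "LC"), "FFvsLF": ("FF", "LF"),
                "FFvsFC": ("FF", "FC"), "LFvsLC": ("LF", "LC")}
    labels = []
    for p in probes:
        means = {}
        folds = {}
        flags = {}
        for c, res in results.items():
            g1, g2 = group_of[c]
            means[g1] = float(res.at[p, "mean1_au"])
            means[g2] = float(res.at[p, "mean2_au"])
            folds[c] = float(res.at[p, "log2_fold"])
            flags[c] = p in significant.get(c, set())
        labels.append(classify_diet_response(means, folds, flags))
    return pd.Series(labels, index=probes, name="diet_response")
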