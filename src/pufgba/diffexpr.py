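"""Moderated differential expression between strains at matched phases.

Per protein, a group-means linear model over (strain, timepoint) groups
gives a log2 fold change and a residual variance ``s_g^2`` on ``d_g``
degrees of freedom.  An empirical-Bayes prior with an abundance trend is
estimated across proteins: the prior variance ``s_0^2(A)`` comes from a
lowess fit of ``log s_g^2`` against average abundance, and the prior
degrees of freedom ``d_0`` from the method of moments on the residual
spread of ``log s_g^2`` (whose marginal is a scaled log-F under the
model), optionally winsorized for robustness against variance outliers.
The moderated statistic uses the posterior variance

    s_post^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

with a t reference on ``d_0 + d_g`` degrees of freedom; p-values are
two-sided and Benjamini-Hochberg adjusted per contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .proteoquant import AbundanceStudy

__all__ = [
    "DeConfig",
    "DesignSpec",
    "GeneFit",
    "ModerationPrior",
    "filter_low_abundance",
    "fit_group_means",
    "estimate_prior",
    "moderated_test",
    "bh_adjust",
    "sample_pca",
    "run_de",
]


@dataclass
class DeConfig:
    low_abundance_cutoff: float = 23.0
    alpha: float = 0.05
    trend_span: float = 0.3
    robust: bool = True
    winsor_limits: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class DesignSpec:
    """Sample grouping and the strain-vs-strain contrasts to test.

    ``groups`` maps (strain, timepoint) to sample ids; ``contrasts`` are
    (groupA, groupB, label) triples, by default one per matched growth
    phase.  A phase override (e.g. treating a slower strain's second
    timepoint as mid-log) is applied when building the default design.
    """

    groups: dict[tuple[str, str], list[str]]
    contrasts: list[tuple[tuple[str, str], tuple[str, str], str]]

    def __post_init__(self) -> None:
        for ga, gb, _ in self.contrasts:
            for g in (ga, gb):
                if g not in self.groups:
                    raise ValueError(f"contrast references unknown group {g}")
        for g, sids in self.groups.items():
            if len(sids) < 2:
                raise ValueError(f"group {g} has fewer than 2 samples")

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "DesignSpec":
        """Default per-phase strain contrasts from sample metadata.

        Uses the ``phase`` column: for each phase present in both
        strains with exactly one timepoint per strain, contrasts strainB
        against strainA under the label of that phase.
        """
        groups: dict[tuple[str, str], list[str]] = {}
        for sid, row in samples.iterrows():
            groups.setdefault((row["strain"], row["timepoint"]), []).append(sid)
        strains = list(dict.fromkeys(samples["strain"]))
        if len(strains) != 2:
            raise ValueError("default design expects exactly 2 strains")
        contrasts = []
        for phase in ("early", "mid", "late"):
            tps = {}
            for strain in strains:
                sel = samples[(samples["strain"] == strain)
                              & (samples["phase"] == phase)]
                tp = list(dict.fromkeys(sel["timepoint"]))
                if len(tp) == 1:
                    tps[strain] = tp[0]
            if len(tps) == 2:
                contrasts.append(((strains[1], tps[strains[1]]),
                                  (strains[0], tps[strains[0]]), phase))
        return cls(groups=groups, contrasts=contrasts)


@dataclass
class GeneFit:
    proteins: list[str]
    group_names: list[tuple[str, str]]
    means: pd.DataFrame          # protein x group
    s2: pd.Series                # pooled residual variance
    df_resid: int
    avg_abundance: pd.Series
    group_sizes: dict[tuple[str, str], int]


@dataclass
class ModerationPrior:
    d0: float                    # prior degrees of freedom (may be inf)
    s02: pd.Series               # trended prior variance per protein
    robust: bool = False


def filter_low_abundance(study: AbundanceStudy, config: DeConfig | None = None):
    """Drop proteins whose grand-mean abundance is below the cutoff.

    The boundary is closed above: a protein at exactly the cutoff is
    retained.  Returns ``(study, report)`` with retained/removed counts.
    """
    config = config or DeConfig()
    grand = study.matrix.mean(axis=1)
    keep = grand >= config.low_abundance_cutoff
    from dataclasses import replace
    out = replace(study, matrix=study.matrix.loc[keep],
                  proteins=study.proteins.loc[keep[keep].index],
                  imputed_mask=None if study.imputed_mask is None
                  else study.imputed_mask.loc[keep])
    report = {"retained": int(keep.sum()), "removed": int((~keep).sum())}
    return out, report


def fit_group_means(study: AbundanceStudy, design: DesignSpec) -> GeneFit:
    """Group-means linear model with a pooled residual variance.

    Residual df is ``N - G`` over the samples covered by the design's
    groups.
    """
    X = study.matrix
    group_names = list(design.groups)
    n_samples = 0
    means = {}
    ss = np.zeros(len(X))
    for g in group_names:
        sids = design.groups[g]
        if len(sids) < 2:
            raise ValueError(f"group {g} has a single sample; variance undefined")
        sub = X[sids]
        mu = sub.mean(axis=1)
        means[g] = mu
        ss += ((sub.sub(mu, axis=0)) ** 2).sum(axis=1).to_numpy()
        n_samples += len(sids)
    df_resid = n_samples - len(group_names)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = pd.Series(ss / df_resid, index=X.index)
    used = [sid for g in group_names for sid in design.groups[g]]
    return GeneFit(
        proteins=list(X.index), group_names=group_names,
        means=pd.DataFrame(means, index=X.index), s2=s2, df_resid=df_resid,
        avg_abundance=X[used].mean(axis=1),
        group_sizes={g: len(design.groups[g]) for g in group_names},
    )


def _winsorize(z: np.ndarray, limits: tuple[float, float]) -> np.ndarray:
    lo, hi = np.quantile(z, limits)
    return np.clip(z, lo, hi)


def estimate_prior(fits: GeneFit, config: DeConfig | None = None) -> ModerationPrior:
    """Trended, optionally robust empirical-Bayes variance prior.

    Fits a lowess trend of ``z = log s_g^2`` on average abundance; the
    de-trended spread of ``z`` in excess of ``trigamma(d_g / 2)`` (the
    variance of a log chi-square) determines ``d_0`` through
    ``trigamma(d_0 / 2) = var(z - trend) - trigamma(d_g / 2)``, and the
    trend is bias-corrected to the prior variance scale using the
    matching digamma identities.  Non-positive excess spread means the
    gene variances are exhausted by sampling noise and ``d_0 = inf``.
    """
    config = config or DeConfig()
    if len(fits.proteins) < 20:
        raise ValueError("need at least 20 proteins to estimate the prior")
    dg = fits.df_resid
    s2 = fits.s2.to_numpy(dtype=float)
    if np.all(s2 == 0):
        import warnings
        warnings.warn("all residual variances are zero; d0 set to infinity")
        return ModerationPrior(d0=math.inf,
                               s02=pd.Series(np.full(len(s2), 1e-12),
                                             index=fits.s2.index),
                               robust=config.robust)
    floor = max(s2[s2 > 0].min() * 1e-6, 1e-300)
    z = np.log(np.maximum(s2, floor))
    A = fits.avg_abundance.to_numpy(dtype=float)
    trend = lowess(z, A, frac=config.trend_span, return_sorted=False)
    resid = z - trend
    if config.robust:
        resid = _winsorize(resid, config.winsor_limits)
    excess = resid.var(ddof=1) - special.polygamma(1, dg / 2.0)
    if excess <= 0:
        d0 = math.inf
    else:
        # invert trigamma(d0/2) = excess
        f = lambda d: special.polygamma(1, d / 2.0) - excess
        lo, hi = 1e-6, 1e8
        d0 = brentq(f, lo, hi) if f(lo) > 0 and f(hi) < 0 else math.inf
    # bias-correct the trend onto the prior-variance scale
    correction = special.digamma(dg / 2.0) - np.log(dg / 2.0)
    if math.isfinite(d0):
        correction -= special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    s02 = np.exp(trend - correction)
    return ModerationPrior(d0=float(d0), s02=pd.Series(s02, index=fits.s2.index),
                           robust=config.robust)


def moderated_test(fits: GeneFit, prior: ModerationPrior,
                   contrast: tuple[tuple[str, str], tuple[str, str], str],
                   config: DeConfig | None = None) -> pd.DataFrame:
    """Moderated t-test for one contrast (pre-adjustment).

    Returns a frame with ``log2FC``, ``t``, ``p`` and ``avg_abundance``
    per protein; ``d0 = 0`` reduces to the ordinary two-sample t on the
    pooled residual variance and ``d0 = inf`` uses the trend alone.
    """
    config = config or DeConfig()
    ga, gb, label = contrast
    beta = fits.means[ga] - fits.means[gb]
    v = 1.0 / fits.group_sizes[ga] + 1.0 / fits.group_sizes[gb]
    dg, d0 = fits.df_resid, prior.d0
    s2 = fits.s2.to_numpy(dtype=float)
    s02 = prior.s02.to_numpy(dtype=float)
    if math.isinf(d0):
        s2_post = s02
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta.to_numpy() / np.sqrt(s2_post * v)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({
        "protein": fits.proteins, "contrast": label,
        "log2FC": beta.to_numpy(), "t": t, "p": p,
        "avg_abundance": fits.avg_abundance.to_numpy(),
    })


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sample_pca(study: AbundanceStudy, n_components: int = 2):
    """Centered PCA of samples for growth-phase QC.

    Sign convention: each component is flipped so its largest-|loading|
    coordinate is positive, making coordinates reproducible.  Returns
    ``(coordinates, variance_explained)``.
    """
    from sklearn.decomposition import PCA

    X = study.matrix.to_numpy(dtype=float).T  # samples x proteins
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for PCA")
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete (imputed) study")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    for k in range(coords.shape[1]):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1.0
    frame = pd.DataFrame(coords, index=study.matrix.columns,
                         columns=[f"PC{k + 1}" for k in range(coords.shape[1])])
    return frame, pca.explained_variance_ratio_


def run_de(study: AbundanceStudy, design: DesignSpec | None = None,
           config: DeConfig | None = None) -> pd.DataFrame:
    """Filter, fit, moderate and BH-adjust every contrast.

    Returns the tidy DE table with ``q`` and ``significant`` columns
    (adjustment within contrast).
    """
    config = config or DeConfig()
    design = design or DesignSpec.from_samples(study.samples)
    filtered, _ = filter_low_abundance(study, config)
    fits = fit_group_means(filtered, design)
    prior = estimate_prior(fits, config)
    frames = []
    for contrast in design.contrasts:
        res = moderated_test(fits, prior, contrast, config)
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["q"] < config.alpha
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
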