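"""Sloan neutral community model (NCM) for occurrence-frequency data.

The model treats each sample (here: a human gut plasmidome) as a local
community assembled by stochastic immigration from a shared regional pool.
For an entity (plasmid or plasmid segment) with mean relative abundance
``p`` in the pool, its local relative abundance is approximately
Beta(Nm*p, Nm*(1-p)) distributed, where ``Nm`` is the metacommunity size
times the immigration rate.  With a detection limit ``d`` (the smallest
relative abundance at which an entity is called present), the expected
occurrence frequency across samples is

    f(p) = 1 - I_d(Nm*p, Nm*(1-p))

with ``I`` the regularized incomplete beta function.  A single free
parameter ``Nm`` is fitted by least squares to the observed (p, f) cloud;
the resulting R^2 quantifies how neutral dispersal is, and entities lying
far above the fitted curve are flagged as candidates under positive
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "OccurrenceStats",
    "NCMFit",
    "NeutralCommunityModel",
    "occurrence_stats",
    "predict_freq",
    "fit_ncm",
    "subsample_compare",
    "select_deviant",
]

_EPS = 1e-12
_LOG10_NM_BOUNDS = (-2.0, 12.0)


@dataclass
class OccurrenceStats:
    """Per-entity mean relative abundance ``p`` and occurrence frequency ``f``."""

    entity_ids: np.ndarray
    p: np.ndarray
    f: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.entity_ids = np.asarray(self.entity_ids)
        self.p = np.asarray(self.p, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("mean relative abundances must be nonnegative")
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValueError("occurrence frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.p)

    def subset(self, idx) -> "OccurrenceStats":
        return OccurrenceStats(self.entity_ids[idx], self.p[idx], self.f[idx], self.n_samples)


@dataclass
class NCMFit:
    """Result of fitting the neutral model to an :class:`OccurrenceStats`."""

    Nm: float
    d: float
    r2: float
    stats: OccurrenceStats
    f_pred: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    residual: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.residual = self.stats.f - self.f_pred

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entity_id": self.stats.entity_ids,
                "p": self.stats.p,
                "f": self.stats.f,
                "f_pred": self.f_pred,
                "residual": self.residual,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def occurrence_stats(abundance: pd.DataFrame, presence: pd.DataFrame,
                     entities=None) -> OccurrenceStats:
    """Compute per-entity (p, f) from a samples x entities abundance matrix.

    ``p`` is the mean across samples of the sample-normalized relative
    abundance; ``f`` is the fraction of samples in which the entity is
    present.  Entities absent from every sample are excluded with a warning.
    """
    if entities is not None:
        abundance = abundance[list(entities)]
        presence = presence[list(entities)]
    abundance, presence = abundance.align(presence, join="inner")
    row_sums = abundance.sum(axis=1)
    row_sums = row_sums.replace(0.0, np.nan)
    rel = abundance.div(row_sums, axis=0).fillna(0.0)
    p = rel.mean(axis=0).to_numpy()
    f = presence.to_numpy(dtype=float).mean(axis=0)
    keep = f > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} entities absent from all samples")
    return OccurrenceStats(abundance.columns.to_numpy()[keep], p[keep], f[keep],
                           n_samples=len(abundance))


def predict_freq(p, Nm: float, d: float):
    """Expected occurrence frequency ``1 - I_d(Nm*p, Nm*(1-p))``.

    ``p`` outside (0, 1) is clipped to [1e-12, 1-1e-12] with a warning.
    """
    if not 0 < d < 1:
        raise ValueError(f"detection limit d must be in (0, 1), got {d}")
    if Nm <= 0:
        raise ValueError(f"Nm must be positive, got {Nm}")
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("clipping mean abundances to the open unit interval")
        p = np.clip(p, _EPS, 1 - _EPS)
    out = 1.0 - special.betainc(Nm * p, Nm * (1.0 - p), d)
    return float(out[0]) if scalar else out


def _sse(log10_nm: float, p: np.ndarray, f: np.ndarray, d: float) -> float:
    pred = 1.0 - special.betainc(10.0 ** log10_nm * p, 10.0 ** log10_nm * (1.0 - p), d)
    return float(np.sum((f - pred) ** 2))


def fit_ncm(stats: OccurrenceStats, d: float, coarse_step: float = 0.1) -> NCMFit:
    """Fit Nm by bounded 1-D least squares on a log10 scale.

    A coarse grid over log10(Nm) in [-2, 12] locates the basin; Brent's
    method then refines within +/- one grid step.  R^2 is computed about the
    mean of the observed frequencies; per-entity 95% bands are Wilson score
    intervals around the predicted frequency at the fitted sample size.
    """
    p = np.clip(stats.p, _EPS, 1 - _EPS)
    f = stats.f
    if len(p) == 0:
        raise ValueError("no entities to fit")
    lo, hi = _LOG10_NM_BOUNDS
    grid = np.arange(lo, hi + coarse_step / 2, coarse_step)
    sse = np.array([_sse(x, p, f, d) for x in grid])
    i = int(np.argmin(sse))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(_sse, bounds=(a, b), args=(p, f, d), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"NCM fit did not converge; SSE profile min {sse.min():.4g} "
                           f"at log10(Nm)={grid[i]:.2f}")
    nm = 10.0 ** float(res.x)
    f_pred = predict_freq(p, nm, d)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("all observed frequencies identical; R^2 undefined")
        r2 = np.nan
    else:
        r2 = 1.0 - float(res.fun) / ss_tot
    count = f_pred * stats.n_samples
    ci_lower, ci_upper = proportion_confint(count, stats.n_samples, alpha=0.05,
                                            method="wilson")
    return NCMFit(Nm=nm, d=d, r2=r2, stats=stats, f_pred=f_pred,
                  ci_lower=np.asarray(ci_lower), ci_upper=np.asarray(ci_upper))


def default_detection_limit(abundance: pd.DataFrame) -> float:
    """Minimum nonzero per-sample relative abundance in the matrix."""
    rel = abundance.div(abundance.sum(axis=1).replace(0.0, np.nan), axis=0)
    vals = rel.to_numpy()
    nz = vals[np.isfinite(vals) & (vals > 0)]
    if nz.size == 0:
        raise ValueError("abundance matrix has no nonzero entries")
    return float(nz.min())


def subsample_compare(stats_big: OccurrenceStats, stats_small: OccurrenceStats,
                      d: float, n_iter: int = 1000, seed: int = 0):
    """Empirical p-value for R^2(small) exceeding subsampled R^2(big).

    Draws ``len(stats_small)`` entities from the big group without
    replacement ``n_iter`` times, refits, and reports
    ``p = (1 + #{R^2_sub >= R^2_small}) / (1 + n_iter)``.  Degenerate
    subsamples (all frequencies equal) are redrawn and counted.
    """
    if len(stats_big) <= len(stats_small):
        raise ValueError("big group must contain more entities than the small group")
    r2_small = fit_ncm(stats_small, d).r2
    rng = np.random.default_rng(seed)
    r2_null = np.empty(n_iter)
    n_degenerate = 0
    for it in range(n_iter):
        while True:
            idx = rng.choice(len(stats_big), size=len(stats_small), replace=False)
            sub = stats_big.subset(idx)
            if np.ptp(sub.f) > 0:
                break
            n_degenerate += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2_null[it] = fit_ncm(sub, d).r2
    p = (1 + int(np.sum(r2_null >= r2_small))) / (1 + n_iter)
    return {"p": p, "r2_small": r2_small, "r2_null": r2_null,
            "n_degenerate_redrawn": n_degenerate}


def select_deviant(fit: NCMFit, pct: float = 95.0, rule: str = "quantile") -> np.ndarray:
    """Flag entities over-represented relative to the neutral prediction.

    rule "quantile": top (100-pct)% of both frequency and positive deviation
    from the fit (deviation measured on the frequency axis).
    rule "ci": frequency above pct/100 and above the upper Wilson band of the
    predicted frequency.
    """
    f = fit.stats.f
    if rule == "quantile":
        q_f = np.quantile(f, pct / 100.0)
        q_res = np.quantile(fit.residual, pct / 100.0)
        mask = (f >= q_f) & (fit.residual >= q_res)
    elif rule == "ci":
        mask = (f > pct / 100.0) & (f > fit.ci_upper)
    else:
        raise ValueError(f"unknown selection rule {rule!r}; use 'quantile' or 'ci'")
    return fit.stats.entity_ids[mask]


def plot_fit(fit: NCMFit, path, selected=None) -> None:
    """Occurrence frequency vs mean relative abundance with the fitted curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogx(fit.stats.p, fit.stats.f, ".", ms=4, alpha=0.6, label="observed")
    grid = np.logspace(np.log10(max(fit.stats.p.min(), 1e-9)),
                       np.log10(fit.stats.p.max()), 200)
    ax.semilogx(grid, predict_freq(grid, fit.Nm, fit.d), "-",
                label=f"NCM fit (Nm={fit.Nm:.3g}, R$^2$={fit.r2:.2f})")
    if selected is not None and len(selected):
        mask = np.isin(fit.stats.entity_ids, list(selected))
        ax.semilogx(fit.stats.p[mask], fit.stats.f[mask], "o", mfc="none",
                    mec="red", label="selected")
    ax.set_xlabel("mean relative abundance")
    ax.set_ylabel("occurrence frequency")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class NeutralCommunityModel:
    """Estimator-style wrapper around the NCM fit.

    Parameters
    ----------
    d : float or None
        Detection limit; if None, inferred from the abundance matrix as the
        minimum nonzero per-sample relative abundance.

    Attributes (after :meth:`fit`)
    ------------------------------
    Nm_ : fitted migration parameter.
    r2_ : goodness of fit about the mean observed frequency.
    fit_ : the underlying :class:`NCMFit`.
    """

    def __init__(self, d: float | None = None):
        self.d = d

    def get_params(self, deep: bool = True) -> dict:
        return {"d": self.d}

    def set_params(self, **params) -> "NeutralCommunityModel":
        for k, v in params.items():
            if k != "d":
                raise ValueError(f"unknown parameter {k!r}")
            self.d = v
        return self

    def fit(self, stats: OccurrenceStats, d: float | None = None) -> "NeutralCommunityModel":
        d = d if d is not None else self.d
        if d is None:
            raise ValueError("detection limit d must be given")
        self.fit_ = fit_ncm(stats, d)
        self.Nm_ = self.fit_.Nm
        self.r2_ = self.fit_.r2
        return self

    def predict(self, p) -> np.ndarray:
        return predict_freq(p, self.Nm_, self.fit_.d)
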