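"""Epigenetic clock application, age regression, group tests and plateau fits.

Two clock flavours are supported:

* ``weighted`` — the classic linear age estimator: score = intercept +
  sum_i w_i * beta_i over a fixed CpG panel.  Scores are unbounded and may
  be negative (phenotypic-age style estimators are calibrated to risk, not
  clamped to calendar time).
* ``mean`` — the mean beta over a panel of signature CpGs, as used for
  region-based proliferative-history signatures.

Regression utilities quantify how a clock score tracks an age axis
(chronological months or cumulative divisions) and whether it saturates:
a bounded signature must plateau once its CpGs approach full methylation,
so a saturating-exponential fit compared with a straight line by AIC makes
the plateau quantitative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .methio import BetaMatrix

__all__ = [
    "ClockModel",
    "RegressionFit",
    "PlateauFit",
    "read_clock",
    "write_clock",
    "apply_clock",
    "fit_age_regression",
    "compare_groups",
    "fit_plateau",
]


# ---------------------------------------------------------------------------
# clock models
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    """A weighted-CpG linear age estimator or a mean-of-sites signature."""

    kind: str  # "weighted" | "mean"
    sites: list[str]
    weights: np.ndarray | None = None
    intercept: float = 0.0
    reference: dict[str, float] | None = None  # per-site means for imputation
    name: str = "clock"

    def __post_init__(self) -> None:
        if self.kind not in ("weighted", "mean"):
            raise ValueError("kind must be 'weighted' or 'mean'")
        self.sites = list(self.sites)
        if self.kind == "weighted":
            if self.weights is None:
                raise ValueError("weighted clock needs weights")
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.sites):
                raise ValueError("one weight per site required")
        elif self.weights is not None:
            raise ValueError("mean clock takes no weights")


def write_clock(model: ClockModel, path) -> None:
    """TSV with header ``site_id\tweight`` and an ``#intercept=`` comment line."""
    with open(path, "w") as fh:
        fh.write(f"#name={model.name}\n#kind={model.kind}\n")
        if model.kind == "weighted":
            fh.write(f"#intercept={float(model.intercept)!r}\n")
        fh.write("site_id\tweight\n")
        for i, s in enumerate(model.sites):
            if model.kind == "weighted":
                fh.write(f"{s}\t{float(model.weights[i])!r}\n")
            else:
                fh.write(f"{s}\t\n")


def read_clock(path) -> ClockModel:
    kind, name, intercept = "weighted", Path(path).stem, 0.0
    sites, weights = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "intercept":
                    intercept = float(val)
                elif key == "kind":
                    kind = val
                elif key == "name":
                    name = val
                continue
            if line.startswith("site_id"):
                continue
            sid, _, w = line.partition("\t")
            sites.append(sid)
            if w.strip():
                weights.append(float(w))
    if kind == "mean":
        return ClockModel(kind="mean", sites=sites, name=name)
    return ClockModel(
        kind="weighted", sites=sites, weights=np.array(weights), intercept=intercept, name=name
    )


def apply_clock(
    bm: BetaMatrix,
    model: ClockModel,
    missing_policy: str = "impute",
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Score every sample with a clock.

    Missing values (panel sites absent from the matrix, or NaN betas) are
    handled per ``missing_policy``:

    * ``impute`` — fill from the model's reference means, else the cohort
      mean of that site; sites missing everywhere with no reference are
      dropped from the panel.  Errors if any sample's missing fraction
      exceeds ``max_missing_frac``.
    * ``drop``   — per sample, sum/mean over its covered panel sites only.
    * ``error``  — any missing value raises.

    Returns a frame with sample_id, score, clock, n_sites_used,
    n_sites_imputed.
    """
    if missing_policy not in ("impute", "drop", "error"):
        raise ValueError("missing_policy must be impute, drop or error")
    ids = bm.site_ids()
    lookup = pd.Series(np.arange(len(ids)), index=ids)
    idx = lookup.reindex(model.sites)
    present = idx.notna().to_numpy()
    n_panel = len(model.sites)
    n_samples = len(bm.samples)

    panel = np.full((n_panel, n_samples), np.nan)
    panel[present] = bm.beta[idx[present].astype(int).to_numpy()]
    missing = np.isnan(panel)

    if missing_policy == "error" and missing.any():
        bad = [model.sites[i] for i in np.flatnonzero(missing.any(axis=1))[:5]]
        raise ValueError(f"missing panel sites under error policy (e.g. {bad})")

    weights = model.weights if model.kind == "weighted" else None
    n_imputed = np.zeros(n_samples, dtype=int)

    if missing_policy == "impute":
        ref = np.full(n_panel, np.nan)
        if model.reference:
            for i, s in enumerate(model.sites):
                ref[i] = model.reference.get(s, np.nan)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
            cohort = np.nanmean(np.where(missing, np.nan, panel), axis=1)
        fill = np.where(np.isnan(ref), cohort, ref)
        resolvable = ~np.isnan(fill)
        frac_missing = missing[resolvable].mean(axis=0) if resolvable.any() else np.ones(n_samples)
        if (frac_missing > max_missing_frac).any():
            worst = float(frac_missing.max())
            raise ValueError(
                f"missing fraction {worst:.2f} exceeds max_missing_frac={max_missing_frac}"
            )
        n_imputed = (missing & resolvable[:, None]).sum(axis=0)
        panel = np.where(missing, fill[:, None], panel)
        used = resolvable
        panel = panel[used]
        w_used = weights[used] if weights is not None else None
        n_used = np.full(n_samples, int(used.sum()))
        if model.kind == "weighted":
            score = model.intercept + (w_used[:, None] * panel).sum(axis=0)
        else:
            score = panel.mean(axis=0)
    else:  # drop (and error, which has no missing left)
        ok = ~missing
        n_used = ok.sum(axis=0)
        if model.kind == "weighted":
            contrib = np.where(ok, weights[:, None] * panel, 0.0)
            score = model.intercept + contrib.sum(axis=0)
        else:
            with np.errstate(invalid="ignore"):
                score = np.nanmean(panel, axis=0)
        score = np.where(n_used > 0, score, np.nan)

    return pd.DataFrame(
        {
            "sample_id": bm.samples,
            "score": score,
            "clock": model.name,
            "n_sites_used": n_used,
            "n_sites_imputed": n_imputed,
        }
    )


# ---------------------------------------------------------------------------
# regression against age
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float

    def se_fit(self, x) -> np.ndarray:
        """Standard error of the fitted mean at x (for the 1.96-SE band)."""
        x = np.asarray(x, dtype=float)
        return self.residual_sd * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _paired(scores: pd.DataFrame | pd.Series, ages: Mapping[str, float] | pd.Series):
    if isinstance(scores, pd.DataFrame):
        s = scores.set_index("sample_id")["score"] if "sample_id" in scores else scores["score"]
    else:
        s = scores
    a = pd.Series(ages)
    common = s.index.intersection(a.index)
    pair = pd.DataFrame({"score": s.loc[common], "age": a.loc[common]}).dropna()
    return pair["age"].to_numpy(float), pair["score"].to_numpy(float)


def fit_age_regression(scores, ages) -> RegressionFit:
    """Ordinary least squares of clock score on age, with Pearson r.

    ``scores`` is an apply_clock frame or a sample-indexed Series; ``ages``
    maps sample ids to ages.  Raises on fewer than 3 pairs or zero age
    variance.
    """
    x, y = _paired(scores, ages)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("zero age variance: slope undefined")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = n - 2
    residual_sd = math.sqrt(float((resid**2).sum()) / dof) if dof > 0 else 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=n,
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        sxx=sxx,
    )


def compare_groups(
    scores, groups: Mapping[str, str] | pd.Series, pairs: Sequence[tuple[str, str]] | None = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Two-sided t-test of clock scores between groups.

    Welch's unequal-variance test by default (``pooled=True`` for the classic
    equal-variance variant).  ``pairs`` selects comparisons; all unordered
    group pairs by default.
    """
    if isinstance(scores, pd.DataFrame):
        s = scores.set_index("sample_id")["score"] if "sample_id" in scores else scores["score"]
    else:
        s = scores
    g = pd.Series(groups)
    by = {lab: s.loc[g[g == lab].index.intersection(s.index)].dropna() for lab in g.unique()}
    if pairs is None:
        labs = sorted(by)
        pairs = [(a, b) for i, a in enumerate(labs) for b in labs[i + 1 :]]
    rows = []
    for a, b in pairs:
        xa, xb = by[a], by[b]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {a if len(xa) < 2 else b} has fewer than 2 samples")
        t, p = stats.ttest_ind(xb, xa, equal_var=pooled)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "t": float(t),
                "p": float(p),
                "n_a": len(xa),
                "n_b": len(xb),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plateau detection
# ---------------------------------------------------------------------------

@dataclass
class PlateauFit:
    """Saturating fit score = a + b(1 - exp(-c age)) versus a straight line."""

    a: float
    b: float
    c: float
    linear_slope: float
    linear_intercept: float
    aic_saturating: float
    aic_linear: float
    delta_aic: float  # saturating - linear; negative favours saturation
    saturation_age: float  # age reaching 95% of the asymptote: 3/c
    converged: bool


def _sat(x, a, b, c):
    return a + b * (1.0 - np.exp(-c * x))


def fit_plateau(scores, ages) -> PlateauFit:
    """Fit the saturating model by multi-start nonlinear least squares.

    Five fixed initial rates spanning slow-to-fast saturation relative to
    the age range are tried; c is bounded below by 0.  If no start
    converges, the linear fit is returned with ``converged=False``.
    """
    x, y = _paired(scores, ages)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    span = float(x.max() - x.min())
    if span <= 0:
        raise ValueError("degenerate age range")

    lin = stats.linregress(x, y)
    rss_lin = float(((y - (lin.intercept + lin.slope * x)) ** 2).sum())

    best = None
    y_span = float(y.max() - y.min()) or 1.0
    for c0 in (0.1, 0.5, 1.0, 3.0, 10.0):
        p0 = (float(y.min()), y_span, c0 / span)
        try:
            res = optimize.least_squares(
                lambda p: _sat(x, *p) - y,
                p0,
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                max_nfev=2000,
            )
        except Exception:
            continue
        # accept the best point found even if the evaluation budget stopped the
        # search: on exactly-linear data c -> 0 is approached asymptotically
        if not np.isfinite(res.x).all():
            continue
        rss = float(2.0 * res.cost)
        if np.isfinite(rss) and (best is None or rss < best[1]):
            best = (res.x, rss)

    # RSS below numerical noise is "a perfect fit": floor both models there so
    # AIC stays finite and a nested perfect fit costs exactly its extra params
    floor = 1e-6 * n * max(float(np.var(y)), 1e-12)

    def aic(rss, k):
        return n * math.log(max(rss, floor) / n) + 2 * k

    aic_lin = aic(rss_lin, 2)
    if best is None:
        return PlateauFit(
            a=math.nan, b=math.nan, c=math.nan,
            linear_slope=float(lin.slope), linear_intercept=float(lin.intercept),
            aic_saturating=math.inf, aic_linear=aic_lin, delta_aic=math.inf,
            saturation_age=math.nan, converged=False,
        )
    (a, b, c), rss_sat = best
    aic_sat = aic(rss_sat, 3)
    return PlateauFit(
        a=float(a), b=float(b), c=float(c),
        linear_slope=float(lin.slope), linear_intercept=float(lin.intercept),
        aic_saturating=aic_sat, aic_linear=aic_lin, delta_aic=aic_sat - aic_lin,
        saturation_age=(-math.log(0.05) / c) if c > 0 else math.inf,
        converged=True,
    )
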