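"""Staged differential-expression engine.

Implements the bulk RNA-seq workflow for a differentiation time course with a
small number of donors: CPM-based expression filtering, log-CPM with
mean-variance precision weights, per-gene weighted linear models contrasting
every stage against the iPSC baseline while blocking on donor, empirical-Bayes
variance moderation, Benjamini-Hochberg adjustment, and DE calling at strict
thresholds (q < 0.01 and |log2FC| > 1 by default).

With one differentiation per donor the residual degrees of freedom are
``n_samples - (n_stages + n_donors - 1)`` -- e.g. 24 - 10 = 14 for 3 donors and
8 stages.  Moderation borrows strength across genes via a scaled-inverse-chi^2
prior on the residual variances, which is what makes per-gene inference usable
at n = 3 donors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "FitResult",
    "filter_expressed",
    "voom_normalize",
    "fit_contrasts",
    "ebayes_moderate",
    "adjust_bh",
    "call_de",
    "run_de",
]


class DesignError(ValueError):
    """Raised when the sample layout cannot support the requested model."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts with per-sample donor and stage labels.

    ``counts`` is a genes x samples DataFrame; ``donor_of_sample`` and
    ``stage_of_sample`` are Series indexed by sample id.  Each (donor, stage)
    pair may occur at most once: every donor is differentiated once.
    """

    counts: pd.DataFrame
    donor_of_sample: pd.Series
    stage_of_sample: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.counts.columns)
        for name, series in (
            ("donor_of_sample", self.donor_of_sample),
            ("stage_of_sample", self.stage_of_sample),
        ):
            missing = set(samples) - set(series.index)
            if missing:
                raise DesignError(f"{name} missing labels for samples {sorted(missing)}")
        pairs = list(zip(self.donor_of_sample[samples], self.stage_of_sample[samples]))
        if len(pairs) != len(set(pairs)):
            raise DesignError("a (donor, stage) pair occurs more than once")
        if (self.counts.to_numpy() < 0).any():
            raise DesignError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def stages(self) -> list[str]:
        """Stage labels in order of first appearance across samples."""
        return list(dict.fromkeys(self.stage_of_sample[self.sample_ids]))

    def donors(self) -> list[str]:
        return list(dict.fromkeys(self.donor_of_sample[self.sample_ids]))

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[gene_ids], self.donor_of_sample, self.stage_of_sample
        )


@dataclass
class NormalizedMatrix:
    """log2-CPM values with inverse-variance observation weights."""

    logcpm: pd.DataFrame
    weights: pd.DataFrame
    lib_sizes: pd.Series
    design: np.ndarray
    coef_names: list[str]
    stage_coef_names: list[str]

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValueError("weights must be strictly positive and finite")
        if not np.all(np.isfinite(self.logcpm.to_numpy())):
            raise ValueError("logcpm must be finite")


@dataclass
class FitResult:
    """Per-gene weighted least-squares fit of the donor + stage model."""

    coef: pd.DataFrame              # genes x coefficients
    stdev_unscaled: pd.DataFrame    # genes x coefficients, SE for sigma = 1
    s2: pd.Series                   # residual variances
    df_resid: float
    coef_names: list[str]
    stage_coef_names: list[str]     # the stage-vs-baseline contrasts


def cpm(counts: pd.DataFrame, prior_count: float = 0.0) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    return (counts + prior_count).div(lib + 2.0 * prior_count, axis=1) * 1e6


def filter_expressed(cm: CountMatrix, cpm_threshold: float = 1.0) -> CountMatrix:
    """Keep genes with CPM above threshold in *all donors* of >= 1 stage.

    The rule is strict (CPM > threshold) and requires every donor's sample of
    some single stage to pass; a gene passing in 2 of 3 donors at every stage
    is dropped.
    """
    vals = cpm(cm.counts).to_numpy()
    stages = np.asarray(cm.stage_of_sample[cm.sample_ids])
    keep = np.zeros(vals.shape[0], dtype=bool)
    for stage in dict.fromkeys(stages):
        cols = stages == stage
        keep |= (vals[:, cols] > cpm_threshold).all(axis=1)
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return cm.subset_genes(np.asarray(cm.counts.index)[keep])


def build_design(
    cm: CountMatrix, baseline: str = "iPSC"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + stage dummies (baseline = reference) + donor dummies.

    The stage coefficients are directly the log2 fold changes of each stage
    versus the baseline; donor dummies absorb donor-specific offsets.
    """
    stages = cm.stages()
    donors = cm.donors()
    if baseline not in stages:
        raise DesignError(f"baseline stage {baseline!r} has no samples")
    stage_levels = [baseline] + [s for s in stages if s != baseline]
    samples = cm.sample_ids
    st = np.asarray(cm.stage_of_sample[samples])
    dn = np.asarray(cm.donor_of_sample[samples])
    for s in stage_levels:
        if not (st == s).any():
            raise DesignError(f"stage {s!r} has no samples")
    for d in donors:
        if not (dn == d).any():
            raise DesignError(f"donor {d!r} has no samples")
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    stage_names = []
    for s in stage_levels[1:]:
        cols.append((st == s).astype(float))
        names.append(f"stage_{s}")
        stage_names.append(f"stage_{s}")
    for d in donors[1:]:
        cols.append((dn == d).astype(float))
        names.append(f"donor_{d}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    if X.shape[0] < X.shape[1]:
        raise DesignError("fewer samples than design columns")
    return X, names, stage_names


def voom_normalize(
    cm: CountMatrix,
    baseline: str = "iPSC",
    prior_count: float = 0.5,
    span: float = 0.5,
    simple_mode: bool = False,
) -> NormalizedMatrix:
    """log2-CPM with precision weights from the mean-variance trend.

    ``logcpm = log2((count + prior_count) / (lib_size + 2 * prior_count) * 1e6)``.
    A preliminary unweighted fit of the donor + stage design yields per-gene
    residual standard deviations; sqrt(SD) is regressed on mean log2-count by
    lowess, and each observation's weight is the inverse of the trend-predicted
    variance at its fitted log2-count.  ``simple_mode`` sets all weights to 1
    (useful for comparing the fit against a plain least-squares oracle).
    """
    X, names, stage_names = build_design(cm, baseline)
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    eff_lib = lib + 2.0 * prior_count
    logcpm = np.log2((counts + prior_count) / eff_lib * 1e6)

    if simple_mode:
        w = np.ones_like(logcpm)
    else:
        # Preliminary unweighted fit shared across genes.
        pinv = np.linalg.pinv(X)
        beta = logcpm @ pinv.T                      # genes x p
        fitted = beta @ X.T
        resid = logcpm - fitted
        df = X.shape[0] - X.shape[1]
        if df <= 0:
            raise DesignError("no residual degrees of freedom for the trend fit")
        sigma = np.sqrt((resid**2).sum(axis=1) / df)
        # Mean log2-count per gene and fitted log2-count per observation.
        mean_logcount = logcpm.mean(axis=1) + np.mean(np.log2(eff_lib)) - np.log2(1e6)
        sqrt_sd = np.sqrt(sigma)
        trend = lowess(sqrt_sd, mean_logcount, frac=span, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        fitted_logcount = fitted + np.log2(eff_lib)[None, :] - np.log2(1e6)
        # Flat extrapolation beyond the fitted range, as in rule-2 interpolation.
        pred = np.interp(fitted_logcount, tx, ty, left=ty[0], right=ty[-1])
        pred = np.clip(pred, 1e-6, None)
        w = pred**-4

    idx, cols = cm.counts.index, cm.counts.columns
    return NormalizedMatrix(
        logcpm=pd.DataFrame(logcpm, index=idx, columns=cols),
        weights=pd.DataFrame(w, index=idx, columns=cols),
        lib_sizes=pd.Series(lib, index=cols),
        design=X,
        coef_names=names,
        stage_coef_names=stage_names,
    )


def fit_contrasts(norm: NormalizedMatrix) -> FitResult:
    """Gene-wise weighted least squares of log2-CPM on the donor + stage design.

    Each gene g solves ``min_b sum_i w_gi (y_gi - x_i' b)^2``; the stage
    coefficients are log2FCs versus the baseline.  Residual variance uses the
    weighted residual sum of squares over ``n - p`` degrees of freedom.
    """
    X = norm.design
    Y = norm.logcpm.to_numpy()
    W = norm.weights.to_numpy()
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise DesignError("no residual degrees of freedom")
    A = np.einsum("ni,gn,nj->gij", X, W, X)         # genes x p x p
    b = np.einsum("ni,gn,gn->gi", X, W, Y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    cov_unscaled = np.linalg.inv(A)
    se_unscaled = np.sqrt(np.diagonal(cov_unscaled, axis1=1, axis2=2))
    resid = Y - beta @ X.T
    s2 = np.einsum("gn,gn->g", W, resid**2) / df
    idx = norm.logcpm.index
    return FitResult(
        coef=pd.DataFrame(beta, index=idx, columns=norm.coef_names),
        stdev_unscaled=pd.DataFrame(se_unscaled, index=idx, columns=norm.coef_names),
        s2=pd.Series(s2, index=idx),
        df_resid=float(df),
        coef_names=norm.coef_names,
        stage_coef_names=norm.stage_coef_names,
    )


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < tol:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-inverse-chi^2 prior (d0, s0^2) to residual variances.

    Works on log s^2: under the model ``e_g = log s2_g - digamma(d/2) + log(d/2)``
    has mean ``log s0^2 + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond the sampling term ``trigamma(d/2)``; the excess is
    inverted through the trigamma function.  Non-positive excess means the
    variances are essentially exchangeable: d0 = inf with a pooled s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = np.exp(emean + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s0_sq)


_MAX_DF = 1e9  # t with this many df is numerically normal


def ebayes_moderate(
    fit: FitResult,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics for every stage-vs-baseline contrast.

    Posterior variance ``s2_post = (d0 * s0^2 + d * s2_g) / (d0 + d)``;
    ``t_mod = coef / (se_unscaled * sqrt(s2_post))`` on ``d0 + d`` degrees of
    freedom.  ``prior_df``/``prior_var`` override the moment estimates (d0 = 0
    recovers the ordinary t-test; d0 = inf pools all variances at s0^2).

    Returns a long DataFrame (gene_id, contrast, log2fc, t_mod, p) with the
    hyperparameters in ``.attrs``.
    """
    s2 = fit.s2.to_numpy()
    d = fit.df_resid
    if prior_df is None or prior_var is None:
        d0_est, s0_est = estimate_variance_prior(s2, d)
        d0 = d0_est if prior_df is None else prior_df
        s0_sq = s0_est if prior_var is None else prior_var
    else:
        d0, s0_sq = prior_df, prior_var
    if d0 < 0 or s0_sq <= 0:
        raise ValueError("need prior df >= 0 and prior variance > 0")

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    df_total = min(d0 + d, _MAX_DF)

    rows = []
    for name in fit.stage_coef_names:
        stage = name.removeprefix("stage_")
        coef = fit.coef[name].to_numpy()
        se = fit.stdev_unscaled[name].to_numpy() * np.sqrt(s2_post)
        t_mod = coef / se
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": fit.coef.index,
                    "contrast": stage,
                    "log2fc": coef,
                    "t_mod": t_mod,
                    "p": p,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table.attrs["prior_df"] = float(d0)
    table.attrs["prior_var"] = float(s0_sq)
    table.attrs["df_resid"] = float(d)
    return table


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, q_max: float = 0.01, lfc_min: float = 1.0) -> pd.DataFrame:
    """Add per-contrast q-values and the DE flag (strict inequalities).

    A contrast is DE iff ``q < q_max`` and ``|log2fc| > lfc_min``; genes sitting
    exactly on either boundary are not called.
    """
    out = table.copy()
    out["q"] = np.nan
    for _, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "q"] = adjust_bh(out.loc[idx, "p"].to_numpy())
    out["is_de"] = (out["q"] < q_max) & (out["log2fc"].abs() > lfc_min)
    out.attrs.update(table.attrs)
    return out


def run_de(
    cm: CountMatrix,
    baseline: str = "iPSC",
    q_max: float = 0.01,
    lfc_min: float = 1.0,
    cpm_threshold: float = 1.0,
    simple_mode: bool = False,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Full pipeline: filter -> weights -> fit -> moderate -> BH -> call."""
    filtered = filter_expressed(cm, cpm_threshold)
    norm = voom_normalize(filtered, baseline=baseline, simple_mode=simple_mode)
    fit = fit_contrasts(norm)
    table = ebayes_moderate(fit, prior_df=prior_df)
    return call_de(table, q_max=q_max, lfc_min=lfc_min)
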