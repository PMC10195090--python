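"""Normalization and the statistical contrasts of the ASE pipeline.

Five contrasts are computed per transcript, all on TMM/library-normalized
counts:

* ED      — parental expression divergence (NB likelihood-ratio test)
* AI      — allelic imbalance between the two alleles within hybrids (NB LRT)
* RATIO   — hybrid allele ratio vs parental ratio (binomial logit GLM);
            a significant difference is evidence of a trans component
* H_vs_P1 / H_vs_P2 — hybrid total expression vs each parent (NB LRT)

The NB test is a deviance test with a plug-in common dispersion: group
means are fitted by Fisher scoring with a log link and library-size
offsets, and twice the log-likelihood difference between the free-means and
equal-means fits is referred to chi-square with 1 df.  Dispersion is
estimated once by maximizing the NB profile likelihood across transcripts.

Significance uses the dual rule: BH-adjusted q below ``alpha`` AND
|log2 fold change| above ``fc_threshold`` (defaults 0.05 and 1.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, xlogy
from scipy.stats import chi2, norm, rankdata
from statsmodels.stats.multitest import multipletests

CONTRASTS = ("ED", "AI", "RATIO", "H_vs_P1", "H_vs_P2")

RESULT_COLUMNS = ["log2fc", "p", "q", "significant"]


@dataclass(frozen=True)
class StatConfig:
    """Testing thresholds and the NB dispersion.

    alpha: FDR level for the BH-adjusted q-values.
    fc_threshold: |log2FC| a transcript must additionally exceed.
    dispersion: NB dispersion phi (variance = mu + phi * mu^2); None means
        estimate it from the data.
    fc_threshold_on_ratio: whether the fold-change rule also applies to the
        binomial ratio test (on |T|); switch off to call trans effects on
        FDR alone.
    """

    alpha: float = 0.05
    fc_threshold: float = 1.25
    dispersion: float | None = None
    fc_threshold_on_ratio: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be >= 0")
        if self.dispersion is not None and self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Trimmed, weighted mean of M-values of one column against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method weights: asymptotic variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return float(2.0 ** f)


def tmm_factors(counts, ref_column=None, trim_m: float = 0.3,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    counts may be a CountMatrix, DataFrame or 2-D array (transcripts x
    samples).  The reference column defaults to the sample whose
    upper-quartile expression rate is closest to the across-sample mean.
    """
    df = getattr(counts, "df", counts)
    if not isinstance(df, pd.DataFrame):
        df = pd.DataFrame(np.asarray(counts))
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = df.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("TMM requires positive library sizes")
    if ref_column is None:
        uq = df.apply(lambda c: np.quantile(c / c.sum(), 0.75), axis=0)
        ref_column = (uq - uq.mean()).abs().idxmin()
    ref = df[ref_column].to_numpy()
    n_ref = float(lib[ref_column])
    fac = {}
    for col in df.columns:
        if col == ref_column:
            fac[col] = 1.0
        else:
            fac[col] = _tmm_pair(df[col].to_numpy(), ref, float(lib[col]),
                                 n_ref, trim_m, trim_a)
    out = pd.Series(fac, index=df.columns, name="tmm_factor")
    return out / np.exp(np.log(out).mean())


def effective_lib_sizes(counts, factors: pd.Series | None = None) -> pd.Series:
    """Column totals scaled by TMM factors."""
    df = getattr(counts, "df", counts)
    if factors is None:
        factors = tmm_factors(df)
    return df.sum(axis=0).astype(float) * factors


# ---------------------------------------------------------------------------
# negative-binomial likelihood machinery
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-observation NB log-likelihood (Poisson when phi == 0)."""
    mu = np.maximum(mu, 1e-300)
    if phi == 0:
        return xlogy(y, mu) - mu - gammaln(y + 1)
    r = 1.0 / phi
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + xlogy(y, mu / (r + mu)))


def _fit_mean(y: np.ndarray, s: np.ndarray, phi: float,
              n_iter: int = 60, tol: float = 1e-12) -> np.ndarray:
    """MLE of the normalized mean lambda with mu_j = s_j * lambda.

    Fisher scoring on log(lambda); vectorized over leading axes of y.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    lam = np.maximum(y.sum(axis=-1) / s.sum(axis=-1), 1e-12)
    if phi == 0:
        return lam  # closed form in the Poisson limit
    for _ in range(n_iter):
        mu = s * lam[..., None]
        denom = 1.0 + phi * mu
        grad = ((y - mu) / denom).sum(axis=-1)          # = lam * dll/dlam
        info = (mu / denom).sum(axis=-1)                # = lam^2 * I(lam)
        step = grad / np.maximum(info, 1e-300)
        step = np.clip(step, -4.0, 4.0)
        lam = lam * np.exp(step)
        if np.max(np.abs(step)) < tol:
            break
    return lam


def _as2d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def nb_two_group_test(a, b, lib_sizes=None, phi: float = 0.0,
                      transcript_ids=None) -> pd.DataFrame:
    """NB likelihood-ratio test of equal normalized means between two groups.

    a, b: replicate counts, shape (n_transcripts, r) or (r,).
    lib_sizes: (sizes_a, sizes_b) effective library sizes; equal if None.
    Returns a DataFrame with log2fc (log2 lambda_a / lambda_b) and the
    two-sided p from deviance vs chi-square(1).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a, b = _as2d(a), _as2d(b)
    if lib_sizes is None:
        sa = np.ones(a.shape[1])
        sb = np.ones(b.shape[1])
    else:
        sa = np.asarray(lib_sizes[0], dtype=float)
        sb = np.asarray(lib_sizes[1], dtype=float)
    if (sa <= 0).any() or (sb <= 0).any():
        raise ValueError("effective library sizes must be positive")
    # rescale offsets to a mean of 1 so lambda stays on the count scale
    scale = np.concatenate([sa, sb]).mean()
    sa, sb = sa / scale, sb / scale
    lam_a = _fit_mean(a, sa, phi)
    lam_b = _fit_mean(b, sb, phi)
    yc = np.concatenate([a, b], axis=1)
    sc = np.concatenate([sa, sb])
    lam_0 = _fit_mean(yc, sc, phi)
    ll_alt = (_nb_loglik(a, sa * lam_a[:, None], phi).sum(axis=1)
              + _nb_loglik(b, sb * lam_b[:, None], phi).sum(axis=1))
    ll_null = _nb_loglik(yc, sc * lam_0[:, None], phi).sum(axis=1)
    dev = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = chi2.sf(dev, df=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(lam_a) - np.log2(lam_b)
    idx = transcript_ids if transcript_ids is not None else range(len(p))
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=pd.Index(idx, name="transcript_id"))


def estimate_common_dispersion(counts, groups, lib_sizes=None,
                               bounds=(1e-6, 10.0)) -> float:
    """Common NB dispersion shared by all transcripts, clamped to ``bounds``.

    Maximizes the conditional profile likelihood given each group's total
    count, which eliminates the downward bias the plain MLE suffers when
    every group mean must be estimated from a handful of replicates.
    Library sizes are equalized first by scaling counts to pseudo-counts at
    the geometric-mean depth (the conditional likelihood assumes equal
    sizes within a group).

    counts: (n_transcripts, n_samples) array/DataFrame/CountMatrix;
    groups: per-column labels.  At least one group needs >= 2 replicates.
    """
    df = getattr(counts, "df", counts)
    y = np.asarray(df, dtype=float)
    groups = np.asarray(groups)
    if lib_sizes is None:
        s = y.sum(axis=0).astype(float)
    else:
        s = np.asarray(lib_sizes, dtype=float)
    ref = np.exp(np.log(s).mean())
    y = np.round(y * (ref / s))
    labels = pd.unique(groups)
    group_cols = [np.flatnonzero(groups == g) for g in labels]
    group_cols = [c for c in group_cols if len(c) >= 2]
    if not group_cols:
        raise ValueError(
            "no group has replication; set StatConfig.dispersion explicitly"
        )

    def neg_cond(log_phi: float) -> float:
        r = 1.0 / float(np.exp(log_phi))
        total = 0.0
        for cols in group_cols:
            yg = y[:, cols]
            ng = len(cols)
            z = yg.sum(axis=1)
            total += (gammaln(yg + r).sum(axis=1) - ng * gammaln(r)
                      + gammaln(ng * r) - gammaln(z + ng * r)).sum()
        return -total

    res = minimize_scalar(neg_cond,
                          bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-4})
    return float(np.clip(np.exp(res.x), bounds[0], bounds[1]))


# ---------------------------------------------------------------------------
# binomial ratio test (trans effects)
# ---------------------------------------------------------------------------

def _pearson_scale(blocks) -> tuple[np.ndarray, int]:
    """Quasi-binomial dispersion from replicate heterogeneity.

    blocks: iterable of (successes, totals) arrays, one per group, shape
    (n_transcripts, replicates).  Returns (scale floored at 1, df).
    """
    x2 = None
    df = 0
    for x, tot in blocks:
        ph = x.sum(axis=1) / tot.sum(axis=1)
        mu = tot * ph[:, None]
        denom = mu * (1.0 - ph[:, None])
        ok = denom > 0
        contrib = np.where(ok, (x - mu) ** 2 / np.where(ok, denom, 1.0), 0.0)
        x2 = contrib.sum(axis=1) if x2 is None else x2 + contrib.sum(axis=1)
        df += x.shape[1] - 1
    if df == 0:
        return np.ones_like(x2), 0
    return np.maximum(x2 / df, 1.0), df


def binomial_ratio_test(hybrid_a1, hybrid_a2, parent1, parent2,
                        transcript_ids=None,
                        dispersion_adjust: bool = True) -> pd.DataFrame:
    """Logit GLM comparing the hybrid allele ratio with the parental ratio.

    Models allele-1 counts out of per-group totals with a hybrid-vs-parent
    indicator; with a single binary covariate the fitted proportions are the
    pooled per-group proportions, so the Wald test has closed form.  The
    effect is reported as T = Rp - Rh on the log2 scale.

    Biological replicates are noisier than binomial sampling, so by default
    the Wald standard error is inflated by a quasi-binomial scale estimated
    from the Pearson statistic of the per-replicate proportions (floored at
    1); set ``dispersion_adjust=False`` for the plain binomial Wald test.
    Where the standard error degenerates (separation: a pooled count of
    zero), the p-value falls back to the binomial likelihood-ratio test of
    equal proportions.
    """
    a1, a2 = _as2d(hybrid_a1), _as2d(hybrid_a2)
    p1, p2 = _as2d(parent1), _as2d(parent2)
    xh, nh = a1.sum(axis=1), (a1 + a2).sum(axis=1)
    xp, npar = p1.sum(axis=1), (p1 + p2).sum(axis=1)
    if (nh == 0).any() or (npar == 0).any():
        raise ValueError("all replicate totals must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        rh = np.log2(xh) - np.log2(nh - xh)
        rp = np.log2(xp) - np.log2(npar - xp)
        t_effect = rp - rh
        se = np.sqrt(1.0 / xh + 1.0 / (nh - xh) + 1.0 / xp + 1.0 / (npar - xp))
        if dispersion_adjust:
            scale, _ = _pearson_scale([(a1, a1 + a2), (p1, p1 + p2)])
            se = se * np.sqrt(scale)
        z = (t_effect * np.log(2.0)) / se
    p_wald = 2.0 * norm.sf(np.abs(z))
    # LRT fallback for degenerate (separated) tables
    x0, n0 = xh + xp, nh + npar
    ll_free = (_binom_ll(xh, nh) + _binom_ll(xp, npar))
    ll_null = _binom_ll_at(xh, nh, x0 / n0) + _binom_ll_at(xp, npar, x0 / n0)
    dev = np.maximum(2.0 * (ll_free - ll_null), 0.0)
    p_lrt = chi2.sf(dev, df=1)
    degenerate = ~np.isfinite(se) | ~np.isfinite(t_effect)
    p = np.where(degenerate, p_lrt, p_wald)
    idx = transcript_ids if transcript_ids is not None else range(len(p))
    return pd.DataFrame({"log2fc": t_effect, "p": p},
                        index=pd.Index(idx, name="transcript_id"))


def _binom_ll(x, n):
    with np.errstate(divide="ignore", invalid="ignore"):
        ph = x / n
    return xlogy(x, ph) + xlogy(n - x, 1 - ph)


def _binom_ll_at(x, n, prob):
    return xlogy(x, prob) + xlogy(n - x, 1 - prob)


# ---------------------------------------------------------------------------
# multiple testing and the dual significance rule
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significance(results: pd.DataFrame, cfg: StatConfig | None = None,
                      apply_fc_threshold: bool = True) -> pd.DataFrame:
    """Attach q-values and the dual significance flag to a result frame.

    significant <=> q < alpha AND |log2fc| > fc_threshold (the fold-change
    clause can be switched off, e.g. for the ratio test when configured).
    """
    cfg = cfg or StatConfig()
    out = results.copy()
    out["q"] = bh_fdr(out["p"].to_numpy())
    sig = out["q"] < cfg.alpha
    if apply_fc_threshold:
        sig &= out["log2fc"].abs() > cfg.fc_threshold
    out["significant"] = sig
    return out
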