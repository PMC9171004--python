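"""Admixture-informed maximum-likelihood selection scan (AIMLESS).

Per site *i*, the target population's counted-allele count is modelled as
X_i ~ Binomial(N_i, f) and two nested hypotheses are compared:

* unconstrained: f is free; its MLE is the observed frequency
  f_i = X_i / N_i, with log-likelihood l0;
* constrained: f must be expressible as a two-source admixture
  f̂_i^T = γ̂_i f_i^S1 + (1 − γ̂_i) f_i^S2, where γ̂_i ∈ [0, 1] minimises
  the squared deviation (f_i − [γ f^S1 + (1 − γ) f^S2])², with
  log-likelihood l1.

Since f_i is the binomial MLE, l0 ≥ l1, and the likelihood-ratio statistic
Λ_i = 2 (l0 − l1) ≥ 0 is referred to a χ² distribution with two degrees of
freedom: p = exp(−Λ/2) in closed form.  A large Λ means the target's
frequency cannot be explained by any mixture of the two sources — the
signature of post-admixture allele-frequency change, e.g. selection.

Source frequencies are treated as fixed known quantities in the likelihood;
their sampling noise is not propagated.  This, plus the boundary constraint
on γ, makes the χ²₂ reference conservative (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import AlleleCounts, chrom_sort_key

_LN10 = np.log(10.0)

#: Smallest representable p-value; smaller values are floored and flagged.
P_FLOOR = 1e-320
LOG10_P_FLOOR = -320.0


@dataclass
class AimlessScanConfig:
    """Site filters and significance cutoff for a genome scan.

    ``min_individuals_per_pop``: a site is tested only when at least this
    many individuals have a genotype call in *each* of the three role
    populations (default 10; the count is individuals, not allele calls).
    ``require_source_freq_nonzero``: drop sites where the counted allele is
    absent from either source (default on).  ``require_source_freq_not_fixed``
    additionally drops sites fixed for the counted allele in a source
    (default off).  ``significance_cutoff``: p-value threshold, default 1e-8
    (calibrated to zero false discoveries by simulation; see calibration).
    """

    min_individuals_per_pop: int = 10
    require_source_freq_nonzero: bool = True
    require_source_freq_not_fixed: bool = False
    significance_cutoff: float = 1e-8

    def __post_init__(self) -> None:
        if self.min_individuals_per_pop < 1:
            raise ValueError("min_individuals_per_pop must be >= 1")
        if not 0.0 < self.significance_cutoff < 1.0:
            raise ValueError("significance_cutoff must be in (0, 1)")


def estimate_gamma(f_t, f_s1, f_s2):
    """Least-squares mixing proportion γ̂ ∈ [0, 1] of source 1 in the target.

    Minimises (f_t − [γ f_s1 + (1 − γ) f_s2])² over γ ∈ [0, 1]: the
    unconstrained minimiser (f_t − f_s2)/(f_s1 − f_s2) clamped to [0, 1].
    When the sources are equally frequent (f_s1 = f_s2) every γ is optimal
    and γ̂ is defined to be 1 exactly.  Accepts scalars or arrays.
    """
    f_t, f_s1, f_s2 = np.asarray(f_t, float), np.asarray(f_s1, float), np.asarray(f_s2, float)
    for name, v in (("f_t", f_t), ("f_s1", f_s1), ("f_s2", f_s2)):
        if ((v < 0) | (v > 1)).any() or np.isnan(v).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    equal = f_s1 == f_s2
    denom = np.where(equal, 1.0, f_s1 - f_s2)
    raw = (f_t - f_s2) / denom
    gamma = np.where(equal, 1.0, np.clip(raw, 0.0, 1.0))
    return gamma if gamma.ndim else float(gamma)


def site_lrt(x_t, n_t, f_s1, f_s2) -> pd.DataFrame:
    """Likelihood-ratio test of the two-source admixture constraint per site.

    Vectorised over sites.  Returns a DataFrame with columns ``f_t``,
    ``gamma_hat``, ``f_hat_t``, ``l_unconstrained``, ``l_constrained``,
    ``lambda``, ``p_value``, ``log10_p`` and ``degenerate``.

    Conventions: 0·log 0 ≡ 0 at the binomial support boundary (the scipy
    log-pmf already obeys this); |Λ| < 1e-9 is clamped to 0 (floating-point
    guard); when the constrained frequency is exactly 0 or 1 while
    0 < x_t < n_t the constrained likelihood is −∞, reported as Λ = +inf
    with p floored at 1e-320 and ``degenerate=True``.
    """
    x = np.atleast_1d(np.asarray(x_t, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n_t, dtype=np.int64))
    f1 = np.broadcast_to(np.asarray(f_s1, float), x.shape).astype(float)
    f2 = np.broadcast_to(np.asarray(f_s2, float), x.shape).astype(float)
    if (n < 1).any():
        raise ValueError("n_t must be >= 1")
    if ((x < 0) | (x > n)).any():
        raise ValueError("need 0 <= x_t <= n_t")
    f_t = x / n
    gamma = np.asarray(estimate_gamma(f_t, f1, f2))
    f_hat = gamma * f1 + (1.0 - gamma) * f2
    l0 = stats.binom.logpmf(x, n, f_t)
    with np.errstate(divide="ignore"):
        l1 = stats.binom.logpmf(x, n, f_hat)
    lam = 2.0 * (l0 - l1)
    lam = np.where(np.abs(lam) < 1e-9, 0.0, lam)
    if (lam < 0).any():
        raise AssertionError("negative likelihood-ratio statistic beyond rounding")
    degenerate = np.isinf(lam)
    with np.errstate(over="ignore"):
        p = np.maximum(np.exp(-lam / 2.0), P_FLOOR)
    log10_p = np.maximum(-lam / 2.0 / _LN10, LOG10_P_FLOOR)
    return pd.DataFrame(
        {
            "f_t": f_t,
            "gamma_hat": gamma,
            "f_hat_t": f_hat,
            "l_unconstrained": l0,
            "l_constrained": l1,
            "lambda": lam,
            "p_value": p,
            "log10_p": log10_p,
            "degenerate": degenerate,
        }
    )


def filter_sites(counts: AlleleCounts, cfg: AimlessScanConfig | None = None) -> pd.DataFrame:
    """Per-site pass/fail with reason codes for the scan's site filters.

    A site passes iff every role population has at least
    ``min_individuals_per_pop`` individuals observed and the counted-allele
    frequency in both sources is > 0 (and < 1 when that option is enabled).
    Reasons are semicolon-joined codes such as ``min_individuals:source1``
    or ``source_freq_zero:source2``; passing sites have an empty reason.
    """
    cfg = cfg or AimlessScanConfig()
    n_sites = counts.n_sites
    reasons = [[] for _ in range(n_sites)]
    for role in ("target", "source1", "source2"):
        pop = counts.role_pop(role)
        low = counts.n_ind[pop] < cfg.min_individuals_per_pop
        for i in np.flatnonzero(low):
            reasons[i].append(f"min_individuals:{role}")
    for role in ("source1", "source2"):
        pop = counts.role_pop(role)
        f = counts.freq(pop)
        if cfg.require_source_freq_nonzero:
            for i in np.flatnonzero(~(f > 0)):  # catches NaN too
                reasons[i].append(f"source_freq_zero:{role}")
        if cfg.require_source_freq_not_fixed:
            for i in np.flatnonzero(f >= 1):
                reasons[i].append(f"source_freq_one:{role}")
    return pd.DataFrame(
        {
            "passed": [not r for r in reasons],
            "filter_reason": [";".join(r) for r in reasons],
        }
    )


def aimless_scan(counts: AlleleCounts, cfg: AimlessScanConfig | None = None) -> pd.DataFrame:
    """Run the admixture-constraint LRT over an allele-count table.

    Requires ``counts.roles`` naming the target and the two sources.  Returns
    one row per site sorted by (chromosome, position): filtered sites carry
    their reason codes and NaN statistics; tested sites carry γ̂, f̂ᵀ, Λ,
    p, −log10 p (``minus_log10_p``, the Manhattan-plot ordinate) and a
    ``significant`` flag (p < cutoff).  An empty passing set is returned as
    such, not raised.
    """
    cfg = cfg or AimlessScanConfig()
    if counts.n_sites == 0:
        raise ValueError("empty allele-count table")
    t = counts.role_pop("target")
    s1 = counts.role_pop("source1")
    s2 = counts.role_pop("source2")
    flt = filter_sites(counts, cfg)
    out = counts.snp[["snp_id", "chrom", "pos"]].copy()
    out["x_t"] = counts.x[t]
    out["n_t"] = counts.n_alleles[t]
    out["f_s1"] = counts.freq(s1)
    out["f_s2"] = counts.freq(s2)
    stat_cols = [
        "f_t", "gamma_hat", "f_hat_t", "lambda", "p_value", "log10_p",
    ]
    for c in stat_cols:
        out[c] = np.nan
    out["degenerate"] = False
    stat_cols.append("degenerate")
    mask = flt["passed"].to_numpy()
    if mask.any():
        res = site_lrt(
            out.loc[mask, "x_t"].to_numpy(),
            out.loc[mask, "n_t"].to_numpy(),
            out.loc[mask, "f_s1"].to_numpy(),
            out.loc[mask, "f_s2"].to_numpy(),
        )
        for c in stat_cols:
            out.loc[mask, c] = res[c].to_numpy()
    out["minus_log10_p"] = -out["log10_p"]
    out["significant"] = mask & (out["p_value"].to_numpy() < cfg.significance_cutoff)
    out["filter_reason"] = flt["filter_reason"]
    order = sorted(
        range(len(out)),
        key=lambda i: (chrom_sort_key(out["chrom"].iat[i]), out["pos"].iat[i]),
    )
    return out.iloc[order].reset_index(drop=True)
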