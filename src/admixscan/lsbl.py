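"""Locus-specific branch lengths (LSBL) from per-SNP pairwise Fst.

For three populations A, B, C the three pairwise per-SNP Fst values are
decomposed into additive branch lengths

    branch_A = (Fst_AB + Fst_AC − Fst_BC) / 2      (and cyclically),

so that branch_A + branch_B = Fst_AB exactly.  A long branch specific to
one population marks a locus whose frequency moved in that population
relative to both comparators — the classic single-locus outlier signature
of positive selection.  Sites are prioritised by the empirical upper-tail
quantile of the focal branch (top 1% by default).

The default per-SNP Fst is Hudson's estimator with the finite-sample
correction,

    num = (p̂1 − p̂2)² − p̂1(1 − p̂1)/(n1 − 1) − p̂2(1 − p̂2)/(n2 − 1)
    den = p̂1(1 − p̂2) + p̂2(1 − p̂1),

where n_k counts observed allele calls.  Raw values may be negative by
finite-sample noise; ranking uses raw values (truncating first would create
massive ties at 0) and a truncated-at-zero variant is also reported.  A
Weir–Cockerham variant (allele-count form) is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import AlleleCounts, ConfigurationError, chrom_sort_key


def hudson_fst(x1, n1, x2, n2):
    """Per-SNP Hudson Fst from allele counts of two populations.

    Returns ``(fst, valid)``; ``valid`` is False where a population has
    fewer than 2 observed alleles or the denominator is 0 (both populations
    fixed for the same allele).  Invalid sites get NaN.
    """
    x1, n1 = np.asarray(x1, float), np.asarray(n1, float)
    x2, n2 = np.asarray(x2, float), np.asarray(n2, float)
    enough = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = x1 / n1
        p2 = x2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        valid = enough & (den > 0)
        fst = np.where(valid, num / np.where(den > 0, den, 1.0), np.nan)
    if fst.ndim:
        return fst, valid
    return float(fst), bool(valid)


def weir_cockerham_fst(x1, n1, x2, n2):
    """Weir–Cockerham θ̂ for two populations from allele counts.

    Uses the allele-count (haploid-observation) form, appropriate for
    pseudohaploid data where within-individual heterozygosity is not
    observed.  Same ``(fst, valid)`` contract as :func:`hudson_fst`.
    """
    x1, n1 = np.asarray(x1, float), np.asarray(n1, float)
    x2, n2 = np.asarray(x2, float), np.asarray(n2, float)
    enough = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = x1 / n1, x2 / n2
        nt = n1 + n2
        pbar = (x1 + x2) / nt
        nc = (nt - (n1**2 + n2**2) / nt)  # r - 1 = 1
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # / (r-1) = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nt - 2)
        den = msp + (nc - 1) * msg
        valid = enough & (den > 0)
        fst = np.where(valid, (msp - msg) / np.where(den > 0, den, 1.0), np.nan)
    if fst.ndim:
        return fst, valid
    return float(fst), bool(valid)


_ESTIMATORS = {"hudson": hudson_fst, "weir-cockerham": weir_cockerham_fst}


def lsbl_branches(fst_ab, fst_ac, fst_bc):
    """Decompose three pairwise Fst values into per-population branch lengths."""
    fst_ab, fst_ac, fst_bc = (np.asarray(v, float) for v in (fst_ab, fst_ac, fst_bc))
    a = (fst_ab + fst_ac - fst_bc) / 2.0
    b = (fst_bc + fst_ab - fst_ac) / 2.0
    c = (fst_ac + fst_bc - fst_ab) / 2.0
    return a, b, c


def empirical_quantile(values) -> np.ndarray:
    """Upper-tail empirical quantile: share of finite values >= each value.

    Ties share a quantile; the largest value gets 1/n_valid, so quantiles
    lie in (0, 1].  NaN inputs receive NaN.  The paper-style "empirical P
    value" of an outlier scan is exactly this rank-based quantity.
    """
    v = np.asarray(values, float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d array of branch lengths")
    finite = np.isfinite(v)
    n_valid = int(finite.sum())
    if n_valid == 0:
        raise ValueError("no valid values to rank")
    sorted_vals = np.sort(v[finite])
    q = np.full(v.shape, np.nan)
    q[finite] = (n_valid - np.searchsorted(sorted_vals, v[finite], side="left")) / n_valid
    return q


def lsbl_scan(
    counts: AlleleCounts,
    focal: str,
    comparator1: str,
    comparator2: str,
    threshold: float = 0.01,
    inclusive: bool = True,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Three-population LSBL outlier scan over an allele-count table.

    ``focal``/``comparator1``/``comparator2`` are population labels in
    ``counts`` (use :meth:`AlleleCounts.pool` first to build merged groups
    such as a combined early-farmer population).  Per site the output carries
    the three pairwise Fst values, raw and truncated branch lengths, the
    upper-tail quantile of each branch among valid sites, and ``top_focal``
    marking the prioritised set: focal-branch quantile <= ``threshold``
    (default top 1%), or strictly < with ``inclusive=False``.  Sites invalid
    in any pairwise comparison are excluded from ranking and never flagged.
    """
    pops = (focal, comparator1, comparator2)
    if len(set(pops)) != 3:
        raise ConfigurationError(f"need three distinct populations, got {pops}")
    for p in pops:
        if p not in counts.x:
            raise ConfigurationError(f"population {p!r} not in the count table")
    if estimator not in _ESTIMATORS:
        raise ConfigurationError(f"estimator must be one of {sorted(_ESTIMATORS)}")
    fst = _ESTIMATORS[estimator]
    a, b, c = pops
    f_ab, v_ab = fst(counts.x[a], counts.n_alleles[a], counts.x[b], counts.n_alleles[b])
    f_ac, v_ac = fst(counts.x[a], counts.n_alleles[a], counts.x[c], counts.n_alleles[c])
    f_bc, v_bc = fst(counts.x[b], counts.n_alleles[b], counts.x[c], counts.n_alleles[c])
    valid = v_ab & v_ac & v_bc
    br_a, br_b, br_c = lsbl_branches(
        np.where(valid, f_ab, np.nan),
        np.where(valid, f_ac, np.nan),
        np.where(valid, f_bc, np.nan),
    )
    out = counts.snp[["snp_id", "chrom", "pos"]].copy()
    out["fst_ab"], out["fst_ac"], out["fst_bc"] = f_ab, f_ac, f_bc
    out["valid"] = valid
    for name, br in (("a", br_a), ("b", br_b), ("c", br_c)):
        out[f"branch_{name}"] = br
        out[f"branch_{name}_trunc"] = np.maximum(br, 0.0)
        out[f"quantile_{name}"] = (
            empirical_quantile(br) if np.isfinite(br).any() else np.nan
        )
    q = out["quantile_a"].to_numpy()
    out["top_focal"] = np.where(
        valid, (q <= threshold) if inclusive else (q < threshold), False
    )
    order = sorted(
        range(len(out)),
        key=lambda i: (chrom_sort_key(out["chrom"].iat[i]), out["pos"].iat[i]),
    )
    return out.iloc[order].reset_index(drop=True)
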