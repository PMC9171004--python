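"""Simulation study calibrating the scan's significance cutoff.

Generates three-population allele-count data under a known two-source
admixture truth — null sites whose target frequency is exactly the mixture
γ f^S1 + (1 − γ) f^S2, and "selected" sites whose target frequency is
additionally shifted by ±δ — runs the admixture-constraint LRT on it, and
tabulates false and positive discovery rates over a grid of p-value
cutoffs.  The chosen cutoff is the largest one with zero false discoveries
(equivalently, the zero-FDR cutoff with the highest positive discovery
rate, since detections only grow with the cutoff).

The same truth model drives :func:`generate_synthetic_dataset`, which emits
individual-level pseudohaploid EIGENSTRAT genotypes and is the package's
universal test fixture: every draw comes from a named random stream keyed
on (seed, stream name), so enlarging a simulation extends existing draws
instead of reshuffling them.

Defaults emulate an ancient-DNA capture cohort: ~100 observed allele calls
per population per site (one per pseudohaploid individual), admixture
proportion γ = 0.93 of source 1, selection shift δ = 0.35, and source
frequencies drawn uniformly on (0.05, 0.95) (an empirical frequency table
can be supplied instead to mimic observed source-population spectra).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aimless import AimlessScanConfig, aimless_scan
from .genotype_io import (
    MISSING,
    AlleleCounts,
    ConfigurationError,
    GenotypeMatrix,
    PopulationMap,
    compute_counts,
    write_eigenstrat,
    write_population_map,
)

ROLES = ("target", "source1", "source2")

#: Cutoff grid 1e-2 .. 1e-12 used when none is supplied.
DEFAULT_GRID = tuple(10.0 ** -k for k in range(2, 13))


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for the named stream of a global integer seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SimulationConfig:
    """Study conditions for the calibration simulation.

    ``sample_sizes`` are observed allele calls per population per site
    (equal to individuals for pseudohaploid data), ordered target, source1,
    source2.  ``source_freq_model`` is ``("uniform", a, b)``,
    ``("beta", alpha, beta)`` — both draw the two sources independently —
    or ``("empirical", table)`` with an (m, 2) array of joint
    (f_s1, f_s2) rows sampled with replacement.  ``selection_effect`` is the
    additive frequency shift δ applied to the target at selected sites,
    with randomised sign and clamped to [0, 1].
    """

    n_null_sites: int = 100_000
    n_selected_sites: int = 1_000
    source_freq_model: tuple = ("uniform", 0.05, 0.95)
    admixture_gamma: float = 0.93
    sample_sizes: tuple[int, int, int] = (100, 100, 100)
    selection_effect: float = 0.35
    missing_rate: float | dict = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null_sites < 1:
            raise ConfigurationError("n_null_sites must be >= 1")
        if not 0.0 <= self.admixture_gamma <= 1.0:
            raise ConfigurationError("admixture_gamma must be in [0, 1]")
        if not 0.0 <= self.selection_effect <= 1.0:
            raise ConfigurationError("selection_effect must be in [0, 1]")

    def rate(self, role: str) -> float:
        mr = self.missing_rate
        return float(mr.get(role, 0.0)) if isinstance(mr, dict) else float(mr)


def _draw_source_freqs(cfg: SimulationConfig, group: str, n: int) -> np.ndarray:
    rng = stream_rng(cfg.seed, f"{group}_source_freq")
    model = cfg.source_freq_model
    kind = model[0]
    if kind == "uniform":
        return rng.uniform(model[1], model[2], size=(n, 2))
    if kind == "beta":
        return rng.beta(model[1], model[2], size=(n, 2))
    if kind == "empirical":
        if len(model) < 2 or model[1] is None:
            raise ConfigurationError("empirical source_freq_model needs a table")
        table = np.asarray(model[1], float)
        if table.ndim != 2 or table.shape[1] != 2:
            raise ConfigurationError("empirical frequency table must be (m, 2)")
        return table[rng.integers(0, len(table), size=n)]
    raise ConfigurationError(f"unknown source_freq_model kind {kind!r}")


def draw_truth(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-site true frequencies and selection labels (null sites first)."""
    parts = []
    for group, n in (("null", cfg.n_null_sites), ("selected", cfg.n_selected_sites)):
        if n == 0:
            continue
        fs = _draw_source_freqs(cfg, group, n)
        mix = cfg.admixture_gamma * fs[:, 0] + (1 - cfg.admixture_gamma) * fs[:, 1]
        if group == "selected":
            sign = np.where(
                stream_rng(cfg.seed, "selected_sign").random(n) < 0.5, -1.0, 1.0
            )
            f_target = np.clip(mix + sign * cfg.selection_effect, 0.0, 1.0)
        else:
            f_target = mix
        parts.append(
            pd.DataFrame(
                {
                    "selected": group == "selected",
                    "true_f_s1": fs[:, 0],
                    "true_f_s2": fs[:, 1],
                    "true_gamma": cfg.admixture_gamma,
                    "true_f_target": f_target,
                }
            )
        )
    truth = pd.concat(parts, ignore_index=True)
    truth.insert(0, "snp_id", [f"s{i + 1:07d}" for i in range(len(truth))])
    truth.insert(1, "chrom", "1")
    truth.insert(2, "pos", np.arange(1, len(truth) + 1) * 1000)
    return truth


def simulate_counts(cfg: SimulationConfig) -> tuple[AlleleCounts, pd.DataFrame]:
    """Draw per-population allele counts under the configured truth.

    Source counts are binomial at each source's own true frequency (source
    frequencies are later *estimated* from these, as in a real scan);
    target counts are binomial at the true mixture (null) or shifted
    mixture (selected).  Missingness thins each population's observed
    allele calls binomially.  Fully reproducible from ``cfg.seed``.
    """
    truth = draw_truth(cfg)
    n_sites = len(truth)
    true_f = {
        "target": truth["true_f_target"].to_numpy(),
        "source1": truth["true_f_s1"].to_numpy(),
        "source2": truth["true_f_s2"].to_numpy(),
    }
    x, n_alleles, n_ind = {}, {}, {}
    for role, n_pop in zip(ROLES, cfg.sample_sizes):
        rate = cfg.rate(role)
        if rate > 0:
            n_obs = stream_rng(cfg.seed, f"missing_{role}").binomial(
                n_pop, 1.0 - rate, size=n_sites
            )
        else:
            n_obs = np.full(n_sites, n_pop, dtype=np.int64)
        x[role] = stream_rng(cfg.seed, f"counts_{role}").binomial(n_obs, true_f[role])
        n_alleles[role] = n_obs
        n_ind[role] = n_obs  # pseudohaploid: one allele call per individual
    snp = truth[["snp_id", "chrom", "pos"]].copy()
    snp["gpos"] = 0.0
    snp["ref"] = "A"
    snp["alt"] = "G"
    counts = AlleleCounts(
        snp[["snp_id", "chrom", "gpos", "pos", "ref", "alt"]],
        x,
        n_alleles,
        n_ind,
        roles={r: r for r in ROLES},
    )
    return counts, truth


@dataclass
class CalibrationReport:
    """FDR/PDR over a cutoff grid with the chosen zero-FDR cutoff.

    ``table`` has one row per cutoff: false/true positive counts, FDR =
    FP/(FP+TP) (0 when nothing is called) and PDR = TP / number of truly
    selected sites simulated.  ``chosen_cutoff`` is the zero-FDR cutoff
    with the highest positive discovery rate; exact PDR ties break toward
    the smaller (more conservative) cutoff.  None if every cutoff on the
    grid yields a false discovery.
    """

    table: pd.DataFrame
    chosen_cutoff: float | None
    n_null: int
    n_selected: int
    notes: dict = field(default_factory=dict)

    def at(self, cutoff: float) -> pd.Series:
        row = self.table.loc[np.isclose(self.table["cutoff"], cutoff)]
        if row.empty:
            raise KeyError(f"cutoff {cutoff} not on the grid")
        return row.iloc[0]


def calibrate_cutoff(p_null, p_selected, grid=DEFAULT_GRID, n_selected_total=None) -> CalibrationReport:
    """Tabulate FDR and PDR over a sorted grid of p-value cutoffs.

    ``p_null``/``p_selected`` are the scan p-values of truly-null and
    truly-selected sites.  ``n_selected_total`` (default: len(p_selected))
    is the PDR denominator — pass the number of selected sites *simulated*
    when some were removed by site filters before testing.
    """
    p_null = np.sort(np.asarray(p_null, float))
    p_selected = np.sort(np.asarray(p_selected, float))
    if p_null.size == 0 or (p_selected.size == 0 and not n_selected_total):
        raise ValueError("both p-value lists must be non-empty")
    denom = int(n_selected_total or p_selected.size)
    grid = np.sort(np.asarray(grid, float))
    fp = np.searchsorted(p_null, grid, side="left")  # strict p < cutoff
    tp = np.searchsorted(p_selected, grid, side="left")
    calls = fp + tp
    with np.errstate(invalid="ignore"):
        fdr = np.where(calls > 0, fp / np.maximum(calls, 1), 0.0)
    table = pd.DataFrame(
        {
            "cutoff": grid,
            "false_positives": fp,
            "true_positives": tp,
            "fdr": fdr,
            "pdr": tp / denom,
        }
    ).sort_values("cutoff", ascending=False, ignore_index=True)
    zero = table.loc[table["fdr"] == 0]
    chosen = None
    if not zero.empty:
        best_tp = zero["true_positives"].max()
        # PDR ties break toward the smaller cutoff; table is sorted descending
        chosen = float(zero.loc[zero["true_positives"] == best_tp, "cutoff"].iloc[-1])
    return CalibrationReport(table, chosen, p_null.size, denom)


def run_calibration(
    cfg: SimulationConfig,
    grid=DEFAULT_GRID,
    scan_cfg: AimlessScanConfig | None = None,
) -> CalibrationReport:
    """End-to-end calibration: simulate, scan, tabulate FDR/PDR."""
    counts, truth = simulate_counts(cfg)
    scan = aimless_scan(counts, scan_cfg)
    merged = scan.merge(truth[["snp_id", "selected"]], on="snp_id", validate="1:1")
    tested = merged.loc[merged["filter_reason"] == ""]
    report = calibrate_cutoff(
        tested.loc[~tested["selected"], "p_value"],
        tested.loc[tested["selected"], "p_value"],
        grid,
        n_selected_total=cfg.n_selected_sites,
    )
    report.notes["n_tested"] = len(tested)
    report.notes["n_filtered"] = len(merged) - len(tested)
    return report


def generate_synthetic_dataset(
    cfg: SimulationConfig,
    out_prefix=None,
    pop_labels: tuple[str, str, str] = ROLES,
) -> tuple[GenotypeMatrix, PopulationMap, AlleleCounts, pd.DataFrame]:
    """Individual-level pseudohaploid genotypes under the same truth model.

    ``cfg.sample_sizes`` are interpreted as individuals per population (one
    allele call each).  Per site and individual, a single allele is drawn
    Bernoulli at the population's true frequency (coded 0/2) and masked
    missing at the population's missing rate, so ``compute_counts`` on the
    returned matrix reproduces the returned count table exactly.  When
    ``out_prefix`` is given, writes ``<prefix>.geno/.snp/.ind``,
    ``<prefix>.pops.tsv`` and the per-site truth as ``<prefix>.truth.tsv``.
    """
    truth = draw_truth(cfg)
    n_sites = len(truth)
    true_f = {
        "target": truth["true_f_target"].to_numpy(),
        "source1": truth["true_f_s1"].to_numpy(),
        "source2": truth["true_f_s2"].to_numpy(),
    }
    blocks, ind_rows = [], []
    for role, label, n_pop in zip(ROLES, pop_labels, cfg.sample_sizes):
        rng = stream_rng(cfg.seed, f"geno_{role}")
        alleles = (rng.random((n_sites, n_pop)) < true_f[role][:, None]).astype(np.int8) * 2
        rate = cfg.rate(role)
        if rate > 0:
            miss = stream_rng(cfg.seed, f"genomiss_{role}").random((n_sites, n_pop)) < rate
            alleles[miss] = MISSING
        blocks.append(alleles)
        ind_rows += [(f"{label}_{k + 1:03d}", "U", label) for k in range(n_pop)]
    codes = np.concatenate(blocks, axis=1)
    snp = truth[["snp_id", "chrom", "pos"]].copy()
    snp["gpos"] = 0.0
    snp["ref"] = "A"
    snp["alt"] = "G"
    gm = GenotypeMatrix(
        snp[["snp_id", "chrom", "gpos", "pos", "ref", "alt"]],
        pd.DataFrame(ind_rows, columns=["individual_id", "sex", "population"]),
        codes,
        np.ones(codes.shape[1], dtype=np.int8),
    )
    pm = PopulationMap(
        *pop_labels, assignments={r[0]: r[2] for r in ind_rows}
    )
    counts = compute_counts(gm, pm)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        try:
            write_eigenstrat(gm, out_prefix)
            write_population_map(pm, f"{out_prefix}.pops.tsv")
            truth.to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
        except OSError as exc:
            raise OSError(f"writing synthetic dataset to {out_prefix}: {exc}") from exc
    return gm, pm, counts, truth
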