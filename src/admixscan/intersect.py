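"""Candidate-set intersection across selection scans.

Different scans flag different false positives (sampling noise, drift,
imputation artefacts), so loci supported by several independent statistics
are the robust candidates.  This module loads candidate SNP sets from the
admixture-constraint LRT, the LSBL outlier scan and externally computed
XP-EHH score tables (selscan ``.norm`` or rehh-style layouts), keys them by
(chromosome, position) — scans often disagree on SNP-ID dialects while
positions are stable — and reports all pairwise and full overlaps.
Chromosome labels are normalised ("chr1" == "1") before keying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class CandidateSetError(ValueError):
    pass


def normalize_chrom(chrom) -> str:
    s = str(chrom)
    if s.lower().startswith("chr"):
        logger.info("normalizing chromosome label %r -> %r", s, s[3:])
        s = s[3:]
    return s


@dataclass
class CandidateSet:
    """A named set of candidate sites keyed by (chromosome, position)."""

    scan_name: str
    frame: pd.DataFrame  # columns: chrom, pos (+ optional snp_id, score)
    threshold_rule: str = ""

    def __post_init__(self) -> None:
        df = self.frame.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(int)
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            dupes = df.loc[dup, ["chrom", "pos"]].head(5).itertuples(index=False)
            raise CandidateSetError(
                f"{self.scan_name}: duplicate site keys "
                + ", ".join(f"{c}:{p}" for c, p in dupes)
            )
        self.frame = df.reset_index(drop=True)

    @property
    def keys(self) -> set[tuple[str, int]]:
        return set(zip(self.frame["chrom"], self.frame["pos"]))

    def __len__(self) -> int:
        return len(self.frame)


def from_scan_table(df: pd.DataFrame, scan_name: str, flag_column: str, rule: str = "") -> CandidateSet:
    """Candidate set from a scan result table's boolean flag column."""
    flags = df[flag_column].to_numpy()
    sel = df.loc[[bool(v) and v == v for v in flags]]  # NaN counts as False
    cols = [c for c in ("snp_id", "chrom", "pos") if c in sel.columns]
    return CandidateSet(scan_name, sel[cols].copy(), rule or f"{flag_column} is true")


# Accepted column-name dialects for XP-EHH tables (selscan .norm, rehh).
_POS_COLS = ("pos", "position", "POSITION", "POS")
_CHR_COLS = ("chr", "chrom", "chromosome", "CHR", "CHROM")
_SCORE_COLS = ("normxpehh", "xpehh_norm", "XPEHH", "xpehh", "normihs")
_ID_COLS = ("id", "ID", "locus", "rs")


def load_xpehh(path, abs_threshold: float = 2.0, chrom: str | None = None) -> CandidateSet:
    """Load an XP-EHH score table, keeping sites with |score| > threshold.

    Auto-detects selscan ``.norm`` headers (``id pos ... normxpehh``; these
    files are per-chromosome, so pass ``chrom=``) and rehh-style layouts
    with explicit chromosome columns.  The strict ">" matches the
    conventional "absolute normalised XP-EHH above 2" candidate rule.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}

    def pick(options):
        for o in options:
            if o.lower() in cols:
                return cols[o.lower()]
        return None

    pos_col, score_col = pick(_POS_COLS), pick(_SCORE_COLS)
    if pos_col is None or score_col is None:
        raise CandidateSetError(
            f"{path}: unrecognized XP-EHH layout (columns {list(df.columns)}); "
            f"accepted: selscan .norm ({' '.join(_POS_COLS[:1] + _SCORE_COLS[:1])}) "
            f"or rehh-style with columns from {_CHR_COLS}/{_POS_COLS}/{_SCORE_COLS}"
        )
    chr_col = pick(_CHR_COLS)
    if chr_col is None:
        if chrom is None:
            raise CandidateSetError(
                f"{path}: no chromosome column and no chrom= given "
                "(selscan .norm files are per-chromosome)"
            )
        df["chrom"] = chrom
    else:
        df["chrom"] = df[chr_col]
    out = pd.DataFrame(
        {"chrom": df["chrom"], "pos": df[pos_col], "score": df[score_col]}
    )
    id_col = pick(_ID_COLS)
    if id_col is not None:
        out["snp_id"] = df[id_col]
    kept = out.loc[out["score"].abs() > abs_threshold].copy()
    if kept.empty:
        logger.warning("load_xpehh(%s): no sites pass |score| > %s", path, abs_threshold)
    return CandidateSet(
        "xpehh", kept, threshold_rule=f"absolute XP-EHH value > {abs_threshold}"
    )


@dataclass
class IntersectionReport:
    """Set sizes and all pairwise / full overlaps of the input scans."""

    set_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], set[tuple[str, int]]]
    full: set[tuple[str, int]]
    sets: list[CandidateSet] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Full-overlap site list as a sorted DataFrame."""
        from .genotype_io import chrom_sort_key

        rows = sorted(self.full, key=lambda k: (chrom_sort_key(k[0]), k[1]))
        return pd.DataFrame(rows, columns=["chrom", "pos"])

    def summary(self) -> pd.DataFrame:
        rows = [("size", name, n) for name, n in self.set_sizes.items()]
        rows += [
            ("overlap", f"{a}&{b}", len(s)) for (a, b), s in self.pairwise.items()
        ]
        rows.append(("overlap", "&".join(self.set_sizes), len(self.full)))
        return pd.DataFrame(rows, columns=["kind", "sets", "count"])


def intersect(sets: list[CandidateSet]) -> IntersectionReport:
    """Exact key-based intersection of two or more candidate sets."""
    if len(sets) < 2:
        raise CandidateSetError("need at least two candidate sets")
    names = [s.scan_name for s in sets]
    if len(set(names)) != len(names):
        raise CandidateSetError(f"scan names must be distinct, got {names}")
    keys = {s.scan_name: s.keys for s in sets}
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = keys[a] & keys[b]
    full = set.intersection(*keys.values())
    return IntersectionReport(
        {n: len(keys[n]) for n in names}, pairwise, full, list(sets)
    )


def annotate_bed(report_frame: pd.DataFrame, bed_path) -> pd.DataFrame:
    """Join candidate positions against BED intervals (gene annotation).

    BED is 0-based half-open; candidate positions are 1-based, so position
    p falls in interval [start, end) iff start < p <= end.  Returns the
    input frame with an ``annotation`` column of comma-joined interval
    names ("" where none overlap).
    """
    trees: dict[str, IntervalTree] = {}
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom = normalize_chrom(fields[0])
        start, end = int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    out = report_frame.copy()
    annos = []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        tree = trees.get(normalize_chrom(chrom))
        hits = sorted(iv.data for iv in tree.at(int(pos) - 1)) if tree else []
        annos.append(",".join(hits))
    out["annotation"] = annos
    return out
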