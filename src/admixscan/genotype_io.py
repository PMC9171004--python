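"""Genotype input/output and per-population allele counting.

Reads and writes genotype data in EIGENSTRAT triplet (.geno/.snp/.ind) and
VCF formats, applies a population assignment with target/source1/source2
roles, and reduces genotype matrices to per-population allele-count tables —
the input of the frequency-based selection scans in this package.

Coordinates are 1-based and inclusive throughout, as in .snp files and VCF.
Internally genotype codes always count copies of the ALT (variant) allele of
the site; the ``counted_allele`` switches on the readers/``compute_counts``
convert to and from the other polarity, because the EIGENSTRAT convention is
not universal across producers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in :class:`GenotypeMatrix.codes`.
#: EIGENSTRAT files use the character ``9`` on disk.
MISSING = -1

SNP_COLUMNS = ["snp_id", "chrom", "gpos", "pos", "ref", "alt"]
IND_COLUMNS = ["individual_id", "sex", "population"]


class GenotypeFormatError(ValueError):
    """Malformed genotype file (dimension mismatch, bad character, ...)."""


class ConfigurationError(ValueError):
    """Inconsistent population/role configuration."""


def chrom_sort_key(chrom: str):
    """Natural ordering key for chromosome labels: numeric first, then text."""
    s = str(chrom)
    if s.lower().startswith("chr"):
        s = s[3:]
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Sites x individuals genotype codes with per-individual ploidy.

    ``codes[i, j]`` is the number of ALT-allele copies carried by individual
    ``j`` at site ``i`` (0/1/2), or :data:`MISSING`.  Pseudohaploid
    individuals (one randomly sampled allele per site, the standard
    representation for low-coverage ancient DNA) have ploidy 1 and codes
    restricted to {0, 2, MISSING}: the single observed allele counts as one
    allele observation but is coded on the diploid 0/2 scale on disk.
    """

    snp: pd.DataFrame
    ind: pd.DataFrame
    codes: np.ndarray
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        n_sites, n_ind = self.codes.shape
        if len(self.snp) != n_sites or len(self.ind) != n_ind:
            raise GenotypeFormatError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.snp)} sites x {len(self.ind)} individuals"
            )
        if self.ploidy.shape != (n_ind,):
            raise GenotypeFormatError("ploidy must have one entry per individual")
        if self.snp["snp_id"].duplicated().any():
            dup = self.snp.loc[self.snp["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise GenotypeFormatError(f"duplicate snp_id {dup!r}")
        if (self.snp["pos"] < 1).any():
            raise GenotypeFormatError("positions must be >= 1 (1-based)")
        if (self.snp["ref"] == self.snp["alt"]).any():
            bad = self.snp.loc[self.snp["ref"] == self.snp["alt"], "snp_id"].iloc[0]
            raise GenotypeFormatError(f"ref == alt at snp {bad!r}")
        het_in_haploid = (self.codes == 1) & (self.ploidy[None, :] == 1)
        if het_in_haploid.any():
            j = int(np.argwhere(het_in_haploid)[0, 1])
            raise GenotypeFormatError(
                f"heterozygous code for pseudohaploid individual "
                f"{self.ind['individual_id'].iloc[j]!r}"
            )

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]


def infer_ploidy(codes: np.ndarray) -> np.ndarray:
    """Per-individual ploidy: 1 when all non-missing codes are in {0, 2}.

    An individual with no non-missing calls is treated as pseudohaploid.
    The inference is overridable by every reader's ``ploidy`` argument — a
    diploid individual that happens to carry no heterozygous call among the
    retained sites is indistinguishable from a pseudohaploid one.
    """
    has_het = (codes == 1).any(axis=0)
    return np.where(has_het, 2, 1).astype(np.int8)


def _resolve_ploidy(codes: np.ndarray, ploidy) -> np.ndarray:
    n_ind = codes.shape[1]
    if isinstance(ploidy, str) and ploidy == "infer":
        return infer_ploidy(codes)
    if np.isscalar(ploidy):
        return np.full(n_ind, int(ploidy), dtype=np.int8)
    arr = np.asarray(ploidy, dtype=np.int8)
    if arr.shape != (n_ind,):
        raise ConfigurationError("ploidy array length must equal individual count")
    return arr


# ---------------------------------------------------------------------------
# EIGENSTRAT triplet
# ---------------------------------------------------------------------------

def read_eigenstrat(prefix, ploidy="infer", counted_allele: str = "ALT") -> GenotypeMatrix:
    """Read an EIGENSTRAT triplet ``prefix.geno/.snp/.ind``.

    Parameters
    ----------
    prefix
        Path prefix of the three files.
    ploidy
        ``"infer"`` (default), a scalar 1/2, or a per-individual array.
    counted_allele
        Which allele the on-disk codes count, ``"ALT"`` (default) or
        ``"REF"``.  Codes are converted to ALT copies internally.
    """
    prefix = Path(prefix)
    snp = pd.read_csv(
        f"{prefix}.snp", sep=r"\s+", names=SNP_COLUMNS, dtype={"chrom": str}
    )
    ind = pd.read_csv(f"{prefix}.ind", sep=r"\s+", names=IND_COLUMNS)
    geno_lines = Path(f"{prefix}.geno").read_text().splitlines()
    if len(geno_lines) != len(snp):
        raise GenotypeFormatError(
            f"{prefix}.geno has {len(geno_lines)} rows but {prefix}.snp "
            f"lists {len(snp)} sites"
        )
    n_ind = len(ind)
    codes = np.empty((len(snp), n_ind), dtype=np.int8)
    for i, line in enumerate(geno_lines):
        if len(line) != n_ind:
            raise GenotypeFormatError(
                f"{prefix}.geno line {i + 1}: width {len(line)} != "
                f"{n_ind} individuals in {prefix}.ind"
            )
        row = np.frombuffer(line.encode("ascii", "replace"), dtype=np.uint8)
        bad = (row < ord("0")) | (row > ord("9"))
        if bad.any():
            raise GenotypeFormatError(
                f"{prefix}.geno line {i + 1} (site index {i}): "
                f"non-digit genotype character {line[int(np.argmax(bad))]!r}"
            )
        codes[i] = row - ord("0")
    if not np.isin(codes, (0, 1, 2, 9)).all():
        i, j = map(int, np.argwhere(~np.isin(codes, (0, 1, 2, 9)))[0])
        raise GenotypeFormatError(
            f"{prefix}.geno line {i + 1} (site index {i}): genotype code "
            f"{codes[i, j]} not in 0/1/2/9"
        )
    codes[codes == 9] = MISSING
    if counted_allele == "REF":
        obs = codes != MISSING
        codes[obs] = 2 - codes[obs]
    elif counted_allele != "ALT":
        raise ConfigurationError("counted_allele must be 'ALT' or 'REF'")
    return GenotypeMatrix(snp, ind, codes, _resolve_ploidy(codes, ploidy))


def _format_gpos(g: float) -> str:
    return f"{g:g}"


def write_eigenstrat(gm: GenotypeMatrix, prefix, counted_allele: str = "ALT") -> None:
    """Write a canonical tab-separated EIGENSTRAT triplet.

    ``write_eigenstrat`` after ``read_eigenstrat`` reproduces canonical
    files byte-identically.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    codes = gm.codes.copy()
    if counted_allele == "REF":
        obs = codes != MISSING
        codes[obs] = 2 - codes[obs]
    codes[codes == MISSING] = 9
    with open(f"{prefix}.geno", "w") as fh:
        for row in codes:
            fh.write("".join(map(str, row)) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for r in gm.snp.itertuples(index=False):
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{_format_gpos(r.gpos)}\t{r.pos}"
                f"\t{r.ref}\t{r.alt}\n"
            )
    with open(f"{prefix}.ind", "w") as fh:
        for r in gm.ind.itertuples(index=False):
            fh.write(f"{r.individual_id}\t{r.sex}\t{r.population}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, ploidy="infer", multiallelic: str = "skip") -> GenotypeMatrix:
    """Read GT calls from a (plain or bgzipped) VCF into a GenotypeMatrix.

    Haploid calls ("0"/"1") are coded 0/2 with ploidy 1, matching the
    pseudohaploid EIGENSTRAT convention; "./." and "." become MISSING.
    Multi-allelic records are skipped with a logged count by default
    (``multiallelic="error"`` raises instead).
    """
    if multiallelic not in ("skip", "error"):
        raise ConfigurationError("multiallelic must be 'skip' or 'error'")
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise GenotypeFormatError(f"{path}: VCF has no sample columns")
    snp_rows, code_rows = [], []
    n_multi = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            if multiallelic == "error":
                raise GenotypeFormatError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}"
                )
            n_multi += 1
            continue
        row = np.full(len(samples), MISSING, dtype=np.int8)
        haploid = np.zeros(len(samples), dtype=bool)
        for j, name in enumerate(samples):
            sample = rec.samples[name]
            if "GT" not in sample:
                raise GenotypeFormatError(
                    f"{path}: no GT field at {rec.chrom}:{rec.pos}"
                )
            gt = sample["GT"]
            alleles = [a for a in gt if a is not None]
            if not alleles:
                continue
            if len(gt) == 1:
                haploid[j] = True
                row[j] = 2 * alleles[0]
            else:
                row[j] = sum(alleles)
        snp_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
        snp_rows.append((snp_id, str(rec.chrom), 0.0, rec.pos, rec.ref, alts[0]))
        code_rows.append((row, haploid))
    if n_multi:
        logger.info("read_vcf(%s): skipped %d multi-allelic records", path, n_multi)
    if not code_rows:
        raise GenotypeFormatError(f"{path}: no biallelic records with GT found")
    codes = np.stack([r for r, _ in code_rows])
    haploid_any = np.stack([h for _, h in code_rows]).any(axis=0)
    snp = pd.DataFrame(snp_rows, columns=SNP_COLUMNS)
    ind = pd.DataFrame(
        {"individual_id": samples, "sex": "U", "population": "unknown"}
    )
    if isinstance(ploidy, str) and ploidy == "infer":
        p = infer_ploidy(codes)
        p[haploid_any] = 1
    else:
        p = _resolve_ploidy(codes, ploidy)
    return GenotypeMatrix(snp, ind, codes, p)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal GT-only VCF (plain text).

    Pseudohaploid individuals are written as haploid GT ("0"/"1"/".").
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    hap = {0: "0", 2: "1", MISSING: "."}
    dip = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.snp["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.ind["individual_id"])
            + "\n"
        )
        for i, r in enumerate(gm.snp.itertuples(index=False)):
            gts = [
                hap[c] if p == 1 else dip[c]
                for c, p in zip(gm.codes[i], gm.ploidy)
            ]
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.snp_id}\t{r.ref}\t{r.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Population assignment
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """Role labels (target/source1/source2) plus individual assignments.

    ``assignments`` maps an individual id to its population label.  The
    three role populations must be pairwise disjoint, which is automatic
    because each individual has exactly one label.
    """

    target: str
    source1: str
    source2: str
    assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = (self.target, self.source1, self.source2)
        if len(set(roles)) != 3:
            raise ConfigurationError(
                f"target/source1/source2 labels must be distinct, got {roles}"
            )

    @property
    def roles(self) -> dict[str, str]:
        return {"target": self.target, "source1": self.source1, "source2": self.source2}

    def members(self, population: str) -> list[str]:
        return [i for i, p in self.assignments.items() if p == population]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        known = set(gm.ind["individual_id"])
        missing = sorted(set(self.assignments) - known)
        if missing:
            raise ConfigurationError(
                f"individuals not present in the genotype matrix: {missing[:5]}"
            )
        for role, label in self.roles.items():
            if not self.members(label):
                raise ConfigurationError(f"{role} population {label!r} is empty")


def read_population_map(path) -> PopulationMap:
    """Parse a pops.tsv: ``#role=label`` header lines, then individual<TAB>pop.

    Example::

        #target=LBK
        #source1=Anatolia_N
        #source2=WHG
        DER001	LBK
        Bar8	Anatolia_N
    """
    roles: dict[str, str] = {}
    assignments: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                role, label = body.split("=", 1)
                roles[role.strip()] = label.strip()
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise GenotypeFormatError(f"{path} line {lineno}: expected 'individual<TAB>population'")
        assignments[parts[0]] = parts[1]
    for role in ("target", "source1", "source2"):
        if role not in roles:
            raise ConfigurationError(
                f"{path}: missing '#{role}=LABEL' header line"
            )
    return PopulationMap(roles["target"], roles["source1"], roles["source2"], assignments)


def write_population_map(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for role, label in pm.roles.items():
            fh.write(f"#{role}={label}\n")
        for ind, pop in pm.assignments.items():
            fh.write(f"{ind}\t{pop}\n")


# ---------------------------------------------------------------------------
# Allele-count tables
# ---------------------------------------------------------------------------

@dataclass
class AlleleCounts:
    """Per-site, per-population counted-allele counts.

    For population ``p``: ``x[p]`` counted-allele copies summed over
    non-missing individuals, ``n_alleles[p]`` total observed allele calls
    (1 per pseudohaploid, 2 per diploid individual), ``n_ind[p]`` individuals
    with a call.  ``freq(p) = x/n_alleles``, NaN where nothing was observed.
    """

    snp: pd.DataFrame
    x: dict[str, np.ndarray]
    n_alleles: dict[str, np.ndarray]
    n_ind: dict[str, np.ndarray]
    roles: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for pop in self.x:
            x, n, ni = self.x[pop], self.n_alleles[pop], self.n_ind[pop]
            if not ((x >= 0) & (x <= n)).all():
                raise ValueError(f"population {pop!r}: need 0 <= x <= n_alleles")
            if not ((ni <= n) & (n <= 2 * ni)).all():
                raise ValueError(
                    f"population {pop!r}: need n_ind <= n_alleles <= 2*n_ind"
                )

    @property
    def populations(self) -> list[str]:
        return list(self.x)

    @property
    def n_sites(self) -> int:
        return len(self.snp)

    def freq(self, pop: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_alleles[pop] > 0,
                self.x[pop] / np.maximum(self.n_alleles[pop], 1),
                np.nan,
            )

    def role_pop(self, role: str) -> str:
        if not self.roles or role not in self.roles:
            raise ConfigurationError(f"no population assigned to role {role!r}")
        return self.roles[role]

    def pool(self, pops: list[str], label: str) -> "AlleleCounts":
        """Return a copy with ``pops`` summed into a new population ``label``.

        Summing x and n over disjoint populations is exact count pooling
        (count conservation), used e.g. to form the merged early-farmer
        group from target + source1.
        """
        x = dict(self.x)
        n = dict(self.n_alleles)
        ni = dict(self.n_ind)
        x[label] = np.sum([self.x[p] for p in pops], axis=0)
        n[label] = np.sum([self.n_alleles[p] for p in pops], axis=0)
        ni[label] = np.sum([self.n_ind[p] for p in pops], axis=0)
        return AlleleCounts(self.snp, x, n, ni, self.roles)

    # -- TSV round trip used by the CLI ------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = self.snp[["snp_id", "chrom", "pos"]].copy()
        for pop in self.populations:
            df[f"x:{pop}"] = self.x[pop]
            df[f"n:{pop}"] = self.n_alleles[pop]
            df[f"nind:{pop}"] = self.n_ind[pop]
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.roles:
                roles = " ".join(f"{r}={p}" for r, p in self.roles.items())
                fh.write(f"#roles {roles}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlleleCounts":
        roles = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#roles"):
                roles = dict(tok.split("=", 1) for tok in first.split()[1:])
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
        pops = [c.split(":", 1)[1] for c in df.columns if c.startswith("x:")]
        snp = df[["snp_id", "chrom", "pos"]].copy()
        snp["gpos"] = 0.0
        snp["ref"] = "N"  # allele identity is not carried through count TSVs
        snp["alt"] = "A"
        return cls(
            snp[SNP_COLUMNS],
            {p: df[f"x:{p}"].to_numpy() for p in pops},
            {p: df[f"n:{p}"].to_numpy() for p in pops},
            {p: df[f"nind:{p}"].to_numpy() for p in pops},
            roles,
        )


def compute_counts(gm: GenotypeMatrix, pm, counted_allele: str = "ALT") -> AlleleCounts:
    """Reduce genotypes to per-population counted-allele counts.

    ``pm`` is a :class:`PopulationMap` (role populations are validated
    non-empty) or a plain individual -> population mapping (no roles).
    x = sum of counted-allele copies over non-missing individuals;
    n_alleles = sum of ploidies of non-missing individuals.  Missing calls
    contribute to neither.
    """
    if counted_allele not in ("ALT", "REF"):
        raise ConfigurationError("counted_allele must be 'ALT' or 'REF'")
    if isinstance(pm, PopulationMap):
        pm.validate_against(gm)
        assignments, roles = pm.assignments, pm.roles
    else:
        assignments, roles = dict(pm), None
        unknown = sorted(set(assignments) - set(gm.ind["individual_id"]))
        if unknown:
            raise ConfigurationError(
                f"individuals not present in the genotype matrix: {unknown[:5]}"
            )
    ind_ids = gm.ind["individual_id"].to_numpy()
    pops = sorted(set(assignments.values()))
    x, n_alleles, n_ind = {}, {}, {}
    for pop in pops:
        members = {i for i, p in assignments.items() if p == pop}
        cols = np.flatnonzero(np.isin(ind_ids, list(members)))
        sub = gm.codes[:, cols]
        pl = gm.ploidy[cols].astype(np.int64)
        obs = sub != MISSING
        n = obs @ pl
        # a pseudohaploid call is coded 0/2 on disk but contributes one allele
        copies = np.where(obs, sub, 0).astype(np.int64)
        alt = (copies * (pl[None, :] == 2)).sum(1) + (copies // 2 * (pl[None, :] == 1)).sum(1)
        x[pop] = alt if counted_allele == "ALT" else n - alt
        n_alleles[pop] = n
        n_ind[pop] = obs.sum(axis=1)
    return AlleleCounts(gm.snp.copy(), x, n_alleles, n_ind, roles)
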