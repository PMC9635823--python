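"""Genotype I/O and panel construction for pseudo-haploid data.

The central container is :class:`GenotypeMatrix`: individuals x SNPs calls
counted as copies of ``allele1`` of the corresponding SNP record, with -1 for
missing.  Pseudo-haploid individuals (one sampled allele per site, encoded as
a homozygous 0/2 call) never carry a heterozygous 1.  Male X genotypes are
hemizygous and likewise encoded 0/2 with single-allele ploidy.

Only the text EIGENSTRAT dialect is supported (one .geno row per SNP, one
digit per individual, 9 = missing); it is transparent and diffable, which is
what synthetic fixtures need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1

SNP_COLUMNS = ["snp_id", "chrom", "gen_pos", "pos", "allele1", "allele2"]

#: chromosome labels treated as the X chromosome
X_LABELS = frozenset({"X", "23", "chrX"})


def _is_x(chrom: pd.Series | np.ndarray) -> np.ndarray:
    return np.isin(np.asarray(chrom, dtype=object), list(X_LABELS))


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype calls.

    Parameters
    ----------
    snps
        DataFrame with columns ``snp_id, chrom, gen_pos, pos, allele1,
        allele2``, sorted by (chrom, pos); positions are 1-based.
    individuals
        Sample identifiers, unique, one per row of ``calls``.
    calls
        ``(n_individuals, n_snps)`` int8 array of allele1 copy counts
        (0/1/2) with ``-1`` for missing.
    pseudo_haploid
        Boolean per individual; pseudo-haploid rows may only hold {-1, 0, 2}.
    sex
        Optional per-individual labels ``'F'/'M'/'U'``; used to treat male X
        genotypes as hemizygous (ploidy 1).
    par_mask
        Optional boolean per SNP marking pseudoautosomal X sites; these are
        excluded from every X-chromosome analysis.
    """

    snps: pd.DataFrame
    individuals: list[str]
    calls: np.ndarray
    pseudo_haploid: np.ndarray
    sex: np.ndarray | None = None
    par_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.pseudo_haploid = np.asarray(self.pseudo_haploid, dtype=bool)
        if list(self.snps.columns[:6]) != SNP_COLUMNS:
            self.snps = self.snps.rename(
                columns=dict(zip(self.snps.columns[:6], SNP_COLUMNS))
            )
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        if self.calls.shape != (self.n_individuals, self.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{self.n_individuals} individuals x {self.n_snps} SNPs"
            )
        if len(set(self.individuals)) != self.n_individuals:
            raise ValueError("duplicate individual ids")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        het = (self.calls == 1) & self.pseudo_haploid[:, None]
        if het.any():
            i, j = np.argwhere(het)[0]
            raise ValueError(
                f"pseudo-haploid individual {self.individuals[i]} carries a "
                f"heterozygous call at SNP index {j}"
            )
        a1 = self.snps["allele1"].to_numpy()
        a2 = self.snps["allele2"].to_numpy()
        if (a1 == a2).any():
            raise ValueError("SNP with allele1 == allele2")
        if (self.snps["pos"].to_numpy() < 1).any():
            raise ValueError("physical positions must be >= 1")

    def index_of(self, individual: str) -> int:
        return self.individuals.index(individual)

    # -- ploidy ------------------------------------------------------------
    def ploidy(self) -> np.ndarray:
        """Per-cell allele count: 1 for pseudo-haploid rows and male X, 2 otherwise."""
        ploidy = np.full(self.calls.shape, 2, dtype=np.int8)
        ploidy[self.pseudo_haploid, :] = 1
        if self.sex is not None:
            male = np.asarray(self.sex) == "M"
            xcol = _is_x(self.snps["chrom"])
            ploidy[np.ix_(male, xcol)] = 1
        return ploidy

    def dosage(self) -> np.ndarray:
        """Copies of allele1 on the ploidy scale (0/1 for haploid cells), NaN missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d * self.ploidy() / 2.0

    # -- subsetting --------------------------------------------------------
    def take_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            full = np.zeros(self.n_snps, dtype=bool)
            full[mask] = True
            mask = full
        return replace(
            self,
            snps=self.snps.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask],
            par_mask=None if self.par_mask is None else self.par_mask[mask],
        )

    def take_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.index_of(i) for i in ids]
        return replace(
            self,
            individuals=list(ids),
            calls=self.calls[idx],
            pseudo_haploid=self.pseudo_haploid[idx],
            sex=None if self.sex is None else np.asarray(self.sex)[idx],
        )

    def autosomal(self) -> "GenotypeMatrix":
        return self.take_snps(~_is_x(self.snps["chrom"]))

    def x_non_par(self) -> "GenotypeMatrix":
        mask = _is_x(self.snps["chrom"])
        if self.par_mask is not None:
            mask = mask & ~np.asarray(self.par_mask, dtype=bool)
        return self.take_snps(mask)


@dataclass
class SampleMeta:
    """Per-individual metadata: site, building, sex, coordinates, dating."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ["id", "population", "site", "building", "sex", "lat", "lon"]

    def __post_init__(self) -> None:
        if len(self.table):
            if self.table["id"].duplicated().any():
                raise ValueError("duplicate ids in sample metadata")
            lat = self.table["lat"].astype(float)
            lon = self.table["lon"].astype(float)
            if (lat.abs() > 90).any() or (lon.abs() > 180).any():
                raise ValueError("coordinates out of range")

    @classmethod
    def read_tsv(cls, path) -> "SampleMeta":
        return cls(pd.read_csv(path, sep="\t", dtype={"id": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# EIGENSTRAT text dialect
# ---------------------------------------------------------------------------

def read_eigenstrat(prefix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a text EIGENSTRAT trio ``<prefix>.geno/.snp/.ind``.

    Returns the genotype matrix plus a stub metadata frame (id, sex,
    population) from the .ind file.  Row/column counts are cross-validated;
    a dimension mismatch or stray character raises with the offending line.
    """
    prefix = str(prefix)
    snps = pd.read_csv(
        prefix + ".snp",
        sep=r"\s+",
        names=SNP_COLUMNS,
        dtype={"snp_id": str, "chrom": str, "allele1": str, "allele2": str},
    )
    ind = pd.read_csv(
        prefix + ".ind", sep=r"\s+", names=["id", "sex", "population"], dtype=str
    )
    n_ind = len(ind)
    calls = np.empty((len(snps), n_ind), dtype=np.int8)
    decode = {ord("0"): 0, ord("1"): 1, ord("2"): 2, ord("9"): MISSING}
    with open(prefix + ".geno") as fh:
        row = -1
        for row, line in enumerate(fh):
            line = line.rstrip("\n")
            if row >= len(snps):
                raise ValueError(
                    f"{prefix}.geno has more rows than {prefix}.snp "
                    f"({len(snps)} SNPs): extra row {row + 1}"
                )
            if len(line) != n_ind:
                raise ValueError(
                    f"{prefix}.geno line {row + 1}: width {len(line)} != "
                    f"{n_ind} individuals in {prefix}.ind"
                )
            for col, ch in enumerate(line):
                try:
                    calls[row, col] = decode[ord(ch)]
                except KeyError:
                    raise ValueError(
                        f"{prefix}.geno line {row + 1}, column {col + 1}: "
                        f"invalid character {ch!r}"
                    ) from None
        if row + 1 != len(snps):
            raise ValueError(
                f"{prefix}.geno has {row + 1} rows but {prefix}.snp lists "
                f"{len(snps)} SNPs"
            )
    # hemizygous/pseudo-haploid state is not encoded in the format; infer
    # pseudo-haploid rows as those without any het call (refined by callers)
    calls = np.ascontiguousarray(calls.T)
    ph = ~(calls == 1).any(axis=1)
    matrix = GenotypeMatrix(
        snps=snps,
        individuals=list(ind["id"]),
        calls=calls,
        pseudo_haploid=ph,
        sex=ind["sex"].to_numpy(),
    )
    return matrix, ind


def write_eigenstrat(matrix: GenotypeMatrix, prefix, meta: pd.DataFrame | None = None) -> None:
    """Write ``<prefix>.geno/.snp/.ind`` (byte-deterministic, round-trips)."""
    prefix = str(prefix)
    matrix.validate()
    with open(prefix + ".snp", "w") as fh:
        for rec in matrix.snps.itertuples(index=False):
            fh.write(
                f"{rec.snp_id}\t{rec.chrom}\t{rec.gen_pos:g}\t{int(rec.pos)}"
                f"\t{rec.allele1}\t{rec.allele2}\n"
            )
    if meta is None:
        sex = matrix.sex if matrix.sex is not None else ["U"] * matrix.n_individuals
        meta = pd.DataFrame(
            {"id": matrix.individuals, "sex": sex, "population": "pop"}
        )
    with open(prefix + ".ind", "w") as fh:
        for rec in meta.itertuples(index=False):
            fh.write(f"{rec.id}\t{rec.sex}\t{rec.population}\n")
    encode = np.array(["0", "1", "2"] + [""] * 6 + ["9"])
    with open(prefix + ".geno", "w") as fh:
        for j in range(matrix.n_snps):
            col = matrix.calls[:, j]
            fh.write("".join(encode[col]) + "\n")


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def random_haploid_call(
    pileups: dict[str, list[list[str]]],
    snps: pd.DataFrame,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Pseudo-haploid calls by drawing one observed base per site.

    ``pileups`` maps individual id to a per-SNP list of observed bases
    (simplified pileup, qualities already filtered upstream).  The drawn base
    is encoded 2 if it equals ``allele1``, 0 if ``allele2``, missing
    otherwise (empty lists and triallelic draws both become missing; the
    non-matching count is logged).
    """
    rng = np.random.default_rng(seed)
    a1 = snps["allele1"].to_numpy()
    a2 = snps["allele2"].to_numpy()
    out = np.full((len(pileups), len(snps)), MISSING, dtype=np.int8)
    n_nonmatching = 0
    for i, (ind, bases) in enumerate(pileups.items()):
        if len(bases) != len(snps):
            raise ValueError(
                f"pileup for {ind} has {len(bases)} sites, panel has {len(snps)}"
            )
        for j, site in enumerate(bases):
            if not site:
                continue
            base = site[int(rng.integers(len(site)))]
            if base == a1[j]:
                out[i, j] = 2
            elif base == a2[j]:
                out[i, j] = 0
            else:
                n_nonmatching += 1
    if n_nonmatching:
        logger.info("random_haploid_call: %d draws matched neither allele", n_nonmatching)
    return out


def filter_maf_biallelic(
    matrix: GenotypeMatrix,
    panel_ids: list[str],
    maf_threshold: float = 0.10,
) -> tuple[GenotypeMatrix, dict]:
    """Keep SNPs whose minor-allele frequency in the panel strictly exceeds the threshold.

    Monomorphic SNPs (MAF 0) are removed regardless of threshold; SNPs with
    zero called panel alleles are dropped and counted in the report.
    """
    panel = matrix.take_individuals(panel_ids)
    dos = panel.dosage()
    ploidy = panel.ploidy().astype(float)
    ploidy[np.isnan(dos)] = 0.0
    n_alleles = ploidy.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dos, axis=0) / n_alleles
    maf = np.minimum(p, 1.0 - p)
    uncalled = n_alleles == 0
    keep = ~uncalled & (maf > maf_threshold)
    report = {
        "n_input": matrix.n_snps,
        "n_kept": int(keep.sum()),
        "n_removed_maf": int((~keep & ~uncalled).sum()),
        "n_removed_uncalled": int(uncalled.sum()),
    }
    if report["n_removed_uncalled"]:
        logger.info(
            "filter_maf_biallelic: %d SNPs had no called panel alleles",
            report["n_removed_uncalled"],
        )
    return matrix.take_snps(keep), report


# ---------------------------------------------------------------------------
# genetic sexing from read counts
# ---------------------------------------------------------------------------

@dataclass
class SexCall:
    n_y: int
    n_xy: int
    r_y: float
    ci: tuple[float, float]
    verdict: str


def determine_sex_ry(
    n_y: int,
    n_xy: int,
    xx_threshold: float = 0.016,
    xy_threshold: float = 0.075,
) -> SexCall:
    """Genetic sex from the Y-read fraction R_Y = n_Y / n_{X+Y}.

    The verdict compares the normal-approximation 95% CI of R_Y against the
    XX and XY thresholds: a CI wholly below the XX threshold is female (XX),
    wholly above the XY threshold male (XY); a CI excluding only one region
    yields the intermediate "consistent with ... but not ..." verdicts, and a
    CI straddling both is undetermined.
    """
    if n_y < 0 or n_xy < 0 or n_y > n_xy:
        raise ValueError("require 0 <= n_y <= n_xy")
    if n_xy == 0:
        return SexCall(0, 0, float("nan"), (float("nan"), float("nan")), "undetermined")
    r = n_y / n_xy
    se = np.sqrt(r * (1.0 - r) / n_xy)
    z = stats.norm.ppf(0.975)
    lo, hi = max(0.0, r - z * se), min(1.0, r + z * se)
    if hi < xx_threshold:
        verdict = "XX"
    elif lo > xy_threshold:
        verdict = "XY"
    elif lo > xx_threshold and hi >= xy_threshold:
        verdict = "consistent-with-XY-not-XX"
    elif hi < xy_threshold and lo <= xx_threshold:
        verdict = "consistent-with-XX-not-XY"
    else:
        verdict = "undetermined"
    return SexCall(n_y, n_xy, r, (lo, hi), verdict)
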