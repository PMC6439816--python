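"""Readers, writers and validation for every external format in the pipeline.

Formats
-------
* Phenotypes: long TSV, two rows per twin pair (``pair_id``, ``twin_order``,
  ``zygosity``, ``sex``, ``age_cohort``, then named continuous measures and
  0/1 diagnoses).  Missing values are empty fields or ``NA``.
* Genotypes: PLINK-1 binary bed/bim/fam triplets (SNP-major) or VCF with GT.
  Dosages count allele1 (the bim A1 / the VCF ALT) and lie in {0, 1, 2},
  with NaN for missing calls.
* GWAS summary statistics: TSV with a configurable column map.
* Results: one TSV per logical table, deterministic order, fixed precision.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ZYGOSITY_GROUPS

logger = logging.getLogger("twinprs")

PHENO_KEY_COLUMNS = ["pair_id", "twin_order", "zygosity", "sex", "age_cohort"]
MISSING_CODES = ("", "NA")

SUMSTATS_DEFAULT_COLUMNS = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
}


class FormatError(ValueError):
    """The file cannot be parsed as the expected format."""


class ValidationError(ValueError):
    """The file parses but violates a data-model invariant."""


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Validated long-format twin phenotype table.

    ``measures`` and ``diagnoses`` name the continuous and binary columns of
    ``df``.  Each pair_id appears exactly twice (twin_order 1 and 2); the
    zygosity label is constant within a pair and consistent with the twins'
    sexes (same-sex groups concordant, DZOS discordant).
    """

    df: pd.DataFrame
    measures: list[str] = field(default_factory=list)
    diagnoses: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "PhenotypeTable":
        df = self.df
        missing_cols = [c for c in PHENO_KEY_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"missing required columns: {missing_cols}")
        dup = df.duplicated(subset=["pair_id", "twin_order"])
        if dup.any():
            bad = df.loc[dup, "pair_id"].iloc[0]
            raise FormatError(f"duplicate (pair_id, twin_order): pair {bad!r}")
        counts = df.groupby("pair_id")["twin_order"].agg(["size", "sum"])
        bad_pairs = counts[(counts["size"] != 2) | (counts["sum"] != 3)]
        if len(bad_pairs):
            raise ValidationError(
                f"pair {bad_pairs.index[0]!r} does not have exactly "
                "twin_order 1 and 2"
            )
        bad_zyg = set(df["zygosity"]) - set(ZYGOSITY_GROUPS)
        if bad_zyg:
            raise ValidationError(f"unknown zygosity labels: {sorted(bad_zyg)}")
        bad_sex = set(df["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
        w1 = df[df["twin_order"] == 1].set_index("pair_id")
        w2 = df[df["twin_order"] == 2].set_index("pair_id").reindex(w1.index)
        zyg_mismatch = w1["zygosity"] != w2["zygosity"]
        if zyg_mismatch.any():
            pid = w1.index[zyg_mismatch][0]
            raise ValidationError(f"pair {pid!r}: inconsistent zygosity")
        zyg = w1["zygosity"]
        s1, s2 = w1["sex"], w2["sex"]
        bad = pd.Series(False, index=w1.index)
        dzos = zyg == "DZOS"
        bad |= dzos & (s1 == s2)
        male_groups = zyg.isin(("MZM", "DZM"))
        bad |= male_groups & ~((s1 == "M") & (s2 == "M"))
        female_groups = zyg.isin(("MZF", "DZF"))
        bad |= female_groups & ~((s1 == "F") & (s2 == "F"))
        if bad.any():
            pid = bad.index[bad][0]
            raise ValidationError(
                f"pair {pid!r}: sexes inconsistent with zygosity group "
                f"{zyg.loc[pid]}"
            )
        for col in self.diagnoses:
            vals = df[col].dropna().unique()
            if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                raise ValidationError(f"diagnosis column {col!r} is not 0/1")
        return self

    @property
    def n_pairs(self) -> int:
        return self.df["pair_id"].nunique()

    def to_pairs(self, trait: str, diagnosis: str) -> pd.DataFrame:
        """Wide one-row-per-pair view for one (trait, diagnosis) pairing.

        Columns: pair_id, zygosity, zyg_class (MZ/DZ), sex1, sex2, t1, t2,
        y1, y2 (NaN where missing).
        """
        df = self.df
        w1 = df[df["twin_order"] == 1].set_index("pair_id")
        w2 = df[df["twin_order"] == 2].set_index("pair_id")
        out = pd.DataFrame(
            {
                "zygosity": w1["zygosity"],
                "sex1": w1["sex"],
                "sex2": w2["sex"],
                "t1": pd.to_numeric(w1[trait]),
                "t2": pd.to_numeric(w2[trait]),
                "y1": pd.to_numeric(w1[diagnosis]),
                "y2": pd.to_numeric(w2[diagnosis]),
            }
        )
        out["zyg_class"] = np.where(
            out["zygosity"].str.startswith("MZ"), "MZ", "DZ"
        )
        return out.reset_index()


def read_phenotypes(
    path: str | os.PathLike,
    measures: list[str] | None = None,
    diagnoses: list[str] | None = None,
) -> PhenotypeTable:
    """Read and validate a long-format phenotype TSV.

    If ``measures``/``diagnoses`` are not given, non-key columns whose
    non-missing values are all in {0, 1} are classified as diagnoses and the
    rest as continuous measures.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", na_values=list(MISSING_CODES),
                     keep_default_na=False, dtype={"pair_id": str})
    extra = [c for c in df.columns if c not in PHENO_KEY_COLUMNS]
    for col in extra:
        df[col] = pd.to_numeric(df[col])
    if measures is None and diagnoses is None:
        diagnoses = [
            c for c in extra
            if set(df[c].dropna().unique()) <= {0, 1, 0.0, 1.0}
        ]
        measures = [c for c in extra if c not in diagnoses]
    return PhenotypeTable(df=df, measures=list(measures or []),
                          diagnoses=list(diagnoses or []))


def write_phenotypes(table: PhenotypeTable, path: str | os.PathLike) -> None:
    df = table.df.copy()
    for col in table.diagnoses:
        df[col] = df[col].astype("Int64")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeData:
    """Hard-call genotypes: individuals x variants dosage matrix.

    ``dosages[i, j]`` counts copies of ``variants.allele1[j]`` carried by
    individual ``ids[i]`` (0/1/2, NaN for missing).
    """

    ids: list[str]
    variants: pd.DataFrame  # columns: id, chrom, pos, allele1, allele2
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "GenotypeData":
        n, m = self.dosages.shape
        if n != len(self.ids):
            raise ValidationError("dosage rows do not match individual ids")
        if m != len(self.variants):
            raise ValidationError("dosage columns do not match variants")
        if len(set(self.ids)) != n:
            raise ValidationError("individual ids are not unique")
        if self.variants["id"].duplicated().any():
            raise ValidationError("variant ids are not unique")
        for chrom, grp in self.variants.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValidationError("dosages must be 0/1/2 or missing")
        return self

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Allele1 frequency per variant from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> allele1 dosage
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | os.PathLike) -> GenotypeData:
    """Read a PLINK-1 bed/bim/fam triplet (SNP-major bed)."""
    prefix = str(prefix)
    bed_path, bim_path, fam_path = (prefix + s for s in (".bed", ".bim", ".fam"))
    for p in (bed_path, bim_path, fam_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "allele1", "allele2"],
                      dtype={"chrom": str, "id": str, "allele1": str,
                             "allele2": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise FormatError(f"{bed_path}: bad PLINK bed magic number")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * m:
        raise FormatError(f"{bed_path}: size inconsistent with fam/bim")
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_DECODE[codes].T.copy()
    variants = bim[["id", "chrom", "pos", "allele1", "allele2"]].copy()
    return GenotypeData(ids=list(fam["iid"]), variants=variants, dosages=dosages)


def write_plink(geno: GenotypeData, prefix: str | os.PathLike,
                fam_extra: pd.DataFrame | None = None) -> None:
    """Write a GenotypeData as a PLINK-1 bed/bim/fam triplet."""
    prefix = str(prefix)
    n, m = geno.dosages.shape
    if fam_extra is None:
        fam = pd.DataFrame({
            "fid": geno.ids, "iid": geno.ids, "pat": 0, "mat": 0,
            "sex": 0, "pheno": -9,
        })
    else:
        fam = fam_extra
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        "chrom": geno.variants["chrom"], "id": geno.variants["id"], "cm": 0,
        "pos": geno.variants["pos"], "allele1": geno.variants["allele1"],
        "allele2": geno.variants["allele2"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    d = geno.dosages.T  # SNP-major
    codes = np.full(d.shape, 1, dtype=np.uint8)  # 01 = missing
    codes[d == 2.0] = 0b00
    codes[d == 1.0] = 0b10
    codes[d == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(m, -1, 4)
    shifts = np.arange(4) * 2
    packed = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: str | os.PathLike) -> GenotypeData:
    """Read diploid GT hard calls from a VCF (biallelic records only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows = []
    columns = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FormatError(
                f"{variant.ID or variant.POS}: only biallelic records supported"
            )
        gts = variant.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(ids))
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise FormatError(
                    f"{variant.ID or variant.POS}: ploidy != 2 for sample {ids[i]}"
                )
            if any(a < 0 for a in alleles):
                dos[i] = np.nan
            else:
                dos[i] = sum(a == 1 for a in alleles)
        rows.append(dos)
        columns.append({
            "id": variant.ID or f"{variant.CHROM}:{variant.POS}",
            "chrom": str(variant.CHROM),
            "pos": int(variant.POS),
            "allele1": variant.ALT[0],
            "allele2": variant.REF,
        })
    variants = pd.DataFrame(columns, columns=["id", "chrom", "pos",
                                              "allele1", "allele2"])
    dosages = np.array(rows).T if rows else np.empty((len(ids), 0))
    return GenotypeData(ids=ids, variants=variants, dosages=dosages)


def read_genotypes(path: str | os.PathLike, format: str = "plink1") -> GenotypeData:
    """Read genotypes from a PLINK-1 prefix or a VCF file."""
    if format == "plink1":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(
    path: str | os.PathLike,
    columns: dict[str, str] | None = None,
    or_column: bool = False,
) -> pd.DataFrame:
    """Read per-variant discovery GWAS effects into canonical columns.

    Returns a DataFrame with columns id, chrom, pos, effect_allele,
    other_allele, beta, se, p, n.  If ``or_column`` is set, the beta column
    of the file holds odds ratios and is log-transformed.  Rows with p
    outside (0, 1], missing beta, or a duplicate id (first kept) are dropped
    and the counts logged.
    """
    colmap = dict(SUMSTATS_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep="\t")
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"summary statistics missing columns: {missing}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    df = df[list(colmap)]
    df["id"] = df["id"].astype(str)
    if or_column:
        df["beta"] = np.log(df["beta"])
    n0 = len(df)
    bad_p = ~((df["p"] > 0) & (df["p"] <= 1))
    bad_beta = ~np.isfinite(df["beta"])
    df = df[~(bad_p | bad_beta)]
    n_filtered = n0 - len(df)
    dup = df["id"].duplicated()
    n_dup = int(dup.sum())
    df = df[~dup]
    if n_filtered or n_dup:
        logger.info(
            "read_summary_stats: dropped %d rows with invalid p/beta and "
            "%d duplicate ids from %s", n_filtered, n_dup, path,
        )
    bad_alleles = (df["effect_allele"] == df["other_allele"]).sum()
    if bad_alleles:
        raise ValidationError(
            f"{bad_alleles} rows with identical effect and other allele"
        )
    return df.reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path: str | os.PathLike,
                        columns: dict[str, str] | None = None) -> None:
    colmap = dict(SUMSTATS_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    out = df.rename(columns=colmap)
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame],
                  out_dir: str | os.PathLike) -> list[Path]:
    """Write each result table to ``<out_dir>/<name>.tsv`` deterministically.

    Column order is preserved as given; floats use fixed %.6g precision, so
    identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False, na_rep="NA",
                            float_format="%.6g")
        written.append(path)
    return written
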