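"""Core containers and file I/O for case-control genotype cohorts.

The analysis operates on a single harmonized dosage matrix (samples x
variants, effect-allele dosage in [0, 2], NaN for missing) carrying per-variant
metadata (position, alleles, minor allele frequency, imputation quality) and
per-sample metadata (sex, case/control phenotype, cohort label).  All
coordinates are 1-based (VCF convention); the genome build is a metadata
string and is never validated against a reference.  Strand-ambiguous (A/T,
C/G) variants are kept but flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("male", "female", "unknown")
PHENOTYPES = ("case", "control")
COHORTS = ("A", "B", "unassigned")

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

ASSOC_COLUMNS = [
    "CHR", "SNP", "BP", "A1", "QUALITY_R2", "GENOTYPED",
    "MAF", "N", "OR", "L95", "U95", "P",
]


class VCFParseError(ValueError):
    """A VCF record could not be interpreted as a biallelic dosage record."""


@dataclass(frozen=True)
class VariantInfo:
    """Metadata for one variant.

    ``effect_allele`` is the allele the dosage counts (ALT on VCF intake);
    ``quality_r2`` is the imputation quality score (1.0 for genotyped
    variants); ``maf`` is the minor allele frequency folded into [0, 0.5].
    """

    chrom: str
    pos: int
    id: str
    effect_allele: str
    other_allele: str | None = None
    maf: float = float("nan")
    quality_r2: float = 1.0
    genotyped: bool = True
    strand_ambiguous: bool = False
    build: str = "hg38"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if not math.isnan(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")
        if not 0.0 <= self.quality_r2 <= 1.0:
            raise ValueError(
                f"variant {self.id}: quality_r2 {self.quality_r2} outside [0, 1]"
            )


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: str = "unknown"
    phenotype: str = "control"
    cohort: str = "unassigned"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sample {self.sample_id}: bad sex {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"sample {self.sample_id}: bad phenotype {self.phenotype!r}"
            )
        if self.cohort not in COHORTS:
            raise ValueError(f"sample {self.sample_id}: bad cohort {self.cohort!r}")

    @property
    def is_case(self) -> bool:
        return self.phenotype == "case"


class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix with aligned metadata.

    Dosages are floats in [0, 2]; missing values are NaN.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        samples: Sequence[SampleInfo],
        variants: Sequence[VariantInfo],
    ):
        dosages = np.asarray(dosages)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if dosages.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        finite = dosages[np.isfinite(dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        self.dosages = dosages
        self.samples = list(samples)
        self.variants = list(variants)
        self._vindex: dict[str, int] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self) -> dict[str, int]:
        if self._vindex is None:
            self._vindex = {v.id: i for i, v in enumerate(self.variants)}
        return self._vindex

    def phenotype_array(self) -> np.ndarray:
        """0/1 array, 1 = case."""
        return np.array([1 if s.is_case else 0 for s in self.samples], dtype=np.int8)

    def subset_samples(self, which) -> "GenotypeMatrix":
        idx = _as_indices(which, self.n_samples)
        return GenotypeMatrix(
            self.dosages[idx, :], [self.samples[i] for i in idx], self.variants
        )

    def subset_variants(self, which) -> "GenotypeMatrix":
        idx = _as_indices(which, self.n_variants)
        return GenotypeMatrix(
            self.dosages[:, idx], self.samples, [self.variants[i] for i in idx]
        )

    def with_samples(self, samples: Sequence[SampleInfo]) -> "GenotypeMatrix":
        """Replace sample metadata (same ids, e.g. after cohort assignment)."""
        if [s.sample_id for s in samples] != self.sample_ids:
            raise ValueError("replacement sample ids do not match matrix order")
        return GenotypeMatrix(self.dosages, samples, self.variants)


def _as_indices(which, n: int) -> np.ndarray:
    arr = np.asarray(which)
    if arr.dtype == bool:
        if arr.shape != (n,):
            raise ValueError("boolean mask has wrong length")
        return np.nonzero(arr)[0]
    return arr.astype(int)


# ---------------------------------------------------------------------------
# VCF intake
# ---------------------------------------------------------------------------

def read_vcf(path, multiallelic: str = "error"):
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosage is taken from the ``DS`` FORMAT field when present, otherwise from
    ``GT`` as the ALT-allele count; the effect allele is ALT.  Multi-allelic
    records are rejected (``multiallelic="error"``) or skipped
    (``multiallelic="skip"``).  Sample order is preserved.

    Returns ``(GenotypeMatrix, variants, sample_stubs)``; the sample stubs
    carry ids only (sex/phenotype placeholders) and are meant to be replaced
    via :func:`attach_phenotypes`.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("error", "skip"):
        raise ValueError("multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    variants: list[VariantInfo] = []
    for recno, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            if multiallelic == "skip":
                continue
            raise VCFParseError(
                f"record {recno} ({rec.CHROM}:{rec.POS}): multi-allelic record"
            )
        fmts = list(rec.FORMAT)
        if "DS" in fmts:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
            dos = ds.copy()
            dos[(dos < 0) | (dos > 2)] = np.nan
        elif "GT" in fmts:
            dos = np.empty(len(sample_ids))
            for j, gt in enumerate(rec.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    dos[j] = np.nan
                else:
                    dos[j] = float(sum(1 for a in alleles if a == 1))
        else:
            raise VCFParseError(
                f"record {recno} ({rec.CHROM}:{rec.POS}): neither DS nor GT present"
            )
        if len(dos) != len(sample_ids):
            raise VCFParseError(
                f"record {recno} ({rec.CHROM}:{rec.POS}): malformed sample fields"
            )
        ref, alt = rec.REF, rec.ALT[0]
        r2 = rec.INFO.get("R2", rec.INFO.get("DR2", None))
        typed = rec.INFO.get("TYPED", None) is not None
        imputed = rec.INFO.get("IMPUTED", None) is not None
        genotyped = typed or (r2 is None and not imputed)
        if genotyped and r2 is None:
            r2 = 1.0
        elif r2 is None:
            r2 = 1.0
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{ref}:{alt}"
        variants.append(
            VariantInfo(
                chrom=str(rec.CHROM).removeprefix("chr"),
                pos=rec.POS,
                id=vid,
                effect_allele=alt,
                other_allele=ref,
                maf=_folded_maf(dos),
                quality_r2=float(min(max(float(r2), 0.0), 1.0)),
                genotyped=genotyped,
                strand_ambiguous=(ref, alt) in _AMBIGUOUS_PAIRS,
            )
        )
        columns.append(dos)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    stubs = [SampleInfo(sample_id=s) for s in sample_ids]
    return GenotypeMatrix(dosages, stubs, variants), variants, stubs


def _folded_maf(dos: np.ndarray) -> float:
    ok = np.isfinite(dos)
    if not ok.any():
        return float("nan")
    p = float(np.mean(dos[ok]) / 2.0)
    return min(p, 1.0 - p)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> list[SampleInfo]:
    """Read a phenotype TSV with columns sample_id, sex, phenotype[, cohort].

    Blank/unrecognized sex becomes ``unknown`` (records are kept: cases of
    undetermined sex stay in the analysis); phenotype parsing is strict.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "sex", "phenotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in phenotype file")
    out = []
    for _, row in df.iterrows():
        sex = row["sex"].strip().lower()
        if sex not in ("male", "female"):
            sex = "unknown"
        pheno = row["phenotype"].strip().lower()
        if pheno not in PHENOTYPES:
            raise ValueError(
                f"sample {row['sample_id']}: unparseable phenotype {row['phenotype']!r}"
            )
        cohort = row.get("cohort", "unassigned")
        cohort = cohort.strip() if isinstance(cohort, str) else "unassigned"
        if cohort not in COHORTS:
            cohort = "unassigned"
        out.append(SampleInfo(row["sample_id"], sex, pheno, cohort))
    return out


def attach_phenotypes(G: GenotypeMatrix, samples: Iterable[SampleInfo]) -> GenotypeMatrix:
    """Replace VCF sample stubs with phenotype records, matched by id."""
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in G.sample_ids if sid not in by_id]
    if missing:
        raise ValueError(f"phenotypes missing for samples: {missing[:5]} ...")
    return G.with_samples([by_id[sid] for sid in G.sample_ids])


def write_phenotypes(samples: Sequence[SampleInfo], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "sex": [s.sex for s in samples],
            "phenotype": [s.phenotype for s in samples],
            "cohort": [s.cohort for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

def filter_variants(
    variants: Sequence[VariantInfo],
    min_quality_r2: float = 0.3,
    maf_range: tuple[float, float] = (0.0, 0.5),
) -> list[VariantInfo]:
    """Imputation-quality and MAF filter, all bounds inclusive.

    The quality threshold mirrors the post-imputation QC convention of keeping
    variants with R^2 >= 0.3.  Genotyped variants count as quality 1.0 when no
    score is carried.  Variants with unknown MAF fail a restrictive MAF filter.
    """
    lo, hi = maf_range
    out = []
    for v in variants:
        r2 = 1.0 if (v.genotyped and v.quality_r2 is None) else v.quality_r2
        if r2 < min_quality_r2:
            continue
        if math.isnan(v.maf):
            if (lo, hi) != (0.0, 0.5):
                continue
        elif not (lo <= v.maf <= hi):
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Cohort split
# ---------------------------------------------------------------------------

def split_cohorts(
    samples: Sequence[SampleInfo], seed: int
) -> tuple[list[SampleInfo], list[SampleInfo]]:
    """Random half-split into cohorts A and B, stratified by phenotype.

    Within each phenotype stratum the samples are shuffled (deterministic for
    a given seed) and cohort A receives the extra sample when the stratum
    count is odd.  Returns new records with the cohort field set; output order
    follows the input order within each cohort.
    """
    for s in samples:
        if s.cohort != "unassigned":
            raise ValueError(f"sample {s.sample_id} already assigned to a cohort")
    rng = np.random.default_rng(seed)
    assign: dict[str, str] = {}
    for pheno in PHENOTYPES:
        stratum = [s for s in samples if s.phenotype == pheno]
        if len(stratum) < 2:
            raise ValueError(
                f"phenotype stratum {pheno!r} has fewer than 2 samples"
            )
        order = rng.permutation(len(stratum))
        n_a = (len(stratum) + 1) // 2
        for rank, idx in enumerate(order):
            assign[stratum[idx].sample_id] = "A" if rank < n_a else "B"
    cohort_a = [replace(s, cohort="A") for s in samples if assign[s.sample_id] == "A"]
    cohort_b = [replace(s, cohort="B") for s in samples if assign[s.sample_id] == "B"]
    return cohort_a, cohort_b


# ---------------------------------------------------------------------------
# Association records and tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssocResult:
    """Per-variant case-control association record (one table row).

    ``beta`` is the log odds ratio for the effect allele, ``se`` its standard
    error; ``l95``/``u95`` bound the 95% CI of the odds ratio.
    """

    variant: VariantInfo
    effect_allele: str
    n: int
    beta: float
    se: float
    or_: float
    l95: float
    u95: float
    p: float
    test: str = "wald"

    def __post_init__(self):
        if self.test not in ("wald", "firth"):
            raise ValueError(f"unknown test {self.test!r}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.variant.id}: p {self.p} outside (0, 1]")
        if abs(math.log(self.or_) - self.beta) > 1e-6 * max(1.0, abs(self.beta)):
            raise ValueError(f"{self.variant.id}: or_ inconsistent with beta")
        if self.se > 0 and not (self.l95 < self.or_ < self.u95):
            raise ValueError(f"{self.variant.id}: CI does not bracket OR")

    @classmethod
    def from_fit(cls, variant, effect_allele, n, beta, se, p, test="wald"):
        return cls(
            variant=variant,
            effect_allele=effect_allele,
            n=n,
            beta=beta,
            se=se,
            or_=math.exp(beta),
            l95=math.exp(beta - 1.96 * se),
            u95=math.exp(beta + 1.96 * se),
            p=p,
            test=test,
        )


def assoc_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    """Association records as a table mirroring the standard layout."""
    rows = []
    for r in results:
        v = r.variant
        rows.append(
            {
                "CHR": v.chrom,
                "SNP": v.id,
                "BP": v.pos,
                "A1": r.effect_allele,
                "QUALITY_R2": v.quality_r2,
                "GENOTYPED": "Genotyped" if v.genotyped else "Imputed",
                "MAF": v.maf,
                "N": r.n,
                "OR": r.or_,
                "L95": r.l95,
                "U95": r.u95,
                "P": r.p,
            }
        )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def write_assoc_table(results: Sequence[AssocResult], path) -> None:
    assoc_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_assoc_table(path) -> list[AssocResult]:
    """Read an association TSV back into records.

    ``beta`` is recovered as ln(OR) and ``se`` from the 95% CI width using the
    1.96 normal quantile (the convention the CI was built with).
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    out = []
    for _, row in df.iterrows():
        or_, l95, u95 = float(row["OR"]), float(row["L95"]), float(row["U95"])
        beta = math.log(or_)
        se = math.log(u95 / l95) / (2 * 1.96) if u95 > l95 > 0 else 0.0
        variant = VariantInfo(
            chrom=str(row["CHR"]),
            pos=int(row["BP"]),
            id=str(row["SNP"]),
            effect_allele=str(row["A1"]),
            maf=float(row["MAF"]),
            quality_r2=float(row["QUALITY_R2"]),
            genotyped=str(row["GENOTYPED"]).lower().startswith("g"),
        )
        out.append(
            AssocResult(
                variant=variant,
                effect_allele=str(row["A1"]),
                n=int(row["N"]),
                beta=beta,
                se=se,
                or_=or_,
                l95=l95,
                u95=u95,
                p=float(row["P"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Known-locus BED intake
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a known-locus BED (0-based half-open) into 1-based inclusive
    (chrom, start, end) intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            chrom = parts[0].removeprefix("chr")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end0 <= start0 or start0 < 0:
                raise ValueError(f"{path}:{lineno}: malformed BED interval")
            out.append((chrom, start0 + 1, end0))
    return out
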