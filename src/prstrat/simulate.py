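"""Synthetic two-subtype case-control cohort generator.

The generator emulates a disease cohort in which the large majority of cases
belong to an "autoimmune-like" subtype driven by a small panel of common
variants with large effects (an HLA-like risk locus with OR ~ 6, a second
moderate risk locus, and an INS-like protective locus with OR ~ 0.44), while a
small minority subtype (default 8% of cases, inside the 5-10% range reported
for antibody-negative presentations) is driven by a panel of rare variants
(MAF 0.2-3.5%, OR 2-9).  Controls are non-cases from the same mixture
population.  The per-subtype disease model is logistic:

    logit Pr(case | G, subtype s) = a_s + sum_{i in panel(s)} ln(OR_i) * G_i

with the intercept a_s solved numerically so that each subtype's marginal
case probability equals ``baseline_prevalence``.  Genotypes are
Hardy-Weinberg binomial(2, maf) draws, independent across variants (no LD).
Optional two-subpopulation structure draws per-variant null allele
frequencies from a Balding-Nichols-style Beta divergence around the base
frequency, with configurable case/control subpopulation imbalance to induce
confounding; the causal panels keep their base frequencies in both
subpopulations so the disease-model calibration is unaffected.

Cases are accumulated by rejection sampling per subtype, which keeps the
configured odds ratios interpretable as the simulation's own parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import GenotypeMatrix, SampleInfo, VariantInfo

DEFAULT_COMMON_PANEL = ((0.25, 6.0), (0.10, 2.2), (0.25, 0.44))
DEFAULT_RARE_PANEL = (
    (0.002, 9.0),
    (0.003, 6.0),
    (0.005, 6.0),
    (0.007, 4.0),
    (0.010, 3.5),
    (0.015, 3.0),
    (0.025, 2.5),
    (0.035, 2.0),
)

# chromosomes hosting the planted panels; nulls are spread over 1..22
_COMMON_CHROMS = ("6", "1", "11", "2", "3", "5", "7")
_RARE_CHROMS = ("4", "5", "7", "8", "9", "10", "12", "13", "14", "15", "16", "17")


@dataclass(frozen=True)
class StructureConfig:
    """Two-subpopulation divergence for population-stratification testing."""

    fst: float = 0.05
    case_pop1_fraction: float = 0.5
    control_pop1_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        for f in (self.case_pop1_fraction, self.control_pop1_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("subpopulation fractions must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 6599
    n_controls: int = 12350
    n_null_variants: int = 20000
    common_panel: tuple[tuple[float, float], ...] = DEFAULT_COMMON_PANEL
    rare_panel: tuple[tuple[float, float], ...] = DEFAULT_RARE_PANEL
    subtype_fraction: float = 0.08
    baseline_prevalence: float = 0.004
    structure: StructureConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.subtype_fraction < 1.0:
            raise ValueError("subtype_fraction must be in (0, 1)")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        for maf, or_ in tuple(self.common_panel) + tuple(self.rare_panel):
            if not 0.0 < maf < 0.5:
                raise ValueError(f"panel maf {maf} outside (0, 0.5)")
            if or_ <= 0:
                raise ValueError(f"panel odds ratio {or_} must be > 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort, for recovery tests.

    ``variants`` has columns id/causal/panel/true_beta; ``samples`` has
    columns sample_id/subtype/subpop.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame

    def to_tsv(self, variants_path, samples_path) -> None:
        self.variants.to_csv(variants_path, sep="\t", index=False)
        self.samples.to_csv(samples_path, sep="\t", index=False)


class SimulationError(RuntimeError):
    """Raised when a configuration cannot yield the requested cohort."""


# ---------------------------------------------------------------------------
# Analytic machinery: panel score distribution and intercept calibration
# ---------------------------------------------------------------------------

def _hw_probs(maf: float) -> np.ndarray:
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])


def panel_score_distribution(
    panel: Sequence[tuple[float, float]], max_atoms: int = 200_000
):
    """Distribution of S = sum_i ln(OR_i) * G_i under Hardy-Weinberg.

    Exact atom-by-atom convolution with pruning of negligible mass; for dense
    panels whose atom count explodes, falls back to a fine-grid
    linear-interpolation convolution.  Returns (values, probabilities).
    """
    atoms: dict[float, float] = {0.0: 1.0}
    for maf, or_ in panel:
        b = math.log(or_)
        hw = _hw_probs(maf)
        new: dict[float, float] = {}
        for v, pr in atoms.items():
            for g in range(3):
                key = round(v + b * g, 12)
                new[key] = new.get(key, 0.0) + pr * hw[g]
        atoms = {v: pr for v, pr in new.items() if pr > 1e-15}
        if len(atoms) > max_atoms:
            return _grid_score_distribution(panel)
    vals = np.array(sorted(atoms))
    probs = np.array([atoms[v] for v in vals])
    return vals, probs / probs.sum()


def _grid_score_distribution(panel, n_bins: int = 400_001):
    betas = [math.log(or_) for _, or_ in panel]
    lo = sum(min(0.0, 2 * b) for b in betas) - 1e-9
    hi = sum(max(0.0, 2 * b) for b in betas) + 1e-9
    grid = np.linspace(lo, hi, n_bins)
    step = grid[1] - grid[0]
    dist = np.zeros(n_bins)
    i0 = int(np.clip(round((0.0 - lo) / step), 0, n_bins - 1))
    dist[i0] = 1.0
    for (maf, _), b in zip(panel, betas):
        hw = _hw_probs(maf)
        new = hw[0] * dist
        for g in (1, 2):
            shift = g * b / step
            k = math.floor(shift)
            frac = shift - k
            shifted = np.zeros(n_bins)
            src = dist * hw[g]
            if k >= 0:
                shifted[k:] += (1 - frac) * src[: n_bins - k]
                if k + 1 < n_bins:
                    shifted[k + 1 :] += frac * src[: n_bins - k - 1]
            else:
                shifted[: n_bins + k] += (1 - frac) * src[-k:]
                shifted[: n_bins + k + 1] += frac * src[-k - 1 :]
            new = new + shifted
        dist = new
    keep = dist > 1e-300
    return grid[keep], dist[keep] / dist[keep].sum()


def solve_intercept(
    panel: Sequence[tuple[float, float]], prevalence: float
) -> float:
    """Intercept a such that E_G[expit(a + S)] equals the target prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    if len(panel) == 0:
        return float(logit(prevalence))
    vals, probs = panel_score_distribution(panel)

    def resid(a: float) -> float:
        return float(probs @ expit(a + vals)) - prevalence

    root = brentq(resid, -60.0, 30.0, xtol=1e-12, rtol=1e-14)
    if abs(resid(root)) > 1e-8:
        raise RuntimeError("intercept calibration did not reach tolerance")
    return float(root)


def expected_case_frequency(maf: float, or_: float, intercept: float) -> float:
    """Effect-allele frequency among cases for a single-variant logistic model.

    Closed 3-term enumeration over genotype classes g in {0, 1, 2}:
    sum_g (g/2) HW(g) Pr(case|g) / sum_g HW(g) Pr(case|g).
    """
    if not 0.0 < maf < 0.5:
        raise ValueError("maf must be in (0, 0.5)")
    hw = _hw_probs(maf)
    g = np.arange(3)
    w = hw * expit(intercept + math.log(or_) * g)
    return float((g / 2.0) @ w / w.sum())


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _variant_layout(config: SimulationConfig, rng) -> list[VariantInfo]:
    """Deterministic placement: null variants tile chromosomes 1..22 at 1 Mb
    spacing; planted panels sit at high positions on dedicated chromosomes so
    they never fall within locus-merging distance of a null variant."""
    variants = []
    for i, (maf, _) in enumerate(config.common_panel):
        chrom = _COMMON_CHROMS[i % len(_COMMON_CHROMS)]
        pos = 900_000_000 + (i // len(_COMMON_CHROMS)) * 3_000_000
        variants.append(
            VariantInfo(
                chrom=chrom, pos=pos, id=f"common{i + 1}",
                effect_allele="A", other_allele="G", maf=maf,
                quality_r2=float(rng.uniform(0.95, 1.0)), genotyped=False,
            )
        )
    for i, (maf, _) in enumerate(config.rare_panel):
        chrom = _RARE_CHROMS[i % len(_RARE_CHROMS)]
        pos = 920_000_000 + (i // len(_RARE_CHROMS)) * 3_000_000
        variants.append(
            VariantInfo(
                chrom=chrom, pos=pos, id=f"rare{i + 1}",
                effect_allele="A", other_allele="G", maf=maf,
                quality_r2=float(rng.uniform(0.8, 1.0)), genotyped=False,
            )
        )
    null_mafs = rng.uniform(0.01, 0.5, size=config.n_null_variants)
    null_r2 = rng.uniform(0.7, 1.0, size=config.n_null_variants)
    null_typed = rng.random(config.n_null_variants) < 0.3
    for j in range(config.n_null_variants):
        chrom = str(j % 22 + 1)
        pos = (j // 22 + 1) * 1_000_000
        variants.append(
            VariantInfo(
                chrom=chrom, pos=pos, id=f"null{j + 1}",
                effect_allele="A", other_allele="G", maf=float(null_mafs[j]),
                quality_r2=1.0 if null_typed[j] else float(null_r2[j]),
                genotyped=bool(null_typed[j]),
            )
        )
    return variants


def _draw_cases(n_needed, mafs, betas, panel_slice, intercept, rng, prevalence):
    """Rejection-sample panel genotype rows for cases of one subtype.

    ``mafs``/``betas`` cover the full causal panel (both subtypes
    concatenated); only the columns in ``panel_slice`` carry risk for this
    subtype.  Returns an (n_needed, len(mafs)) integer array.
    """
    if n_needed == 0:
        return np.empty((0, len(mafs)), dtype=np.int8)
    rows = []
    got = 0
    drawn = 0
    max_draws = int(max(1e6, 50 * n_needed / prevalence))
    chunk = int(min(max(10 * n_needed / prevalence, 10_000), 2_000_000))
    while got < n_needed:
        if drawn > max_draws:
            raise SimulationError(
                "rejection sampling exceeded its draw budget; the requested "
                "subtype mix is unattainable under this configuration"
            )
        G = rng.binomial(2, mafs, size=(chunk, len(mafs))).astype(np.int8)
        eta = intercept + G[:, panel_slice].astype(float) @ betas[panel_slice]
        accept = rng.random(chunk) < expit(eta)
        drawn += chunk
        if accept.any():
            rows.append(G[accept])
            got += int(accept.sum())
    return np.concatenate(rows, axis=0)[:n_needed]


def _draw_controls(n_needed, mafs, betas, sl_common, sl_rare, a_major, a_minor,
                   subtype_fraction, rng):
    """Rejection-sample controls (non-cases) from the subtype mixture.

    Returns (genotype rows, subtype labels)."""
    rows, subs = [], []
    got = 0
    while got < n_needed:
        chunk = int(min(max(int(1.5 * (n_needed - got)) + 16, 1000), 2_000_000))
        G = rng.binomial(2, mafs, size=(chunk, len(mafs))).astype(np.int8)
        minority = rng.random(chunk) < subtype_fraction
        eta = np.where(
            minority,
            a_minor + G[:, sl_rare].astype(float) @ betas[sl_rare],
            a_major + G[:, sl_common].astype(float) @ betas[sl_common],
        )
        accept = rng.random(chunk) >= expit(eta)
        rows.append(G[accept])
        subs.append(minority[accept])
        got += int(accept.sum())
    G = np.concatenate(rows, axis=0)[:n_needed]
    minority = np.concatenate(subs)[:n_needed]
    return G, minority


def simulate_cohort(config: SimulationConfig):
    """Generate a cohort under the two-subtype mixture model.

    Returns ``(GenotypeMatrix, samples, variants, TruthTable)``; the matrix
    already carries the sample and variant metadata.  Deterministic for a
    given config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    variants = _variant_layout(config, rng)

    panel = list(config.common_panel) + list(config.rare_panel)
    mafs = np.array([maf for maf, _ in panel])
    betas = np.array([math.log(or_) for _, or_ in panel])
    n_common = len(config.common_panel)
    sl_common = slice(0, n_common)
    sl_rare = slice(n_common, len(panel))

    a_major = solve_intercept(config.common_panel, config.baseline_prevalence)
    a_minor = solve_intercept(config.rare_panel, config.baseline_prevalence)

    n_minor = int(round(config.subtype_fraction * config.n_cases))
    n_major = config.n_cases - n_minor
    G_cases_major = _draw_cases(
        n_major, mafs, betas, sl_common, a_major, rng, config.baseline_prevalence
    )
    G_cases_minor = _draw_cases(
        n_minor, mafs, betas, sl_rare, a_minor, rng, config.baseline_prevalence
    )
    G_ctrl, ctrl_minority = _draw_controls(
        config.n_controls, mafs, betas, sl_common, sl_rare,
        a_major, a_minor, config.subtype_fraction, rng,
    )

    n_total = config.n_cases + config.n_controls
    panel_dosages = np.concatenate([G_cases_major, G_cases_minor, G_ctrl], axis=0)

    # subpopulation assignment (only matters with structure enabled)
    if config.structure is not None:
        st = config.structure
        pop_cases = (rng.random(config.n_cases) >= st.case_pop1_fraction).astype(np.int8)
        pop_ctrl = (rng.random(config.n_controls) >= st.control_pop1_fraction).astype(np.int8)
        subpop = np.concatenate([pop_cases, pop_ctrl])
    else:
        subpop = np.zeros(n_total, dtype=np.int8)

    n_planted = len(panel)
    dosages = np.empty((n_total, n_planted + config.n_null_variants), dtype=np.float32)
    dosages[:, :n_planted] = panel_dosages
    for j in range(config.n_null_variants):
        p = variants[n_planted + j].maf
        if config.structure is not None:
            f = config.structure.fst
            a, b = p * (1 - f) / f, (1 - p) * (1 - f) / f
            p_sub = np.clip(rng.beta(a, b, size=2), 1e-4, 1 - 1e-4)
            dosages[:, n_planted + j] = rng.binomial(2, p_sub[subpop])
        else:
            dosages[:, n_planted + j] = rng.binomial(2, p, size=n_total)

    sexes = np.where(rng.random(n_total) < 0.525, "male", "female").astype(object)
    sexes[rng.random(n_total) < 0.001] = "unknown"
    samples = []
    subtype = []
    for i in range(n_total):
        is_case = i < config.n_cases
        if is_case:
            minority = i >= n_major
        else:
            minority = bool(ctrl_minority[i - config.n_cases])
        subtype.append("minority" if minority else "majority")
        samples.append(
            SampleInfo(
                sample_id=f"case{i + 1:06d}" if is_case else f"ctrl{i - config.n_cases + 1:06d}",
                sex=str(sexes[i]),
                phenotype="case" if is_case else "control",
            )
        )

    # fold realized frequencies back into the variant metadata
    realized = []
    for j, v in enumerate(variants):
        col = dosages[:, j]
        p_hat = float(col.mean() / 2.0)
        realized.append(
            VariantInfo(
                chrom=v.chrom, pos=v.pos, id=v.id,
                effect_allele=v.effect_allele, other_allele=v.other_allele,
                maf=min(p_hat, 1 - p_hat), quality_r2=v.quality_r2,
                genotyped=v.genotyped,
            )
        )
    variants = realized

    G = GenotypeMatrix(dosages, samples, variants)
    truth_variants = pd.DataFrame(
        {
            "id": [v.id for v in variants],
            "causal": [j < n_planted for j in range(len(variants))],
            "panel": (
                ["common"] * n_common
                + ["rare"] * (len(panel) - n_common)
                + [""] * config.n_null_variants
            ),
            "true_beta": np.concatenate([betas, np.zeros(config.n_null_variants)]),
        }
    )
    truth_samples = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "subtype": subtype,
            "subpop": subpop,
        }
    )
    truth = TruthTable(variants=truth_variants, samples=truth_samples)
    return G, samples, variants, truth


# ---------------------------------------------------------------------------
# VCF export (for the CLI round trip)
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write integer-valued dosages as a minimal VCF 4.2 with GT and DS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Genotyped">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(G.variants):
            info = f"R2={v.quality_r2:.5g}" + (";TYPED" if v.genotyped else "")
            fields = [
                v.chrom, str(v.pos), v.id, v.other_allele or "G",
                v.effect_allele, ".", "PASS", info, "GT:DS",
            ]
            col = G.dosages[:, j]
            for d in col:
                if not np.isfinite(d):
                    fields.append("./.:.")
                else:
                    g = int(round(float(d)))
                    fields.append(f"{gt_codes[g]}:{float(d):.3g}")
            fh.write("\t".join(fields) + "\n")
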