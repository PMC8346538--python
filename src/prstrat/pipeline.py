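"""Orchestration of the full stratified-discovery flow.

One direction of the analysis: train a per-variant GWAS on one cohort half
(sex + principal components as covariates), build C+T PRS models over a
threshold grid, select the inclusion threshold by AUC in the other half,
dichotomize that test half at the MCC-optimal PRS cutoff, run the
case-control GWAS restricted to low-PRS cases vs low-PRS controls, run the
overall GWAS on the same test half, compare odds ratios between the two
analyses at lead variants, and call/classify loci from the low-PRS hits.
The cohort switch repeats the procedure with the halves exchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .assoc import (
    CovariateSet,
    HetTest,
    _chrom_key,
    genome_wide_hits,
    gwas,
    or_heterogeneity,
    pca_covariates,
)
from .cohort import (
    AssocResult,
    GenotypeMatrix,
    SampleInfo,
    assoc_frame,
    filter_variants,
    split_cohorts,
    write_assoc_table,
)
from .evaluate import CutoffReport, stratify
from .prs import CTPRS, DEFAULT_GRID


@dataclass
class PipelineConfig:
    """Tunable parameters of the stratified pipeline (one flat namespace)."""

    seed: int = 0
    grid: tuple[float, ...] = DEFAULT_GRID
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    n_pcs: int = 10
    recompute_pcs: bool = True  # recompute PCs within the low-PRS stratum
    pca_maf_min: float = 0.05
    min_quality_r2: float = 0.3
    merge_kb: float = 500.0
    flank_kb: float = 300.0
    alpha: float = 5e-8
    cutoff_rule: str = "mcc"

    def __post_init__(self):
        if self.cutoff_rule != "mcc":
            raise ValueError("only the MCC cutoff rule is supported")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from the nested config layout
        (split.seed, prs.grid, prs.clump.{r2,window_kb}, cutoff.rule,
        assoc.n_pcs, loci.{merge_kb,flank_kb}, alpha)."""
        kw = {}
        split = d.get("split", {})
        if "seed" in split:
            kw["seed"] = int(split["seed"])
        prs = d.get("prs", {})
        if "grid" in prs:
            kw["grid"] = tuple(float(x) for x in prs["grid"])
        clump_cfg = prs.get("clump", {})
        if "r2" in clump_cfg:
            kw["clump_r2"] = float(clump_cfg["r2"])
        if "window_kb" in clump_cfg:
            kw["clump_window_kb"] = float(clump_cfg["window_kb"])
        cutoff = d.get("cutoff", {})
        if "rule" in cutoff:
            kw["cutoff_rule"] = str(cutoff["rule"])
        assoc_cfg = d.get("assoc", {})
        if "n_pcs" in assoc_cfg:
            kw["n_pcs"] = int(assoc_cfg["n_pcs"])
        if "recompute_pcs" in assoc_cfg:
            kw["recompute_pcs"] = bool(assoc_cfg["recompute_pcs"])
        loci = d.get("loci", {})
        if "merge_kb" in loci:
            kw["merge_kb"] = float(loci["merge_kb"])
        if "flank_kb" in loci:
            kw["flank_kb"] = float(loci["flank_kb"])
        if "alpha" in d:
            kw["alpha"] = float(d["alpha"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class LocusCall:
    """A merged association region with its lead variant and classification."""

    chrom: str
    start: int
    end: int
    lead_id: str
    lead_pos: int
    lead_p: float
    lead_maf: float
    lead_quality_r2: float
    n_hits: int
    novelty: str  # {known, novel}
    quality_class: str  # {high, low}: lead quality_r2 > 0.9
    rare_flag: bool  # lead MAF < 0.05


@dataclass
class StratifiedResult:
    """Everything one direction of the pipeline produces."""

    direction: str  # "A->B" or "B->A"
    p_threshold: float
    auc_table: pd.DataFrame
    cutoff_report: CutoffReport
    proportions: dict
    low_assoc: list[AssocResult]
    overall_assoc: list[AssocResult]
    het: dict[str, HetTest]
    loci: list[LocusCall]
    counts: dict


# ---------------------------------------------------------------------------
# Locus calling
# ---------------------------------------------------------------------------

def call_loci(
    hits: Sequence[AssocResult],
    merge_kb: float = 500.0,
    known_loci: Sequence[tuple[str, int, int]] | None = None,
    flank_kb: float = 300.0,
) -> list[LocusCall]:
    """Single-linkage merge of hits into loci, then classify each lead.

    Hits within ``merge_kb`` of each other on a chromosome form one region.
    The lead is the smallest-P hit (tie: smaller position).  A locus is
    ``known`` iff its lead lies within ``flank_kb`` of any known-locus
    interval; quality is ``high`` iff the lead's imputation quality exceeds
    0.9; ``rare_flag`` marks lead MAF < 0.05.
    """
    if known_loci:
        for chrom, start, end in known_loci:
            if end < start:
                raise ValueError(f"malformed known-locus interval {chrom}:{start}-{end}")
    if not hits:
        return []
    ordered = sorted(hits, key=lambda r: (_chrom_key(r.variant.chrom), r.variant.pos))
    merge_bp = merge_kb * 1000.0
    groups: list[list[AssocResult]] = []
    for r in ordered:
        if (
            groups
            and groups[-1][-1].variant.chrom == r.variant.chrom
            and r.variant.pos - groups[-1][-1].variant.pos <= merge_bp
        ):
            groups[-1].append(r)
        else:
            groups.append([r])
    flank_bp = flank_kb * 1000.0
    out = []
    for grp in groups:
        lead = min(grp, key=lambda r: (r.p, r.variant.pos))
        v = lead.variant
        known = False
        if known_loci:
            for chrom, start, end in known_loci:
                if chrom.removeprefix("chr") != v.chrom.removeprefix("chr"):
                    continue
                dist = max(start - v.pos, v.pos - end, 0)
                if dist <= flank_bp:
                    known = True
                    break
        out.append(
            LocusCall(
                chrom=v.chrom,
                start=min(r.variant.pos for r in grp),
                end=max(r.variant.pos for r in grp),
                lead_id=v.id,
                lead_pos=v.pos,
                lead_p=lead.p,
                lead_maf=v.maf,
                lead_quality_r2=v.quality_r2,
                n_hits=len(grp),
                novelty="known" if known else "novel",
                quality_class="high" if v.quality_r2 > 0.9 else "low",
                rare_flag=bool(v.maf < 0.05),
            )
        )
    return out


def loci_frame(loci: Sequence[LocusCall]) -> pd.DataFrame:
    return pd.DataFrame([asdict(l) for l in loci])


def manhattan_table(results: Sequence[AssocResult], out=None) -> pd.DataFrame:
    """Plot-ready (chrom, pos, -log10 P) table sorted by genomic position."""
    ordered = sorted(results, key=lambda r: (_chrom_key(r.variant.chrom), r.variant.pos))
    df = pd.DataFrame(
        {
            "chrom": [r.variant.chrom for r in ordered],
            "pos": [r.variant.pos for r in ordered],
            "neglog10_p": [-np.log10(r.p) for r in ordered],
        }
    )
    if out is not None:
        df.to_csv(out, sep="\t", index=False, float_format="%.6g")
    return df


# ---------------------------------------------------------------------------
# Pipeline directions
# ---------------------------------------------------------------------------

def _cohort_masks(samples: Sequence[SampleInfo]):
    a = np.array([s.cohort == "A" for s in samples])
    b = np.array([s.cohort == "B" for s in samples])
    return a, b


def run_direction(
    G: GenotypeMatrix,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    config: PipelineConfig,
    known_loci=None,
    direction: str = "A->B",
    out_dir=None,
) -> StratifiedResult:
    """One pass of the stratified analysis (train half -> test half)."""
    if np.any(train_mask & test_mask):
        raise ValueError("training and testing cohorts must be disjoint")

    # variant QC: imputation quality filter on intake metadata
    qc_pass = {v.id for v in filter_variants(G.variants, config.min_quality_r2)}
    keep = [j for j, v in enumerate(G.variants) if v.id in qc_pass]
    Gq = G.subset_variants(keep) if len(keep) < G.n_variants else G

    G_train = Gq.subset_samples(train_mask)
    G_test = Gq.subset_samples(test_mask)
    y_test = G_test.phenotype_array()

    covs_train = pca_covariates(G_train, config.n_pcs, maf_min=config.pca_maf_min)

    prs = CTPRS(
        p_threshold="auto",
        grid=config.grid,
        clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
    )
    prs.fit(G_train, covariates=covs_train)
    prs.select_threshold(G_test)
    scores = prs.decision_function(G_test)
    prs.fit_cutoff(G_test)
    report = prs.cutoff_report_

    low_mask, _high, conf, proportions = stratify(scores, y_test, prs.cutoff_)
    if conf.fn == 0 or conf.tn == 0:
        raise ValueError(
            f"empty low-PRS stratum at cutoff {prs.cutoff_:g} "
            f"(low cases {conf.fn}, low controls {conf.tn})"
        )

    G_low = G_test.subset_samples(low_mask)
    if config.recompute_pcs:
        covs_low = pca_covariates(G_low, config.n_pcs, maf_min=config.pca_maf_min)
        covs_test = pca_covariates(G_test, config.n_pcs, maf_min=config.pca_maf_min)
    else:
        covs_test = pca_covariates(G_test, config.n_pcs, maf_min=config.pca_maf_min)
        low_idx = np.nonzero(low_mask)[0]
        covs_low = CovariateSet(
            sample_ids=[covs_test.sample_ids[i] for i in low_idx],
            sex=covs_test.sex[low_idx],
            pcs=covs_test.pcs[low_idx],
        )
    low_assoc, low_skipped = gwas(G_low, covariates=covs_low)
    overall_assoc, overall_skipped = gwas(G_test, covariates=covs_test)

    hits_low = genome_wide_hits(low_assoc, config.alpha)
    hits_overall = genome_wide_hits(overall_assoc, config.alpha)
    loci_low = call_loci(hits_low, config.merge_kb, known_loci, config.flank_kb)
    loci_overall = call_loci(hits_overall, config.merge_kb, known_loci, config.flank_kb)

    low_by_id = {r.variant.id: r for r in low_assoc}
    overall_by_id = {r.variant.id: r for r in overall_assoc}
    het: dict[str, HetTest] = {}
    lead_ids = sorted(
        {l.lead_id for l in loci_low} | {l.lead_id for l in loci_overall}
    )
    for vid in lead_ids:
        if vid in low_by_id and vid in overall_by_id:
            het[vid] = or_heterogeneity(low_by_id[vid], overall_by_id[vid])

    counts = {
        "n_train_cases": int(G_train.phenotype_array().sum()),
        "n_train_controls": int((1 - G_train.phenotype_array()).sum()),
        "n_test_cases": int(y_test.sum()),
        "n_test_controls": int((1 - y_test).sum()),
        "n_low_cases": conf.fn,
        "n_low_controls": conf.tn,
        "n_variants": Gq.n_variants,
        "n_skipped_low": len(low_skipped),
        "n_skipped_overall": len(overall_skipped),
    }
    result = StratifiedResult(
        direction=direction,
        p_threshold=prs.p_threshold_,
        auc_table=prs.auc_table_,
        cutoff_report=report,
        proportions=proportions,
        low_assoc=low_assoc,
        overall_assoc=overall_assoc,
        het=het,
        loci=loci_low,
        counts=counts,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def run_switched(
    G: GenotypeMatrix,
    config: PipelineConfig,
    known_loci=None,
    out_dir=None,
) -> tuple[StratifiedResult, StratifiedResult]:
    """Run both directions of the cohort switch.

    Samples without cohort labels are first split (stratified by phenotype,
    deterministic for config.seed).
    """
    if all(s.cohort == "unassigned" for s in G.samples):
        a, b = split_cohorts(G.samples, config.seed)
        by_id = {s.sample_id: s for s in a + b}
        G = G.with_samples([by_id[sid] for sid in G.sample_ids])
    mask_a, mask_b = _cohort_masks(G.samples)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both cohorts must be assigned")
    out_ab = Path(out_dir) / "direction_A_to_B" if out_dir else None
    out_ba = Path(out_dir) / "direction_B_to_A" if out_dir else None
    res_ab = run_direction(
        G, mask_a, mask_b, config, known_loci, direction="A->B", out_dir=out_ab
    )
    res_ba = run_direction(
        G, mask_b, mask_a, config, known_loci, direction="B->A", out_dir=out_ba
    )
    if out_dir is not None:
        _write_run_log(Path(out_dir), config, (res_ab, res_ba))
    return res_ab, res_ba


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def het_frame(het: dict[str, HetTest]) -> pd.DataFrame:
    rows = []
    for vid, h in het.items():
        rows.append(
            {"variant_id": vid, "beta_low": h.beta1, "se_low": h.se1,
             "beta_overall": h.beta2, "se_overall": h.se2,
             "z": h.z, "p_het": h.p_het}
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "beta_low", "se_low", "beta_overall",
                       "se_overall", "z", "p_het"],
    )


def _persist(result: StratifiedResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.auc_table.to_csv(out_dir / "auc_grid.tsv", sep="\t", index=False,
                            float_format="%.6g")
    result.cutoff_report.to_frame().to_csv(
        out_dir / "cutoff_report.tsv", sep="\t", index=False, float_format="%.6g"
    )
    write_assoc_table(result.low_assoc, out_dir / "low_prs_assoc.tsv")
    write_assoc_table(result.overall_assoc, out_dir / "overall_assoc.tsv")
    het_frame(result.het).to_csv(out_dir / "heterogeneity.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    loci_frame(result.loci).to_csv(out_dir / "loci.tsv", sep="\t", index=False,
                                   float_format="%.6g")
    manhattan_table(result.low_assoc, out_dir / "manhattan_low.tsv")
    manhattan_table(result.overall_assoc, out_dir / "manhattan_overall.tsv")


def _write_run_log(out_dir: Path, config: PipelineConfig, results) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "prstrat_version": _version,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "directions": [
            {
                "direction": r.direction,
                "selected_p_threshold": r.p_threshold,
                "prs_cutoff": r.cutoff_report.cutoff,
                "mcc": r.cutoff_report.mcc,
                "auc": r.cutoff_report.auc,
                "counts": r.counts,
                "n_loci": len(r.loci),
            }
            for r in results
        ],
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
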