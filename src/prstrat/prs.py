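"""Clumping-and-thresholding (C+T) polygenic risk scores.

A scoring model is built from a training-cohort GWAS: variants are greedily
LD-clumped (smallest P first, removing correlated neighbours within a window),
an inclusion P-threshold selects the surviving entries, and each entry
contributes beta = ln(OR) per effect allele.  The per-sample score uses the
average-per-allele convention

    S_j = sum_i beta_i G_ij / (2 M_j)

where M_j counts the model variants with a non-missing dosage for sample j.
The inclusion threshold is chosen from a grid by AUC of the scores in an
independent test cohort.

:class:`CTPRS` packages the procedure as a scikit-learn style estimator
(fit / decision_function / predict with get_params/set_params); the
module-level functions are the primitive operations it composes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .assoc import CovariateSet, _chrom_key, _impute_and_freq, gwas
from .cohort import AssocResult, GenotypeMatrix
from .evaluate import auc, best_mcc_cutoff

#: inclusion-threshold grid: 1e-10 .. 1e-4 by decades, then
#: 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1 (14 values)
DEFAULT_GRID = (
    1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4,
    0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0,
)


@dataclass(frozen=True)
class PRSModel:
    """A trained C+T score: clumped entries with betas and the P-threshold."""

    entries: pd.DataFrame  # columns: variant_id, effect_allele, beta, train_p
    p_threshold: float
    clump_params: tuple[float, float]  # (r2_threshold, window_kb)

    def __post_init__(self):
        required = {"variant_id", "effect_allele", "beta", "train_p"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"model entries need columns {sorted(required)}")
        if len(self.entries) and self.entries["train_p"].max() > self.p_threshold:
            raise ValueError("an entry's training P exceeds the model threshold")

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path, p_threshold=1.0, clump_params=(0.1, 250.0)):
        return cls(pd.read_csv(path, sep="\t"), p_threshold, tuple(clump_params))


@dataclass
class PRSScores:
    """Per-sample scores with the count of model variants actually used."""

    sample_ids: list[str]
    scores: np.ndarray
    m_used: np.ndarray
    n_unmatched: int = 0

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": self.sample_ids, "prs": self.scores,
             "m_variants_used": self.m_used}
        ).to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def clump(
    train_results: Sequence[AssocResult],
    G_ref: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping: smallest P claims its window.

    Repeatedly takes the unclaimed variant with the smallest P as an index
    variant and claims every unclaimed variant within ``window_kb`` on the
    same chromosome whose dosage correlation r^2 with it (computed on the
    reference genotypes) exceeds the threshold.  Ties break by P then
    position.  Variants absent from the reference are excluded (with a
    warning summarizing the count).
    """
    vindex = G_ref.variant_index()
    present = [r for r in train_results if r.variant.id in vindex]
    n_missing = len(train_results) - len(present)
    if n_missing:
        warnings.warn(f"clump: {n_missing} variant(s) absent from the LD reference")
    order = sorted(present, key=lambda r: (r.p, _chrom_key(r.variant.chrom), r.variant.pos))
    chroms = [r.variant.chrom for r in order]
    pos = np.array([r.variant.pos for r in order])
    cols = [vindex[r.variant.id] for r in order]
    X = np.column_stack(
        [_impute_and_freq(G_ref.dosages[:, c])[0] for c in cols]
    ) if order else np.empty((G_ref.n_samples, 0))
    claimed = np.zeros(len(order), dtype=bool)
    kept: list[str] = []
    win = window_kb * 1000.0
    for i, r in enumerate(order):
        if claimed[i]:
            continue
        kept.append(r.variant.id)
        claimed[i] = True
        xi = X[:, i]
        si = xi.std()
        for j in range(len(order)):
            if claimed[j] or chroms[j] != chroms[i] or abs(pos[j] - pos[i]) > win:
                continue
            xj = X[:, j]
            sj = xj.std()
            if si == 0 or sj == 0:
                continue
            r2 = float(np.corrcoef(xi, xj)[0, 1]) ** 2
            if r2 > r2_threshold:
                claimed[j] = True
    return kept


def build_model(
    train_results: Sequence[AssocResult],
    clumped_ids: Sequence[str],
    p_threshold: float,
    clump_params: tuple[float, float] = (0.1, 250.0),
) -> PRSModel:
    """Model = clumped variants with training P <= threshold, beta = ln(OR)."""
    by_id = {r.variant.id: r for r in train_results}
    unknown = [v for v in clumped_ids if v not in by_id]
    if unknown:
        raise ValueError(f"clumped ids not in training results: {unknown[:5]}")
    rows = []
    for vid in clumped_ids:
        r = by_id[vid]
        if r.p <= p_threshold:
            rows.append(
                {"variant_id": vid, "effect_allele": r.effect_allele,
                 "beta": r.beta, "train_p": r.p}
            )
    if not rows:
        raise ValueError(f"no variant passes the P-threshold {p_threshold:g}")
    return PRSModel(pd.DataFrame(rows), p_threshold, tuple(clump_params))


def score(model: PRSModel, G: GenotypeMatrix) -> PRSScores:
    """Average-per-allele PRS of every sample in ``G``.

    Model entries whose effect allele matches the matrix's other allele are
    flipped (dosage 2 - G, same beta).  Entries absent from the matrix, or
    with irreconcilable alleles, are excluded from both numerator and
    denominator and counted in ``n_unmatched``.
    """
    if len(model) == 0:
        raise ValueError("cannot score with an empty model")
    vindex = G.variant_index()
    betas, cols_matched = [], []
    n_unmatched = 0
    D = []
    for row in model.entries.itertuples(index=False):
        j = vindex.get(row.variant_id)
        if j is None:
            n_unmatched += 1
            continue
        v = G.variants[j]
        col = G.dosages[:, j].astype(float)
        if row.effect_allele == v.effect_allele:
            D.append(col)
        elif v.other_allele is not None and row.effect_allele == v.other_allele:
            D.append(2.0 - col)  # NaN propagates through the flip
        else:
            n_unmatched += 1
            continue
        betas.append(row.beta)
        cols_matched.append(j)
    if not D:
        raise ValueError("no model variant could be matched to the genotype matrix")
    Dm = np.column_stack(D)
    B = np.array(betas)
    contrib = Dm * B
    num = np.nansum(contrib, axis=1)
    m_used = np.isfinite(Dm).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(m_used > 0, num / (2.0 * np.maximum(m_used, 1)), np.nan)
    return PRSScores(
        sample_ids=G.sample_ids, scores=s, m_used=m_used, n_unmatched=n_unmatched
    )


def select_p_threshold(
    train_results: Sequence[AssocResult],
    G_ref: GenotypeMatrix,
    test_G: GenotypeMatrix,
    test_pheno: np.ndarray | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
):
    """Grid search over inclusion thresholds, scored by test-cohort AUC.

    Returns ``(best_threshold, table)`` where the table has one row per grid
    value (threshold, number of model variants, AUC; AUC is NaN for empty
    models).  Ties in AUC resolve to the smaller threshold.
    """
    if not len(grid):
        raise ValueError("threshold grid is empty")
    y = test_G.phenotype_array() if test_pheno is None else np.asarray(test_pheno)
    clumped = clump(train_results, G_ref, r2_threshold, window_kb)
    rows = []
    best_thr, best_auc = None, -np.inf
    for thr in sorted(grid):
        try:
            model = build_model(train_results, clumped, thr, (r2_threshold, window_kb))
        except ValueError:
            rows.append({"p_threshold": thr, "n_variants": 0, "auc": np.nan})
            continue
        sc = score(model, test_G)
        ok = np.isfinite(sc.scores)
        a = auc(sc.scores[ok], y[ok])
        rows.append({"p_threshold": thr, "n_variants": len(model), "auc": a})
        if a > best_auc:  # strict: first (smallest) threshold wins ties
            best_auc, best_thr = a, thr
    if best_thr is None:
        raise ValueError("every grid threshold produced an empty model")
    return best_thr, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class CTPRS(BaseEstimator):
    """Clumping-and-thresholding PRS as a scikit-learn style estimator.

    Parameters
    ----------
    p_threshold : float or "auto"
        Inclusion P-threshold.  With ``"auto"``, call
        :meth:`select_threshold` on an independent cohort after fitting.
    grid : sequence of float
        Candidate thresholds for automatic selection.
    clump_r2, clump_window_kb : float
        Greedy LD-clumping parameters (reference = the training genotypes).

    Fitted attributes (trailing underscore): ``train_results_``,
    ``clumped_ids_``, ``model_``, ``auc_table_``, ``p_threshold_``,
    ``cutoff_report_``, ``cutoff_``.
    """

    def __init__(
        self,
        p_threshold="auto",
        grid: Sequence[float] = DEFAULT_GRID,
        clump_r2: float = 0.1,
        clump_window_kb: float = 250.0,
    ):
        self.p_threshold = p_threshold
        self.grid = grid
        self.clump_r2 = clump_r2
        self.clump_window_kb = clump_window_kb

    def fit(self, G: GenotypeMatrix, y=None, covariates: CovariateSet | None = None):
        """Run the training GWAS and clump; freeze the model if the threshold
        is numeric."""
        self.train_results_, self.skipped_ = gwas(G, covariates=covariates, phenotype=y)
        self.clumped_ids_ = clump(
            self.train_results_, G, self.clump_r2, self.clump_window_kb
        )
        if self.p_threshold != "auto":
            self.p_threshold_ = float(self.p_threshold)
            self.model_ = build_model(
                self.train_results_, self.clumped_ids_, self.p_threshold_,
                (self.clump_r2, self.clump_window_kb),
            )
        return self

    def select_threshold(self, G: GenotypeMatrix, y=None):
        """Pick the inclusion threshold by AUC on an independent cohort."""
        self._check_fitted()
        yv = G.phenotype_array() if y is None else np.asarray(y)
        rows = []
        best_thr, best_auc = None, -np.inf
        for thr in sorted(self.grid):
            try:
                model = build_model(
                    self.train_results_, self.clumped_ids_, thr,
                    (self.clump_r2, self.clump_window_kb),
                )
            except ValueError:
                rows.append({"p_threshold": thr, "n_variants": 0, "auc": np.nan})
                continue
            sc = score(model, G)
            ok = np.isfinite(sc.scores)
            a = auc(sc.scores[ok], yv[ok])
            rows.append({"p_threshold": thr, "n_variants": len(model), "auc": a})
            if a > best_auc:
                best_auc, best_thr = a, thr
        if best_thr is None:
            raise ValueError("every grid threshold produced an empty model")
        self.p_threshold_ = best_thr
        self.auc_table_ = pd.DataFrame(rows)
        self.model_ = build_model(
            self.train_results_, self.clumped_ids_, best_thr,
            (self.clump_r2, self.clump_window_kb),
        )
        return self

    def decision_function(self, G: GenotypeMatrix) -> np.ndarray:
        self._check_fitted()
        if not hasattr(self, "model_"):
            raise ValueError("threshold not selected; call select_threshold first")
        return score(self.model_, G).scores

    def fit_cutoff(self, G: GenotypeMatrix, y=None):
        """Choose the MCC-optimal score cutoff on a labelled cohort."""
        yv = G.phenotype_array() if y is None else np.asarray(y)
        s = self.decision_function(G)
        ok = np.isfinite(s)
        self.cutoff_report_ = best_mcc_cutoff(s[ok], yv[ok])
        self.cutoff_ = self.cutoff_report_.cutoff
        return self

    def predict(self, G: GenotypeMatrix) -> np.ndarray:
        """1 = predicted case (score above the MCC-optimal cutoff)."""
        if not hasattr(self, "cutoff_"):
            raise ValueError("no cutoff fitted; call fit_cutoff first")
        return (self.decision_function(G) > self.cutoff_).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "train_results_"):
            raise ValueError("estimator is not fitted")
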