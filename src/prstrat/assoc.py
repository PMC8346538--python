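"""Per-variant case-control association with sex and principal-component
covariates, plus the odds-ratio heterogeneity test between two analyses.

The association model is the additive-dosage logistic regression

    logit Pr(case) = b0 + b * G + gamma' * covariates

fit by iteratively reweighted least squares (Newton scoring, tolerance 1e-8,
25 iterations) with a Wald test on b.  Rare variants in modest strata often
produce quasi-separation, so non-convergence or fitted probabilities hitting
the boundary trigger a refit with the Firth (Jeffreys-prior) penalty, which
always yields finite estimates.  Missing dosages are mean-imputed per
variant; sex is coded 0/1 with unknown sex mean-imputed so that samples of
undetermined sex remain in the analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

from .cohort import AssocResult, GenotypeMatrix, VariantInfo

_CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, 1))  # 0.4549...


class ConstantVariantError(ValueError):
    """The variant has no dosage variation in the analysis sample set."""


# ---------------------------------------------------------------------------
# Covariates: sex coding, LD pruning, PCA
# ---------------------------------------------------------------------------

@dataclass
class CovariateSet:
    """Per-sample sex code and principal-component coordinates."""

    sample_ids: list[str]
    sex: np.ndarray
    pcs: np.ndarray

    def matrix(self) -> np.ndarray:
        if self.pcs.size:
            return np.column_stack([self.sex, self.pcs])
        return self.sex.reshape(-1, 1)

    @property
    def k(self) -> int:
        return self.pcs.shape[1] if self.pcs.size else 0


def sex_code(samples) -> np.ndarray:
    """male=1, female=0; unknown mean-imputed from the known samples."""
    raw = np.array(
        [1.0 if s.sex == "male" else 0.0 if s.sex == "female" else np.nan
         for s in samples]
    )
    known = raw[np.isfinite(raw)]
    fill = float(known.mean()) if known.size else 0.5
    raw[~np.isfinite(raw)] = fill
    return raw


def _impute_and_freq(col: np.ndarray) -> tuple[np.ndarray, float]:
    x = np.asarray(col, dtype=float).copy()
    ok = np.isfinite(x)
    if not ok.any():
        return x, float("nan")
    mean = float(x[ok].mean())
    x[~ok] = mean
    return x, mean / 2.0


def ld_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """PLINK-style index-window LD pruning on dosage correlation.

    Slides a window of ``window`` variants by ``step``; within each window,
    for every pair with squared correlation above the threshold, the
    later-positioned variant is removed.  Returns the kept variant indices.
    """
    m = G.n_variants
    removed = np.zeros(m, dtype=bool)
    X = np.empty_like(G.dosages, dtype=float)
    for j in range(m):
        X[:, j], _ = _impute_and_freq(G.dosages[:, j])
    start = 0
    while start < m:
        idx = [j for j in range(start, min(start + window, m)) if not removed[j]]
        if len(idx) > 1:
            sub = X[:, idx]
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(sub, rowvar=False)
            r2 = np.nan_to_num(corr) ** 2
            for a in range(len(idx)):
                if removed[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if removed[idx[b]]:
                        continue
                    if r2[a, b] > r2_threshold:
                        removed[idx[b]] = True
        if start + window >= m:
            break
        start += step
    return np.nonzero(~removed)[0]


def compute_pcs(G: GenotypeMatrix, k: int) -> CovariateSet:
    """Principal components of standardized dosages.

    Dosages are mean-imputed, centered, and scaled by sqrt(2 p (1-p));
    constant variants drop out.  PC coordinates are the top-k left singular
    vectors scaled by their singular values; the sign convention makes each
    component's largest-magnitude variant loading positive.  The caller is
    expected to supply common (MAF >= 0.05), LD-pruned variants — see
    :func:`pca_covariates`.
    """
    n, m = G.dosages.shape
    cols = []
    for j in range(m):
        x, p = _impute_and_freq(G.dosages[:, j])
        scale = math.sqrt(2 * p * (1 - p)) if 0 < p < 1 else 0.0
        if scale <= 0 or np.allclose(x, x[0]):
            continue  # constant column contributes nothing
        cols.append((x - x.mean()) / scale)
    if not cols:
        raise ValueError("no variable variants available for PCA")
    X = np.column_stack(cols)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10))
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the dosage matrix")
    for comp in range(k):
        lead = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, lead] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    scores = U[:, :k] * S[:k]
    return CovariateSet(sample_ids=G.sample_ids, sex=sex_code(G.samples), pcs=scores)


def pca_covariates(
    G: GenotypeMatrix,
    k: int,
    maf_min: float = 0.05,
    prune: bool = True,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.2,
) -> CovariateSet:
    """Convenience wrapper: MAF filter + LD pruning + :func:`compute_pcs`."""
    mafs = np.array([_impute_and_freq(G.dosages[:, j])[1] for j in range(G.n_variants)])
    folded = np.minimum(mafs, 1 - mafs)
    keep = np.nonzero(folded >= maf_min)[0]
    if keep.size == 0:
        raise ValueError("no variants pass the PCA MAF filter")
    sub = G.subset_variants(keep)
    if prune:
        kept = ld_prune(sub, window=window, step=step, r2_threshold=r2_threshold)
        sub = sub.subset_variants(kept)
    return compute_pcs(sub, k)


# ---------------------------------------------------------------------------
# Logistic regression (IRLS + Firth fallback)
# ---------------------------------------------------------------------------

def _loglik(y, p):
    eps = 1e-300
    return float(y @ np.log(p + eps) + (1 - y) @ np.log(1 - p + eps))


def _irls(X, y, start=None, tol=1e-8, max_iter=25):
    n, q = X.shape
    beta = np.zeros(q) if start is None else start.copy()
    converged = False
    XtWX = None
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        XtWX = X.T @ (X * w[:, None])
        score = X.T @ (y - p)
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            return beta, None, False, p
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    if XtWX is None:
        return beta, None, False, p
    w = np.clip(p * (1 - p), 1e-12, None)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        return beta, None, False, p
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return beta, se, converged, p


def _firth(X, y, start=None, tol=1e-8, max_iter=50):
    """Firth-penalized logistic fit (Jeffreys prior), Newton with step-halving."""
    n, q = X.shape
    beta = np.zeros(q) if start is None else start.copy()

    def penalized_ll(b):
        p = expit(X @ b)
        w = np.clip(p * (1 - p), 1e-12, None)
        XtWX = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(XtWX)
        return _loglik(y, p) + 0.5 * (logdet if sign > 0 else -np.inf)

    ll = penalized_ll(beta)
    converged = False
    cov = None
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        XtWX = X.T @ (X * w[:, None])
        cov = np.linalg.pinv(XtWX)
        # leverage of the weighted design: h_i = w_i x_i' (X'WX)^-1 x_i
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w
        U = X.T @ (y - p + h * (0.5 - p))
        delta = cov @ U
        step = 1.0
        for _ in range(12):
            ll_new = penalized_ll(beta + step * delta)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        ll = penalized_ll(beta)
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    XtWX = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(XtWX)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return beta, se, converged


def _fit_variant(X, y, start=None):
    """Fit one variant; returns (beta, se, test) for the last column of X."""
    beta, se, converged, p = _irls(X, y, start=start)
    boundary = (p < 1e-8).any() or (p > 1 - 1e-8).any()
    if converged and se is not None and not boundary and np.isfinite(se[-1]) and se[-1] > 0:
        return float(beta[-1]), float(se[-1]), "wald"
    beta, se, _ = _firth(X, y, start=None)
    if not np.isfinite(se[-1]) or se[-1] <= 0:
        raise ConstantVariantError("no information for the variant effect")
    return float(beta[-1]), float(se[-1]), "firth"


def logistic_assoc(
    G: GenotypeMatrix,
    variant,
    covariates: CovariateSet | None = None,
    phenotype: np.ndarray | None = None,
) -> AssocResult:
    """Single-variant additive logistic association (Wald, Firth fallback).

    ``variant`` is a variant id or column index.  The phenotype defaults to
    the matrix's own sample metadata.
    """
    j = G.variant_index()[variant] if isinstance(variant, str) else int(variant)
    y = G.phenotype_array() if phenotype is None else np.asarray(phenotype)
    if len(np.unique(y)) < 2:
        raise ValueError("need both cases and controls")
    x, _ = _impute_and_freq(G.dosages[:, j])
    if np.allclose(x, x[0]):
        raise ConstantVariantError(f"variant {G.variants[j].id} is constant")
    Xc = _design(G, covariates)
    X = np.column_stack([Xc, x])
    beta, se, test = _fit_variant(X, y.astype(float))
    p = 2 * float(norm.sf(abs(beta / se)))
    p = min(max(p, 5e-324), 1.0)
    return AssocResult.from_fit(
        G.variants[j], G.variants[j].effect_allele, len(y), beta, se, p, test=test
    )


def _design(G: GenotypeMatrix, covariates: CovariateSet | None) -> np.ndarray:
    n = G.n_samples
    if covariates is None:
        return np.ones((n, 1))
    if covariates.sample_ids != G.sample_ids:
        raise ValueError("covariate rows do not align with the sample set")
    return np.column_stack([np.ones(n), covariates.matrix()])


def gwas(
    G: GenotypeMatrix,
    covariates: CovariateSet | None = None,
    phenotype: np.ndarray | None = None,
) -> tuple[list[AssocResult], list[tuple[str, str]]]:
    """Per-variant association scan over the whole matrix.

    Constant variants are skipped with a recorded reason rather than aborting
    the scan.  Returns (results, skipped) where skipped is a list of
    (variant id, reason).
    """
    y = G.phenotype_array() if phenotype is None else np.asarray(phenotype)
    if len(np.unique(y)) < 2:
        raise ValueError("need both cases and controls")
    yf = y.astype(float)
    Xc = _design(G, covariates)
    # warm start every per-variant fit from the covariate-only null model
    null_beta, _, null_conv, _ = _irls(Xc, yf)
    start0 = np.append(null_beta if null_conv else np.zeros(Xc.shape[1]), 0.0)
    n, q = Xc.shape
    X = np.empty((n, q + 1))
    X[:, :q] = Xc
    results: list[AssocResult] = []
    skipped: list[tuple[str, str]] = []
    for j, v in enumerate(G.variants):
        x, _ = _impute_and_freq(G.dosages[:, j])
        if not np.isfinite(x).all() or np.allclose(x, x[0]):
            skipped.append((v.id, "constant or all-missing dosage"))
            continue
        X[:, q] = x
        try:
            beta, se, test = _fit_variant(X, yf, start=start0)
        except ConstantVariantError as exc:
            skipped.append((v.id, str(exc)))
            continue
        p = 2 * float(norm.sf(abs(beta / se)))
        p = min(max(p, 5e-324), 1.0)
        results.append(
            AssocResult.from_fit(v, v.effect_allele, n, beta, se, p, test=test)
        )
    return results, skipped


# ---------------------------------------------------------------------------
# Hit filtering, heterogeneity, inflation
# ---------------------------------------------------------------------------

def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


def genome_wide_hits(
    results: Sequence[AssocResult], alpha: float = 5e-8
) -> list[AssocResult]:
    """Records with p <= alpha (inclusive), sorted by (chrom, pos)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    hits = [r for r in results if r.p <= alpha]
    hits.sort(key=lambda r: (_chrom_key(r.variant.chrom), r.variant.pos))
    return hits


@dataclass(frozen=True)
class HetTest:
    """Two-sample z-test of log-odds-ratio heterogeneity.

    z = (beta2 - beta1) / sqrt(se1^2 + se2^2), two-sided normal P.  The two
    analyses are treated as independent; when one stratum is nested in the
    other this is an approximation, retained because it reproduces published
    heterogeneity P-values computed the same way.
    """

    beta1: float
    se1: float
    beta2: float
    se2: float
    z: float
    p_het: float


def _se_from_result(r: AssocResult) -> float:
    if r.se is not None and np.isfinite(r.se) and r.se > 0:
        return float(r.se)
    return math.log(r.u95 / r.l95) / (2 * 1.96)


def or_heterogeneity(r1: AssocResult, r2: AssocResult) -> HetTest:
    """Odds-ratio heterogeneity between two analyses of the same variant.

    Requires matching variant and effect allele (no silent allele flipping).
    Standard errors absent from a record are recovered from its 95% CI using
    the 1.96 normal quantile.
    """
    if r1.variant.id != r2.variant.id:
        raise ValueError(
            f"heterogeneity requires the same variant ({r1.variant.id} vs {r2.variant.id})"
        )
    if r1.effect_allele != r2.effect_allele:
        raise ValueError(
            f"{r1.variant.id}: mismatched effect alleles "
            f"({r1.effect_allele} vs {r2.effect_allele}); flip upstream"
        )
    se1, se2 = _se_from_result(r1), _se_from_result(r2)
    z = (r2.beta - r1.beta) / math.hypot(se1, se2)
    p = 2 * float(norm.sf(abs(z)))
    return HetTest(beta1=r1.beta, se1=se1, beta2=r2.beta, se2=se2, z=z, p_het=min(p, 1.0))


def genomic_inflation(results) -> float:
    """Genomic inflation factor lambda from a set of association P-values.

    lambda = median of the implied 1-df chi-square statistics divided by the
    1-df chi-square median (~0.4549).
    """
    if (not isinstance(results, np.ndarray) and len(results)
            and isinstance(results[0], AssocResult)):
        pvals = np.array([r.p for r in results])
    else:
        pvals = np.asarray(results, dtype=float)
    if pvals.size < 100:
        raise ValueError("need at least 100 P-values for a stable lambda")
    stats = chi2.isf(pvals, 1)
    return float(np.median(stats) / _CHI2_MEDIAN_1DF)
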