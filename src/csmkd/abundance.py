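"""Batch-aware differential-abundance testing and sample-level QC.

The core test is a per-gene negative-binomial (NB2) GLM with a log link,
log-size-factor offsets, batch as a fixed-effect factor and a single condition
coefficient. Significance comes from the likelihood-ratio statistic of the
full (batch + condition) vs reduced (batch only) fit on one chi-square degree
of freedom, with Benjamini-Hochberg correction across genes.

Dispersion is profiled per gene by Cox-Reid adjusted profile likelihood and,
for matrix-wide testing, shrunk toward a fitted mean-dispersion trend in log
space — small designs (3 vs 3) leave too few residual degrees of freedom for
stable per-gene estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError
from .types import CountMatrix, SampleDesign

LN2 = np.log(2.0)
MIN_ALPHA = 1e-8
MAX_ALPHA = 50.0


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference
    (genes with all-positive counts only), normalised to geometric mean 1.
    Falls back to total-count scaling when no gene is positive everywhere."""
    counts = cm.values().astype(float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1)
        factors = np.exp(np.median(logc - ref[:, None], axis=0))
    else:
        warnings.warn("no gene with all-positive counts; using total-count size factors", stacklevel=2)
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise InputError("samples with zero total counts cannot be normalised")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def normalized_counts(cm: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    sf = size_factors(cm) if sf is None else sf
    return cm.counts / sf.reindex(cm.sample_ids).to_numpy()


def log_transform(cm: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    """log2(normalised count + 1), the transform shared by PCA, correlation QC
    and clustering."""
    return np.log2(normalized_counts(cm, sf) + 1.0)


# ---------------------------------------------------------------------------
# NB GLM machinery
# ---------------------------------------------------------------------------


def design_matrix(design: SampleDesign, formula: str, treated: str = "injected") -> pd.DataFrame:
    """Encode ``batch`` or ``batch+condition`` as a full-rank design matrix.

    Batches enter as treatment-coded dummies (first sorted level is the
    reference); the condition column is an indicator for the treated condition,
    so its coefficient is the natural-log fold change treated/reference.
    """
    if formula not in ("batch+condition", "batch"):
        raise ParameterError(f"unknown formula {formula!r}")
    df = design.to_frame()
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df["sample_id"])
    batches = sorted(df["batch"].unique())
    for b in batches[1:]:
        X[f"batch_{b}"] = (df["batch"] == b).astype(float).to_numpy()
    if formula == "batch+condition":
        conditions = sorted(df["condition"].unique())
        if len(conditions) != 2 or treated not in conditions:
            raise InputError(f"need exactly two conditions including {treated!r}, got {conditions}")
        X["condition"] = (df["condition"] == treated).astype(float).to_numpy()
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise InputError("design matrix is rank deficient")
    return X


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    mu = np.clip(mu, 1e-12, None)
    if alpha < MIN_ALPHA:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1) + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def _fit_fixed_alpha(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    family = sm.families.Poisson() if alpha < MIN_ALPHA else sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=family, offset=offset)
        res = model.fit(maxiter=200, tol=1e-9)
    return res


def _cr_adjustment(X: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    w = mu / (1.0 + alpha * mu)
    info = X.T @ (w[:, None] * X)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return -0.5 * logdet


def estimate_dispersion(y: np.ndarray, X: np.ndarray, offset: np.ndarray, n_iter: int = 3) -> float:
    """Cox-Reid adjusted profile likelihood dispersion estimate.

    Alternates a fixed-alpha GLM fit (to update the fitted means) with a
    bounded one-dimensional maximisation of the CR-adjusted NB likelihood over
    log(alpha) holding the means fixed; the means depend only weakly on alpha,
    so a few rounds converge."""
    y = np.asarray(y, dtype=float)
    # method-of-moments start from a Poisson fit
    res = _fit_fixed_alpha(y, X, offset, 0.0)
    mu = np.clip(res.fittedvalues, 1e-8, None)
    num = float(np.sum((y - mu) ** 2 - mu))
    den = float(np.sum(mu**2))
    alpha = min(max(num / den if den > 0 else MIN_ALPHA, MIN_ALPHA), MAX_ALPHA)
    for _ in range(n_iter):
        res = _fit_fixed_alpha(y, X, offset, alpha)
        mu = np.clip(res.fittedvalues, 1e-8, None)

        def neg_apl(log_a: float) -> float:
            a = float(np.exp(log_a))
            return -(_nb_loglik(y, mu, a) + _cr_adjustment(X, mu, a))

        opt = optimize.minimize_scalar(
            neg_apl, bounds=(np.log(MIN_ALPHA), np.log(MAX_ALPHA)), method="bounded",
            options={"xatol": 1e-3},
        )
        new_alpha = float(np.exp(opt.x))
        if abs(np.log(new_alpha) - np.log(alpha)) < 1e-3:
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha


@dataclass
class NBFitResult:
    gene_id: str
    coefficients: dict[str, float]
    log2_fold_change: float | None
    lfc_se: float | None
    dispersion: float
    loglik: float
    converged: bool


def fit_nb_glm(
    y: np.ndarray,
    design: SampleDesign,
    formula: str = "batch+condition",
    offsets: np.ndarray | None = None,
    alpha: float | None = None,
    treated: str = "injected",
    gene_id: str = "",
) -> NBFitResult:
    """Maximum-likelihood NB fit of one gene's counts; dispersion profiled by
    CR-APL when not supplied."""
    y = np.asarray(y, dtype=float)
    Xdf = design_matrix(design, formula, treated=treated)
    X = Xdf.to_numpy()
    if len(y) != X.shape[0]:
        raise InputError("count vector length does not match design")
    offset = np.zeros(len(y)) if offsets is None else np.asarray(offsets, dtype=float)
    try:
        if alpha is None:
            alpha = estimate_dispersion(y, X, offset)
        res = _fit_fixed_alpha(y, X, offset, alpha)
        mu = np.clip(res.fittedvalues, 1e-12, None)
        ll = _nb_loglik(y, mu, alpha)
        converged = bool(getattr(res, "converged", True)) and np.all(np.isfinite(res.params))
        coefs = dict(zip(Xdf.columns, res.params))
        lfc = lfc_se = None
        if "condition" in Xdf.columns:
            i = list(Xdf.columns).index("condition")
            lfc = float(res.params[i]) / LN2
            lfc_se = float(res.bse[i]) / LN2
        return NBFitResult(gene_id, coefs, lfc, lfc_se, float(max(alpha, MIN_ALPHA)), ll, converged)
    except (np.linalg.LinAlgError, ValueError, optimize.OptimizeWarning) as exc:  # noqa: PERF203
        return NBFitResult(gene_id, {}, None, None, float(alpha or MIN_ALPHA), -np.inf, False)


@dataclass
class LrtResult:
    gene_id: str
    lrt_statistic: float
    df: int
    p_value: float
    log2_fold_change: float
    lfc_se: float
    dispersion: float
    converged: bool


def lrt_counts(
    y: np.ndarray,
    design: SampleDesign,
    offsets: np.ndarray | None = None,
    alpha: float | None = None,
    treated: str = "injected",
    gene_id: str = "",
) -> LrtResult:
    """Full (batch+condition) vs reduced (batch) likelihood-ratio test on one
    count vector. The dispersion is estimated once under the full model (or
    given) and shared by both fits; the statistic is clipped at zero and
    referred to chi-square with 1 df."""
    conditions = {s.condition for s in design.samples}
    if len(conditions) < 2:
        # constant condition column: the full model degenerates to the reduced
        reduced = fit_nb_glm(y, design, "batch", offsets, alpha=alpha, gene_id=gene_id)
        return LrtResult(gene_id, 0.0, 1, 1.0, 0.0, np.nan, reduced.dispersion, reduced.converged)
    full = fit_nb_glm(y, design, "batch+condition", offsets, alpha=alpha, treated=treated, gene_id=gene_id)
    reduced = fit_nb_glm(y, design, "batch", offsets, alpha=full.dispersion, treated=treated, gene_id=gene_id)
    ok = full.converged and reduced.converged
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik)) if ok else np.nan
    p = float(stats.chi2.sf(stat, df=1)) if ok else np.nan
    return LrtResult(
        gene_id,
        float(stat),
        1,
        p,
        full.log2_fold_change if full.log2_fold_change is not None else np.nan,
        full.lfc_se if full.lfc_se is not None else np.nan,
        full.dispersion,
        ok,
    )


def lrt_condition(cm: CountMatrix, gene_id: str, design: SampleDesign, treated: str = "injected") -> LrtResult:
    """LRT for one gene of a count matrix, with size-factor offsets computed
    from the whole matrix."""
    cm = cm.align_to(design)
    if gene_id not in cm.counts.index:
        raise KeyError(gene_id)
    sf = size_factors(cm)
    y = cm.counts.loc[gene_id].to_numpy()
    return lrt_counts(y, design, offsets=np.log(sf.to_numpy()), treated=treated, gene_id=gene_id)


# ---------------------------------------------------------------------------
# matrix-wide testing
# ---------------------------------------------------------------------------


def _apl_matrix(Y: np.ndarray, mus: np.ndarray, X: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood for every gene at every grid
    dispersion, holding each gene's fitted means fixed. Returns (G, len(grid))."""
    G, n = Y.shape
    out = np.empty((G, grid.size))
    ly = gammaln(Y + 1.0)
    for j, a in enumerate(grid):
        r = 1.0 / a
        ll = (
            gammaln(Y + r)
            - gammaln(r)
            - ly
            + r * np.log(r / (r + mus))
            + Y * np.log(mus / (r + mus))
        ).sum(axis=1)
        W = mus / (1.0 + a * mus)  # G x n
        info = np.einsum("gn,ni,nj->gij", W, X, X)
        sign, logdet = np.linalg.slogdet(info)
        adj = np.where(sign > 0, -0.5 * logdet, -np.inf)
        out[:, j] = ll + adj
    return out


@dataclass
class DispersionEstimates:
    """Per-gene shrunk dispersions plus the fitted trend and common value."""

    alpha: pd.Series
    trend: pd.Series
    common: float


def estimate_dispersions_matrix(
    cm: CountMatrix,
    design: SampleDesign,
    offsets: np.ndarray,
    genes: list[str] | None = None,
    prior_df: float = 10.0,
    treated: str = "injected",
    n_grid: int = 120,
) -> DispersionEstimates:
    """Ensemble dispersion estimation across a count matrix.

    Each gene's means are fitted once (full model, moderate starting
    dispersion), the CR-adjusted profile likelihood is evaluated on a log grid,
    and the trend is the grid maximiser of the summed APL within abundance
    bins. The per-gene estimate maximises its own APL plus ``prior_df``
    residual-df-equivalents of its bin's average APL (weighted-likelihood
    shrinkage); with few genes everything collapses to the common maximiser.
    """
    Xdf = design_matrix(design, "batch+condition", treated=treated)
    X = Xdf.to_numpy()
    n, p = X.shape
    df_res = max(n - p, 1)
    genes = list(cm.gene_ids) if genes is None else list(genes)
    Y = cm.counts.loc[genes].to_numpy().astype(float)
    mus = np.empty_like(Y)
    for i in range(len(genes)):
        res = _fit_fixed_alpha(Y[i], X, offsets, 0.1)
        mus[i] = np.clip(res.fittedvalues, 1e-8, None)
    grid = np.exp(np.linspace(np.log(1e-6), np.log(MAX_ALPHA), n_grid))
    apl = _apl_matrix(Y, mus, X, grid)

    common = float(grid[np.argmax(apl.mean(axis=0))])

    means = Y.mean(axis=1)
    order = np.argsort(means)
    n_bins = max(1, min(8, len(genes) // 50))
    bins = np.array_split(order, n_bins)
    trend = np.empty(len(genes))
    bin_mean_apl = np.empty((n_bins, grid.size))
    for b, idx in enumerate(bins):
        bin_mean_apl[b] = apl[idx].mean(axis=0)
        trend[idx] = grid[np.argmax(bin_mean_apl[b])]

    w = prior_df / df_res
    alpha = np.empty(len(genes))
    for b, idx in enumerate(bins):
        obj = apl[idx] + w * bin_mean_apl[b][None, :]
        alpha[idx] = grid[np.argmax(obj, axis=1)]
    return DispersionEstimates(
        pd.Series(alpha, index=genes, name="dispersion"),
        pd.Series(trend, index=genes, name="trend"),
        common,
    )


def group_dispersion(member_means: np.ndarray, member_alphas: np.ndarray) -> float:
    """Dispersion of a sum of independent NB genes: the summed variance
    ``sum(mu_i + alpha_i mu_i^2)`` rewritten as NB2 of the summed mean gives
    ``alpha_G = sum(alpha_i mu_i^2) / (sum mu_i)^2``."""
    m = np.asarray(member_means, dtype=float)
    a = np.asarray(member_alphas, dtype=float)
    tot = m.sum()
    if tot <= 0:
        return MIN_ALPHA
    return float(max(np.sum(a * m**2) / tot**2, MIN_ALPHA))


def volcano_table(
    cm: CountMatrix,
    design: SampleDesign,
    method: str = "lrt",
    min_mean: float = 5.0,
    dispersion_mode: str = "shrunk",
    prior_df: float = 10.0,
    treated: str = "injected",
) -> pd.DataFrame:
    """Per-gene LFC and p-value table with BH adjustment.

    Genes whose mean normalised count falls below ``min_mean`` are excluded
    from testing (independent filtering; status ``low_count``). ``method`` is
    ``lrt`` (default) or ``wald``. ``dispersion_mode``: ``shrunk`` (per-gene
    CR-APL shrunk toward the mean-dispersion trend with ``prior_df`` prior
    weight), ``per-gene``, or ``common``.
    """
    if method not in ("lrt", "wald"):
        raise ParameterError("method must be 'lrt' or 'wald'")
    if dispersion_mode not in ("shrunk", "per-gene", "common"):
        raise ParameterError("unknown dispersion_mode")
    cm = cm.align_to(design)
    sf = size_factors(cm)
    offsets = np.log(sf.to_numpy())
    norm_means = normalized_counts(cm, sf).mean(axis=1)

    genes = cm.gene_ids
    tested = [g for g in genes if norm_means[g] >= min_mean]
    if not tested:
        skipped = pd.DataFrame({"gene": genes, "status": "low_count"})
        for c in ("base_mean", "lfc", "se", "stat", "p", "dispersion", "padj"):
            skipped[c] = np.nan
        return skipped

    est = estimate_dispersions_matrix(cm, design, offsets, genes=tested, prior_df=prior_df, treated=treated)
    if dispersion_mode == "per-gene":
        est = estimate_dispersions_matrix(cm, design, offsets, genes=tested, prior_df=0.0, treated=treated)
        final_alpha = est.alpha.to_numpy()
    elif dispersion_mode == "common":
        final_alpha = np.full(len(tested), est.common)
    else:
        final_alpha = est.alpha.to_numpy()

    rows = []
    for g, a in zip(tested, final_alpha):
        y = cm.counts.loc[g].to_numpy()
        a = None if not np.isfinite(a) else float(a)
        res = lrt_counts(y, design, offsets=offsets, alpha=a, treated=treated, gene_id=g)
        if method == "wald" and res.converged and res.lfc_se > 0:
            z = res.log2_fold_change / res.lfc_se
            p = float(2.0 * stats.norm.sf(abs(z)))
            stat = z * z
        else:
            p, stat = res.p_value, res.lrt_statistic
        rows.append(
            {
                "gene": g,
                "base_mean": float(norm_means[g]),
                "lfc": res.log2_fold_change,
                "se": res.lfc_se,
                "stat": stat,
                "p": p,
                "dispersion": res.dispersion,
                "status": "ok" if res.converged else "fit_failed",
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        mask = table["status"].eq("ok") & table["p"].notna()
        padj = np.full(len(table), np.nan)
        if mask.any():
            padj[mask.to_numpy()] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
        table["padj"] = padj
    else:
        table = pd.DataFrame(columns=["gene", "base_mean", "lfc", "se", "stat", "p", "dispersion", "status", "padj"])
    skipped = pd.DataFrame(
        {
            "gene": [g for g in genes if g not in set(tested)],
            "status": "low_count",
        }
    )
    out = pd.concat([table, skipped], ignore_index=True)
    return out.set_index("gene").reindex(genes).reset_index()


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    coordinates: pd.DataFrame
    variance_pct: np.ndarray
    degenerate: bool


def pca_samples(cm: CountMatrix) -> PcaResult:
    """Centered PCA of samples on the log2(normalised+1) transform."""
    if len(cm.sample_ids) < 3:
        raise InputError("PCA needs at least 3 samples")
    X = log_transform(cm).to_numpy().T  # samples x genes
    if np.allclose(X.var(axis=0).sum(), 0.0):
        return PcaResult(pd.DataFrame(index=cm.sample_ids), np.array([]), True)
    pca = PCA(n_components=None, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        pd.DataFrame(coords, index=cm.sample_ids, columns=cols),
        pca.explained_variance_ratio_ * 100.0,
        False,
    )


def correlation_qc(cm: CountMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples on the PCA transform."""
    if len(cm.sample_ids) < 2:
        raise InputError("correlation QC needs at least 2 samples")
    X = log_transform(cm)
    return X.corr(method="pearson")


def depth_qc(cm: CountMatrix, floor: float = 1e7) -> pd.Series:
    """Pass/fail per sample: total assigned counts >= floor."""
    return cm.counts.sum(axis=0) >= float(floor)


def cluster_samples(cm: CountMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering on 1 - Pearson distance over the
    PCA transform; returns the scipy linkage matrix and the sample order."""
    if len(cm.sample_ids) < 3:
        raise InputError("clustering needs at least 3 samples")
    corr = correlation_qc(cm).to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, cm.sample_ids
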