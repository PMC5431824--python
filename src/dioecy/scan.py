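"""Per-SNP association scan of genotype against binary sex.

The workhorse is the Cochran-Armitage / score trend test on allele dosage
(statistic N*r^2 against chi-square with 1 df, where r is the Pearson
correlation of dosage with the 0/1 sex indicator over complete cases);
a per-SNP logistic regression with a likelihood-ratio test of the dosage
term is available as an alternative. Both accept nuisance covariates
(principal components of the non-sex-associated genotype matrix) for
population-structure correction. Family-wise error is controlled by
Bonferroni over the SNPs that survive the minor-allele-frequency and
call-rate filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, StructuralError
from .types import GenotypeMatrix

# reason codes for SNPs whose test is undefined
REASON_OK = ""
REASON_CONSTANT = "constant_dosage"
REASON_ONE_CLASS = "one_sex_class"
REASON_TOO_FEW = "too_few_complete_cases"
REASON_SEPARATION = "perfect_separation"


@dataclass
class FilterSettings:
    """SNP inclusion thresholds: MAF >= maf_min and call rate >= call_rate_min."""

    maf_min: float = 0.05
    call_rate_min: float = 0.9

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int = 1
    reason: str = REASON_OK
    separation: bool = False

    @property
    def defined(self) -> bool:
        return self.reason in (REASON_OK, REASON_SEPARATION)


def snp_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP minor-allele frequency and call rate.

    MAF is computed on non-missing calls as min(freq_ALT, 1 - freq_ALT);
    a fully missing SNP gets MAF nan and call rate 0.
    """
    if G.n_snps == 0 or G.n_samples == 0:
        raise StructuralError("empty genotype matrix")
    d = G.dosages
    n_called = np.sum(~np.isnan(d), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_freq = np.nansum(d, axis=0) / (2.0 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf[n_called == 0] = np.nan
    return pd.DataFrame({
        "id": G.snps["id"].to_numpy(),
        "maf": maf,
        "call_rate": n_called / G.n_samples,
    })


def filter_snps(G: GenotypeMatrix, settings: FilterSettings | None = None
                ) -> pd.DataFrame:
    """Apply MAF / call-rate filters; returns per-SNP stats with a pass mask."""
    settings = settings or FilterSettings()
    out = snp_stats(G)
    out["passed_filters"] = (
        (out["maf"].to_numpy() >= settings.maf_min)
        & (out["call_rate"].to_numpy() >= settings.call_rate_min)
        & ~np.isnan(out["maf"].to_numpy())
    )
    return out


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residual of v after OLS projection on [1, covariates]."""
    n = v.shape[0]
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def trend_test(dosage, y, covariates=None) -> TestResult:
    """Score (Cochran-Armitage trend) test of dosage against binary sex.

    Complete cases only. The statistic is N*r^2 with r the Pearson
    correlation of dosage and y (partial correlation given the covariates,
    when supplied); p comes from chi-square with 1 df. Undefined cases
    (one sex class absent, constant dosage, <2 samples per class) return a
    flagged result with a reason code instead of raising.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(dosage) & ~np.isnan(y)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != dosage.shape[0]:
            covariates = covariates.T
        keep &= ~np.isnan(covariates).any(axis=1)
    d, yy = dosage[keep], y[keep]
    n = d.size
    n1 = int(yy.sum())
    if n1 < 2 or n - n1 < 2:
        return TestResult(np.nan, np.nan, reason=REASON_ONE_CLASS)
    if np.ptp(d) == 0:
        return TestResult(np.nan, np.nan, reason=REASON_CONSTANT)
    C = covariates[keep] if covariates is not None else None
    dr = _residualize(d, C)
    yr = _residualize(yy, C)
    denom = np.sqrt((dr * dr).sum() * (yr * yr).sum())
    if denom == 0:
        return TestResult(np.nan, np.nan, reason=REASON_CONSTANT)
    r = float((dr * yr).sum() / denom)
    stat = n * r * r
    return TestResult(stat, float(stats.chi2.sf(stat, 1)))


def _logistic_ll(y: np.ndarray, X: np.ndarray) -> float:
    """ML log-likelihood of a logistic regression (statsmodels backend)."""
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return float(fit.llf)


def logistic_assoc(dosage, y, covariates=None) -> TestResult:
    """Likelihood-ratio test of the dosage term in a logistic model of sex.

    Fully sex-linked SNPs separate the classes perfectly; the MLE then
    diverges, so the result carries a ``separation`` flag and the p-value is
    the deviance bound: the saturated-dosage log-likelihood is capped at 0
    and the LRT statistic at -2*ll(reduced). Such SNPs remain maximally
    significant rather than failing.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(dosage) & ~np.isnan(y)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != dosage.shape[0]:
            covariates = covariates.T
        keep &= ~np.isnan(covariates).any(axis=1)
    d, yy = dosage[keep], y[keep]
    n = d.size
    n1 = int(yy.sum())
    if n1 < 2 or n - n1 < 2:
        return TestResult(np.nan, np.nan, reason=REASON_ONE_CLASS)
    if np.ptp(d) == 0:
        return TestResult(np.nan, np.nan, reason=REASON_CONSTANT)
    C = covariates[keep] if covariates is not None else None
    X0 = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ConfigError("covariates are rank-deficient")
    X1 = np.column_stack([X0, d])

    ll0 = _logistic_ll(yy, X0)
    # complete separation: the two classes' dosage ranges do not overlap
    separated = (d[yy == 1].min() > d[yy == 0].max()
                 or d[yy == 1].max() < d[yy == 0].min())
    if separated:
        stat = max(0.0, -2.0 * ll0)   # cap ll(full) at 0
        return TestResult(stat, float(stats.chi2.sf(stat, 1)),
                          reason=REASON_SEPARATION, separation=True)
    try:
        ll1 = _logistic_ll(yy, X1)
    except Exception:
        stat = max(0.0, -2.0 * ll0)
        return TestResult(stat, float(stats.chi2.sf(stat, 1)),
                          reason=REASON_SEPARATION, separation=True)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return TestResult(stat, float(stats.chi2.sf(stat, 1)))


@dataclass
class PCAResult:
    scores: np.ndarray        # n_samples x k
    loadings: np.ndarray      # n_snps_used x k
    eigenvalues: np.ndarray   # length k
    snp_ids: list             # SNPs entering the decomposition


def genotype_pca(G: GenotypeMatrix, exclude=None, k: int = 2) -> PCAResult:
    """PCA of the mean-imputed, per-SNP standardized dosage matrix.

    ``exclude`` masks SNPs (e.g. sex-associated ones) out of the
    decomposition. Deterministic up to sign; the sign of each component is
    fixed so that its largest-magnitude SNP loading is positive.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        G = G.take_snps(~exclude)
    d = G.dosages.copy()
    if d.size == 0:
        raise StructuralError("no SNPs left for PCA")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    d -= col_mean
    sd = d.std(axis=0, ddof=1)
    keep = sd > 0
    d = d[:, keep] / sd[keep]
    snp_ids = list(G.snps["id"].to_numpy()[keep])

    U, S, Vt = np.linalg.svd(d, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    if k > rank:
        raise ConfigError(f"k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    # sign convention: the largest-|loading| entry of each PC is positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    eig = (S[:k] ** 2) / max(G.n_samples - 1, 1)
    return PCAResult(scores=scores, loadings=loadings,
                     eigenvalues=eig, snp_ids=snp_ids)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test p threshold controlling family-wise error at alpha over m tests."""
    if m < 1:
        raise ConfigError("number of tests m must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise ConfigError(f"alpha must be in (0, 1], got {alpha!r}")
    return alpha / m


def run_scan(G: GenotypeMatrix, samples: pd.DataFrame, *,
             test: str = "trend", pca_correction: int = 0,
             alpha: float = 0.05, filters: FilterSettings | None = None,
             min_known: int = 20) -> pd.DataFrame:
    """Genome-wide sex-association scan.

    Uses samples with a known sex label ('F'/'M'), applies the MAF/call-rate
    filters, runs the chosen per-SNP test, and marks Bonferroni significance
    at ``alpha`` over the number of SNPs actually tested. When
    ``pca_correction`` = k > 0, the top-k principal components of the
    background genotype matrix enter the model as covariates (SNPs are
    scanned in a first unadjusted pass and those reaching Bonferroni
    significance are excluded from the PCA, so the components capture
    population structure, not the SDR).

    Returns a DataFrame ordered by p-value (undefined tests last) with
    columns ``chrom, pos, id, maf, call_rate, stat, df, p, passed_filters,
    significant_bonferroni, reason, separation, rank``.
    """
    if test not in ("trend", "logistic"):
        raise ConfigError(f"test must be 'trend' or 'logistic', got {test!r}")
    sex = samples.set_index("sample_id")["sex"].astype(str).str.upper().str[0]
    known = sex[sex.isin(["F", "M"])]
    known = known[known.index.isin(G.samples)]
    if len(known) < min_known:
        raise StructuralError(
            f"only {len(known)} samples with known sex; need >= {min_known}")
    Gk = G.take_samples(list(known.index))
    y = (known == "M").to_numpy(float)
    if y.min() == y.max():
        raise StructuralError("both sex classes must be present")

    table = filter_snps(Gk, filters)
    passed = table["passed_filters"].to_numpy()

    covs = None
    if pca_correction > 0:
        base = _scan_pass(Gk, y, passed, test="trend", covs=None)
        m_tested = int(np.sum(passed & ~np.isnan(base["p"])))
        thr = bonferroni_threshold(alpha, max(m_tested, 1))
        sexassoc = passed & (np.nan_to_num(base["p"], nan=1.0) < thr)
        covs = genotype_pca(Gk, exclude=sexassoc, k=pca_correction).scores

    res = _scan_pass(Gk, y, passed, test=test, covs=covs)
    m_tested = int(np.sum(passed & ~np.isnan(res["p"])))
    thr = bonferroni_threshold(alpha, max(m_tested, 1))

    out = pd.DataFrame({
        "chrom": Gk.snps["chrom"], "pos": Gk.snps["pos"], "id": Gk.snps["id"],
        "maf": table["maf"], "call_rate": table["call_rate"],
        "stat": res["stat"], "df": 1, "p": res["p"],
        "passed_filters": passed,
        "reason": res["reason"], "separation": res["separation"],
    })
    out["significant_bonferroni"] = (
        passed & (np.nan_to_num(out["p"].to_numpy(), nan=1.0) < thr))
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["n_tested"] = m_tested
    out = out.sort_values(
        ["p", "chrom", "pos"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _scan_pass(G: GenotypeMatrix, y: np.ndarray, passed: np.ndarray, *,
               test: str, covs) -> dict:
    m = G.n_snps
    stat = np.full(m, np.nan)
    p = np.full(m, np.nan)
    reason = np.array([""] * m, dtype=object)
    sep = np.zeros(m, dtype=bool)
    fn = trend_test if test == "trend" else logistic_assoc
    for j in np.flatnonzero(passed):
        r = fn(G.dosages[:, j], y, covariates=covs)
        stat[j], p[j] = r.statistic, r.p_value
        reason[j], sep[j] = r.reason, r.separation
    return {"stat": stat, "p": p, "reason": reason, "separation": sep}
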