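"""Sexual-dimorphism test battery for quantitative traits.

Each trait is tested for a sex effect while correcting for geographic
population structure (latitude/longitude, or genotype-PCA axes where
available). Traits with clonal ramet replication use a Gaussian linear mixed
model with a genotype random intercept; unreplicated traits use ordinary
linear models. Models are fitted by maximum likelihood (not REML) so that
likelihood-ratio tests on fixed effects are valid, covariate sets are chosen
by BIC, sex-by-geography interactions are screened and retained only when
significant, and effect sizes are reported as omega-squared (a bias-adjusted
share of total trait variance) computed on genotype-mean collapsed data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ModelError

# numeric covariate terms; interactions are written "sex:latitude" etc.
_NUMERIC = ("latitude", "longitude", "PC1", "PC2")
_BINARY = {"sex": ("sex", "M"), "scenario": ("scenario", "later"),
           "temperature": ("temperature", 20)}


@dataclass(frozen=True)
class ModelSpec:
    """A model formula: response, ordered fixed terms, optional genotype
    random intercept."""

    response: str = "value"
    fixed_terms: tuple = ()
    random_terms: tuple = ()

    def __post_init__(self):
        for t in self.fixed_terms:
            if ":" in t:
                a, b = t.split(":", 1)
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise ModelError(
                        f"interaction {t!r} requires both main effects present")
        for t in self.random_terms:
            if t != "genotype":
                raise ModelError(f"unsupported random term {t!r}")


@dataclass
class ModelFit:
    """A fitted model: ML log-likelihood, BIC and the data it was fit on."""

    spec: ModelSpec
    params: pd.Series
    varcomp: dict
    log_likelihood: float
    n_obs: int
    n_params: int
    boundary: bool = False
    data: pd.DataFrame | None = field(default=None, repr=False)
    row_signature: int = 0

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n_obs)


def _term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    if term in _NUMERIC or term == "planting_year":
        return data[term].to_numpy(float)
    if term in _BINARY:
        col, hi = _BINARY[term]
        v = data[col]
        if term == "sex":
            return (v.astype(str).str.upper().str[0] == "M").to_numpy(float)
        if term == "temperature":
            return (v.to_numpy(float) == np.max(v.to_numpy(float))).astype(float)
        return (v.astype(str) == str(hi)).to_numpy(float)
    raise ModelError(f"unknown model term {term!r}")


def build_design(data: pd.DataFrame, fixed_terms) -> tuple:
    """Intercept + one column per term; interactions are products.

    Returns (X, column_names). Raises :class:`ModelError` naming the
    collinear terms when the design is rank-deficient.
    """
    cols, names = [np.ones(len(data))], ["Intercept"]
    for term in fixed_terms:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(_term_column(data, a) * _term_column(data, b))
        else:
            cols.append(_term_column(data, term))
        names.append(term)
    X = np.column_stack(cols)
    # incremental rank check to name the offending terms
    bad = []
    r = 1
    for j in range(1, X.shape[1]):
        rj = np.linalg.matrix_rank(X[:, :j + 1])
        if rj == r:
            bad.append(names[j])
        r = rj
    if bad:
        raise ModelError(f"rank-deficient design; collinear terms: {bad}")
    return X, names


def _complete_cases(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    need = {spec.response}
    for t in spec.fixed_terms:
        for part in t.split(":"):
            need.add(_BINARY[part][0] if part in _BINARY else part)
    if spec.random_terms:
        need.add("genotype_id")
    missing = need - set(data.columns)
    if missing:
        raise ModelError(f"data lacks columns {sorted(missing)}")
    return data.dropna(subset=sorted(need))


def _row_signature(data: pd.DataFrame) -> int:
    return hash(tuple(data.index.to_list()))


def fit_lm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Ordinary least squares with the Gaussian ML log-likelihood.

    n_params counts the mean parameters plus the residual variance, so
    BIC = -2 logL + n_params ln(n).
    """
    if spec.random_terms:
        raise ModelError("fit_lm takes no random terms; use fit_lmm")
    d = _complete_cases(data, spec)
    if len(d) < 3:
        raise ModelError(f"only {len(d)} complete cases")
    y = d[spec.response].to_numpy(float)
    X, names = build_design(d, spec.fixed_terms)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n          # ML estimate
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return ModelFit(
        spec=spec, params=pd.Series(beta, index=names),
        varcomp={"residual": sigma2},
        log_likelihood=llf, n_obs=n, n_params=X.shape[1] + 1,
        data=d, row_signature=_row_signature(d))


def fit_lmm(data: pd.DataFrame, spec: ModelSpec,
            boundary_tol: float = 1e-4) -> ModelFit:
    """Gaussian mixed model with a genotype random intercept, fitted by ML.

    A near-zero genotype variance (relative to total) marks the fit as a
    boundary solution rather than raising.
    """
    import statsmodels.regression.mixed_linear_model as mlm

    if spec.random_terms != ("genotype",):
        raise ModelError("fit_lmm requires random_terms=('genotype',)")
    d = _complete_cases(data, spec)
    groups = d["genotype_id"].to_numpy()
    counts = pd.Series(groups).value_counts()
    if (counts >= 2).sum() < 2:
        raise ModelError("need >= 2 genotypes with >= 2 ramets for a mixed model")
    y = d[spec.response].to_numpy(float)
    X, names = build_design(d, spec.fixed_terms)
    fit = None
    last_exc: Exception | None = None
    # optimizers differ in robustness to covariate scaling; try in turn
    for method in ("lbfgs", "bfgs", "cg", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = mlm.MixedLM(y, X, groups=groups).fit(
                    reml=False, method=method)
            break
        except Exception as exc:   # singular Hessian, non-convergence
            last_exc = exc
    if fit is None:
        raise ModelError(f"mixed-model fit failed: {last_exc}")
    var_g = float(np.asarray(fit.cov_re)[0, 0])
    var_e = float(fit.scale)
    total = var_g + var_e
    return ModelFit(
        spec=spec, params=pd.Series(np.asarray(fit.fe_params), index=names),
        varcomp={"genotype": var_g, "residual": var_e},
        log_likelihood=float(fit.llf), n_obs=len(y),
        n_params=X.shape[1] + 2,
        boundary=bool(total > 0 and var_g / total < boundary_tol),
        data=d, row_signature=_row_signature(d))


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Dispatch to the LM or LMM engine by the spec's random terms."""
    return fit_lmm(data, spec) if spec.random_terms else fit_lm(data, spec)


def lrt(full: ModelFit, reduced: ModelFit) -> float:
    """Likelihood-ratio p-value for nested ML fits on identical rows.

    The statistic 2*(llf_full - llf_reduced) is clamped at zero; df is the
    difference in parameter counts. Identical specs give p = 1.
    """
    if full.row_signature != reduced.row_signature or full.n_obs != reduced.n_obs:
        raise ModelError("LRT requires both models fit on identical rows")
    if not set(reduced.spec.fixed_terms) <= set(full.spec.fixed_terms):
        raise ModelError("reduced model is not nested in the full model")
    if reduced.spec.random_terms != full.spec.random_terms:
        raise ModelError("LRT compares fixed effects; random terms must match")
    df = full.n_params - reduced.n_params
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    if df <= 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def select_model_bic(data: pd.DataFrame, specs) -> ModelFit:
    """Fit every candidate on the identical complete-case rows and return the
    minimum-BIC fit; ties break toward fewer parameters."""
    specs = list(specs)
    if not specs:
        raise ModelError("no candidate models")
    # common complete-case rows across all candidates
    rows = None
    for spec in specs:
        d = _complete_cases(data, spec)
        rows = d.index if rows is None else rows.intersection(d.index)
    common = data.loc[rows]
    fits = [fit_model(common, spec) for spec in specs]
    sigs = {f.row_signature for f in fits}
    if len(sigs) != 1:
        raise ModelError("candidates were fit on differing row sets")
    return min(fits, key=lambda f: (round(f.bic, 10), f.n_params))


def omega_squared(fit: ModelFit, term: str) -> dict:
    """Bias-adjusted variance share of one fixed term in an OLS fit.

    omega^2 = (SS_term - df_term * MS_error) / (SS_total + MS_error), with
    SS_term the type-II sum of squares (RSS without the term, all other
    terms retained, minus RSS of the full model). Returns the raw value and
    the value clamped to [0, 1] for reporting.
    """
    if fit.spec.random_terms:
        raise ModelError("omega_squared is defined for OLS fits")
    if term not in fit.spec.fixed_terms:
        raise ModelError(f"term {term!r} not in the fitted model")
    d = fit.data
    y = d[fit.spec.response].to_numpy(float)
    n = len(y)

    def rss(terms):
        X, _ = build_design(d, terms)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    full_terms = fit.spec.fixed_terms
    # drop the term and any interaction containing it (marginality)
    reduced_terms = tuple(
        t for t in full_terms
        if t != term and term not in t.split(":"))
    rss_full, k_full = rss(full_terms)
    rss_red, k_red = rss(reduced_terms)
    ss_term = max(0.0, rss_red - rss_full)
    df_term = k_full - k_red
    df_err = n - k_full
    if df_err <= 0:
        raise ModelError("no residual degrees of freedom")
    ms_err = rss_full / df_err
    if ms_err <= 0:
        return {"raw": np.nan, "reported": np.nan, "undefined": True}
    ss_total = float(np.sum((y - y.mean()) ** 2))
    raw = (ss_term - df_term * ms_err) / (ss_total + ms_err)
    return {"raw": raw, "reported": float(np.clip(raw, 0.0, 1.0)),
            "undefined": False}


@dataclass
class DimorphismResult:
    """Per-trait outcome of the dimorphism pipeline."""

    trait: str
    engine: str = ""
    covariates: tuple = ()
    p_interaction: float = np.nan
    interaction_retained: bool = False
    p_sex: float = np.nan
    omega2_sex: float = np.nan
    omega2_sex_raw: float = np.nan
    omega2_geography: float = np.nan
    significant_nominal: bool = False
    repeatable: bool | None = None
    n_obs: int = 0
    status: str = "ok"
    boundary: bool = False


def _has_replication(d: pd.DataFrame) -> bool:
    return bool((d["genotype_id"].value_counts() >= 2).sum() >= 2)


def genotype_means(d: pd.DataFrame, extra_cols=()) -> pd.DataFrame:
    """Collapse a trait table to one row per genotype (mean value; metadata
    from the genotype's first row)."""
    keep = ["sex", "latitude", "longitude", "PC1", "PC2", "planting_year",
            "site", "year", *extra_cols]
    keep = [c for c in keep if c in d.columns]
    g = d.groupby("genotype_id", sort=True)
    out = g[keep].first()
    out["value"] = g["value"].mean()
    return out.reset_index()


def test_trait(table: pd.DataFrame, trait: str,
               geography_mode: str = "latlon", *,
               interaction_alpha: float = 0.05,
               select_covariates: bool = True,
               forced_covariates: tuple | None = None) -> DimorphismResult:
    """Full per-trait pipeline: engine choice, BIC covariate selection,
    interaction screen, sex LRT and omega-squared partition.

    ``select_covariates=False`` with ``forced_covariates`` fits exactly the
    given geographic terms (used, e.g., to demonstrate confounding when
    geography is deliberately omitted).
    """
    if geography_mode not in ("latlon", "pcs"):
        raise ModelError(f"geography_mode must be 'latlon' or 'pcs'")
    d = table[table["trait"] == trait].dropna(subset=["value"]).copy()
    sex = d["sex"].astype(str).str.upper().str[0]
    if (sex == "F").sum() < 3 or (sex == "M").sum() < 3:
        return DimorphismResult(trait=trait, status="insufficient_data",
                                n_obs=len(d))

    geo_pool = ("latitude", "longitude") if geography_mode == "latlon" else ("PC1", "PC2")
    geo_pool = tuple(g for g in geo_pool
                     if g in d.columns and d[g].notna().any()
                     and d[g].nunique() > 1)
    extra = tuple(
        t for t in ("planting_year",)
        if t in d.columns and d[t].notna().any() and d[t].nunique() > 1)

    engine = "lmm" if _has_replication(d) else "lm"
    random = ("genotype",) if engine == "lmm" else ()

    def spec(terms):
        return ModelSpec(fixed_terms=tuple(terms), random_terms=random)

    if select_covariates:
        candidates = []
        for r in range(len(geo_pool) + 1):
            for combo in itertools.combinations(geo_pool, r):
                candidates.append(spec((*combo, *extra)))
        best = select_model_bic(d, candidates)
        geo = tuple(t for t in best.spec.fixed_terms if t in geo_pool)
    else:
        geo = tuple(forced_covariates or ())

    base_terms = (*geo, *extra)
    ints = tuple(f"sex:{g}" for g in geo)

    p_int, retained = np.nan, False
    if ints:
        full_i = fit_model(d, spec((*base_terms, "sex", *ints)))
        red_i = fit_model(full_i.data, spec((*base_terms, "sex")))
        p_int = lrt(full_i, red_i)
        retained = p_int < interaction_alpha

    if retained:
        full = fit_model(d, spec((*base_terms, "sex", *ints)))
        reduced = fit_model(full.data, spec(base_terms))
    else:
        full = fit_model(d, spec((*base_terms, "sex")))
        reduced = fit_model(full.data, spec(base_terms))
    p_sex = lrt(full, reduced)

    # effect sizes on genotype-mean collapsed OLS fit
    gm = genotype_means(full.data)
    om_terms = (*geo, "sex")
    om_fit = fit_lm(gm, ModelSpec(fixed_terms=om_terms))
    om_sex = omega_squared(om_fit, "sex")
    om_geo = 0.0
    for g in geo:
        r = omega_squared(om_fit, g)
        if not r["undefined"]:
            om_geo += r["reported"]

    return DimorphismResult(
        trait=trait, engine=engine, covariates=base_terms,
        p_interaction=p_int, interaction_retained=retained,
        p_sex=p_sex,
        omega2_sex=om_sex["reported"], omega2_sex_raw=om_sex["raw"],
        omega2_geography=om_geo if geo else np.nan,
        significant_nominal=bool(p_sex < 0.05),
        n_obs=full.n_obs, boundary=full.boundary)


def run_battery(table: pd.DataFrame, traits=None,
                geography_mode: str = "latlon", **kwargs) -> pd.DataFrame:
    """Run :func:`test_trait` over many traits; adds Benjamini-Hochberg
    q-values over the nominal sex p-values as a convenience column."""
    from statsmodels.stats.multitest import multipletests

    if traits is None:
        traits = sorted(table["trait"].unique())
    results = [test_trait(table, t, geography_mode, **kwargs) for t in traits]
    out = pd.DataFrame([{
        "trait": r.trait, "engine": r.engine,
        "covariates": ",".join(r.covariates),
        "p_interaction": r.p_interaction, "p_sex": r.p_sex,
        "omega2_sex": r.omega2_sex, "omega2_geo": r.omega2_geography,
        "significant_nominal": r.significant_nominal,
        "n_obs": r.n_obs, "status": r.status,
    } for r in results])
    ok = out["p_sex"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = multipletests(
            out.loc[ok, "p_sex"], method="fdr_bh")[1]
    return out


def multi_site_battery(tables_by_stratum: dict, trait: str,
                       geography_mode: str = "latlon", **kwargs) -> dict:
    """Test one trait independently per stratum (site/year) on genotype
    means; report per-stratum p and omega^2 and whether the sex effect is
    repeatable (nominally significant in every stratum)."""
    if len(tables_by_stratum) < 2:
        raise ModelError("multi-site battery needs >= 2 strata")
    per_stratum = {}
    for name, tab in tables_by_stratum.items():
        d = tab[tab["trait"] == trait]
        gm = genotype_means(d)
        gm["trait"] = trait
        gm["genotype_id"] = gm["genotype_id"].to_numpy()
        per_stratum[name] = test_trait(gm, trait, geography_mode, **kwargs)
    ok = [r for r in per_stratum.values() if r.status == "ok"]
    repeatable = bool(ok) and all(r.significant_nominal for r in ok)
    for r in per_stratum.values():
        r.repeatable = repeatable
    return {
        "trait": trait,
        "per_stratum": per_stratum,
        "p_sex": {k: r.p_sex for k, r in per_stratum.items()},
        "omega2_sex": {k: r.omega2_sex for k, r in per_stratum.items()},
        "repeatable": repeatable,
    }


def factorial_response_test(table: pd.DataFrame,
                            trait: str | None = None) -> dict:
    """Paired 2x2 warming experiment: scenario x temperature mixed model with
    a genotype random intercept; LRT p-values for the scenario-by-temperature
    interaction, for sex, and for the sex-by-design interactions."""
    d = table if trait is None else table[table["trait"] == trait]
    d = d.dropna(subset=["value"]).copy()
    cells = d.groupby(["scenario", "temperature"], observed=True).size()
    if len(cells) < 4:
        raise ModelError(
            f"factorial design incomplete: {len(cells)}/4 cells present")

    random = ("genotype",)
    base = ("scenario", "temperature", "scenario:temperature", "sex")

    def fit(terms, data):
        return fit_lmm(data, ModelSpec(fixed_terms=terms, random_terms=random))

    full = fit(base, d)
    rows = full.data
    p_scen_temp = lrt(full, fit(
        ("scenario", "temperature", "sex"), rows))
    p_sex = lrt(full, fit(
        ("scenario", "temperature", "scenario:temperature"), rows))
    p_sex_scen = lrt(fit((*base, "sex:scenario"), rows), full)
    p_sex_temp = lrt(fit((*base, "sex:temperature"), rows), full)
    return {
        "p_scenario_temperature": p_scen_temp,
        "p_sex": p_sex,
        "p_sex_scenario": p_sex_scen,
        "p_sex_temperature": p_sex_temp,
        "n_obs": full.n_obs,
        "varcomp": full.varcomp,
    }
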