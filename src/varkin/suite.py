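"""Eight-model GBLUP family: fitting, boundary-corrected LRT selection, variance ratios.

Model codes combine the additive term (A, always present) with dominance
(D), maternal (M, identity covariance over dams) and additive-by-additive
epistasis (E): A, AD, AE, AM, ADE, ADM, AME, ADME. Each model also carries
fixed effects and (by default) the genomic-homozygosity covariate capturing
directional dominance.

Sub-models are compared to the full ADME model with likelihood-ratio tests
whose null distribution is a mixture of χ² distributions (boundary
correction for variance components tested at zero): with q omitted
components the mixture weights are binomial(q, i)/2^q on χ²_i, i = 0..q,
where χ²_0 is a point mass at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .kernels import RelationshipMatrix, legarra_factor
from .reml import FitResult, KernelREML, ModelSpec, ratio_se

__all__ = [
    "MODEL_CODES",
    "LETTER_TERMS",
    "build_model",
    "ModelSuite",
    "SuiteResult",
    "RatioSet",
    "fit_suite",
    "mixture_critical_value",
    "mixture_pvalue",
    "variance_ratios",
    "fullsib_excess_variance",
    "build_design",
]

LETTER_TERMS = {"D": "dominance", "E": "epistatic_aa", "M": "maternal"}
EXTENSION_TERMS = {"ad": "epistatic_ad", "dd": "epistatic_dd"}

#: The standard eight-model family, keyed by code, valued by random terms.
MODEL_CODES: dict[str, tuple[str, ...]] = {
    "A": ("additive",),
    "AD": ("additive", "dominance"),
    "AE": ("additive", "epistatic_aa"),
    "AM": ("additive", "maternal"),
    "ADE": ("additive", "dominance", "epistatic_aa"),
    "ADM": ("additive", "dominance", "maternal"),
    "AME": ("additive", "epistatic_aa", "maternal"),
    "ADME": ("additive", "dominance", "epistatic_aa", "maternal"),
}

CANONICAL_TERMS = ("additive", "dominance", "epistatic_aa", "maternal", "residual")
#: model that drops exactly one letter from the full ADME model
DROP_ONE = {"D": "AME", "E": "ADM", "M": "ADE"}
#: canonical code for a set of letters
LETTERS_TO_CODE = {
    frozenset(): "A",
    frozenset("D"): "AD",
    frozenset("E"): "AE",
    frozenset("M"): "AM",
    frozenset("DE"): "ADE",
    frozenset("DM"): "ADM",
    frozenset("EM"): "AME",
    frozenset("DEM"): "ADME",
}
RATIO_NUMERATORS = {
    "h2": ("additive",),
    "d2": ("dominance",),
    "m2": ("maternal",),
    "e2aa": ("epistatic_aa",),
    "H2": ("additive", "dominance", "epistatic_aa"),
}


def parse_model_code(code: str) -> tuple[str, ...]:
    """Random terms for a model code; extensions like ``ADME+ad+dd`` allowed."""
    base, *ext = code.split("+")
    if base not in MODEL_CODES:
        raise ValueError(
            f"unknown model code {base!r}; valid codes: {sorted(MODEL_CODES)}"
        )
    terms = list(MODEL_CODES[base])
    for e in ext:
        if e not in EXTENSION_TERMS:
            raise ValueError(f"unknown model extension {e!r}; valid: ad, dd")
        terms.append(EXTENSION_TERMS[e])
    return tuple(terms)


def build_model(
    code: str,
    kernels: Mapping[str, RelationshipMatrix],
    dam_factor: str = "dam",
    include_homozygosity: bool = True,
    response: str = "y",
    fixed_factors: Sequence[str] = (),
) -> ModelSpec:
    """Assemble a :class:`~varkin.reml.ModelSpec` for a model code.

    Kernel-backed terms must be present in ``kernels``; the maternal term is
    an identity covariance over the levels of ``dam_factor``.
    """
    terms = parse_model_code(code)
    random_terms: list[tuple[str, object]] = []
    for t in terms:
        if t == "maternal":
            random_terms.append(("maternal", dam_factor))
        else:
            if t not in kernels:
                raise ValueError(f"model {code!r} needs kernel {t!r}")
            random_terms.append((t, kernels[t]))
    return ModelSpec(
        response=response,
        fixed_factors=list(fixed_factors),
        covariates=["homozygosity"] if include_homozygosity else [],
        random_terms=random_terms,
        include_homozygosity=include_homozygosity,
    )


# ------------------------------------------------------------- mixture chi2
def _mixture_weights(n_components: int) -> np.ndarray:
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    q = n_components
    return np.array([math.comb(q, i) / 2.0**q for i in range(q + 1)])


def mixture_pvalue(n_components: int, lrt_stat: float) -> float:
    """Tail probability of the boundary-corrected χ² mixture at ``lrt_stat``.

    Statistics in [−1e−6, 0) are clamped to 0 (numerical slack); a zero
    statistic has p = 1 (the point mass at zero is in the tail).
    """
    if lrt_stat < -1e-6:
        raise ValueError(f"negative LRT statistic {lrt_stat}")
    stat = max(lrt_stat, 0.0)
    w = _mixture_weights(n_components)
    if stat <= 0.0:
        return 1.0
    return float(sum(w[i] * chi2.sf(stat, df=i) for i in range(1, len(w))))


def mixture_critical_value(n_components: int, alpha: float) -> float:
    """Critical value c with Σ_i w_i P(χ²_i > c) = ``alpha`` for the mixture."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    w = _mixture_weights(n_components)
    if alpha >= 1.0 - w[0]:
        return 0.0

    def tail(c: float) -> float:
        return sum(w[i] * chi2.sf(c, df=i) for i in range(1, len(w))) - alpha

    return float(brentq(tail, 1e-12, 200.0, xtol=1e-10, rtol=1e-12))


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ------------------------------------------------------------------ ratios
@dataclass
class RatioSet:
    """Phenotypic variance and variance ratios with delta-method SEs.

    Components are Legarra-corrected (each multiplied by the mean-diagonal
    minus grand-mean of its kernel) before summing to σ²_P, so that all
    ratios refer to genetic variance within the study population. Terms not
    in the model contribute zero.
    """

    sigma_p: float
    ratios: dict[str, float]
    ratio_se: dict[str, float | None]
    corrected_components: dict[str, float]
    factors: dict[str, float]
    sigma_p_se: float | None = None

    def __getitem__(self, key: str) -> float:
        return self.ratios[key]

    def to_dict(self) -> dict:
        return {
            "sigma_p": self.sigma_p,
            "sigma_p_se": self.sigma_p_se,
            "ratios": dict(self.ratios),
            "ratio_se": dict(self.ratio_se),
            "corrected_components": dict(self.corrected_components),
            "legarra_factors": dict(self.factors),
        }


def ratio_set_from_components(
    components: Mapping[str, float],
    covariance: np.ndarray | None = None,
    cov_terms: Sequence[str] | None = None,
    factors: Mapping[str, float] | None = None,
) -> RatioSet:
    """Build a :class:`RatioSet` from (possibly Legarra-corrected) components.

    Used both on fit results and on components transcribed from published
    tables. ``covariance`` is the sampling covariance of the raw components
    over ``cov_terms`` (factors are propagated through it).
    """
    factors = dict(factors or {})
    corrected = {t: 0.0 for t in CANONICAL_TERMS}
    for t, v in components.items():
        corrected[t] = v * factors.get(t, 1.0)
    sigma_p = sum(corrected.values())
    if sigma_p <= 0:
        raise ValueError("sigma_P is non-positive; ratios undefined")
    ratios: dict[str, float] = {}
    ses: dict[str, float | None] = {}
    cov_c = None
    terms_c: list[str] = []
    sigma_p_se = None
    if covariance is not None and cov_terms is not None and len(cov_terms) > 0:
        F = np.diag([factors.get(t, 1.0) for t in cov_terms])
        cov_c = F @ np.asarray(covariance, dtype=float) @ F
        terms_c = list(cov_terms)
        ones = np.ones(len(terms_c))
        sigma_p_se = float(np.sqrt(max(ones @ cov_c @ ones, 0.0)))
    for name, num_terms in RATIO_NUMERATORS.items():
        r = sum(corrected[t] for t in num_terms) / sigma_p
        ratios[name] = r
        if cov_c is not None:
            _, se = ratio_se(corrected, cov_c, terms_c, num_terms)
            ses[name] = se
        else:
            ses[name] = None
    return RatioSet(sigma_p, ratios, ses, corrected, factors, sigma_p_se)


def variance_ratios(
    fit: FitResult,
    kernels: Mapping[str, RelationshipMatrix] | None = None,
    apply_legarra: bool = True,
) -> RatioSet:
    """Variance ratios (h², d², m², e²aa, H²) with SEs from a fit.

    With ``apply_legarra`` each component is multiplied by its kernel's
    reference-population factor (1 for identity-covariance terms such as the
    maternal and residual, and ≈1 for NOIA kernels by construction).
    """
    if not fit.converged:
        raise ValueError("fit did not converge; ratios not computed")
    factors: dict[str, float] = {}
    if apply_legarra and kernels:
        for t in fit.components:
            if t in kernels:
                factors[t] = legarra_factor(kernels[t])
    try:
        C, free = fit.component_covariance()
    except (ValueError, np.linalg.LinAlgError):
        C, free = None, None
    return ratio_set_from_components(fit.components, C, free, factors)


def fullsib_excess_variance(
    sigma_d2: float, sigma_eaa2: float, sigma_ead2: float = 0.0, sigma_edd2: float = 0.0
) -> float:
    """Extra within-full-sib-family variance beyond parental additive variance.

    Full sibs share ¼ of dominance and ⅛ of each pairwise epistatic variance:
    ¼σ²_D + ⅛σ²_Eaa + ⅛σ²_Ead + ⅛σ²_Edd.
    """
    vals = (sigma_d2, sigma_eaa2, sigma_ead2, sigma_edd2)
    if any(v < 0 for v in vals):
        raise ValueError("variance components must be non-negative")
    return 0.25 * sigma_d2 + 0.125 * (sigma_eaa2 + sigma_ead2 + sigma_edd2)


# ------------------------------------------------------------------ design
def build_design(
    data: pd.DataFrame,
    fixed_factors: Sequence[str],
    covariates: Sequence[str] = (),
) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed-effects design: intercept, treatment-coded factors, covariates.

    The first level of each factor is the reference; factors with a single
    observed level are dropped with a warning.
    """
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    for f in fixed_factors:
        levels = pd.unique(data[f])
        if len(levels) < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped", stacklevel=2)
            continue
        levels = sorted(levels, key=str)
        for lev in levels[1:]:
            cols.append((data[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    for c in covariates:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


# ------------------------------------------------------------------- suite
@dataclass
class SuiteResult:
    """All eight fits, LRTs vs the full ADME model, and the selected model."""

    trait: str
    approach: str
    fits: dict[str, FitResult]
    table: pd.DataFrame  # model, n_terms, df, logL, lrt, p, stars, converged
    best_model: str
    alpha: float
    kernels: dict[str, RelationshipMatrix] = field(default_factory=dict, repr=False)
    apply_legarra: bool = True

    def ratios(self, model: str | None = None) -> RatioSet:
        code = model or self.best_model
        return variance_ratios(self.fits[code], self.kernels, self.apply_legarra)

    def render(self) -> str:
        lines = [f"trait {self.trait} ({self.approach} approach)"]
        lines.append(f"{'model':<6}{'logL':>12}{'LRT':>10}{'d.f.':>6}{'p':>10}  sig")
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['model']:<6}{r['logL']:>12.3f}{r['lrt']:>10.3f}"
                f"{int(r['df']):>6}{r['p']:>10.4f}  {r['stars']}"
            )
        lines.append(f"best model: {self.best_model}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "approach": self.approach,
            "alpha": self.alpha,
            "best_model": self.best_model,
            "table": self.table.to_dict(orient="records"),
            "fits": {code: fit.to_dict() for code, fit in self.fits.items()},
            "ratios_best": self.ratios().to_dict(),
        }


class ModelSuite(BaseEstimator):
    """Fit the eight-model GBLUP family for one trait and select the best model.

    Parameters
    ----------
    approach
        Which kernel parameterization tag is being fitted ('noia' or 'hwe');
        informational, the kernels themselves are passed to :meth:`fit`.
    include_homozygosity
        Fit the genomic-homozygosity covariate (directional dominance).
    alpha
        Significance level of the boundary-corrected LRT used for selection.
    codes
        Model codes to fit (default: the standard eight).
    apply_legarra
        Rescale components to the study population when reporting ratios.
    selection
        ``"drop_one"`` (default): a variance component is retained when
        dropping it alone from the full model is rejected by the df-1
        boundary-corrected LRT; the best model is the additive model plus
        the retained letters. ``"parsimonious"``: the most parsimonious
        model whose LRT against ADME is not rejected at ``alpha``, ties
        broken by fewer variance components.
    """

    def __init__(
        self,
        approach: str = "noia",
        include_homozygosity: bool = True,
        alpha: float = 0.05,
        codes: Sequence[str] = tuple(MODEL_CODES),
        apply_legarra: bool = True,
        selection: str = "drop_one",
        max_iter: int = 100,
        verbose: int = 0,
    ) -> None:
        self.approach = approach
        self.include_homozygosity = include_homozygosity
        self.alpha = alpha
        self.codes = codes
        self.apply_legarra = apply_legarra
        self.selection = selection
        self.max_iter = max_iter
        self.verbose = verbose

    def fit(
        self,
        data: pd.DataFrame,
        trait: str,
        kernels: Mapping[str, RelationshipMatrix],
        fixed_factors: Sequence[str] = (),
        dam_col: str = "dam",
        id_col: str = "id",
        hom_col: str = "homozygosity",
    ):
        """Fit all models on individuals with complete trait/factor records.

        ``kernels`` must carry ids; rows of ``data`` are matched on
        ``id_col`` and the kernels aligned to the phenotyped subset.
        """
        codes = list(self.codes)
        full = "ADME"
        if full not in codes:
            raise ValueError("suite requires the full ADME model")
        needed = [trait, dam_col, id_col] + list(fixed_factors)
        if self.include_homozygosity:
            needed.append(hom_col)
        sub = data.dropna(subset=needed).copy()
        n_dropped = len(data) - len(sub)
        if n_dropped and self.verbose:
            print(f"dropped {n_dropped} individuals with missing records for {trait}")
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 usable records for trait {trait!r}")

        ref = next(iter(kernels.values()))
        if ref.ids is None:
            raise ValueError("kernels must carry individual ids for alignment")
        genotyped = set(ref.ids)
        sub = sub[sub[id_col].astype(str).isin(genotyped)]
        ids = sub[id_col].astype(str).tolist()
        aligned = {name: k.align(ids) for name, k in kernels.items()}

        covs = [hom_col] if self.include_homozygosity else []
        X, names = build_design(sub, fixed_factors, covs)
        y = sub[trait].to_numpy(dtype=float)

        fits: dict[str, FitResult] = {}
        theta_full: dict[str, float] = {}
        # fit the full model first; warm-start sub-models from it
        order = [full] + [c for c in codes if c != full]
        for code in order:
            terms = parse_model_code(code)
            kern = {
                t: aligned[t].values for t in terms if t != "maternal"
            }
            grp = {"maternal": sub[dam_col].astype(str).tolist()} if "maternal" in terms else None
            est = KernelREML(kernels=kern, groups=grp, max_iter=self.max_iter)
            est.feature_names_ = names
            theta0 = None
            if theta_full:
                vals = [theta_full.get(t, 0.0) for t in terms]
                dropped = sum(v for t, v in theta_full.items() if t not in terms and t != "residual")
                theta0 = np.array(vals + [theta_full["residual"] + dropped])
            est.fit(X, y, theta0=theta0)
            fits[code] = est.result(names)
            if code == full:
                theta_full = dict(est.variance_components_)

        rows = []
        logl_full = fits[full].logL
        n_full = len(parse_model_code(full))
        for code in codes:
            fit = fits[code]
            n_terms = len(parse_model_code(code))
            df = n_full - n_terms
            lrt = max(2.0 * (logl_full - fit.logL), 0.0) if code != full else 0.0
            if code != full and 2.0 * (logl_full - fit.logL) < -1e-6:
                warnings.warn(
                    f"sub-model {code} logL exceeds ADME by "
                    f"{fit.logL - logl_full:.2e}; check convergence",
                    stacklevel=2,
                )
            p = 1.0 if df == 0 else mixture_pvalue(df, lrt)
            rows.append(
                {
                    "model": code,
                    "n_terms": n_terms,
                    "df": df,
                    "logL": fit.logL,
                    "lrt": lrt,
                    "p": p,
                    "stars": _stars(p) if code != full else "",
                    "converged": fit.converged,
                }
            )
        table = pd.DataFrame(rows)

        if not table["converged"].all():
            bad = table.loc[~table["converged"], "model"].tolist()
            warnings.warn(f"non-converged fits excluded from selection: {bad}", stacklevel=2)
        tab = table.set_index("model")
        if self.selection == "drop_one":
            kept = set()
            for letter, drop_code in DROP_ONE.items():
                if drop_code not in fits or not tab.loc[drop_code, "converged"]:
                    kept.add(letter)  # cannot assess: keep conservatively
                    continue
                if tab.loc[drop_code, "p"] < self.alpha:
                    kept.add(letter)
            best = LETTERS_TO_CODE[frozenset(kept)]
        elif self.selection == "parsimonious":
            candidates = table[table["converged"]].sort_values(["n_terms", "model"])
            best = full
            for _, r in candidates.iterrows():
                if r["p"] >= self.alpha:
                    best = r["model"]
                    break
        else:
            raise ValueError(f"unknown selection rule {self.selection!r}")

        self.result_ = SuiteResult(
            trait=trait,
            approach=self.approach,
            fits=fits,
            table=table,
            best_model=best,
            alpha=self.alpha,
            kernels=dict(kernels),
            apply_legarra=self.apply_legarra,
        )
        self.best_model_ = best
        return self


def fit_suite(
    trait: str,
    kernels: Mapping[str, RelationshipMatrix],
    data: pd.DataFrame,
    approach: str = "noia",
    **kwargs,
) -> SuiteResult:
    """Functional wrapper: fit the eight-model family and return a :class:`SuiteResult`."""
    fit_kwargs = {
        k: kwargs.pop(k)
        for k in ("fixed_factors", "dam_col", "id_col", "hom_col")
        if k in kwargs
    }
    suite = ModelSuite(approach=approach, **kwargs)
    suite.fit(data, trait, kernels, **fit_kwargs)
    return suite.result_
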