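"""Confirmatory factor analysis of the clinical FTD items.

A congeneric three-correlated-factor model (each item loads on exactly one
factor; loadings, uniquenesses and factor correlations free; factor
variances fixed to 1), fit by maximum-likelihood discrepancy minimisation on
the item correlation matrix.  The default item-to-factor map assigns the
SANS items to *emptiness* and splits the SAPS items between
*disorganization* and *incoherence*; the map is configurable because the
assignment derives from prior validation work, not from this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .factors import FactorAnalysisError, factor_scores, FactorSolution

FTD_FACTORS = ("disorganization", "emptiness", "incoherence")

#: Default item -> factor assignment (editable; see module docstring).
DEFAULT_FTD_MODEL: dict[str, str] = {
    "derailment": "disorganization",
    "tangentiality": "disorganization",
    "circumstantiality": "disorganization",
    "pressure_of_speech": "disorganization",
    "distractibility": "disorganization",
    "poverty_of_speech": "emptiness",
    "poverty_of_content": "emptiness",
    "blocking": "emptiness",
    "increased_latency": "emptiness",
    "incoherence": "incoherence",
    "illogicality": "incoherence",
    "clanging": "incoherence",
}


@dataclass
class CfaModel:
    """Item-to-factor assignment for a congeneric CFA."""

    assignment: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FTD_MODEL))
    factors: tuple[str, ...] = FTD_FACTORS

    def __post_init__(self) -> None:
        unknown = {f for f in self.assignment.values() if f not in self.factors}
        if unknown:
            raise ValueError(f"items assigned to unknown factors: {unknown}")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def pattern_mask(self) -> np.ndarray:
        """Boolean p x k matrix of which loading is free."""
        items = self.items
        mask = np.zeros((len(items), len(self.factors)), dtype=bool)
        for i, item in enumerate(items):
            mask[i, self.factors.index(self.assignment[item])] = True
        return mask

    def n_free_parameters(self) -> int:
        p, k = len(self.items), len(self.factors)
        return p + p + k * (k - 1) // 2  # loadings + uniquenesses + factor corrs

    def degrees_of_freedom(self) -> int:
        p = len(self.items)
        return p * (p + 1) // 2 - self.n_free_parameters()


@dataclass
class CfaFit:
    """Fitted CFA: estimates, fit statistics and factor scores."""

    model: CfaModel
    loadings: np.ndarray
    factor_correlations: np.ndarray
    uniquenesses: np.ndarray
    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    srmr: float
    n: int
    scores: np.ndarray | None = None
    heywood: bool = False


def _implied(lam: np.ndarray, phi: np.ndarray, psi: np.ndarray,
             mask: np.ndarray) -> np.ndarray:
    L = np.zeros(mask.shape)
    L[mask] = lam
    return L @ phi @ L.T + np.diag(psi)


def _phi_from_params(z: np.ndarray, k: int) -> np.ndarray:
    phi = np.eye(k)
    iu = np.triu_indices(k, 1)
    phi[iu] = np.tanh(z)
    phi[(iu[1], iu[0])] = np.tanh(z)
    return phi


def _ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e6
    sign_s, logdet_s = np.linalg.slogdet(S)
    p = S.shape[0]
    try:
        tr = np.trace(linalg.solve(sigma, S, assume_a="sym"))
    except linalg.LinAlgError:
        return 1e6
    return float(logdet_sigma + tr - logdet_s - p)


def fit_cfa(item_matrix: np.ndarray, model: CfaModel | None = None,
            item_names: tuple[str, ...] | None = None,
            compute_scores: bool = True) -> CfaFit:
    """Fit the congeneric correlated-factor model to an n x p item matrix.

    Items enter through their sample Pearson correlation matrix.  Reported
    fit statistics: the likelihood-ratio chi-square ``(n-1) * F_ML``, CFI
    against the independence baseline, RMSEA, and SRMR over the lower
    triangle of the residual correlation matrix.
    """
    model = model or CfaModel()
    X = np.asarray(item_matrix, dtype=float)
    if item_names is not None:
        missing = [it for it in model.items if it not in item_names]
        if missing:
            raise FactorAnalysisError(f"modeled items absent from data: {missing}")
        X = X[:, [item_names.index(it) for it in model.items]]
    elif X.shape[1] != len(model.items):
        raise FactorAnalysisError(
            f"item matrix has {X.shape[1]} columns but the model names "
            f"{len(model.items)} items"
        )
    n, p = X.shape
    if n <= model.n_free_parameters():
        raise FactorAnalysisError("too few observations for the free parameters")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise FactorAnalysisError("zero-variance item column")
    S = np.corrcoef(X, rowvar=False)
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise FactorAnalysisError("item correlation matrix not positive definite")

    mask = model.pattern_mask()
    p_items, k = mask.shape
    n_phi = k * (k - 1) // 2

    def unpack(theta):
        lam = theta[:p_items]
        psi = theta[p_items:2 * p_items]
        phi = _phi_from_params(theta[2 * p_items:], k)
        return lam, psi, phi

    def objective(theta):
        lam, psi, phi = unpack(theta)
        return _ml_discrepancy(S, _implied(lam, phi, psi, mask))

    theta0 = np.concatenate([
        np.full(p_items, 0.6), np.full(p_items, 0.6), np.zeros(n_phi)
    ])
    bounds = ([(-2.0, 2.0)] * p_items + [(1e-3, 2.0)] * p_items
              + [(-3.0, 3.0)] * n_phi)
    res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                            bounds=bounds, options={"maxiter": 2000})
    if not res.success and res.fun > 1e5:
        raise FactorAnalysisError(f"CFA did not converge: {res.message}")
    lam, psi, phi = unpack(res.x)
    heywood = bool(np.any(psi <= 1e-3 + 1e-12))

    L = np.zeros(mask.shape)
    L[mask] = lam
    # orient each factor so its loadings are predominantly positive
    signs = np.sign(L.sum(axis=0))
    signs[signs == 0] = 1.0
    L = L * signs
    phi = phi * np.outer(signs, signs)

    F = res.fun
    chi2 = (n - 1) * F
    df = model.degrees_of_freedom()
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # independence baseline: Sigma = I for a correlation input
    F_base = _ml_discrepancy(S, np.eye(p_items))
    chi2_base = (n - 1) * F_base
    df_base = p_items * (p_items - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, num, 1e-12)
    cfi = 1.0 - num / den
    rmsea = np.sqrt(num / (df * (n - 1))) if df > 0 else 0.0
    resid = S - _implied(lam, phi, psi, mask)
    tril = np.tril_indices(p_items)
    srmr = float(np.sqrt(np.mean(resid[tril] ** 2)))

    scores = None
    if compute_scores:
        sol = FactorSolution(
            loadings=L, factor_correlations=phi,
            uniquenesses=np.clip(psi, 1e-3, 1.0),
            variance_explained=np.diag(phi @ L.T @ L) / p_items,
            total_variance_explained=float(
                np.sum(np.diag(phi @ L.T @ L)) / p_items),
            method="ml", rotation="none",
        )
        scores = factor_scores(sol, X)
    return CfaFit(
        model=model, loadings=L, factor_correlations=phi, uniquenesses=psi,
        chi2=float(chi2), df=df, p_value=p_value, cfi=float(cfi),
        rmsea=float(rmsea), srmr=srmr, n=n, scores=scores, heywood=heywood,
    )
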