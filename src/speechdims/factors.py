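"""Exploratory factor analysis of the speech-feature matrix.

Suitability diagnostics (correlation/VIF screen, KMO, Bartlett's sphericity),
factor-number selection by multiple empirical criteria, extraction by
unweighted least squares / maximum likelihood / principal axis factoring,
varimax and promax rotation, case-resampling bootstrap with congruence-based
column alignment, multi-method solution averaging, and regression factor
scores.

Conventions: the correlation matrix R is always the analysis input
(features are standardised implicitly); oblique solutions are reported as
pattern matrices with factor correlation matrix Phi; columns are ordered by
explained variance with the sign fixed so each column's largest-magnitude
loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from scipy.optimize import linear_sum_assignment


class FactorAnalysisError(RuntimeError):
    """Numerical failure or contract violation in the factor stage."""


# ---------------------------------------------------------------------------
# Suitability diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CorrelationScreen:
    """Multicollinearity screen: correlations and variance inflation factors."""

    R: np.ndarray
    max_abs_offdiag: float
    vif: np.ndarray
    flags: list[str] = field(default_factory=list)

    CORR_LIMIT = 0.80
    VIF_LIMIT = 5.0


def screen_features(X: np.ndarray) -> CorrelationScreen:
    """Pearson correlations and VIFs of an n x p feature matrix.

    ``vif_j = 1/(1 - R^2_j)`` with ``R^2_j`` from regressing feature j on all
    the others; a singular design yields an infinite VIF sentinel plus a flag.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise FactorAnalysisError(f"need n > p, got n={n}, p={p}")
    if np.any(X.std(axis=0) == 0):
        raise FactorAnalysisError("constant feature column in screen input")
    R = np.corrcoef(X, rowvar=False)
    off = R[~np.eye(p, dtype=bool)]
    max_off = float(np.max(np.abs(off))) if p > 1 else 0.0

    vif = np.empty(p)
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    for j in range(p):
        others = np.delete(Z, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, Z[:, j], rcond=None)
        resid = Z[:, j] - others @ coef
        r2 = 1.0 - resid @ resid / (Z[:, j] @ Z[:, j])
        vif[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)

    flags = []
    if max_off > CorrelationScreen.CORR_LIMIT:
        flags.append(f"max |r| = {max_off:.3f} exceeds 0.80")
    if np.any(np.isinf(vif)):
        flags.append("singular design: infinite VIF")
    elif np.any(vif >= CorrelationScreen.VIF_LIMIT):
        flags.append(f"max VIF = {np.max(vif):.2f} >= 5")
    return CorrelationScreen(R=R, max_abs_offdiag=max_off, vif=vif, flags=flags)


def kmo(R: np.ndarray) -> dict[str, object]:
    """Kaiser-Meyer-Olkin sampling adequacy from anti-image correlations.

    With S = R^-1, the partial (anti-image) correlation is
    ``q_ij = -S_ij / sqrt(S_ii S_jj)``; overall KMO is the ratio of summed
    squared correlations to summed squared correlations plus squared
    partials, off-diagonal only.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    try:
        S = linalg.inv(R)
    except linalg.LinAlgError as exc:
        raise FactorAnalysisError("singular correlation matrix in KMO") from exc
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)
    mask = ~np.eye(p, dtype=bool)
    r2 = R[mask] ** 2
    q2 = Q[mask] ** 2
    denom = r2.sum() + q2.sum()
    if denom == 0:
        raise FactorAnalysisError("KMO undefined for an identity correlation matrix")
    per = np.empty(p)
    for j in range(p):
        rj = np.delete(R[j], j) ** 2
        qj = np.delete(Q[j], j) ** 2
        dj = rj.sum() + qj.sum()
        per[j] = rj.sum() / dj if dj > 0 else np.nan
    return {"overall": float(r2.sum() / denom), "per_variable": per}


def bartlett_sphericity(R: np.ndarray, n: int) -> dict[str, float]:
    """Bartlett's test that R is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det R on p(p-1)/2 degrees of freedom.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise FactorAnalysisError("non-positive determinant in Bartlett's test")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return {"chi2": float(chi2), "df": float(df),
            "p": float(stats.chi2.sf(chi2, df))}


# ---------------------------------------------------------------------------
# Factor-number selection
# ---------------------------------------------------------------------------

def _parallel_analysis(X: np.ndarray, rng: np.random.Generator,
                       n_sim: int = 50, quantile: float = 95.0) -> int:
    n, p = X.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    sims = np.empty((n_sim, p))
    for b in range(n_sim):
        Z = rng.standard_normal((n, p))
        sims[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresh = np.percentile(sims, quantile, axis=0)
    k = 0
    for lam, t in zip(obs, thresh):
        if lam > t:
            k += 1
        else:
            break
    return k


def _velicer_map(R: np.ndarray, max_k: int) -> int:
    """Velicer's minimum-average-partial criterion."""
    p = R.shape[0]
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    fm = []
    mask = ~np.eye(p, dtype=bool)
    fm0 = np.mean(R[mask] ** 2)
    for m in range(1, max_k + 1):
        L = eigvec[:, :m] * np.sqrt(np.maximum(eigval[:m], 0))
        C = R - L @ L.T
        d = np.sqrt(np.diag(C))
        if np.any(d < 1e-8):
            break
        P = C / np.outer(d, d)
        fm.append(np.mean(P[mask] ** 2))
    if not fm:
        return 0
    best = int(np.argmin(fm)) + 1
    return 0 if fm0 < min(fm) else best


def select_n_factors(X: np.ndarray, seed: int,
                     max_k: int | None = None) -> dict[str, object]:
    """Factor count by majority vote of Kaiser, parallel analysis and MAP.

    Ties (no majority) are resolved in favour of Horn's parallel analysis.
    A vote of 0 factors overall is an error demanding an explicit k.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_k = max_k or max(1, p // 2)
    R = np.corrcoef(X, rowvar=False)
    rng = np.random.default_rng(seed)
    votes = {
        "kaiser": int(np.sum(np.linalg.eigvalsh(R) > 1.0)),
        "parallel_analysis": _parallel_analysis(X, rng),
        "map": _velicer_map(R, max_k),
    }
    counts: dict[int, int] = {}
    for v in votes.values():
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    if top >= 2:
        k = max(kk for kk, c in counts.items() if c == top)
    else:
        k = votes["parallel_analysis"]
    if k == 0:
        raise FactorAnalysisError(
            f"no common factor supported by the criteria (votes: {votes}); "
            "supply k explicitly"
        )
    return {"k": int(k), "votes": votes}


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

_PSI_FLOOR = 1e-3


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (communality start values)."""
    try:
        Rinv = linalg.inv(R)
        return np.clip(1.0 - 1.0 / np.diag(Rinv), 0.0, 1.0 - _PSI_FLOOR)
    except linalg.LinAlgError:
        return np.full(R.shape[0], 0.5)


def _loadings_from_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    Rs = R.copy()
    np.fill_diagonal(Rs, 1.0 - psi)
    eigval, eigvec = np.linalg.eigh(Rs)
    order = np.argsort(eigval)[::-1][:k]
    vals = np.maximum(eigval[order], 0.0)
    return eigvec[:, order] * np.sqrt(vals)


def _uls_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    L = _loadings_from_psi(R, psi, k)
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return float(np.sum(resid ** 2))


def _ml_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    sp = np.sqrt(psi)
    Rt = R / np.outer(sp, sp)
    eigval = np.sort(np.linalg.eigvalsh(Rt))[::-1]
    tail = np.maximum(eigval[k:], 1e-12)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _ml_loadings(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    sp = np.sqrt(psi)
    Rt = R / np.outer(sp, sp)
    eigval, eigvec = np.linalg.eigh(Rt)
    order = np.argsort(eigval)[::-1][:k]
    vals = np.maximum(eigval[order] - 1.0, 0.0)
    return (eigvec[:, order] * np.sqrt(vals)) * sp[:, None]


def _extract(R: np.ndarray, k: int, method: str,
             max_iter: int = 1000) -> tuple[np.ndarray, bool]:
    """Unrotated loadings by the requested discrepancy; returns (L, heywood)."""
    p = R.shape[0]
    psi0 = 1.0 - _smc(R)
    bounds = [(_PSI_FLOOR, 1.0)] * p
    if method in ("uls", "ml"):
        fun = _uls_objective if method == "uls" else _ml_objective
        res = optimize.minimize(fun, psi0, args=(R, k), method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": max_iter})
        if not res.success and res.nit >= max_iter:
            raise FactorAnalysisError(
                f"{method} extraction failed to converge after {res.nit} iterations"
            )
        psi = res.x
        L = (_loadings_from_psi(R, psi, k) if method == "uls"
             else _ml_loadings(R, psi, k))
    elif method == "paf":
        h2 = _smc(R)
        for _ in range(max_iter):
            L = _loadings_from_psi(R, 1.0 - h2, k)
            h2_new = np.clip(np.sum(L ** 2, axis=1), 0.0, 1.0)
            if np.max(np.abs(h2_new - h2)) < 1e-7:
                h2 = h2_new
                break
            h2 = h2_new
        L = _loadings_from_psi(R, 1.0 - h2, k)
    else:
        raise ValueError(f"unknown extraction method {method!r}")

    h2 = np.sum(L ** 2, axis=1)
    heywood = bool(np.any(h2 > 1.0 - _PSI_FLOOR + 1e-12))
    if heywood:  # rescale offending rows so psi stays >= the floor
        scale = np.sqrt(np.minimum(1.0, (1.0 - _PSI_FLOOR) / np.maximum(h2, 1e-12)))
        L = L * scale[:, None]
    return L, heywood


# ---------------------------------------------------------------------------
# Rotation
# ---------------------------------------------------------------------------

def varimax(L: np.ndarray, normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (with Kaiser row normalisation by default)."""
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    if normalize:
        h = np.sqrt(np.sum(L ** 2, axis=1))
        h[h == 0] = 1.0
        A = L / h[:, None]
    else:
        A = L.copy()
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ T
        u, s, vt = np.linalg.svd(
            A.T @ (B ** 3 - B @ np.diag(np.sum(B ** 2, axis=0)) / p)
        )
        T = u @ vt
        d_new = float(np.sum(s))
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    out = A @ T
    if normalize:
        out = out * h[:, None]
    return out, T


def promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation (varimax followed by an oblique Procrustes
    step toward the element-wise ``|loading|^power`` target).

    Returns (pattern matrix, factor correlation matrix Phi).  The
    transformation is scaled so Phi has a unit diagonal; the model-implied
    correlation matrix is unchanged by the rotation.
    """
    X, _ = varimax(L)
    k = X.shape[1]
    if k < 2:
        return X, np.eye(k)
    Q = X * np.abs(X) ** (power - 1)
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    d = np.diag(linalg.inv(U.T @ U))
    U = U * np.sqrt(d)
    pattern = X @ U
    phi = linalg.inv(U.T @ U)
    phi = (phi + phi.T) / 2.0
    return pattern, phi


def _order_and_sign(L: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort columns by explained variance, sign-fix the dominant loading."""
    ss = np.diag(phi @ L.T @ L)
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    L = L * signs
    phi = phi * np.outer(signs, signs)
    return L, phi


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

@dataclass
class FactorSolution:
    """A (rotated) factor solution in pattern-matrix form."""

    loadings: np.ndarray          # p x k pattern matrix
    factor_correlations: np.ndarray  # k x k Phi (identity when orthogonal)
    uniquenesses: np.ndarray      # length p
    variance_explained: np.ndarray   # per-factor proportion of total variance
    total_variance_explained: float
    method: str
    rotation: str
    heywood: bool = False

    @property
    def structure(self) -> np.ndarray:
        """Structure matrix (factor-variable correlations) = pattern @ Phi."""
        return self.loadings @ self.factor_correlations

    def implied_correlation(self) -> np.ndarray:
        Rhat = (self.loadings @ self.factor_correlations @ self.loadings.T
                + np.diag(self.uniquenesses))
        return Rhat

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses


def fit_efa(X: np.ndarray, k: int, method: str = "uls",
            rotation: str = "promax", promax_power: int = 4,
            is_correlation: bool = False) -> FactorSolution:
    """Fit a k-factor model to data (n x p) or a correlation matrix.

    ``method``: ``uls`` (unweighted least squares / minres), ``ml``
    (maximum likelihood) or ``paf`` (principal axis).  ``rotation``:
    ``promax``, ``varimax`` or ``none``.
    """
    X = np.asarray(X, dtype=float)
    R = X if is_correlation else np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise FactorAnalysisError(
            "correlation matrix contains non-finite entries "
            "(constant or missing feature column?)")
    p = R.shape[0]
    if not 1 <= k < p:
        raise FactorAnalysisError(f"need 1 <= k < p, got k={k}, p={p}")
    L, heywood = _extract(R, k, method)

    if rotation == "promax" and k >= 2:
        pattern, phi = promax(L, power=promax_power)
    elif rotation == "varimax" and k >= 2:
        pattern, _ = varimax(L)
        phi = np.eye(k)
    elif rotation in ("none", "promax", "varimax"):
        pattern, phi = L, np.eye(k)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    pattern, phi = _order_and_sign(pattern, phi)
    h2 = np.clip(np.diag(pattern @ phi @ pattern.T), 0.0, 1.0 - _PSI_FLOOR)
    psi = 1.0 - h2
    ss = np.diag(phi @ pattern.T @ pattern)
    return FactorSolution(
        loadings=pattern,
        factor_correlations=phi,
        uniquenesses=psi,
        variance_explained=ss / p,
        total_variance_explained=float(np.sum(ss) / p),
        method=method,
        rotation=rotation,
        heywood=heywood,
    )


# ---------------------------------------------------------------------------
# Congruence alignment
# ---------------------------------------------------------------------------

def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's coefficient of congruence between two loading columns."""
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        return 0.0
    return float(x @ y / denom)


def congruence_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tucker congruence between columns of A and columns of B."""
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (A / na).T @ (B / nb)


def alignment_map(reference: np.ndarray, L: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Column permutation and sign flips matching L's columns to reference.

    ``L[:, perm] * signs`` best matches the reference under total absolute
    Tucker congruence (optimal assignment).
    """
    C = congruence_matrix(reference, L)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty_like(cols)
    perm[rows] = cols
    signs = np.empty(len(perm))
    s = np.sign(C[rows, cols])
    s[s == 0] = 1.0
    signs[rows] = s
    return perm, signs


def align_to(reference: np.ndarray, L: np.ndarray,
             phi: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Permute and sign-flip columns of L to best match the reference.

    The permutation maximises total |Tucker congruence| (optimal assignment);
    signs follow the matched congruence.  Returns the aligned loadings, the
    correspondingly permuted Phi, and the mean absolute congruence achieved.
    """
    perm, signs = alignment_map(reference, L)
    aligned = L[:, perm] * signs
    phi_out = None
    if phi is not None:
        phi_out = phi[np.ix_(perm, perm)] * np.outer(signs, signs)
    C = congruence_matrix(reference, aligned)
    mean_cong = float(np.mean(np.abs(np.diag(C))))
    return aligned, phi_out, mean_cong


# ---------------------------------------------------------------------------
# Bootstrap & averaging
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSolution:
    """Case-resampling bootstrap of an EFA solution."""

    B: int
    point: FactorSolution
    mean_loadings: np.ndarray
    loading_ci: np.ndarray        # p x k x 2 percentile bounds
    alignment_congruence: np.ndarray  # per-kept-resample mean |congruence|
    n_dropped: int


def bootstrap_efa(X: np.ndarray, k: int, B: int, seed: int,
                  method: str = "uls", rotation: str = "promax",
                  ci: float = 0.95) -> BootstrapSolution:
    """Bootstrap the loading matrix by resampling participants.

    Each resample is refit and aligned to the point-estimate solution by
    optimal column permutation and sign flip before averaging; resamples
    whose fit fails are dropped and counted (more than 10% dropped is an
    error).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    point = fit_efa(X, k, method=method, rotation=rotation)
    rng = np.random.default_rng(seed)
    kept, congs = [], []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            sol = fit_efa(X[idx], k, method=method, rotation=rotation)
            aligned, _, cong = align_to(point.loadings, sol.loadings,
                                        sol.factor_correlations)
        except (FactorAnalysisError, ValueError, np.linalg.LinAlgError):
            dropped += 1
            continue
        kept.append(aligned)
        congs.append(cong)
    if dropped > 0.10 * B:
        raise FactorAnalysisError(
            f"{dropped}/{B} bootstrap resamples failed to converge"
        )
    stack = np.stack(kept)
    alpha = (1.0 - ci) / 2.0
    lo = np.percentile(stack, 100 * alpha, axis=0)
    hi = np.percentile(stack, 100 * (1 - alpha), axis=0)
    return BootstrapSolution(
        B=B,
        point=point,
        mean_loadings=stack.mean(axis=0),
        loading_ci=np.stack([lo, hi], axis=-1),
        alignment_congruence=np.array(congs),
        n_dropped=dropped,
    )


def average_solution(X: np.ndarray, k: int,
                     methods: tuple[str, ...] = ("uls", "ml", "paf"),
                     rotation: str = "promax") -> FactorSolution:
    """Average factor solution across extraction methods.

    Every method's solution is aligned (permutation + sign by congruence) to
    the first method's before loadings and Phi are averaged.  Methods whose
    fit fails are reported and skipped; fewer than two survivors is an error.
    """
    if len(methods) < 2:
        raise FactorAnalysisError("averaging needs at least 2 methods")
    fits: list[tuple[np.ndarray, np.ndarray]] = []
    failures: list[str] = []
    reference = None
    for m in methods:
        try:
            sol = fit_efa(X, k, method=m, rotation=rotation)
        except (FactorAnalysisError, np.linalg.LinAlgError) as exc:
            failures.append(f"{m}: {exc}")
            continue
        if reference is None:
            reference = sol.loadings
            fits.append((sol.loadings, sol.factor_correlations))
        else:
            aligned, phi, _ = align_to(reference, sol.loadings,
                                       sol.factor_correlations)
            fits.append((aligned, phi))
    if len(fits) < 2:
        raise FactorAnalysisError(
            f"fewer than 2 methods converged (failures: {failures})"
        )
    L = np.mean([f[0] for f in fits], axis=0)
    phi = np.mean([f[1] for f in fits], axis=0)
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    p = L.shape[0]
    h2 = np.clip(np.diag(L @ phi @ L.T), 0.0, 1.0 - _PSI_FLOOR)
    ss = np.diag(phi @ L.T @ L)
    return FactorSolution(
        loadings=L, factor_correlations=phi, uniquenesses=1.0 - h2,
        variance_explained=ss / p, total_variance_explained=float(ss.sum() / p),
        method="average", rotation=rotation,
    )


# ---------------------------------------------------------------------------
# Factor scores
# ---------------------------------------------------------------------------

def factor_scores(solution: FactorSolution, X: np.ndarray,
                  method: str = "regression") -> np.ndarray:
    """Per-participant factor scores (regression/Thurstone by default).

    scores = Z R^-1 S with Z the standardised data and S the structure
    matrix; Bartlett weighting available via ``method="bartlett"``.  Columns
    are re-standardised to mean 0, sd 1.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise FactorAnalysisError("zero-variance feature column in scoring input")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    S = solution.structure
    if method == "regression":
        try:
            W = linalg.solve(R, S, assume_a="sym")
        except linalg.LinAlgError:
            W = linalg.solve(R + 1e-8 * np.eye(R.shape[0]), S, assume_a="sym")
    elif method == "bartlett":
        L = solution.loadings
        Pinv = np.diag(1.0 / np.maximum(solution.uniquenesses, _PSI_FLOOR))
        W = Pinv @ L @ linalg.inv(L.T @ Pinv @ L)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    scores = Z @ W
    ssd = scores.std(axis=0, ddof=1)
    if np.any(ssd == 0):
        raise FactorAnalysisError("degenerate factor scores (zero variance)")
    return (scores - scores.mean(axis=0)) / ssd
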