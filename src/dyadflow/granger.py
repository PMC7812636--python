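"""Vector-autoregressive modelling and multivariate conditional Granger causality.

A zero-mean M-variate process is modelled as a VAR(p), Y_n = sum_k A_k
Y_{n-k} + U_n, fitted by ordinary least squares.  Granger causality from a
driver set to a target set, given a conditioning set, is the log-ratio of
generalized prediction-error variances

    F = ln( det Sigma_restricted / det Sigma_full )

where the restricted regression omits the driver's past.  For scalar
targets the generalized variance reduces to the residual variance.  Both
regressions use maximum-likelihood (1/n_eff) residual covariances so that
under the null n_eff * F is asymptotically chi-squared with
p * dim(driver) * dim(target) degrees of freedom, which the link test uses.

Significance against an empirical null is assessed with phase-randomized
surrogates: per-column Fourier phase randomization preserves every power
spectrum while destroying all cross-dependences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VarModel",
    "GcValue",
    "DyadGc",
    "PairwiseGc",
    "SurrogateEnsemble",
    "GcTestResult",
    "fit_var_ols",
    "select_order",
    "block_gc",
    "dyad_gc",
    "dyad_gc_batch",
    "pairwise_conditional_gc",
    "gc_chi2_pvalue",
    "phase_randomize_surrogates",
    "surrogate_gc_means",
    "empirical_surrogate_test",
]

SUBJECT_A = (0, 1, 2)
SUBJECT_B = (3, 4, 5)


# ---------------------------------------------------------------------------
# model containers


@dataclass
class VarModel:
    """Fitted VAR(p): coefficient matrices and residual covariance."""

    order: int
    coeffs: np.ndarray  # (p, M, M); coeffs[k] maps Y_{n-k-1} -> Y_n
    resid_cov: np.ndarray  # (M, M), effective-sample normalized
    n_obs: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite VAR coefficients")
        if not np.allclose(self.resid_cov, self.resid_cov.T, atol=1e-10):
            raise ValueError("residual covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.resid_cov)
        if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
            raise ValueError("residual covariance must be positive semi-definite")

    @property
    def m(self) -> int:
        return self.coeffs.shape[1]

    def companion_spectral_radius(self) -> float:
        p, m, _ = self.coeffs.shape
        comp = np.zeros((m * p, m * p))
        comp[:m, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[m:, :-m] = np.eye(m * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class GcValue:
    """One Granger-causality estimate between (possibly multivariate) blocks."""

    F: float
    driver: tuple[int, ...]
    target: tuple[int, ...]
    cond: tuple[int, ...]
    lam_restricted: float
    lam_full: float
    n_eff: int
    order: int
    clamped: bool = False

    @property
    def dof(self) -> int:
        return self.order * len(self.driver) * len(self.target)

    @property
    def pvalue(self) -> float:
        return gc_chi2_pvalue(self.F, self.n_eff, self.order, len(self.driver), len(self.target))


@dataclass
class DyadGc:
    """Dyad-level GC in both directions plus the direction-agnostic summary."""

    f_ab: GcValue
    f_ba: GcValue

    @property
    def summary(self) -> float:
        return 0.5 * (self.f_ab.F + self.f_ba.F)


@dataclass
class PairwiseGc:
    """All-pairs conditional GC: F and asymptotic p-values (NaN diagonal)."""

    F: np.ndarray
    pvalues: np.ndarray
    n_eff: int
    order: int
    conditional: bool


@dataclass
class SurrogateEnsemble:
    """Phase-randomized copies of a multivariate series."""

    data: np.ndarray  # (n_surr, n, M)
    seed: int
    block_wise: bool = False

    @property
    def n_surr(self) -> int:
        return self.data.shape[0]


@dataclass
class GcTestResult:
    """Real-vs-surrogate comparison across dyads (paired t, Cohen's d)."""

    real_values: np.ndarray
    surrogate_means: np.ndarray
    t: float
    p: float
    d: float


# ---------------------------------------------------------------------------
# estimation internals


def _lagged(E: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lag-stacked design for a batch of series.

    E is (S, n, M); returns X (S, n-p, M*p) with lag-major column blocks and
    the aligned targets (S, n-p, M).
    """
    S, n, M = E.shape
    X = np.concatenate([E[:, p - k : n - k, :] for k in range(1, p + 1)], axis=2)
    return X, E[:, p:, :]


def _var_columns(var_idx: Sequence[int], M: int, p: int) -> list[int]:
    """Design-matrix columns holding all p lags of the given variables."""
    return [k * M + v for k in range(p) for v in var_idx]


def _resid_cov_batch(G: np.ndarray, C: np.ndarray, YtY: np.ndarray, n_eff: int) -> np.ndarray:
    """MLE residual covariance from normal-equation blocks.

    G = X'X (S,k,k), C = X'Y (S,k,t), YtY = Y'Y (S,t,t).
    """
    try:
        B = np.linalg.solve(G, C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("rank-deficient regressor matrix") from exc
    cov = (YtY - np.swapaxes(C, -1, -2) @ B) / n_eff
    return cov


def _gen_variance(cov: np.ndarray) -> np.ndarray:
    """Generalized variance: determinant (plain variance for 1x1 blocks)."""
    if cov.shape[-1] == 1:
        return cov[..., 0, 0]
    return np.linalg.det(cov)


def fit_var_ols(Y: np.ndarray, p: int) -> VarModel:
    """Fit a VAR(p) to an (n, M) zero-mean matrix by ordinary least squares."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (samples, variables)")
    n, M = Y.shape
    if p < 1:
        raise ValueError("order must be >= 1")
    if n - p <= M * p + 10:
        raise ValueError(f"insufficient samples: need n - p > {M * p + 10}")
    X, T = _lagged(Y[None], p)
    X, T = X[0], T[0]
    n_eff = X.shape[0]
    B, residues, rank, _ = np.linalg.lstsq(X, T, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient regressor matrix")
    E = T - X @ B
    denom = n - p - M * p - 1
    if denom < 1:
        raise ValueError("not enough effective observations for the covariance")
    resid_cov = E.T @ E / denom
    coeffs = B.reshape(p, M, M).transpose(0, 2, 1)  # A_k maps Y_{n-k} -> Y_n
    return VarModel(order=p, coeffs=coeffs, resid_cov=resid_cov, n_obs=n)


def select_order(Y: np.ndarray, p_max: int = 5, criterion: str = "bic") -> int:
    """Model order minimizing BIC (default) or AIC over 1..p_max.

    All candidates are scored on the same effective sample (the last
    n - p_max observations) so the criteria are comparable.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    Y = np.asarray(Y, dtype=float)
    n, M = Y.shape
    N = n - p_max
    best_p, best_score = 1, np.inf
    for p in range(1, p_max + 1):
        X = np.concatenate([Y[p_max - k : n - k, :] for k in range(1, p + 1)], axis=1)
        T = Y[p_max:, :]
        B, *_ = np.linalg.lstsq(X, T, rcond=None)
        E = T - X @ B
        cov = E.T @ E / N
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            continue
        k = M * M * p
        penalty = (np.log(N) if criterion == "bic" else 2.0) * k / N
        score = logdet + penalty
        if score < best_score - 1e-12:
            best_p, best_score = p, score
    return best_p


def _block_gc_batch(
    E: np.ndarray,
    driver: Sequence[int],
    target: Sequence[int],
    cond: Sequence[int],
    p: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Batched block GC over the leading axis of E (S, n, M).

    Returns (F, lam_restricted, lam_full, n_eff); negative F are clamped to
    zero (callers can detect clamping from lam values).
    """
    S, n, M = E.shape
    driver, target, cond = tuple(driver), tuple(target), tuple(cond)
    all_vars = driver + target + cond
    if len(set(all_vars)) != len(all_vars):
        raise ValueError("driver/target/cond sets must be disjoint")
    if max(all_vars) >= M or min(all_vars) < 0:
        raise ValueError("variable index out of range")
    if p < 1:
        raise ValueError("order must be >= 1")

    X, T = _lagged(E[:, :, list(all_vars)], p)
    n_eff = X.shape[1]
    m_loc = len(all_vars)
    tgt_loc = list(range(len(driver), len(driver) + len(target)))
    restr_vars = list(range(len(driver), m_loc))  # target + cond, driver omitted

    Yt = T[:, :, tgt_loc]
    G = np.swapaxes(X, 1, 2) @ X
    C = np.swapaxes(X, 1, 2) @ Yt
    YtY = np.swapaxes(Yt, 1, 2) @ Yt
    cov_full = _resid_cov_batch(G, C, YtY, n_eff)

    rcols = _var_columns(restr_vars, m_loc, p)
    Gr = G[:, rcols][:, :, rcols]
    Cr = C[:, rcols, :]
    cov_restr = _resid_cov_batch(Gr, Cr, YtY, n_eff)

    lam_full = _gen_variance(cov_full)
    lam_restr = _gen_variance(cov_restr)
    if np.any(lam_full <= 0) or np.any(lam_restr <= 0):
        raise np.linalg.LinAlgError("singular residual covariance")
    F = np.log(lam_restr / lam_full)
    F = np.maximum(F, 0.0)
    return F, lam_restr, lam_full, n_eff


def block_gc(
    Y: np.ndarray,
    driver_set: Sequence[int],
    target_set: Sequence[int],
    cond_set: Sequence[int] = (),
    p: int = 1,
) -> GcValue:
    """Granger causality from a driver block to a target block, conditioned
    on a further block, all other series ignored."""
    Y = np.asarray(Y, dtype=float)
    F, lam_r, lam_f, n_eff = _block_gc_batch(Y[None], driver_set, target_set, cond_set, p)
    raw = float(np.log(lam_r[0] / lam_f[0]))
    return GcValue(
        F=float(F[0]),
        driver=tuple(driver_set),
        target=tuple(target_set),
        cond=tuple(cond_set),
        lam_restricted=float(lam_r[0]),
        lam_full=float(lam_f[0]),
        n_eff=n_eff,
        order=p,
        clamped=raw < 0,
    )


def dyad_gc(Y: np.ndarray, p: int) -> DyadGc:
    """Dyad-level GC: each subject's 3-column block drives the other's.

    The direction-agnostic summary (mean of the two directions) is what the
    screening stage compares against surrogates; both directions are kept.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] != 6:
        raise ValueError("dyad GC expects a 6-column matrix")
    f_ab = block_gc(Y, SUBJECT_A, SUBJECT_B, (), p)
    f_ba = block_gc(Y, SUBJECT_B, SUBJECT_A, (), p)
    return DyadGc(f_ab=f_ab, f_ba=f_ba)


def dyad_gc_batch(E: np.ndarray, p: int) -> np.ndarray:
    """Vectorized dyad-GC summaries for a batch (S, n, 6) of matrices."""
    F_ab, *_ = _block_gc_batch(E, SUBJECT_A, SUBJECT_B, (), p)
    F_ba, *_ = _block_gc_batch(E, SUBJECT_B, SUBJECT_A, (), p)
    return 0.5 * (F_ab + F_ba)


def pairwise_conditional_gc(Y: np.ndarray, p: int) -> PairwiseGc:
    """Conditional GC for every ordered pair of scalar series.

    Each link i -> j is conditioned on the remaining M-2 series, so links
    mediated entirely by a third series are suppressed.  For M < 3 there is
    nothing to condition on and plain pairwise GC is computed.
    """
    Y = np.asarray(Y, dtype=float)
    n, M = Y.shape
    if M < 2:
        raise ValueError("need at least two series")
    F = np.full((M, M), np.nan)
    if M < 3:
        for i in range(M):
            for j in range(M):
                if i != j:
                    F[i, j] = block_gc(Y, (i,), (j,), (), p).F
        n_eff = n - p
        pvals = _pairwise_pvalues(F, n_eff, p)
        return PairwiseGc(F=F, pvalues=pvals, n_eff=n_eff, order=p, conditional=False)

    X, T = _lagged(Y[None], p)
    X, T = X[0], T[0]
    n_eff = X.shape[0]
    G = X.T @ X
    C = X.T @ T
    YtY = T.T @ T
    cov_full = _resid_cov_batch(G[None], C[None], YtY[None], n_eff)[0]
    var_full = np.diag(cov_full)
    if np.any(var_full <= 0):
        raise np.linalg.LinAlgError("singular residual covariance")
    for i in range(M):
        keep = [v for v in range(M) if v != i]
        cols = _var_columns(keep, M, p)
        Gr = G[np.ix_(cols, cols)]
        Cr = C[np.ix_(cols, range(M))]
        cov_r = _resid_cov_batch(Gr[None], Cr[None], YtY[None], n_eff)[0]
        var_r = np.diag(cov_r)
        for j in range(M):
            if j == i:
                continue
            F[i, j] = max(0.0, np.log(var_r[j] / var_full[j]))
    pvals = _pairwise_pvalues(F, n_eff, p)
    return PairwiseGc(F=F, pvalues=pvals, n_eff=n_eff, order=p, conditional=True)


def _pairwise_pvalues(F: np.ndarray, n_eff: int, p: int) -> np.ndarray:
    pvals = np.full_like(F, np.nan)
    mask = ~np.isnan(F)
    pvals[mask] = stats.chi2.sf(n_eff * F[mask], df=p)
    return pvals


def gc_chi2_pvalue(F: float, n_eff: int, p: int, d_driver: int, d_target: int) -> float:
    """Asymptotic link test: under zero causality, n_eff * F ~ chi2 with
    p * dim(driver) * dim(target) degrees of freedom."""
    if F < 0:
        raise ValueError("F must be nonnegative")
    dof = p * d_driver * d_target
    if dof < 1:
        raise ValueError("invalid degrees of freedom")
    return float(stats.chi2.sf(n_eff * F, df=dof))


# ---------------------------------------------------------------------------
# surrogate testing


def phase_randomize_surrogates(
    values: np.ndarray, n_surr: int, seed: int, block_wise: bool = False
) -> SurrogateEnsemble:
    """Fourier phase-randomized surrogates of an (n, M) matrix.

    Each column keeps its amplitude spectrum exactly; phases of all
    non-DC/non-Nyquist bins are redrawn uniformly, independently per column
    and per surrogate.  With ``block_wise`` the two 3-column subject blocks
    each share one phase draw, preserving within-subject cross-spectra while
    still destroying between-subject dependences.
    """
    if n_surr < 1:
        raise ValueError("need at least one surrogate")
    values = np.asarray(values, dtype=float)
    n, M = values.shape
    spec = np.fft.rfft(values, axis=0)  # (n_bins, M)
    n_bins = spec.shape[0]
    free = np.ones(n_bins, dtype=bool)
    free[0] = False
    if n % 2 == 0:
        free[-1] = False

    rng = np.random.default_rng(seed)
    if block_wise:
        draws = rng.uniform(0, 2 * np.pi, size=(n_surr, n_bins, 2))
        phases = np.empty((n_surr, n_bins, M))
        phases[:, :, :3] = draws[:, :, :1]
        phases[:, :, 3:] = draws[:, :, 1:]
    else:
        phases = rng.uniform(0, 2 * np.pi, size=(n_surr, n_bins, M))
    rot = np.where(free[None, :, None], np.exp(1j * phases), 1.0)
    amp = np.abs(spec)[None, :, :]
    keep_phase = np.exp(1j * np.angle(spec))[None, :, :]
    surr_spec = np.where(free[None, :, None], amp * rot, amp * keep_phase)
    data = np.fft.irfft(surr_spec, n=n, axis=1)
    return SurrogateEnsemble(data=data, seed=seed, block_wise=block_wise)


def surrogate_gc_means(ensemble: SurrogateEnsemble, p: int) -> float:
    """Mean dyad-GC summary over all surrogates of one dyad."""
    return float(np.mean(dyad_gc_batch(ensemble.data, p)))


def empirical_surrogate_test(
    real_per_dyad: Sequence[float],
    ensembles: Sequence[SurrogateEnsemble] | None = None,
    p: int = 1,
    surrogate_means: Sequence[float] | None = None,
) -> GcTestResult:
    """Paired comparison of real dyad GC against surrogate means.

    ``surrogate_means`` may be passed directly when the per-dyad surrogate
    GC averages were already computed (the screening stage batches them);
    otherwise they are derived from ``ensembles``.
    """
    real = np.asarray(real_per_dyad, dtype=float)
    if surrogate_means is None:
        if ensembles is None:
            raise ValueError("provide ensembles or surrogate_means")
        surrogate_means = [surrogate_gc_means(e, p) for e in ensembles]
    surr = np.asarray(surrogate_means, dtype=float)
    if real.size != surr.size:
        raise ValueError("real and surrogate arrays must align per dyad")
    if real.size < 3:
        raise ValueError("need at least 3 dyads for the paired test")
    diff = real - surr
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        t_stat, p_val = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf * np.sign(diff.mean()), 0.0)
        d = 0.0 if np.allclose(diff, 0) else np.inf * np.sign(diff.mean())
    else:
        t_stat, p_val = stats.ttest_rel(real, surr)
        d = float(np.mean(diff) / sd)
    return GcTestResult(
        real_values=real,
        surrogate_means=surr,
        t=float(t_stat),
        p=float(p_val),
        d=float(d),
    )
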