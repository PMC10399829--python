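"""Negative-binomial latent variable ordination by penalized joint maximum likelihood.

The model regresses each taxon's counts, through a log link, on a per-sample
abundance offset, a per-taxon intercept, and the inner product of sample-level
latent scores with taxon-level loadings:

    log mu_ij = alpha_i + beta0_j + u_i . theta_j,     y_ij ~ NB(mu_ij, phi_j)

with per-taxon dispersion phi_j parameterizing the variance as
mu + mu^2 / phi.  The fixed sample effects alpha_i absorb variation in total
abundance so the latent axes describe composition only; the latent scores u_i
are the sample ordination and the loadings theta_j the taxon ordination.

Estimation treats the latent scores as free parameters optimized jointly with
the rest, under the standard-normal prior u_i ~ N(0, I) and — by default — a
Laplace correction (minus half the log-determinant of each sample's score
Hessian) that approximates the marginal likelihood.  The correction matters:
a purely joint maximum lets a spare latent axis interpolate the single most
overdispersed abundant taxon exactly (its dispersion then diverges), because
per-cell likelihood gains from interpolation grow linearly in the sample
count while ridge-type penalties grow only quadratically in the loading; the
log-determinant term grows with log(dispersion) per sample and removes the
incentive.  ``marginalize=False`` selects the plain penalized joint fit.
A mild ridge (default 1e-4) on the loadings keeps the problem well scaled;
the fit is deterministic given the initialization seed.

Identifiability: the loading matrix is constrained lower-triangular during
optimization (removing rotational freedom from the search), and the returned
fit is put in a canonical form — latent score columns centered and whitened,
loading columns centered (their mean is a gauge freedom under fixed row
effects) and rotated onto principal axes ordered by loading variance, signs
fixed.  LV1 is therefore always the dominant composition axis, making
marginal loading distributions comparable across independent fits.  Fitted
means are invariant under all of these transforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.linalg import orthogonal_procrustes
from scipy.special import gammaln, digamma
from scipy.stats import nbinom, norm

from .datamodel import CommunityMatrix

__all__ = [
    "GLLVMConfig",
    "GLLVMFit",
    "ResidualDiagnostics",
    "count_parameters",
    "observations_per_parameter",
    "fit_gllvm",
    "nb_loglik",
    "residual_diagnostics",
    "model_aic",
    "align_ordination",
]

_ETA_CLIP = 30.0  # keeps exp() finite; never binding for data on a count scale


def count_parameters(n_taxa: int, n_samples: int, n_lv: int,
                     row_effect: str = "fixed", method: str = "model-based") -> int:
    """Number of free quantities an ordination of this size estimates.

    For the model-based ordination each taxon carries an intercept, a
    dispersion and ``n_lv`` loadings, each sample a fixed effect (if
    ``row_effect='fixed'``) and ``n_lv`` latent scores.  An NMDS-style
    distance ordination places only the samples: ``n_samples * n_lv``.
    """
    for name, v in (("n_taxa", n_taxa), ("n_samples", n_samples), ("n_lv", n_lv)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if method == "nmds-style":
        return n_samples * n_lv
    if method != "model-based":
        raise ValueError(f"unknown method {method!r}")
    n = n_taxa * (2 + n_lv) + n_samples * n_lv
    if row_effect == "fixed":
        n += n_samples
    elif row_effect != "none":
        raise ValueError(f"unknown row_effect {row_effect!r}")
    return n


def observations_per_parameter(n_taxa: int, n_samples: int, n_params: int) -> float:
    """Cells of the count matrix per estimated parameter."""
    if n_params <= 0:
        raise ValueError("n_params must be positive")
    return (n_taxa * n_samples) / n_params


@dataclass
class GLLVMConfig:
    """Settings for the latent-variable fit.

    n_lv: number of latent axes d (0 = intercept/dispersion model only).
    row_effect: 'fixed' per-sample abundance offsets, or 'none'.
    ridge: L2 penalty weight on the loadings (and, when marginalize is
        False, on the latent scores).
    marginalize: apply the N(0, I) score prior with the Laplace
        log-determinant correction (approximate marginal likelihood).
    alpha_shrink: optional ridge pulling sample effects toward their
        farm x year group mean (0 disables; requires groups at fit time).
    """

    n_lv: int = 2
    row_effect: str = "fixed"
    max_iter: int = 3000
    gtol: float = 1e-3
    ridge: float = 1e-4
    marginalize: bool = True
    alpha_shrink: float = 0.0
    seed: int = 0

    def validate(self, n_taxa: int, n_samples: int) -> None:
        if self.n_lv < 0 or self.n_lv > min(n_taxa, n_samples):
            raise ValueError(f"n_lv must be in [0, min(n_taxa, n_samples)], got {self.n_lv}")
        if self.row_effect not in ("fixed", "none"):
            raise ValueError(f"row_effect must be 'fixed' or 'none', got {self.row_effect!r}")
        if self.gtol <= 0 or self.max_iter <= 0:
            raise ValueError("tolerances and iteration limits must be positive")
        if self.ridge < 0 or self.alpha_shrink < 0:
            raise ValueError("penalty weights must be non-negative")


@dataclass
class GLLVMFit:
    """Fitted model: parameters, log-likelihood and convergence state."""

    alpha: np.ndarray
    beta0: np.ndarray
    theta: np.ndarray
    u: np.ndarray
    phi: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    config: GLLVMConfig
    farm_year_group: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.alpha)

    @property
    def n_taxa(self) -> int:
        return len(self.beta0)

    def linear_predictor(self) -> np.ndarray:
        eta = self.alpha[:, None] + self.beta0[None, :]
        if self.theta.size:
            eta = eta + self.u @ self.theta.T
        return eta

    def mu(self) -> np.ndarray:
        """Fitted mean counts, exp of the linear predictor."""
        return np.exp(self.linear_predictor())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "alpha": self.alpha.tolist(),
            "beta0": self.beta0.tolist(),
            "theta": self.theta.tolist(),
            "u": self.u.tolist(),
            "phi": self.phi.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "config": asdict(self.config),
            "farm_year_group": self.farm_year_group,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GLLVMFit":
        d = json.loads(Path(path).read_text())
        return cls(alpha=np.asarray(d["alpha"]), beta0=np.asarray(d["beta0"]),
                   theta=np.asarray(d["theta"]), u=np.asarray(d["u"]),
                   phi=np.asarray(d["phi"]), loglik=d["loglik"], converged=d["converged"],
                   n_iter=d["n_iter"], config=GLLVMConfig(**d["config"]),
                   farm_year_group=d.get("farm_year_group"))


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> float:
    """Total NB log-likelihood, variance mu + mu^2/phi, phi per taxon (columns)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    ph = np.broadcast_to(np.asarray(phi, dtype=float), (1, y.shape[1]))
    ll = (gammaln(y + ph) - gammaln(ph) - gammaln(y + 1.0)
          + ph * np.log(ph) + y * np.log(mu) - (y + ph) * np.log(ph + mu))
    return float(ll.sum())


def _design(n_samples: int, n_taxa: int, cfg: GLLVMConfig):
    """Index layout of the packed parameter vector."""
    d = cfg.n_lv
    has_alpha = cfg.row_effect == "fixed"
    sizes = {
        "alpha": n_samples if has_alpha else 0,
        "beta0": n_taxa,
        "theta": 0,
        "u": n_samples * d,
        "lphi": n_taxa,
    }
    # lower-triangular loading mask: theta[j, l] free iff l <= j (rows below d: all free)
    mask = np.zeros((n_taxa, d), dtype=bool)
    for j in range(n_taxa):
        mask[j, : min(j + 1, d)] = True
    sizes["theta"] = int(mask.sum())
    offsets, pos = {}, 0
    for k in ("alpha", "beta0", "theta", "u", "lphi"):
        offsets[k] = (pos, pos + sizes[k])
        pos += sizes[k]
    return offsets, mask, pos


def _unpack(x: np.ndarray, offsets, mask, n_samples, n_taxa, cfg):
    d = cfg.n_lv
    a0, a1 = offsets["alpha"]
    alpha = x[a0:a1] if a1 > a0 else np.zeros(0)
    beta0 = x[slice(*offsets["beta0"])]
    theta = np.zeros((n_taxa, d))
    theta[mask] = x[slice(*offsets["theta"])]
    u = x[slice(*offsets["u"])].reshape(n_samples, d)
    lphi = x[slice(*offsets["lphi"])]
    return alpha, beta0, theta, u, lphi


def _objective(x, y, offsets, mask, cfg, group_idx):
    n_samples, n_taxa = y.shape
    alpha, beta0, theta, u, lphi = _unpack(x, offsets, mask, n_samples, n_taxa, cfg)
    has_alpha = alpha.size > 0
    ac = alpha - alpha.mean() if has_alpha else np.zeros(n_samples)

    eta = ac[:, None] + beta0[None, :] + (u @ theta.T if theta.size else 0.0)
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    phi = np.exp(lphi)[None, :]

    ll = (gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
          + phi * np.log(phi) + y * eta - (y + phi) * np.log(phi + mu))
    f = -ll.sum()

    G = y - (y + phi) * mu / (phi + mu)          # d ll / d eta
    dl_lphi = phi * (digamma(y + phi) - digamma(phi) + np.log(phi) + 1.0
                     - np.log(phi + mu) - (y + phi) / (phi + mu))
    g_lphi = -dl_lphi.sum(axis=0)
    g_theta_extra = 0.0

    if cfg.marginalize and theta.size:
        # Laplace correction: + 0.5 log det(I + Theta' W_i Theta) per sample,
        # W_i the diagonal of per-cell NB curvatures w = -d2 ll / d eta2;
        # score prior 0.5 ||u_i||^2 is added with the other penalties below.
        w = (y + phi) * phi * mu / (phi + mu) ** 2
        d = theta.shape[1]
        A = np.eye(d)[None, :, :] + np.einsum("ij,ja,jb->iab", w, theta, theta)
        if d == 1:
            detA = A[:, 0, 0]
            Ainv = (1.0 / detA)[:, None, None]
        elif d == 2:
            detA = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
            Ainv = np.empty_like(A)
            Ainv[:, 0, 0] = A[:, 1, 1]
            Ainv[:, 1, 1] = A[:, 0, 0]
            Ainv[:, 0, 1] = -A[:, 0, 1]
            Ainv[:, 1, 0] = -A[:, 1, 0]
            Ainv /= detA[:, None, None]
        else:
            detA = np.linalg.det(A)
            Ainv = np.linalg.inv(A)
        f += 0.5 * float(np.log(detA).sum())
        q = np.einsum("ja,iab,jb->ij", theta, Ainv, theta)
        dw_deta = (y + phi) * phi * mu * (phi - mu) / (phi + mu) ** 3
        dw_dlphi = phi * mu * (mu * (y + 2 * phi) - phi * y) / (phi + mu) ** 3
        G = G - 0.5 * q * dw_deta
        g_lphi = g_lphi + 0.5 * (q * dw_dlphi).sum(axis=0)
        g_theta_extra = np.einsum("ij,iab,jb->ja", w, Ainv, theta)

    g_beta0 = -G.sum(axis=0)
    g_theta = -(G.T @ u)[mask] if theta.size else np.zeros(0)
    if cfg.marginalize and theta.size:
        g_theta = g_theta + g_theta_extra[mask]
    g_u = (-(G @ theta)).ravel() if theta.size else np.zeros(0)

    if has_alpha:
        row = G.sum(axis=1)
        g_alpha = -(row - row.mean())
        # pin the constant flat direction (alpha shifted vs beta0) very weakly
        f += 1e-8 * float(alpha @ alpha)
        g_alpha = g_alpha + 2e-8 * alpha
        if cfg.alpha_shrink > 0 and group_idx is not None:
            gmeans = np.bincount(group_idx, weights=ac) / np.bincount(group_idx)
            dev = ac - gmeans[group_idx]
            f += cfg.alpha_shrink * float(dev @ dev)
            g_alpha = g_alpha + 2 * cfg.alpha_shrink * (dev - dev.mean())
    else:
        g_alpha = np.zeros(0)

    if theta.size:
        if cfg.ridge > 0:
            f += cfg.ridge * float((theta**2).sum())
            g_theta = g_theta + 2 * cfg.ridge * theta[mask]
        if cfg.marginalize:
            f += 0.5 * float((u**2).sum())       # N(0, I) score prior
            g_u = g_u + u.ravel()
        elif cfg.ridge > 0:
            f += cfg.ridge * float((u**2).sum())
            g_u = g_u + 2 * cfg.ridge * u.ravel()

    grad = np.concatenate([g_alpha, g_beta0, g_theta, g_u, g_lphi])
    return f, grad


def _initial_values(y: np.ndarray, cfg: GLLVMConfig, rng: np.random.Generator):
    n_samples, n_taxa = y.shape
    d = cfg.n_lv
    L = np.log1p(y.astype(float))
    beta0 = np.log(np.maximum(y.mean(axis=0), 1e-3))
    alpha = L.mean(axis=1) - L.mean()
    if d > 0:
        C = L - L.mean(axis=0) - L.mean(axis=1, keepdims=True) + L.mean()
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        sc = np.sqrt(np.maximum(s[:d], 1e-6))
        u0 = U[:, :d] * sc + rng.normal(0.0, 0.01, size=(n_samples, d))
        th0 = Vt[:d].T * sc + rng.normal(0.0, 0.01, size=(n_taxa, d))
        # rotate into the lower-triangular convention expected by the mask
        q, _ = np.linalg.qr(th0[:d].T)
        th0, u0 = th0 @ q, u0 @ q
    else:
        u0 = np.zeros((n_samples, 0))
        th0 = np.zeros((n_taxa, 0))
    m, v = y.mean(axis=0), y.var(axis=0, ddof=1) if n_samples > 1 else y.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi0 = np.where(v > m, m**2 / np.maximum(v - m, 1e-8), 10.0)
    lphi = np.log(np.clip(phi0, 0.05, 1e4))
    return alpha, beta0, th0, u0, lphi


def _canonicalize(alpha, beta0, theta, u, center_loadings):
    """Put the fit in its canonical form; fitted means are unchanged.

    The latent bilinear term u theta' is invariant under invertible linear
    transforms of the axes, and with fixed row effects a constant shift of a
    loading column is a pure row term absorbable into the sample effects.
    The canonical form fixes all of these gauges: score columns are centered
    (shift into beta0) and whitened (unit variance, uncorrelated; scale into
    theta), loading columns are centered (shift into alpha/beta0) and rotated
    onto their principal axes ordered by loading variance — so LV1 is always
    the dominant composition axis — with the sign set so each column's
    largest-magnitude loading is positive.
    """
    d = theta.shape[1]
    if d == 0:
        return alpha, beta0, theta, u
    beta0 = beta0 + theta @ u.mean(axis=0)
    u = u - u.mean(axis=0)
    if center_loadings:
        tbar = theta.mean(axis=0)
        theta = theta - tbar
        shift = u @ tbar              # row term absorbed by the sample effects
        alpha = alpha + shift - shift.mean()
        beta0 = beta0 + shift.mean()
    # whiten the scores: u -> u B with B = chol(cov)^{-T}, theta -> theta B^{-T}
    C = np.cov(u, rowvar=False, ddof=1).reshape(d, d)
    C = C + 1e-10 * np.eye(d)
    L = np.linalg.cholesky(C)
    u = np.linalg.solve(L, u.T).T
    theta = theta @ L
    # principal-axis rotation of the loadings (whitened scores stay whitened)
    _, _, Vt = np.linalg.svd(theta, full_matrices=False)
    theta, u = theta @ Vt.T, u @ Vt.T
    for l in range(d):
        j = int(np.argmax(np.abs(theta[:, l])))
        if theta[j, l] < 0:
            theta[:, l] *= -1.0
            u[:, l] *= -1.0
    return alpha, beta0, theta, u


def fit_gllvm(cm: CommunityMatrix, config: GLLVMConfig | None = None,
              groups: list[str] | None = None) -> GLLVMFit:
    """Fit the latent variable model to a community matrix.

    ``groups`` optionally labels each sample with its farm x year cell; it is
    recorded on the fit (for downstream spatial analysis) and used by the
    optional ``alpha_shrink`` penalty.  Deterministic given ``config.seed``.
    """
    config = config or GLLVMConfig()
    y = cm.counts.astype(float)
    n_samples, n_taxa = y.shape
    config.validate(n_taxa, n_samples)
    zero = cm.zero_taxa()
    if zero:
        raise ValueError(f"all-zero taxa cannot be fitted (dispersion unidentifiable): {zero}")
    if groups is not None and len(groups) != n_samples:
        raise ValueError("groups must have one label per sample")

    offsets, mask, n_free = _design(n_samples, n_taxa, config)
    rng = np.random.default_rng(config.seed)
    alpha0, beta00, th0, u0, lphi0 = _initial_values(y, config, rng)
    x0 = np.zeros(n_free)
    if config.row_effect == "fixed":
        x0[slice(*offsets["alpha"])] = alpha0
    x0[slice(*offsets["beta0"])] = beta00
    x0[slice(*offsets["theta"])] = th0[mask]
    x0[slice(*offsets["u"])] = u0.ravel()
    x0[slice(*offsets["lphi"])] = lphi0

    group_idx = None
    if groups is not None:
        _, group_idx = np.unique(np.asarray(groups), return_inverse=True)

    bounds = [(None, None)] * n_free
    lo, hi = offsets["lphi"]
    for i in range(lo, hi):
        bounds[i] = (-6.0, 12.0)

    res = minimize(_objective, x0, args=(y, offsets, mask, config, group_idx),
                   jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": config.max_iter, "gtol": config.gtol,
                            "maxfun": 10 * config.max_iter})

    alpha, beta0, theta, u, lphi = _unpack(res.x, offsets, mask, n_samples, n_taxa, config)
    if alpha.size:
        alpha = alpha - alpha.mean()
    else:
        alpha = np.zeros(n_samples)
    alpha, beta0, theta, u = _canonicalize(alpha, beta0, theta, u,
                                           center_loadings=config.row_effect == "fixed")
    phi = np.exp(lphi)
    eta = np.clip(alpha[:, None] + beta0[None, :] + (u @ theta.T if theta.size else 0.0),
                  -_ETA_CLIP, _ETA_CLIP)
    ll = nb_loglik(y, np.exp(eta), phi)
    return GLLVMFit(alpha=alpha, beta0=beta0, theta=theta, u=u, phi=phi,
                    loglik=ll, converged=bool(res.success), n_iter=int(res.nit),
                    config=config, farm_year_group=list(groups) if groups is not None else None)


@dataclass
class ResidualDiagnostics:
    """Randomized-quantile (Dunn-Smyth) residuals and fit-quality summaries."""

    residuals: np.ndarray
    sample_means: np.ndarray
    sample_sds: np.ndarray
    taxon_means: np.ndarray
    taxon_sds: np.ndarray
    qq_theoretical: np.ndarray
    qq_empirical: np.ndarray
    taxon_fitted_means: np.ndarray
    taxon_dispersions: np.ndarray


def residual_diagnostics(fit: GLLVMFit, cm: CommunityMatrix, seed: int = 0) -> ResidualDiagnostics:
    """Dunn-Smyth residuals: uniform draw within the NB CDF step, probit-transformed.

    Under a correctly specified model these are standard normal; systematic
    departures flag the mean model (residual-vs-fit plots) or the dispersion
    model (Q-Q curvature).
    """
    y = cm.counts
    if y.shape != (fit.n_samples, fit.n_taxa):
        raise ValueError(
            f"fit is {fit.n_samples}x{fit.n_taxa} but data is {y.shape[0]}x{y.shape[1]}"
        )
    mu = fit.mu()
    phi = fit.phi[None, :]
    p = phi / (phi + mu)
    lo = np.where(y > 0, nbinom.cdf(y - 1, phi, p), 0.0)
    hi = nbinom.cdf(y, phi, p)
    rng = np.random.default_rng(seed)
    q = lo + rng.uniform(size=y.shape) * (hi - lo)
    resid = norm.ppf(np.clip(q, 1e-12, 1 - 1e-12))
    flat = np.sort(resid.ravel())
    n = flat.size
    theo = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return ResidualDiagnostics(
        residuals=resid,
        sample_means=resid.mean(axis=1), sample_sds=resid.std(axis=1, ddof=1),
        taxon_means=resid.mean(axis=0), taxon_sds=resid.std(axis=0, ddof=1),
        qq_theoretical=theo, qq_empirical=flat,
        taxon_fitted_means=mu.mean(axis=0), taxon_dispersions=fit.phi.copy(),
    )


def model_aic(fit: GLLVMFit) -> float:
    """AIC at the optimum: -2 loglik + 2 x (number of fitted parameters)."""
    k = count_parameters(fit.n_taxa, fit.n_samples, fit.config.n_lv,
                         row_effect=fit.config.row_effect)
    return -2.0 * fit.loglik + 2.0 * k


def align_ordination(reference_loadings: np.ndarray, target_loadings: np.ndarray):
    """Orthogonal Procrustes alignment of one loading set onto another.

    Latent axes are identified only up to rotation/reflection, so loadings
    from two fits are comparable only after aligning.  Returns
    ``(rotation, aligned, residual_norm)`` with ``aligned = target @ rotation``.
    """
    ref = np.asarray(reference_loadings, dtype=float)
    tgt = np.asarray(target_loadings, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tgt.shape}")
    R, _ = orthogonal_procrustes(tgt, ref)
    aligned = tgt @ R
    return R, aligned, float(np.linalg.norm(aligned - ref))
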