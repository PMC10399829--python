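"""Study-shaped synthetic communities with known ground truth.

The generator emulates the statistical structure the analysis assumes for a
biweekly multi-farm arthropod survey: 6 farms x 2 years x 10 occasions = 120
samples of 36 taxa, overdispersed negative-binomial counts spanning several
orders of magnitude in abundance, two taxon modules whose relative dominance
crosses over through the season, and farm-level variation both in composition
and in total abundance.

Correlation between taxa is induced through the latent-variable mechanism
itself — taxa in the same module share the sign of their loading on the
seasonal axis — so the generator produces exactly the data-generating process
the ordination model assumes, giving clean parameter-recovery semantics.  The
copula randomizer in :mod:`commodular.nullmodels` provides the alternative,
marginal-preserving construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, SampleMeta

__all__ = ["StudyDesign", "StudyTruth", "generate_study", "generate_from_gllvm"]


@dataclass
class StudyDesign:
    """Dimensions and generating parameters of a synthetic survey.

    Defaults reproduce the study design: 6 farms x 2 years x 10 biweekly
    occasions (120 samples) of 36 taxa in 2 modules.  ``crossover`` scales
    the seasonal swing of the first latent axis from module A dominance to
    module B dominance; ``axis2_strength`` sets the relative amplitude of the
    minor second axis (a mid-season hump); ``farm_sd_composition`` and ``farm_sd_abundance``
    are the standard deviations of farm-level shifts on the latent scores
    and on the per-sample abundance offsets; ``score_noise_sd`` adds
    sample-level latent noise shared by all taxa.  Baseline mean counts are
    log-spaced over three orders of magnitude and per-taxon dispersions lie
    in [0.2, 5] (strong overdispersion for most taxa).
    """

    n_farms: int = 6
    n_years: int = 2
    n_times: int = 10
    n_taxa: int = 36
    n_modules: int = 2
    mean_range: tuple[float, float] = (0.5, 500.0)
    dispersion_range: tuple[float, float] = (0.2, 5.0)
    crossover: float = 1.5
    axis2_strength: float = 0.4
    farm_sd_composition: float = 0.3
    farm_sd_abundance: float = 0.3
    score_noise_sd: float = 0.25
    sample_noise_sd: float = 0.2
    aphid_outbreak: bool = False
    plants_per_sample: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_farms", "n_years", "n_times", "n_taxa", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_modules > self.n_taxa:
            raise ValueError("n_modules cannot exceed n_taxa")
        if self.dispersion_range[0] <= 0:
            raise ValueError("dispersions must be positive")
        if self.mean_range[0] <= 0:
            raise ValueError("baseline means must be positive")
        for name in ("crossover", "axis2_strength", "farm_sd_composition", "farm_sd_abundance",
                     "score_noise_sd", "sample_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_farms * self.n_years * self.n_times

    @property
    def total_plants(self) -> int:
        """Plants inspected over the whole survey (protocol arithmetic)."""
        return self.plants_per_sample * self.n_times * self.n_farms * self.n_years


@dataclass
class StudyTruth:
    """Every generating parameter of a synthetic study, for recovery checks."""

    module_labels: np.ndarray
    beta0: np.ndarray
    theta: np.ndarray
    u: np.ndarray
    alpha: np.ndarray
    phi: np.ndarray
    design: StudyDesign

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = {
            "module_labels": self.module_labels.tolist(),
            "beta0": self.beta0.tolist(),
            "theta": self.theta.tolist(),
            "u": self.u.tolist(),
            "alpha": self.alpha.tolist(),
            "phi": self.phi.tolist(),
            "design": asdict(self.design),
        }
        path.write_text(json.dumps(d, indent=1))
        return path


def _seasonal_trend(time_index: np.ndarray, n_times: int) -> np.ndarray:
    """Linear ramp from -1 (first occasion) to +1 (last)."""
    if n_times == 1:
        return np.zeros_like(time_index, dtype=float)
    return 2.0 * (time_index - 1) / (n_times - 1) - 1.0


def generate_study(design: StudyDesign | None = None):
    """Draw one synthetic survey: counts, metadata, and the generating truth.

    Latent axis 1 carries the seasonal module crossover (module A taxa load
    negative, module B positive; scores ramp from -crossover to +crossover
    through the season).  Axis 2 carries residual shared variation.  Farms
    shift both latent axes (composition) and the abundance offsets (total
    abundance).  Counts are negative binomial around the log-linear mean.
    Deterministic given ``design.seed``.
    """
    design = design or StudyDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)
    nf, ny, nt, m = design.n_farms, design.n_years, design.n_times, design.n_taxa
    n = design.n_samples

    # --- design table -----------------------------------------------------
    farms = np.repeat(np.arange(1, nf + 1), ny * nt)
    years = np.tile(np.repeat(np.arange(1, ny + 1), nt), nf)
    times = np.tile(np.arange(1, nt + 1), nf * ny)
    sample_ids = [f"F{f}_Y{y}_T{t:02d}" for f, y, t in zip(farms, years, times)]
    meta = SampleMeta(pd.DataFrame({
        "sample_id": sample_ids,
        "farm": [f"farm{f}" for f in farms],
        "year": [f"year{y}" for y in years],
        "time_index": times,
    }))

    # --- taxon-side parameters -------------------------------------------
    lo, hi = design.mean_range
    base_means = np.exp(rng.permutation(np.linspace(np.log(lo), np.log(hi), m)))
    beta0 = np.log(base_means)
    dlo, dhi = design.dispersion_range
    phi = np.exp(rng.uniform(np.log(dlo), np.log(dhi), size=m))
    # modules alternate down the baseline-abundance ranking (round robin on
    # expected means), so module identity is decoupled from abundance;
    # realized-count ranks can differ slightly, so the label truth is stored
    order = np.argsort(-base_means, kind="stable")
    labels = np.empty(m, dtype=int)
    labels[order] = np.arange(m) % design.n_modules + 1
    sign = np.where(labels == 1, -1.0, 1.0)  # module 1 negative on axis 1
    theta = np.column_stack([
        sign * rng.uniform(0.5, 1.0, size=m),
        rng.normal(0.0, 0.6, size=m),
    ])

    # --- sample-side parameters ------------------------------------------
    farm_shift = rng.normal(0.0, design.farm_sd_composition, size=(nf, 2))
    farm_abund = rng.normal(0.0, design.farm_sd_abundance, size=nf)
    trend = _seasonal_trend(times.astype(float), nt)
    # axis 2 carries a weaker mid-season hump (a peaked phenology orthogonal
    # to the crossover gradient): a genuine but minor second axis, as the
    # dominant structure is the module crossover itself
    hump = 1.0 - 2.0 * trend**2
    u = np.column_stack([
        design.crossover * trend,
        design.axis2_strength * design.crossover * hump,
    ])
    u += farm_shift[farms - 1]
    if design.score_noise_sd > 0:
        u += rng.normal(0.0, design.score_noise_sd, size=(n, 2))
    alpha = farm_abund[farms - 1] + rng.normal(0.0, design.sample_noise_sd, size=n)
    alpha = alpha - alpha.mean()

    eta = alpha[:, None] + beta0[None, :] + u @ theta.T
    if design.aphid_outbreak:
        # aphid-style stress: the most abundant taxon explodes late in year 1
        j = int(order[0])
        eta[:, j] += np.where((years == 1) & (times > nt // 2), 2.5, 0.0)
    counts = _draw_nb(eta, phi, rng)

    cm = CommunityMatrix(counts=counts, sample_ids=sample_ids,
                         taxon_ids=[f"taxon{j + 1:02d}" for j in range(m)])
    truth = StudyTruth(module_labels=labels, beta0=beta0, theta=theta, u=u,
                       alpha=alpha, phi=phi, design=design)
    return cm, meta, truth


def _draw_nb(eta: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    if not np.isfinite(mu).all():
        raise ValueError("non-finite mean in NB simulation")
    ph = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    # NB as gamma-mixed Poisson: lam ~ Gamma(phi, mu/phi), y ~ Poisson(lam)
    lam = rng.gamma(shape=ph, scale=mu / ph)
    return rng.poisson(lam).astype(np.int64)


def generate_from_gllvm(beta0: np.ndarray, theta: np.ndarray, u: np.ndarray,
                        alpha: np.ndarray, phi: np.ndarray, seed: int = 0,
                        sample_ids=None, taxon_ids=None) -> CommunityMatrix:
    """Forward-simulate counts from explicit latent-variable model parameters.

    Each cell is negative binomial with mean exp(alpha_i + beta0_j +
    u_i . theta_j) and per-taxon dispersion phi_j (variance mu + mu^2/phi).
    Deterministic given ``seed``.
    """
    beta0 = np.asarray(beta0, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n, m = alpha.size, beta0.size
    if theta.shape[0] != m or u.shape[0] != n or theta.shape[1] != u.shape[1]:
        raise ValueError("parameter dimensions are inconsistent")
    if (phi <= 0).any():
        raise ValueError("dispersions must be positive")
    eta = alpha[:, None] + beta0[None, :] + (u @ theta.T if theta.size else 0.0)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    rng = np.random.default_rng(seed)
    counts = _draw_nb(eta, phi, rng)
    return CommunityMatrix(
        counts=counts,
        sample_ids=sample_ids or [f"s{i + 1}" for i in range(n)],
        taxon_ids=taxon_ids or [f"taxon{j + 1:02d}" for j in range(m)],
    )
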