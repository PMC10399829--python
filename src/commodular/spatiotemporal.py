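"""Temporal composition trajectories and the farm random-effect test.

The latent scores u_i place each sample in composition space; averaging them
over farms within each (year, biweekly occasion) traces the community's
seasonal trajectory.  Whether farms differ systematically — i.e. whether the
surrounding species pool leaves a spatial signature — is tested by a linear
mixed model

    response ~ time + (1 | farm) + (1 | year)

fitted by maximum likelihood, with the farm random intercept's significance
assessed by a likelihood-ratio test against the model without it
(chi-square, df = 1 — conservative at the boundary; an optional 50:50
mixture correction halves the p-value's mass at zero).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .datamodel import SampleMeta

__all__ = ["CentroidSeries", "LmmLrtResult", "temporal_centroids", "lmm_farm_lrt",
           "mean_log_abundance"]


@dataclass
class CentroidSeries:
    """Per (year, time_index) mean latent scores across farms, with SE."""

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def temporal_centroids(scores: np.ndarray, meta: SampleMeta) -> CentroidSeries:
    """Average latent scores over farms for each (year, time_index) cell.

    SE is the standard deviation across farms divided by sqrt(n_farms); it is
    reported missing when only one farm contributes.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    t = meta.table
    if len(t) != scores.shape[0]:
        raise ValueError(f"{scores.shape[0]} score rows but {len(t)} metadata rows")
    d = scores.shape[1]
    df = t.copy()
    for l in range(d):
        df[f"lv{l + 1}"] = scores[:, l]
    rows = []
    for (year, ti), grp in df.groupby(["year", "time_index"], sort=True):
        n = len(grp)
        row = {"year": year, "time_index": ti, "n_farms": n}
        for l in range(d):
            vals = grp[f"lv{l + 1}"].to_numpy()
            row[f"mean_LV{l + 1}"] = float(vals.mean())
            row[f"se_LV{l + 1}"] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(row)
    return CentroidSeries(table=pd.DataFrame(rows))


@dataclass
class LmmLrtResult:
    """Likelihood-ratio test of the farm random intercept."""

    chi2: float
    p: float
    loglik_full: float
    loglik_reduced: float
    variance_components: dict
    singular: bool

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path


def mean_log_abundance(counts: np.ndarray) -> np.ndarray:
    """Per-sample mean of ln(1 + count): the total-abundance response."""
    return np.log1p(np.asarray(counts, dtype=float)).mean(axis=1)


def _fit_vc(df: pd.DataFrame, vc: dict) -> tuple[float, dict, bool]:
    """ML fit of response ~ time with crossed random intercepts as variance components."""
    model = sm.MixedLM.from_formula("response ~ time_index", groups="all_one",
                                    vc_formula=vc, re_formula="0", data=df)
    singular = False
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # variance components near the zero boundary trip up individual
        # optimizers; run two and keep the better likelihood
        for method in ("powell", "lbfgs"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=1000)
            except Exception:
                continue
            if fit is None or cand.llf > fit.llf:
                fit = cand
        if fit is None:
            raise RuntimeError("mixed-model fit failed under all optimizers")
        if not getattr(fit, "converged", True):
            singular = True
        vcomp = {k: float(v) for k, v in zip(model.exog_vc.names, np.atleast_1d(fit.vcomp))}
        if any(v < 1e-8 for v in vcomp.values()):
            singular = True
    vcomp["residual"] = float(fit.scale)
    return float(fit.llf), vcomp, singular


def lmm_farm_lrt(response: np.ndarray, meta: SampleMeta,
                 boundary_correction: bool = False) -> LmmLrtResult:
    """Test the farm random intercept by a likelihood-ratio test.

    Fits ``response ~ time + (1|farm) + (1|year)`` and the same model without
    the farm intercept, both by ML, and refers 2 x the log-likelihood
    difference to chi-square with df = 1.  With ``boundary_correction=True``
    the p-value uses the 50:50 chi0/chi1 mixture appropriate for a variance
    on the boundary; the default keeps the plain (conservative) chi-square.
    Singular fits (a variance component estimated at zero, or
    non-convergence) are flagged on the result, not raised.
    """
    response = np.asarray(response, dtype=float)
    t = meta.table
    if len(t) != response.size:
        raise ValueError("response must align with metadata")
    if t["farm"].nunique() < 2:
        raise ValueError("need >= 2 farms to test a farm effect")
    df = pd.DataFrame({
        "response": response,
        "time_index": t["time_index"].to_numpy(dtype=float),
        "farm": t["farm"].to_numpy(),
        "year": t["year"].to_numpy(),
        "all_one": np.ones(len(t), dtype=int),
    })
    vc_full = {"farm": "0 + C(farm)", "year": "0 + C(year)"}
    vc_red = {"year": "0 + C(year)"}
    ll_full, vcomp, sing_full = _fit_vc(df, vc_full)
    ll_red, _, sing_red = _fit_vc(df, vc_red)
    chi2 = 2.0 * (ll_full - ll_red)
    if chi2 < -1e-6:
        # optimizer noise: the full model can never truly fit worse
        sing_full = True
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, 1))
    if boundary_correction:
        p = 0.5 * p if chi2 > 0 else 1.0
    return LmmLrtResult(chi2=float(chi2), p=float(min(p, 1.0)),
                        loglik_full=ll_full, loglik_reduced=ll_red,
                        variance_components=vcomp, singular=bool(sing_full or sing_red))
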