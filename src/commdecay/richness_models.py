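"""GLMs of infracommunity species richness.

Two log-link count models address whether parasite richness per host
individual varies with fish length and with fish species: a Poisson GLM
and, as an overdispersion check, a negative-binomial GLM whose dispersion
is profiled by maximum likelihood. Models are ranked by AIC and nested
models compared with likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar

from .core_io import HostMetadata, InfectionTable
from .descriptors import infracommunity_frame
from .exceptions import ConvergenceError, DomainError, SingularDesignError

FAMILIES = ("poisson", "negbinomial")


@dataclass(frozen=True)
class GlmFit:
    family: str
    params: pd.Series
    bse: pd.Series
    log_likelihood: float
    aic: float
    deviance: float
    converged: bool
    n_obs: int
    n_params: int  # includes the NB dispersion parameter
    dispersion_k: float | None = None  # NB: variance = mu + mu^2 / k

    def summary_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "std_errors": {k: float(v) for k, v in self.bse.items()},
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "deviance": self.deviance,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "dispersion_k": self.dispersion_k,
        }


def _check_design(x: pd.DataFrame) -> pd.DataFrame:
    arr = x.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise SingularDesignError("rank-deficient design matrix")
    return x


def _with_intercept(design: pd.DataFrame) -> pd.DataFrame:
    if "const" in design.columns or "Intercept" in design.columns:
        return design
    return sm.add_constant(design, has_constant="add")


def fit_count_glm(
    response,
    design: pd.DataFrame,
    family: str = "poisson",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit a log-link count GLM by IRLS (via statsmodels).

    ``family`` is ``poisson`` or ``negbinomial``; for the latter the
    dispersion ``k`` (variance = mu + mu^2/k) is profiled on a log grid and
    refined by bounded scalar optimization, and counts toward the AIC
    parameter total.
    """
    y = np.asarray(response, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise DomainError("response must be nonnegative integer counts")
    x = _check_design(_with_intercept(design.astype(float)))

    if family == "poisson":
        model = sm.GLM(y, x, family=sm.families.Poisson())
        res = model.fit(maxiter=max_iter, tol=tol)
        if not res.converged:
            raise ConvergenceError(f"Poisson IRLS did not converge in {max_iter} iterations")
        n_params = x.shape[1]
        llf = float(res.llf)
        return GlmFit(
            family="poisson",
            params=pd.Series(res.params, index=x.columns),
            bse=pd.Series(res.bse, index=x.columns),
            log_likelihood=llf,
            aic=-2 * llf + 2 * n_params,
            deviance=float(res.deviance),
            converged=True,
            n_obs=len(y),
            n_params=n_params,
        )

    if family != "negbinomial":
        raise DomainError(f"unknown family {family!r}; choose from {FAMILIES}")

    def fit_at(log_k: float):
        k = float(np.exp(log_k))
        fam = sm.families.NegativeBinomial(alpha=1.0 / k)
        return sm.GLM(y, x, family=fam).fit(maxiter=max_iter, tol=tol), k

    # coarse profile over k, then golden-section refinement
    grid = np.linspace(np.log(0.01), np.log(100.0), 17)
    llfs = []
    for lk in grid:
        try:
            res_k, _ = fit_at(lk)
            llfs.append(float(res_k.llf))
        except Exception:
            llfs.append(-np.inf)
    best = int(np.argmax(llfs))
    lo = grid[max(0, best - 1)]
    hi = grid[min(len(grid) - 1, best + 1)]
    opt = minimize_scalar(
        lambda lk: -fit_at(lk)[0].llf, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6, "maxiter": max_iter},
    )
    res, k = fit_at(float(opt.x))
    if not res.converged:
        raise ConvergenceError("negative-binomial IRLS did not converge")
    n_params = x.shape[1] + 1  # + dispersion
    llf = float(res.llf)
    return GlmFit(
        family="negbinomial",
        params=pd.Series(res.params, index=x.columns),
        bse=pd.Series(res.bse, index=x.columns),
        log_likelihood=llf,
        aic=-2 * llf + 2 * n_params,
        deviance=float(res.deviance),
        converged=True,
        n_obs=len(y),
        n_params=n_params,
        dispersion_k=k,
    )


def likelihood_ratio_test(full: GlmFit, reduced: GlmFit) -> tuple[float, int, float]:
    """LRT of nested GLMs: chi2 = 2(l_full - l_reduced), df = param diff."""
    if full.family != reduced.family:
        raise DomainError("LRT requires the same family")
    if full.n_obs != reduced.n_obs:
        raise DomainError("LRT requires the same observations")
    df = full.n_params - reduced.n_params
    if df < 0 or not set(reduced.params.index) <= set(full.params.index):
        raise DomainError("reduced model is not nested in full model")
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    if df == 0:
        chi2 = 0.0
    return chi2, df, p


# ---------------------------------------------------------------------------
# Study-level convenience: richness ~ length and richness ~ species
# ---------------------------------------------------------------------------


def species_design(species: pd.Series) -> pd.DataFrame:
    """Treatment-coded design for a categorical species effect."""
    dummies = pd.get_dummies(species.astype(str), prefix="sp", drop_first=True, dtype=float)
    return dummies


def richness_glms(
    table: InfectionTable,
    metadata: HostMetadata | None = None,
    families: tuple[str, ...] = FAMILIES,
) -> dict:
    """Fit the richness-vs-length and richness-vs-species models.

    Individuals without length data are dropped listwise for the length
    model. For each predictor, both Poisson and negative-binomial fits are
    returned with their AIC, plus the LRT of the predictor against the
    intercept-only model (Poisson, the family chosen in the source design).
    """
    frame = infracommunity_frame(table)
    out: dict = {}

    # species model: all individuals
    y = frame["richness"].to_numpy()
    design_sp = species_design(frame["host_species"])
    design_null = pd.DataFrame(index=frame.index)
    fits_sp = {fam: fit_count_glm(y, design_sp, family=fam) for fam in families}
    null_sp = fit_count_glm(y, design_null, family="poisson")
    chi2, df, p = likelihood_ratio_test(fits_sp["poisson"], null_sp)
    out["species"] = {
        "fits": fits_sp,
        "lrt": {"chi2": chi2, "df": df, "p": p},
        "aic": {fam: fits_sp[fam].aic for fam in families},
    }

    if metadata is not None:
        has_len = frame["individual_id"].isin(metadata.length_cm)
        sub = frame[has_len]
        if len(sub) >= 3:
            y_len = sub["richness"].to_numpy()
            design_len = pd.DataFrame(
                {"length_cm": [metadata.length_cm[i] for i in sub["individual_id"]]},
                index=sub.index,
            )
            fits_len = {fam: fit_count_glm(y_len, design_len, family=fam) for fam in families}
            null_len = fit_count_glm(y_len, pd.DataFrame(index=sub.index), family="poisson")
            chi2, df, p = likelihood_ratio_test(fits_len["poisson"], null_len)
            out["length"] = {
                "fits": fits_len,
                "lrt": {"chi2": chi2, "df": df, "p": p},
                "aic": {fam: fits_len[fam].aic for fam in families},
                "n_with_length": int(len(sub)),
            }
    return out
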