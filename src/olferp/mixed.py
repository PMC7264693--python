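"""Mixed-effect estimation backend.

Every model in the pipeline is specified as fixed-effect columns plus
crossed random intercepts (participant, item) and a by-participant trial
slope.  The backend contract is: point estimate, standard error, 95%
interval and a two-sided p per fixed term.  Linear outcomes go through
REML (statsmodels ``MixedLM`` with the crossed factors expressed as
variance components in a single group); binary outcomes go through the
variational-Bayes fit of ``BinomialBayesMixedGLM``, whose posterior mean
and SD fill the same contract.  The p-value is the frequentist analogue
of a doubled posterior tail probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ModelFit:
    """Named coefficients with SEs, 95% intervals and two-sided p-values."""

    terms: dict[str, dict[str, float]]  # term -> beta/se/ci_low/ci_high/p
    model_id: str
    n_obs: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, t in self.terms.items():
            if not (t["ci_low"] <= t["beta"] <= t["ci_high"]):
                raise ValueError(f"interval does not bracket estimate for {name}")

    def beta(self, term: str) -> float:
        return self.terms[term]["beta"]

    def ci(self, term: str) -> tuple[float, float]:
        t = self.terms[term]
        return (t["ci_low"], t["ci_high"])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.terms).T
        df.index.name = "term"
        return df[["beta", "se", "ci_low", "ci_high", "p"]]


def _pack(names, beta, se, n_obs, model_id, converged, notes=None) -> ModelFit:
    z = stats.norm.ppf(0.975)
    terms = {}
    for i, name in enumerate(names):
        b, s = float(beta[i]), float(se[i])
        if not np.isfinite(s) or s < 0:
            s = 0.0
        p = 2.0 * stats.norm.sf(abs(b) / s) if s > 0 else 0.0
        terms[name] = {"beta": b, "se": s, "ci_low": min(b, b - z * s),
                       "ci_high": max(b, b + z * s), "p": p}
    return ModelFit(terms, model_id, n_obs, converged, notes or [])


def _vc_matrices(groups: dict[str, pd.Series],
                 slopes: dict[str, tuple[pd.Series, np.ndarray]]):
    """Dummy/indicator design blocks for the variance components."""
    blocks: dict[str, np.ndarray] = {}
    for name, fac in groups.items():
        blocks[name] = pd.get_dummies(fac, dtype=float).to_numpy()
    for name, (fac, x) in slopes.items():
        blocks[name] = pd.get_dummies(fac, dtype=float).to_numpy() * x[:, None]
    return blocks


def fit_lmm(y: np.ndarray, X: pd.DataFrame,
            participant: pd.Series, item: pd.Series | None = None,
            trial_slope: np.ndarray | None = None,
            model_id: str = "lmm", reml: bool = True) -> ModelFit:
    """Linear mixed model with crossed random intercepts via REML.

    The crossed factors (participant, item, by-participant trial slope)
    enter as variance components of a single all-encompassing group.
    Falls back to a reduced random structure (dropping the trial slope,
    then the item intercept) if the full fit fails or does not converge.
    """
    import statsmodels.formula.api as smf

    y = np.asarray(y, dtype=float)
    notes: list[str] = []

    df = X.copy()
    fe_cols = list(X.columns)
    safe = {c: f"x{i}" for i, c in enumerate(fe_cols)}
    df = df.rename(columns=safe)
    df["_y"] = y
    df["_one"] = 1
    df["_participant"] = np.asarray(participant)
    if item is not None:
        df["_item"] = np.asarray(item)
    if trial_slope is not None:
        df["_tslope"] = np.asarray(trial_slope, dtype=float)
    formula = "_y ~ 0 + " + " + ".join(safe.values())

    full_vc = {"participant": "0 + C(_participant)"}
    if item is not None:
        full_vc["item"] = "0 + C(_item)"
    structures = []
    if trial_slope is not None:
        structures.append({**full_vc,
                           "trial_by_participant": "0 + C(_participant):_tslope"})
    structures.append(dict(full_vc))
    if item is not None:
        structures.append({"participant": "0 + C(_participant)"})

    last_err: Exception | None = None
    last_fit: ModelFit | None = None
    for vc in structures:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups="_one",
                                    vc_formula=vc, re_formula="0")
                res = model.fit(reml=reml, method="lbfgs", maxiter=300)
            k = len(fe_cols)
            fit = _pack(fe_cols, np.asarray(res.params)[:k],
                        np.asarray(res.bse)[:k], len(y), model_id,
                        bool(res.converged), list(notes))
            if res.converged:
                return fit
            notes.append("non-convergence; trying reduced random structure")
            last_fit = fit
        except Exception as err:  # singular fits etc.
            last_err = err
            notes.append(f"fit failed ({type(err).__name__}); reduced structure")
    if last_fit is not None:
        last_fit.converged = False
        return last_fit
    raise RuntimeError(f"all random-effect structures failed: {last_err}")


def fit_glmm_logit(y: np.ndarray, X: pd.DataFrame,
                   participant: pd.Series, item: pd.Series | None = None,
                   trial_slope: np.ndarray | None = None,
                   model_id: str = "glmm") -> ModelFit:
    """Logistic mixed model via variational Bayes.

    The weak normal prior on the fixed effects acts as the ridge guard
    against quasi-separation.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    y = np.asarray(y, dtype=float)
    groups = {"participant": participant}
    if item is not None:
        groups["item"] = item
    slopes = ({"trial_by_participant": (participant, trial_slope)}
              if trial_slope is not None else {})
    blocks = _vc_matrices(groups, slopes)

    exog_vc = np.hstack(list(blocks.values()))
    ident = np.concatenate([
        np.full(b.shape[1], i) for i, b in enumerate(blocks.values())
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM(
            y, X.to_numpy(), exog_vc, ident,
            vcp_p=2.0, fe_p=2.0,
        )
        # explicit start values keep the fit fully deterministic
        n_par = model.k_fep + model.k_vcp + model.k_vc
        res = model.fit_vb(sd=np.full(n_par, np.exp(-0.5)))
    k = X.shape[1]
    return _pack(list(X.columns), res.fe_mean[:k], res.fe_sd[:k],
                 len(y), model_id, True, [])
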