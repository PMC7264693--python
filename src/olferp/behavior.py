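"""Behavioral RT and accuracy models with the study's covariate machinery.

Reaction times are modelled on the natural-log scale with a linear mixed
model; accuracy on the log-odds scale with a logistic mixed model.  Both
carry fixed effects for congruence, target modality and their
interaction, plus control covariates (trial number, tone delay, object
category, sex, and a perceptual between-category similarity index),
crossed random intercepts for participant and stimulus pairing, and a
by-participant trial slope.

Coding conventions (shared with the synthetic generator so that fitted
models are correctly specified): binary factors are effect-coded through
centering (±0.5 when balanced) and continuous covariates are centred and
divided by two standard deviations, making coefficients comparable
across binary and continuous predictors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mixed import ModelFit, fit_glmm_logit, fit_lmm

logger = logging.getLogger(__name__)

#: Reference (0) and non-reference (1) level per factor; the coefficient
#: sign convention follows from this order.
FACTOR_LEVELS = {
    "congruence": ("congruent", "incongruent"),
    "modality": ("olfactory", "visual"),
    "category": ("fruit", "flower"),
    "sex": ("F", "M"),
}

RT_BOUNDS_S = (0.2, 5.0)

FIXED_TERMS = ["intercept", "congruence", "modality", "interaction",
               "category", "sex", "trial", "delay", "similarity"]


def standardize_covariate(x) -> np.ndarray:
    """Centre and divide by two sample SDs (so the result has SD 0.5)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant covariate")
    return (x - x.mean()) / (2.0 * sd)


def effect_code(factor, levels: tuple[str, str] | None = None):
    """Effect-code a binary factor through centering.

    Returns ``(codes, level_map)`` where ``codes`` equals the 0/1 level
    indicator minus its observed mean (±0.5 for a balanced factor) and
    ``level_map`` maps each level to its centred code.
    """
    factor = pd.Series(factor)
    if levels is None:
        levels = tuple(sorted(factor.unique()))
    if len(levels) != 2:
        raise ValueError("effect_code handles binary factors only")
    unknown = set(factor.unique()) - set(levels)
    if unknown:
        raise ValueError(f"unexpected levels: {unknown}")
    ind = (factor == levels[1]).astype(float)
    codes = (ind - ind.mean()).to_numpy()
    level_map = {levels[0]: -float(ind.mean()), levels[1]: 1.0 - float(ind.mean())}
    return codes, level_map


def item_id(trials: pd.DataFrame) -> pd.Series:
    """The stimulus-pairing random factor: the 12 odor-picture combinations."""
    return trials["odor"].astype(str) + "|" + trials["picture"].astype(str)


def build_design_matrix(trials: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect columns for the full models, coded as documented above.

    Missing optional covariates (sex, similarity) are filled with zeros
    (i.e. held at the grand mean) with a log notice.
    """
    X = pd.DataFrame(index=trials.index)
    X["intercept"] = 1.0
    cong, _ = effect_code(trials["congruence"], FACTOR_LEVELS["congruence"])
    mod, _ = effect_code(trials["modality"], FACTOR_LEVELS["modality"])
    X["congruence"] = cong
    X["modality"] = mod
    X["interaction"] = cong * mod
    cat, _ = effect_code(trials["category"], FACTOR_LEVELS["category"])
    X["category"] = cat
    if "sex" in trials:
        X["sex"], _ = effect_code(trials["sex"], FACTOR_LEVELS["sex"])
    else:
        logger.info("no sex column; covariate held at grand mean")
        X["sex"] = 0.0
    X["trial"] = standardize_covariate(trials["trial"])
    X["delay"] = standardize_covariate(trials["delay_ms"])
    if "similarity" in trials and trials["similarity"].std(ddof=1) > 0:
        X["similarity"] = standardize_covariate(trials["similarity"])
    else:
        logger.info("no usable similarity column; covariate held at grand mean")
        X["similarity"] = 0.0
    return X[FIXED_TERMS]


def condition_label(trials: pd.DataFrame) -> pd.Series:
    return trials["modality"].astype(str) + "-" + trials["congruence"].astype(str)


def dummy_design_matrix(trials: pd.DataFrame, within: str) -> pd.DataFrame:
    """Dummy scheme for simple effects of modality within a congruence level.

    The olfactory cell of the ``within`` level is the reference; the
    model keeps the intercept plus dummies for the three remaining
    condition cells, so the ``visual-<within>`` coefficient is the
    modality contrast inside that level.  Control covariates ride along
    unchanged.
    """
    if within not in ("congruent", "incongruent"):
        raise ValueError("within must be 'congruent' or 'incongruent'")
    X = build_design_matrix(trials)
    X = X.drop(columns=["congruence", "modality", "interaction"])
    cond = condition_label(trials)
    reference = f"olfactory-{within}"
    for cell in sorted(cond.unique()):
        if cell != reference:
            X[cell] = (cond == cell).astype(float)
    return X


def trial_filter_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct trials with RTs inside the behavioral bounds."""
    lo, hi = RT_BOUNDS_S
    keep = (trials["correct"] == 1) & trials["rt_s"].between(lo, hi)
    return trials.loc[keep]


def fit_rt_model(trials: pd.DataFrame) -> ModelFit:
    """Log-RT linear mixed model on correct, in-bounds trials."""
    data = trial_filter_rt(trials).reset_index(drop=True)
    if data.empty:
        raise ValueError("no trials survive the RT/correctness filter")
    X = build_design_matrix(data)
    return fit_lmm(
        np.log(data["rt_s"].to_numpy()), X,
        participant=data["participant"], item=item_id(data),
        trial_slope=X["trial"].to_numpy(), model_id="rt",
    )


def fit_accuracy_model(trials: pd.DataFrame) -> ModelFit:
    """Logistic mixed model of response accuracy on in-bounds trials."""
    lo, hi = RT_BOUNDS_S
    data = trials.loc[trials["rt_s"].between(lo, hi)].reset_index(drop=True)
    if data.empty:
        raise ValueError("no trials survive the RT filter")
    X = build_design_matrix(data)
    return fit_glmm_logit(
        data["correct"].to_numpy(float), X,
        participant=data["participant"], item=item_id(data),
        trial_slope=X["trial"].to_numpy(), model_id="accuracy",
    )


def simple_effect_modality(trials: pd.DataFrame, congruence_level: str,
                           outcome: str = "rt") -> ModelFit:
    """Modality contrast within one congruence level via the dummy scheme.

    The coefficient of interest is the ``visual-<level>`` term.
    """
    if outcome == "rt":
        data = trial_filter_rt(trials).reset_index(drop=True)
        X = dummy_design_matrix(data, congruence_level)
        return fit_lmm(
            np.log(data["rt_s"].to_numpy()), X,
            participant=data["participant"], item=item_id(data),
            trial_slope=X["trial"].to_numpy(),
            model_id=f"rt_simple_{congruence_level}",
        )
    if outcome == "accuracy":
        lo, hi = RT_BOUNDS_S
        data = trials.loc[trials["rt_s"].between(lo, hi)].reset_index(drop=True)
        X = dummy_design_matrix(data, congruence_level)
        return fit_glmm_logit(
            data["correct"].to_numpy(float), X,
            participant=data["participant"], item=item_id(data),
            trial_slope=X["trial"].to_numpy(),
            model_id=f"accuracy_simple_{congruence_level}",
        )
    raise ValueError("outcome must be 'rt' or 'accuracy'")


def similarity_index(ratings: pd.DataFrame) -> pd.DataFrame:
    """Participant-wise between-category similarity index.

    All of a participant's ratings are z-scored jointly (making rating
    scales comparable across participants; the index is thus invariant
    to affine transforms of an individual's scale use), then averaged
    within participant x cue stimulus x modality.  With two competitor
    stimuli rated twice each, the index is the mean of four standardized
    ratings.  A participant with zero rating variance contributes
    indices of 0 (logged).
    """
    required = {"participant", "cue", "modality", "competitor", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table lacks columns: {sorted(missing)}")
    from .design import category_of
    for _, row in ratings.iterrows():
        if category_of(row["cue"]) == category_of(row["competitor"]):
            raise ValueError("cue and competitor must be of different categories")

    def _z(group: pd.Series) -> pd.Series:
        sd = group.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("participant with zero rating variance; index set to 0")
            return group * 0.0
        return (group - group.mean()) / sd

    z = ratings.groupby("participant")["rating"].transform(_z)
    out = (ratings.assign(z=z)
           .groupby(["participant", "cue", "modality"], as_index=False)["z"]
           .mean()
           .rename(columns={"z": "similarity"}))
    return out
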