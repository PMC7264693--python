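"""Factorial bimodal odor-picture design: pairings, blocks, delays, geometry.

The task crosses congruence (odor and picture denote the same object or
not), target modality (which cue the delayed tone points at), object
category (fruit/flower) and the two exemplars per category.  Eight
repetitions of the 16 factorial cells give the 128-trial session, split
over four blocks.  All randomization is seeded and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The four stimulus objects and their categories.
CATEGORY = {"lemon": "fruit", "pear": "fruit", "lavender": "flower", "lilac": "flower"}
OBJECTS = list(CATEGORY)
CATEGORIES = ("fruit", "flower")
MODALITIES = ("olfactory", "visual")
CONGRUENCE = ("congruent", "incongruent")

#: Tone-target delays (ms): 1000-2000 ms post stimulus offset in 200-ms steps.
DELAY_LEVELS_MS = (1000, 1200, 1400, 1600, 1800, 2000)

#: counterbalance_id -> (modality signalled by the low tone, button map label)
COUNTERBALANCE = {
    1: ("olfactory", "fruit-left"),
    2: ("olfactory", "flower-left"),
    3: ("visual", "fruit-left"),
    4: ("visual", "flower-left"),
}

TRIAL_COLUMNS = ["participant", "block", "trial", "congruence", "modality",
                 "category", "odor", "picture", "delay_ms", "tone", "button_map"]


@dataclass
class DesignConfig:
    n_repetitions: int = 8
    n_blocks: int = 4
    counterbalance_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.counterbalance_id not in COUNTERBALANCE:
            raise ValueError("counterbalance_id must be in 1-4")
        if self.n_repetitions < 1 or self.n_blocks < 1:
            raise ValueError("n_repetitions and n_blocks must be positive")


def category_of(obj: str) -> str:
    try:
        return CATEGORY[obj]
    except KeyError:
        raise ValueError(f"unknown stimulus object: {obj!r}") from None


def competitors(obj: str) -> list[str]:
    """The two objects of the other category."""
    return [o for o in OBJECTS if CATEGORY[o] != CATEGORY[obj]]


def enumerate_pairings(congruence: str) -> list[tuple[str, str]]:
    """All (odor, picture) pairings for a congruence level.

    Congruent pairs each object with itself (4); incongruent crosses the
    categories in both directions (8).
    """
    if congruence == "congruent":
        return [(o, o) for o in OBJECTS]
    if congruence == "incongruent":
        return [(o, p) for o in OBJECTS for p in competitors(o)]
    raise ValueError(f"unknown congruence label: {congruence!r}")


def _tone_for(modality: str, low_tone_modality: str) -> str:
    return "low" if modality == low_tone_modality else "high"


def _cells() -> list[tuple[str, str, str]]:
    """(congruence, modality, target object) for the 16 factorial cells."""
    return [(c, m, o) for c in CONGRUENCE for m in MODALITIES for o in OBJECTS]


def _draw_delays(n: int, rng: np.random.Generator) -> np.ndarray:
    """n delays, each level appearing floor(n/6) or ceil(n/6) times."""
    reps = np.tile(DELAY_LEVELS_MS, n // len(DELAY_LEVELS_MS))
    extra = rng.choice(DELAY_LEVELS_MS, size=n % len(DELAY_LEVELS_MS), replace=False)
    out = np.concatenate([reps, extra])
    rng.shuffle(out)
    return out


def build_design(config: DesignConfig, participant: str = "P01") -> pd.DataFrame:
    """Full factorial session for one participant.

    Each of the 16 cells repeats ``n_repetitions`` times, spread as evenly
    as possible over blocks.  Within each incongruent cell the two
    cross-category distractors alternate, so every target co-occurs with
    each distractor exactly n_repetitions/2 times (hence the even-
    repetitions requirement).  Trial order is randomized within block and
    delays are drawn balanced over the six levels within each
    congruence-by-modality group.
    """
    if config.n_repetitions % 2:
        raise ValueError("n_repetitions must be even to balance the two "
                         "incongruent distractors")
    rng = np.random.default_rng(config.seed)
    low_tone_mod, button_map = COUNTERBALANCE[config.counterbalance_id]

    rows: list[dict] = []
    for congruence, modality, target in _cells():
        if congruence == "congruent":
            distractors = [target] * config.n_repetitions
        else:
            pair = competitors(target)
            # balanced list, shuffled: each distractor exactly n_rep/2 times
            distractors = [pair[r % 2] for r in range(config.n_repetitions)]
            rng.shuffle(distractors)
        offset = rng.integers(config.n_blocks)
        for rep, dist in enumerate(distractors):
            other = dist if congruence == "incongruent" else target
            odor, picture = (target, other) if modality == "olfactory" else (other, target)
            rows.append({
                "participant": participant,
                "block": int((rep + offset) % config.n_blocks) + 1,
                "congruence": congruence,
                "modality": modality,
                "category": category_of(target),
                "odor": odor,
                "picture": picture,
                "tone": _tone_for(modality, low_tone_mod),
                "button_map": button_map,
            })
    table = pd.DataFrame(rows)

    # balanced delays within each congruence x modality group
    table["delay_ms"] = 0
    for _, idx in table.groupby(["congruence", "modality"]).groups.items():
        table.loc[idx, "delay_ms"] = _draw_delays(len(idx), rng)

    # randomize order within block, then number trials sequentially
    order = np.concatenate([
        rng.permutation(np.flatnonzero(table["block"].to_numpy() == b))
        for b in sorted(table["block"].unique())
    ])
    table = table.iloc[order].reset_index(drop=True)
    table["trial"] = np.arange(1, len(table) + 1)
    table.attrs["seed"] = config.seed
    return table[TRIAL_COLUMNS]


def build_training_design(config: DesignConfig, participant: str = "P01") -> pd.DataFrame:
    """One trial per factorial cell (16), with the modality cue displayed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7261]))
    low_tone_mod, button_map = COUNTERBALANCE[config.counterbalance_id]
    rows = []
    for congruence, modality, target in _cells():
        other = rng.choice(competitors(target)) if congruence == "incongruent" else target
        odor, picture = (target, other) if modality == "olfactory" else (other, target)
        rows.append({
            "participant": participant, "block": 0,
            "congruence": congruence, "modality": modality,
            "category": category_of(target), "odor": odor, "picture": picture,
            "delay_ms": int(rng.choice(DELAY_LEVELS_MS)),
            "tone": _tone_for(modality, low_tone_mod), "button_map": button_map,
        })
    table = pd.DataFrame(rows)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table["trial"] = np.arange(1, len(table) + 1)
    table["show_modality_cue"] = True
    table.attrs["seed"] = config.seed
    return table[TRIAL_COLUMNS + ["show_modality_cue"]]


def validate_design(table: pd.DataFrame) -> None:
    """Raise if the trial table violates the design invariants."""
    for _, row in table.iterrows():
        if category_of(row["odor"]) == category_of(row["picture"]):
            if row["congruence"] != "congruent" or row["odor"] != row["picture"]:
                raise ValueError(f"bad pairing in trial {row['trial']}")
        elif row["congruence"] != "incongruent":
            raise ValueError(f"bad pairing in trial {row['trial']}")
        if row["delay_ms"] not in DELAY_LEVELS_MS:
            raise ValueError(f"delay outside the 6-level set in trial {row['trial']}")


def visual_angle(extent_cm: float, distance_cm: float) -> float:
    """Visual angle (degrees) subtended by ``extent_cm`` at ``distance_cm``.

    2 * arctan(extent / (2 * distance)).
    """
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    if extent_cm < 0:
        raise ValueError("extent must be non-negative")
    return float(np.degrees(2.0 * np.arctan2(extent_cm, 2.0 * distance_cm)))
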