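"""Canonical enumeration of the 16 experimental conditions.

The task is a four-key Stroop task whose four colors (and the matching
color words) are split into two fixed sets, ``red``/``blue`` and
``yellow``/``green``.  Words and colors combine within a set only, giving
8 unique stimuli; crossing each stimulus with the item-specific proportion
congruency (ISPC) level of its color set (mostly congruent, MC, vs mostly
incongruent, MI) yields the 16 conditions used throughout decoding and RSA.

Every module that needs condition structure (design generation, regressor
construction, class maps) imports the single table built here so that the
``condition_id`` ordering is defined exactly once.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

COLORS: tuple[str, ...] = ("red", "blue", "yellow", "green")
SETS: dict[str, tuple[str, str]] = {"A": ("red", "blue"), "B": ("yellow", "green")}
SET_OF_COLOR: dict[str, str] = {c: s for s, pair in SETS.items() for c in pair}
PARTNER: dict[str, str] = {
    c: (pair[1] if c == pair[0] else pair[0]) for pair in SETS.values() for c in pair
}
ISPC_LEVELS: tuple[str, str] = ("mc", "mi")

#: 8 unique stimuli as (color, word): congruent pair then the two
#: incongruent combinations, set A before set B.
STIMULI: tuple[tuple[str, str], ...] = (
    ("red", "red"),
    ("blue", "blue"),
    ("red", "blue"),
    ("blue", "red"),
    ("yellow", "yellow"),
    ("green", "green"),
    ("yellow", "green"),
    ("green", "yellow"),
)


def most_likely_response(word: str, ispc: str) -> str:
    """Response most often paired with *word* under the given ISPC level.

    Under MC a word mostly appears congruently, so its most-likely response
    is its own color's key; under MI it mostly appears incongruently and,
    because each set holds exactly two colors, the alternative response is
    unique: the other color of the word's set.
    """
    return word if ispc == "mc" else PARTNER[word]


def condition_label(ispc: str, color: str, word: str) -> str:
    cong = "c" if color == word else "i"
    return f"{ispc}{cong}{color[0]}{word[0]}"


@lru_cache(maxsize=1)
def condition_table() -> pd.DataFrame:
    """One row per condition_id (1..16), fixed canonical order.

    Order: all 8 stimuli under MC (ids 1-8, stimulus order as in
    :data:`STIMULI`), then the same stimuli under MI (ids 9-16).  Derived
    columns give the 8-way stimulus-control (SC: color x ISPC) and
    stimulus-response (SR: word x most-likely response) class labels and
    the frequent/infrequent status implied by the 75/25 manipulation.
    """
    rows = []
    for i_ispc, ispc in enumerate(ISPC_LEVELS):
        for i_stim, (color, word) in enumerate(STIMULI):
            congruency = "congruent" if color == word else "incongruent"
            frequent = (ispc == "mc") == (congruency == "congruent")
            mlr = most_likely_response(word, ispc)
            rows.append(
                {
                    "condition_id": i_ispc * 8 + i_stim + 1,
                    "label": condition_label(ispc, color, word),
                    "ispc": ispc,
                    "color": color,
                    "word": word,
                    "set": SET_OF_COLOR[color],
                    "congruency": congruency,
                    "frequency": "frequent" if frequent else "infrequent",
                    "most_likely_response": mlr,
                    "correct_response": color,
                    "sc_class": i_ispc * 4 + COLORS.index(color) + 1,
                    "sr_class": i_ispc * 4 + COLORS.index(word) + 1,
                }
            )
    return pd.DataFrame(rows)


def condition_id(ispc: str, color: str, word: str) -> int:
    tab = condition_table()
    hit = tab[(tab.ispc == ispc) & (tab.color == color) & (tab.word == word)]
    if hit.empty:
        raise ValueError(f"no such condition: ispc={ispc} color={color} word={word}")
    return int(hit.condition_id.iloc[0])


def sharing_matrix(factor: str) -> np.ndarray:
    """16 x 16 binary matrix: conditions i, j share the level of *factor*.

    ``identity`` marks i == j; ``sc``/``sr`` share iff the respective 8-way
    class coincides.
    """
    tab = condition_table()
    if factor == "identity":
        return np.eye(16)
    col = {
        "color": "color",
        "word": "word",
        "congruency": "congruency",
        "ispc": "ispc",
        "sc": "sc_class",
        "sr": "sr_class",
        "frequency": "frequency",
        "set": "set",
    }[factor]
    v = tab[col].to_numpy()
    return (v[:, None] == v[None, :]).astype(float)
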