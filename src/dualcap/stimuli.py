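"""Constrained letter-string stimulus generators.

Two stimulus sets are produced, mirroring the two tasks:

* Experiment 1 (vowel detection): *vowel-present* strings have exactly
  one vowel (a, e, i, o, u) and four consonants; *vowel-absent* strings
  are five consonants and always include at least one of q, j, c, n, s
  (consonants visually similar to a vowel).  No string is pronounceable,
  none contains "y", and each has at least four unique letters.

* Experiment 2 (pronounceability): both categories have exactly one
  vowel and four consonants; *pronounceable* strings are built from an
  onset + vowel + coda template using a whitelist of legal English
  syllable onsets and codas, *unpronounceable* strings violate it.  The
  two categories are matched on starting letter (equal counts per
  letter).

Pronounceability is a deterministic orthographic-legality rule (the
whitelists below), not a corpus n-gram model: the task only needs a
documented, reproducible rule ("crult" is legal — onset "cr", coda
"lt" — while "crtul" is not).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusItem",
    "is_pronounceable",
    "gen_stimuli_exp1",
    "gen_stimuli_exp2",
    "write_stimuli",
]

VOWELS = "aeiou"
# No "y" anywhere, per the stimulus constraints.
CONSONANTS = "bcdfghjklmnpqrstvwxz"
VOWEL_LIKE = set("qjcns")

# Legal syllable onsets by length.  Single-consonant onsets exclude "x"
# (never word-initial in English) and "q" (requires "u" + vowel).
ONSETS_1 = set("bcdfghjklmnprstvwz")
ONSETS_2 = {
    "bl", "br", "cl", "cr", "dr", "fl", "fr", "gl", "gr", "pl", "pr",
    "sc", "sk", "sl", "sm", "sn", "sp", "st", "sw", "tr", "tw",
    "ch", "sh", "th", "wh",
}
ONSETS_3 = {"scr", "spl", "spr", "str", "shr", "thr"}

# Legal syllable codas by length.
CODAS_1 = set("bdfgklmnprstxz")
CODAS_2 = {
    "ck", "ct", "ft", "ld", "lf", "lk", "lm", "lp", "lt", "mp", "nd",
    "ng", "nk", "nt", "pt", "rb", "rd", "rf", "rg", "rk", "rl", "rm",
    "rn", "rp", "rt", "sk", "sp", "st", "sh", "ch", "th",
}
CODAS_3 = {"rst", "mpt", "nch", "tch", "nth", "rth", "lth", "rsh", "rch"}

_ONSETS = {1: ONSETS_1, 2: ONSETS_2, 3: ONSETS_3}
_CODAS = {1: CODAS_1, 2: CODAS_2, 3: CODAS_3}

STRING_LENGTH = 5
MIN_UNIQUE_LETTERS = 4


@dataclass(frozen=True)
class StimulusItem:
    """One letter-string stimulus with its binary category label.

    ``category`` is ``"present"`` (vowel present / pronounceable) or
    ``"absent"`` (vowel absent / unpronounceable).
    """

    text: str
    category: str
    experiment: int

    def __post_init__(self) -> None:
        if len(self.text) != STRING_LENGTH or not self.text.islower():
            raise ValueError(f"stimulus must be 5 lowercase letters: {self.text!r}")
        if "y" in self.text:
            raise ValueError(f"'y' not allowed: {self.text!r}")
        if len(set(self.text)) < MIN_UNIQUE_LETTERS:
            raise ValueError(f"needs >= {MIN_UNIQUE_LETTERS} unique letters: {self.text!r}")
        if self.category not in ("present", "absent"):
            raise ValueError(f"bad category {self.category!r}")
        if self.experiment not in (1, 2):
            raise ValueError(f"experiment must be 1 or 2, got {self.experiment}")


def is_pronounceable(text: str) -> bool:
    """Orthographic legality: onset + single vowel + coda, both whitelisted."""
    if len(text) != STRING_LENGTH or "y" in text:
        return False
    vowel_positions = [i for i, ch in enumerate(text) if ch in VOWELS]
    if len(vowel_positions) != 1:
        return False
    i = vowel_positions[0]
    if i < 1 or i > 3:
        return False
    onset, coda = text[:i], text[i + 1 :]
    return onset in _ONSETS[len(onset)] and coda in _CODAS[len(coda)]


def _valid_common(text: str) -> bool:
    return len(set(text)) >= MIN_UNIQUE_LETTERS and "y" not in text


def _rejection_sample(rng, n, propose, accept, what, max_factor=2000):
    """Draw n unique accepted strings or raise if the space seems exhausted."""
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    limit = max_factor * n + 10_000
    while len(out) < n:
        attempts += 1
        if attempts > limit:
            raise ValueError(
                f"could not generate {n} unique {what} stimuli "
                f"(found {len(out)} after {attempts} attempts); "
                "the constraint set may not support that many items"
            )
        s = propose()
        if s in seen or not accept(s):
            continue
        seen.add(s)
        out.append(s)
    return out


def gen_stimuli_exp1(n_per_category: int, seed: int = 0) -> list[StimulusItem]:
    """Vowel-present and vowel-absent strings for the letter task."""
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    cons = np.array(list(CONSONANTS))

    def propose_present() -> str:
        letters = rng.choice(cons, size=4).tolist()
        vowel = VOWELS[rng.integers(len(VOWELS))]
        pos = int(rng.integers(STRING_LENGTH))
        letters.insert(pos, vowel)
        return "".join(letters)

    def accept_present(s: str) -> bool:
        return _valid_common(s) and not is_pronounceable(s)

    def propose_absent() -> str:
        return "".join(rng.choice(cons, size=STRING_LENGTH).tolist())

    def accept_absent(s: str) -> bool:
        return _valid_common(s) and bool(set(s) & VOWEL_LIKE)

    present = _rejection_sample(rng, n_per_category, propose_present,
                                accept_present, "vowel-present")
    absent = _rejection_sample(rng, n_per_category, propose_absent,
                               accept_absent, "vowel-absent")
    return [StimulusItem(s, "present", 1) for s in present] + [
        StimulusItem(s, "absent", 1) for s in absent
    ]


def _all_pronounceable() -> list[str]:
    out = []
    for k in (1, 2, 3):
        for onset in sorted(_ONSETS[k]):
            for v in VOWELS:
                for coda in sorted(_CODAS[4 - k]):
                    s = onset + v + coda
                    if _valid_common(s):
                        out.append(s)
    return out


def gen_stimuli_exp2(n_per_category: int, seed: int = 0) -> list[StimulusItem]:
    """Pronounceable and unpronounceable one-vowel strings, matched on
    starting letter (equal counts per letter across categories)."""
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    pool = _all_pronounceable()
    if n_per_category > len(pool):
        raise ValueError(
            f"only {len(pool)} distinct pronounceable strings exist under the "
            f"legality whitelists; requested {n_per_category}"
        )
    idx = rng.choice(len(pool), size=n_per_category, replace=False)
    pron = [pool[i] for i in idx]

    cons = np.array(list(CONSONANTS))
    unpron: list[str] = []
    seen: set[str] = set(pron)
    for first in pron:  # match the starting letter one-for-one
        head = first[0]

        def propose() -> str:
            rest = rng.choice(cons, size=3).tolist()
            vowel = VOWELS[rng.integers(len(VOWELS))]
            pos = int(rng.integers(1, STRING_LENGTH))
            tail = rest[:]
            tail.insert(pos - 1, vowel)
            return head + "".join(tail)

        def accept(s: str) -> bool:
            return s not in seen and _valid_common(s) and not is_pronounceable(s)

        attempts = 0
        while True:
            attempts += 1
            if attempts > 50_000:
                raise ValueError(
                    f"could not build an unpronounceable match starting with {head!r}"
                )
            s = propose()
            if accept(s):
                seen.add(s)
                unpron.append(s)
                break

    return [StimulusItem(s, "present", 2) for s in pron] + [
        StimulusItem(s, "absent", 2) for s in unpron
    ]


def write_stimuli(items: list[StimulusItem], path: str | Path) -> None:
    """Write a stimulus list as a 2-column CSV (text, category)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["text", "category"])
        for it in items:
            w.writerow([it.text, it.category])
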