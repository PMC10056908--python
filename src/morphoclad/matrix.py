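"""Core containers for discrete morphological characters and geographic ranges.

A :class:`CharacterMatrix` holds unordered multistate characters coded with
integer states ``0..6``.  Two special codes follow standard cladistic
conventions: ``?`` marks an unobserved (missing) cell and ``-`` marks an
inapplicable one.  Both are treated as complete ambiguity (any state) when
trees are scored; the distinction is purely notational and is preserved on
round-trip through the file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel cell codes (stored in the int8 ``states`` array).
UNOBSERVED: int = -1
INAPPLICABLE: int = -2

#: Largest supported integer state (states are single digits 0..MAX_STATE).
MAX_STATE: int = 6

_TOKEN_OF = {UNOBSERVED: "?", INAPPLICABLE: "-"}
_CODE_OF = {"?": UNOBSERVED, "-": INAPPLICABLE}


class MatrixFormatError(ValueError):
    """Raised when a character-matrix document is malformed."""


def token_to_code(tok: str) -> int:
    """Map a one-character cell token to its integer cell code."""
    if tok in _CODE_OF:
        return _CODE_OF[tok]
    if len(tok) == 1 and tok.isdigit():
        s = int(tok)
        if s <= MAX_STATE:
            return s
    raise MatrixFormatError(f"unknown state token {tok!r} (expected 0-{MAX_STATE}, '?' or '-')")


def code_to_token(code: int) -> str:
    if code in _TOKEN_OF:
        return _TOKEN_OF[code]
    if 0 <= code <= MAX_STATE:
        return str(code)
    raise MatrixFormatError(f"cell code {code} not representable as a single-digit token")


@dataclass
class CharacterMatrix:
    """Taxa-by-characters matrix of unordered multistate codings.

    Parameters
    ----------
    taxa:
        Ordered taxon labels; unique and non-empty.
    states:
        ``(n_taxa, n_characters)`` int8 array; entries are ``0..6``,
        :data:`UNOBSERVED` or :data:`INAPPLICABLE`.
    character_labels:
        Optional descriptions, one per character.
    """

    taxa: list[str]
    states: np.ndarray
    character_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise MatrixFormatError("states must be a 2-D array")
        if len(self.taxa) != self.states.shape[0]:
            raise MatrixFormatError(
                f"{len(self.taxa)} taxon labels but {self.states.shape[0]} matrix rows"
            )
        seen: set[str] = set()
        for t in self.taxa:
            if not t:
                raise MatrixFormatError("empty taxon label")
            if t in seen:
                raise MatrixFormatError(f"duplicate taxon {t!r}")
            seen.add(t)
        bad = (self.states > MAX_STATE) | (self.states < INAPPLICABLE)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixFormatError(
                f"invalid cell code {int(self.states[i, j])} at taxon {self.taxa[i]!r}, character {j}"
            )
        if self.character_labels is not None and len(self.character_labels) != self.n_characters:
            raise MatrixFormatError("character_labels length mismatch")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def subset_taxa(self, keep: list[str]) -> "CharacterMatrix":
        """Restrict to the given taxa (in the given order)."""
        idx = [self.taxa.index(t) for t in keep]
        return CharacterMatrix(list(keep), self.states[idx].copy(), self.character_labels)

    def subset_characters(self, cols) -> "CharacterMatrix":
        """Restrict/reorder characters, e.g. for a bootstrap pseudo-replicate."""
        cols = np.asarray(cols, dtype=int)
        labels = None
        if self.character_labels is not None:
            labels = [self.character_labels[c] for c in cols]
        return CharacterMatrix(list(self.taxa), self.states[:, cols].copy(), labels)

    def observed_states(self, char: int) -> np.ndarray:
        """Distinct observed states of one character (missing codes excluded)."""
        col = self.states[:, char]
        return np.unique(col[col >= 0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self.taxa == other.taxa and np.array_equal(self.states, other.states)


@dataclass
class AreaMatrix:
    """Binary taxon-by-area presence matrix for ancestral-range analysis.

    Areas are short ordered codes (here A-D for Europe, Middle East/Western
    Asia, Central Asia, Eastern Asia).  A taxon may occupy several areas;
    every taxon must occupy at least one.
    """

    taxa: list[str]
    areas: list[str]
    presence: np.ndarray = field(default=None)  # (n_taxa, n_areas) uint8

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.shape != (len(self.taxa), len(self.areas)):
            raise ValueError("presence shape does not match taxa x areas")
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("duplicate area codes")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        empty = np.flatnonzero(self.presence.sum(axis=1) == 0)
        if empty.size:
            raise ValueError(f"taxon {self.taxa[int(empty[0])]!r} has no area")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def ranges(self) -> dict[str, str]:
        """Taxon -> concatenated area codes, e.g. ``'ACD'``."""
        out = {}
        for i, t in enumerate(self.taxa):
            out[t] = "".join(a for j, a in enumerate(self.areas) if self.presence[i, j])
        return out

    def subset_taxa(self, keep: list[str]) -> "AreaMatrix":
        idx = [self.taxa.index(t) for t in keep]
        return AreaMatrix(list(keep), list(self.areas), self.presence[idx].copy())
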