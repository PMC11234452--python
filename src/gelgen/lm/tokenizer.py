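"""Regex-based SMILES tokenization and vocabulary handling.

Multi-character atom symbols (Cl, Br), bracket atoms (``[nH]``, ``[C@@H]``)
and two-digit ring-closure labels (``%10``) are single tokens; a character
model would split them and generate chemically meaningless strings.
Sequences carry START/END sentinels; PAD fills training windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

PAD, START, END = "<pad>", "<s>", "</s>"
SPECIALS = (PAD, START, END)

# the standard published SMILES token pattern
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|N|O|S|P|F|I|B|C|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%\d{2}|\d)"
)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; raise on uncovered characters."""
    if not smiles:
        raise ValueError("cannot tokenize an empty SMILES string")
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        covered = set("".join(tokens))
        bad = sorted(set(smiles) - covered)
        raise ValueError(f"cannot tokenize {smiles!r}: unknown characters {bad}")
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Dense token <-> index mapping with PAD/START/END at fixed positions."""

    tokens: tuple[str, ...]
    index: dict = field(repr=False, hash=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def start_id(self) -> int:
        return self.index[START]

    @property
    def end_id(self) -> int:
        return self.index[END]

    @classmethod
    def from_corpus(cls, smiles: list[str]) -> "Vocabulary":
        """Build a vocabulary covering every token in the corpus."""
        seen: set[str] = set()
        for s in smiles:
            seen.update(tokenize(s))
        return cls(tuple(SPECIALS) + tuple(sorted(seen)))

    def encode(self, smiles: str) -> list[int]:
        """START + token ids + END; raises naming any out-of-vocabulary token."""
        ids = [self.start_id]
        for tok in tokenize(smiles):
            if tok not in self.index:
                raise ValueError(f"token {tok!r} not in vocabulary")
            ids.append(self.index[tok])
        ids.append(self.end_id)
        return ids

    def decode(self, ids: list[int]) -> str:
        """Inverse of encode; sentinels and padding are stripped."""
        skip = {self.pad_id, self.start_id, self.end_id}
        return "".join(self.tokens[i] for i in ids if i not in skip)
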