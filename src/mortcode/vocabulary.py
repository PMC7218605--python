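"""ICD-10 code tokens, chapter mapping, and vocabulary construction.

Codes are stored in a single canonical form: uppercase, dot removed
("F11.2" -> "F112"), one letter followed by 2 or 3 digits.  A
:class:`Vocabulary` maps the distinct codes observed in a corpus onto
contiguous integer indices ``0..V-1`` and reserves two extra indices for
grid padding and for codes unseen at training time.
"""

from __future__ import annotations

import csv
import hashlib
import re
import string
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "CodeError",
    "parse_code",
    "chapter_of",
    "Vocabulary",
    "build_vocabulary",
    "make_synthetic_vocabulary",
]

_CODE_RE = re.compile(r"^[A-Z][0-9]{2,3}$")


class CodeError(ValueError):
    """Raised for malformed ICD-10 code tokens."""


def parse_code(token: str) -> str:
    """Normalize and validate an ICD-10 code token.

    Uppercases and strips the decimal dot, then checks the canonical
    shape (one letter + 2-3 digits).

    >>> parse_code("f11.2")
    'F112'
    """
    if not isinstance(token, str) or not token.strip():
        raise CodeError(f"empty or non-string ICD-10 code token: {token!r}")
    norm = token.strip().upper().replace(".", "")
    if not _CODE_RE.match(norm):
        raise CodeError(
            f"malformed ICD-10 code token {token!r} "
            "(expected one letter followed by 2-3 digits, e.g. 'F11' or 'X42')"
        )
    return norm


def _load_chapter_table() -> list[tuple[str, str, str]]:
    with resources.files("mortcode.data").joinpath("icd10_chapters.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        rows = list(csv.DictReader(fh))
    return [(r["start"], r["end"], r["chapter"]) for r in rows]


_CHAPTER_RANGES = _load_chapter_table()

#: The 22 ICD-10 chapter labels in order.
CHAPTERS = tuple(ch for _, _, ch in _CHAPTER_RANGES)


def chapter_of(code: str) -> str:
    """Map a valid ICD-10 code to its chapter label (roman numeral).

    The chapter is a pure function of the 3-character category: e.g.
    "H00" lies in H00-H59, diseases of the eye and adnexa, chapter VII;
    "X42" lies in V01-Y98, external causes, chapter XX.
    """
    norm = parse_code(code)
    category = norm[:3]
    for start, end, chapter in _CHAPTER_RANGES:
        if start <= category <= end:
            return chapter
    raise CodeError(f"code {code!r} falls outside every ICD-10 chapter range")


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between observed ICD-10 codes and indices ``0..V-1``.

    Two reserved indices sit immediately after the code range:
    ``pad_index = V`` marks empty grid cells and ``unknown_index = V+1``
    absorbs codes unseen at training time.  ``chapter_map`` overrides the
    bundled ICD-10 chapter ranges (used by synthetic vocabularies whose
    chapters are declared at construction).
    """

    codes: tuple[str, ...]
    chapter_map: dict[str, str] | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("vocabulary requires at least one code")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.codes)}
        )
        if len(self._index) != len(self.codes):
            raise ValueError("vocabulary codes must be distinct")

    @property
    def size(self) -> int:
        return len(self.codes)

    @property
    def pad_index(self) -> int:
        return len(self.codes)

    @property
    def unknown_index(self) -> int:
        return len(self.codes) + 1

    def index_of(self, code: str, *, strict: bool = False) -> int:
        """Index of ``code``; unknown codes map to ``unknown_index``
        unless ``strict`` is set."""
        idx = self._index.get(code)
        if idx is None:
            if strict:
                raise KeyError(f"code {code!r} not in vocabulary")
            return self.unknown_index
        return idx

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def code_at(self, index: int) -> str:
        return self.codes[index]

    def chapter_of_index(self, index: int) -> str:
        code = self.codes[index]
        if self.chapter_map is not None:
            return self.chapter_map[code]
        return chapter_of(code)

    def chapters(self) -> tuple[str, ...]:
        """Distinct chapter labels present, in first-appearance order."""
        seen: dict[str, None] = {}
        for i in range(self.size):
            seen.setdefault(self.chapter_of_index(i), None)
        return tuple(seen)

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update("\n".join(self.codes).encode())
        if self.chapter_map is not None:
            h.update(b"\x00")
            h.update(
                "\n".join(f"{c},{ch}" for c, ch in sorted(self.chapter_map.items())).encode()
            )
        return h.hexdigest()

    def to_dict(self) -> dict:
        return {"codes": list(self.codes), "chapter_map": self.chapter_map}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        cm = d.get("chapter_map")
        return cls(tuple(d["codes"]), dict(cm) if cm else None)


def build_vocabulary(
    codes: list[str], chapter_map: dict[str, str] | None = None
) -> Vocabulary:
    """Deduplicate, validate and lexicographically order ``codes``.

    Construction is order-insensitive: any permutation of the input list
    yields the identical vocabulary.
    """
    if not codes:
        raise ValueError("cannot build a vocabulary from an empty code list")
    normed = sorted({parse_code(c) for c in codes})
    return Vocabulary(tuple(normed), chapter_map)


def read_code_list(path) -> Vocabulary:
    """Load a two-column ``code,chapter`` CSV (header required, UTF-8)."""
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"code", "chapter"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header with 'code,chapter' columns")
        rows = [(parse_code(r["code"]), r["chapter"].strip()) for r in reader]
    if not rows:
        raise ValueError(f"{path}: no codes found")
    return build_vocabulary([c for c, _ in rows], chapter_map=dict(rows))


def write_code_list(vocab: Vocabulary, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "chapter"])
        for i, code in enumerate(vocab.codes):
            w.writerow([code, vocab.chapter_of_index(i)])


def make_synthetic_vocabulary(
    n_chapters: int, codes_per_chapter: int, seed: int
) -> Vocabulary:
    """Build a synthetic code set: one letter per chapter, zero-padded numbers.

    The chapter of a synthetic code is declared at construction (its
    letter), not looked up in the real ICD-10 ranges.  Deterministic in
    ``seed``: the seed picks which letters stand for which chapter.
    """
    import numpy as np

    if not 2 <= n_chapters <= 26:
        raise ValueError("n_chapters must be between 2 and 26")
    if not 2 <= codes_per_chapter <= 100:
        raise ValueError("codes_per_chapter must be between 2 and 100")
    rng = np.random.default_rng(seed)
    letters = list(string.ascii_uppercase)
    rng.shuffle(letters)
    letters = sorted(letters[:n_chapters])
    codes, chapter_map = [], {}
    for k, letter in enumerate(letters):
        for j in range(codes_per_chapter):
            code = f"{letter}{j:02d}"
            codes.append(code)
            chapter_map[code] = f"S{k + 1:02d}"
    return build_vocabulary(codes, chapter_map)
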