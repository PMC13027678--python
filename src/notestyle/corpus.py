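"""Grouped note-corpus data model, normalization, segmentation and I/O.

A :class:`Note` carries one free-text clinical note together with its author
metadata (specialty, generator, optional model name, case id) and the derived
text views the downstream analyses consume: NFKC-normalized text, a token
sequence, and a sentence segmentation.  A :class:`GroupedCorpus` is a list of
notes plus a group-key function (default: specialty x generator, the study's
four author groups).

Tokenization is a pluggable contract (:class:`TokenizerSpec`): the analyses are
tokenizer-agnostic, so the default is whitespace splitting on normalized text;
a morphological analyzer (MeCab/Sudachi-style) can be injected for Japanese
text without any change to the rest of the package.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "Note", "GroupedCorpus", "TokenizerSpec", "WHITESPACE_TOKENIZER",
    "DEFAULT_PUNCTUATION", "DEFAULT_SENTENCE_DELIMITERS",
    "normalize_text", "segment_sentences", "make_note",
    "load_corpus", "save_corpus", "SchemaError",
]

SPECIALTIES = ("psychiatry", "internal_medicine", "other")
GENERATORS = ("human", "llm")

#: Punctuation removed during normalization.  The Japanese marks cover the
#: common full-width set; the ASCII set mirrors them.  Configurable per call.
DEFAULT_PUNCTUATION = frozenset("。、・「」『』（）.,;:!?()\"'")

#: Sentence boundaries: ideographic/ASCII full stop or a line break.
DEFAULT_SENTENCE_DELIMITERS = frozenset({"。", ".", "\n"})

_WS_RE = re.compile(r"\s+")


class SchemaError(ValueError):
    """A corpus record violates the input schema."""


def normalize_text(raw: str, punctuation_set: Iterable[str] = DEFAULT_PUNCTUATION) -> str:
    """Normalize raw note text.

    Applies, in order: Unicode NFKC normalization, removal of every character
    in ``punctuation_set``, collapse of whitespace runs to single spaces, and
    stripping of leading/trailing whitespace.  Punctuation is removed before
    whitespace collapse so the result never contains the double spaces that
    removal inside already-collapsed text would create.  Idempotent.
    """
    text = unicodedata.normalize("NFKC", raw)
    punct = set(punctuation_set)
    if punct:
        text = "".join(ch for ch in text if ch not in punct)
    text = _WS_RE.sub(" ", text).strip()
    return text


def segment_sentences(
    text: str, delimiters: Iterable[str] = DEFAULT_SENTENCE_DELIMITERS
) -> list[str]:
    """Split ``text`` at any delimiter character; drop empty segments.

    Segmentation runs on text that still contains its delimiters — i.e. before
    punctuation removal — since the default punctuation set includes the
    sentence-final marks.  Segments are stripped; order is preserved.
    """
    delims = set(delimiters)
    if not delims:
        raise ValueError("delimiters must be non-empty")
    out: list[str] = []
    buf: list[str] = []
    for ch in text:
        if ch in delims:
            seg = "".join(buf).strip()
            if seg:
                out.append(seg)
            buf = []
        else:
            buf.append(ch)
    seg = "".join(buf).strip()
    if seg:
        out.append(seg)
    return out


@dataclass(frozen=True)
class TokenizerSpec:
    """A named, deterministic tokenizer contract.

    ``tokenize`` maps normalized text to a token sequence; same input must
    always yield the same tokens, and tokens must contain no whitespace.
    """

    name: str
    tokenize: Callable[[str], Sequence[str]]

    def __call__(self, text: str) -> list[str]:
        tokens = list(self.tokenize(text))
        for t in tokens:
            if not t or _WS_RE.search(t):
                raise ValueError(
                    f"tokenizer {self.name!r} produced an empty or "
                    f"whitespace-containing token: {t!r}"
                )
        return tokens


WHITESPACE_TOKENIZER = TokenizerSpec("whitespace", lambda s: s.split())


@dataclass(frozen=True)
class Note:
    """One note with metadata and derived text views."""

    note_id: str
    specialty: str
    generator: str
    case_id: str
    raw_text: str
    norm_text: str
    tokens: tuple[str, ...]
    sentences: tuple[tuple[str, ...], ...]
    model_name: str | None = None

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_chars(self) -> int:
        return len(self.norm_text)


def make_note(
    note_id: str,
    specialty: str,
    generator: str,
    case_id: str,
    raw_text: str,
    model_name: str | None = None,
    tokenizer: TokenizerSpec = WHITESPACE_TOKENIZER,
    punctuation_set: Iterable[str] = DEFAULT_PUNCTUATION,
    sentence_delimiters: Iterable[str] = DEFAULT_SENTENCE_DELIMITERS,
) -> Note:
    """Build a :class:`Note`, deriving norm_text, tokens and sentences.

    Sentences are segmented on the NFKC-normalized text *before* punctuation
    removal (the sentence delimiters are themselves punctuation), then each
    sentence is normalized and tokenized; sentences that normalize to nothing
    are dropped.
    """
    if specialty not in SPECIALTIES:
        raise SchemaError(
            f"note {note_id!r}: unknown specialty {specialty!r} "
            f"(expected one of {SPECIALTIES})"
        )
    if generator not in GENERATORS:
        raise SchemaError(
            f"note {note_id!r}: unknown generator {generator!r} "
            f"(expected one of {GENERATORS})"
        )
    nfkc = unicodedata.normalize("NFKC", raw_text)
    norm = normalize_text(raw_text, punctuation_set)
    sentences = []
    for seg in segment_sentences(nfkc, sentence_delimiters):
        toks = tuple(tokenizer(normalize_text(seg, punctuation_set)))
        if toks:
            sentences.append(toks)
    return Note(
        note_id=note_id,
        specialty=specialty,
        generator=generator,
        case_id=case_id,
        raw_text=raw_text,
        norm_text=norm,
        tokens=tuple(tokenizer(norm)),
        sentences=tuple(sentences),
        model_name=model_name,
    )


def default_group_key(note: Note) -> str:
    return f"{note.specialty}_{note.generator}"


@dataclass
class GroupedCorpus:
    """A sequence of notes plus a note -> group-label function."""

    notes: list[Note]
    group_key: Callable[[Note], str] = field(default=default_group_key)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for n in self.notes:
            if n.note_id in seen:
                raise SchemaError(f"duplicate note_id {n.note_id!r}")
            seen.add(n.note_id)

    def __len__(self) -> int:
        return len(self.notes)

    def __iter__(self):
        return iter(self.notes)

    @property
    def note_ids(self) -> list[str]:
        return [n.note_id for n in self.notes]

    def groups(self) -> dict[str, list[Note]]:
        """Group label -> member notes, in first-appearance order."""
        out: dict[str, list[Note]] = {}
        for n in self.notes:
            out.setdefault(self.group_key(n), []).append(n)
        return out

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups())

    def group(self, label: str) -> list[Note]:
        groups = self.groups()
        if label not in groups:
            raise KeyError(
                f"unknown group {label!r}; available: {sorted(groups)}"
            )
        return groups[label]

    def labels(self) -> list[str]:
        """Per-note group labels, aligned with :attr:`notes`."""
        return [self.group_key(n) for n in self.notes]

    def require_multiple_groups(self) -> None:
        if len(self.groups()) < 2:
            raise ValueError(
                "between-group operation requires at least two non-empty groups"
            )


_REQUIRED_FIELDS = ("note_id", "specialty", "generator", "case_id")


def _record_to_note(rec: dict, where: str, tokenizer: TokenizerSpec,
                    punctuation_set, sentence_delimiters) -> Note:
    missing = [k for k in _REQUIRED_FIELDS if k not in rec]
    if "text" not in rec:
        missing.append("text")
    if missing:
        raise SchemaError(f"{where}: missing field(s) {missing}")
    return make_note(
        note_id=str(rec["note_id"]),
        specialty=rec["specialty"],
        generator=rec["generator"],
        case_id=str(rec["case_id"]),
        raw_text=rec["text"],
        model_name=rec.get("model_name"),
        tokenizer=tokenizer,
        punctuation_set=punctuation_set,
        sentence_delimiters=sentence_delimiters,
    )


def load_corpus(
    path: str | Path,
    format: str = "jsonl",
    tokenizer: TokenizerSpec = WHITESPACE_TOKENIZER,
    punctuation_set: Iterable[str] = DEFAULT_PUNCTUATION,
    sentence_delimiters: Iterable[str] = DEFAULT_SENTENCE_DELIMITERS,
    group_key: Callable[[Note], str] = default_group_key,
) -> GroupedCorpus:
    """Load a grouped corpus from JSONL or a manifest directory.

    ``jsonl``: one JSON object per line with keys note_id, specialty,
    generator, case_id, text, optional model_name.  ``manifest_dir``: a
    directory containing ``manifest.csv`` (columns note_id, specialty,
    generator, model_name, case_id, file) with UTF-8 plain-text note files.
    """
    path = Path(path)
    notes: list[Note] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as e:
                    raise SchemaError(f"{path}:{lineno}: invalid JSON: {e}") from e
                notes.append(_record_to_note(
                    rec, f"{path}:{lineno}", tokenizer,
                    punctuation_set, sentence_delimiters))
    elif format == "manifest_dir":
        manifest = path / "manifest.csv"
        if not manifest.exists():
            raise FileNotFoundError(f"manifest not found: {manifest}")
        with manifest.open(encoding="utf-8", newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh), 1):
                fname = row.pop("file", None)
                if fname is None:
                    raise SchemaError(f"{manifest}:row {i}: missing 'file' column")
                txt_path = path / fname
                if not txt_path.exists():
                    raise FileNotFoundError(
                        f"{manifest}:row {i}: note file not found: {txt_path}")
                row = {k: (v if v != "" else None) for k, v in row.items()}
                row["text"] = txt_path.read_text(encoding="utf-8")
                notes.append(_record_to_note(
                    row, f"{manifest}:row {i}", tokenizer,
                    punctuation_set, sentence_delimiters))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return GroupedCorpus(notes, group_key=group_key)


def save_corpus(corpus: GroupedCorpus, path: str | Path) -> None:
    """Write the corpus as JSONL (raw text plus metadata; derived views are
    recomputed on load)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for n in corpus.notes:
            rec = {
                "note_id": n.note_id,
                "specialty": n.specialty,
                "generator": n.generator,
                "case_id": n.case_id,
                "text": n.raw_text,
            }
            if n.model_name is not None:
                rec["model_name"] = n.model_name
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
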