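"""Seeded generator of multi-group synthetic note corpora.

The generator emulates the stylistic contrasts between author groups that the
analyses are designed to detect, with one :class:`StyleParams` per group:

- note length: token counts drawn from a truncated normal (floor 5) —
  LLM-like groups are ~3x longer than human-like groups by default;
- template reuse: each group has an *ordered* template skeleton (clinical
  notes follow a canonical section order); the i-th body sentence of a note is
  the verbatim i-mod-pool template with probability ``template_reuse_p`` (high
  in LLM-like groups), else sampled fresh from the group vocabulary;
- sentence repetition: the previous sentence is duplicated with probability
  ``sentence_repeat_p``;
- lexical diversity: vocabulary size and offset into a shared synthetic
  lexicon control type-token ratio and between-group lexical overlap;
- concept variants: surface forms of a clinical concept are injected according
  to a per-group probability vector, so groups differ in variant entropy
  (psychiatrist-like most diverse, internist-like least by default).

Tokens are synthetic ("w0412"-style) — the analyses are language-agnostic, so
no natural-language text is required.  Generation is bit-reproducible from a
:class:`SyntheticTruth` (the ground-truth parameters plus seed), which can be
serialized next to the corpus for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .corpus import GroupedCorpus, Note, make_note
from .variation import VariantDictionary

__all__ = ["StyleParams", "SyntheticTruth", "generate_corpus",
           "default_study_truth", "default_variant_dictionary",
           "DEPRESSIVE_STATE_FORMS"]

#: Surface forms of the built-in "depressive state" concept (multiword forms
#: span several tokens in the generated text).
DEPRESSIVE_STATE_FORMS = (
    "depressive state", "depressed mood", "depressive mood", "depression",
    "depressive symptoms", "melancholy", "low mood", "dysthymic state",
)

_FILLERS = ("hedge_possibly", "hedge_overall", "hedge_noted",
            "hedge_reported", "hedge_currently")

_CASES = ("case_depression", "case_schizophrenia")

_MODEL_NAMES = ("model_a", "model_b", "model_c", "model_d")


def _lex(i: int) -> str:
    return f"w{i:04d}"


@dataclass
class StyleParams:
    """Per-group style knobs (see module docstring for semantics)."""

    mean_len: float = 60.0
    sd_len: float = 12.0
    vocab_size: int = 300
    template_pool: int = 6
    template_reuse_p: float = 0.5
    sentence_repeat_p: float = 0.05
    filler_rate: float = 0.1
    variant_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    marker_tokens: tuple[str, ...] = ()
    vocab_offset: int = 0
    #: inclusive-exclusive token-count range of one sentence; short ranges give
    #: bullet-like template lines (few unique words per sentence)
    sentence_len_range: tuple[int, int] = (6, 13)

    def __post_init__(self) -> None:
        if self.mean_len <= 0:
            raise ValueError("mean_len must be > 0")
        for p in (self.template_reuse_p, self.sentence_repeat_p, self.filler_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for concept, probs in self.variant_probs.items():
            vec = np.array(list(probs.values()), dtype=float)
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"variant probabilities for {concept!r} must lie on the simplex")
        lo, hi = self.sentence_len_range
        if not 1 <= lo < hi:
            raise ValueError("sentence_len_range must satisfy 1 <= lo < hi")


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic study: per-group style parameters,
    group sizes, and the generation seed."""

    groups: dict[str, StyleParams]
    group_sizes: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        if set(self.groups) != set(self.group_sizes):
            raise ValueError("groups and group_sizes must have identical keys")
        if any(s < 1 for s in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "group_sizes": self.group_sizes,
            "groups": {g: asdict(p) for g, p in self.groups.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        groups = {}
        for g, p in payload["groups"].items():
            p["marker_tokens"] = tuple(p.get("marker_tokens", ()))
            p["sentence_len_range"] = tuple(p.get("sentence_len_range", (6, 13)))
            groups[g] = StyleParams(**p)
        return cls(groups=groups, group_sizes=payload["group_sizes"],
                   seed=payload["seed"])


def _split_label(label: str) -> tuple[str, str]:
    """'internal_medicine_llm' -> ('internal_medicine', 'llm')."""
    specialty, generator = label.rsplit("_", 1)
    return specialty, generator


def _make_templates(rng: np.random.Generator, params: StyleParams) -> list[list[str]]:
    templates = []
    for t in range(params.template_pool):
        length = int(rng.integers(*params.sentence_len_range))
        idx = rng.integers(0, params.vocab_size, size=length)
        toks = [_lex(params.vocab_offset + int(i)) for i in idx]
        if params.marker_tokens:
            marker = params.marker_tokens[t % len(params.marker_tokens)]
            pos = int(rng.integers(0, len(toks) + 1))
            toks.insert(pos, marker)
        templates.append(toks)
    return templates


def _fresh_sentence(rng: np.random.Generator, params: StyleParams) -> list[str]:
    length = int(rng.integers(*params.sentence_len_range))
    idx = rng.integers(0, params.vocab_size, size=length)
    toks = [_lex(params.vocab_offset + int(i)) for i in idx]
    if rng.random() < params.filler_rate:
        filler = _FILLERS[int(rng.integers(0, len(_FILLERS)))]
        toks.insert(int(rng.integers(0, len(toks) + 1)), filler)
    return toks


def _sample_note_sentences(rng: np.random.Generator,
                           params: StyleParams,
                           templates: list[list[str]]) -> list[list[str]]:
    target = max(5, int(round(rng.normal(params.mean_len, params.sd_len))))

    # Concept-variant mentions are drawn first; they are later embedded inside
    # body sentences and count toward the length target.
    mentions: list[list[str]] = []
    for concept, probs in params.variant_probs.items():
        forms = list(probs)
        weights = np.array([probs[f] for f in forms])
        n_mentions = 1 + int(rng.poisson(1.5))
        for _ in range(n_mentions):
            form = forms[int(rng.choice(len(forms), p=weights))]
            mentions.append(form.split())

    total = sum(len(m) for m in mentions)
    body: list[list[str]] = []
    slot = 0  # position in the group's ordered template skeleton
    while total < target:
        if body and rng.random() < params.sentence_repeat_p:
            sent = list(body[-1])
        else:
            if templates and rng.random() < params.template_reuse_p:
                sent = list(templates[slot % len(templates)])
            else:
                sent = _fresh_sentence(rng, params)
            slot += 1
        body.append(sent)
        total += len(sent)
    if total > target and body:
        excess = total - target
        last = body[-1]
        if excess >= len(last):
            body.pop()
        else:
            body[-1] = last[:len(last) - excess]

    # Embed each mention contiguously inside a body sentence (clinicians name
    # the concept mid-sentence); standalone sentence only if there is no body.
    for m in mentions:
        if body:
            sent = body[int(rng.integers(0, len(body)))]
            pos = int(rng.integers(0, len(sent) + 1))
            sent[pos:pos] = m
        else:
            body.append(list(m))
    return body


def generate_corpus(truth: SyntheticTruth) -> GroupedCorpus:
    """Generate the grouped corpus described by ``truth`` (bit-reproducible)."""
    rng = np.random.default_rng(truth.seed)
    notes: list[Note] = []
    for label, params in truth.groups.items():
        specialty, generator = _split_label(label)
        templates = _make_templates(rng, params)
        for k in range(truth.group_sizes[label]):
            sentences = _sample_note_sentences(rng, params, templates)
            raw_text = "\n".join(" ".join(s) for s in sentences)
            model_name = (_MODEL_NAMES[k % len(_MODEL_NAMES)]
                          if generator == "llm" else None)
            notes.append(make_note(
                note_id=f"{label}_{k:03d}",
                specialty=specialty,
                generator=generator,
                case_id=_CASES[k % len(_CASES)],
                raw_text=raw_text,
                model_name=model_name,
            ))
    return GroupedCorpus(notes)


def default_variant_dictionary() -> VariantDictionary:
    """Dictionary with the built-in "depressive state" concept."""
    return VariantDictionary({"depressive state": list(DEPRESSIVE_STATE_FORMS)})


def default_study_truth(seed: int = 0) -> SyntheticTruth:
    """Ground truth mirroring the default study conditions.

    Four specialty x generator groups sized 70/48/4/4.  LLM-like groups are
    ~3x longer with heavy template reuse, frequent sentence repetition, short
    bullet-like sentences and a small vocabulary; human-like groups are
    shorter overall but lexically diverse with longer sentences.
    Group vocabularies are partially disjoint blocks of the shared lexicon
    (clinical sublanguages overlap but are not identical).  The variant
    distribution of the "depressive state" concept is most diverse for the
    psychiatrist-like group and least for the internist-like group, with the
    LLM-like groups in between.  All constants are documented here and fixed.
    """
    fd = DEPRESSIVE_STATE_FORMS

    def vp(forms_probs: dict[str, float]) -> dict[str, dict[str, float]]:
        return {"depressive state": forms_probs}

    groups = {
        "psychiatry_human": StyleParams(
            mean_len=70, sd_len=9, vocab_size=400, vocab_offset=0,
            template_pool=6, template_reuse_p=0.80, sentence_repeat_p=0.02,
            filler_rate=0.10,
            marker_tokens=("suicidal_ideation", "psychotherapy"),
            variant_probs=vp({f: 1 / 8 for f in fd}),  # H = 3 bits
        ),
        "internal_medicine_human": StyleParams(
            mean_len=45, sd_len=6, vocab_size=300, vocab_offset=200,
            template_pool=6, template_reuse_p=0.80, sentence_repeat_p=0.02,
            filler_rate=0.10,
            marker_tokens=("ssri_started", "vital_signs"),
            variant_probs=vp({fd[0]: 0.60, fd[3]: 0.25, fd[1]: 0.15}),  # ~1.35
        ),
        "psychiatry_llm": StyleParams(
            mean_len=210, sd_len=25, vocab_size=120, vocab_offset=600,
            template_pool=3, template_reuse_p=0.90, sentence_repeat_p=0.25,
            filler_rate=0.20, sentence_len_range=(4, 9),
            marker_tokens=("comprehensive_assessment", "biopsychosocial"),
            variant_probs=vp({fd[0]: 0.30, fd[1]: 0.20, fd[2]: 0.15,
                              fd[3]: 0.15, fd[4]: 0.10, fd[5]: 0.10}),  # ~2.47
        ),
        "internal_medicine_llm": StyleParams(
            mean_len=120, sd_len=15, vocab_size=120, vocab_offset=760,
            template_pool=3, template_reuse_p=0.90, sentence_repeat_p=0.25,
            filler_rate=0.20, sentence_len_range=(4, 9),
            marker_tokens=("differential_diagnosis", "follow_up_plan"),
            variant_probs=vp({fd[0]: 0.40, fd[3]: 0.30,
                              fd[1]: 0.20, fd[2]: 0.10}),  # ~1.85
        ),
    }
    sizes = {"psychiatry_human": 70, "internal_medicine_human": 48,
             "psychiatry_llm": 4, "internal_medicine_llm": 4}
    return SyntheticTruth(groups=groups, group_sizes=sizes, seed=seed)
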