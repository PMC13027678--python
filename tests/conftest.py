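import pytest

from notestyle import GroupedCorpus, generate_corpus, default_study_truth, make_note


def note_of(tokens, note_id="n1", specialty="psychiatry", generator="human",
            case_id="case_1"):
    """Note whose token sequence is exactly ``tokens`` (one sentence)."""
    return make_note(note_id=note_id, specialty=specialty, generator=generator,
                     case_id=case_id, raw_text=" ".join(tokens))


def corpus_of(token_lists, specialties=None, generators=None):
    """Corpus with one single-sentence note per token list."""
    n = len(token_lists)
    specialties = specialties or ["psychiatry"] * n
    generators = generators or ["human"] * n
    notes = [note_of(toks, note_id=f"n{i}", specialty=s, generator=g)
             for i, (toks, s, g) in enumerate(zip(token_lists, specialties, generators))]
    return GroupedCorpus(notes)


@pytest.fixture(scope="session")
def study_corpus():
    """The default four-group synthetic study corpus (70/48/4/4), seed 1."""
    return generate_corpus(default_study_truth(seed=1))
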