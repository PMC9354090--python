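"""Character tokenization, punctuation codec, BIO codec, sentence splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlee.seqlabels import (
    AlignmentError,
    BioEncodingError,
    NONE_TAG,
    PunctuationLabelSpace,
    Span,
    apply_punct_tags,
    bio_decode,
    bio_encode,
    char_tokenize,
    punct_targets,
    split_sentences,
    strip_punctuation,
)

SPACE = PunctuationLabelSpace()


def test_char_tokenize_is_per_code_point():
    assert len(char_tokenize("发热2天")) == 4
    assert len(char_tokenize("")) == 0
    mixed = "WBC12.5×10⁹发热"
    assert len(char_tokenize(mixed)) == len(list(mixed))  # code-point counter


def test_punct_targets_hand_aligned():
    raw = char_tokenize("咳嗽，发热。")
    corrected = char_tokenize("咳嗽。发热。")
    tags = punct_targets(raw, corrected)
    assert tags == [NONE_TAG, "。", NONE_TAG, "。"]


def test_punct_targets_identity_and_insertion():
    seq = char_tokenize("发热")
    assert punct_targets(seq, seq) == [NONE_TAG, NONE_TAG]
    assert punct_targets(seq, char_tokenize("发热。")) == [NONE_TAG, "。"]


def test_punct_targets_rejects_content_edit():
    with pytest.raises(AlignmentError):
        punct_targets(char_tokenize("发热"), char_tokenize("发冷"))


def test_punct_targets_rejects_consecutive_marks():
    with pytest.raises(AlignmentError):
        punct_targets(char_tokenize("发热"), char_tokenize("发热。。"))


def test_apply_punct_tags_rebuilds():
    seq = char_tokenize("咳嗽发热")
    assert apply_punct_tags(seq, [NONE_TAG, "。", NONE_TAG, "。"]) == "咳嗽。发热。"
    assert apply_punct_tags(seq, [NONE_TAG] * 4) == "咳嗽发热"
    assert apply_punct_tags(char_tokenize(""), []) == ""
    with pytest.raises(ValueError):
        apply_punct_tags(seq, [NONE_TAG])


def test_split_sentences_basic():
    sents = split_sentences("A。B。")
    assert [s.text for s in sents] == ["A。", "B。"]
    assert sents[1].offsets[0] == 2
    # comma-only text stays one sentence; trailing text is not lost
    assert [s.text for s in split_sentences("发热，咳嗽")] == ["发热，咳嗽"]
    assert [s.text for s in split_sentences("A。B")] == ["A。", "B"]


@given(st.text(alphabet="发热咳嗽天查体温。，？！", max_size=60))
@settings(max_examples=200, derandomize=True)
def test_split_conserves_content(text):
    sents = split_sentences(text)
    assert "".join(s.text for s in sents) == text
    assert all(len(s) > 0 for s in sents)


def _random_pair(rng):
    """Random (raw, corrected) differing only in punctuation placement."""
    core = "".join(rng.choice(list("发热咳嗽天体温咽痛abc123")) for _ in range(rng.integers(1, 15)))

    def sprinkle(no_consecutive):
        out = []
        prev_mark = True  # disallow a mark before the first character
        for ch in core:
            out.append(ch)
            prev_mark = False
            if rng.random() < 0.35 and not (no_consecutive and prev_mark):
                out.append(str(rng.choice(list(SPACE.marks))))
                prev_mark = True
        return "".join(out)

    return sprinkle(False), sprinkle(True)


def test_punct_codec_roundtrip_random():
    rng = np.random.default_rng(42)
    for _ in range(300):
        raw_text, corrected_text = _random_pair(rng)
        raw = char_tokenize(raw_text)
        corrected = char_tokenize(corrected_text)
        tags = punct_targets(raw, corrected)
        assert apply_punct_tags(strip_punctuation(raw), tags) == corrected_text


def test_bio_encode_decode_basic():
    seq = char_tokenize("发热三天了")
    tags = bio_encode([Span("Fever", 0, 5)], seq)
    assert tags == ["B-Fever", "I-Fever", "I-Fever", "I-Fever", "I-Fever"]
    assert bio_encode([], seq) == ["O"] * 5
    spans = bio_decode(["O", "I-Fever", "I-Fever", "O", "O"], seq)
    assert [(s.label, s.start, s.end) for s in spans] == [("Fever", 1, 3)]


def test_bio_encode_rejects_overlap():
    seq = char_tokenize("abcdef")
    with pytest.raises(BioEncodingError):
        bio_encode([Span("x", 0, 3), Span("y", 2, 5)], seq)


def test_bio_decode_repairs_label_switch():
    seq = char_tokenize("abcd")
    spans = bio_decode(["B-x", "I-y", "I-y", "O"], seq)
    assert [(s.label, s.start, s.end) for s in spans] == [("x", 0, 1), ("y", 1, 3)]


@given(st.data())
@settings(max_examples=200, derandomize=True)
def test_bio_roundtrip_random(data):
    n = data.draw(st.integers(1, 25))
    seq = char_tokenize("甲" * n)
    labels = ["Fever", "Cough", "Value"]
    spans = []
    pos = 0
    while pos < n:
        start = data.draw(st.integers(pos, n))
        if start >= n:
            break
        end = data.draw(st.integers(start + 1, n))
        spans.append(Span(data.draw(st.sampled_from(labels)), start, end))
        pos = end + data.draw(st.integers(0, 3))
    tags = bio_encode(spans, seq)
    decoded = bio_decode(tags, seq)
    assert [(s.label, s.start, s.end) for s in decoded] == [
        (s.label, s.start, s.end) for s in spans
    ]
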