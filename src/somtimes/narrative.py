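"""Conversation narrative-arc construction.

A conversation is a stream of word tokens, each carrying a temporal
reference tag (``past``, ``present``, ``future`` or ``none`` for
non-verbs).  Narrative time is stratified into ten equal deciles of the
word count, and each decile scores the proportion of future-tense verbs
among past + future verbs — values above 0.5 mean more future talk.
The ten-point arc is then smoothed with a 2nd-order, 9-step
Savitzky–Golay filter before being clustered like any other series.

Deciles containing no past or future verb are filled with the neutral
value 0.5 (the decision threshold) so every conversation yields a
complete arc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import ParameterError, TooShortError

__all__ = [
    "TaggedToken",
    "NarrativeSeries",
    "decile_series",
    "savgol_smooth",
    "build_corpus",
]

N_DECILES = 10
NEUTRAL = 0.5
TAGS = frozenset({"past", "present", "future", "none"})


@dataclass
class TaggedToken:
    """One word: its position in the conversation and its temporal tag."""

    position: int
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in TAGS:
            raise ParameterError(f"unknown temporal tag {self.tag!r}")


@dataclass
class NarrativeSeries:
    """Ten-decile future-vs-past arc for one conversation."""

    values: np.ndarray
    conversation_id: str = ""
    word_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != N_DECILES:
            raise ParameterError("a narrative series has exactly ten deciles")


def _coerce_tokens(tokens) -> list[tuple[int, str]]:
    out = []
    for tok in tokens:
        if isinstance(tok, TaggedToken):
            out.append((tok.position, tok.tag))
        else:
            pos, tag = tok
            if tag not in TAGS:
                raise ParameterError(f"unknown temporal tag {tag!r}")
            out.append((int(pos), tag))
    return out


def decile_series(tokens, total_words: int, conversation_id: str = "") -> NarrativeSeries:
    """Per-decile proportion future / (future + past), neutral-filled.

    Decile ``d`` covers word positions ``[floor(d*T/10), floor((d+1)*T/10))``
    for total word count ``T``.  Present-tense and non-verb tokens never
    influence the arc.
    """
    if total_words < N_DECILES:
        raise TooShortError("conversation must span at least ten words")
    toks = _coerce_tokens(tokens)
    future = np.zeros(N_DECILES)
    past = np.zeros(N_DECILES)
    edges = [total_words * d // N_DECILES for d in range(N_DECILES + 1)]
    for pos, tag in toks:
        if tag not in ("future", "past"):
            continue
        d = min(int(np.searchsorted(edges, pos, side="right")) - 1, N_DECILES - 1)
        if tag == "future":
            future[d] += 1
        else:
            past[d] += 1
    denom = future + past
    values = np.full(N_DECILES, NEUTRAL)
    nz = denom > 0
    values[nz] = future[nz] / denom[nz]
    return NarrativeSeries(values=values, conversation_id=conversation_id,
                           word_count=total_words)


def savgol_smooth(values, order: int = 2, window: int = 9) -> np.ndarray:
    """Savitzky–Golay smoothing with least-squares boundary handling.

    Each point is replaced by the value of a degree-``order`` polynomial
    fit over the centered window; points too close to an edge use the
    polynomial fitted on the nearest full window (no padding is
    invented).  Linear in the input; constants and straight lines pass
    through unchanged.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ParameterError("window must be odd and positive")
    if order >= window:
        raise ParameterError("order must be smaller than the window")
    if window > values.size:
        raise ParameterError("window exceeds series length")
    return savgol_filter(values, window_length=window, polyorder=order, mode="interp")


def build_corpus(conversations, min_words: int = 100, order: int = 2, window: int = 9):
    """Filter short conversations, build and smooth all arcs.

    ``conversations`` is an iterable of token streams (lists of
    ``TaggedToken`` or ``(position, tag)`` pairs).  The smoothed arcs are
    clamped to ``[0, 1]`` since the filter may overshoot.  Conversations
    shorter than ``min_words`` are dropped; the result may be empty.
    """
    out: list[NarrativeSeries] = []
    for i, tokens in enumerate(conversations):
        toks = _coerce_tokens(tokens)
        total = (max(p for p, _ in toks) + 1) if toks else 0
        if total < max(min_words, N_DECILES):
            continue
        arc = decile_series(toks, total, conversation_id=str(i))
        smoothed = np.clip(savgol_smooth(arc.values, order=order, window=window), 0.0, 1.0)
        out.append(NarrativeSeries(values=smoothed, conversation_id=arc.conversation_id,
                                   word_count=total))
    return out
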