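"""P300 speller decoding chain.

For every row/column intensification a post-stimulus window of 0-667 ms is
cut, band-passed with an 8th-order Chebyshev type-I filter (0.1-10 Hz,
causal, second-order sections) and decimated by keeping every k-th sample
with k = floor(fs / (2 * f_high)) — the band-pass already provides the
anti-aliasing.  The decimated channels are concatenated channel-major into
one vector per intensification: at the 240 Hz reference rate each channel
contributes floor(0.667*240) = 160 -> 14 samples, i.e. 896 dimensions over
64 channels.

Decoding is two-phase: a binary classifier scores each vector for
P300-ness, then per-character scores are summed over repetitions for each
of the 12 row/column ids and the symbol at the intersection of the best
row and best column is emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .eeg_core import Epoch, EventKind, Recording, extract_epochs
from .mi_classify import ModelSpec, train_model

__all__ = [
    "SpellerLayout",
    "default_layout",
    "PostStimulusVector",
    "P300_WINDOW_S",
    "p300_epoch",
    "bandpass_cheby1",
    "decimation_factor",
    "decimate_epoch",
    "assemble_vector",
    "preprocess_session",
    "train_p300",
    "score_p300",
    "decode_symbol",
    "decode_characters",
    "spell_session",
]

P300_WINDOW_S = 0.667


@dataclass(frozen=True)
class SpellerLayout:
    """6x6 symbol matrix; rc ids 1-6 are columns, 7-12 are rows."""

    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != 6 or any(len(r) != 6 for r in self.rows):
            raise ValueError("layout must be a 6x6 grid")
        symbols = "".join(self.rows)
        if len(set(symbols)) != 36:
            raise ValueError("layout must contain 36 unique symbols")

    def rc_for_char(self, ch: str) -> tuple[int, int]:
        """(row_id, col_id) of a symbol; row ids 7-12, column ids 1-6."""
        for i, row in enumerate(self.rows):
            j = row.find(ch)
            if j >= 0:
                return i + 7, j + 1
        raise KeyError(f"symbol {ch!r} not in layout")

    def symbol_at(self, row_id: int, col_id: int) -> str:
        if not (7 <= row_id <= 12 and 1 <= col_id <= 6):
            raise ValueError("row id must be 7-12 and column id 1-6")
        return self.rows[row_id - 7][col_id - 1]


def default_layout() -> SpellerLayout:
    return SpellerLayout(("ABCDEF", "GHIJKL", "MNOPQR", "STUVWX", "YZ1234", "56789_"))


@dataclass
class PostStimulusVector:
    values: np.ndarray
    label: bool | None
    rc_id: int
    char_index: int


# ---------------------------------------------------------------------------
# signal chain


def p300_epoch(rec: Recording, window_s: float = P300_WINDOW_S) -> list[Epoch]:
    """One epoch per intensification, window [0, window_s) s, labelled
    target/nontarget."""
    epochs, _ = extract_epochs(rec, EventKind.INTENSIFICATION, 0.0, window_s)
    return epochs


def bandpass_cheby1(
    epoch: Epoch,
    order: int = 8,
    band: tuple[float, float] = (0.1, 10.0),
    ripple_db: float = 0.5,
) -> Epoch:
    """Chebyshev type-I band-pass, causal, in second-order sections.

    ``order`` is the overall filter order (an 8th-order band-pass comes
    from a 4th-order prototype).
    """
    if epoch.fs <= 2 * band[1]:
        raise ValueError(f"fs={epoch.fs} too low for a {band[1]} Hz upper cutoff")
    if order % 2:
        raise ValueError("band-pass order must be even")
    sos = signal.cheby1(
        order // 2, ripple_db, band, btype="bandpass", fs=epoch.fs, output="sos"
    )
    out = signal.sosfilt(sos, epoch.data, axis=1)
    if not np.all(np.isfinite(out)):
        raise ValueError("unstable filter output; check order/band at this fs")
    return replace(epoch, data=out)


def decimation_factor(fs: float, f_high: float) -> int:
    """k = floor(fs / (2 * f_high)); 240 Hz with a 10 Hz cutoff gives 12."""
    k = int(math.floor(fs / (2.0 * f_high)))
    if k < 1:
        raise ValueError(f"decimation factor < 1 at fs={fs}, f_high={f_high}")
    return k


def decimate_epoch(epoch: Epoch, f_high: float = 10.0) -> Epoch:
    """Keep every k-th sample starting at index 0 (no extra anti-aliasing:
    the preceding band-pass is the anti-alias filter).

    Output length is ceil(n / k); 160 samples at 240 Hz become 14.
    """
    k = decimation_factor(epoch.fs, f_high)
    return replace(epoch, data=epoch.data[:, ::k].copy(), fs=epoch.fs / k)


def assemble_vector(epoch: Epoch) -> PostStimulusVector:
    """Channel-major concatenation of the decimated channels."""
    return PostStimulusVector(
        values=epoch.data.ravel(order="C"),
        label=epoch.label if isinstance(epoch.label, bool) else None,
        rc_id=epoch.rc_id if epoch.rc_id is not None else -1,
        char_index=epoch.char_index if epoch.char_index is not None else -1,
    )


def preprocess_session(
    rec: Recording,
    window_s: float = P300_WINDOW_S,
    order: int = 8,
    band: tuple[float, float] = (0.1, 10.0),
    ripple_db: float = 0.5,
) -> list[PostStimulusVector]:
    """Full epoch -> filter -> decimate -> vector chain for one session."""
    out = []
    for ep in p300_epoch(rec, window_s):
        ep = bandpass_cheby1(ep, order=order, band=band, ripple_db=ripple_db)
        ep = decimate_epoch(ep, f_high=band[1])
        out.append(assemble_vector(ep))
    return out


# ---------------------------------------------------------------------------
# two-phase decoding


def train_p300(vectors: list[PostStimulusVector], spec: ModelSpec | None = None):
    """Phase 1: fit the binary target/nontarget classifier (default RF)."""
    spec = spec or ModelSpec(algorithm="RF")
    X = np.vstack([v.values for v in vectors])
    y = np.array([bool(v.label) for v in vectors])
    return train_model(X, y, spec)


def score_p300(model, vectors: list[PostStimulusVector]) -> np.ndarray:
    """Monotone P300-ness score per vector (higher = more P300-like)."""
    X = np.vstack([v.values for v in vectors])
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        target_col = list(model.classes_).index(True)
        return proba[:, target_col]
    scores = model.decision_function(X)
    return np.asarray(scores, dtype=float).ravel()


def decode_symbol(
    scores: list[tuple[int, int, float]], layout: SpellerLayout
) -> str:
    """Phase 2: sum scores per rc id over repetitions and emit the symbol at
    the intersection of the best row and best column.

    ``scores`` holds (rc_id, repetition, score) triples covering all 12
    ids; ties break toward the lowest rc id.
    """
    totals = {rc: 0.0 for rc in range(1, 13)}
    seen = set()
    for rc_id, _rep, s in scores:
        if rc_id not in totals:
            raise ValueError(f"rc_id {rc_id} outside 1..12")
        totals[rc_id] += float(s)
        seen.add(rc_id)
    if seen != set(range(1, 13)):
        raise ValueError(f"scores missing rc ids: {sorted(set(range(1, 13)) - seen)}")
    best_col = max(range(1, 7), key=lambda rc: (totals[rc], -rc))
    best_row = max(range(7, 13), key=lambda rc: (totals[rc], -rc))
    return layout.symbol_at(best_row, best_col)


def decode_characters(
    vectors: list[PostStimulusVector],
    scores: np.ndarray,
    layout: SpellerLayout | None = None,
    max_repetitions: int | None = None,
) -> str:
    """Group scored vectors by character and decode each one.

    ``max_repetitions`` limits how many of the recorded repetitions per
    character are used (each repetition is one block of 12 intensifications,
    in recording order).
    """
    layout = layout or default_layout()
    by_char: dict[int, list[tuple[int, int, float]]] = {}
    rep_count: dict[tuple[int, int], int] = {}
    for v, s in zip(vectors, scores):
        rep = rep_count.get((v.char_index, v.rc_id), 0)
        rep_count[(v.char_index, v.rc_id)] = rep + 1
        if max_repetitions is not None and rep >= max_repetitions:
            continue
        by_char.setdefault(v.char_index, []).append((v.rc_id, rep, float(s)))
    return "".join(decode_symbol(by_char[ci], layout) for ci in sorted(by_char))


def spell_session(
    rec: Recording,
    model,
    layout: SpellerLayout | None = None,
    max_repetitions: int | None = None,
    **chain_kw,
) -> str:
    """Decode every character of a speller session recording."""
    vectors = preprocess_session(rec, **chain_kw)
    scores = score_p300(model, vectors)
    return decode_characters(vectors, scores, layout, max_repetitions)
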