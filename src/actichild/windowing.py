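"""Non-overlapping fixed-duration windows with majority-rule labels.

A recording is tiled from its first sample in steps of ``duration_s x rate``;
a trailing partial window is dropped.  Each window is labeled with the code
covering a strict majority (>50%) of its samples.  Windows whose majority
code is OUT_OF_VIEW or UNLABELED, or where no code reaches a strict majority
(e.g. an exact 50/50 split), are labeled EXCLUDED.  Excluded windows stay in
the returned sequence so that lag/lead indexing over neighbors remains
contiguous; they are dropped from feature tables downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UsageError
from .io_annotation import (
    CODE_TO_INT,
    EVENT_CODES,
    EXCLUDED,
    INT_TO_CODE,
    OUT_OF_VIEW,
    Recording,
)

_OOV_INT = CODE_TO_INT[OUT_OF_VIEW]


@dataclass
class LabeledWindow:
    subject_id: str
    placement: str
    window_index: int
    duration_s: float
    samples: np.ndarray  # (m, 3) view into the recording
    label: str  # ActivityClass or EXCLUDED
    mixed: bool
    label_fraction: float


def segment(rec: Recording, labels: np.ndarray, duration_s: float) -> list[LabeledWindow]:
    """Segment an annotated recording into labeled windows.

    ``labels`` is the per-sample int8 array from
    :func:`actichild.io_annotation.annotate_samples`.
    """
    if not duration_s > 0:
        raise UsageError("window duration must be positive")
    labels = np.asarray(labels)
    if labels.shape[0] != rec.n_samples:
        raise UsageError("labels length must equal the number of samples")
    m = int(round(duration_s * rec.sample_rate_hz))
    if m < 1:
        raise UsageError("window duration shorter than one sample period")
    n_win = rec.n_samples // m
    windows: list[LabeledWindow] = []
    lab2d = labels[: n_win * m].reshape(n_win, m)
    n_codes = len(EVENT_CODES)
    for i in range(n_win):
        # shift by +1 so UNLABELED (-1) lands in bin 0
        counts = np.bincount(lab2d[i] + 1, minlength=n_codes + 1)
        code_counts = counts[1:]  # real codes only
        present = int((code_counts > 0).sum())
        mixed = present > 1
        top = int(code_counts.argmax())
        top_count = int(code_counts[top])
        frac = top_count / m
        if top_count * 2 > m and top != _OOV_INT and top_count > 0:
            label = INT_TO_CODE[top]
        else:
            label = EXCLUDED
        windows.append(
            LabeledWindow(
                subject_id=rec.subject_id,
                placement=rec.placement,
                window_index=i,
                duration_s=duration_s,
                samples=rec.samples[i * m : (i + 1) * m],
                label=label,
                mixed=mixed,
                label_fraction=frac,
            )
        )
    return windows


def mixed_fraction(windows: Sequence[LabeledWindow]) -> float:
    """Fraction of non-EXCLUDED windows that contain more than one code."""
    usable = [w for w in windows if w.label != EXCLUDED]
    if not usable:
        raise UsageError("no usable (non-EXCLUDED) windows")
    return sum(w.mixed for w in usable) / len(usable)
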