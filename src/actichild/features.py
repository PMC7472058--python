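"""Per-window feature extraction: 20 base features plus 5 lag/lead features.

Base features are computed on the vector magnitude (VM) of the tri-axial
signal within a window, except the three cross-axis Pearson correlations,
which require the raw axes.  Conventions (the field literature rarely states
them, so they are pinned down here):

* all standard deviations use the population convention (divide by N);
* ``vm_cv`` = vm_sd / vm_mean, and 0 when the mean is 0;
* ``vm_power`` is mean squared VM, so the feature is window-length invariant;
* percentiles interpolate linearly between order statistics;
* median crossings count strict sign changes of VM minus the window median —
  samples exactly on the median do not count;
* a zero-variance axis yields correlation 0 rather than NaN;
* the spectrum is the magnitude of the FFT of the mean-removed VM,
  zero-padded to at least 1024 points so the 0.25-5.0 Hz search band is
  resolvable even for 1 s windows; amplitudes are scaled by 2/n so a
  bin-aligned unit sinusoid has magnitude ~1 (off-bin peaks lose up to the
  usual 2/pi scalloping factor).  Ties break toward the lower frequency.

The five temporal features summarize VM variability in the two windows
before (lag) and after (lead) the current one: the neighbor windows' own VM
standard deviations, plus the population SD of the five per-window VM means
centered on the current window.  Edge windows replicate their nearest
existing neighbor.  A pooled-samples variant of the five-window SD (one SD
over all samples of the five windows) is available via ``five_window_sd``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq

from .errors import UsageError
from .io_annotation import EXCLUDED, EventLog, Recording, annotate_samples
from .windowing import LabeledWindow, segment

logger = logging.getLogger(__name__)

FREQ_BAND_HZ = (0.25, 5.0)
MIN_NFFT = 1024

#: Stable order of the 20 base features.
BASE_FEATURES: tuple[str, ...] = (
    "vm_mean", "vm_sd", "vm_min", "vm_max", "vm_iqr",
    "vm_p10", "vm_p25", "vm_p50", "vm_p75", "vm_p95",
    "vm_cv", "vm_sum", "vm_power", "vm_p2p", "vm_median_crossings",
    "corr_xy", "corr_xz", "corr_yz", "dom_freq_hz", "dom_freq_mag",
)

#: Stable order of the 5 lag/lead temporal features.
TEMPORAL_FEATURES: tuple[str, ...] = (
    "sd_lag1", "sd_lag2", "sd_lead1", "sd_lead2", "sd_5win",
)

META_COLUMNS: tuple[str, ...] = (
    "subject_id", "placement", "window_index", "label", "mixed",
)


def vector_magnitude(samples: np.ndarray) -> np.ndarray:
    """Euclidean norm of (ax, ay, az) per sample."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise UsageError("empty sample array")
    return np.sqrt((samples ** 2).sum(axis=1))


def dominant_frequency(vm: np.ndarray, rate: float) -> tuple[float, float]:
    """Frequency (Hz) and amplitude of the largest spectral peak in 0.25-5 Hz.

    The mean is removed first; for a constant signal every in-band magnitude
    is zero and the low-frequency tie-break returns the lowest band frequency.
    """
    vm = np.asarray(vm, dtype=float)
    n = vm.shape[0]
    if n < 2:
        raise UsageError("dominant frequency needs at least two samples")
    if rate < 10.0:
        logger.warning(
            "sample rate %.3g Hz cannot fully resolve the %s Hz band", rate, FREQ_BAND_HZ
        )
    nfft = max(MIN_NFFT, n)
    mag = np.abs(rfft(vm - vm.mean(), n=nfft)) * 2.0 / n
    freqs = rfftfreq(nfft, d=1.0 / rate)
    band = (freqs >= FREQ_BAND_HZ[0]) & (freqs <= FREQ_BAND_HZ[1])
    if not band.any():
        raise UsageError("no spectral bins inside the search band at this rate")
    f_band, m_band = freqs[band], mag[band]
    k = int(m_band.argmax())  # argmax returns the first (lowest-frequency) max
    return float(f_band[k]), float(m_band[k])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def base_features(window, rate: float) -> dict[str, float]:
    """Compute the 20 base features for one window.

    ``window`` is a :class:`~actichild.windowing.LabeledWindow` or a raw
    (m, 3) sample array.
    """
    samples = window.samples if hasattr(window, "samples") else np.asarray(window, float)
    if samples.shape[0] < 2:
        raise UsageError("base features need at least two samples")
    vm = vector_magnitude(samples)
    p10, p25, p50, p75, p95 = np.percentile(vm, [10, 25, 50, 75, 95])
    mean = vm.mean()
    sd = vm.std()  # population
    d = vm - p50
    crossings = int(((d[:-1] * d[1:]) < 0).sum())
    dom_hz, dom_mag = dominant_frequency(vm, rate)
    x, y, z = samples[:, 0], samples[:, 1], samples[:, 2]
    return {
        "vm_mean": float(mean),
        "vm_sd": float(sd),
        "vm_min": float(vm.min()),
        "vm_max": float(vm.max()),
        "vm_iqr": float(p75 - p25),
        "vm_p10": float(p10),
        "vm_p25": float(p25),
        "vm_p50": float(p50),
        "vm_p75": float(p75),
        "vm_p95": float(p95),
        "vm_cv": float(sd / mean) if mean != 0.0 else 0.0,
        "vm_sum": float(vm.sum()),
        "vm_power": float((vm ** 2).mean()),
        "vm_p2p": float(vm.max() - vm.min()),
        "vm_median_crossings": float(crossings),
        "corr_xy": _pearson(x, y),
        "corr_xz": _pearson(x, z),
        "corr_yz": _pearson(y, z),
        "dom_freq_hz": dom_hz,
        "dom_freq_mag": dom_mag,
    }


def _temporal_from_stats(
    sds: np.ndarray,
    means: np.ndarray,
    index: int,
    vms: Sequence[np.ndarray] | None = None,
    five_window_sd: str = "window_means",
) -> dict[str, float]:
    k = len(sds)
    clamp = lambda j: min(max(j, 0), k - 1)  # noqa: E731 - replication padding
    neighborhood = [clamp(index + off) for off in (-2, -1, 0, 1, 2)]
    if five_window_sd == "window_means":
        sd5 = float(np.std(means[neighborhood]))
    elif five_window_sd == "pooled_samples":
        if vms is None:
            raise UsageError("pooled_samples mode needs the per-window VM sequences")
        sd5 = float(np.std(np.concatenate([vms[j] for j in neighborhood])))
    else:
        raise UsageError(f"unknown five_window_sd mode {five_window_sd!r}")
    return {
        "sd_lag1": float(sds[clamp(index - 1)]),
        "sd_lag2": float(sds[clamp(index - 2)]),
        "sd_lead1": float(sds[clamp(index + 1)]),
        "sd_lead2": float(sds[clamp(index + 2)]),
        "sd_5win": sd5,
    }


def temporal_features(
    window_sequence: Sequence[LabeledWindow],
    index: int,
    five_window_sd: str = "window_means",
) -> dict[str, float]:
    """Lag/lead VM-variability features for ``window_sequence[index]``.

    The sequence must be contiguous in window_index for one subject and
    placement; EXCLUDED neighbors still contribute signal.
    """
    if len(window_sequence) < 1:
        raise UsageError("window sequence is empty")
    if not 0 <= index < len(window_sequence):
        raise UsageError("index outside the window sequence")
    vms = [vector_magnitude(w.samples) for w in window_sequence]
    sds = np.array([v.std() for v in vms])
    means = np.array([v.mean() for v in vms])
    return _temporal_from_stats(sds, means, index, vms, five_window_sd)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def _single_placement_table(
    recordings: dict[tuple[str, str], Recording],
    logs: dict[str, EventLog],
    placement: str,
    window_s: float,
    include_temporal: bool,
    five_window_sd: str,
) -> pd.DataFrame:
    rows = []
    subjects = sorted({sid for sid, plc in recordings if plc == placement})
    for sid in subjects:
        rec = recordings[(sid, placement)]
        labels = annotate_samples(rec, logs[sid])
        windows = segment(rec, labels, window_s)
        if not windows:
            continue
        vms = [vector_magnitude(w.samples) for w in windows]
        sds = np.array([v.std() for v in vms])
        means = np.array([v.mean() for v in vms])
        for i, w in enumerate(windows):
            if w.label == EXCLUDED:
                continue
            feats = base_features(w, rec.sample_rate_hz)
            if include_temporal:
                feats.update(_temporal_from_stats(sds, means, i, vms, five_window_sd))
            rows.append(
                {
                    "subject_id": sid,
                    "placement": placement,
                    "window_index": w.window_index,
                    "label": w.label,
                    "mixed": w.mixed,
                    **feats,
                }
            )
    cols = list(META_COLUMNS) + list(BASE_FEATURES)
    if include_temporal:
        cols += list(TEMPORAL_FEATURES)
    return pd.DataFrame(rows, columns=cols)


def build_feature_table(
    recordings,
    logs,
    window_s: float,
    include_temporal: bool = True,
    placement: str = "hip",
    five_window_sd: str = "window_means",
) -> pd.DataFrame:
    """Build the windowed feature table for one placement (or the fusion).

    Parameters
    ----------
    recordings
        Iterable of :class:`Recording` or dict keyed by (subject_id, placement).
    logs
        Iterable of :class:`EventLog` or dict keyed by subject_id.
    placement
        ``"hip"``, ``"wrist"``, or ``"hip_wrist"`` for feature fusion, in
        which case the hip and wrist blocks are concatenated column-wise with
        placement-prefixed names and windows usable at only one placement are
        dropped.
    """
    if not isinstance(recordings, dict):
        recordings = {(r.subject_id, r.placement): r for r in recordings}
    if not isinstance(logs, dict):
        logs = {lg.subject_id: lg for lg in logs}

    if placement in ("hip", "wrist"):
        return _single_placement_table(
            recordings, logs, placement, window_s, include_temporal, five_window_sd
        )
    if placement != "hip_wrist":
        raise UsageError(f"unknown placement {placement!r}")

    feat_cols = list(BASE_FEATURES) + (list(TEMPORAL_FEATURES) if include_temporal else [])
    blocks = {}
    for plc in ("hip", "wrist"):
        tbl = _single_placement_table(
            recordings, logs, plc, window_s, include_temporal, five_window_sd
        )
        renamed = tbl.rename(columns={c: f"{plc}_{c}" for c in feat_cols})
        blocks[plc] = renamed
    merged = blocks["hip"].merge(
        blocks["wrist"].drop(columns=["placement", "label", "mixed"]),
        on=["subject_id", "window_index"],
        how="inner",
    )
    n_drop = len(blocks["hip"]) + len(blocks["wrist"]) - 2 * len(merged)
    if n_drop:
        logger.info("feature fusion dropped %d single-placement windows", n_drop)
    merged["placement"] = "hip_wrist"
    cols = list(META_COLUMNS) + [f"{p}_{c}" for p in ("hip", "wrist") for c in feat_cols]
    return merged[cols]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a feature table, in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]
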