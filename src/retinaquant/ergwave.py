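"""Flash-ERG response averaging, filtering and a-/b-wave feature extraction.

The a-wave amplitude is measured baseline-to-trough and the b-wave
trough-to-peak (switchable to baseline-to-peak); latencies are implicit
times from stimulus onset to the respective extremum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from retinaquant import statcore
from retinaquant._exceptions import ValidationError
from retinaquant.synthgen import SyntheticERGTrace

__all__ = [
    "ERGFeatures",
    "average_responses",
    "bandpass",
    "extract_ab_waves",
    "intensity_series",
]


@dataclass
class ERGFeatures:
    """a-/b-wave amplitudes (uV) and implicit times (ms) of one response."""

    a_amplitude_uv: float
    a_latency_ms: float
    b_amplitude_uv: float
    b_latency_ms: float
    baseline_uv: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.a_amplitude_uv < 0 or self.b_amplitude_uv < 0:
            raise ValidationError("amplitudes must be >= 0")
        if (
            "a_absent" not in self.flags
            and "b_absent" not in self.flags
            and not (self.b_latency_ms > self.a_latency_ms)
        ):
            raise ValidationError("b latency must exceed a latency when both waves present")


def average_responses(trace: SyntheticERGTrace) -> SyntheticERGTrace:
    """Pointwise mean across repetitions -> single-repetition trace."""
    v = np.asarray(trace.voltage_uv, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[0] < 1:
        raise ValidationError("need at least one repetition")
    if v.shape[1] != trace.time_ms.size:
        raise ValidationError("repetition length does not match the time grid")
    return replace(trace, voltage_uv=v.mean(axis=0)[None, :])


def bandpass(trace: SyntheticERGTrace, low_hz: float = 3.0, high_hz: float = 300.0, order: int = 2) -> SyntheticERGTrace:
    """Zero-phase Butterworth band-limit; the DC offset is removed."""
    fs = trace.sampling_rate_hz
    if high_hz * 2.0 >= fs:
        raise ValidationError(
            f"high cutoff {high_hz} Hz violates Nyquist at {fs} Hz sampling"
        )
    if not (0 < low_hz < high_hz):
        raise ValidationError("need 0 < low_hz < high_hz")
    v = np.atleast_2d(np.asarray(trace.voltage_uv, dtype=float))
    v = v - v.mean(axis=1, keepdims=True)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, v, axis=1)
    return replace(trace, voltage_uv=out)


def extract_ab_waves(
    trace: SyntheticERGTrace,
    a_window_ms: float = 50.0,
    b_window_ms: float = 150.0,
    detection_floor_uv: float = 5.0,
    b_mode: str = "trough-to-peak",
) -> ERGFeatures:
    """Measure a/b amplitudes and implicit times on an averaged trace.

    Baseline is the pre-onset mean.  The a-trough is the minimum in
    ``(onset, onset + a_window_ms]``; the b-peak is the maximum after the
    trough within ``(onset, onset + b_window_ms]``.  Deflections smaller
    than ``detection_floor_uv`` raise an ``a_absent``/``b_absent`` flag; an
    absent a-wave makes the b amplitude baseline-referenced.
    """
    v = np.asarray(trace.voltage_uv, dtype=float)
    if v.ndim == 2:
        if v.shape[0] != 1:
            raise ValidationError("extract_ab_waves expects an averaged single trace")
        v = v[0]
    t = trace.time_ms
    onset = trace.stimulus_onset_ms
    pre = t < onset
    baseline = float(v[pre].mean()) if pre.any() else 0.0
    post_a = (t > onset) & (t <= onset + a_window_ms)
    post_b = (t > onset) & (t <= onset + b_window_ms)
    if not post_a.any() or not post_b.any():
        raise ValidationError("no post-onset samples inside the analysis windows")

    flags: list[str] = []
    ia = np.flatnonzero(post_a)[np.argmin(v[post_a])]
    a_amp = baseline - v[ia]
    a_lat = t[ia] - onset
    if a_amp < detection_floor_uv:
        flags.append("a_absent")
        a_amp = max(a_amp, 0.0)
        trough_val, search_from = baseline, onset
    else:
        trough_val, search_from = v[ia], t[ia]

    post_peak = (t > search_from) & post_b
    if not post_peak.any():
        post_peak = post_b
    ib = np.flatnonzero(post_peak)[np.argmax(v[post_peak])]
    if b_mode == "trough-to-peak":
        b_amp = v[ib] - trough_val
    elif b_mode == "baseline-to-peak":
        b_amp = v[ib] - baseline
    else:
        raise ValidationError(f"unknown b_mode {b_mode!r}")
    b_lat = t[ib] - onset
    if v[ib] - baseline < detection_floor_uv and b_amp < detection_floor_uv:
        flags.append("b_absent")
        b_amp = max(b_amp, 0.0)
    return ERGFeatures(
        a_amplitude_uv=float(max(a_amp, 0.0)),
        a_latency_ms=float(a_lat),
        b_amplitude_uv=float(max(b_amp, 0.0)),
        b_latency_ms=float(b_lat),
        baseline_uv=baseline,
        flags=flags,
    )


_FEATURES = ["a_amplitude_uv", "a_latency_ms", "b_amplitude_uv", "b_latency_ms"]


def intensity_series(
    features: pd.DataFrame,
    compare_groups: bool = True,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize per-intensity features and compare groups feature-wise.

    ``features`` needs columns ``group``, ``intensity`` and the four feature
    columns (one row per eye).  Returns ``(summary, comparisons)``:
    per-group/intensity mean +/- SEM, and per-intensity between-group exact
    rank-sum comparisons Bonferroni-corrected over the whole feature x
    intensity family.
    """
    required = {"group", "intensity", *_FEATURES}
    missing = required - set(features.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    if features["intensity"].nunique() < 1:
        raise ValidationError("need at least one intensity")

    summary = (
        features.groupby(["group", "intensity"])[_FEATURES]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]

    comparisons = pd.DataFrame()
    if compare_groups:
        groups = sorted(features["group"].unique())
        if len(groups) != 2:
            raise ValidationError("group comparison requires exactly two groups")
        rows = []
        intensities = sorted(features["intensity"].unique())
        family_m = len(intensities) * len(_FEATURES)
        for intensity in intensities:
            sub = features[features["intensity"] == intensity]
            a = sub[sub["group"] == groups[0]]
            b = sub[sub["group"] == groups[1]]
            for feat in _FEATURES:
                res = statcore.compare(a[feat].to_numpy(), b[feat].to_numpy(), method="wilcoxon")
                p_corr = min(1.0, res.p_value * family_m)
                rows.append(
                    {
                        "intensity": intensity,
                        "feature": feat,
                        "estimate": res.estimate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": p_corr,
                        "p_raw": res.p_value,
                        "method": res.method,
                        "correction": "bonferroni",
                        "family_m": family_m,
                        "significant": p_corr < alpha,
                    }
                )
        comparisons = pd.DataFrame(rows)
    return summary, comparisons
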