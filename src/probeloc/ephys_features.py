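"""Extracellular preprocessing and per-depth feature profiles.

The raw signal is split into the local-field-potential band (low-pass 300 Hz,
resampled to 2.5 kHz) and the action-potential band (band-pass 300–5000 Hz at
the native rate, nominally 30 kHz).  Before the band split each channel's
temporal median is subtracted (baseline offset) and the per-sample median
across channels is subtracted (common average referencing, which removes
noise shared across the probe).  Multiunit activity is registered as
negative threshold crossings of the AP band at −50 μV.

From the event train and the LFP we compute per-depth feature profiles —
spike rate, median event amplitude, LFP power — which carry the recognizable
signatures of anatomic landmarks: the brain surface shows up as a step in
LFP power and spiking, white matter as a quiet low-amplitude stretch, and so
on.  Only the surface detector is automated here; the other signatures are
exposed as profiles for a human (or downstream tool) to match, which is how
the landmarks are identified in practice.  Photostimulation-evoked activity
is summarized as a baseline-subtracted per-depth count in a configurable
post-stimulus window (0–5 ms for direct axonal responses, 5–20 ms for
synaptic responses), plus a PSTH.

All amplitudes are handled in μV (int16 samples × ``uV_per_bit``), so
thresholds are independent of acquisition gain.  Filters are zero-phase
(forward-backward) order-3 Butterworth: the corner frequencies are the
physical contract, and zero-phase filtering preserves event timing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "RawRecording",
    "EventTrain",
    "FeatureProfile",
    "remove_offset",
    "common_average_reference",
    "split_bands",
    "detect_multiunit",
    "spike_rate_map",
    "depth_profiles",
    "detect_surface",
    "evoked_profile",
    "read_recording",
    "write_recording",
]

MUA_THRESHOLD_UV = -50.0
DEAD_TIME_MS = 1.0
LFP_CORNER_HZ = 300.0
LFP_RATE_HZ = 2500.0
AP_BAND_HZ = (300.0, 5000.0)
FILTER_ORDER = 3


@dataclass
class RawRecording:
    """Channel-by-time extracellular recording.

    ``samples`` may be int16 raw counts or float μV; ``in_uv`` records which.
    ``channel_depth_um`` is each channel's shank depth (distance from the tip
    reference) and must be strictly monotone.
    """

    samples: np.ndarray  # (n_channels, n_samples)
    sample_rate_hz: float
    uV_per_bit: float = 1.0
    channel_depth_um: np.ndarray | None = None
    in_uv: bool = False

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.channel_depth_um is None:
            self.channel_depth_um = np.arange(self.n_channels, dtype=float)
        self.channel_depth_um = np.asarray(self.channel_depth_um, dtype=float)
        if len(self.channel_depth_um) != self.n_channels:
            raise ValueError("channel_depth_um must have one entry per channel")
        d = np.diff(self.channel_depth_um)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("channel depths must be strictly monotone")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def to_uv(self) -> "RawRecording":
        if self.in_uv:
            return self
        return replace(self, samples=self.samples.astype(float) * self.uV_per_bit,
                       in_uv=True)


@dataclass
class EventTrain:
    """Threshold-crossing events: (channel, time_s, amplitude_uV) triples."""

    channel: np.ndarray
    time_s: np.ndarray
    amplitude_uV: np.ndarray
    threshold_uV: float = MUA_THRESHOLD_UV
    dead_time_ms: float = DEAD_TIME_MS

    def __post_init__(self) -> None:
        self.channel = np.asarray(self.channel, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.amplitude_uV = np.asarray(self.amplitude_uV, dtype=float)

    def __len__(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.channel, "time_s": self.time_s,
            "amplitude_uV": self.amplitude_uV,
        })


@dataclass
class FeatureProfile:
    """Scalar-per-depth-bin profile (``kind`` tags what the scalar is)."""

    depth_bins_um: np.ndarray  # (n_bins + 1,) edges
    values: np.ndarray  # (n_bins,)
    kind: str = "spike_rate"
    missing: np.ndarray | None = None  # bins with no valid sample

    def __post_init__(self) -> None:
        self.depth_bins_um = np.asarray(self.depth_bins_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.depth_bins_um) - 1:
            raise ValueError("values must have one entry per bin")

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.depth_bins_um[:-1] + self.depth_bins_um[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth_um": self.bin_centers_um, "value": self.values})


# ---- preprocessing ---------------------------------------------------------


def remove_offset(rec: RawRecording) -> RawRecording:
    """Subtract each channel's temporal median (baseline offset removal)."""
    rec = rec.to_uv()
    med = np.median(rec.samples, axis=1, keepdims=True)
    return replace(rec, samples=rec.samples - med)


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the cross-channel median at every sample (common noise removal)."""
    if rec.n_channels < 2:
        raise ValueError("common average referencing needs >= 2 channels")
    rec = rec.to_uv()
    med = np.median(rec.samples, axis=0, keepdims=True)
    return replace(rec, samples=rec.samples - med)


def split_bands(
    rec: RawRecording,
    lfp_corner_hz: float = LFP_CORNER_HZ,
    lfp_rate_hz: float = LFP_RATE_HZ,
    ap_band_hz: tuple[float, float] = AP_BAND_HZ,
) -> tuple[RawRecording, RawRecording]:
    """Split into (AP band, LFP band).

    LFP: zero-phase low-pass at ``lfp_corner_hz`` then decimation to
    ``lfp_rate_hz`` (polyphase anti-aliased resampling when the factor is not
    an integer).  AP: zero-phase band-pass at the native rate, with the upper
    corner clipped below Nyquist for low-rate inputs.
    """
    if rec.sample_rate_hz < 10_000:
        raise ValueError(
            f"sample rate {rec.sample_rate_hz} Hz is too low for an AP band"
        )
    rec = rec.to_uv()
    nyq = rec.sample_rate_hz / 2.0
    lo, hi = ap_band_hz
    sos_ap = scipy.signal.butter(
        FILTER_ORDER, [lo, min(hi, 0.95 * nyq)], btype="bandpass",
        fs=rec.sample_rate_hz, output="sos",
    )
    ap = replace(rec, samples=scipy.signal.sosfiltfilt(sos_ap, rec.samples, axis=1))

    sos_lfp = scipy.signal.butter(
        FILTER_ORDER, lfp_corner_hz, btype="lowpass",
        fs=rec.sample_rate_hz, output="sos",
    )
    low = scipy.signal.sosfiltfilt(sos_lfp, rec.samples, axis=1)
    ratio = rec.sample_rate_hz / lfp_rate_hz
    if abs(ratio - round(ratio)) < 1e-9:
        low = low[:, :: int(round(ratio))]
    else:
        from fractions import Fraction

        frac = Fraction(lfp_rate_hz / rec.sample_rate_hz).limit_denominator(1000)
        low = scipy.signal.resample_poly(low, frac.numerator, frac.denominator, axis=1)
    lfp = replace(rec, samples=low, sample_rate_hz=lfp_rate_hz)
    return ap, lfp


# ---- event detection -------------------------------------------------------


def detect_multiunit(
    ap: RawRecording,
    threshold_uV: float = MUA_THRESHOLD_UV,
    dead_time_ms: float = DEAD_TIME_MS,
) -> EventTrain:
    """Negative threshold crossings of the AP band, per channel.

    An event is registered at the first sub-threshold sample of each
    excursion; its amplitude is the trough within the dead-time window, and
    further crossings within the dead time of a prior event are suppressed
    (one spike, one event).
    """
    ap = ap.to_uv()
    dead = max(1, int(round(dead_time_ms * 1e-3 * ap.sample_rate_hz)))
    chans, times, amps = [], [], []
    x = ap.samples
    below = x < threshold_uV
    for c in range(ap.n_channels):
        onsets = np.flatnonzero(below[c, 1:] & ~below[c, :-1]) + 1
        if below[c, 0]:
            onsets = np.r_[0, onsets]
        if len(onsets) == 0:
            continue
        kept = []
        last = -dead - 1
        for i in onsets:
            if i - last > dead:
                kept.append(i)
                last = i
        kept = np.asarray(kept, dtype=int)
        trough = np.array([x[c, i: i + dead].min() for i in kept])
        chans.append(np.full(len(kept), c))
        times.append(kept / ap.sample_rate_hz)
        amps.append(trough)
    if chans:
        channel = np.concatenate(chans)
        time_s = np.concatenate(times)
        amplitude = np.concatenate(amps)
        order = np.argsort(time_s, kind="stable")
        channel, time_s, amplitude = channel[order], time_s[order], amplitude[order]
    else:
        channel = np.empty(0, int)
        time_s = np.empty(0)
        amplitude = np.empty(0)
    return EventTrain(channel=channel, time_s=time_s, amplitude_uV=amplitude,
                      threshold_uV=threshold_uV, dead_time_ms=dead_time_ms)


# ---- binned maps & profiles ------------------------------------------------


def _depth_edges(channel_depth_um: np.ndarray, depth_bin_um: float) -> np.ndarray:
    # bins are centered on the channel grid so a channel sitting exactly on
    # the bin pitch contributes to the bin whose center is its own depth
    lo = channel_depth_um.min() - depth_bin_um / 2.0
    n = max(1, int(round((channel_depth_um.max() - channel_depth_um.min())
                         / depth_bin_um)) + 1)
    return lo + depth_bin_um * np.arange(n + 1)


def spike_rate_map(
    events: EventTrain,
    channel_depth_um: np.ndarray,
    duration_s: float,
    t_bin_s: float = 10.0,
    depth_bin_um: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event rate in (time, depth) bins; returns (map Hz, time edges, depth edges).

    Total events are conserved: ``sum(map) * t_bin_s`` equals the event count
    within the recording duration.
    """
    channel_depth_um = np.asarray(channel_depth_um, dtype=float)
    t_edges = t_bin_s * np.arange(int(np.ceil(duration_s / t_bin_s)) + 1)
    d_edges = _depth_edges(channel_depth_um, depth_bin_um)
    depths = channel_depth_um[events.channel]
    counts, _, _ = np.histogram2d(events.time_s, depths, bins=[t_edges, d_edges])
    return counts / t_bin_s, t_edges, d_edges


def depth_profiles(
    events: EventTrain,
    lfp: RawRecording,
    channel_depth_um: np.ndarray | None = None,
    depth_bin_um: float = 20.0,
    lfp_band_hz: tuple[float, float] | None = None,
) -> dict[str, FeatureProfile]:
    """Per-depth spike rate, median |event amplitude|, and LFP power.

    LFP power is the mean squared μV per channel, over the full LFP band by
    default or band-passed to ``lfp_band_hz`` first.  These are the profiles a
    practitioner matches against the anatomic landmark catalog.
    """
    lfp = lfp.to_uv()
    if channel_depth_um is None:
        channel_depth_um = lfp.channel_depth_um
    channel_depth_um = np.asarray(channel_depth_um, dtype=float)
    edges = _depth_edges(channel_depth_um, depth_bin_um)
    nbins = len(edges) - 1
    duration = lfp.duration_s

    depths = channel_depth_um[events.channel]
    counts, _ = np.histogram(depths, bins=edges)
    # rate per channel in the bin, not per bin, so sparse/dense rows compare
    ch_bin = np.clip(np.digitize(channel_depth_um, edges) - 1, 0, nbins - 1)
    ch_per_bin = np.bincount(ch_bin, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = counts / np.maximum(ch_per_bin, 1) / duration
    rate[ch_per_bin == 0] = 0.0

    amp = np.zeros(nbins)
    ev_bin = np.clip(np.digitize(depths, edges) - 1, 0, nbins - 1) if len(events) else []
    for b in range(nbins):
        sel = np.asarray(ev_bin) == b if len(events) else np.zeros(0, bool)
        if len(events) and sel.any():
            amp[b] = np.median(np.abs(events.amplitude_uV[sel]))

    sig = lfp.samples
    if lfp_band_hz is not None:
        sos = scipy.signal.butter(FILTER_ORDER, lfp_band_hz, btype="bandpass",
                                  fs=lfp.sample_rate_hz, output="sos")
        sig = scipy.signal.sosfiltfilt(sos, sig, axis=1)
    ch_power = np.mean(sig ** 2, axis=1)
    power = np.zeros(nbins)
    np.add.at(power, ch_bin, ch_power)
    power = power / np.maximum(ch_per_bin, 1)

    return {
        "spike_rate": FeatureProfile(edges, rate, kind="spike_rate"),
        "amplitude": FeatureProfile(edges, amp, kind="amplitude"),
        "lfp_power": FeatureProfile(edges, power, kind="lfp_power"),
    }


# ---- surface detection -----------------------------------------------------


def detect_surface(
    lfp_power: FeatureProfile,
    min_confidence: float = 2.0,
    plateau_frac: float = 0.25,
) -> tuple[float, int, float]:
    """Locate the brain surface as the step in the LFP-power profile.

    Outside the brain (saline/CSF) LFP power and spiking are low; entry into
    the brain is a sharp increase.  Channels are ordered by shank depth, so
    the *shallow* plateau (largest depths — farthest from the tip) is out of
    the brain and the *deep* plateau (smallest depths) is inside.  The
    surface is the first bin, scanning from the out-of-brain end, whose value
    exceeds the midpoint of the two plateau medians.

    Returns ``(depth_um, bin_index, confidence)`` where confidence is plateau
    separation over pooled spread.  Raises if no step is detectable
    (confidence below ``min_confidence``).
    """
    vals = lfp_power.values
    n = len(vals)
    k = max(1, int(round(plateau_frac * n)))
    inside = vals[:k]  # small shank depth = deep in the brain
    outside = vals[-k:]  # large shank depth = above the surface
    lo, hi = np.median(outside), np.median(inside)
    spread = np.sqrt(0.5 * (np.var(outside) + np.var(inside)))
    sep = hi - lo
    confidence = np.inf if spread == 0 and sep > 0 else (
        0.0 if spread == 0 else sep / spread
    )
    if sep <= 0 or confidence < min_confidence:
        raise ValueError(
            f"no surface transition detected (confidence {confidence:.2f} < "
            f"{min_confidence}); the profile may not span the brain surface"
        )
    mid = 0.5 * (lo + hi)
    above = vals > mid
    # scan from the out-of-brain end toward the tip; the surface is the first
    # bin above the midpoint whose deeper neighbor is also above (guards
    # against an isolated noise excursion in the out-of-brain stretch)
    idx = None
    for i in range(n - 1, -1, -1):
        if above[i] and (i == 0 or above[i - 1]):
            idx = i
            break
    if idx is None:
        raise ValueError("no surface transition detected (profile never crosses midpoint)")
    return float(lfp_power.bin_centers_um[idx]), int(idx), float(confidence)


# ---- evoked activity -------------------------------------------------------


def evoked_profile(
    events: EventTrain,
    stim_times_s: np.ndarray,
    window_ms: tuple[float, float] = (0.0, 5.0),
    channel_depth_um: np.ndarray | None = None,
    depth_bin_um: float = 20.0,
    psth_bin_ms: float = 0.5,
    psth_span_ms: float = 25.0,
) -> tuple[FeatureProfile, pd.DataFrame]:
    """Per-depth evoked event count and a PSTH around stimulus onsets.

    For every stimulus, events with latency inside ``window_ms`` are counted
    per depth bin and summed over repetitions; an equal-duration pre-stimulus
    window gives the baseline that is subtracted.  The axonal window (0–5 ms)
    captures direct fiber responses; the synaptic window (5–20 ms) captures
    postsynaptic responses one relay downstream.
    """
    stim = np.sort(np.asarray(stim_times_s, dtype=float))
    if len(stim) == 0:
        raise ValueError("stim_times is empty")
    if channel_depth_um is None:
        raise ValueError("channel_depth_um is required")
    channel_depth_um = np.asarray(channel_depth_um, dtype=float)
    edges = _depth_edges(channel_depth_um, depth_bin_um)
    w0, w1 = (w * 1e-3 for w in window_ms)
    wlen = w1 - w0
    depths = channel_depth_um[events.channel]

    def window_counts(t0: np.ndarray, t1: np.ndarray) -> np.ndarray:
        counts = np.zeros(len(edges) - 1)
        i0 = np.searchsorted(events.time_s, t0)
        i1 = np.searchsorted(events.time_s, t1)
        for a, b in zip(i0, i1):
            if b > a:
                c, _ = np.histogram(depths[a:b], bins=edges)
                counts += c
        return counts

    evoked = window_counts(stim + w0, stim + w1)
    baseline = window_counts(stim + w0 - wlen - 1e-9, stim + w0 - 1e-9)
    profile = FeatureProfile(edges, evoked - baseline, kind="evoked_count")

    # PSTH at psth_bin_ms resolution over [-span/5, span] around onset
    t_edges = np.arange(-psth_span_ms / 5, psth_span_ms + psth_bin_ms, psth_bin_ms)
    latencies = []
    for t in stim:
        sel = (events.time_s >= t + t_edges[0] * 1e-3) & (
            events.time_s < t + t_edges[-1] * 1e-3
        )
        latencies.append((events.time_s[sel] - t) * 1e3)
    lat = np.concatenate(latencies) if latencies else np.empty(0)
    hist, _ = np.histogram(lat, bins=t_edges)
    psth = pd.DataFrame({
        "time_ms": 0.5 * (t_edges[:-1] + t_edges[1:]),
        "rate_hz": hist / len(stim) / (psth_bin_ms * 1e-3),
    })
    return profile, psth


# ---- file I/O --------------------------------------------------------------


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Flat binary int16, channel-major frames, with a JSON metadata sidecar."""
    path = Path(path)
    if rec.in_uv:
        data = np.round(rec.samples / rec.uV_per_bit).astype(np.int16)
    else:
        data = rec.samples.astype(np.int16)
    # frame-major on disk: sample index varies slowest across frames
    data.T.tofile(path)
    meta = {
        "n_channels": rec.n_channels,
        "sample_rate_hz": rec.sample_rate_hz,
        "uV_per_bit": rec.uV_per_bit,
        "channel_depth_um": rec.channel_depth_um.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    return path


def read_recording(path: str | Path, meta: dict | None = None) -> RawRecording:
    """Read a flat binary int16 recording.

    Metadata comes from the JSON sidecar ``<file>.json`` or an acquisition-
    system ``.meta`` text file of ``key=value`` lines next to the binary
    (keys ``nSavedChans`` and ``imSampRate``/``niSampRate`` are recognized).
    """
    path = Path(path)
    if meta is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        metafile = path.with_suffix(".meta")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        elif metafile.exists():
            meta = _parse_meta_text(metafile.read_text())
        else:
            raise FileNotFoundError(
                f"no metadata for {path}: expected {sidecar.name} or {metafile.name}"
            )
    n_ch = int(meta["n_channels"])
    raw = np.fromfile(path, dtype=np.int16)
    if len(raw) % n_ch:
        raise IOError(f"{path}: size not divisible by {n_ch} channels")
    samples = raw.reshape(-1, n_ch).T
    depth = meta.get("channel_depth_um")
    return RawRecording(
        samples=samples,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        uV_per_bit=float(meta.get("uV_per_bit", 1.0)),
        channel_depth_um=np.asarray(depth, float) if depth is not None else None,
    )


def _parse_meta_text(text: str) -> dict:
    kv = {}
    for line in text.splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            kv[k.strip().lstrip("~")] = v.strip()
    meta: dict = {}
    if "nSavedChans" in kv:
        meta["n_channels"] = int(kv["nSavedChans"])
    for key in ("imSampRate", "niSampRate", "sample_rate_hz"):
        if key in kv:
            meta["sample_rate_hz"] = float(kv[key])
            break
    if "uV_per_bit" in kv:
        meta["uV_per_bit"] = float(kv["uV_per_bit"])
    if "n_channels" not in meta or "sample_rate_hz" not in meta:
        raise ValueError("acquisition metadata lacks channel count or sample rate")
    return meta
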