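"""Groundtruth accuracy analysis for electrode localization.

The localization accuracy is assessed by comparing two independent readouts
of the same anatomy along a localized probe: the fluorescence of labeled
axonal projections sampled at each site's assigned 3D position, and the
photostimulation-evoked multiunit activity recorded on the sites themselves.
If the sites are placed correctly, the two per-depth profiles peak at the
same place.  Each profile is fitted with a multi-term Gaussian model

    f(x) = sum_k A_k exp(-(x - mu_k)^2 / (2 sigma_k^2)) + c,

corresponding peaks are matched greedily by nearest mean, and the absolute
peak-location difference |Δ| (in mm along the probe) is the localization
error.  Per penetration the matched |Δ| are averaged; the study summary is
the mean ± sample SD over penetrations.  Unmatched peaks (unequal component
counts) are reported but never enter the accuracy statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

from .electrodes import ElectrodeLocalization
from .ephys_features import FeatureProfile
from .volume_io import Volume3D

__all__ = [
    "MultiGaussFit",
    "AccuracyResult",
    "fluorescence_profile",
    "fit_multigauss",
    "match_peaks",
    "accuracy_summary",
    "paired_comparison",
]


@dataclass
class MultiGaussFit:
    """Fitted sum-of-Gaussians: per-component (amplitude, mean_mm, sigma_mm) + offset."""

    amplitudes: np.ndarray
    means_mm: np.ndarray
    sigmas_mm: np.ndarray
    offset: float
    residual_norm: float
    converged: bool

    @property
    def K(self) -> int:
        return len(self.means_mm)

    def __call__(self, x_mm: np.ndarray) -> np.ndarray:
        x = np.asarray(x_mm, dtype=float)[..., None]
        return (
            self.amplitudes
            * np.exp(-((x - self.means_mm) ** 2) / (2 * self.sigmas_mm ** 2))
        ).sum(axis=-1) + self.offset


@dataclass
class AccuracyResult:
    """Accuracy summary over penetrations: mean ± sample SD of per-penetration |Δ|."""

    per_penetration_mm: np.ndarray
    mean_mm: float
    sd_mm: float
    n_penetrations: int
    single_penetration: bool = False


# ---- profiles --------------------------------------------------------------


def fluorescence_profile(
    vol: Volume3D,
    localization: ElectrodeLocalization,
    radius_um: float = 20.0,
    space: str | None = None,
) -> FeatureProfile:
    """Mean fluorescence in a ``radius_um`` sphere around each site, vs shank depth.

    Intensities are trilinearly sampled on a fixed stencil of points inside
    the sphere and normalized to [0, 1] over the probe so fluorescence and
    evoked-count profiles share an amplitude scale.  Sites whose sample
    sphere falls entirely outside the volume are flagged missing; an
    all-outside probe is an error.
    """
    from scipy.interpolate import RegularGridInterpolator

    space = space or vol.space_name
    if space not in localization.coords_um:
        raise ValueError(
            f"localization has no coordinates in space {space!r}; "
            f"available: {list(localization.coords_um)}"
        )
    coords = localization.coords_um[space]
    axes = [vol.origin[i] + vol.spacing[i] * np.arange(vol.shape[i]) for i in range(3)]
    interp = RegularGridInterpolator(
        axes, np.asarray(vol.data, dtype=float), method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    # stencil: center + 6 face + 8 corner points of the sphere
    r = radius_um
    face = r * np.vstack([np.eye(3), -np.eye(3)])
    corner = (r / np.sqrt(3)) * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    stencil = np.vstack([[0.0, 0.0, 0.0], face, corner])
    samples = interp((coords[:, None, :] + stencil[None, :, :]).reshape(-1, 3))
    samples = samples.reshape(len(coords), -1)
    finite = np.isfinite(samples)
    n_ok = finite.sum(axis=1)
    values = np.where(finite, samples, 0.0).sum(axis=1) / np.maximum(n_ok, 1)
    values[n_ok == 0] = np.nan
    missing = ~np.isfinite(values)
    if missing.all():
        raise ValueError("every site lies outside the fluorescence volume")
    vmin = np.nanmin(values)
    vmax = np.nanmax(values)
    span = vmax - vmin
    norm = (values - vmin) / span if span > 0 else np.zeros_like(values)
    norm[missing] = np.nan

    depth = localization.shank_depth_um
    order = np.argsort(depth)
    depth, norm, missing = depth[order], norm[order], missing[order]
    # one bin per site row; rows share depths, so average duplicates
    uniq, inv = np.unique(depth, return_inverse=True)
    acc = np.full(len(uniq), np.nan)
    for i in range(len(uniq)):
        v = norm[inv == i]
        v = v[np.isfinite(v)]
        if len(v):
            acc[i] = v.mean()
    pitch = np.min(np.diff(uniq)) if len(uniq) > 1 else radius_um
    edges = np.r_[uniq - pitch / 2, uniq[-1] + pitch / 2]
    return FeatureProfile(edges, acc, kind="fluorescence",
                          missing=~np.isfinite(acc))


# ---- Gaussian fitting ------------------------------------------------------


def _multigauss(x: np.ndarray, params: np.ndarray, K: int) -> np.ndarray:
    A = params[0:K]
    mu = params[K:2 * K]
    sig = params[2 * K:3 * K]
    c = params[3 * K]
    return (A * np.exp(-((x[:, None] - mu) ** 2) / (2 * sig ** 2))).sum(axis=1) + c


def fit_multigauss(
    profile: FeatureProfile, K: int, x_scale_mm: float = 1e-3
) -> MultiGaussFit:
    """Nonlinear least-squares fit of ``K`` Gaussians + offset to a depth profile.

    ``K`` is chosen by the analyst from the profile's shape (the number of
    distinct projection targets along the probe).  Depths are converted to mm
    via ``x_scale_mm``.  Initialization is multi-start from the K largest
    local maxima; degenerate (flat or nearly empty) profiles and K too large
    for the informative points raise instead of returning nonsense.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    x = profile.bin_centers_um * x_scale_mm
    y = profile.values.astype(float)
    good = np.isfinite(y)
    x, y = x[good], y[good]
    if len(x) < 3 * K + 1:
        raise ValueError(
            f"profile has {len(x)} informative points; K={K} needs >= {3 * K + 1}"
        )
    span = y.max() - y.min()
    if span <= 0:
        raise ValueError("flat profile: nothing to fit")

    # candidate component centers: local maxima with a minimum separation so
    # two starts never land inside the same noisy peak top, largest first
    import scipy.signal

    min_sep = max(2, int(round(len(y) / (4 * K))))
    cand, _ = scipy.signal.find_peaks(y, distance=min_sep)
    cand = cand[np.argsort(y[cand])[::-1]]
    if len(cand) < K:
        extra = np.argsort(y)[::-1]
        cand = np.unique(np.r_[cand, extra])[:max(K, len(cand))]
        cand = cand[np.argsort(y[cand])[::-1]]
    width0 = (x.max() - x.min()) / (4 * K)
    baseline = np.percentile(y, 10)

    def pack(idx: np.ndarray) -> np.ndarray:
        return np.r_[
            np.maximum(y[idx] - baseline, 0.05 * span),
            x[idx],
            np.full(K, width0),
            baseline,
        ]

    starts = [pack(cand[:K])]
    if len(cand) > K:  # second start: spread the candidate centers out
        sel = np.unique(np.linspace(0, len(cand) - 1, K).astype(int))
        if len(sel) == K:
            starts.append(pack(cand[sel]))
    # third start: evenly spaced centers, immune to spurious maxima
    even = np.clip(((np.arange(K) + 0.5) / K * len(x)).astype(int), 0, len(x) - 1)
    starts.append(pack(even))

    lo = np.r_[np.zeros(K), np.full(K, x.min() - 3 * width0),
               np.full(K, 1e-4), -np.inf]
    hi = np.r_[np.full(K, 10 * span), np.full(K, x.max() + 3 * width0),
               np.full(K, x.max() - x.min()), np.inf]

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
        try:
            res = scipy.optimize.least_squares(
                lambda p: _multigauss(x, p, K) - y, p0, bounds=(lo, hi),
                method="trf", max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ValueError("multi-Gaussian fit failed to converge")
    p = best.x
    order = np.argsort(p[K:2 * K])
    fit = MultiGaussFit(
        amplitudes=p[0:K][order], means_mm=p[K:2 * K][order],
        sigmas_mm=p[2 * K:3 * K][order], offset=float(p[3 * K]),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
    )
    if not fit.converged:
        raise ValueError("multi-Gaussian fit did not converge")
    return fit


# ---- peak matching & summaries ---------------------------------------------


def match_peaks(
    fit_a: MultiGaussFit, fit_b: MultiGaussFit
) -> tuple[list[tuple[float, float, float]], list[float], list[float]]:
    """Greedy nearest-mean peak matching.

    Repeatedly pairs the globally closest (mean_a, mean_b) until one side is
    exhausted; each peak is used once.  Returns
    ``(pairs, unmatched_a, unmatched_b)`` with pairs as
    ``(mean_a_mm, mean_b_mm, abs_diff_mm)``.  Swapping the inputs permutes the
    pairs but preserves the multiset of |Δ|.
    """
    for name, f in (("first", fit_a), ("second", fit_b)):
        if not f.converged:
            raise ValueError(f"{name} fit did not converge; cannot match peaks")
    a = list(enumerate(fit_a.means_mm))
    b = list(enumerate(fit_b.means_mm))
    pairs = []
    while a and b:
        ia = ja = 0
        dmin = np.inf
        for i, (ai, ma) in enumerate(a):
            for j, (bj, mb) in enumerate(b):
                d = abs(ma - mb)
                if d < dmin:
                    dmin, (ia, ja) = d, (i, j)
        ma = a.pop(ia)[1]
        mb = b.pop(ja)[1]
        pairs.append((float(ma), float(mb), float(abs(ma - mb))))
    return pairs, [float(m) for _, m in a], [float(m) for _, m in b]


def accuracy_summary(per_penetration_diffs_mm) -> AccuracyResult:
    """Mean ± sample SD (n−1) of per-penetration |Δ| in mm.

    Each element is one penetration's summary |Δ| (the mean over its matched
    pairs).  A single penetration reports SD 0 with a flag.
    """
    diffs = np.asarray(list(per_penetration_diffs_mm), dtype=float)
    if diffs.size == 0:
        raise ValueError("no penetrations to summarize")
    if np.any(diffs < 0):
        raise ValueError("per-penetration differences must be absolute values")
    single = diffs.size == 1
    sd = 0.0 if single else float(np.std(diffs, ddof=1))
    return AccuracyResult(
        per_penetration_mm=diffs, mean_mm=float(diffs.mean()), sd_mm=sd,
        n_penetrations=int(diffs.size), single_penetration=single,
    )


def paired_comparison(errors_a, errors_b) -> tuple[float, int, float]:
    """Two-tailed paired t test between matched per-penetration error vectors.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))``, ``d = a−b``,
    ``df = n−1``.  Zero-variance differences are degenerate (t undefined)
    unless every difference is 0, which returns ``(0, df, 1)``.
    """
    a = np.asarray(list(errors_a), dtype=float)
    b = np.asarray(list(errors_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("paired comparison needs n >= 2")
    d = a - b
    sd = np.std(d, ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t is degenerate")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * scipy.stats.t.sf(abs(t), df=n - 1))
    return t, n - 1, p
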