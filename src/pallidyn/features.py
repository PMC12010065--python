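"""Neuron-level featurization of pallidal spike trains.

Computes the 28 continuous metrics of the cohort summary table — firing rate
and regularity, ISI moments, local variation, histogram-based burst/asymmetry
indices, Poisson-surprise burst statistics, 50 ms-split pause statistics, and
per-band oscillation peak frequencies — plus the binary discharge flags
(tonic / irregular / bursting, per-band oscillatory).

Undefined semantics: a metric that cannot be computed (too few spikes, no
detected bursts, band not significant) is NaN, never zero; burst and
oscillation summary statistics therefore pertain exclusively to bursting and
oscillatory neurons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, special, stats

from .types import SpikeTrain

logger = logging.getLogger("pallidyn")

#: frequency bands in Hz: delta, theta, alpha, beta, gamma
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

#: the 28 continuous metrics, in cohort-table order
METRICS = [
    "firing_rate",
    "firing_regularity",
    "cv",
    "local_variation",
    "isi_mean_ms",
    "isi_std_ms",
    "isi_skewness",
    "isi_corr_coefficient",
    "asymmetry_index",
    "burst_index",
    "burst_duration_s",
    "burst_frequency_hz",
    "interburst_duration_s",
    "burst_count",
    "burst_avg_spike_count",
    "burst_spike_proportion_pct",
    "pause_index",
    "pause_ratio",
    "pause_duration_s",
    "pause_frequency_hz",
    "pause_count",
    "pause_spike_proportion_pct",
    "pause_time_proportion_pct",
    "delta_freq_hz",
    "theta_freq_hz",
    "alpha_freq_hz",
    "beta_freq_hz",
    "gamma_freq_hz",
]

FLAGS = ["is_tonic", "is_irregular", "is_bursting",
         "osc_delta", "osc_theta", "osc_alpha", "osc_beta", "osc_gamma", "osc_any"]


@dataclass
class FeatureConfig:
    """Every threshold of the featurization pipeline, exposed in one place."""

    # ISI histogram indices
    isi_bin_width_s: float = 0.005
    min_isi_for_histogram: int = 20
    # burst detection (Poisson surprise)
    surprise_min: float = 5.0
    burst_min_spikes: int = 3
    burst_lookahead: int = 10
    # pause detection
    pause_min_s: float = 0.25
    pause_split_s: float = 0.05
    # oscillation detection
    n_surrogates: int = 100
    surrogate_percentile: float = 95.0
    welch_nperseg: int = 4096
    bin_ms: float = 1.0
    min_spikes_osc: int = 50
    compute_oscillations: bool = True
    # discharge classification
    burst_density_min: float = 0.1  # bursts/s
    burst_prop_min_pct: float = 2.0
    regularity_min: float = 0.15
    # minimum-data gates
    min_isi_regularity: int = 10
    seed: int = 0


# ---------------------------------------------------------------------------
# ISI descriptive statistics
# ---------------------------------------------------------------------------

def isi_descriptives(train: SpikeTrain) -> dict[str, float]:
    """Firing rate, ISI mean/std (ms), CV, skewness and lag-1 serial correlation.

    Needs >= 2 ISIs for rate/mean/std/CV and >= 4 ISIs for skewness and lag-1
    correlation; ungated metrics are NaN.
    """
    out = {k: np.nan for k in
           ("firing_rate", "isi_mean_ms", "isi_std_ms", "cv", "isi_skewness", "isi_corr_coefficient")}
    isi = train.isi()
    if isi.size < 2:
        return out
    out["firing_rate"] = train.rate
    m = float(np.mean(isi))
    s = float(np.std(isi, ddof=1))
    out["isi_mean_ms"] = m * 1000.0
    out["isi_std_ms"] = s * 1000.0
    out["cv"] = s / m
    if isi.size >= 4:
        out["isi_skewness"] = float(stats.skew(isi))
        if np.std(isi[:-1]) > 0 and np.std(isi[1:]) > 0:
            out["isi_corr_coefficient"] = float(np.corrcoef(isi[:-1], isi[1:])[0, 1])
    return out


def local_variation(isi: np.ndarray) -> float:
    """Local variation Lv: 3/(n-1) * sum(((I_i - I_{i+1})/(I_i + I_{i+1}))^2).

    0 for clockwork firing, ~1 for a Poisson process; sequence-sensitive, so
    robust to slow rate drift that inflates the CV.
    """
    isi = np.asarray(isi, dtype=float)
    if isi.size < 2:
        raise ValueError("local variation needs at least 2 ISIs")
    if np.any(isi <= 0):
        raise ValueError("ISIs must be strictly positive")
    d = (isi[:-1] - isi[1:]) / (isi[:-1] + isi[1:])
    return float(3.0 * np.mean(d**2))


def firing_regularity(isi: np.ndarray, min_isi: int = 10) -> float:
    """log10 of the ML gamma shape fitted to the ISIs.

    0 for Poisson firing; positive = more regular than Poisson, negative =
    more irregular/bursty. NaN when fewer than ``min_isi`` intervals or the
    fit fails.
    """
    isi = np.asarray(isi, dtype=float)
    if isi.size < min_isi or np.any(isi <= 0):
        return np.nan
    if np.std(isi) / np.mean(isi) < 1e-6:
        return 6.0  # clockwork firing: shape diverges; cap keeps the score finite
    try:
        shape, _, _ = stats.gamma.fit(isi, floc=0)
    except Exception:  # non-convergent fit
        logger.warning("gamma MLE failed on %d ISIs", isi.size)
        return np.nan
    return float(np.log10(shape)) if shape > 0 else np.nan


def isi_histogram_indices(isi: np.ndarray, bin_width_s: float = 0.005) -> tuple[float, float]:
    """(burst index, asymmetry index) from the ISI histogram.

    burst index = mean(ISI) / mode(ISI); asymmetry index = mode / mean, where
    the mode is the center of the maximal histogram bin (lowest bin wins ties).
    Degenerate constant-ISI input uses mode = the single value.
    """
    isi = np.asarray(isi, dtype=float)
    if isi.size < 1:
        return np.nan, np.nan
    mean = float(np.mean(isi))
    if np.max(isi) == np.min(isi):
        mode = float(isi[0])
    else:
        edges = np.arange(0.0, np.max(isi) + bin_width_s, bin_width_s)
        counts, _ = np.histogram(isi, bins=edges)
        if counts.sum() == 0:
            return np.nan, np.nan
        imax = int(np.argmax(counts))  # argmax takes the lowest index on ties
        mode = float((edges[imax] + edges[imax + 1]) / 2)
    if mode <= 0 or mean <= 0:
        return np.nan, np.nan
    return mean / mode, mode / mean


# ---------------------------------------------------------------------------
# burst detection: Poisson surprise
# ---------------------------------------------------------------------------

def poisson_surprise(k: int, expected: float) -> float:
    """-log10 P(Poisson(expected) >= k): the burst surprise score.

    Uses the identity P(Poisson(mu) >= k) = P(Gamma(k) <= mu), i.e. the
    regularized lower incomplete gamma function, which is much cheaper than
    summing the Poisson tail.
    """
    if expected <= 0:
        return np.inf if k > 0 else 0.0
    tail = special.gammainc(k, expected)
    if tail > 0:
        return float(-np.log10(tail))
    # extreme tail underflowed; fall back to the log survival function
    return float(-stats.poisson.logsf(k - 1, expected) / np.log(10))


@dataclass
class BurstSet:
    """Detected bursts of one train plus their summary metrics (NaN when empty)."""

    bursts: list[tuple[float, float, int, float]] = field(default_factory=list)  # onset, offset, n_spikes, surprise
    burst_duration_s: float = np.nan
    burst_frequency_hz: float = np.nan
    interburst_duration_s: float = np.nan
    burst_count: float = np.nan
    burst_avg_spike_count: float = np.nan
    burst_spike_proportion_pct: float = np.nan

    @property
    def n(self) -> int:
        return len(self.bursts)


def _surprise_of(times: np.ndarray, rate: float, s: int, e: int) -> float:
    # the window is anchored at spike s, so the surprise counts the e - s
    # further spikes observed within the span (renewal restart at the anchor)
    span = times[e] - times[s]
    return poisson_surprise(e - s, rate * span) if span > 0 else 0.0


def detect_bursts(train: SpikeTrain, cfg: FeatureConfig | None = None) -> BurstSet:
    """Poisson-surprise burst detection (surprise-maximization scan).

    Candidate bursts start at runs of ``burst_min_spikes - 1`` consecutive ISIs
    shorter than half the mean ISI; the end is extended (with a lookahead over
    transient dips) and the start trimmed to maximize the surprise
    S = -log10 P(>= k spikes in the window | homogeneous Poisson at the
    train's mean rate). Windows with S >= ``surprise_min`` are kept; bursts
    are non-overlapping and ordered. Zero bursts is a valid outcome.
    Detection depends on ISIs only, so it is invariant to time offsets.
    """
    cfg = cfg or FeatureConfig()
    out = BurstSet()
    n = train.n_spikes
    if n < cfg.burst_min_spikes:
        return out
    times = train.times
    rate = n / train.duration
    isi = np.diff(times)
    dense = isi < 0.5 / rate  # ISIs shorter than half the mean ISI
    min_run = cfg.burst_min_spikes - 1

    bursts: list[tuple[float, float, int, float]] = []
    i = 0
    while i <= n - cfg.burst_min_spikes:
        if not np.all(dense[i : i + min_run]):
            i += 1
            continue
        s, e = i, i + min_run
        best = _surprise_of(times, rate, s, e)
        # extend the end, tolerating up to `lookahead` non-improving spikes
        j = e + 1
        miss = 0
        while j < n and miss < cfg.burst_lookahead:
            sc = _surprise_of(times, rate, s, j)
            if sc > best:
                best, e = sc, j
                miss = 0
            else:
                miss += 1
            j += 1
        # trim the start
        while e - s + 1 > cfg.burst_min_spikes:
            sc = _surprise_of(times, rate, s + 1, e)
            if sc > best:
                best, s = sc, s + 1
            else:
                break
        if best >= cfg.surprise_min:
            bursts.append((float(times[s]), float(times[e]), e - s + 1, best))
            i = e + 1
        else:
            i += 1

    if not bursts:
        return out
    onsets = np.array([b[0] for b in bursts])
    offsets = np.array([b[1] for b in bursts])
    counts = np.array([b[2] for b in bursts], dtype=float)
    durs = offsets - onsets
    out.bursts = bursts
    out.burst_duration_s = float(np.mean(durs))
    out.burst_frequency_hz = float(np.mean((counts - 1) / durs))
    out.interburst_duration_s = float(np.mean(onsets[1:] - offsets[:-1])) if len(bursts) > 1 else np.nan
    out.burst_count = float(len(bursts))
    out.burst_avg_spike_count = float(np.mean(counts))
    out.burst_spike_proportion_pct = float(100.0 * counts.sum() / n)
    return out


# ---------------------------------------------------------------------------
# pause detection: 50 ms split + 250 ms events
# ---------------------------------------------------------------------------

@dataclass
class PauseSet:
    """Detected pauses (prolonged ISIs) and the classical 50 ms-split indices."""

    pauses: list[tuple[float, float]] = field(default_factory=list)
    pause_index: float = np.nan
    pause_ratio: float = np.nan
    pause_duration_s: float = np.nan
    pause_frequency_hz: float = np.nan
    pause_count: float = 0.0
    pause_spike_proportion_pct: float = np.nan
    pause_time_proportion_pct: float = np.nan


def detect_pauses(train: SpikeTrain, cfg: FeatureConfig | None = None) -> PauseSet:
    """Pause events are ISIs >= ``pause_min_s`` (default 250 ms).

    pause index = #(ISI > 50 ms) / #(ISI <= 50 ms); pause ratio = the same
    ratio on summed durations; pause frequency = event count / summed event
    duration; proportions are relative to the ISI count and the recording
    duration respectively. The index/ratio are NaN (with a log entry) when no
    ISI falls at or below the 50 ms split.
    """
    cfg = cfg or FeatureConfig()
    out = PauseSet()
    isi = train.isi()
    if isi.size < 2:
        return out
    long_mask = isi > cfg.pause_split_s
    n_short = int((~long_mask).sum())
    if n_short == 0:
        logger.warning("unit %s: no ISIs <= %g s; pause index/ratio undefined",
                       train.unit_id, cfg.pause_split_s)
    else:
        out.pause_index = float(long_mask.sum() / n_short)
        out.pause_ratio = float(isi[long_mask].sum() / isi[~long_mask].sum())
    ev = np.flatnonzero(isi >= cfg.pause_min_s)
    out.pauses = [(float(train.times[i]), float(train.times[i + 1])) for i in ev]
    out.pause_count = float(ev.size)
    total = float(isi[ev].sum())
    out.pause_time_proportion_pct = 100.0 * total / train.duration
    out.pause_spike_proportion_pct = 100.0 * ev.size / isi.size
    if ev.size:
        out.pause_duration_s = total / ev.size
        out.pause_frequency_hz = ev.size / total
    return out


# ---------------------------------------------------------------------------
# oscillation detection: Welch spectrum vs ISI-shuffled surrogates
# ---------------------------------------------------------------------------

def _band_peaks(x: np.ndarray, fs: float, nperseg: int) -> tuple[np.ndarray, np.ndarray]:
    f, p = signal.welch(x, fs=fs, nperseg=min(nperseg, x.size), detrend="constant")
    return f, p


def detect_oscillations(train: SpikeTrain, cfg: FeatureConfig | None = None, seed: int | None = None) -> dict:
    """Per-band oscillation test of the 1 ms-binned spike indicator.

    The Welch spectrum's peak in each band is compared with the 95th percentile
    of the peak distribution over ``n_surrogates`` ISI-shuffled surrogate
    trains (shuffling preserves rate and the ISI distribution while destroying
    temporal order). Flagged bands report the observed peak frequency.

    Returns ``{band: {"significant": bool, "peak_freq": float, "ratio": float}}``
    with all bands ``significant=None`` (undefined) for short/sparse trains.
    """
    cfg = cfg or FeatureConfig()
    seed = cfg.seed if seed is None else seed
    undefined = {b: {"significant": None, "peak_freq": np.nan, "ratio": np.nan} for b in BANDS}
    lowest_edge = min(lo for lo, _ in BANDS.values())
    if train.duration < 2.0 / lowest_edge or train.n_spikes < cfg.min_spikes_osc:
        return undefined

    fs = 1000.0 / cfg.bin_ms
    nbins = int(np.ceil(train.duration * fs))

    def binned(times: np.ndarray) -> np.ndarray:
        x = np.zeros(nbins)
        idx = np.minimum((times * fs).astype(int), nbins - 1)
        np.add.at(x, idx, 1.0)
        return x

    f, p = _band_peaks(binned(train.times), fs, cfg.welch_nperseg)

    obs = {}
    for band, (lo, hi) in BANDS.items():
        m = (f >= lo) & (f < hi)
        k = int(np.argmax(p[m]))
        obs[band] = (float(p[m][k]), float(f[m][k]))

    # surrogate peak distributions: ISI shuffling, deterministic per unit
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, hash(train.unit_id) & 0x7FFFFFFF]))
    isi = train.isi()
    t0 = train.times[0]
    surr_peaks = {b: np.empty(cfg.n_surrogates) for b in BANDS}
    for i in range(cfg.n_surrogates):
        st = t0 + np.concatenate([[0.0], np.cumsum(rng.permutation(isi))])
        _, ps = _band_peaks(binned(st), fs, cfg.welch_nperseg)
        for band, (lo, hi) in BANDS.items():
            m = (f >= lo) & (f < hi)
            surr_peaks[band][i] = ps[m].max()

    out = {}
    for band in BANDS:
        thresh = float(np.percentile(surr_peaks[band], cfg.surrogate_percentile))
        power, freq = obs[band]
        sig = bool(power > thresh)
        out[band] = {
            "significant": sig,
            "peak_freq": freq if sig else np.nan,
            "ratio": power / thresh if thresh > 0 else np.inf,
        }
    return out


# ---------------------------------------------------------------------------
# discharge classification and cohort featurization
# ---------------------------------------------------------------------------

def classify_discharge(burst_set: BurstSet, regularity: float, duration: float,
                       cfg: FeatureConfig | None = None) -> str:
    """Assign exactly one of {'bursting', 'tonic', 'irregular'}.

    bursting: detected burst density >= ``burst_density_min`` bursts/s or
    burst spike proportion >= ``burst_prop_min_pct``; otherwise tonic when
    firing regularity >= ``regularity_min``, else irregular. Returns
    'undefined' when regularity is NaN and the burst gate is not met.
    """
    cfg = cfg or FeatureConfig()
    if burst_set.n > 0:
        density = burst_set.n / duration
        if density >= cfg.burst_density_min or burst_set.burst_spike_proportion_pct >= cfg.burst_prop_min_pct:
            return "bursting"
    if np.isnan(regularity):
        return "undefined"
    return "tonic" if regularity >= cfg.regularity_min else "irregular"


def featurize_train(train: SpikeTrain, cfg: FeatureConfig | None = None) -> dict:
    """All metrics and flags for one neuron (NaN = undefined)."""
    cfg = cfg or FeatureConfig()
    row: dict = {"unit_id": train.unit_id, "patient_id": train.patient_id,
                 "gene": train.gene, "duration_s": train.duration}
    row.update({m: np.nan for m in METRICS})
    for fl in FLAGS:
        row[fl] = False
    row["discharge"] = "undefined"

    isi = train.isi()
    row.update(isi_descriptives(train))
    if isi.size >= 2 and np.all(isi > 0):
        row["local_variation"] = local_variation(isi)
    row["firing_regularity"] = firing_regularity(isi, cfg.min_isi_regularity)
    if isi.size >= cfg.min_isi_for_histogram:
        bi, ai = isi_histogram_indices(isi, cfg.isi_bin_width_s)
        row["burst_index"], row["asymmetry_index"] = bi, ai

    bs = detect_bursts(train, cfg)
    if bs.n > 0:
        row["burst_duration_s"] = bs.burst_duration_s
        row["burst_frequency_hz"] = bs.burst_frequency_hz
        row["interburst_duration_s"] = bs.interburst_duration_s
        row["burst_count"] = bs.burst_count
        row["burst_avg_spike_count"] = bs.burst_avg_spike_count
        row["burst_spike_proportion_pct"] = bs.burst_spike_proportion_pct

    ps = detect_pauses(train, cfg)
    row["pause_index"] = ps.pause_index
    row["pause_ratio"] = ps.pause_ratio
    row["pause_duration_s"] = ps.pause_duration_s
    row["pause_frequency_hz"] = ps.pause_frequency_hz
    row["pause_count"] = ps.pause_count
    row["pause_spike_proportion_pct"] = ps.pause_spike_proportion_pct
    row["pause_time_proportion_pct"] = ps.pause_time_proportion_pct

    if cfg.compute_oscillations:
        osc = detect_oscillations(train, cfg)
        any_sig = False
        for band in BANDS:
            r = osc[band]
            if r["significant"]:
                row[f"{band}_freq_hz"] = r["peak_freq"]
                row[f"osc_{band}"] = True
                any_sig = True
        row["osc_any"] = any_sig

    label = classify_discharge(bs, row["firing_regularity"], train.duration, cfg)
    row["discharge"] = label
    for lab in ("tonic", "irregular", "bursting"):
        row[f"is_{lab}"] = label == lab
    return row


def featurize_cohort(trains: list[SpikeTrain], cfg: FeatureConfig | None = None) -> pd.DataFrame:
    """One row per neuron with all metric columns and discharge/oscillation flags.

    Per-neuron failures are logged and yield undefined cells, never an abort.
    """
    cfg = cfg or FeatureConfig()
    rows = []
    for tr in trains:
        try:
            rows.append(featurize_train(tr, cfg))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("unit %s failed featurization: %s", tr.unit_id, exc)
    df = pd.DataFrame(rows)
    cols = ["unit_id", "patient_id", "gene", "duration_s"] + METRICS + FLAGS + ["discharge"]
    return df[cols]
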