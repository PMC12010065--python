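"""Synthetic spike-train and clinical-cohort generators.

Every generator is a pure function of its parameters and an integer seed:
per-train random streams are derived with a counter-based splitting rule
(``np.random.SeedSequence([seed, *counters])``), so cohorts are bitwise
reproducible and order-independent.

The building blocks emulate the discharge regimes of pallidal neurons under
general anesthesia: gamma-renewal firing with controllable regularity (shape 1
is Poisson, large shapes approach clockwork firing), superimposed dense burst
epochs with planted ground truth, deleted-spike pause windows, and sinusoidal
rate modulation realized either by thinning (Poisson) or by time-rescaling of
a gamma renewal process.
"""

from __future__ import annotations

import math

import numpy as np

from .types import GeneProfile, SimConfig, SpikeTrain

__all__ = [
    "gen_gamma_renewal",
    "gen_bursty_train",
    "gen_oscillatory_train",
    "gen_modulated_renewal",
    "inject_pauses",
    "gen_cohort",
    "gen_synthetic_clinical",
]


def _rng(*counters: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(c) & 0x7FFFFFFF for c in counters]))


def _gamma_isi_times(rng: np.random.Generator, rate: float, shape: float, duration: float) -> np.ndarray:
    """Cumulative gamma ISIs clipped to [0, duration). Mean ISI = 1/rate."""
    scale = 1.0 / (rate * shape)
    n_guess = max(int(rate * duration * 1.5) + 20, 50)
    times = np.cumsum(rng.gamma(shape, scale, size=n_guess))
    while times.size and times[-1] < duration:
        extra = np.cumsum(rng.gamma(shape, scale, size=n_guess)) + times[-1]
        times = np.concatenate([times, extra])
    return times[times < duration]


def gen_gamma_renewal(
    rate: float,
    shape: float,
    duration: float,
    seed: int,
    *,
    unit_id: str = "sim",
    patient_id: str = "sim",
    gene: str = "SIM",
) -> SpikeTrain:
    """Gamma-renewal spike train: i.i.d. gamma ISIs with mean 1/rate.

    ISI CV is 1/sqrt(shape); shape 1 recovers a homogeneous Poisson process.
    """
    if rate <= 0 or shape <= 0 or duration <= 0:
        raise ValueError("rate, shape and duration must be positive")
    if rate * duration < 2:
        raise ValueError(
            f"expected spike count {rate * duration:.2f} < 2; use a longer duration or higher rate"
        )
    times = _gamma_isi_times(_rng(seed, 0), rate, shape, duration)
    return SpikeTrain(unit_id, patient_id, gene, times, duration)


def gen_bursty_train(cfg: SimConfig, *, unit_id: str = "sim", patient_id: str = "sim", gene: str = "SIM") -> SpikeTrain:
    """Background gamma renewal plus Poisson-placed dense burst epochs.

    Bursts are placed homogeneously in time at ``cfg.burst_rate`` with
    non-overlap enforced by rejection; each carries a geometric number of
    spikes (mean ``cfg.burst_len``, minimum 2) at ``cfg.intra_burst_rate``.
    Planted burst windows are recorded in ``annotations['bursts']``.
    With ``burst_rate=0`` the output is identical to :func:`gen_gamma_renewal`
    called with the same seed.
    """
    base = gen_gamma_renewal(
        cfg.base_rate, cfg.shape, cfg.duration, cfg.seed,
        unit_id=unit_id, patient_id=patient_id, gene=gene,
    )
    if cfg.burst_rate == 0:
        return base
    if cfg.intra_burst_rate <= cfg.base_rate:
        raise ValueError("intra_burst_rate must exceed base_rate: bursts are denser than background")

    rng = _rng(cfg.seed, 1)
    n_bursts = rng.poisson(cfg.burst_rate * cfg.duration)
    windows: list[tuple[float, float]] = []
    spikes = [base.times]
    for _ in range(n_bursts):
        k = max(2, int(rng.geometric(1.0 / cfg.burst_len)))
        isis = rng.gamma(2.0, 1.0 / (2.0 * cfg.intra_burst_rate), size=k - 1)
        length = float(np.sum(isis))
        placed = False
        for _attempt in range(100):  # rejection keeps bursts disjoint
            t0 = rng.uniform(0, max(cfg.duration - length, 1e-6))
            if all(t0 + length < a or t0 > b for a, b in windows):
                placed = True
                break
        if not placed:
            continue
        burst_times = t0 + np.concatenate([[0.0], np.cumsum(isis)])
        windows.append((t0, t0 + length))
        spikes.append(burst_times[burst_times < cfg.duration])

    merged = np.sort(np.concatenate(spikes))
    # enforce strictly increasing times (collisions between background and burst spikes)
    keep = np.concatenate([[True], np.diff(merged) > 1e-6])
    merged = merged[keep]
    return SpikeTrain(
        unit_id, patient_id, gene, merged, cfg.duration,
        annotations={"bursts": sorted(windows)},
    )


def gen_oscillatory_train(
    rate: float,
    osc_freq: float,
    osc_depth: float,
    duration: float,
    seed: int,
    *,
    unit_id: str = "sim",
    patient_id: str = "sim",
    gene: str = "SIM",
) -> SpikeTrain:
    """Inhomogeneous Poisson train with intensity rate*(1 + depth*sin(2*pi*f*t)),
    realized by thinning a homogeneous process at the intensity ceiling."""
    if not (0 <= osc_depth <= 1):
        raise ValueError("osc_depth must be in [0, 1]")
    rng = _rng(seed, 2)
    lam_max = rate * (1 + osc_depth)
    n = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0, duration, size=n))
    accept = rng.uniform(size=n) * lam_max < rate * (1 + osc_depth * np.sin(2 * np.pi * osc_freq * cand))
    times = cand[accept]
    times = times[np.concatenate([[True], np.diff(times) > 1e-9])] if times.size else times
    return SpikeTrain(unit_id, patient_id, gene, times, duration)


def gen_modulated_renewal(
    rate: float,
    shape: float,
    osc_freq: float,
    osc_depth: float,
    duration: float,
    seed: int,
    **labels,
) -> SpikeTrain:
    """Gamma renewal with sinusoidal rate modulation via time rescaling.

    A unit-mean-rate gamma renewal process is generated in operational time and
    mapped through the inverse integrated intensity
    Lambda(t) = rate*t + rate*depth/(2*pi*f)*(1 - cos(2*pi*f*t)), which
    preserves the mean rate and the local regularity of the renewal process.
    """
    if osc_depth == 0 or osc_freq == 0:
        return gen_gamma_renewal(rate, shape, duration, seed, **labels)
    op_total = rate * duration + rate * osc_depth / (2 * np.pi * osc_freq) * (
        1 - math.cos(2 * np.pi * osc_freq * duration)
    )
    u = _gamma_isi_times(_rng(seed, 3), 1.0, shape, op_total / 1.0)
    grid = np.linspace(0, duration, max(int(duration * 1000), 1000))
    lam_grid = rate * grid + rate * osc_depth / (2 * np.pi * osc_freq) * (1 - np.cos(2 * np.pi * osc_freq * grid))
    times = np.interp(u, lam_grid, grid)
    times = times[(times >= 0) & (times < duration)]
    times = times[np.concatenate([[True], np.diff(times) > 1e-9])] if times.size else times
    return SpikeTrain(labels.get("unit_id", "sim"), labels.get("patient_id", "sim"), labels.get("gene", "SIM"), times, duration)


def inject_pauses(train: SpikeTrain, pause_rate: float, pause_dur_mean: float, seed: int) -> SpikeTrain:
    """Delete spikes inside Poisson-placed exponential-length silence windows.

    The recording duration is unchanged; planted windows are recorded in
    ``annotations['pauses']`` as ground truth.
    """
    if pause_rate < 0:
        raise ValueError("pause_rate must be >= 0")
    if pause_rate == 0:
        return train
    rng = _rng(seed, 4)
    n = rng.poisson(pause_rate * train.duration)
    onsets = np.sort(rng.uniform(0, train.duration, size=n))
    lengths = rng.exponential(pause_dur_mean, size=n)
    windows = [(float(a), float(min(a + L, train.duration))) for a, L in zip(onsets, lengths)]
    keep = np.ones(train.n_spikes, dtype=bool)
    for a, b in windows:
        keep &= ~((train.times >= a) & (train.times < b))
    ann = dict(train.annotations)
    ann["pauses"] = windows
    return SpikeTrain(train.unit_id, train.patient_id, train.gene, train.times[keep], train.duration, ann)


# ---------------------------------------------------------------------------
# cohort generation calibrated to per-gene profiles
# ---------------------------------------------------------------------------

_BAND_CHOICES = ((1.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 30.0))
_BAND_PROBS = (0.40, 0.30, 0.20, 0.10)  # pallidal oscillations are low-frequency dominated


def _one_neuron(profile: GeneProfile, duration: float, seed: int, gene_idx: int, idx: int) -> SpikeTrain:
    rng = _rng(seed, gene_idx, idx, 5)
    labels = dict(
        unit_id=f"{profile.gene}_{idx:04d}",
        patient_id=f"{profile.gene}_pat{idx % 4}",
        gene=profile.gene,
    )
    sub_seed = int(rng.integers(0, 2**31 - 1))

    mu, sd = profile.metrics.get("firing_rate", (20.0, 5.0))
    rate = float(np.clip(rng.normal(mu, sd), 3.0, 120.0))

    p = (profile.frac_tonic, profile.frac_irregular, profile.frac_bursting)
    regime = rng.choice(3, p=np.asarray(p) / sum(p))
    oscillatory = rng.uniform() < profile.frac_oscillatory

    if oscillatory:
        # shallow modulation: deep sinusoidal drive concentrates spikes into
        # periodic clusters that the surprise detector rightly calls bursts,
        # which would contaminate the planted discharge-regime fractions
        lo, hi = _BAND_CHOICES[rng.choice(len(_BAND_CHOICES), p=_BAND_PROBS)]
        osc_freq, osc_depth = float(rng.uniform(lo, hi)), 0.35
    else:
        osc_freq, osc_depth = 0.0, 0.0

    if regime == 0:  # tonic: regular renewal, regularity = log10(shape) well above 0.15
        shape = 10 ** rng.uniform(0.6, 1.2)
        return gen_modulated_renewal(rate, shape, osc_freq, osc_depth, duration, sub_seed, **labels)
    if regime == 1:  # irregular: near-Poisson renewal; shapes slightly above 1
        # keep the regime from drifting into genuinely bursty sub-Poisson firing
        shape = 10 ** rng.uniform(0.0, 0.12)
        return gen_modulated_renewal(rate, shape, osc_freq, osc_depth, duration, sub_seed, **labels)
    # bursting: sub-Poisson background plus planted dense bursts; base rate is
    # reduced by the expected burst contribution to keep the mean rate on target
    burst_rate = 0.3
    burst_len = float(rng.uniform(8, 14))
    base = max(rate - burst_rate * burst_len, 2.0)
    cfg = SimConfig(
        base_rate=base,
        shape=10 ** rng.uniform(-0.3, 0.0),
        duration=duration,
        burst_rate=burst_rate,
        intra_burst_rate=float(rng.uniform(120, 250)),
        burst_len=burst_len,
        seed=sub_seed,
    )
    return gen_bursty_train(cfg, **labels)


def gen_cohort(
    profiles: dict[str, GeneProfile],
    n_per_gene: int,
    duration: float = 20.0,
    seed: int = 0,
) -> list[SpikeTrain]:
    """Synthetic cohort: ``n_per_gene`` neurons per gene, drawn from a mixture of
    tonic / irregular / bursting regimes matching each gene's target fractions,
    with base rates sampled around the profile's firing-rate mean."""
    if n_per_gene < 1:
        raise ValueError("n_per_gene must be >= 1")
    trains = []
    for gene_idx, gene in enumerate(sorted(profiles)):
        for i in range(n_per_gene):
            trains.append(_one_neuron(profiles[gene], duration, seed, gene_idx, i))
    return trains


def gen_synthetic_clinical(n_patients: int, group_effect: float, seed: int) -> "pd.DataFrame":
    """Synthetic pre/post BFMDRS pairs for two patient groups.

    ``group_effect`` is the planted between-group difference in mean percent
    change (group A improves by ``group_effect`` percentage points less than
    group B). Scores are clipped to the 0-128 scale.
    """
    import pandas as pd

    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    rng = _rng(seed, 6)
    n_a = n_patients // 2
    rows = []
    for i in range(n_patients):
        group = "A" if i < n_a else "B"
        pre = rng.uniform(15, 95)
        pct = rng.normal(-40 + (group_effect if group == "A" else 0.0), 18)
        post = float(np.clip(pre * (1 + pct / 100), 0, 128))
        rows.append({"patient_id": f"SynPat{i}", "group": group, "bfmdrs_pre": round(pre, 1), "bfmdrs_fu1": round(post, 1)})
    return pd.DataFrame(rows)
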