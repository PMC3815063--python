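"""Marey-map recombination profiling and pericentromere boundary calling.

A Marey map plots genetic position (cM) against physical position (Mb); its
local slope is the recombination rate.  Marker maps are noisy, so genetic
positions are first regularized with an isotonic (monotone non-decreasing)
fit before finite differencing over sliding windows.  Pericentromeric
heterochromatin shows up as a long run of near-zero rate, which is what the
boundary caller extracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.isotonic import IsotonicRegression


@dataclass
class MareyProfile:
    chromosome: str
    physical_Mb: np.ndarray  # sorted anchor positions
    genetic_cM: np.ndarray  # raw genetic positions (anchor order)
    fitted_cM: np.ndarray  # isotonic regularization, non-decreasing
    window_Mb: float
    step_Mb: float
    window_start_Mb: np.ndarray = field(default_factory=lambda: np.array([]))
    window_rates: np.ndarray = field(default_factory=lambda: np.array([]))
    window_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def window_mid_Mb(self) -> np.ndarray:
        return self.window_start_Mb + self.window_Mb / 2.0


def marey_profile(
    anchors: Sequence[Tuple[float, float]],
    chromosome: str = "chr",
    window_Mb: float = 5.0,
    step_Mb: float = 1.0,
) -> MareyProfile:
    """Build a windowed recombination-rate profile from (bp, cM) anchors.

    Parameters
    ----------
    anchors : sequence of (physical_bp, genetic_cM)
        Marker anchors on one chromosome; physical positions in base pairs.
    window_Mb, step_Mb : float
        Sliding-window geometry for the rate estimate (cM/Mb per window).
    """
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors for a Marey profile")
    arr = np.asarray(sorted(anchors), dtype=float)
    phys_mb = arr[:, 0] / 1e6
    cm = arr[:, 1]
    if phys_mb[0] == phys_mb[-1]:
        raise ValueError("all anchors at one physical position")

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(phys_mb, cm)

    starts = []
    rates = []
    counts = []
    pos = phys_mb[0]
    end = phys_mb[-1]
    while pos < end:
        w_end = min(pos + window_Mb, end)
        if w_end - pos <= 0:
            break
        g0 = float(np.interp(pos, phys_mb, fitted))
        g1 = float(np.interp(w_end, phys_mb, fitted))
        starts.append(pos)
        rates.append(max(0.0, (g1 - g0) / (w_end - pos)))
        counts.append(int(np.sum((phys_mb >= pos) & (phys_mb <= w_end))))
        if pos + window_Mb >= end:
            break
        pos += step_Mb

    return MareyProfile(
        chromosome=chromosome,
        physical_Mb=phys_mb,
        genetic_cM=cm,
        fitted_cM=fitted,
        window_Mb=window_Mb,
        step_Mb=step_Mb,
        window_start_Mb=np.array(starts),
        window_rates=np.array(rates),
        window_counts=np.array(counts, dtype=int),
    )


def call_pericentromere(
    profile: MareyProfile,
    rate_threshold: float = 0.1,
    min_span_Mb: float = 2.0,
) -> Optional[Tuple[float, float]]:
    """Locate the pericentromeric region as the longest low-recombination run.

    Scans consecutive windows with rate below ``rate_threshold`` (cM/Mb) and
    returns the physical interval (Mb) of the longest maximal run whose span
    is at least ``min_span_Mb``; ties go to the more proximal (smaller start)
    run.  Returns ``None`` when no run qualifies.
    """
    rates = profile.window_rates
    if rates.size == 0:
        return None
    starts = profile.window_start_Mb
    window = profile.window_Mb

    best: Optional[Tuple[float, float]] = None
    best_span = 0.0
    i = 0
    n = len(rates)
    while i < n:
        if rates[i] >= rate_threshold:
            i += 1
            continue
        j = i
        while j + 1 < n and rates[j + 1] < rate_threshold:
            j += 1
        run_start = float(starts[i])
        run_end = float(min(starts[j] + window, profile.physical_Mb[-1]))
        span = run_end - run_start
        if span >= min_span_Mb and span > best_span:
            best, best_span = (run_start, run_end), span
        i = j + 1
    return best


def write_marey_tsv(profile: MareyProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("#window_start_Mb\twindow_mid_Mb\trate_cM_per_Mb\tn_anchors\n")
        for s, m, r, c in zip(
            profile.window_start_Mb,
            profile.window_mid_Mb,
            profile.window_rates,
            profile.window_counts,
        ):
            fh.write(f"{s:.3f}\t{m:.3f}\t{r:.4f}\t{c}\n")


def plot_marey(profile: MareyProfile, path) -> None:
    """Two-panel Marey plot (cM vs Mb; windowed rate). Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    ax0.plot(profile.physical_Mb, profile.genetic_cM, ".", ms=3, alpha=0.5, label="anchors")
    ax0.plot(profile.physical_Mb, profile.fitted_cM, "-", lw=1.5, label="isotonic fit")
    ax0.set_ylabel("genetic position (cM)")
    ax0.legend(frameon=False)
    ax1.step(profile.window_mid_Mb, profile.window_rates, where="mid")
    ax1.set_xlabel("physical position (Mb)")
    ax1.set_ylabel("rate (cM/Mb)")
    fig.suptitle(profile.chromosome)
    fig.savefig(path, dpi=150)
    plt.close(fig)
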