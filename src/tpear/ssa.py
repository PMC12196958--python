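"""Singular spectrum analysis of 1-D acceleration signals.

A signal of length N is embedded into an L x K Hankel trajectory matrix
(K = N - L + 1), decomposed by SVD, and each eigentriple is mapped back to a
length-N series by anti-diagonal (Hankel) averaging.  The elementary series
sum exactly to the input.  Components are then grouped into

* ``trend``    — the leading components whose energy is essentially below
  0.5 Hz (slow drift, gravity leakage),
* ``dominant`` — the harmonic pair (or lone component) carrying the gait
  oscillation: the non-trend pair of adjacent components whose spectral peak
  frequencies agree within 20 % and whose combined singular-value energy is
  maximal,
* ``residual`` — everything else, including the tail beyond the retained
  eigentriples.

The embedding window defaults to 2 s of signal; for trials shorter than 4 s
it falls back to 1 s so that enough columns remain for a stable
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel, svd

from .exceptions import FlatSignalError, SignalTooShortError

WINDOW_SECONDS = 2.0
SHORT_TRIAL_S = 4.0
FALLBACK_WINDOW_SECONDS = 1.0
MAX_COMPONENTS = 30
TREND_MAX_HZ = 0.5
TREND_ENERGY_FRAC = 0.95
PAIR_FREQ_TOL = 0.2


@dataclass
class SsaDecomposition:
    """Elementary reconstructed components of one signal plus grouping labels.

    ``components[i]`` is the diagonal-averaged series of eigentriple i
    (ordered by decreasing singular value); ``tail`` collects the contribution
    of any eigentriples beyond the retained cap so that
    ``components.sum(axis=0) + tail`` reproduces the input exactly.
    """

    signal: np.ndarray
    window_samples: int
    components: np.ndarray        # (k, N)
    singular_values: np.ndarray   # (k,)
    grouping: list[str]           # per component: trend | dominant | residual
    tail: np.ndarray              # (N,) remainder beyond the retained cap
    fs: float

    def reconstruct(self) -> np.ndarray:
        return self.components.sum(axis=0) + self.tail

    def group_sum(self, label: str) -> np.ndarray:
        mask = [g == label for g in self.grouping]
        if not any(mask):
            return np.zeros_like(self.signal)
        return self.components[np.asarray(mask)].sum(axis=0)


def ssa_decompose(signal: np.ndarray, window_seconds: float = WINDOW_SECONDS,
                  fs: float = 100.0, max_components: int = MAX_COMPONENTS,
                  ) -> SsaDecomposition:
    """Decompose ``signal`` and label trend / dominant / residual groups.

    Trials shorter than 4 s use a 1 s embedding window instead of the
    requested one; raises SignalTooShortError when the signal still does not
    exceed the window.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < SHORT_TRIAL_S * fs:
        window_seconds = min(window_seconds, FALLBACK_WINDOW_SECONDS)
    L = int(round(window_seconds * fs))
    if n <= L:
        raise SignalTooShortError(
            f"signal of {n} samples does not exceed the {L}-sample window")
    K = n - L + 1
    X = hankel(x[:L], x[L - 1:])
    u, s, vt = svd(X, full_matrices=False)
    if s[0] > 0:
        rank = int(np.sum(s > s[0] * 1e-10))
    else:
        rank = 0
    k = min(rank, max_components) if rank else 1
    counts = np.convolve(np.ones(L), np.ones(K))
    comps = np.empty((k, n))
    for i in range(k):
        comps[i] = np.convolve(u[:, i] * s[i], vt[i]) / counts
    tail = x - comps.sum(axis=0)
    grouping = _group(comps, s[:k], fs)
    return SsaDecomposition(signal=x, window_samples=L, components=comps,
                            singular_values=s[:k].copy(), grouping=grouping,
                            tail=tail, fs=fs)


def _spectral_profile(comp: np.ndarray, fs: float) -> tuple[float, float]:
    """(dominant frequency, energy fraction below the trend cut-off)."""
    spec = np.abs(np.fft.rfft(comp)) ** 2
    freqs = np.fft.rfftfreq(comp.size, d=1.0 / fs)
    total = spec.sum()
    if total <= 0:
        return 0.0, 1.0
    low = spec[freqs < TREND_MAX_HZ].sum() / total
    return float(freqs[np.argmax(spec)]), float(low)


def _group(comps: np.ndarray, s: np.ndarray, fs: float) -> list[str]:
    k = len(comps)
    profiles = [_spectral_profile(c, fs) for c in comps]
    labels = ["residual"] * k
    # trend: maximal leading run of essentially sub-0.5 Hz components
    n_trend = 0
    while n_trend < k and profiles[n_trend][1] > TREND_ENERGY_FRAC:
        labels[n_trend] = "trend"
        n_trend += 1
    # dominant: best adjacent non-trend pair with matching spectral peaks
    best_pair, best_energy = None, -1.0
    for i in range(n_trend, k - 1):
        f1, f2 = profiles[i][0], profiles[i + 1][0]
        if f1 <= 0 or f2 <= 0:
            continue
        if abs(f1 - f2) <= PAIR_FREQ_TOL * max(f1, f2):
            energy = s[i] ** 2 + s[i + 1] ** 2
            if energy > best_energy:
                best_pair, best_energy = i, energy
    if best_pair is not None:
        labels[best_pair] = labels[best_pair + 1] = "dominant"
    else:
        # lone oscillatory component with the largest singular value
        for i in range(n_trend, k):
            if profiles[i][0] > 0:
                labels[i] = "dominant"
                break
    return labels


def dominant_oscillation(dec: SsaDecomposition) -> np.ndarray:
    """Sum of the components labelled dominant — the gait oscillation."""
    if "dominant" not in dec.grouping:
        raise FlatSignalError("no oscillatory component found")
    return dec.group_sum("dominant")


def trend_removed(dec: SsaDecomposition) -> np.ndarray:
    """Original signal minus the trend-group reconstruction."""
    return dec.signal - dec.group_sum("trend")


def dump_components(dec: SsaDecomposition, path) -> None:
    """Write the decomposition to CSV for debugging, one component per column."""
    import pandas as pd

    data = {f"c{i}_{g}": dec.components[i]
            for i, g in enumerate(dec.grouping)}
    data["tail"] = dec.tail
    pd.DataFrame(data).to_csv(path, index=False)
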