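"""Empirical mode decomposition (EMD) and its ensemble variant (EEMD).

EMD adaptively sifts a signal into intrinsic mode functions (IMFs), ordered
from the highest local frequency (IMF1) to the lowest, plus a monotone-ish
residue. The fatigue pipeline consumes IMF1 — the high-frequency component
of the sEMG — whose median frequency is the fatigue-sensitive quantity.

EEMD repeats EMD on many white-noise-perturbed copies of the signal and
averages the IMFs component-wise; the uncorrelated noise cancels in the
ensemble mean while populating all time scales, which suppresses the mode
mixing plain EMD is prone to.

Implementation notes
--------------------
* Envelopes are natural cubic splines through the local extrema, with two
  extrema mirrored past each boundary to damp end swings.
* Sifting stops on a Cauchy-style criterion
  SD = Σ(h_prev − h)² / Σ h_prev² < `sift_sd_tol`, combined with the IMF
  condition |#extrema − #zero-crossings| ≤ 1, or after `max_sifts` passes.
* Per-realization ensemble noise comes from substreams spawned off one
  master seed by realization index, so enlarging the ensemble never
  reshuffles earlier realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InputError, ParameterError
from .trace import SignalTrace

__all__ = ["IMFSet", "emd", "eemd"]


@dataclass(frozen=True)
class IMFSet:
    """Ordered IMFs plus residue from one (ensemble) decomposition."""

    imfs: np.ndarray  # shape (k, n); row 0 is IMF1
    residue: np.ndarray  # shape (n,)
    meta: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruction(self) -> np.ndarray:
        """Sum of all IMFs plus the residue."""
        return self.imfs.sum(axis=0) + self.residue

    def zero_crossing_rates(self) -> np.ndarray:
        """Zero crossings per sample for each IMF (frequency-ordering check)."""
        rates = []
        for row in self.imfs:
            s = np.sign(row)
            s = s[s != 0]
            rates.append(np.count_nonzero(s[1:] != s[:-1]) / max(row.size, 1))
        return np.asarray(rates)


def _fill_zero_signs(s: np.ndarray) -> np.ndarray:
    """Forward-fill zeros in a sign sequence so plateaus inherit the prior slope."""
    if not (s == 0).any():
        return s
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return s
    pos = np.searchsorted(nz, np.arange(s.size), side="right") - 1
    pos = np.clip(pos, 0, nz.size - 1)
    return s[nz[pos]]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima of x."""
    s = _fill_zero_signs(np.sign(np.diff(x)))
    maxima = np.flatnonzero((s[:-1] > 0) & (s[1:] < 0)) + 1
    minima = np.flatnonzero((s[:-1] < 0) & (s[1:] > 0)) + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _mirrored(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two extrema past each end so the spline spans [0, n-1]."""
    k = min(2, idx.size)
    left_i = (-idx[:k])[::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    ti = np.concatenate([left_i, idx, right_i])
    tv = np.concatenate([left_v, val, right_v])
    ti, keep = np.unique(ti, return_index=True)
    return ti, tv[keep]


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    """Mean of the upper/lower cubic-spline envelopes, or None if undefined."""
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    n = x.size
    ti, tv = _mirrored(maxima, x[maxima], n)
    upper = CubicSpline(ti, tv, bc_type="natural")(np.arange(n))
    ti, tv = _mirrored(minima, x[minima], n)
    lower = CubicSpline(ti, tv, bc_type="natural")(np.arange(n))
    return 0.5 * (upper + lower)


def _sift(x: np.ndarray, sd_tol: float, max_sifts: int) -> np.ndarray:
    h = x
    for _ in range(max_sifts):
        m = _mean_envelope(h)
        if m is None:
            break
        h_new = h - m
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_tol:
            maxima, minima = _local_extrema(h)
            n_ext = maxima.size + minima.size
            if abs(n_ext - _zero_crossings(h)) <= 1:
                break
    return h


def _is_exhausted(r: np.ndarray) -> bool:
    """True when the residue is monotone or has fewer than 3 extrema."""
    maxima, minima = _local_extrema(r)
    return maxima.size + minima.size < 3


def emd(
    trace: SignalTrace | np.ndarray,
    max_imfs: int = 8,
    sift_sd_tol: float = 0.2,
    max_sifts: int = 50,
) -> IMFSet:
    """Plain empirical mode decomposition.

    Returns an :class:`IMFSet` whose components sum exactly (to float
    round-off) back to the input — each IMF is literally subtracted from
    the running residue. A monotone input yields zero IMFs with
    residue = input.
    """
    x = trace.samples if isinstance(trace, SignalTrace) else np.asarray(trace, dtype=float)
    if x.size < 8:
        raise InputError(f"EMD needs at least 8 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InputError("EMD input contains non-finite samples")
    if max_imfs < 1:
        raise ParameterError(f"max_imfs must be >= 1, got {max_imfs}")

    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs and not _is_exhausted(residue):
        imf = _sift(residue, sift_sd_tol, max_sifts)
        if not np.any(imf):
            break
        imfs.append(imf)
        residue = residue - imf
    stacked = np.vstack(imfs) if imfs else np.empty((0, x.size))
    meta = {
        "method": "emd",
        "max_imfs": max_imfs,
        "sift_sd_tol": sift_sd_tol,
        "max_sifts": max_sifts,
    }
    return IMFSet(imfs=stacked, residue=residue, meta=meta)


def eemd(
    trace: SignalTrace | np.ndarray,
    ensemble_size: int = 100,
    noise_ratio: float = 0.2,
    seed: int = 0,
    max_imfs: int = 8,
    sift_sd_tol: float = 0.2,
    max_sifts: int = 50,
) -> IMFSet:
    """Ensemble EMD: average EMD over white-noise-perturbed copies.

    Each realization m decomposes ``x + noise_ratio * std(x) * w_m`` with
    w_m standard Gaussian white noise from substream m of `seed`.
    Realizations producing fewer IMFs than the ensemble maximum are
    zero-padded in component index before averaging. With
    ``noise_ratio=0, ensemble_size=1`` the result is identical to
    :func:`emd`.
    """
    x = trace.samples if isinstance(trace, SignalTrace) else np.asarray(trace, dtype=float)
    if ensemble_size < 1:
        raise ParameterError(f"ensemble_size must be >= 1, got {ensemble_size}")
    if noise_ratio < 0:
        raise ParameterError(f"noise_ratio must be >= 0, got {noise_ratio}")

    sigma = float(np.std(x))
    per_real: list[np.ndarray] = []  # each (k_m, n)
    residues: list[np.ndarray] = []
    for m in range(ensemble_size):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(m,)))
        noise = noise_ratio * sigma * rng.standard_normal(x.size)
        d = emd(x + noise, max_imfs=max_imfs, sift_sd_tol=sift_sd_tol, max_sifts=max_sifts)
        per_real.append(d.imfs)
        residues.append(d.residue)

    k_max = max((p.shape[0] for p in per_real), default=0)
    acc = np.zeros((k_max, x.size))
    for p in per_real:
        acc[: p.shape[0]] += p
    imfs = acc / ensemble_size
    residue = np.mean(residues, axis=0)
    meta = {
        "method": "eemd",
        "ensemble_size": ensemble_size,
        "noise_ratio": noise_ratio,
        "seed": seed,
        "max_imfs": max_imfs,
        "sift_sd_tol": sift_sd_tol,
        "max_sifts": max_sifts,
    }
    return IMFSet(imfs=imfs, residue=residue, meta=meta)
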