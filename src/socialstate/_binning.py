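"""Time binning shared by the tuning, state and photometry analyses."""

from __future__ import annotations

import numpy as np

_EPS = 1e-9


def bin_means(values, fs: float, t0: float, start_s: float, end_s: float,
              bin_s: float):
    """Mean of samples within complete ``bin_s`` bins of ``[start_s, end_s)``.

    Sample ``i`` (time ``t0 + i/fs``) belongs to bin
    ``floor((t - start_s)/bin_s)``; the trailing partial bin is dropped.

    Parameters
    ----------
    values : array, shape (n_samples,) or (n_neurons, n_samples)

    Returns
    -------
    means : array, shape (..., n_bins)
    bin_starts : array of bin start times in seconds
    """
    if bin_s <= 0:
        raise ValueError(f"bin width must be positive, got {bin_s}")
    duration = end_s - start_s
    n_bins = int(np.floor(duration / bin_s + _EPS))
    if n_bins < 1:
        raise ValueError(
            f"interval [{start_s}, {end_s}) shorter than one {bin_s}-s bin"
        )
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    t = t0 + np.arange(arr.shape[1]) / fs
    rel = t - start_s
    sel = (rel >= -_EPS) & (rel < n_bins * bin_s - _EPS)
    idx = np.floor(rel[sel] / bin_s + _EPS).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        raise ValueError(
            f"bin width {bin_s} s holds no complete sample at {fs} Hz"
        )
    sums = np.zeros((arr.shape[0], n_bins))
    np.add.at(sums.T, idx, arr[:, sel].T)
    means = sums / counts
    if squeeze:
        means = means[0]
    starts = start_s + bin_s * np.arange(n_bins)
    return means, starts
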