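"""Short-channel regression of scalp haemodynamics from long channels."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["short_channel_regress"]


def short_channel_regress(long_series: np.ndarray,
                          short_series: np.ndarray) -> tuple[np.ndarray, int]:
    """Regress out the best-matching short channel from a long channel.

    The short channel with the largest absolute Pearson correlation to the
    long channel is selected and its least-squares projection (with
    intercept) subtracted, leaving a residual exactly orthogonal to the
    chosen (demeaned) short-channel series.

    Parameters
    ----------
    long_series : (n_samples,) array
    short_series : (n_samples, n_short) array of candidate short channels

    Returns
    -------
    residual : (n_samples,) array
    chosen : int
        Column index of the selected short channel, or -1 when all short
        channels are constant (pass-through with warning).
    """
    y = np.asarray(long_series, dtype=float)
    S = np.asarray(short_series, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[0] != y.size:
        raise ValueError("short channels must match the long series length")
    Sc = S - S.mean(axis=0)
    yc = y - y.mean()
    s_sd = Sc.std(axis=0)
    if np.all(s_sd == 0):
        warnings.warn("all short channels are constant; returning input unchanged",
                      UserWarning, stacklevel=2)
        return y.copy(), -1
    y_sd = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Sc * yc[:, None]).mean(axis=0) / (s_sd * y_sd)
    r[~np.isfinite(r)] = 0.0
    chosen = int(np.argmax(np.abs(r)))
    s = Sc[:, chosen]
    beta = float(s @ yc) / float(s @ s)
    residual = y - beta * s
    return residual, chosen
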