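"""Signal conditioning applied before segmentation and feature extraction.

Three operators, all zero-phase (forward-backward filtering) so that event
timing is preserved:

* :func:`comb_notch` — cascaded second-order IIR notches at the powerline
  fundamental and its harmonics, removing acquisition-electronics interference.
* :func:`denoise` — 4th-order Butterworth low-pass.  Fetal movement energy is
  concentrated below ~10 Hz, so the default 20 Hz corner keeps the whole
  physiological band while discarding wideband sensor noise.
* :func:`envelope` — moving average; of the rectified signal on the
  segmentation path, of the raw signal on the discrimination path (where
  rectification would destroy spectral information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError

__all__ = ["PreprocessConfig", "comb_notch", "envelope", "denoise", "condition"]


@dataclass(frozen=True)
class PreprocessConfig:
    mains_hz: float = 50.0
    n_harmonics: int = 0  # 0 = all harmonics up to Nyquist
    notch_q: float = 30.0
    env_window_s: float = 0.25
    denoise_cutoff_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.env_window_s <= 0:
            raise ConfigurationError("env_window_s must be > 0")
        if self.notch_q <= 0:
            raise ConfigurationError("notch_q must be > 0")
        if self.n_harmonics < 0:
            raise ConfigurationError("n_harmonics must be >= 0 (0 = up to Nyquist)")


def comb_notch(x: np.ndarray, fs: float, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Zero-phase comb of notches at ``mains_hz * k``; identity when mains_hz = 0."""
    x = np.asarray(x, dtype=float)
    if cfg.mains_hz == 0:
        return x.copy()
    if cfg.mains_hz >= fs / 2:
        raise ConfigurationError(
            f"mains_hz={cfg.mains_hz} must be below Nyquist ({fs / 2})"
        )
    max_k = int(np.floor((fs / 2 - 1e-9) / cfg.mains_hz))
    n_harm = max_k if cfg.n_harmonics == 0 else min(cfg.n_harmonics, max_k)
    y = x
    for k in range(1, n_harm + 1):
        b, a = sps.iirnotch(w0=cfg.mains_hz * k, Q=cfg.notch_q, fs=fs)
        y = sps.filtfilt(b, a, y)
    return y


def envelope(x: np.ndarray, fs: float, env_window_s: float, rectify: bool = True) -> np.ndarray:
    """Moving average over ``env_window_s`` of |x| (rectify) or x.

    Edges are handled by shrinking the window, so a constant input maps to a
    constant output of the same value.
    """
    if env_window_s <= 0:
        raise ConfigurationError("env_window_s must be > 0")
    x = np.asarray(x, dtype=float)
    w = max(1, int(round(env_window_s * fs)))
    if w < 1:
        raise ConfigurationError("envelope window shorter than one sample")
    v = np.abs(x) if rectify else x
    if v.size == 0:
        return v.copy()
    kernel = np.ones(w)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def denoise(x: np.ndarray, fs: float, denoise_cutoff_hz: float = 20.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass at ``denoise_cutoff_hz``."""
    if not 0 < denoise_cutoff_hz < fs / 2:
        raise ConfigurationError(
            f"denoise cutoff must satisfy 0 < cutoff < fs/2, got "
            f"{denoise_cutoff_hz} at fs={fs}"
        )
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    sos = sps.butter(4, denoise_cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def condition(x: np.ndarray, fs: float, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """comb_notch followed by denoise — the common front-end of both paths."""
    return denoise(comb_notch(x, fs, cfg), fs, cfg.denoise_cutoff_hz)
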