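"""Per-IMF scalar features for motor-imagery EEG epochs.

Six features are computed on every (channel, IMF) pair of an epoch:
signal energy, order-``p`` autoregressive coefficients (Burg), fuzzy
approximate entropy, peak-to-peak amplitude, skewness and excess
kurtosis.  They are concatenated channel-major / IMF-minor into one flat
vector per epoch, giving ``n_channels * K_imfs * (p + 5)`` scalars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import burg as _burg

from .emd import SiftConfig, decompose
from .io import Epoch

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyEntropyParams",
    "FeatureVector",
    "energy",
    "ar_coefficients",
    "fuzzy_approximate_entropy",
    "peak_to_peak",
    "skewness",
    "kurtosis",
    "build_feature_vector",
    "feature_table",
]

#: feature block layout per (channel, IMF): energy, a1..ap, FAP, p2p, skew, kurt
FEATURE_ORDER = ("energy", "ar", "fap", "p2p", "skew", "kurt")


@dataclass(frozen=True)
class FuzzyEntropyParams:
    """Fuzzy approximate entropy parameters.

    ``m`` is the embedding dimension, ``r`` the tolerance factor.  The
    effective tolerance applied inside the exponential similarity kernel
    is ``r * var(signal)``, matching the squared Chebyshev distance in the
    exponent.
    """

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance factor r must be > 0")


@dataclass
class FeatureVector:
    """Flat named feature vector for one epoch."""

    values: np.ndarray
    names: list[str]
    label: int
    flags: list[str]

    def __len__(self) -> int:
        return self.values.size


def energy(g: np.ndarray) -> float:
    """Total energy ``sum |g(n)|^2``."""
    g = np.asarray(g, dtype=float)
    if g.size < 1:
        raise ValueError("energy needs at least one sample")
    return float(np.sum(np.abs(g) ** 2))


def ar_coefficients(g: np.ndarray, p: int = 7) -> np.ndarray:
    """Order-``p`` autoregressive coefficients by the Burg method.

    Coefficients are signed so that the one-step prediction is
    ``g_hat(t) = sum_i a(i) * g(t - i)``; an AR(1) with generating
    coefficient 0.8 yields ``a[0]`` close to +0.8.  The default order 7 is
    the usual choice for motor-imagery EEG.
    """
    g = np.asarray(g, dtype=float)
    if g.size <= 3 * p:
        raise ValueError(f"need more than {3 * p} samples for AR({p})")
    if np.ptp(g) == 0.0:
        raise ValueError("AR fit is degenerate on a constant signal")
    coefs, _sigma2 = _burg(g, order=p, demean=True)
    return np.asarray(coefs, dtype=float)


def fuzzy_approximate_entropy(
    f: np.ndarray, params: FuzzyEntropyParams = FuzzyEntropyParams()
) -> float:
    """Fuzzy approximate entropy ``Phi^m - Phi^(m+1)``.

    Template vectors of length ``m`` are drawn from the signal and
    baseline-removed (each minus its own mean).  Pairwise similarity is
    ``exp(-d^2 / r_eff)`` with ``d`` the Chebyshev distance between
    templates and ``r_eff = r * var(f)``.  ``Phi^m`` averages the log of
    each template's mean similarity to all *other* templates; the entropy
    is the drop in ``Phi`` when the embedding grows by one.  Regular
    signals keep their similarity when extended (small entropy); irregular
    signals lose it (large entropy).

    A zero-variance signal returns 0 by convention (all templates
    identical at any ``m``).
    """
    f = np.asarray(f, dtype=float)
    m = params.m
    n = f.size
    if n <= m + 2:
        raise ValueError(f"need more than m+2={m + 2} samples, got {n}")
    var = float(np.var(f))
    if var == 0.0:
        logger.info("fuzzy_approximate_entropy: zero-variance signal, returning 0")
        return 0.0
    r_eff = params.r * var

    def phi(mm: int) -> float:
        templ = np.lib.stride_tricks.sliding_window_view(f, mm)
        templ = templ - templ.mean(axis=1, keepdims=True)
        n_templ = templ.shape[0]
        # Chebyshev distance between all template pairs
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=2)
        sim = np.exp(-(d**2) / r_eff)
        np.fill_diagonal(sim, 0.0)
        c = sim.sum(axis=1) / n_templ
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def peak_to_peak(f: np.ndarray) -> float:
    """``max(f) - min(f)``."""
    f = np.asarray(f, dtype=float)
    if f.size < 1:
        raise ValueError("peak_to_peak needs at least one sample")
    return float(np.ptp(f))


def skewness(f: np.ndarray) -> float:
    """Sample skewness ``sum (f - mean)^3 / (N * s^3)`` (population s)."""
    f = np.asarray(f, dtype=float)
    if f.size < 3:
        raise ValueError("skewness needs at least 3 samples")
    if np.std(f) == 0.0:
        raise ValueError("skewness is degenerate on a zero-variance signal")
    return float(stats.skew(f, bias=True))


def kurtosis(f: np.ndarray) -> float:
    """Excess kurtosis: 4th standardised moment minus 3."""
    f = np.asarray(f, dtype=float)
    if f.size < 4:
        raise ValueError("kurtosis needs at least 4 samples")
    if np.std(f) == 0.0:
        raise ValueError("kurtosis is degenerate on a zero-variance signal")
    return float(stats.kurtosis(f, fisher=True, bias=True))


def _imf_features(
    c: np.ndarray, p: int, fep: FuzzyEntropyParams, tag: str, flags: list[str]
) -> list[float]:
    """The six-feature block for one IMF; degenerate features become NaN."""
    out: list[float] = [energy(c)]
    try:
        out.extend(ar_coefficients(c, p).tolist())
    except ValueError as exc:
        logger.warning("%s: AR fit failed (%s); recording NaN", tag, exc)
        flags.append(f"{tag}_ar_nan")
        out.extend([np.nan] * p)
    out.append(fuzzy_approximate_entropy(c, fep))
    out.append(peak_to_peak(c))
    for fn, name in ((skewness, "skew"), (kurtosis, "kurt")):
        try:
            out.append(fn(c))
        except ValueError:
            flags.append(f"{tag}_{name}_nan")
            out.append(np.nan)
    return out


def build_feature_vector(
    epoch: Epoch,
    cfg: SiftConfig = SiftConfig(),
    K_imfs: int = 4,
    p: int = 7,
    fep: FuzzyEntropyParams = FuzzyEntropyParams(),
) -> FeatureVector:
    """Decompose each channel and concatenate per-IMF feature blocks.

    Layout is channel-major, IMF-minor; within a block the order is
    energy, a1..ap, FAP, peak-to-peak, skewness, kurtosis.  Channels that
    yield fewer than ``K_imfs`` IMFs contribute zero blocks for the
    missing ones (flag recorded), so the vector length is always
    ``n_channels * K_imfs * (p + 5)``.
    """
    if K_imfs < 1:
        raise ValueError("K_imfs must be >= 1")
    block = p + 5
    values: list[float] = []
    names: list[str] = []
    flags: list[str] = []
    for ch in range(epoch.data.shape[0]):
        imfset = decompose(epoch.data[ch], cfg)
        for k in range(K_imfs):
            tag = f"ch{ch}_imf{k}"
            if k < len(imfset.imfs):
                values.extend(_imf_features(imfset.imfs[k], p, fep, tag, flags))
            else:
                flags.append(f"{tag}_missing")
                values.extend([0.0] * block)
            names.append(f"{tag}_energy")
            names.extend(f"{tag}_ar{i}" for i in range(1, p + 1))
            names.extend(f"{tag}_{s}" for s in ("fap", "p2p", "skew", "kurt"))
    return FeatureVector(
        values=np.asarray(values, dtype=float),
        names=names,
        label=epoch.label,
        flags=flags,
    )


def feature_table(vectors: list[FeatureVector], subjects: list[int] | None = None) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame with label (and subject) columns.

    Write with ``df.to_csv(path, sep="\\t", index=False)`` for the TSV
    interchange format.
    """
    if not vectors:
        raise ValueError("no feature vectors given")
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]), columns=vectors[0].names
    )
    df["label"] = [v.label for v in vectors]
    if subjects is not None:
        df["subject"] = subjects
    return df
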