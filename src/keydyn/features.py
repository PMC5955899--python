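"""Per-session feature vectors from windowed keystroke-dynamics sequences.

Each variable sequence (HT, NFT, NP) of a session is split into 15 s
non-overlapping time windows (clock starting at the session's first press).
An element belongs to window i when its anchor interval lies inside
((i-1)T, iT): the lower edge is inclusive so the session's first keystroke,
which defines t = 0, belongs to window 1; the upper edge is strict. Windows
with fewer than five elements are omitted.

For the elements a_k of each valid window we compute

* mu      = sum_k a_k / n
* sigma   = sqrt( sum_k (a_k - mu)^2 / (n - 1) )
* S       = sum_k ((a_k - mu)/sigma)^3 / n          (skewness)
* K       = sum_k ((a_k - mu)/sigma)^4 / n          (raw, non-excess kurtosis)

and a Gaussian-kernel density estimate f^i(x) on a fixed 10-point grid with a
variable-specific bandwidth (HT 0.0060 s, NFT 0.0289 s, NP 0.0300 - external
reference constants). The sample covariance between window PDFs over the grid
points, C(i, j) = sum_X [f^i - mean f^i][f^j - mean f^j] / (L - 1), is
summarised over its strict upper triangle C_U.

The session feature vector aggregates the window statistics across windows:

    v = [mu_mean, mu_std, sigma_mean, sigma_std, skew_mean, skew_std,
         kurt_mean, kurt_std, cov_mean, cov_std, cov_abs_sum]

(11 components for HT and NP; NFT omits mu_mean/mu_std since the sequence is
zero-mean by construction, giving 9). Constant windows (sigma = 0) are
dropped because their standardized moments are undefined; single-window
sessions get zero across-window dispersions and zero covariance summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConstantWindowError, NoValidWindowsError
from .sequences import (
    FT_MAX_S,
    NFT_INTERVAL_S,
    VariableSequence,
    flight_times,
    hold_times,
    normalise_flight_times,
    pressures,
)
from .session_io import SubjectRecord, TypingSession, validate_session

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "WindowedSubsequence",
    "WindowStats",
    "FEATURE_NAMES",
    "ALL_FEATURE_NAMES",
    "VARIABLES",
    "window_subsequences",
    "moment_stats",
    "estimate_pdf",
    "pdf_covariance",
    "session_feature_vector",
    "extract_feature_table",
]

VARIABLES = ("HT", "NFT", "NP")

_BASE_NAMES = [
    "mu_mean",
    "mu_std",
    "sigma_mean",
    "sigma_std",
    "skew_mean",
    "skew_std",
    "kurt_mean",
    "kurt_std",
    "cov_mean",
    "cov_std",
    "cov_abs_sum",
]

#: Ordered feature names per variable (NFT omits the mean-related pair).
FEATURE_NAMES: dict[str, list[str]] = {
    "HT": list(_BASE_NAMES),
    "NFT": [n for n in _BASE_NAMES if n not in ("mu_mean", "mu_std")],
    "NP": list(_BASE_NAMES),
}
ALL_FEATURE_NAMES = list(_BASE_NAMES)


@dataclass
class FeatureConfig:
    """Windowing, moment and KDE settings (defaults per the study design)."""

    window_seconds: float = 15.0
    min_elements: int = 5
    levels: int = 10  # KDE quantization levels L
    bandwidths: dict[str, float] = field(
        default_factory=lambda: {"HT": 0.0060, "NFT": 0.0289, "NP": 0.0300}
    )
    grid_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "HT": (0.0, 1.0),
            "NFT": NFT_INTERVAL_S,
            "NP": (0.0, 1.0),
        }
    )
    ft_max: float = FT_MAX_S
    nft_interval: tuple[float, float] = NFT_INTERVAL_S

    def grid(self, variable: str) -> np.ndarray:
        lo, hi = self.grid_ranges[variable]
        return np.linspace(lo, hi, self.levels)


@dataclass
class WindowedSubsequence:
    """Elements of one variable falling inside one 15 s window."""

    index: int  # 1-based window index i
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WindowStats:
    mu: float
    sigma: float
    skew: float
    kurt: float


def window_subsequences(
    seq: VariableSequence, config: FeatureConfig | None = None
) -> list[WindowedSubsequence]:
    """Split a sequence into non-overlapping time windows.

    Elements whose anchor interval straddles a window boundary belong to
    neither window. Windows with fewer than ``config.min_elements`` elements
    are omitted; raises :class:`NoValidWindowsError` when none survive.
    """
    config = config or FeatureConfig()
    if len(seq) == 0:
        raise NoValidWindowsError(f"{seq.variable}: empty sequence")
    T = config.window_seconds
    n_windows = int(math.ceil((seq.ends.max() + 1e-12) / T))
    windows = []
    for i in range(1, n_windows + 1):
        mask = (seq.starts >= (i - 1) * T) & (seq.ends < i * T)
        if int(mask.sum()) >= config.min_elements:
            windows.append(WindowedSubsequence(i, seq.values[mask]))
    if not windows:
        raise NoValidWindowsError(
            f"{seq.variable}: no window with >= {config.min_elements} elements"
        )
    return windows


def moment_stats(window: WindowedSubsequence | np.ndarray) -> WindowStats:
    """First- to fourth-order statistics of a window.

    sigma is the (n-1)-denominator sample standard deviation; skewness and
    kurtosis average the third/fourth powers of (a_k - mu)/sigma with an n
    denominator (kurtosis is raw: 3 for a Gaussian). Raises
    :class:`ConstantWindowError` when sigma = 0.
    """
    a = window.values if isinstance(window, WindowedSubsequence) else np.asarray(window, float)
    n = a.size
    mu = a.sum() / n
    sigma = math.sqrt(((a - mu) ** 2).sum() / (n - 1))
    if sigma == 0.0 or np.ptp(a) == 0.0:
        raise ConstantWindowError("zero dispersion: skewness/kurtosis undefined")
    z = (a - mu) / sigma
    return WindowStats(mu, sigma, float((z**3).sum() / n), float((z**4).sum() / n))


def estimate_pdf(
    window: WindowedSubsequence | np.ndarray,
    variable: str,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Gaussian-kernel density estimate on the variable's fixed grid.

    f(x) = (1 / (n b)) * sum_k phi((x - a_k) / b) with the variable-specific
    bandwidth b, evaluated at L equispaced grid points shared by all windows
    of the variable (so between-window covariances are coherent).
    """
    config = config or FeatureConfig()
    a = window.values if isinstance(window, WindowedSubsequence) else np.asarray(window, float)
    b = config.bandwidths[variable]
    x = config.grid(variable)
    z = (x[:, None] - a[None, :]) / b
    return np.exp(-0.5 * z**2).sum(axis=1) / (a.size * b * math.sqrt(2.0 * math.pi))


def pdf_covariance(pdfs: list[np.ndarray] | np.ndarray) -> tuple[float, float, float]:
    """Summaries (mean, std, sum of |.|) of the between-window PDF covariance.

    C(i, j) is the sample covariance (over the L grid points) between the
    window PDFs; summaries are over the strict upper triangle C_U. With one
    window C_U is empty and all three summaries are 0; with a single entry
    the std is 0.
    """
    F = np.asarray(pdfs, dtype=float)
    if F.ndim != 2 or F.shape[0] == 0:
        raise NoValidWindowsError("PDF covariance needs at least one window PDF")
    W = F.shape[0]
    if W == 1:
        logger.debug("single window: covariance features set to 0")
        return 0.0, 0.0, 0.0
    C = np.cov(F, ddof=1)  # 1/(L-1) normalisation over grid points
    cu = C[np.triu_indices(W, k=1)]
    std = float(cu.std(ddof=1)) if cu.size > 1 else 0.0
    return float(cu.mean()), std, float(np.abs(cu).sum())


def _derive_sequence(session: TypingSession, variable: str, config: FeatureConfig):
    if variable == "HT":
        return hold_times(session)
    if variable == "NP":
        return pressures(session)
    if variable == "NFT":
        ft = flight_times(session)
        return normalise_flight_times(ft, config.ft_max, config.nft_interval)
    raise ValueError(f"unknown variable {variable!r}")


def session_feature_vector(
    session: TypingSession, variable: str, config: FeatureConfig | None = None
) -> pd.Series:
    """The session's aggregated feature vector for one variable.

    Aggregates each window moment's mean and std (ddof = 1; 0 when only one
    window survives) across windows and appends the three PDF-covariance
    summaries. Returns a named Series of length 11 (HT, NP) or 9 (NFT).
    """
    config = config or FeatureConfig()
    seq = _derive_sequence(session, variable, config)
    windows = window_subsequences(seq, config)

    stats: list[WindowStats] = []
    pdfs: list[np.ndarray] = []
    for w in windows:
        try:
            stats.append(moment_stats(w))
        except ConstantWindowError:
            logger.warning(
                "%s s%d %s window %d is constant; dropped",
                session.subject_id, session.session_index, variable, w.index,
            )
            continue
        pdfs.append(estimate_pdf(w, variable, config))
    if not stats:
        raise NoValidWindowsError(f"{variable}: all windows degenerate")

    def agg(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values)
        return float(arr.mean()), (float(arr.std(ddof=1)) if arr.size > 1 else 0.0)

    mu_m, mu_s = agg([s.mu for s in stats])
    si_m, si_s = agg([s.sigma for s in stats])
    sk_m, sk_s = agg([s.skew for s in stats])
    ku_m, ku_s = agg([s.kurt for s in stats])
    c_m, c_s, c_abs = pdf_covariance(np.asarray(pdfs))

    full = {
        "mu_mean": mu_m, "mu_std": mu_s,
        "sigma_mean": si_m, "sigma_std": si_s,
        "skew_mean": sk_m, "skew_std": sk_s,
        "kurt_mean": ku_m, "kurt_std": ku_s,
        "cov_mean": c_m, "cov_std": c_s, "cov_abs_sum": c_abs,
    }
    names = FEATURE_NAMES[variable]
    return pd.Series({k: full[k] for k in names}, name=(session.subject_id, session.session_index))


def extract_feature_table(
    subjects: list[SubjectRecord],
    config: FeatureConfig | None = None,
    enforce_typing_rate: bool = True,
) -> pd.DataFrame:
    """Long-format feature table over a cohort.

    One row per (session, variable) with columns ``subject_id``,
    ``session_index``, ``variable``, ``label`` and the 11 feature columns
    (NaN where a feature does not exist for the variable). Sessions failing
    the typing-rate bound are omitted; sessions whose NFT channel is empty
    after filtering simply contribute no NFT row (logged).
    """
    config = config or FeatureConfig()
    rows = []
    for subj in subjects:
        for sess in subj.sessions:
            if enforce_typing_rate and not validate_session(sess).passed:
                logger.info("%s s%d fails typing-rate bound; omitted",
                            subj.subject_id, sess.session_index)
                continue
            for variable in VARIABLES:
                try:
                    vec = session_feature_vector(sess, variable, config)
                except Exception as exc:  # channel missing for this session
                    logger.info("%s s%d %s skipped: %s",
                                subj.subject_id, sess.session_index, variable, exc)
                    continue
                row = {
                    "subject_id": subj.subject_id,
                    "session_index": sess.session_index,
                    "variable": variable,
                    "label": subj.label,
                }
                row.update({k: vec.get(k, np.nan) for k in ALL_FEATURE_NAMES})
                rows.append(row)
    return pd.DataFrame(rows)
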