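"""Two-color intensity processing: M/A computation and normalization.

Each hybridization compares two samples on one array (Cy5 vs Cy3).  Signals
are summarised per probe as M = log2(cy5/cy3) and A = (log2 cy5 +
log2 cy3)/2; dye-swap replicates are negated so that positive M uniformly
means "more methylated in group A".  Intra-array loess regression of M on A
removes intensity-dependent dye bias; quantile normalization across arrays
then equalises the marginal M distributions before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
import statsmodels.api as sm

__all__ = [
    "NormalizationError",
    "Hybridization",
    "compute_ma",
    "build_ma_matrices",
    "loess_normalize",
    "quantile_normalize",
    "scale_normalize",
]


class NormalizationError(ValueError):
    pass


@dataclass
class Hybridization:
    """One two-color array: channel intensities plus sample/dye layout.

    ``dye_swap`` False means group-A sample in Cy5; True means the labels
    were reversed, in which case M is negated at computation time.
    """

    array_id: str
    sample_a: str
    sample_b: str
    dye_swap: bool
    probe_ids: list[str] = field(default_factory=list)
    cy3: np.ndarray = field(default_factory=lambda: np.array([]))
    cy5: np.ndarray = field(default_factory=lambda: np.array([]))


def compute_ma(
    cy3: np.ndarray, cy5: np.ndarray, dye_swap: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe M and A from the two channels.

    M = log2(cy5/cy3), negated on dye-swapped arrays so orientation is
    uniform across the hybridization set; A = (log2 cy5 + log2 cy3)/2.
    Nonpositive intensities are a policy error here — callers are expected
    to flag and drop such probes first (see :func:`build_ma_matrices`).
    """
    cy3 = np.asarray(cy3, dtype=float)
    cy5 = np.asarray(cy5, dtype=float)
    if np.any(cy3 <= 0) or np.any(cy5 <= 0):
        raise NormalizationError(
            "nonpositive intensity encountered; drop or flag these probes "
            "before computing M/A"
        )
    log3, log5 = np.log2(cy3), np.log2(cy5)
    m = log5 - log3
    if dye_swap:
        m = -m
    a = 0.5 * (log5 + log3)
    return m, a


def build_ma_matrices(
    intensities: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    """Long intensity table + array manifest → wide M and A matrices.

    ``intensities`` columns: probe_id, array_id, cy3, cy5 (one row per probe
    per array).  ``manifest`` columns: array_id, sample_a, sample_b,
    dye_swap.  Probes with a nonpositive intensity in either channel on any
    array are excluded from both matrices; their ids are returned so the
    exclusion can be reported.
    """
    for col in ("probe_id", "array_id", "cy3", "cy5"):
        if col not in intensities.columns:
            raise NormalizationError(f"intensity table missing column {col!r}")
    for col in ("array_id", "dye_swap"):
        if col not in manifest.columns:
            raise NormalizationError(f"manifest missing column {col!r}")
    cy3 = intensities.pivot(index="probe_id", columns="array_id", values="cy3")
    cy5 = intensities.pivot(index="probe_id", columns="array_id", values="cy5")
    arrays = [str(a) for a in manifest["array_id"]]
    missing = set(arrays) - set(map(str, cy3.columns))
    if missing:
        raise NormalizationError(f"manifest arrays absent from intensities: {sorted(missing)}")
    cy3 = cy3[arrays]
    cy5 = cy5[arrays]
    ok = (
        cy3.notna().all(axis=1)
        & cy5.notna().all(axis=1)
        & (cy3 > 0).all(axis=1)
        & (cy5 > 0).all(axis=1)
    )
    dropped = cy3.index[~ok]
    cy3, cy5 = cy3.loc[ok], cy5.loc[ok]
    swap = dict(zip(arrays, manifest["dye_swap"].astype(bool)))
    m_cols, a_cols = {}, {}
    for arr in arrays:
        m, a = compute_ma(cy3[arr].to_numpy(), cy5[arr].to_numpy(), swap[arr])
        m_cols[arr], a_cols[arr] = m, a
    M = pd.DataFrame(m_cols, index=cy3.index)
    A = pd.DataFrame(a_cols, index=cy3.index)
    return M, A, dropped


def loess_normalize(
    M: pd.DataFrame | np.ndarray,
    A: pd.DataFrame | np.ndarray,
    span: float = 0.3,
    iterations: int = 3,
) -> pd.DataFrame | np.ndarray:
    """Remove the intensity-dependent trend: per array, M − loess_fit(M ~ A).

    ``span`` is the loess bandwidth as a fraction of the data (must lie in
    (0, 1]); ``iterations`` robustness reweightings protect the fit from the
    minority of genuinely differential probes.  Requires at least 50 probes
    per array for the local fit to be meaningful.
    """
    if not 0 < span <= 1:
        raise NormalizationError(f"loess span must be in (0, 1], got {span}")
    m_arr = np.asarray(M, dtype=float)
    a_arr = np.asarray(A, dtype=float)
    squeeze = False
    if m_arr.ndim == 1:
        m_arr = m_arr[:, None]
        a_arr = a_arr[:, None]
        squeeze = True
    if m_arr.shape[0] < 50:
        raise NormalizationError(
            f"need at least 50 probes per array for loess, got {m_arr.shape[0]}"
        )
    out = np.empty_like(m_arr)
    for j in range(m_arr.shape[1]):
        a = a_arr[:, j]
        # delta trades exactness for speed on dense A grids; 1% of the range
        # is far below the loess bandwidth.
        delta = 0.01 * (a.max() - a.min())
        fitted = sm.nonparametric.lowess(
            m_arr[:, j], a, frac=span, it=iterations, delta=delta,
            return_sorted=False,
        )
        out[:, j] = m_arr[:, j] - fitted
    if squeeze:
        out = out[:, 0]
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(out, index=M.index, columns=M.columns)
    return out


def quantile_normalize(M: pd.DataFrame) -> pd.DataFrame:
    """Force every array's M distribution onto the rank-wise mean distribution.

    After the transform each column's sorted vector is identical; ranks
    within a column are preserved and ties receive the mean of the reference
    values they span.  Applying the transform twice equals applying it once.
    Requires a complete matrix (drop incomplete probes first) and at least
    two arrays.
    """
    if M.shape[1] < 2:
        raise NormalizationError("quantile normalization needs at least 2 arrays")
    values = M.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise NormalizationError(
            "missing values in M matrix; exclude incomplete probes before "
            "quantile normalization"
        )
    reference = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def scale_normalize(M: pd.DataFrame) -> pd.DataFrame:
    """Alternative inter-array step: equalise per-array median absolute deviation.

    Kept as a configurable variant of the inter-array normalization; the
    default pipeline uses :func:`quantile_normalize`.
    """
    values = M.to_numpy(dtype=float)
    mads = np.median(np.abs(values - np.median(values, axis=0)), axis=0)
    if np.any(mads == 0):
        raise NormalizationError("zero MAD on at least one array")
    target = np.exp(np.mean(np.log(mads)))
    return pd.DataFrame(
        values * (target / mads), index=M.index, columns=M.columns
    )
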