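"""Circadian transcript-rhythm statistics.

Pipeline for diurnal expression series sampled at few, unevenly spaced
circadian time points:

1. per-gene oscillation strength as the power spectral density at the
   1/24 h frequency (``pd``), a direct discrete Fourier projection that is
   valid for uneven designs (it coincides with an unnormalized single
   frequency Lomb-Scargle statistic for centered data);
2. permutation p-values by shuffling values over sampling times;
3. the Least-Oscillating Set (LOS) — genes with the weakest evidence of
   oscillation — as a rhythm-free reference set;
4. LOS-anchored Loess normalization of array-level technical trends;
5. phase estimation from the argument of the Fourier projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RhythmResult",
    "NormalizationModel",
    "pd_statistic",
    "permutation_p",
    "select_los",
    "loess_normalize",
    "estimate_phase",
    "rhythm_analysis",
    "read_expression_tsv",
]

_PERIOD = 24.0


@dataclass
class ExpressionMatrix:
    """Genes x arrays log-intensity matrix with circadian sampling times."""

    values: pd.DataFrame                 # genes x arrays
    sample_times: np.ndarray             # CT h per array, in [0, 24)
    replicates: np.ndarray | None = None  # replicate id per array

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float) % _PERIOD
        if len(self.sample_times) != self.values.shape[1]:
            raise ValueError("one sampling time per array required")
        if self.values.isna().any().any():
            raise ValueError("missing values must be imputed or dropped "
                             "before analysis")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.sample_times.copy(),
            None if self.replicates is None else self.replicates.copy(),
        )


@dataclass
class NormalizationModel:
    """Per-array correction curves over the LOS-mean-intensity axis."""

    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # array -> (x grid, corr)
    span: float


def _fourier_projection(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Complex projection of mean-centered values onto exp(-2 pi i t / 24)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    times = np.asarray(times, dtype=float)
    if times.size < 4:
        raise ValueError("at least 4 samples required")
    if np.allclose(times, times[0]):
        raise ValueError("degenerate design: all sampling times equal")
    centered = values - values.mean(axis=1, keepdims=True)
    basis = np.exp(-2j * np.pi * times / _PERIOD)
    return centered @ basis


def pd_statistic(values, times) -> float | np.ndarray:
    """Power spectral density at the 1/day frequency.

    ``pd = |sum_k x_k exp(-2 pi i t_k / 24)|^2 / n`` on mean-centered
    values; replicates enter as separate samples at their own times.
    Accepts a vector (one gene) or a genes x arrays matrix.
    """
    proj = _fourier_projection(values, np.asarray(times))
    out = (np.abs(proj) ** 2) / np.asarray(times).size
    return float(out[0]) if np.ndim(values) == 1 else out


def _ls_phase(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Phase of the least-squares cosine fit at the 1/24 h frequency.

    For uneven designs the sine and cosine basis vectors are not
    orthogonal, so the raw Fourier argument is biased by spectral leakage;
    solving the 2x2 normal equations removes that bias (this is the phase
    of a single-frequency Lomb-Scargle style fit).  Reduces to the plain
    projection argument for evenly spaced samples.
    """
    w = 2 * np.pi / _PERIOD
    c, s = np.cos(w * times), np.sin(w * times)
    c = c - c.mean()
    s = s - s.mean()
    centered = values - values.mean(axis=1, keepdims=True)
    gram = np.array([[c @ c, c @ s], [c @ s, s @ s]])
    rhs = np.stack([centered @ c, centered @ s])
    a, b = np.linalg.solve(gram, rhs)
    # x ~ a cos(wt) + b sin(wt) = A cos(w(t - phi)) with w phi = atan2(b, a)
    return (_PERIOD / (2 * np.pi)) * np.arctan2(b, a) % _PERIOD


def estimate_phase(values, times) -> float | np.ndarray:
    """Circadian time (h, in [0, 24)) of the fitted cosine's peak."""
    times = np.asarray(times, dtype=float)
    proj = _fourier_projection(values, times)
    power = (np.abs(proj) ** 2) / times.size
    if np.any(power <= 0):
        raise ValueError("phase undefined: profile has zero 1/day power")
    phase = _ls_phase(np.atleast_2d(np.asarray(values, dtype=float)), times)
    return float(phase[0]) if np.ndim(values) == 1 else phase


def permutation_p(values, times, n_perm: int = 100_000,
                  seed: int | np.random.Generator = 0) -> float:
    """Permutation tail probability of the observed pd statistic.

    ``p = (1 + #{shuffles with pd >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    observed = pd_statistic(values, times)
    perms = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    null = pd_statistic(perms, times)
    return float((1 + np.sum(null >= observed)) / (n_perm + 1))


def _all_p_values(matrix: ExpressionMatrix, n_perm: int, seed,
                  chunk: int = 256) -> np.ndarray:
    """Vectorized per-gene permutation p-values (one shared null size)."""
    rng = np.random.default_rng(seed)
    x = matrix.values.to_numpy(dtype=float)
    times = matrix.sample_times
    observed = pd_statistic(x, times)
    p = np.empty(x.shape[0])
    for start in range(0, x.shape[0], chunk):
        block = x[start:start + chunk]
        reps = np.repeat(block, n_perm, axis=0)
        null = pd_statistic(rng.permuted(reps, axis=1), times)
        null = null.reshape(block.shape[0], n_perm)
        p[start:start + chunk] = (
            1 + np.sum(null >= observed[start:start + chunk, None], axis=1)
        ) / (n_perm + 1)
    return p


def select_los(matrix: ExpressionMatrix, p_threshold: float,
               n_perm: int = 1000, seed: int = 0,
               p_values: np.ndarray | None = None) -> set[str]:
    """Least-Oscillating Set: genes whose permutation p exceeds the
    threshold (the weakest evidence of diurnal oscillation), computed on
    the raw, pre-normalization matrix."""
    if p_values is None:
        p_values = _all_p_values(matrix, n_perm, seed)
    los = {g for g, p in zip(matrix.genes, p_values) if p > p_threshold}
    if not los:
        raise ValueError(
            "empty Least-Oscillating Set: lower the p threshold "
            "(normalization is undefined without reference genes)"
        )
    return los


def loess_normalize(matrix: ExpressionMatrix, los: set[str],
                    span: float = 0.75):
    """LOS-anchored Loess normalization.

    Per array, a lowess curve of that array's LOS intensities against the
    LOS genes' cross-array mean intensities estimates the array's technical
    deviation as a smooth function of expression level; the curve (linearly
    interpolated over the mean-intensity axis) is then subtracted from
    every gene on that array.  Returns ``(normalized matrix, model)``.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if not los:
        raise ValueError("LOS is empty")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    los_idx = [g for g in matrix.genes if g in los]
    if len(los_idx) < max(5, int(2 / span)):
        raise ValueError("LOS smaller than the minimum local window")

    values = matrix.values
    los_vals = values.loc[los_idx]
    anchor = los_vals.mean(axis=1).to_numpy()          # LOS cross-array means
    gene_anchor = values.mean(axis=1).to_numpy()       # per-gene coordinate

    # deterministic jitter breaks exact ties in the anchor variable
    rank = np.argsort(np.argsort(anchor))
    anchor_j = anchor + 1e-9 * rank

    corrected = values.to_numpy(dtype=float).copy()
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, arr in enumerate(values.columns):
        dev = los_vals.iloc[:, j].to_numpy() - anchor
        fit = lowess(dev, anchor_j, frac=span, return_sorted=True)
        gx, gy = fit[:, 0], fit[:, 1]
        correction = np.interp(gene_anchor, gx, gy)
        corrected[:, j] -= correction
        curves[arr] = (gx, gy)

    out = matrix.copy()
    out.values = pd.DataFrame(corrected, index=values.index,
                              columns=values.columns)
    return out, NormalizationModel(curves=curves, span=span)


@dataclass
class RhythmResult:
    """Per-gene rhythm statistics."""

    table: pd.DataFrame  # columns: pd, p_value, phase, in_los
    los: set[str] = field(default_factory=set)

    def __getitem__(self, gene: str) -> pd.Series:
        return self.table.loc[gene]


def rhythm_analysis(matrix: ExpressionMatrix, n_perm: int = 1000,
                    los_threshold: float = 0.5, seed: int = 0,
                    span: float = 0.75, normalize: bool = True):
    """Full pipeline: pd and permutation p on the raw matrix, LOS
    selection, Loess normalization, then final statistics on the
    normalized matrix.  Returns ``(RhythmResult, normalized matrix)``.
    """
    raw_p = _all_p_values(matrix, n_perm, seed)
    los = select_los(matrix, los_threshold, p_values=raw_p)
    norm = matrix
    if normalize:
        norm, _ = loess_normalize(matrix, los, span=span)
        p = _all_p_values(norm, n_perm, seed + 1)
    else:
        p = raw_p
    x = norm.values.to_numpy(dtype=float)
    power = pd_statistic(x, norm.sample_times)
    phase = _ls_phase(x, norm.sample_times)
    phase = np.where(power > 0, phase, np.nan)
    table = pd.DataFrame(
        {"pd": power, "p_value": p, "phase": phase,
         "in_los": [g in los for g in norm.genes]},
        index=norm.genes,
    )
    return RhythmResult(table=table, los=los), norm


def read_expression_tsv(expr_path: str, times_path: str) -> ExpressionMatrix:
    """Load a genes x arrays TSV plus a companion array-to-time table.

    The times table needs columns ``array``, ``time`` and optionally
    ``replicate``.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(times_path, sep="\t")
    meta = meta.set_index("array").reindex(values.columns)
    if meta["time"].isna().any():
        missing = meta.index[meta["time"].isna()].tolist()
        raise ValueError(f"no sampling time for arrays: {missing}")
    reps = meta["replicate"].to_numpy() if "replicate" in meta else None
    return ExpressionMatrix(values=values,
                            sample_times=meta["time"].to_numpy(float),
                            replicates=reps)
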