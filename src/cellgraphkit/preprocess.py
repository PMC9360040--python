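"""Cell filtering, count normalisation and feature selection.

Normalisation comes in two flavours matching the two assay types:

* library-size scaling for scRNA-seq, ``y_fc = S * x_fc / sum_f' x_f'c``
  with optional ``ln(1 + y)`` transform;
* TF-IDF for scATAC-seq peak counts,
  ``y_fc = (x_fc / n_Fc) * ln(1 + N_C / n_Cf)``, where ``n_Fc`` is the
  number of accessible peaks in cell *c*, ``n_Cf`` the number of cells in
  which peak *f* is accessible, and ``N_C`` the total cell count.

Feature selection is trend-corrected highly-variable-gene (HVG) picking for
RNA (lowess fit of log-variance on log-mean over per-bin representative
genes; HVGs ranked by observed minus expected variance) and prevalence
scores (TF-IDF column sums) for ATAC peaks.

All operations are chunk-aware: global statistics are accumulated in one
streaming pass and per-block transforms use only those global statistics,
so results are independent of the chunking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .store import AssayStore, iter_chunks

__all__ = [
    "NormalizationParams",
    "TfidfStats",
    "HvgSelection",
    "auto_filter_cells",
    "normalize_library_size",
    "compute_tfidf_stats",
    "normalize_tfidf",
    "mean_var_stream",
    "select_hvgs",
    "peak_prevalence",
    "select_top_peaks",
    "DEFAULT_DISQUALIFY_PREFIXES",
]

# Minimal default disqualification list: mitochondrial, ribosomal and a
# short cell-cycle panel.  These gene families track technical covariates
# (stress, capture efficiency, cycle phase) more than cell identity, so
# they are excluded from HVG selection unless the caller overrides.
DEFAULT_DISQUALIFY_PREFIXES = (
    "MT-",
    "RPS",
    "RPL",
    "MRPS",
    "MRPL",
    "CCNB1",
    "CCNB2",
    "CDC20",
    "CDK1",
    "MKI67",
    "TOP2A",
    "UBE2C",
)


@dataclass
class NormalizationParams:
    """Library-size scaling factor ``S`` (> 0) and optional log1p."""

    S: float = 1000.0
    log_transform: bool = False

    def __post_init__(self):
        if self.S <= 0:
            raise ValueError(f"scaling factor S must be positive, got {self.S}")


@dataclass
class TfidfStats:
    """Global TF-IDF statistics, computed once over the whole matrix."""

    n_Fc: np.ndarray  # per-cell count of non-zero features
    n_Cf: np.ndarray  # per-feature count of non-zero cells
    N_C: int


@dataclass
class HvgSelection:
    mean: np.ndarray
    variance: np.ndarray
    expected_variance: np.ndarray
    corrected_variance: np.ndarray
    selected_mask: np.ndarray


def auto_filter_cells(values, x: float = 0.01):
    """Two-sided normal-quantile filter on a per-cell attribute.

    Fits N(mean, sd) by maximum likelihood to ``values`` and marks cells
    below quantile ``x`` or above quantile ``1 - x`` as False.  ``x = 0``
    keeps everything; zero variance keeps everything with a warning.
    """
    values = np.asarray(values, dtype=float)
    if not (0 <= x < 0.5):
        raise ValueError(f"tail probability x must lie in [0, 0.5), got {x}")
    finite = values[np.isfinite(values)]
    if finite.size < 3:
        raise ValueError("need at least 3 finite values to fit a normal")
    mu, sd = finite.mean(), finite.std()
    if sd == 0:
        warnings.warn("zero variance in cell attribute; keeping all cells")
        return np.ones(values.shape[0], dtype=bool)
    if x == 0:
        return np.ones(values.shape[0], dtype=bool)
    lo = stats.norm.ppf(x, loc=mu, scale=sd)
    hi = stats.norm.ppf(1 - x, loc=mu, scale=sd)
    return (values >= lo) & (values <= hi)


def normalize_library_size(
    block: np.ndarray,
    params: NormalizationParams | None = None,
    cell_ids=None,
) -> np.ndarray:
    """Scale each cell (row) to total S; optionally ln(1 + y)."""
    if params is None:
        params = NormalizationParams()
    block = np.asarray(block, dtype=float)
    sums = block.sum(axis=1)
    bad = np.flatnonzero(sums == 0)
    if bad.size:
        name = cell_ids[bad[0]] if cell_ids is not None else f"row {bad[0]}"
        raise ValueError(f"cell {name} has zero total count; cannot normalize")
    out = params.S * block / sums[:, None]
    if params.log_transform:
        out = np.log1p(out)
    return out


def compute_tfidf_stats(store: AssayStore) -> TfidfStats:
    """One streaming pass accumulating global TF-IDF statistics."""
    n_Cf = np.zeros(store.n_features, dtype=np.int64)
    n_Fc_parts = []
    for blk in iter_chunks(store):
        nz = blk > 0
        n_Cf += nz.sum(axis=0)
        n_Fc_parts.append(nz.sum(axis=1))
    return TfidfStats(
        n_Fc=np.concatenate(n_Fc_parts), n_Cf=n_Cf, N_C=store.n_cells
    )


def normalize_tfidf(
    block: np.ndarray,
    stats_: TfidfStats,
    row_offset: int = 0,
    cell_ids=None,
) -> np.ndarray:
    """TF-IDF-transform a block using *global* statistics.

    ``row_offset`` locates the block inside the full matrix so per-cell
    ``n_Fc`` values line up.  Zeros stay zero; a cell with no accessible
    peaks is an error (its term frequency is undefined).
    """
    block = np.asarray(block, dtype=float)
    n_fc = stats_.n_Fc[row_offset : row_offset + block.shape[0]]
    bad = np.flatnonzero(n_fc == 0)
    if bad.size:
        i = row_offset + bad[0]
        name = cell_ids[i] if cell_ids is not None else f"row {i}"
        raise ValueError(f"cell {name} has no non-zero features; TF undefined")
    idf = np.zeros(block.shape[1])
    hit = stats_.n_Cf > 0
    idf[hit] = np.log(1.0 + stats_.N_C / stats_.n_Cf[hit])
    return (block / n_fc[:, None]) * idf[None, :]


def mean_var_stream(store: AssayStore, params: NormalizationParams | None = None):
    """Per-gene mean and variance of normalized values, streamed.

    Uses sum / sum-of-squares accumulation; variance is the population
    variance (ddof 0), matching a single full-matrix computation to
    rounding error regardless of chunking.
    """
    if params is None:
        params = NormalizationParams()
    n = store.n_cells
    s1 = np.zeros(store.n_features)
    s2 = np.zeros(store.n_features)
    for i, blk in enumerate(
        iter_chunks(store)
    ):
        norm = normalize_library_size(blk, params)
        s1 += norm.sum(axis=0)
        s2 += (norm**2).sum(axis=0)
    mean = s1 / n
    var = np.maximum(s2 / n - mean**2, 0.0)
    return mean, var


def _trend_expected_variance(
    log_mean, log_var, eligible, n_bins, bin_pick, lowess_frac, lowess_it
):
    """Fit the mean-variance trend on per-bin representative genes.

    Genes are split into equal-count bins on log-mean; from each bin one
    representative is taken (lowest log-variance by default, lowest
    log-mean under the literal reading) and a lowess curve through the
    representatives predicts expected log-variance by linear interpolation.
    """
    idx = np.flatnonzero(eligible)
    order = idx[np.argsort(log_mean[idx], kind="stable")]
    bins = np.array_split(order, n_bins)
    rep_x, rep_y = [], []
    for b in bins:
        if b.size == 0:
            continue
        if bin_pick == "lowest_variance":
            rep = b[np.argmin(log_var[b])]
        elif bin_pick == "lowest_mean":
            rep = b[np.argmin(log_mean[b])]
        else:
            raise ValueError(f"unknown bin_pick {bin_pick!r}")
        rep_x.append(log_mean[rep])
        rep_y.append(log_var[rep])
    rep_x = np.asarray(rep_x)
    rep_y = np.asarray(rep_y)
    if rep_x.size == 1:
        return np.full(log_mean.shape, rep_y[0])
    with np.errstate(invalid="ignore"):
        fitted = lowess(
            rep_y, rep_x, frac=lowess_frac, it=lowess_it, return_sorted=True
        )
    # np.interp needs strictly usable x; collapse duplicate support points
    xs, keep = np.unique(fitted[:, 0], return_index=True)
    ys = fitted[keep, 1]
    if not np.isfinite(ys).all():  # degenerate support (e.g. all-equal means)
        return np.full(log_mean.shape, float(np.mean(rep_y)))
    return np.interp(log_mean, xs, ys)


def select_hvgs(
    means,
    variances,
    n_bins: int = 20,
    n_top: int = 2500,
    min_mean=None,
    max_mean=None,
    min_var=None,
    feature_ids=None,
    disqualify_prefixes=DEFAULT_DISQUALIFY_PREFIXES,
    bin_pick: str = "lowest_variance",
    lowess_frac: float = 0.4,
    lowess_it: int = 3,
) -> HvgSelection:
    """Trend-corrected highly-variable-gene selection.

    Mean and variance (of normalized values) are log-transformed; the
    fitted trend's prediction is subtracted from the observed log-variance
    and the top ``n_top`` genes by this corrected variance are selected,
    subject to optional mean/variance constraints.  Genes whose ids match
    ``disqualify_prefixes`` (case-insensitive prefixes) are never selected.
    Ties and ranking use stable feature order.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    expressed = means > 0
    log_mean = np.full(means.shape, -np.inf)
    log_var = np.full(means.shape, -np.inf)
    log_mean[expressed] = np.log(means[expressed])
    pos_var = variances > 0
    log_var[expressed & pos_var] = np.log(variances[expressed & pos_var])
    log_var[expressed & ~pos_var] = np.log(np.finfo(float).tiny)

    eligible = expressed.copy()
    if feature_ids is not None and disqualify_prefixes:
        ids_up = np.char.upper(np.asarray(feature_ids, dtype=str))
        banned = np.zeros(means.shape, dtype=bool)
        for p in disqualify_prefixes:
            banned |= np.char.startswith(ids_up, p.upper())
        eligible &= ~banned

    expected = np.full(means.shape, np.nan)
    corrected = np.full(means.shape, -np.inf)
    if eligible.any():
        exp_on = _trend_expected_variance(
            log_mean, log_var, eligible, n_bins, bin_pick, lowess_frac, lowess_it
        )
        expected[eligible] = exp_on[eligible]
        corrected[eligible] = log_var[eligible] - exp_on[eligible]

    ok = eligible.copy()
    if min_mean is not None:
        ok &= means >= min_mean
    if max_mean is not None:
        ok &= means <= max_mean
    if min_var is not None:
        ok &= corrected >= min_var

    n_ok = int(ok.sum())
    if n_top > n_ok:
        warnings.warn(
            f"requested {n_top} HVGs but only {n_ok} genes are eligible; "
            "selecting all eligible genes"
        )
        n_top = n_ok
    mask = np.zeros(means.shape, dtype=bool)
    if n_top:
        cand = np.flatnonzero(ok)
        # descending corrected variance, stable on ties
        order = cand[np.argsort(-corrected[cand], kind="stable")]
        mask[order[:n_top]] = True
    return HvgSelection(
        mean=means,
        variance=variances,
        expected_variance=expected,
        corrected_variance=corrected,
        selected_mask=mask,
    )


def peak_prevalence(store: AssayStore, stats_: TfidfStats | None = None) -> np.ndarray:
    """Per-peak prevalence: column sums of the TF-IDF-normalized matrix."""
    if stats_ is None:
        stats_ = compute_tfidf_stats(store)
    prev = np.zeros(store.n_features)
    offset = 0
    for blk in iter_chunks(store):
        prev += normalize_tfidf(blk, stats_, row_offset=offset).sum(axis=0)
        offset += blk.shape[0]
    return prev


def select_top_peaks(scores, n: int) -> np.ndarray:
    """Boolean mask of the n highest-prevalence peaks (stable on ties)."""
    scores = np.asarray(scores, dtype=float)
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    n = min(n, scores.size)
    order = np.argsort(-scores, kind="stable")
    mask = np.zeros(scores.size, dtype=bool)
    mask[order[:n]] = True
    return mask
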