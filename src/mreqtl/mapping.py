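"""Mass simple-linear-regression eQTL mapping with genome-scale BH-FDR.

Every SNP-feature pair is fit by ordinary least squares of expression on
allele dosage (0/1/2).  The t statistic is computed from the Pearson
correlation r as t = r * sqrt((n-2) / (1 - r^2)) with a two-sided p-value
from Student's t on n-2 degrees of freedom, and the Benjamini-Hochberg
step-up procedure is applied across ALL m = n_snp * n_feature tests.

At genome scale (m ~ 4e8) the full p-value vector is never materialised:
correlations are computed in SNP chunks with one BLAS product per chunk,
pairs with p <= ``p_store_threshold`` are kept exactly, and the remaining
p-values enter a fixed log-spaced histogram over (p_store_threshold, 0.1]
that establishes exact global rank bounds.  Because a pair with p > q can
never satisfy the step-up condition p_(i) <= i*q/m (i <= m implies
m*p/i >= p), the histogram suffices to (a) certify at run time that no
unstored pair can be detected and (b) bound the tail term of the adjusted
values.  Detection flags are therefore exactly those of textbook BH on the
dense p-value vector; adjusted values are exact for every detected pair and
for any stored pair at or below the detection boundary (see docs/methods.md
for the semantics of adjusted values above it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_TINY_P = np.nextafter(0.0, 1.0)  # smallest positive subnormal double

#: largest p-value the rank histogram covers; BH at q <= this is exact
_HIST_P_MAX = 0.1


@dataclass(frozen=True)
class MapperConfig:
    """Settings for :func:`map_eqtls`.

    ``p_store_threshold`` caps which associations are returned as records;
    it is validated at run time against the BH detection boundary so that
    every detectable pair is stored.  ``dense_limit`` is the number of pairs
    up to which the full p-value vector is kept (making adjusted values
    textbook-exact everywhere); above it the histogram scheme is used.
    """

    fdr_threshold: float = 0.01
    p_store_threshold: float = 1e-4
    chunk_size: int = 1024
    n_hist_bins: int = 10_000
    dense_limit: int = 4_000_000
    screen_dtype: str = "float64"  # "float32" halves the correlation-screen cost

    def __post_init__(self):
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not (0 < self.p_store_threshold <= 1):
            raise ValueError("p_store_threshold must be in (0, 1]")
        if self.chunk_size < 1 or self.n_hist_bins < 10:
            raise ValueError("chunk_size >= 1 and n_hist_bins >= 10 required")
        if self.screen_dtype not in ("float32", "float64"):
            raise ValueError("screen_dtype must be 'float32' or 'float64'")


def bh_adjust(p: np.ndarray, m: Optional[int] = None) -> np.ndarray:
    """Textbook Benjamini-Hochberg adjusted values.

    ``m`` is the total number of hypotheses; it may exceed ``len(p)`` when
    the unsupplied p-values are all known to be larger than ``max(p)`` (their
    m*p/rank terms then cannot lower the running minimum below ``max(p)``,
    which is accounted for by capping at 1).  adjusted_(i) = min_{j>=i}
    (m * p_(j) / j), capped at 1, returned in the original order.
    """
    p = np.asarray(p, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be >= the number of supplied p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


@dataclass
class MapResult:
    """Output of :func:`map_eqtls`.

    ``records`` holds one row per stored pair (p <= p_store_threshold),
    sorted by (p, snp index, feature index): columns snp_id, feature_id,
    beta, t, p, fdr, detected.  ``m`` is the total number of tests.
    """

    records: pd.DataFrame
    m: int
    n_snp: int
    n_feature: int
    n_sample: int
    config: MapperConfig
    _p_sorted: np.ndarray
    _keys_sorted: np.ndarray  # flat pair keys aligned with _p_sorted
    _hist_counts: Optional[np.ndarray]
    _hist_p_lo: Optional[np.ndarray]

    @property
    def n_detected(self) -> int:
        return int(self.records["detected"].sum())

    def _validate_store_threshold(self, q: float) -> None:
        """Certify that no unstored pair can pass BH step-up at level q."""
        cfg = self.config
        if self._hist_counts is None:
            return  # everything stored
        if q > _HIST_P_MAX:
            raise ValueError(
                f"fdr level {q} exceeds the rank histogram range {_HIST_P_MAX}"
            )
        s = len(self._p_sorted)
        cum_hi = s + np.cumsum(self._hist_counts)
        occupied = self._hist_counts > 0
        # an unstored pair in a bin has p > p_lo and rank <= cum_hi
        if np.any(occupied & (self._hist_p_lo * self.m <= cum_hi * q)):
            raise ValueError(
                "p_store_threshold too small: an unstored p-value could reach "
                "the BH detection boundary; increase p_store_threshold"
            )

    def detection_cutoff(self, q: Optional[float] = None) -> int:
        """Number of detections under BH step-up at level q (strict <)."""
        q = self.config.fdr_threshold if q is None else q
        self._validate_store_threshold(q)
        s = len(self._p_sorted)
        if s == 0:
            return 0
        qual = np.nonzero(self._p_sorted * self.m < np.arange(1, s + 1) * q)[0]
        if len(qual) == 0:
            return 0
        p_cut = self._p_sorted[qual[-1]]
        # every pair tied with the boundary p is rejected with it
        return int(np.searchsorted(self._p_sorted, p_cut, side="right"))

    def detected_keys(self, q: Optional[float] = None) -> np.ndarray:
        """Flat pair keys (snp_idx * n_feature + feat_idx) detected at q."""
        return self._keys_sorted[: self.detection_cutoff(q)]

    def detected_at(self, q: float) -> np.ndarray:
        """Boolean detection flags aligned with ``records`` rows."""
        flags = np.zeros(len(self.records), dtype=bool)
        flags[: self.detection_cutoff(q)] = True
        return flags


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # constant columns up to representation error carry no usable signal
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    safe = np.where(zero, 1.0, sd)
    Z = (X - mu) / safe
    Z[:, zero] = 0.0
    return Z, sd, zero


def map_eqtls(
    G,
    Y,
    config: Optional[MapperConfig] = None,
    snp_ids: Optional[Sequence[str]] = None,
    feature_ids: Optional[Sequence[str]] = None,
) -> MapResult:
    """Map eQTLs by per-pair simple linear regression with BH-FDR control.

    Parameters
    ----------
    G, Y
        Sample-by-SNP dosage matrix and sample-by-feature expression matrix
        (arrays, DataFrames, or the simulation module's container types)
        sharing the sample dimension, with no missing values.
    """
    from mreqtl.simulation import ExpressionMatrix, GenotypeMatrix

    if isinstance(G, GenotypeMatrix):
        if snp_ids is None:
            snp_ids = G.snp_map["id"].to_numpy()
        G = G.dosages
    if isinstance(Y, ExpressionMatrix):
        if feature_ids is None:
            feature_ids = Y.feature_map["id"].to_numpy()
        Y = Y.values
    if isinstance(G, pd.DataFrame):
        if snp_ids is None:
            snp_ids = G.columns.to_numpy()
        G = G.to_numpy()
    if isinstance(Y, pd.DataFrame):
        if feature_ids is None:
            feature_ids = Y.columns.to_numpy()
        Y = Y.to_numpy()
    G = np.asarray(G, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if G.ndim != 2 or Y.ndim != 2 or G.shape[0] != Y.shape[0]:
        raise ValueError("G and Y must be 2-D and share the sample dimension")
    n, n_snp = G.shape
    n_feat = Y.shape[1]
    if n < 4:
        raise ValueError("at least 4 samples are required")
    if not (np.isfinite(G).all() and np.isfinite(Y).all()):
        raise ValueError("missing or non-finite values are not supported")
    cfg = config or MapperConfig()
    m = n_snp * n_feat
    df = n - 2

    dense = m <= cfg.dense_limit
    p_store = 1.0 if dense else cfg.p_store_threshold
    # r^2 cut corresponding to the storage threshold: t^2 = r^2*df/(1-r^2)
    if p_store >= 1.0:
        r2_store = -1.0  # store everything
    else:
        t_store = stats.t.isf(p_store / 2.0, df)
        r2_store = t_store**2 / (t_store**2 + df)

    if dense:
        hist_counts = hist_p_lo = None
        r2_edges = None
    else:
        # log-spaced p bins over (p_store, 0.1]; r^2 is decreasing in p
        p_edges = np.logspace(
            np.log10(p_store), np.log10(_HIST_P_MAX), cfg.n_hist_bins + 1
        )
        t_edges = stats.t.isf(p_edges / 2.0, df)
        r2_bin_edges = t_edges**2 / (t_edges**2 + df)  # descending
        r2_edges = r2_bin_edges[::-1].copy()  # ascending for searchsorted
        hist_counts = np.zeros(cfg.n_hist_bins, dtype=np.int64)
        hist_p_lo = p_edges[:-1]

    Gs, g_sd, g_zero = _standardise(G)
    Ys, y_sd, y_zero = _standardise(Y)
    Gs /= np.sqrt(n)
    Ys /= np.sqrt(n)
    # the screen may run in single precision; all stored pairs are then
    # recomputed in double precision below, and the detection boundary sits
    # orders of magnitude inside the storage threshold, so screen rounding
    # cannot move a detectable pair out of the stored set
    Gs_s = Gs.astype(np.float32) if cfg.screen_dtype == "float32" else Gs
    Ys_s = Ys.astype(np.float32) if cfg.screen_dtype == "float32" else Ys

    snp_parts, feat_parts, r_parts = [], [], []
    for lo in range(0, n_snp, cfg.chunk_size):
        hi = min(lo + cfg.chunk_size, n_snp)
        r = Gs_s[:, lo:hi].T @ Ys_s
        r2 = r * r
        if not dense:
            # histogram the unstored mid-range for exact global rank bounds
            mid = (r2 > r2_edges[0]) & (r2 < r2_store)
            if mid.any():
                idx = np.searchsorted(r2_edges, r2[mid].astype(np.float64), side="left") - 1
                hist_counts += np.bincount(
                    cfg.n_hist_bins - 1 - idx, minlength=cfg.n_hist_bins
                )
            keep = r2 >= r2_store
        else:
            keep = np.ones_like(r2, dtype=bool)
        si, fi = np.nonzero(keep)
        snp_parts.append((si + lo).astype(np.int64))
        feat_parts.append(fi.astype(np.int64))
        r_parts.append(np.asarray(r[keep], dtype=np.float64))

    snp_idx = np.concatenate(snp_parts)
    feat_idx = np.concatenate(feat_parts)
    r = np.concatenate(r_parts)
    if cfg.screen_dtype == "float32" and len(r):
        # exact double-precision correlations for every stored pair
        r = np.einsum("ij,ij->j", Gs[:, snp_idx], Ys[:, feat_idx])
    r = np.clip(r, -1.0, 1.0)
    near_one = np.abs(r) >= 1.0 - 1e-15
    r2 = np.minimum(r * r, 1.0 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[near_one] = _TINY_P
    p = np.maximum(p, _TINY_P)  # keep logs finite after underflow
    # zero-variance pairs carry no evidence: p = 1, never detected
    degenerate = g_zero[snp_idx] | y_zero[feat_idx]
    p[degenerate] = 1.0
    t[degenerate] = 0.0

    beta = r * y_sd[feat_idx] / np.where(g_sd[snp_idx] == 0, 1.0, g_sd[snp_idx])

    order = np.lexsort((feat_idx, snp_idx, p))
    snp_idx, feat_idx = snp_idx[order], feat_idx[order]
    beta, t, p = beta[order], t[order], p[order]
    keys = snp_idx * np.int64(n_feat) + feat_idx

    # adjusted values: textbook cummin over the stored tail, then the
    # histogram lower bound for the unstored tail (exact in the dense case)
    s = len(p)
    ranks = np.arange(1, s + 1, dtype=np.float64)
    terms = p * (m / ranks)
    if dense:
        tail = np.inf
    else:
        cum_hi = s + np.cumsum(hist_counts)
        occ = hist_counts > 0
        tail = (
            np.min(hist_p_lo[occ] * m / cum_hi[occ]) if occ.any() else np.inf
        )
    adj = np.minimum(np.minimum.accumulate(np.minimum(terms, tail)[::-1])[::-1], 1.0)

    if snp_ids is None:
        snp_ids = np.array([f"snp{i}" for i in range(n_snp)])
    else:
        snp_ids = np.asarray(snp_ids)
    if feature_ids is None:
        feature_ids = np.array([f"feat{j}" for j in range(n_feat)])
    else:
        feature_ids = np.asarray(feature_ids)

    records = pd.DataFrame(
        {
            "snp_id": snp_ids[snp_idx],
            "feature_id": feature_ids[feat_idx],
            "beta": beta,
            "t": t,
            "p": p,
            "fdr": adj,
            "detected": False,
        }
    )
    result = MapResult(
        records=records,
        m=m,
        n_snp=n_snp,
        n_feature=n_feat,
        n_sample=n,
        config=cfg,
        _p_sorted=p,
        _keys_sorted=keys,
        _hist_counts=hist_counts,
        _hist_p_lo=hist_p_lo,
    )
    records["detected"] = result.detected_at(cfg.fdr_threshold)
    return result
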