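"""Dual-channel antibody-microarray processing and moderated differential abundance.

The assay follows a reference design: each plasma sample is labelled with one
dye and co-hybridized with a common pooled reference labelled with the other
dye, every antibody printed in quadruplicate. Analysis operates on per-antibody
log-ratios ``M = log2(sample/reference)`` against average log-intensities
``A = ½·log2(sample·reference)``.

Pipeline stages:

1. replicate aggregation — median over quadruplicate spots after optional
   local-background subtraction, floored at a small positive intensity;
2. rank-invariant lowess normalization — antibodies whose within-array ranks
   agree between the two channels (|Δrank|/n ≤ tol) anchor a locally weighted
   regression of M on A whose fitted trend is subtracted from all M values,
   removing smooth intensity-dependent dye bias;
3. moderated contrasts — per-antibody least-squares condition means with an
   empirical-Bayes variance prior: ``s²_post = (d0·s0² + d·s²)/(d0 + d)``,
   the prior (d0, s0²) estimated by method of moments on log s² across
   antibodies, and t referred to a t distribution with d0 + d df;
4. Benjamini–Hochberg adjustment and threshold classification into
   differential / noteworthy / nonsignificant calls;
5. per-antibody z-scoring and average-linkage hierarchical clustering for
   heatmap ordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ArrayExperiment",
    "NormalizedMatrix",
    "Thresholds",
    "RESULTS_THRESHOLDS",
    "METHODS_THRESHOLDS",
    "aggregate_replicates",
    "aggregate_experiment",
    "normalize",
    "moderated_contrast",
    "bh_adjust",
    "classify",
    "cluster_order",
]

logger = logging.getLogger(__name__)

EPSILON = 1.0         # intensity floor before log2
DEFAULT_SPAN = 0.4    # lowess span for the normalization fit
DEFAULT_RANK_TOL = 0.05  # |rank difference| / n defining the invariant set
MIN_INVARIANT = 10    # fall back to median centering below this set size


@dataclass(frozen=True)
class ArrayExperiment:
    """Long-format spot intensities plus the sample sheet.

    ``spots`` columns: sample_id, antibody_id, replicate, channel
    ("sample" | "reference"), intensity, optional background.
    ``samples`` columns: sample_id, group, timepoint.
    """

    spots: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample_id", "antibody_id", "replicate", "channel", "intensity"}
        missing = need - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns: {sorted(missing)}")
        if (self.spots["intensity"].dropna() < 0).any():
            raise ValueError("spot intensities must be non-negative")
        chans = set(self.spots["channel"].unique())
        if not chans <= {"sample", "reference"}:
            raise ValueError(f"unknown channel labels: {chans - {'sample', 'reference'}}")


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalized log-ratios (antibody × sample) and average intensities."""

    m_values: pd.DataFrame
    a_values: pd.DataFrame
    samples: pd.DataFrame


def aggregate_replicates(spots, background=None,
                         epsilon: float = EPSILON) -> tuple[float, float]:
    """Median over replicate spots with optional background subtraction.

    Returns ``(intensity, cv)`` where cv is the coefficient of variation of the
    floored background-corrected replicates. NaN spots are ignored; an
    all-missing set raises.
    """
    vals = np.asarray(spots, dtype=float).ravel()
    if background is not None:
        bg = np.asarray(background, dtype=float).ravel()
        vals = vals - bg
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all replicate spots missing")
    vals = np.maximum(vals, epsilon)
    med = float(np.median(vals))
    cv = float(vals.std(ddof=0) / vals.mean()) if vals.mean() > 0 else 0.0
    return med, cv


def aggregate_experiment(exp: ArrayExperiment,
                         epsilon: float = EPSILON) -> pd.DataFrame:
    """Aggregate spots to one intensity per antibody × sample × channel.

    Background is subtracted spot-wise when a ``background`` column is present.
    Antibody/sample/channel combinations with no finite spot are flagged absent
    (NaN intensity).
    """
    work = exp.spots.copy()
    if "background" in work.columns:
        work["_net"] = work["intensity"] - work["background"].fillna(0.0)
    else:
        work["_net"] = work["intensity"]
    work["_net"] = np.maximum(work["_net"], epsilon)
    g = work.groupby(["antibody_id", "sample_id", "channel"], sort=True)["_net"]
    agg = g.median().rename("intensity").reset_index()
    return agg


def _ma_from_aggregated(agg: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    wide = agg.pivot_table(index="antibody_id", columns=["sample_id", "channel"],
                           values="intensity")
    samples = sorted({s for s, _ in wide.columns})
    m = {}
    a = {}
    for s in samples:
        if (s, "sample") not in wide.columns or (s, "reference") not in wide.columns:
            raise ValueError(f"sample {s!r} lacks one of the two channels")
        smp = np.log2(wide[(s, "sample")])
        ref = np.log2(wide[(s, "reference")])
        m[s] = smp - ref
        a[s] = 0.5 * (smp + ref)
    return pd.DataFrame(m), pd.DataFrame(a)


def normalize(exp: ArrayExperiment,
              span: float = DEFAULT_SPAN,
              invariant_rank_tol: float = DEFAULT_RANK_TOL,
              epsilon: float = EPSILON) -> NormalizedMatrix:
    """Rank-invariant lowess normalization of every array.

    Per array, antibodies whose sample- and reference-channel ranks differ by
    at most ``invariant_rank_tol × n`` form the invariant set, assumed
    unchanged between sample and reference. A lowess fit of M on A over that
    set estimates the intensity-dependent dye bias, which is subtracted from
    every M value (interpolated at each antibody's A). If fewer than
    ``MIN_INVARIANT`` antibodies qualify the array is median-centered instead.
    """
    agg = aggregate_experiment(exp, epsilon=epsilon)
    m_df, a_df = _ma_from_aggregated(agg)
    n = m_df.shape[0]
    if n < 20:
        warnings.warn("fewer than 20 antibodies; normalization fit may be "
                      "unstable", stacklevel=2)
    m_out = m_df.copy()
    for s in m_df.columns:
        m = m_df[s].to_numpy()
        a = a_df[s].to_numpy()
        ok = np.isfinite(m) & np.isfinite(a)
        smp_rank = stats.rankdata(a[ok] + m[ok] / 2.0)   # sample-channel log2
        ref_rank = stats.rankdata(a[ok] - m[ok] / 2.0)   # reference-channel log2
        inv = np.abs(smp_rank - ref_rank) / ok.sum() <= invariant_rank_tol
        if inv.sum() < MIN_INVARIANT:
            logger.warning("array %s: invariant set too small (%d); "
                           "median centering", s, int(inv.sum()))
            warnings.warn(f"array {s}: invariant set too small; "
                          "falling back to median centering", stacklevel=2)
            m_out[s] = m - np.nanmedian(m)
            continue
        fit = lowess(m[ok][inv], a[ok][inv], frac=span, return_sorted=True)
        trend = np.interp(a, fit[:, 0], fit[:, 1])
        m_out[s] = m - trend
    return NormalizedMatrix(m_out, a_df, exp.samples.copy())


# ------------------------------------------------- moderated contrasts

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments empirical-Bayes prior (d0, s0²) from log variances."""
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        return np.inf, float(np.exp(z.mean())) if z.size else 1.0
    e_z = z.mean()
    var_z = z.var(ddof=1)
    rhs = var_z - special.polygamma(1, d / 2.0)
    if rhs <= 0 or not np.isfinite(rhs):
        d0 = np.inf
        s0_2 = np.exp(e_z - special.polygamma(0, d / 2.0) + np.log(d / 2.0))
    else:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_2 = np.exp(e_z - special.polygamma(0, d / 2.0) + np.log(d / 2.0)
                      + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def moderated_contrast(norm: NormalizedMatrix,
                       condition: pd.Series | dict,
                       contrast: dict[str, float],
                       d0: float | None = None,
                       s0_2: float | None = None,
                       thresholds: "Thresholds | None" = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t contrast on normalized log-ratios.

    Parameters
    ----------
    norm : normalized matrix (antibody × sample M values).
    condition : sample_id → condition label (e.g. "ALI_TPP_t6").
    contrast : condition label → weight; weights should sum to 0 for a
        difference contrast (e.g. ``{"ALI_TPP_t6": 1, "baseline": -1}``) or be
        a single ``{label: 1}`` to test a mean log-ratio against zero.
    d0, s0_2 : optional fixed prior df / prior variance. ``d0=0`` disables
        moderation (ordinary per-antibody t); ``d0=np.inf`` pools fully. When
        omitted, both are estimated by method of moments across antibodies.

    Returns a per-antibody frame with ``log_fc, t, p_raw, p_adj, class`` and
    the moderation parameters in ``DataFrame.attrs``.
    """
    cond = pd.Series(condition)
    m = norm.m_values
    used = [s for s in m.columns if s in cond.index and cond[s] in contrast]
    labels = sorted({cond[s] for s in used})
    for lab, w in contrast.items():
        n_lab = sum(cond[s] == lab for s in used)
        if w != 0 and n_lab < 2:
            raise ValueError(f"condition {lab!r} has fewer than 2 samples")
    x = m[used].to_numpy(dtype=float)
    groups = np.array([cond[s] for s in used])
    k = len(labels)
    n_total = len(used)
    d = n_total - k
    if d <= 0:
        raise ValueError("zero residual degrees of freedom; pool conditions "
                         "or use a fixed-prior (pooled-variance) mode")
    means = np.column_stack([x[:, groups == lab].mean(axis=1) for lab in labels])
    resid_ss = np.zeros(x.shape[0])
    for j, lab in enumerate(labels):
        cols = x[:, groups == lab]
        resid_ss += ((cols - means[:, [j]]) ** 2).sum(axis=1)
    s2 = resid_ss / d
    if d0 is None or s0_2 is None:
        d0_est, s0_est = _estimate_prior(s2, d)
        d0 = d0_est if d0 is None else d0
        s0_2 = s0_est if s0_2 is None else s0_2
    if not np.isfinite(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = d
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    w = np.array([contrast.get(lab, 0.0) for lab in labels])
    n_per = np.array([(groups == lab).sum() for lab in labels])
    log_fc = means @ w
    se_factor = np.sqrt((w ** 2 / n_per).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / (np.sqrt(s2_post) * se_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(np.where(np.isfinite(p), p, 1.0), np.nextafter(0, 1), 1.0)
    out = pd.DataFrame({
        "antibody_id": m.index,
        "log_fc": log_fc,
        "t": t,
        "p_raw": p,
    }).set_index("antibody_id")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    thr = thresholds or RESULTS_THRESHOLDS
    out["class"] = classify(out["log_fc"].to_numpy(), out["p_adj"].to_numpy(), thr)
    out.attrs["d0"] = float(d0)
    out.attrs["s0_2"] = float(s0_2)
    out.attrs["residual_df"] = d
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds for per-antibody contrast results.

    ``noteworthy_mode='pvalue'`` labels near-misses by a relaxed adjusted-p
    ceiling at the same fold-change cut; ``'lfc'`` labels them by a lower
    fold-change band at any p.
    """

    lfc: float = 0.5
    alpha: float = 0.05
    noteworthy_mode: str = "pvalue"   # "pvalue" | "lfc"
    noteworthy_alpha: float = 0.9
    noteworthy_lfc_low: float = 0.25


#: defaults used in the reported results and volcano plots
RESULTS_THRESHOLDS = Thresholds()
#: stricter variant: adj p < 0.005, noteworthy by fold-change band 0.25-0.5
METHODS_THRESHOLDS = Thresholds(lfc=0.5, alpha=0.005, noteworthy_mode="lfc")


def classify(log_fc, p_adj, thresholds: Thresholds = RESULTS_THRESHOLDS):
    """Label each antibody differential / noteworthy / nonsignificant."""
    lfc = np.atleast_1d(np.asarray(log_fc, dtype=float))
    p = np.atleast_1d(np.asarray(p_adj, dtype=float))
    out = np.full(lfc.shape, "nonsignificant", dtype=object)
    differential = (np.abs(lfc) > thresholds.lfc) & (p < thresholds.alpha)
    if thresholds.noteworthy_mode == "pvalue":
        noteworthy = ((np.abs(lfc) > thresholds.lfc)
                      & (p >= thresholds.alpha)
                      & (p < thresholds.noteworthy_alpha))
    elif thresholds.noteworthy_mode == "lfc":
        noteworthy = ((np.abs(lfc) > thresholds.noteworthy_lfc_low)
                      & (np.abs(lfc) <= thresholds.lfc))
    else:
        raise ValueError(f"unknown noteworthy_mode {thresholds.noteworthy_mode!r}")
    out[noteworthy] = "noteworthy"
    out[differential] = "differential"
    if np.isscalar(log_fc) or np.ndim(log_fc) == 0:
        return out.item()
    return out


def cluster_order(m_values: pd.DataFrame) -> tuple[list, list]:
    """Heatmap leaf orders from per-antibody z-scored log-ratios.

    Rows (antibodies) are centered and scaled to mean 0, sd 1; average-linkage
    hierarchical clustering with Euclidean distance orders rows and columns.
    Zero-variance antibodies are scaled to all-zero rows with a warning.
    """
    if m_values.shape[0] < 2 or m_values.shape[1] < 2:
        raise ValueError("need at least 2 antibodies and 2 samples")
    x = m_values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance antibody rows scaled "
                      "to zero", stacklevel=2)
    z = np.where(sd > 0, (x - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    row_link = hierarchy.linkage(z, method="average", metric="euclidean")
    col_link = hierarchy.linkage(z.T, method="average", metric="euclidean")
    row_order = [m_values.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [m_values.columns[i] for i in hierarchy.leaves_list(col_link)]
    return row_order, col_order
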