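"""Two-library differential tag abundance.

The classic digital-expression setting: a tag observed x times in a control
library of N1 total tags and y times in a treatment library of N2 tags, no
replicates.  Under the null of equal relative expression, the conditional
law of y given x (with a flat prior on the unknown rate) is negative
binomial,

    P(y | x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))
             = NB(r = x+1, p = N1/(N1+N2)),

the Audic–Claverie two-library test.  The two-sided p-value doubles the
smaller of the two tails (each including the observed point) and caps at 1.
A conditional-binomial backend (y | x+y ~ Binomial(x+y, N2/(N1+N2))) is
available as an independent alternative; unlike the Audic–Claverie form it
is exactly symmetric under swapping the libraries.

Fold changes are tags-per-million ratios with the zero-count pseudocount
rule: a raw count of 0 is set to 1 before normalization, so
library-specific tags get a defined, conservative fold change.  Directions
and fold changes are reported on the infected/control (treatment/control)
scale throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tags import InputError, TagCountTable

NORM_TOTAL = 1_000_000
ALPHA = 0.05
MIN_FC = 2.0
LOG2_CUT = 2.0


def normalize(count: float, lib_size: int, scale: int = NORM_TOTAL) -> float:
    """Scale a raw count to tags per million (``scale`` tags)."""
    if lib_size <= 0:
        raise InputError("lib_size must be positive")
    if count < 0:
        raise InputError("count must be non-negative")
    return count * scale / lib_size


def fold_change(
    x: int, y: int, n1: int, n2: int, pseudocount: int = 1
) -> tuple[float, float, str]:
    """Fold change on the infected/control scale with the zero-count rule.

    Raw zero counts are replaced by ``pseudocount`` before normalization.
    Returns (FC, log2FC, direction) where direction is 'up' when the
    infected library is enriched, 'down' when depleted, 'none' at equality.
    """
    if x == 0 and y == 0:
        raise InputError("fold change undefined for a tag absent from both libraries")
    xp = x if x > 0 else pseudocount
    yp = y if y > 0 else pseudocount
    cpm_ctl = normalize(xp, n1)
    cpm_inf = normalize(yp, n2)
    fc = cpm_inf / cpm_ctl
    log2fc = math.log2(fc)
    direction = "up" if fc > 1 else ("down" if fc < 1 else "none")
    return fc, log2fc, direction


def _ac_pvalues(
    x: np.ndarray, y: np.ndarray, n1: float, n2: float
) -> np.ndarray:
    q = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, q)
    upper = stats.nbinom.sf(y - 1, x + 1, q)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _binom_pvalues(
    x: np.ndarray, y: np.ndarray, n1: float, n2: float
) -> np.ndarray:
    n = x + y
    p2 = n2 / (n1 + n2)
    lower = stats.binom.cdf(y, n, p2)
    upper = stats.binom.sf(y - 1, n, p2)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


_BACKENDS = {"audic-claverie": _ac_pvalues, "binomial": _binom_pvalues}


def tag_test_pvalue(
    x: int, y: int, n1: int, n2: int, method: str = "audic-claverie"
) -> float:
    """Two-sided p-value for a tag's count difference between two libraries.

    Tails are evaluated through the negative-binomial (resp. binomial)
    closed form — regularized incomplete beta functions — so no explicit
    factorials appear and the computation is stable for large counts.
    """
    if x < 0 or y < 0:
        raise InputError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise InputError("library sizes must be positive")
    try:
        backend = _BACKENDS[method]
    except KeyError:
        raise InputError(f"unknown method {method!r}") from None
    return float(backend(np.asarray(x), np.asarray(y), n1, n2))


@dataclass(frozen=True)
class DESummary:
    n_tags: int
    n_sig: int
    n_up: int
    n_down: int
    n_sig_log2gt2: int


def call_significant(
    table: TagCountTable,
    alpha: float = ALPHA,
    min_fc: float = MIN_FC,
    log2_cut: float = LOG2_CUT,
    method: str = "audic-claverie",
    bh: bool = False,
) -> tuple[pd.DataFrame, DESummary]:
    """Per-tag differential-expression results for a cleaned count table.

    Two significance flags are populated: ``sig_2fold`` (p < alpha and fold
    change magnitude >= min_fc — the headline rule) and ``sig_log2gt2``
    (p < alpha and |log2FC| > log2_cut — the stricter cut used upstream of
    functional annotation).  Threshold conventions: p strict, FC inclusive,
    |log2FC| strict.  With ``bh=True`` p-values are Benjamini–Hochberg
    adjusted before thresholding.
    """
    df = table.counts
    x = df["count_ctl"].to_numpy(dtype=np.int64)
    y = df["count_inf"].to_numpy(dtype=np.int64)
    if ((x == 0) & (y == 0)).any():
        raise InputError("all-zero rows must be removed before testing")
    n1, n2 = table.n_ctl, table.n_inf

    xp = np.where(x > 0, x, 1)
    yp = np.where(y > 0, y, 1)
    cpm_ctl = xp * (NORM_TOTAL / n1)
    cpm_inf = yp * (NORM_TOTAL / n2)
    fc = cpm_inf / cpm_ctl
    log2fc = np.log2(fc)
    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))

    p = _BACKENDS[method](x, y, float(n1), float(n2))
    if bh:
        p = stats.false_discovery_control(p, method="bh")

    fc_mag = np.maximum(fc, 1.0 / fc)
    sig_2fold = (p < alpha) & (fc_mag >= min_fc)
    sig_log2 = (p < alpha) & (np.abs(log2fc) > log2_cut)

    results = pd.DataFrame(
        {
            "tag": df["tag"].to_numpy(),
            "count_ctl": x,
            "count_inf": y,
            "cpm_ctl": x * (NORM_TOTAL / n1),
            "cpm_inf": y * (NORM_TOTAL / n2),
            "fc": fc,
            "log2fc": log2fc,
            "pvalue": p,
            "direction": direction,
            "sig_2fold": sig_2fold,
            "sig_log2gt2": sig_log2,
        }
    )
    summary = DESummary(
        n_tags=len(results),
        n_sig=int(sig_2fold.sum()),
        n_up=int((sig_2fold & (direction == "up")).sum()),
        n_down=int((sig_2fold & (direction == "down")).sum()),
        n_sig_log2gt2=int(sig_log2.sum()),
    )
    return results, summary


DEFAULT_FC_BINS = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0, math.inf)


def fc_histogram(
    results: pd.DataFrame,
    bin_edges: tuple[float, ...] = DEFAULT_FC_BINS,
) -> pd.DataFrame:
    """Fold-change-magnitude histogram of significant tags, up vs down.

    Bins are half-open [lo, hi) over the FC magnitude of tags flagged by
    the headline (p, 2-fold) rule.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise InputError("bin_edges must be strictly increasing")
    sig = results[results["sig_2fold"]]
    fc_mag = np.maximum(sig["fc"], 1.0 / sig["fc"])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (fc_mag >= lo) & (fc_mag < hi)
        rows.append(
            (
                lo,
                hi,
                int((in_bin & (sig["direction"] == "up")).sum()),
                int((in_bin & (sig["direction"] == "down")).sum()),
            )
        )
    return pd.DataFrame(rows, columns=["fc_lo", "fc_hi", "n_up", "n_down"])


def frequency_classes(
    table: TagCountTable,
    boundary: float = 1000.0,
    sub_boundaries: tuple[float, ...] = (10.0, 100.0),
) -> pd.DataFrame:
    """Classify tags by expression level (maximum per-library cpm).

    Classes partition (0, inf) with right-closed intervals: the default
    gives low (<=10], average (10, 100] ... with the headline split at
    ``boundary`` cpm separating low/average from high/extremely-high tags.
    Fractions sum to 1 over a non-empty table.
    """
    edges = sorted(set(sub_boundaries) | {boundary})
    if any(e <= 0 for e in edges):
        raise InputError("class boundaries must be positive")
    cpm_max = np.maximum(
        table.counts["count_ctl"] * (NORM_TOTAL / max(table.n_ctl, 1)),
        table.counts["count_inf"] * (NORM_TOTAL / max(table.n_inf, 1)),
    )
    bounds = [0.0] + edges + [math.inf]
    rows = []
    n = len(table)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        count = int(((cpm_max > lo) & (cpm_max <= hi)).sum())
        rows.append((lo, hi, count, count / n if n else 0.0))
    return pd.DataFrame(rows, columns=["cpm_lo", "cpm_hi", "count", "fraction"])
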