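"""Method-comparison statistics: Bland-Altman limits of agreement and errors.

Given paired interval series ``a`` (method under test) and ``b`` (reference),
the differences ``d = a - b`` yield the mean difference and the 95 % limits
of agreement ``mean(d) +/- 1.96 * sd(d)`` (sample SD).  Absolute and relative
error metrics use ``b`` as the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sstats

__all__ = [
    "AgreementReport",
    "bland_altman",
    "error_metrics",
    "compare_series",
    "aggregate_relative_error",
    "plot_bland_altman",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman and error metrics between two paired interval series."""

    mean_diff: float
    loa_low: float
    loa_high: float
    mae: float
    max_abs_err: float
    mean_rel_err: float
    max_rel_err: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _paired_complete(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"series lengths differ: {a.shape} vs {b.shape}")
    ok = ~(np.isnan(a) | np.isnan(b))
    return a[ok], b[ok]


def bland_altman(a, b, loa_multiplier: float | str = 1.96
                 ) -> tuple[float, float, float]:
    """Mean difference and limits of agreement of ``d = a - b``.

    ``loa_multiplier`` defaults to 1.96 (95 % of differences under
    normality); pass ``"t"`` for a small-sample t-based multiplier.
    Requires at least 2 complete pairs.
    """
    a, b = _paired_complete(a, b)
    if a.size < 2:
        raise ValueError(f"need at least 2 complete pairs, got {a.size}")
    d = a - b
    mean_diff = float(d.mean())
    sd = float(np.std(d, ddof=1))
    if loa_multiplier == "t":
        mult = float(sstats.t.ppf(0.975, a.size - 1))
    else:
        mult = float(loa_multiplier)
    return mean_diff, mean_diff - mult * sd, mean_diff + mult * sd


def error_metrics(a, b) -> tuple[float, float, float, float]:
    """(mae, max_abs_err, mean_rel_err, max_rel_err) with ``b`` as reference.

    Pairs with a zero reference are excluded from the relative metrics (and
    logged); relative errors are fractions, not percent.
    """
    a, b = _paired_complete(a, b)
    if a.size < 1:
        raise ValueError("no complete pairs")
    abs_err = np.abs(a - b)
    nz = b != 0
    if not nz.all():
        log.warning("excluding %d zero-reference pair(s) from relative errors",
                    int((~nz).sum()))
    rel = abs_err[nz] / np.abs(b[nz])
    mean_rel = float(rel.mean()) if rel.size else float("nan")
    max_rel = float(rel.max()) if rel.size else float("nan")
    return float(abs_err.mean()), float(abs_err.max()), mean_rel, max_rel


def aggregate_relative_error(a, b) -> float:
    """Alternative aggregation: mean absolute error over the mean reference.

    Some published comparisons report ``mae / mean(|b|)`` rather than the
    mean of per-pair relative errors; both are exposed.
    """
    a, b = _paired_complete(a, b)
    denom = float(np.abs(b).mean())
    if denom == 0:
        return float("nan")
    return float(np.abs(a - b).mean() / denom)


def compare_series(a, b, loa_multiplier: float | str = 1.96) -> AgreementReport:
    """Full agreement report between method ``a`` and reference ``b``."""
    mean_diff, lo, hi = bland_altman(a, b, loa_multiplier)
    mae, max_abs, mean_rel, max_rel = error_metrics(a, b)
    a_c, _ = _paired_complete(a, b)
    return AgreementReport(mean_diff, lo, hi, mae, max_abs, mean_rel, max_rel,
                           n=int(a_c.size))


def plot_bland_altman(a, b, path, title: str = "Bland-Altman") -> None:
    """Save a Bland-Altman plot: pair means on x, differences on y,
    horizontal lines at the mean difference and both limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a_c, b_c = _paired_complete(a, b)
    mean_diff, lo, hi = bland_altman(a_c, b_c)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a_c + b_c) / 2, a_c - b_c, s=14, color="tab:blue")
    ax.axhline(mean_diff, color="green", label=f"mean {mean_diff:.2f}")
    ax.axhline(lo, color="red", linestyle="--", label=f"LoA {lo:.2f}")
    ax.axhline(hi, color="red", linestyle="--", label=f"LoA {hi:.2f}")
    ax.set_xlabel("Mean of methods [ms]")
    ax.set_ylabel("Difference [ms]")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
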