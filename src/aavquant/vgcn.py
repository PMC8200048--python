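"""Absolute viral genome copy number (VGCn) by free-ITR qPCR, plus the
outlier screen and regression used on the downstream measurements.

A linearised plasmid standard is serially diluted 10-fold (1e8 .. 1e4
copies) and amplified in triplicate; the standard curve is the least-squares
line of mean Cq against log10(copies).  Amplification efficiency follows
from the slope: eff% = 100 * (10^(-1/slope) - 1), so a perfect doubling per
cycle gives slope -log2(10) = -3.321928 and 100%.  Unknown samples are read
off the curve as copies = 10^((Cq - intercept) / slope) per 10 ng template
and optionally converted to copies per diploid genome (a diploid mouse
genome weighs ~6.0 pg, i.e. ~1667 genomes per 10 ng).

Measurements are screened with a two-sided single-outlier Grubbs test and
compared between compartments by ordinary least-squares regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: diploid genomes in 10 ng of DNA at 6.0 pg per diploid mouse genome
GENOMES_PER_10NG = 10_000.0 / 6.0  # ~1667

PERFECT_SLOPE = -math.log2(10.0)  # -3.321928...: exact doubling per cycle
DEFAULT_NO_SIGNAL_CQ = 40.0  # cycling runs 40x; no Cq call beyond that


@dataclass
class StandardCurve:
    slope: float  # Cq per log10(copies); negative for valid curves
    intercept: float  # Cq at 1 copy
    r_squared: float
    efficiency_pct: float
    n_points: int
    warning: str | None = None

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def cq_from_copies(self, copies: float) -> float:
        return self.intercept + self.slope * math.log10(copies)


@dataclass
class VgcnResult:
    sample_id: str
    cq_values: tuple[float, ...]
    cq_mean: float
    cq_sd: float
    vgcn_per_10ng: float
    vgcn_per_genome: float
    no_signal: bool = False


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent; 100 iff slope == -log2(10)."""
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def fit_standard_curve(
    dilution_copies: list[float], cq: list[list[float]] | list[float]
) -> StandardCurve:
    """Least-squares fit of mean replicate Cq against log10(input copies).

    Requires at least 3 dilution points spanning at least 2 logs.
    Replicates are aggregated by mean before fitting.  A non-negative
    slope flags the curve instead of raising.
    """
    copies = np.asarray(dilution_copies, dtype=float)
    if len(copies) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    if np.any(copies <= 0):
        raise ValueError("dilution copies must be positive")
    logs = np.log10(copies)
    if logs.max() - logs.min() < 2.0:
        raise ValueError("dilution series must span at least 2 logs")
    mean_cq = np.array([float(np.mean(np.atleast_1d(c))) for c in cq], dtype=float)
    if len(mean_cq) != len(copies):
        raise ValueError("one Cq replicate set per dilution point required")
    fit = sps.linregress(logs, mean_cq)
    warning = None
    if fit.slope >= 0:
        warning = "non-negative slope: Cq should decrease with template amount"
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_pct=efficiency_from_slope(float(fit.slope)) if fit.slope < 0 else float("nan"),
        n_points=len(copies),
        warning=warning,
    )


def quantify_vgcn(
    cq_values: list[float],
    curve: StandardCurve,
    genomes_per_10ng: float = GENOMES_PER_10NG,
    sample_id: str = "sample",
    no_signal_cq: float = DEFAULT_NO_SIGNAL_CQ,
) -> VgcnResult:
    """Copies per 10 ng template (and per diploid genome) for one sample.

    Replicate Cq values are averaged; a mean Cq at or beyond the no-signal
    cutoff reports zero copies with the ``no_signal`` flag set.
    """
    if curve.slope >= 0:
        raise ValueError("cannot quantify against a curve with non-negative slope")
    vals = tuple(float(v) for v in cq_values)
    if not vals:
        raise ValueError("at least one Cq value required")
    mean_cq = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    if mean_cq >= no_signal_cq:
        return VgcnResult(sample_id, vals, mean_cq, sd, 0.0, 0.0, no_signal=True)
    per_10ng = curve.copies_from_cq(mean_cq)
    return VgcnResult(
        sample_id=sample_id,
        cq_values=vals,
        cq_mean=mean_cq,
        cq_sd=sd,
        vgcn_per_10ng=per_10ng,
        vgcn_per_genome=per_10ng / genomes_per_10ng,
    )


def simulate_cq(
    copies: float | np.ndarray,
    slope: float = PERFECT_SLOPE,
    intercept: float = 37.0,
    sd: float = 0.1,
    n_replicates: int = 3,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw replicate Cq values for given template amounts.

    Returns shape (n_points, n_replicates).  The default intercept puts
    1e4 copies around Cq 23.7, typical for a TaqMan ITR assay.
    """
    rng = np.random.default_rng(rng)
    copies = np.atleast_1d(np.asarray(copies, dtype=float))
    mean = intercept + slope * np.log10(copies)
    return mean[:, None] + rng.normal(0.0, sd, size=(len(copies), n_replicates))


def grubbs_test(values: list[float], alpha: float = 0.05) -> tuple[int | None, float, float]:
    """Two-sided single-outlier Grubbs test.

    G = max |x - mean| / sd (sample sd).  The critical value is
    ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    Returns (outlier index or None, G, critical value).  No iterative
    removal is performed.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Grubbs test requires non-zero standard deviation")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = float((n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2)))
    return (idx if g > g_crit else None, g, g_crit)


def linear_regression(x: list[float], y: list[float]) -> tuple[float, float, float, float]:
    """Ordinary least squares: (slope, intercept, r^2, two-sided slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("regression requires n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("regression requires variance in x")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), float(fit.pvalue)


# ---------------------------------------------------------------------------
# CSV interface: sample_id,dilution_or_sample,replicate,cq


def read_cq_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "dilution_or_sample", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    return df


def curve_from_table(df: pd.DataFrame) -> StandardCurve:
    """Fit the standard curve from the dilution rows of a Cq table.

    Dilution rows have ``dilution_or_sample`` parseable as copy number.
    """
    std = df[df["sample_id"].astype(str).str.lower() == "standard"]
    if std.empty:
        raise ValueError("no rows with sample_id == 'standard'")
    groups = std.groupby(std["dilution_or_sample"].astype(float))
    copies = sorted(groups.groups)
    cq_sets = [groups.get_group(c)["cq"].astype(float).tolist() for c in copies]
    return fit_standard_curve(list(copies), cq_sets)


def quantify_samples(
    df: pd.DataFrame,
    curve: StandardCurve,
    genomes_per_10ng: float = GENOMES_PER_10NG,
    no_signal_cq: float = DEFAULT_NO_SIGNAL_CQ,
) -> list[VgcnResult]:
    samples = df[df["sample_id"].astype(str).str.lower() != "standard"]
    out = []
    for sid, grp in samples.groupby("sample_id", sort=False):
        out.append(
            quantify_vgcn(
                grp["cq"].astype(float).tolist(),
                curve,
                genomes_per_10ng=genomes_per_10ng,
                sample_id=str(sid),
                no_signal_cq=no_signal_cq,
            )
        )
    return out


def results_frame(results: list[VgcnResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "cq_mean": r.cq_mean,
                "cq_sd": r.cq_sd,
                "vgcn_per_10ng": r.vgcn_per_10ng,
                "vgcn_per_genome": r.vgcn_per_genome,
                "no_signal": r.no_signal,
            }
            for r in results
        ]
    )
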