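"""Probe-level expression QC and gene-gene correlation analysis.

Implements quantile normalization, the detection-p-value call-rate gate,
probe averaging to gene signals, OLS-based pair correlation, an anchor-gene
target screen, and the Fisher-z contrast of two correlation coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AD_GROUP = "AD"
CONTROL_GROUP = "control"

#: Detection p-value at or above which a probe measurement is a no-call.
DETECTION_ALPHA = 0.05

#: Minimum per-group call rate; probes below this in *both* groups are dropped.
MIN_CALL_RATE = 0.90

#: Absolute Pearson r at or above which a target is flagged highly correlated.
HIGH_CORR_THRESHOLD = 0.7


@dataclass
class CorrelationResult:
    n: int
    r: float
    r2_adj: float
    slope: float
    slope_p: float


class ExpressionMatrix:
    """Probe x sample intensities with detection p-values and group labels."""

    def __init__(
        self,
        intensities: pd.DataFrame,
        detection_p: pd.DataFrame,
        groups: pd.Series,
        probe_gene: pd.Series,
        log2_transformed: bool = False,
    ):
        if not intensities.index.equals(detection_p.index) or not (
            intensities.columns.equals(detection_p.columns)
        ):
            raise ValueError("intensities and detection p-values must be aligned")
        if not set(intensities.columns) <= set(groups.index):
            raise ValueError("every sample needs a group label")
        bad = set(groups.loc[list(intensities.columns)]) - {AD_GROUP, CONTROL_GROUP}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if ((detection_p.values < 0) | (detection_p.values > 1)).any():
            raise ValueError("detection p-values must lie in [0,1]")
        self.intensities = intensities
        self.detection_p = detection_p
        self.groups = groups.loc[list(intensities.columns)]
        self.probe_gene = probe_gene
        self.log2_transformed = log2_transformed

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.intensities.index)

    def probes_for(self, gene: str) -> list[str]:
        return [
            p
            for p in self.intensities.index
            if self.probe_gene.get(p) == gene
        ]

    def log2(self) -> "ExpressionMatrix":
        """log2-transformed copy; a fixed point if already transformed."""
        if self.log2_transformed:
            return self
        return ExpressionMatrix(
            np.log2(self.intensities),
            self.detection_p,
            self.groups,
            self.probe_gene,
            log2_transformed=True,
        )


def quantile_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common row-mean reference distribution.

    The reference is the mean over samples of the column-sorted values; ties
    within a column receive the mean reference value of their tied ranks.
    """
    values = intensities.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires complete intensities")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)


def call_rates(
    matrix: ExpressionMatrix, alpha: float = DETECTION_ALPHA
) -> pd.DataFrame:
    """Per-probe call rate in each group; a call is detection p < alpha."""
    called = matrix.detection_p < alpha
    out = {}
    for grp in (AD_GROUP, CONTROL_GROUP):
        cols = [s for s in matrix.samples if matrix.groups[s] == grp]
        if not cols:
            raise ValueError(f"group {grp!r} has no samples")
        out[grp] = called[cols].mean(axis=1)
    return pd.DataFrame(out)


def call_rate_filter(
    matrix: ExpressionMatrix,
    alpha: float = DETECTION_ALPHA,
    min_rate: float = MIN_CALL_RATE,
) -> list[str]:
    """Probes retained: call rate >= min_rate in at least one group."""
    rates = call_rates(matrix, alpha)
    keep = (rates[AD_GROUP] >= min_rate) | (rates[CONTROL_GROUP] >= min_rate)
    return list(rates.index[keep])


def gene_signal(
    matrix: ExpressionMatrix,
    gene: str,
    probes: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Per-sample mean of log2 probe intensities for one gene."""
    if probes is None:
        probes = matrix.probes_for(gene)
    probes = list(probes)
    if not probes:
        raise ValueError(f"no retained probes for gene {gene!r}")
    m = matrix.log2()
    return m.intensities.loc[probes].mean(axis=0)


def fit_pair(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Ordinary least squares y ~ x with Pearson r and adjusted R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("fit_pair requires n >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CorrelationResult(
        n=n,
        r=float(fit.rvalue),
        r2_adj=float(r2_adj),
        slope=float(fit.slope),
        slope_p=float(fit.pvalue),
    )


def pearson_screen(
    matrix: ExpressionMatrix,
    anchor_gene: str,
    target_genes: Iterable[str],
    retained_probes: Optional[Sequence[str]] = None,
    high_threshold: float = HIGH_CORR_THRESHOLD,
) -> pd.DataFrame:
    """Pearson correlation of every target gene's signal with the anchor.

    Returns a frame (target, r, p, n, high) ranked by |r| descending; genes
    without retained probes are dropped with a log message.
    """

    def _probes(gene: str) -> list[str]:
        probes = matrix.probes_for(gene)
        if retained_probes is not None:
            probes = [p for p in probes if p in set(retained_probes)]
        return probes

    anchor_probes = _probes(anchor_gene)
    if not anchor_probes:
        raise ValueError(f"anchor gene {anchor_gene!r} has no retained probes")
    anchor = gene_signal(matrix, anchor_gene, anchor_probes)

    rows = []
    for gene in target_genes:
        probes = _probes(gene)
        if not probes:
            logger.info("target gene %s has no retained probes; dropped", gene)
            continue
        sig = gene_signal(matrix, gene, probes)
        r, p = stats.pearsonr(anchor.to_numpy(), sig.to_numpy())
        rows.append(
            {
                "target": gene,
                "r": float(r),
                "p": float(p),
                "n": int(anchor.shape[0]),
                "high": bool(abs(r) >= high_threshold),
            }
        )
    frame = pd.DataFrame(rows, columns=["target", "r", "p", "n", "high"])
    if len(frame):
        frame = frame.reindex(
            frame.r.abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return frame


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int, sided: str = "one"
) -> tuple[float, float]:
    """Fisher-z contrast of two correlations from independent samples.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the one-sided
    p tests r1 < r2 (i.e. negative z yields small p).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in each sample")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    if sided == "one":
        p = stats.norm.cdf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
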