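"""Differential expression from first principles.

The DEG call between the two strains follows a three-part criterion applied
with the JpA line as the control: |log2 fold change| >= 1, Benjamini-
Hochberg FDR < 0.05, and per-gene ROC AUC >= 0.8.  Positive log2FC means
higher expression in JpB.

The test itself is a conditional negative-binomial exact-style test: under
the null of equal per-sample means and a common dispersion phi, the
distribution of the strain-B sum conditional on the gene's total is free of
the mean parameter (a Dirichlet-multinomial-type law with size parameters
n_A/phi and n_B/phi), and the two-sided p-value sums all outcomes at most
as probable as the observed split.  As phi -> 0 this reduces to a binomial
split test, the Poisson limit.  Counts are library-size adjusted with
median-of-ratios size factors before summing.

Per-gene dispersions are method-of-moments estimates shrunk 50/50 toward
the common (median) dispersion; genes whose moment estimate is
non-positive fall back to the Poisson limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, rankdata

from .io_formats import CountMatrix

__all__ = [
    "DEGCriteria",
    "DEGResult",
    "normalize",
    "estimate_dispersions",
    "nb_test",
    "roc_auc",
    "bh_fdr",
    "call_degs",
    "pca_qc",
]


@dataclass
class DEGCriteria:
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    auc_min: float = 0.8
    control_strain: str = "JpA"
    # direction-symmetric AUC gate: max(auc, 1-auc) >= auc_min.  Set False to
    # enforce the literal one-sided reading auc >= auc_min.
    symmetric_auc: bool = True

    def __post_init__(self) -> None:
        if self.lfc_min <= 0:
            raise ValueError("lfc_min must be > 0")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0,1)")
        if not 0.5 <= self.auc_min <= 1:
            raise ValueError("auc_min must be in [0.5, 1]")


@dataclass
class DEGResult:
    gene_id: str
    log2fc: float
    p_value: float
    fdr: float
    auc: float
    is_deg: bool
    direction: str  # higher_in_JpA / higher_in_JpB / none


def normalize(counts: CountMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors (geometric mean 1) and the normalized
    matrix count/size_factor.

    Falls back to total-count scaling, with a warning, when no gene is
    positive in every sample.
    """
    frame = counts.counts
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    positive = (frame > 0).all(axis=1)
    if positive.sum() == 0:
        warnings.warn("no gene positive in all samples; using total-count scaling")
        totals = frame.sum(axis=0).astype(float)
        factors = totals / np.exp(np.log(totals).mean())
    else:
        logs = np.log(frame.loc[positive].astype(float))
        log_ref = logs.mean(axis=1)
        ratios = logs.sub(log_ref, axis=0)
        factors = np.exp(ratios.median(axis=0))
        factors = factors / np.exp(np.log(factors).mean())
    return factors, frame.div(factors, axis=1)


def estimate_dispersions(norm: pd.DataFrame, group_a, group_b) -> np.ndarray:
    """Per-gene dispersion: within-group method-of-moments pooled over the
    two groups, shrunk 50/50 toward the common (median positive) value.
    Genes with non-positive moment estimates get dispersion 0 (Poisson)."""
    raws = []
    weights = []
    for cols in (group_a, group_b):
        x = norm[list(cols)].to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raws.append(np.where(m > 0, (v - m) / m**2, np.nan))
        weights.append(len(cols) - 1)
    raw = (weights[0] * raws[0] + weights[1] * raws[1]) / (weights[0] + weights[1])
    positives = raw[np.isfinite(raw) & (raw > 0)]
    common = float(np.median(positives)) if len(positives) else 0.0
    shrunk = 0.5 * raw + 0.5 * common
    out = np.where(np.isfinite(raw) & (raw > 0), shrunk, 0.0)
    return np.maximum(out, 0.0)


_POISSON_EPS = 1e-12


def _conditional_log_pmf(s: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(K_B = k | total = s) for k = 0..s under equal means.

    Computed by cumulative sums of log((r + i) / (i + 1)), which is stable
    for arbitrarily large size parameters r."""
    i = np.arange(s, dtype=float)
    log_b = np.concatenate(([0.0], np.cumsum(np.log(r_b + i) - np.log(i + 1.0))))
    log_a = np.concatenate(([0.0], np.cumsum(np.log(r_a + i) - np.log(i + 1.0))))
    logw = log_b + log_a[::-1]
    return logw - logsumexp(logw)


def nb_test(group_a, group_b, dispersion: float) -> float:
    """Two-sided conditional NB test of equal means between two groups.

    ``group_a``/``group_b`` are (normalized) per-sample counts; the test
    conditions on the rounded total and sums the probability of every split
    at most as likely as the observed one.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    k_a = int(round(a.sum()))
    k_b = int(round(b.sum()))
    s = k_a + k_b
    if s == 0:
        return 1.0
    if dispersion <= _POISSON_EPS:
        logw = binom.logpmf(np.arange(s + 1), s, b.size / (a.size + b.size))
    else:
        logw = _conditional_log_pmf(s, a.size / dispersion, b.size / dispersion)
    obs = logw[k_b]
    p = float(np.exp(logsumexp(logw[logw <= obs + 1e-9])))
    return min(max(p, np.exp(obs)), 1.0)


def roc_auc(group_a, group_b) -> float:
    """Probability that a strain-B sample exceeds a strain-A sample, with the
    half-tie convention; identical to the Mann-Whitney U statistic divided
    by n_A * n_B."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([a, b]))
    rank_sum_b = ranks[a.size :].sum()
    u = rank_sum_b - b.size * (b.size + 1) / 2
    return float(u / (a.size * b.size))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_degs(counts: CountMatrix, criteria: DEGCriteria | None = None) -> list[DEGResult]:
    """Run the full DEG determination on a two-strain count matrix."""
    criteria = criteria or DEGCriteria()
    strains = counts.strains
    if criteria.control_strain not in strains:
        raise ValueError(f"control strain {criteria.control_strain!r} absent from matrix")
    others = [s for s in strains if s != criteria.control_strain]
    if len(others) != 1:
        raise ValueError(f"expected exactly two strains, found {strains}")
    group_a = counts.samples_of(criteria.control_strain)  # control (JpA)
    group_b = counts.samples_of(others[0])

    _, norm = normalize(counts)
    dispersions = estimate_dispersions(norm, group_a, group_b)
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    p_values = np.array(
        [nb_test(a[i], b[i], dispersions[i]) for i in range(len(counts.gene_ids))]
    )
    fdr = bh_fdr(p_values)
    aucs = np.array([roc_auc(a[i], b[i]) for i in range(len(counts.gene_ids))])

    results = []
    for i, gene in enumerate(counts.gene_ids):
        auc_stat = max(aucs[i], 1 - aucs[i]) if criteria.symmetric_auc else aucs[i]
        deg = (
            abs(log2fc[i]) >= criteria.lfc_min
            and fdr[i] < criteria.fdr_max
            and auc_stat >= criteria.auc_min
        )
        if deg:
            direction = "higher_in_JpB" if log2fc[i] > 0 else "higher_in_JpA"
        else:
            direction = "none"
        results.append(
            DEGResult(
                gene_id=gene,
                log2fc=float(log2fc[i]),
                p_value=float(p_values[i]),
                fdr=float(fdr[i]),
                auc=float(aucs[i]),
                is_deg=bool(deg),
                direction=direction,
            )
        )
    return results


def degs_frame(results: list[DEGResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "auc": [r.auc for r in results],
            "is_deg": [r.is_deg for r in results],
            "direction": [r.direction for r in results],
        }
    )


def pca_qc(norm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the first two principal components.

    Genes are centered and unit-scaled (zero-variance genes dropped) before
    the SVD; each component's sign is fixed by forcing its largest-magnitude
    gene loading positive.  Returns (coordinates, explained variance
    fraction of the two components).
    """
    if norm.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    x = norm.to_numpy(dtype=float).T  # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - mu[keep]) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    for j in range(2):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = u[:, :2] * s[:2]
    explained = (s**2 / (s**2).sum())[:2]
    return pd.DataFrame(coords, index=norm.columns, columns=["PC1", "PC2"]), explained
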