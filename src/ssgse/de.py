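"""DE gene calling from posterior inclusion probabilities.

Calling is by direct posterior-expected FDR: genes are ranked by PIP and the
expected FDR of the top-k call set is the mean of (1 - PIP) over it; the call
set is the largest k whose expected FDR stays below the target. The
annotation-informed mode fits the enrichment model with a chosen gene set so
that membership sharpens the PIPs; the annotation-free mode fits the
intercept-only model; Bayesian model averaging pools PIPs across many fitted
gene sets with evidence-based weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import EnrichmentResult, MCMCConfig, fit_gene_set
from .io import GeneStats


@dataclass
class DECallSet:
    """PIP-based DE calls at a target Bayesian FDR."""

    pip: np.ndarray
    local_fdr: np.ndarray          # 1 - pip
    calls: np.ndarray              # boolean call vector
    threshold: float               # smallest PIP among called genes (1.0 if none)
    expected_fdr: float            # posterior expected FDR of the call set
    fit: EnrichmentResult | None = None

    def to_frame(self, gene_id) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": gene_id,
            "pip": self.pip,
            "local_fdr": self.local_fdr,
            "call": self.calls.astype(int),
        })


def bayesian_fdr(pip: np.ndarray, target: float) -> DECallSet:
    """Call DE genes by thresholding the posterior expected FDR at ``target``.

    Sort genes by PIP descending; the expected FDR of the top-k set is
    ``mean(1 - pip)`` over it; calls are the largest k with expected
    FDR <= target. Ties in PIP are broken by stable input order.
    """
    if not (0 <= target < 1):
        raise ValueError("target FDR must lie in [0, 1)")
    pip = np.asarray(pip, dtype=float)
    order = np.argsort(-pip, kind="stable")
    sorted_lfdr = 1.0 - pip[order]
    cum_fdr = np.cumsum(sorted_lfdr) / np.arange(1, len(pip) + 1)
    ok = np.flatnonzero(cum_fdr <= target)
    calls = np.zeros(len(pip), dtype=bool)
    if len(ok):
        k = int(ok[-1]) + 1
        calls[order[:k]] = True
        threshold = float(pip[order[k - 1]])
        expected = float(cum_fdr[k - 1])
    else:
        threshold, expected = 1.0, 0.0
    return DECallSet(pip, 1.0 - pip, calls, threshold, expected)


def de_with_annotation(
    stats_table: GeneStats,
    a: np.ndarray,
    cfg: MCMCConfig = MCMCConfig(),
    fdr_target: float = 0.05,
    **fit_kwargs,
) -> DECallSet:
    """DE calls informed by one gene-set annotation."""
    a = np.asarray(a, dtype=np.int8)
    if a.sum() == 0:
        raise ValueError("annotation is empty")
    res = fit_gene_set(stats_table.z, stats_table.se, a, cfg, **fit_kwargs)
    out = bayesian_fdr(res.pip, fdr_target)
    out.fit = res
    return out


def de_without_annotation(
    stats_table: GeneStats,
    cfg: MCMCConfig = MCMCConfig(),
    fdr_target: float = 0.05,
    **fit_kwargs,
) -> DECallSet:
    """Annotation-free DE calls from the intercept-only model."""
    res = fit_gene_set(stats_table.z, stats_table.se, None, cfg, **fit_kwargs)
    out = bayesian_fdr(res.pip, fdr_target)
    out.fit = res
    return out


def bma_pip(results: list[EnrichmentResult], weights_mode: str = "bic") -> np.ndarray:
    """Bayesian-model-averaged PIPs across gene-set fits.

    Weights are proportional to ``exp(loglik - 1.5 * log(p))`` per set
    (a BIC-style evidence approximation with three free parameters: tau0,
    tau1, sigma_beta^2), normalised to sum to one; ``weights_mode="uniform"``
    averages with equal weights. Output lies in the per-gene convex hull of
    the input PIPs.
    """
    if not results:
        raise ValueError("need at least one fitted gene set")
    pips = np.stack([r.pip for r in results])
    p = pips.shape[1]
    if weights_mode == "uniform":
        w = np.full(len(results), 1.0 / len(results))
    elif weights_mode == "bic":
        ll = np.array([r.loglik for r in results], dtype=float)
        score = ll - 1.5 * np.log(p)
        score -= score.max()
        w = np.exp(score)
        w /= w.sum()
    else:
        raise ValueError(f"unknown weights_mode {weights_mode!r}")
    return w @ pips
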