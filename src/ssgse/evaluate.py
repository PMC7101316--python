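"""Evaluation protocol: power at a fixed FDR, permutation nulls, consistency.

Power is computed either against known simulation truth (the largest call
set whose realised false-discovery proportion stays at or below the target)
or against a permutation-null score pool via the empirical FDR. The DE
permutation null shuffles cell labels, recomputes summary statistics and
reruns only the E-step with the enrichment parameters frozen at their
real-data estimates — re-estimating them on permuted data is overly liberal.
"""

from __future__ import annotations

import numpy as np

from .gse import empirical_fdr
from .inference import EnrichmentResult, MCMCConfig, e_step
from .model import LogisticPriorParams
from .simulate import internal_de_test


def power_at_fdr(
    scores: np.ndarray,
    truth: np.ndarray,
    fdr_target: float = 0.05,
    mode: str = "true_fdr",
    null_scores: np.ndarray | None = None,
    n_perm: int | None = None,
) -> float:
    """Fraction of true signals detected at a fixed false-discovery rate.

    ``scores``: larger = more significant (negate p-values before calling).
    mode="true_fdr" sweeps thresholds and returns TP/#truth for the largest
    call set with realised FDP <= target; mode="empirical_fdr" thresholds at
    the empirical FDR computed from ``null_scores`` (a pool from ``n_perm``
    permutations).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    n_true = int(truth.sum())
    if n_true == 0:
        raise ValueError("no positives in truth: power undefined")
    if mode == "true_fdr":
        order = np.argsort(-scores, kind="stable")
        is_true = truth[order]
        n_called = np.arange(1, len(scores) + 1)
        fdp = np.cumsum(~is_true) / n_called
        ok = np.flatnonzero(fdp <= fdr_target)
        if len(ok) == 0:
            return 0.0
        k = int(ok[-1]) + 1
        return float(is_true[:k].sum() / n_true)
    elif mode == "empirical_fdr":
        if null_scores is None or n_perm is None:
            raise ValueError("empirical_fdr mode needs null_scores and n_perm")
        fdr = empirical_fdr(-scores, -np.asarray(null_scores, dtype=float), n_perm)
        called = fdr <= fdr_target
        return float((called & truth).sum() / n_true)
    raise ValueError(f"unknown mode {mode!r}")


def de_permutation_null(
    counts: np.ndarray,
    labels: np.ndarray,
    depths: np.ndarray,
    annotation: np.ndarray,
    fitted: EnrichmentResult,
    cfg: MCMCConfig = MCMCConfig(),
    n_perm: int = 10,
    rng: np.random.Generator | None = None,
    refit_tau: bool = False,
) -> np.ndarray:
    """Null PIP pool for empirical FDR of DE calls.

    Per permutation: shuffle the cell labels, rerun the internal DE test,
    then rerun only the E-step with the enrichment parameters tau frozen at
    the real-data estimates (``refit_tau=True`` instead re-fits them, which
    is known to yield anticonservative nulls). Returns the pooled null PIPs.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    labels = np.asarray(labels)
    tau = LogisticPriorParams(*fitted.tau_hat)
    pool = []
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        stats_perm = internal_de_test(counts, labels[perm], depths)
        kept = np.array([int(g[1:]) for g in stats_perm.gene_id])
        a_kept = np.asarray(annotation)[kept]
        if refit_tau:
            from .inference import fit_gene_set
            res = fit_gene_set(stats_perm.z, stats_perm.se, a_kept, cfg, rng=rng)
            pool.append(res.pip)
        else:
            es = e_step(stats_perm.z, stats_perm.se, a_kept, tau, cfg, rng,
                        sigma_beta2=None)
            pool.append(es.pip)
    return np.concatenate(pool)


def gse_replicate_pvalue(
    seed: int,
    tau1: float,
    tau0: float = -2.0,
    cr: float = 0.1,
    n_genes: int = 10_000,
    group_sizes: tuple[int, int] = (105, 69),
    cfg: MCMCConfig | None = None,
) -> float:
    """One enrichment p-value from a full count-level simulation replicate.

    Reference-free ZTNB counts with dropout for ``n_genes`` genes over two
    cell groups, DE truth assigned by the logistic prior, summary statistics
    from the internal NB Wald test, then the enrichment fit; returns the
    Louis-corrected Wald p-value for tau1.
    """
    from .inference import fit_gene_set
    from .simulate import assign_truth, reference_free_params, simulate_counts

    rng = np.random.default_rng(seed)
    params, dropout, depths = reference_free_params(n_genes, sum(group_sizes), rng)
    truth = assign_truth(n_genes, cr, tau0, tau1, rng=rng)
    counts, labels, depths = simulate_counts(params, dropout, truth,
                                             group_sizes, depths, rng)
    stats_t = internal_de_test(counts, labels, depths)
    kept = np.array([int(g[1:]) for g in stats_t.gene_id])
    if cfg is None:
        cfg = MCMCConfig(n_sweeps=500, burn_in=250, seed=seed, em_n_sweeps=200)
    res = fit_gene_set(stats_t.z, stats_t.se, truth.a[kept], cfg)
    return res.p_value


def gse_power_study(
    n_enriched: int = 100,
    n_null: int = 400,
    tau1: float = 0.5,
    seed: int = 0,
    fdr_target: float = 0.05,
    **replicate_kwargs,
) -> dict:
    """Count-level GSE power study: enriched vs null replicates, power at FDR.

    Pools the enrichment p-values of ``n_enriched`` replicates simulated with
    the given ``tau1`` and ``n_null`` replicates with ``tau1 = 0``, then
    computes power at the target false-discovery rate against the known
    replicate labels. Per-replicate seeds derive deterministically from
    ``seed``.
    """
    from .gse import derive_set_seed

    p_alt = [
        gse_replicate_pvalue(derive_set_seed(seed, f"alt{i}"), tau1,
                             **replicate_kwargs)
        for i in range(n_enriched)
    ]
    p_null = [
        gse_replicate_pvalue(derive_set_seed(seed, f"null{i}"), 0.0,
                             **replicate_kwargs)
        for i in range(n_null)
    ]
    scores = -np.concatenate([p_alt, p_null])
    truth = np.concatenate([np.ones(n_enriched), np.zeros(n_null)]).astype(bool)
    power = power_at_fdr(scores, truth, fdr_target)
    return {
        "power": power,
        "p_enriched": np.asarray(p_alt),
        "p_null": np.asarray(p_null),
        "fdr_target": fdr_target,
    }


def jaccard_topk(list_a, list_b, k: int) -> float:
    """Jaccard index |A∩B| / |A∪B| of the top-k entries of two ranked lists."""
    if k > min(len(list_a), len(list_b)):
        raise ValueError("k exceeds a list length")
    top_a, top_b = set(list(list_a)[:k]), set(list(list_b)[:k])
    union = top_a | top_b
    return len(top_a & top_b) / len(union) if union else 1.0


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties split."""
    from sklearn.metrics import roc_auc_score

    truth = np.asarray(truth).astype(int)
    if truth.min() == truth.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))
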