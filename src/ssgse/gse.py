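"""Collection-level enrichment scanning, permutation nulls and calibration.

Each gene set is fitted independently (one set at a time) with a per-set seed
derived deterministically from a master seed and the set name, so results do
not depend on scan order or on which other sets are present. Permutation of
gene-set labels across the universe provides an empirical null for the
enrichment p-values, from which an empirical FDR is computed per threshold; a
genomic-control factor summarises calibration; a hypergeometric
over-representation test is provided as a count-based baseline.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import EnrichmentResult, MCMCConfig, fit_gene_set
from .io import GeneSetCollection, GeneStats

logger = logging.getLogger("ssgse")

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


@dataclass
class GSEScanResult:
    """Per-set enrichment table plus raw fit objects and the null p pool."""

    table: pd.DataFrame
    fits: dict[str, EnrichmentResult]
    null_p: np.ndarray | None = None


def derive_set_seed(master_seed: int, set_name: str) -> int:
    """Stable per-set seed: SHA-256 of (master_seed, set_name), below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{set_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_gse_scan(
    stats_table: GeneStats,
    collection: GeneSetCollection,
    cfg: MCMCConfig = MCMCConfig(),
    *,
    n_perm: int = 0,
    perm_mode: str = "joint",
    **fit_kwargs,
) -> GSEScanResult:
    """Fit every gene set in the collection; optionally build a permutation null.

    Per-set failures are recorded (NaN row) and the scan continues. With
    ``n_perm > 0`` the collection's labels are permuted ``n_perm`` times and
    rescanned to populate the null p-value pool and the empirical-FDR column.
    """
    z, se = stats_table.z, stats_table.se
    rows, fits = [], {}
    for name, a in collection.sets.items():
        seed = derive_set_seed(cfg.seed, name)
        set_cfg = MCMCConfig(cfg.n_sweeps, cfg.burn_in, seed,
                             cfg.em_max_iter, cfg.em_tol)
        try:
            res = fit_gene_set(z, se, a, set_cfg, **fit_kwargs)
        except (ValueError, FloatingPointError) as exc:
            logger.warning("gene set %s failed: %s", name, exc)
            rows.append({"set_name": name, "size": int(a.sum()),
                         "coverage": float(a.mean()), "p_value": np.nan})
            continue
        fits[name] = res
        rows.append({
            "set_name": name,
            "size": res.set_size,
            "coverage": res.coverage,
            "tau0": res.tau_hat[0],
            "tau1": res.tau_hat[1],
            "se_tau1": res.se_tau1,
            "p_value": res.p_value,
            "sigma_beta2": res.sigma_beta2_hat,
            "converged": res.converged,
        })
    table = pd.DataFrame(rows)

    null_p = None
    if n_perm > 0:
        rng = np.random.default_rng(derive_set_seed(cfg.seed, "__permutation__"))
        pool = []
        for perm in permute_set_labels(collection, n_perm, rng, mode=perm_mode):
            sub = run_gse_scan(stats_table, perm, cfg, n_perm=0, **fit_kwargs)
            pool.append(sub.table["p_value"].to_numpy())
        null_p = np.concatenate(pool)
        obs = table["p_value"].to_numpy()
        table["empirical_fdr"] = empirical_fdr(obs, null_p, n_perm)
    return GSEScanResult(table, fits, null_p)


def permute_set_labels(
    collection: GeneSetCollection,
    n_perm: int = 10,
    rng: np.random.Generator | None = None,
    mode: str = "joint",
) -> list[GeneSetCollection]:
    """Permute gene-set membership across the gene universe.

    mode="joint" (default) applies one random relabelling of the genes to all
    sets of a permutation simultaneously, which preserves every pairwise set
    overlap exactly; mode="independent" shuffles each set's membership
    independently, preserving only the set sizes. Both preserve each set's
    size exactly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    p = len(collection.universe)
    out = []
    for _ in range(n_perm):
        if mode == "joint":
            order = rng.permutation(p)
            sets = {name: a[order] for name, a in collection.sets.items()}
        elif mode == "independent":
            sets = {name: rng.permutation(a) for name, a in collection.sets.items()}
        else:
            raise ValueError(f"unknown permutation mode {mode!r}")
        out.append(GeneSetCollection(list(collection.universe), sets,
                                     dict(collection.provenance)))
    return out


def empirical_fdr(observed_p: np.ndarray, null_p: np.ndarray, n_perm: int) -> np.ndarray:
    """Permutation-based FDR at each observed p-value.

    ``FDR(t) = [#{null p <= t} / n_perm] / max(1, #{observed p <= t})``,
    monotonised by a cumulative minimum from the largest threshold down.
    Returns the per-observation FDR (clipped to [0, 1]); NaN observations get
    NaN.
    """
    observed_p = np.asarray(observed_p, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    null_p = null_p[np.isfinite(null_p)]
    if null_p.size == 0:
        raise ValueError("empty permutation-null p-value pool")
    finite = np.isfinite(observed_p)
    obs = observed_p[finite]
    order = np.argsort(obs)
    sorted_p = obs[order]
    n_null_le = np.searchsorted(np.sort(null_p), sorted_p, side="right")
    n_obs_le = np.arange(1, len(sorted_p) + 1)
    raw = (n_null_le / n_perm) / np.maximum(1, n_obs_le)
    fdr_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    fdr_sorted = np.clip(fdr_sorted, 0.0, 1.0)
    out = np.full(observed_p.shape, np.nan)
    fin = np.empty(len(sorted_p))
    fin[order] = fdr_sorted
    out[finite] = fin
    return out


def genomic_control_lambda(p: np.ndarray) -> float:
    """Genomic-control factor: median observed chi2_1 statistic / 0.4549364.

    p-values are converted to chi-square(1 df) statistics via the inverse
    upper tail; lambda near 1 indicates calibrated tests.
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2_stats = stats.chi2.isf(p, df=1)
    return float(np.median(chi2_stats) / CHI2_1_MEDIAN)


def hypergeometric_gse(
    stats_table: GeneStats, a: np.ndarray, de_threshold: float = 0.05
) -> float:
    """Hypergeometric over-representation baseline.

    Genes with input p-value below ``de_threshold`` are called DE; the
    one-sided tail probability of seeing at least the observed number of DE
    genes inside the set is returned.
    """
    if not (0 < de_threshold < 1):
        raise ValueError("de_threshold must lie in (0, 1)")
    a = np.asarray(a).astype(bool)
    de = stats_table.p < de_threshold
    n_universe = len(de)
    n_de = int(de.sum())
    n_set = int(a.sum())
    k = int((de & a).sum())
    return float(stats.hypergeom.sf(k - 1, n_universe, n_de, n_set))
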