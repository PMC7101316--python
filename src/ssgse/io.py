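"""Reading, validating and completing DE summary statistics and gene sets.

Summary statistics arrive as delimited text with one row per gene and any of
several column combinations: effect size and standard error, effect size and
p-value, a signed z-score, or a p-value plus a sign column. The four canonical
fields (beta_hat, se, z, p) are completed from whichever subset is present
using the standard normal relations

    z = beta_hat / se,      p = 2 * (1 - Phi(|z|)),
    z = Phi^{-1}(1 - p/2) * sign,      se = |beta_hat / z|.

Gene sets are read from GMT files (or a two-column long-format TSV) and held
as binary membership vectors over an ordered gene universe — by convention the
genes present in the validated summary-statistics table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ssgse")

P_CLAMP = 1e-300  # p-values clamped here before the normal quantile transform

CANONICAL_COLUMNS = ["gene_id", "beta_hat", "se", "z", "p"]


class InputError(ValueError):
    """Malformed or empty input data."""


class ConfigError(ValueError):
    """Unresolvable column mapping or option set."""


@dataclass
class GeneStats:
    """Validated per-gene DE summary statistics.

    Wraps a DataFrame with columns gene_id, beta_hat, se, z, p. All four
    numeric fields are populated and mutually consistent; se > 0; gene ids
    unique. ``n_dropped`` counts rows removed during validation.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"GeneStats table missing columns: {missing}")
        dup = self.table["gene_id"][self.table["gene_id"].duplicated()]
        if len(dup):
            raise InputError(f"duplicate gene_id values: {sorted(set(dup))[:5]}")
        if len(self.table) == 0:
            raise InputError("GeneStats table is empty")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_id(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()

    @property
    def beta_hat(self) -> np.ndarray:
        return self.table["beta_hat"].to_numpy(dtype=float)

    @property
    def se(self) -> np.ndarray:
        return self.table["se"].to_numpy(dtype=float)

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(dtype=float)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Named gene sets as binary membership vectors over an ordered universe."""

    universe: list[str]
    sets: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        p = len(self.universe)
        for name, a in self.sets.items():
            a = np.asarray(a, dtype=np.int8)
            if a.shape != (p,):
                raise InputError(
                    f"membership vector for {name!r} has length {a.shape}, "
                    f"universe has {p}"
                )
            self.sets[name] = a

    def size(self, name: str) -> int:
        return int(self.sets[name].sum())

    def coverage(self, name: str) -> float:
        """Coverage rate: fraction of the universe inside the set."""
        return self.size(name) / len(self.universe)

    def __len__(self) -> int:
        return len(self.sets)


def zscore_from_pvalue(p, sign) -> np.ndarray | float:
    """Signed z-score from a two-sided p-value: ``Phi^{-1}(1 - p/2) * sign``.

    ``p`` is clamped below at 1e-300 before the quantile transform to avoid
    infinities. Raises :class:`InputError` for p <= 0 or p > 1.
    """
    p_arr = np.asarray(p, dtype=float)
    s = np.sign(np.asarray(sign, dtype=float))
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise InputError("p-values must lie in (0, 1]")
    out = stats.norm.isf(np.clip(p_arr, P_CLAMP, None) / 2.0) * np.where(s == 0, 1.0, s)
    return float(out) if out.ndim == 0 else out


def se_from_beta_and_z(beta_hat, z) -> np.ndarray | float:
    """Back-derived standard error ``|beta_hat / z|``; NaN where z == 0.

    Genes with z == 0 have an undefined standard error and are excluded from
    model fitting downstream (the NaN is the exclusion flag).
    """
    beta = np.asarray(beta_hat, dtype=float)
    z_arr = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(z_arr == 0.0, np.nan, np.abs(beta / z_arr))
    return float(out) if out.ndim == 0 else out


def _pvalue_from_z(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    max_p: float | None = None,
) -> GeneStats:
    """Read and complete a summary-statistics table.

    ``column_map`` maps canonical names (gene_id, beta_hat, se, z, p, sign)
    to columns of the file; unmapped canonical names are matched
    case-insensitively against a list of common aliases (gene, logFC,
    log2FoldChange, lfcSE, coef, pvalue, ...). At least one of
    {(beta_hat, se), (beta_hat, p), (z,), (p, sign)} must resolve.

    ``max_p`` optionally drops genes whose completed two-sided p-value
    exceeds it — useful when the upstream DE tool's null p-value
    distribution is skewed and its large p-values are uninformative. Rows
    whose completed fields are non-finite or have se <= 0 are dropped with a
    logged count. Returns a validated :class:`GeneStats`.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if len(df) == 0:
        raise InputError(f"empty summary-statistics file: {path}")
    resolved = _resolve_columns(df.columns, column_map or {})
    out = complete_summary_stats(df, resolved)
    if max_p is not None:
        keep = out.p <= max_p
        n_cut = int((~keep).sum())
        if n_cut:
            logger.info("dropped %d genes with p > %g", n_cut, max_p)
        out = GeneStats(out.table[keep], n_dropped=out.n_dropped + n_cut)
    return out


_ALIASES = {
    "gene_id": ["gene_id", "gene", "genes", "symbol", "id"],
    "beta_hat": ["beta_hat", "beta", "log2foldchange", "logfc", "coef", "effect"],
    "se": ["se", "lfcse", "stderr", "std_err"],
    "z": ["z", "zscore", "z_score", "stat"],
    "p": ["p", "pvalue", "p_value", "pval"],
    "sign": ["sign"],
}


def _resolve_columns(columns, column_map: dict[str, str]) -> dict[str, str]:
    lower = {str(c).lower(): c for c in columns}
    resolved = {}
    for canon, explicit in column_map.items():
        if explicit not in columns:
            raise ConfigError(f"mapped column {explicit!r} for {canon!r} not in file")
        resolved[canon] = explicit
    for canon, aliases in _ALIASES.items():
        if canon in resolved:
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    if "gene_id" not in resolved:
        raise ConfigError("no gene identifier column resolvable")
    have = set(resolved)
    combos = [{"beta_hat", "se"}, {"beta_hat", "p"}, {"z"}, {"p", "sign"}]
    if not any(c <= have for c in combos):
        raise ConfigError(
            "need one of (beta_hat, se), (beta_hat, p), (z), or (p, sign); "
            f"resolved only {sorted(have)}"
        )
    return resolved


def complete_summary_stats(df: pd.DataFrame, resolved: dict[str, str]) -> GeneStats:
    """Populate all four canonical fields from whichever subset is present."""
    n0 = len(df)
    gene_id = df[resolved["gene_id"]].astype(str).to_numpy()
    get = lambda k: (
        df[resolved[k]].to_numpy(dtype=float) if k in resolved else None
    )
    beta, se, z, p = get("beta_hat"), get("se"), get("z"), get("p")
    sign = get("sign")

    if beta is not None and se is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        p = _pvalue_from_z(z)
    elif beta is not None and p is not None:
        z = zscore_from_pvalue(np.clip(p, P_CLAMP, 1.0), np.sign(beta))
        se = se_from_beta_and_z(beta, z)
        p = np.asarray(p, dtype=float)
    elif z is not None:
        p = _pvalue_from_z(z)
        if beta is not None and se is None:
            se = se_from_beta_and_z(beta, z)
        else:
            # scale-invariant fallback: work directly on the z scale
            beta, se = z.copy(), np.ones_like(z)
    else:  # (p, sign)
        z = zscore_from_pvalue(np.clip(p, P_CLAMP, 1.0), sign)
        beta, se = z.copy(), np.ones_like(z)

    out = pd.DataFrame(
        {"gene_id": gene_id, "beta_hat": beta, "se": se, "z": z, "p": p}
    )
    finite = np.isfinite(out[["beta_hat", "se", "z", "p"]].to_numpy()).all(axis=1)
    valid = finite & (out["se"].to_numpy() > 0)
    n_dropped = int(n0 - valid.sum())
    if n_dropped:
        logger.info("dropped %d/%d genes with invalid summary statistics", n_dropped, n0)
    return GeneStats(out[valid], n_dropped=n_dropped)


def write_summary_stats(stats_table: GeneStats, path) -> None:
    """Write the canonical five-column table as TSV, 12 significant digits."""
    stats_table.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gmt(path, universe: list[str]) -> GeneSetCollection:
    """Read a GMT file (set name, description, member genes; tab-separated).

    Membership vectors are computed against ``universe``; member genes absent
    from the universe are ignored with a logged count. Duplicate set names are
    disambiguated by suffixing (_2, _3, ...).
    """
    index = {g: i for i, g in enumerate(universe)}
    sets: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    n_ignored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}: malformed GMT line {lineno} (<3 tab-separated fields)"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            a = np.zeros(len(universe), dtype=np.int8)
            for g in members:
                i = index.get(g)
                if i is None:
                    n_ignored += 1
                else:
                    a[i] = 1
            name = _dedup_name(name, sets)
            sets[name] = a
            provenance[name] = desc
    if n_ignored:
        logger.info("ignored %d gene-set members absent from the universe", n_ignored)
    return GeneSetCollection(list(universe), sets, provenance)


def read_long_tsv(path, universe: list[str]) -> GeneSetCollection:
    """Read a two-column long-format (set_name, gene) TSV with header."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"{path}: long-format gene sets need two columns")
    set_col, gene_col = df.columns[:2]
    index = {g: i for i, g in enumerate(universe)}
    sets: dict[str, np.ndarray] = {}
    n_ignored = 0
    for name, sub in df.groupby(set_col, sort=False):
        a = np.zeros(len(universe), dtype=np.int8)
        for g in sub[gene_col].astype(str):
            i = index.get(g)
            if i is None:
                n_ignored += 1
            else:
                a[i] = 1
        sets[str(name)] = a
    if n_ignored:
        logger.info("ignored %d gene-set members absent from the universe", n_ignored)
    return GeneSetCollection(list(universe), sets)


def _dedup_name(name: str, existing: dict) -> str:
    if name not in existing:
        return name
    k = 2
    while f"{name}_{k}" in existing:
        k += 1
    return f"{name}_{k}"


def prune_gene_sets(
    collection: GeneSetCollection, min_size: int = 20
) -> GeneSetCollection:
    """Drop gene sets with fewer than ``min_size`` members in the universe.

    The default of 20 reflects the common practice of excluding small sets,
    for which enrichment-parameter estimation is unstable. Idempotent.
    """
    if min_size < 1:
        raise InputError("min_size must be >= 1")
    kept = {
        name: a for name, a in collection.sets.items() if int(a.sum()) >= min_size
    }
    logger.info("pruned gene sets: kept %d/%d (min_size=%d)",
                len(kept), len(collection.sets), min_size)
    return GeneSetCollection(
        list(collection.universe),
        kept,
        {k: v for k, v in collection.provenance.items() if k in kept},
    )
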