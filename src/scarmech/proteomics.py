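"""Label-free differential proteomics with s0-moderated permutation FDR.

Implements the Perseus-style analysis chain for MaxQuant proteinGroups
tables: QC filtering of decoy/contaminant/site-only identifications, the
valid-value rule with presence/absence handling and down-shifted imputation,
an s0-moderated two-sample statistic

    t_s0 = (mean(B) - mean(A)) / (s + s0)

where ``s`` is the pooled two-sample standard error and ``s0`` a small
constant (0.1 by default) damping low-variance artifacts, SAM-style
permutation estimation of the false discovery rate, fold-change
classification, row Z-scoring for heatmaps, matrisome annotation, a
cross-species regulation screen over ortholog pairs, and hypergeometric
over-representation analysis with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AbundanceMatrix",
    "CrossSpeciesResult",
    "load_protein_groups",
    "write_protein_groups",
    "filter_and_impute",
    "sam_statistic",
    "permutation_fdr",
    "classify_regulation",
    "zscore_rows",
    "annotate_matrisome",
    "cross_species_screen",
    "ora_enrichment",
    "differential_analysis",
]

FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "identified_by_site": "Only identified by site",
}
LFQ_PREFIX = "LFQ intensity "


@dataclass
class AbundanceMatrix:
    """Proteins x samples log2 LFQ intensities with condition labels and QC flags.

    ``intensities`` is indexed by protein id with one column per sample
    (NaN = invalid/missing value); ``conditions`` maps every sample to
    exactly one condition; ``flags`` holds the boolean QC columns
    reverse / contaminant / identified_by_site per protein.
    """

    intensities: pd.DataFrame
    conditions: pd.Series
    gene_symbols: pd.Series | None = None
    flags: pd.DataFrame | None = None
    presence_absence: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate protein ids: {list(dups[:5])}")
        missing = set(self.intensities.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition assignment: {sorted(missing)}")
        self.conditions = self.conditions.loc[list(self.intensities.columns)]
        if self.conditions.nunique() < 2:
            raise ValueError("need at least two conditions")
        if self.flags is None:
            self.flags = pd.DataFrame(False, index=self.intensities.index,
                                      columns=list(FLAG_COLUMNS))
        if not all(self.flags.dtypes == bool):
            raise ValueError("QC flags must be boolean")

    @property
    def condition_names(self) -> list[str]:
        return list(pd.unique(self.conditions))

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


def load_protein_groups(path, conditions: dict[str, str], *,
                        id_column: str = "Protein IDs",
                        gene_column: str = "Gene names") -> AbundanceMatrix:
    """Read a proteinGroups-style TSV into an :class:`AbundanceMatrix`.

    Intensity columns are recognised by the ``"LFQ intensity "`` prefix,
    log2-transformed, and zeros treated as missing.  ``conditions`` maps each
    sample name (the column suffix) to its condition.
    """
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns:
        raise ValueError(f"missing required column {id_column!r}")
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError("no 'LFQ intensity <sample>' columns found")
    samples = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    unassigned = [s for s in samples if s not in conditions]
    if unassigned:
        raise ValueError(f"samples without condition assignment: {unassigned}")

    raw = df[lfq_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    raw[raw <= 0] = np.nan
    intens = pd.DataFrame(np.log2(raw), index=df[id_column], columns=samples)

    flags = pd.DataFrame(index=intens.index)
    for key, col in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[key] = (df[col].fillna("").astype(str).str.strip() == "+").to_numpy()
        else:
            flags[key] = False
    genes = (pd.Series(df[gene_column].to_numpy(), index=intens.index)
             if gene_column in df.columns else None)
    return AbundanceMatrix(intensities=intens,
                           conditions=pd.Series(conditions),
                           gene_symbols=genes, flags=flags)


def write_protein_groups(m: AbundanceMatrix, path) -> None:
    """Write an :class:`AbundanceMatrix` back to proteinGroups-dialect TSV.

    Log2 intensities are de-logged; missing values become 0, matching the
    MaxQuant convention read by :func:`load_protein_groups`.
    """
    out = pd.DataFrame({"Protein IDs": m.intensities.index})
    if m.gene_symbols is not None:
        out["Gene names"] = m.gene_symbols.to_numpy()
    for s in m.intensities.columns:
        linear = np.exp2(m.intensities[s].to_numpy())
        out[LFQ_PREFIX + s] = np.where(np.isfinite(linear), linear, 0.0)
    for key, col in FLAG_COLUMNS.items():
        out[col] = np.where(m.flags[key].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)


def filter_and_impute(m: AbundanceMatrix, mode: str = "presence_absence", *,
                      seed: int = 0, shift: float = 1.8,
                      width: float = 0.3) -> AbundanceMatrix:
    """Apply the valid-value rules and impute presence/absence rows.

    QC-flagged rows (reverse, contaminant, identified-by-site) are always
    removed.  Then:

    ``mode="presence_absence"``
        Rows with any missing value are removed, except rows completely
        missing in exactly one condition and fully valid in the other; those
        are retained, marked presence/absence, and their missing side is
        imputed from a down-shifted normal per sample,
        N(sample_mean - shift*sample_sd, (width*sample_sd)**2), with the run
        seed.  This keeps proteins undetectable in one condition but clearly
        present in the other.

    ``mode="strict"``
        Only rows valid in every sample are kept.
    """
    if mode not in ("presence_absence", "strict"):
        raise ValueError(f"unknown rule {mode!r}")
    keep = ~m.flags.any(axis=1)
    intens = m.intensities.loc[keep].copy()

    valid = intens.notna()
    all_valid = valid.all(axis=1)
    if mode == "strict":
        sel = intens.loc[all_valid]
        pa = pd.Series(False, index=sel.index)
    else:
        conds = m.condition_names
        full_by_cond = pd.DataFrame(
            {c: valid[m.samples_of(c)].all(axis=1) for c in conds})
        empty_by_cond = pd.DataFrame(
            {c: (~valid[m.samples_of(c)]).all(axis=1) for c in conds})
        # fully absent in exactly one condition, fully valid in all others
        pa_rows = (empty_by_cond.sum(axis=1) == 1) & \
                  ((full_by_cond | empty_by_cond).all(axis=1))
        sel = intens.loc[all_valid | pa_rows].copy()
        pa = pa_rows.loc[sel.index]

        rng = np.random.default_rng(seed)
        all_obs = intens.to_numpy(float)
        all_obs = all_obs[np.isfinite(all_obs)]
        for s in sel.columns:
            col = sel[s]
            obs = intens[s].dropna()
            # fall back to the matrix-wide spread for sparse columns
            scale = obs.std(ddof=1) if len(obs) >= 3 else np.nan
            if not np.isfinite(scale) or scale == 0:
                scale = float(all_obs.std(ddof=1)) if all_obs.size >= 2 else 1.0
            mu = (obs.mean() if len(obs) else float(all_obs.mean())) - shift * scale
            sd = width * scale
            n_missing = int(col.isna().sum())
            if n_missing:
                sel.loc[col.isna(), s] = rng.normal(mu, sd, size=n_missing)

    return AbundanceMatrix(
        intensities=sel,
        conditions=m.conditions.copy(),
        gene_symbols=None if m.gene_symbols is None else m.gene_symbols.loc[sel.index],
        flags=m.flags.loc[sel.index],
        presence_absence=pa,
    )


def sam_statistic(group_a, group_b, s0: float = 0.1):
    """s0-moderated two-sample statistic t_s0 = (mean(B)-mean(A)) / (s + s0).

    ``s`` is the pooled two-sample standard error of the mean difference.
    Inputs may be 1-D (one feature) or 2-D with features on rows.  Reduces to
    the classical pooled two-sample t-statistic when ``s0 = 0``.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = ((na - 1) * a.var(axis=1, ddof=1)
                  + (nb - 1) * b.var(axis=1, ddof=1)) / (na + nb - 2)
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    t = (b.mean(axis=1) - a.mean(axis=1)) / (se + s0)
    return float(t[0]) if np.ndim(group_a) == 1 else t


def _label_splits(n_total: int, n_a: int, n_perm: int, rng: np.random.Generator,
                  *, exclude_observed: bool = False):
    """Distinct assignments of n_a out of n_total columns to group A.

    Exhaustive when there are at most ``n_perm`` distinct splits, otherwise a
    seeded random subset of size ``n_perm``.  With ``exclude_observed`` the
    observed labeling (columns 0..n_a-1 to group A) and, for balanced
    designs, its mirror image are dropped: both reproduce |t_obs| exactly and
    belong to the alternative, not the permutation null.
    """
    identity = tuple(range(n_a))
    mirror = tuple(range(n_a, n_total)) if n_total == 2 * n_a else None
    banned = {identity, mirror} if exclude_observed else set()

    n_splits = math.comb(n_total, n_a)
    if n_splits <= n_perm + len(banned):
        return [np.array(c) for c in itertools.combinations(range(n_total), n_a)
                if c not in banned]
    splits: list[np.ndarray] = []
    seen = set(banned)
    while len(splits) < n_perm:
        c = tuple(sorted(rng.choice(n_total, size=n_a, replace=False)))
        if c not in seen:
            seen.add(c)
            splits.append(np.array(c))
    return splits


def permutation_fdr(m: AbundanceMatrix, *, condition_a: str | None = None,
                    condition_b: str | None = None, s0: float = 0.1,
                    n_perm: int = 250, seed: int = 0, fdr: float = 0.1,
                    estimator: str = "mean") -> pd.DataFrame:
    """SAM-style permutation FDR over all proteins of a filtered matrix.

    For every candidate cut on the observed |t_s0| ranking, the estimated FDR
    is the mean (pooled over permutations, the Perseus convention) or median
    (the classical SAM counting rule) number of permuted statistics exceeding
    the cut divided by the number of observed statistics exceeding it.  The
    pooled mean is the default: with few distinct label splits the median of
    the per-permutation counts collapses to zero too easily, overstating
    confidence on null data.  Each
    protein's q-value is the smallest estimated FDR over cuts that would call
    it; proteins with q < ``fdr`` are flagged significant.  Label splits are
    exhaustive when few enough, otherwise a seeded random subset.

    Returns a DataFrame indexed like the matrix with columns ``log2fc``
    (B - A), ``t``, ``q`` and ``significant``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if estimator not in ("median", "mean"):
        raise ValueError(f"unknown estimator {estimator!r}")
    conds = m.condition_names
    condition_a = condition_a or conds[0]
    condition_b = condition_b or conds[1]
    cols_a = m.samples_of(condition_a)
    cols_b = m.samples_of(condition_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples per condition")
    x = m.intensities[cols_a + cols_b].to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains missing values; run filter_and_impute first")
    na = len(cols_a)

    t_obs = sam_statistic(x[:, :na], x[:, na:], s0)
    log2fc = x[:, na:].mean(axis=1) - x[:, :na].mean(axis=1)
    abs_obs = np.abs(t_obs)

    rng = np.random.default_rng(seed)
    splits = _label_splits(x.shape[1], na, n_perm, rng, exclude_observed=True)
    perm_sorted = []
    for idx_a in splits:
        idx_b = np.setdiff1d(np.arange(x.shape[1]), idx_a)
        t_perm = sam_statistic(x[:, idx_a], x[:, idx_b], s0)
        perm_sorted.append(np.sort(np.abs(t_perm)))
    perm_sorted = np.array(perm_sorted)          # (n_splits, n_prot) ascending

    order = np.argsort(-abs_obs, kind="stable")  # descending |t|
    thresholds = abs_obs[order]
    n_prot = len(abs_obs)
    obs_counts = np.arange(1, n_prot + 1)
    # counts of permuted |t| >= each threshold, per split
    perm_counts = n_prot - np.array(
        [np.searchsorted(row, thresholds, side="left") for row in perm_sorted])
    # add-one smoothing: the observed labeling is itself one admissible
    # relabeling, so the estimated FDR can never be exactly zero
    perm_counts = np.vstack([perm_counts, obs_counts])
    agg = np.median(perm_counts, axis=0) if estimator == "median" \
        else perm_counts.mean(axis=0)
    fdr_at_cut = np.minimum(agg / obs_counts, 1.0)
    q_sorted = np.minimum.accumulate(fdr_at_cut[::-1])[::-1]
    q = np.empty(n_prot)
    q[order] = q_sorted

    return pd.DataFrame({
        "log2fc": log2fc,
        "t": t_obs,
        "q": q,
        "significant": q < fdr,
    }, index=m.intensities.index)


def classify_regulation(log2fc, significant, fc_threshold: float = 1.3):
    """Regulation class from fold change and FDR significance.

    ``up`` iff significant and log2fc >= log2(fc_threshold); ``down`` iff
    significant and log2fc <= -log2(fc_threshold); else ``ns``.
    """
    if fc_threshold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    cut = np.log2(fc_threshold)
    log2fc = np.asarray(log2fc, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    cls = np.where(significant & (log2fc >= cut), "up",
                   np.where(significant & (log2fc <= -cut), "down", "ns"))
    return cls.item() if cls.ndim == 0 else cls


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0 and sample SD 1 (heatmap Z-scores)."""
    x = matrix.to_numpy(float)
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        bad = matrix.index[(sd == 0) | ~np.isfinite(sd)]
        raise ValueError(f"constant or invalid rows cannot be Z-scored: {list(bad[:5])}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def annotate_matrisome(ids, annotation: pd.DataFrame, *, key: str = "gene",
                       normalizer=None) -> pd.DataFrame:
    """Left-join ids against a matrisome annotation table.

    ``annotation`` must contain the ``key`` column plus ``division`` (core
    matrisome / matrisome-associated / putative) and optionally ``category``
    and ``mammalian_ortholog``.  Unmatched ids get division
    ``"non-matrisome"``.  ``normalizer`` is an optional callable applied to
    both sides of the join key (e.g. ``str.casefold``).
    """
    ann = annotation.copy()
    norm = normalizer if normalizer is not None else (lambda s: s)
    ann["_key"] = [norm(str(v)) for v in ann[key]]
    if ann["_key"].duplicated().any():
        dups = ann.loc[ann["_key"].duplicated(), key]
        raise ValueError(f"duplicate annotation keys: {list(dups[:5])}")
    left = pd.DataFrame({key: list(ids)})
    left["_key"] = [norm(str(v)) for v in left[key]]
    out = left.merge(ann.drop(columns=[key]), on="_key", how="left").drop(columns="_key")
    out["division"] = out["division"].fillna("non-matrisome")
    out["is_matrisome"] = out["division"] != "non-matrisome"
    return out.set_index(key)


#: screen bucket names
BUCKET_A_UP = "a_up_b_down_or_ns"
BUCKET_B_UP = "a_down_or_ns_b_up"
BUCKET_CONCORDANT = "concordant"
BUCKET_OTHER = "other"


@dataclass
class CrossSpeciesResult:
    """Ortholog-matched regulation screen between two species' results."""

    table: pd.DataFrame              # index ortholog pair, class_a, class_b, bucket
    counts: dict[str, int]
    dropped_ambiguous: list[tuple] = field(default_factory=list)


def cross_species_screen(res_a: pd.DataFrame, res_b: pd.DataFrame,
                         ortholog_map: pd.DataFrame) -> CrossSpeciesResult:
    """Bucket ortholog pairs by their regulation classes in two species.

    ``res_a``/``res_b`` are per-gene tables with a ``class`` column (up /
    down / ns) and a ``t`` column, indexed by gene.  ``ortholog_map`` has
    columns ``gene_a`` and ``gene_b``.  Many-to-many mappings are resolved to
    the highest-|t| representative on each side; the discarded pairs are
    reported in ``dropped_ambiguous``.

    Buckets partition the matched set: species-A up while B is down or n.s.;
    B up while A is down or n.s.; concordant (same class); other.
    """
    pairs = ortholog_map[["gene_a", "gene_b"]].dropna()
    pairs = pairs[pairs["gene_a"].isin(res_a.index) & pairs["gene_b"].isin(res_b.index)]

    dropped: list[tuple] = []
    for col, res in (("gene_a", res_a), ("gene_b", res_b)):
        dup = pairs[col].duplicated(keep=False)
        if dup.any():
            other = "gene_b" if col == "gene_a" else "gene_a"
            other_res = res_b if col == "gene_a" else res_a
            keep_rows = []
            for _, grp in pairs[dup].groupby(col):
                strength = grp[other].map(lambda g: abs(other_res.loc[g, "t"]))
                winner = strength.idxmax()
                keep_rows.append(winner)
                dropped.extend(tuple(r) for i, r in grp.iterrows() if i != winner)
            pairs = pd.concat([pairs[~dup], pairs.loc[keep_rows]])

    cls_a = pairs["gene_a"].map(res_a["class"]).to_numpy()
    cls_b = pairs["gene_b"].map(res_b["class"]).to_numpy()
    bucket = np.where((cls_a == "up") & (cls_b != "up"), BUCKET_A_UP,
              np.where((cls_b == "up") & (cls_a != "up"), BUCKET_B_UP,
               np.where(cls_a == cls_b, BUCKET_CONCORDANT, BUCKET_OTHER)))
    table = pd.DataFrame({
        "gene_a": pairs["gene_a"].to_numpy(),
        "gene_b": pairs["gene_b"].to_numpy(),
        "class_a": cls_a, "class_b": cls_b, "bucket": bucket,
    })
    counts = {b: int((bucket == b).sum())
              for b in (BUCKET_A_UP, BUCKET_B_UP, BUCKET_CONCORDANT, BUCKET_OTHER)}
    return CrossSpeciesResult(table=table, counts=counts, dropped_ambiguous=dropped)


def ora_enrichment(foreground, background, gene_sets: dict) -> pd.DataFrame:
    """Over-representation analysis: hypergeometric upper tail + Bonferroni.

    For each set, with N background genes, K of them in the set, n foreground
    genes and k of those in the set, the p-value is P(X >= k) for
    X ~ Hypergeom(N, K, n).  Bonferroni multiplies by the number of tested
    sets; sets with adjusted p <= 0.05 are flagged significant.
    """
    fg, bg = set(foreground), set(background)
    if not bg:
        raise ValueError("empty background")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    n_total, n_fg, m_sets = len(bg), len(fg), len(gene_sets)
    rows = []
    for name, genes in gene_sets.items():
        in_bg = set(genes) & bg
        k = len(in_bg & fg)
        p = float(hypergeom.sf(k - 1, n_total, len(in_bg), n_fg))
        rows.append({"set": name, "overlap": k, "set_size": len(in_bg),
                     "p": p, "p_bonferroni": min(1.0, m_sets * p)})
    df = pd.DataFrame(rows).set_index("set")
    df["significant"] = df["p_bonferroni"] <= 0.05
    return df


def differential_analysis(m: AbundanceMatrix, *, mode: str = "presence_absence",
                          s0: float = 0.1, fdr: float = 0.1,
                          fc_threshold: float = 1.3, n_perm: int = 250,
                          seed: int = 0) -> pd.DataFrame:
    """Full chain: filter/impute -> permutation FDR -> regulation classes.

    Returns the :func:`permutation_fdr` table plus ``class`` and
    ``presence_absence`` columns.
    """
    filtered = filter_and_impute(m, mode, seed=seed)
    res = permutation_fdr(filtered, s0=s0, n_perm=n_perm, seed=seed, fdr=fdr)
    res["class"] = classify_regulation(res["log2fc"].to_numpy(),
                                       res["significant"].to_numpy(), fc_threshold)
    res["presence_absence"] = filtered.presence_absence.reindex(res.index).fillna(False)
    return res
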