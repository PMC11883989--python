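"""Transcriptomic statistics: normalization, DE, GSEA, ORA, ΔΔCt.

The workflow mirrors a bulk RNA-seq comparison of injured vs. uninjured
retinal ganglion cell layers: counts are normalized by the median-of-ratios
(size factor) method, differential expression is called by a two-group
permutation test on log fold change with Benjamini-Hochberg FDR, pathway
enrichment uses the weighted Kolmogorov-Smirnov running-sum statistic with
a phenotype-permutation null (normalized enrichment scores and permutation
FDR), over-representation of a fixed gene list is scored with the
hypergeometric upper tail and the (k/n)/(m/N) enrichment ratio, and qPCR
quantification uses the delta-delta Ct method against a reference gene.

The permutation DE test deliberately replaces a parametric
negative-binomial fit: with a handful of replicates per group an exact or
Monte-Carlo relabelling test preserves the downstream thresholds
(FDR < 0.05, |log2FC| > 1) without distributional assumptions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "median_ratio_normalize",
    "de_test",
    "de_filter",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "common_genes",
    "ora",
    "ddct",
    "bh_adjust",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def median_ratio_normalize(counts: pd.DataFrame
                           ) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    ``counts`` is genes x samples.  Reference genes are those with strictly
    positive counts in every sample; each sample's size factor is the
    median over reference genes of count / geometric-mean(count across
    samples), standardized to unit geometric mean so that normalizing an
    already-normalized matrix is a no-op; normalized counts are raw counts
    divided by the factor.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no reference genes: no gene has positive counts "
                         "in every sample")
    ref = x[all_positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / factors
    return sf, normalized


# ---------------------------------------------------------------------------
# Differential expression (permutation test)
# ---------------------------------------------------------------------------

EXHAUSTIVE_LIMIT = 1000


def _group_masks(groups, columns) -> tuple[np.ndarray, list]:
    g = pd.Series(list(groups), index=columns)
    labels = list(dict.fromkeys(g))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    return (g == labels[1]).to_numpy(), labels


def de_test(normalized: pd.DataFrame, groups, *, n_perm: int = 1000,
            seed: int = 0, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene log2 fold change with permutation p and BH FDR.

    ``log2fc = log2((mean2 + pc) / (mean1 + pc))`` (second group over
    first, in group-label order of appearance).  The two-sided p-value
    comes from relabelling the samples: when at most 1000 distinct label
    assignments exist they are enumerated exhaustively and
    ``p = #(non-identity assignments with |stat| >= |observed|) /
    (#assignments - 1)``; otherwise ``n_perm`` Monte-Carlo relabellings are
    drawn with ``seed`` and ``p = (b + 1) / (n_perm + 1)``.
    """
    X = normalized.to_numpy(dtype=float)
    is2, labels = _group_masks(groups, normalized.columns)
    n2 = int(is2.sum())
    n1 = int((~is2).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    S = n1 + n2
    pc = float(pseudocount)

    def stats_for(assign: np.ndarray) -> np.ndarray:
        # assign: S x K boolean, True = group 2
        m2 = X @ assign / n2
        m1 = X @ (~assign) / n1
        return np.log2(m2 + pc) - np.log2(m1 + pc)

    obs = stats_for(is2[:, None])[:, 0]

    n_assign = math.comb(S, n2)
    if n_assign <= EXHAUSTIVE_LIMIT:
        assigns = np.zeros((S, n_assign), dtype=bool)
        identity_col = None
        for k, idx in enumerate(itertools.combinations(range(S), n2)):
            assigns[list(idx), k] = True
            if np.array_equal(assigns[:, k], is2):
                identity_col = k
        stats_all = stats_for(assigns)
        keep = np.ones(n_assign, dtype=bool)
        keep[identity_col] = False
        exceed = (np.abs(stats_all[:, keep])
                  >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)
        p = exceed / (n_assign - 1)
    else:
        rng = np.random.default_rng(seed)
        assigns = np.zeros((S, n_perm), dtype=bool)
        for k in range(n_perm):
            assigns[rng.choice(S, size=n2, replace=False), k] = True
        stats_all = stats_for(assigns)
        exceed = (np.abs(stats_all)
                  >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)
        p = (exceed + 1) / (n_perm + 1)

    p = np.minimum(p, 1.0)
    out = pd.DataFrame({"gene": normalized.index, "log2fc": obs, "p": p,
                        "fdr": bh_adjust(p)})
    out.attrs["comparison"] = f"{labels[1]} vs {labels[0]}"
    out.attrs["method"] = ("exhaustive permutation"
                           if n_assign <= EXHAUSTIVE_LIMIT
                           else f"Monte-Carlo permutation (n_perm={n_perm}, "
                                f"seed={seed})")
    return out


def de_filter(results: pd.DataFrame, fc_thresh: float = 1.0,
              fdr_thresh: float = 0.05) -> tuple[list, list]:
    """Up / down gene lists at strict |log2FC| and FDR thresholds."""
    up = results.loc[(results["log2fc"] > fc_thresh)
                     & (results["fdr"] < fdr_thresh), "gene"]
    down = results.loc[(results["log2fc"] < -fc_thresh)
                       & (results["fdr"] < fdr_thresh), "gene"]
    return list(up), list(down)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def rank_genes(expr: pd.DataFrame, is_group2: np.ndarray,
               metric: str = "s2n") -> np.ndarray:
    """Per-gene ranking scores, higher = up in group 2.

    ``s2n``: signal-to-noise (mean2 - mean1) / (sd1 + sd2) with each sd
    floored at max(0.2 * |its group mean|, 1e-8), the usual stabilisation
    for small replicate numbers.  ``diff_means``: plain mean difference.
    """
    X = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else expr
    g2 = np.asarray(is_group2, dtype=bool)
    x2, x1 = X[:, g2], X[:, ~g2]
    m2, m1 = x2.mean(axis=1), x1.mean(axis=1)
    if metric == "diff_means":
        return m2 - m1
    if metric != "s2n":
        raise ValueError("metric must be 's2n' or 'diff_means'")
    s2 = x2.std(axis=1, ddof=1)
    s1 = x1.std(axis=1, ddof=1)
    s2 = np.maximum(s2, np.maximum(0.2 * np.abs(m2), 1e-8))
    s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 1e-8))
    return (m2 - m1) / (s1 + s2)


def enrichment_score(scores: pd.Series, gene_set, weight: float = 1.0
                     ) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Genes are ranked by decreasing score (ties broken by gene id for
    determinism).  Walking the ranking, hitting a set member adds
    |score|**weight normalized over the set's members; missing subtracts
    1/(N - m).  The ES is the running-sum extremum of largest magnitude.
    """
    # descending by score; ties broken by gene id for determinism
    order = np.lexsort((scores.index.to_numpy(), -scores.to_numpy()))
    genes = scores.index.to_numpy()[order]
    vals = scores.to_numpy()[order]
    in_set = np.isin(genes, list(gene_set))
    m = int(in_set.sum())
    N = len(genes)
    if m == 0 or m == N:
        raise ValueError("gene set must be a proper non-empty subset of the "
                         "universe")
    w = np.abs(vals[in_set]) ** weight
    denom = w.sum()
    if denom == 0:
        w = np.ones(m)
        denom = float(m)
    steps = np.where(in_set, 0.0, -1.0 / (N - m))
    steps[in_set] = w / denom
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _es_for_hits(hit_pos: np.ndarray, hit_w: np.ndarray, N: int) -> float:
    """ES from sorted 0-based hit positions and their weights (vector path
    used by the permutation loop; equivalent to :func:`enrichment_score`)."""
    m = len(hit_pos)
    cw = np.cumsum(hit_w) / hit_w.sum() if hit_w.sum() > 0 \
        else np.arange(1, m + 1) / m
    miss = 1.0 / (N - m)
    after = cw - (hit_pos - np.arange(m)) * miss      # just after each hit
    before = np.concatenate([[0.0], cw[:-1]]) \
        - (hit_pos - np.arange(m)) * miss             # just before each hit
    cands = np.concatenate([after, before, [0.0]])
    return float(cands[np.argmax(np.abs(cands))])


def gsea(expr: pd.DataFrame, groups, gene_sets: dict, *, min_size: int = 5,
         max_size: int = 2000, n_perm: int = 1000, weight: float = 1.0,
         seed: int = 0, metric: str = "s2n") -> pd.DataFrame:
    """GSEA with phenotype permutation.

    ``expr`` is a genes x samples expression matrix (normalized, typically
    log-scale), ``groups`` the two-level sample labels.  Gene sets are
    intersected with the universe and filtered to [min_size, max_size].
    Per set: ES from the weighted running sum on the observed ranking;
    the null re-permutes the sample labels and recomputes the ranking
    metric; NES = ES / mean(|permutation ES| of the same sign); p is the
    same-sign permutation tail; FDR follows the permutation-NES procedure
    (null-vs-observed tail ratio, monotonized).
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    is2, labels = _group_masks(groups, expr.columns)
    universe = expr.index.to_numpy()
    N = len(universe)
    if N == 0:
        raise ValueError("empty gene universe")
    filtered = {}
    for name, members in gene_sets.items():
        inter = [g for g in dict.fromkeys(members) if g in set(universe)]
        if min_size <= len(inter) <= max_size and len(inter) < N:
            filtered[name] = inter
    if not filtered:
        raise ValueError("no gene set survives the size filter")

    X = expr.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(universe)}
    set_idx = {name: np.array([gene_pos[g] for g in members])
               for name, members in filtered.items()}

    # phenotype permutation null: when fewer distinct labelings exist than
    # n_perm, enumerate them all (minus the observed one) instead of
    # sampling with duplicates
    S = len(is2)
    n2 = int(is2.sum())
    n_distinct = math.comb(S, n2)
    if n_distinct <= n_perm:
        perms_list = []
        for idx in itertools.combinations(range(S), n2):
            mask = np.zeros(S, dtype=bool)
            mask[list(idx)] = True
            if not np.array_equal(mask, is2):
                perms_list.append(mask)
        perms = np.array(perms_list)
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty((n_perm, S), dtype=bool)
        for k in range(n_perm):
            perms[k] = rng.permutation(is2)

    def ranking(mask: np.ndarray) -> np.ndarray:
        return rank_genes(X, mask, metric=metric)

    obs_scores = ranking(is2)
    # ranks[k, g] = position of gene g in permutation k's descending order
    all_scores = np.vstack([obs_scores]
                           + [ranking(perms[k]) for k in range(n_perm)])
    order = np.argsort(-all_scores, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows_idx = np.arange(all_scores.shape[0])[:, None]
    ranks[rows_idx, order] = np.arange(N)[None, :]

    records = []
    nes_perm_all: list[np.ndarray] = []
    for name, idx in set_idx.items():
        m = len(idx)
        pos = ranks[:, idx]                       # (1 + n_perm, m)
        wts = np.abs(all_scores[:, idx]) ** weight
        sort_ix = np.argsort(pos, axis=1)
        pos_sorted = np.take_along_axis(pos, sort_ix, axis=1)
        wts_sorted = np.take_along_axis(wts, sort_ix, axis=1)
        es_all = np.array([_es_for_hits(pos_sorted[k], wts_sorted[k], N)
                           for k in range(1 + n_perm)])
        es, es_null = es_all[0], es_all[1:]
        same = es_null * np.sign(es) > 0
        denom_pool = np.abs(es_null[same]) if same.any() else np.abs(es_null)
        mean_same = denom_pool.mean() if denom_pool.size else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        n_same = int(same.sum())
        p = ((np.abs(es_null[same]) >= abs(es)).sum() + 1) / (n_same + 1) \
            if n_same else 1.0
        pos_mean = np.abs(es_null[es_null > 0]).mean() \
            if (es_null > 0).any() else np.nan
        neg_mean = np.abs(es_null[es_null < 0]).mean() \
            if (es_null < 0).any() else np.nan
        nes_null = np.where(es_null > 0,
                            es_null / pos_mean if np.isfinite(pos_mean) else np.nan,
                            es_null / neg_mean if np.isfinite(neg_mean) else np.nan)
        nes_perm_all.append(nes_null[np.isfinite(nes_null)])
        records.append({"set": name, "size": m, "es": es, "nes": nes,
                        "p": min(p, 1.0)})

    res = pd.DataFrame(records)
    null_nes = np.concatenate(nes_perm_all) if nes_perm_all else np.array([])
    obs_nes = res["nes"].to_numpy()
    fdr = np.ones(len(res))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes) or nes == 0:
            continue
        if nes > 0:
            null_tail = (null_nes >= nes).mean() if null_nes.size else 1.0
            obs_tail = (obs_nes >= nes).mean()
        else:
            null_tail = (null_nes <= nes).mean() if null_nes.size else 1.0
            obs_tail = (obs_nes <= nes).mean()
        fdr[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    # step-up monotonicity: a more extreme NES can never have a larger FDR
    for sign in (1, -1):
        sel = np.where(np.sign(obs_nes) == sign)[0]
        if sel.size:
            order2 = sel[np.argsort(-np.abs(obs_nes[sel]))]
            fdr[order2] = np.minimum.accumulate(fdr[order2][::-1])[::-1]
    res["fdr"] = fdr
    res = res.sort_values("nes", ascending=False, ignore_index=True)
    res.attrs.update({"n_perm": n_perm, "seed": seed, "weight": weight,
                      "metric": metric,
                      "comparison": f"{labels[1]} vs {labels[0]}"})
    return res


# ---------------------------------------------------------------------------
# Intersection, ORA, ddCt
# ---------------------------------------------------------------------------

def common_genes(results_a: pd.DataFrame, results_b: pd.DataFrame,
                 results_c: pd.DataFrame, fc_abs: float = 1.5,
                 scale: str = "linear") -> list:
    """Genes exceeding an absolute fold-change cut in all three comparisons.

    ``scale="linear"`` interprets ``fc_abs`` as a linear fold change (the
    signed-fold convention, so |FC| > 1.5 means log2FC beyond
    +-log2(1.5)); ``scale="log2"`` applies the cut to |log2FC| directly.
    Strict inequality in every comparison.
    """
    tables = (results_a, results_b, results_c)
    universes = [frozenset(t["gene"]) for t in tables]
    if len(set(universes)) != 1:
        raise ValueError("gene universes disagree across the three tables")
    if scale == "linear":
        cut = math.log2(fc_abs)
    elif scale == "log2":
        cut = fc_abs
    else:
        raise ValueError("scale must be 'linear' or 'log2'")
    passing = [set(t.loc[t["log2fc"].abs() > cut, "gene"]) for t in tables]
    common = passing[0] & passing[1] & passing[2]
    return sorted(common)


def ora(gene_list, gene_sets: dict, universe) -> pd.DataFrame:
    """Over-representation analysis against user-supplied gene sets.

    Upper-tail hypergeometric p for observing at least k of the list's n
    genes inside a set of m genes drawn from a universe of N, with the
    enrichment ratio (k/n)/(m/N) = observed/expected overlap, BH-adjusted
    across sets.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    glist = list(dict.fromkeys(gene_list))
    if not glist:
        raise ValueError("gene list is empty")
    if not set(glist) <= uni:
        raise ValueError("gene list must be a subset of the universe")
    N, n = len(uni), len(glist)
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & uni
        m = len(mem)
        if m == 0:
            continue
        k = len(mem & set(glist))
        ratio = (k / n) / (m / N)
        p = float(sps.hypergeom.sf(k - 1, N, m, n))
        rows.append({"set": name, "k": k, "m": m, "n": n, "N": N,
                     "enrichment_ratio": ratio, "p": p})
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    res = pd.DataFrame(rows)
    res["fdr"] = bh_adjust(res["p"])
    return res.sort_values("enrichment_ratio", ascending=False,
                           ignore_index=True)


def ddct(cq: pd.DataFrame, target_gene: str, *, reference_gene: str = "gapdh",
         control_group: str = "control") -> pd.DataFrame:
    """Delta-delta Ct relative quantification per sample.

    ``cq`` is tidy with columns ``sample``, ``group``, ``gene``, ``Cq``
    (technical replicates are averaged).  Per sample:
    ΔCt = Cq_target - Cq_reference; ΔΔCt = ΔCt - mean(ΔCt of the control
    group); fold change = 2**(-ΔΔCt).
    """
    required = {"sample", "group", "gene", "Cq"}
    if not required <= set(cq.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    mean_cq = (cq.groupby(["sample", "group", "gene"])["Cq"].mean()
               .reset_index())
    wide = mean_cq.pivot_table(index=["sample", "group"], columns="gene",
                               values="Cq")
    if target_gene not in wide.columns:
        raise ValueError(f"missing target gene {target_gene!r}")
    if reference_gene not in wide.columns or \
            wide[reference_gene].isna().any():
        raise ValueError(f"missing reference gene {reference_gene!r} Cq for "
                         "one or more samples")
    if wide[target_gene].isna().any():
        raise ValueError(f"missing target gene {target_gene!r} Cq for one "
                         "or more samples")
    wide = wide.reset_index()
    wide["dct"] = wide[target_gene] - wide[reference_gene]
    control = wide.loc[wide["group"] == control_group, "dct"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    wide["ddct"] = wide["dct"] - control.mean()
    wide["fold_change"] = 2.0 ** (-wide["ddct"])
    return wide[["sample", "group", "dct", "ddct", "fold_change"]]
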