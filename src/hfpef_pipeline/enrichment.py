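"""Single-sample GSEA over effect-size-ranked protein profiles.

The ranked input is one profile per disease group: the standardized effect
size (Cliff's delta vs non-HF controls) of every measured protein, from the
confounder-aware association analysis.  Enrichment of a gene set is the
ssGSEA integral of the weighted Kolmogorov-Smirnov running sum; a
permutation null over gene labels yields normalized enrichment scores (NES)
and empirical FDR.  Cluster-specific pathways must pass the FDR cut, deviate
from the pathway's cross-group mean NES by at least one SD, and be the row
maximum (up) or minimum (down); redundant pathways sharing more than half
their leading-edge genes with a higher-scoring pathway are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = ""

    def filtered(self, universe: set[str], min_size: int = 1,
                 max_size: int | None = None) -> "GeneSetCollection":
        out = {}
        for name, genes in self.sets.items():
            kept = [g for g in genes if g in universe]
            if len(kept) < min_size:
                continue
            if max_size is not None and len(kept) > max_size:
                continue
            out[name] = kept
        return GeneSetCollection(out, self.source)


@dataclass
class SsgseaParams:
    alpha: float = 0.75
    n_perm: int = 1000
    fdr_cut: float = 0.05
    sd_multiplier: float = 1.0
    overlap_frac: float = 0.5
    min_size: int = 3
    max_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in (0,1)")


@dataclass
class EnrichmentResult:
    pathway: str
    group: str
    es: float
    nes: float = np.nan
    q: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    specific_flag: str = "none"      # up | down | none


class GmtParseError(ValueError):
    pass


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate genes within a set are deduplicated with a warning; a line with
    fewer than three fields raises a parse error naming the line.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name} line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(f"{path.name} line {lineno}: set {name!r} has "
                              f"duplicate genes, deduplicated")
            sets[name] = unique
    return GeneSetCollection(sets, source=path.name)


# --------------------------------------------------------------------------
# Enrichment score
# --------------------------------------------------------------------------

def ssgsea_es(ranked: pd.Series, gene_set: list[str], alpha: float = 0.75
              ) -> tuple[float, list[str]]:
    """ssGSEA enrichment of ``gene_set`` in a score-ranked profile.

    ``ranked`` maps gene -> score (any order; sorted descending internally).
    Walking down the ranking, in-set genes ("hits") increment the running sum
    by |score|^alpha normalized by the total over in-set genes, and misses
    decrement by 1/(N - n_set).  The enrichment score is the sum of the
    running-sum values over all N steps (integral convention); the leading
    edge is the in-set prefix up to the extreme deviation.
    """
    order = ranked.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    scores = order.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    n = genes.size
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the measured universe")
    if n_hit == n:
        raise ValueError("gene set covers the whole universe "
                         "(miss denominator is zero)")
    w = np.abs(scores) ** alpha
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = in_set.astype(float)      # all-zero scores: unweighted walk
        denom = hit_w.sum()
    steps = hit_w / denom - (~in_set) / (n - n_hit)
    running = np.cumsum(steps)
    es = float(running.sum())
    peak = int(np.argmax(np.abs(running)))
    leading = [g for g, flag in zip(genes[:peak + 1], in_set[:peak + 1]) if flag]
    return es, leading


def ssgsea_es_bruteforce(ranked: pd.Series, gene_set: list[str],
                         alpha: float = 0.75) -> float:
    """Step-by-step loop oracle for the enrichment walk (cross-check only)."""
    order = ranked.sort_values(ascending=False, kind="mergesort")
    members = set(gene_set)
    n = len(order)
    n_hit = sum(1 for g in order.index if g in members)
    denom = sum(abs(order[g]) ** alpha for g in order.index if g in members)
    rs, total = 0.0, 0.0
    for g in order.index:
        if g in members:
            rs += (abs(order[g]) ** alpha) / denom if denom > 0 else 1.0 / n_hit
        else:
            rs -= 1.0 / (n - n_hit)
        total += rs
    return total


# --------------------------------------------------------------------------
# Normalization + FDR
# --------------------------------------------------------------------------

def normalize_and_fdr(ranked_by_group: dict[str, pd.Series],
                      collection: GeneSetCollection,
                      params: SsgseaParams | None = None
                      ) -> list[EnrichmentResult]:
    """ES, NES and BH q for every (pathway, group).

    The null distribution is built by permuting gene labels of the ranked
    profile (seeded); NES divides each ES by the mean |null ES| of matching
    sign; the empirical two-sided p counts null scores at least as extreme.
    Pathways whose null is degenerate (all zero) are flagged and excluded.
    """
    params = params or SsgseaParams()
    rng = np.random.default_rng(params.seed)
    results: list[EnrichmentResult] = []
    for group, ranked in ranked_by_group.items():
        universe = set(ranked.index)
        coll = collection.filtered(universe, params.min_size, params.max_size)
        group_res: list[EnrichmentResult] = []
        # one shared permutation family per group, seeded
        perms = [pd.Series(ranked.to_numpy(),
                           index=rng.permutation(ranked.index.to_numpy()))
                 for _ in range(params.n_perm)]
        for name, genes in coll.sets.items():
            es, leading = ssgsea_es(ranked, genes, params.alpha)
            null = np.array([ssgsea_es(p, genes, params.alpha)[0] for p in perms])
            if np.allclose(null, 0):
                warnings.warn(f"pathway {name!r}: degenerate permutation null, "
                              "excluded")
                continue
            same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
            scale = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
            nes = es / scale if scale > 0 else 0.0
            p = (1.0 + (np.abs(null) >= abs(es)).sum()) / (params.n_perm + 1.0)
            group_res.append(EnrichmentResult(name, group, es, float(nes),
                                              float(p), leading))
        if group_res:
            qs = multipletests([r.q for r in group_res], method="fdr_bh")[1]
            for r, qv in zip(group_res, qs):
                r.q = float(qv)
        results.extend(group_res)
    return results


def results_matrices(results: list[EnrichmentResult]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot results to pathway-by-group NES and q matrices."""
    frame = pd.DataFrame([{"pathway": r.pathway, "group": r.group,
                           "nes": r.nes, "q": r.q} for r in results])
    nes = frame.pivot(index="pathway", columns="group", values="nes")
    q = frame.pivot(index="pathway", columns="group", values="q")
    return nes, q


# --------------------------------------------------------------------------
# Cluster specificity, redundancy, top table
# --------------------------------------------------------------------------

def cluster_specific(nes: pd.DataFrame, q: pd.DataFrame,
                     params: SsgseaParams | None = None) -> pd.DataFrame:
    """Flag (pathway, group) cells "up"/"down" when significant, at least
    ``sd_multiplier`` cross-group SDs from the pathway's mean NES, and the
    strict row maximum (minimum).  Ties for the extremum flag nothing."""
    params = params or SsgseaParams()
    if nes.shape[1] < 2:
        raise ValueError("cluster specificity needs >= 2 groups")
    flags = pd.DataFrame("none", index=nes.index, columns=nes.columns)
    for pathway in nes.index:
        row = nes.loc[pathway]
        mu, sd = row.mean(), row.std(ddof=1)
        for grp in nes.columns:
            val = row[grp]
            if not np.isfinite(val) or q.loc[pathway, grp] >= params.fdr_cut:
                continue
            if abs(val - mu) < params.sd_multiplier * sd or sd == 0:
                continue
            if val == row.max() and (row == row.max()).sum() == 1:
                flags.loc[pathway, grp] = "up"
            elif val == row.min() and (row == row.min()).sum() == 1:
                flags.loc[pathway, grp] = "down"
    return flags


def redundancy_filter(results: list[EnrichmentResult],
                      params: SsgseaParams | None = None
                      ) -> list[EnrichmentResult]:
    """Greedy removal of redundant pathways within a group.

    Process flagged pathways in descending |NES|; drop any whose leading-edge
    overlap with an already-retained pathway exceeds ``overlap_frac`` of its
    own leading edge.
    """
    params = params or SsgseaParams()
    retained: list[EnrichmentResult] = []
    by_group: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)
    for group, rs in by_group.items():
        kept: list[EnrichmentResult] = []
        for r in sorted(rs, key=lambda r: (-abs(r.nes), r.pathway)):
            mine = set(r.leading_edge)
            redundant = False
            for k in kept:
                if not mine:
                    break
                overlap = len(mine & set(k.leading_edge)) / len(mine)
                if overlap > params.overlap_frac:
                    redundant = True
                    break
            if not redundant:
                kept.append(r)
        retained.extend(kept)
    return retained


def top_table(retained: list[EnrichmentResult], k: int = 5) -> pd.DataFrame:
    """Per group: the k highest-NES up-flagged and k lowest-NES down-flagged
    pathways (fewer if unavailable), ties broken by pathway name."""
    rows = []
    groups = sorted({r.group for r in retained})
    for grp in groups:
        ups = sorted([r for r in retained if r.group == grp
                      and r.specific_flag == "up"],
                     key=lambda r: (-r.nes, r.pathway))[:k]
        downs = sorted([r for r in retained if r.group == grp
                        and r.specific_flag == "down"],
                       key=lambda r: (r.nes, r.pathway))[:k]
        for r in ups + downs:
            rows.append({"group": grp, "pathway": r.pathway,
                         "direction": r.specific_flag, "nes": r.nes, "q": r.q})
    return pd.DataFrame(rows, columns=["group", "pathway", "direction",
                                       "nes", "q"])


def apply_specificity(results: list[EnrichmentResult],
                      params: SsgseaParams | None = None
                      ) -> list[EnrichmentResult]:
    """Annotate results with cluster-specificity flags (in place)."""
    nes, q = results_matrices(results)
    flags = cluster_specific(nes, q, params)
    for r in results:
        r.specific_flag = flags.loc[r.pathway, r.group]
    return results
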