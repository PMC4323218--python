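"""Expression arm: differential expression, tag lists and connectivity.

Differential expression between a treatment and a control group is called
with a moderated t-test: per-gene pooled variances are shrunk toward a
common prior fitted by the method of moments on the log variances
(empirical Bayes, scaled inverse-chi-square prior), giving t statistics
with d0 + d degrees of freedom and Benjamini-Hochberg q-values. Genes with
q < 0.05 form the up- and down-regulated "tag lists".

Connectivity of a tag-list pair with a reference rank profile follows the
two-sided Kolmogorov-Smirnov enrichment convention of expression
connectivity mapping: per reference instance an up-score and a down-score
are computed from the tag positions in the ranked list; when they share a
sign the instance scores 0, otherwise s = ks_up - ks_down. Instance scores
are max-scaled to [-1, 1] across the instances of a query, the per
reference-set score is the mean of its instances, and a permutation
p-value resamples tag lists of the same sizes. A food-drug connection is
called (anti-)correlated only if |score| > 0.75, permutation p < 0.01 and
the non-null percentage exceeds 80.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

logger = logging.getLogger("dfi")


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    NS = "ns"


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene_id; columns log_fc, t, p_value, fdr_q, direction
    d0: float  # prior degrees of freedom
    s0_sq: float  # prior variance


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log(s2) against the theoretical
    moments of a scaled F distribution: for sample variances with d df and
    prior d0, e = log(s2) - digamma(d/2) + log(d/2) has variance
    trigamma(d/2) + trigamma(d0/2) and mean log(s0^2) - digamma(d0/2)
    + log(d0/2). Returns (d0, s0_sq); d0 = inf when the observed spread is
    at or below the sampling floor (no excess variability to shrink).
    """
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
        return d0, s0_sq
    # invert trigamma(d0/2) = e_var by Newton iteration on y = d0/2
    y = 0.5 + 1.0 / e_var  # asymptotic start (trigamma(y) ~ 1/y)
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        deriv = float(special.polygamma(2, y))
        step = tri * (1 - tri / e_var) / deriv
        y = max(y + step, 1e-8)
        if abs(tri - e_var) < 1e-10:
            break
    d0 = 2 * y
    s0_sq = float(np.exp(np.mean(e) + special.digamma(y) - np.log(y)))
    return d0, s0_sq


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    config: PipelineConfig | None = None,
) -> DEResult:
    """Moderated two-group t-test per gene with BH correction.

    ``matrix`` is genes x samples (already normalized, log scale);
    ``groups`` maps sample -> {'treatment', 'control'}. Genes with zero
    variance in both groups and zero difference get p = 1 and are flagged
    in the log.
    """
    config = config or PipelineConfig()
    groups = groups.reindex(matrix.columns)
    t_cols = groups[groups == "treatment"].index
    c_cols = groups[groups == "control"].index
    n1, n2 = len(t_cols), len(c_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("differential expression needs >= 2 samples per group")

    X1 = matrix[t_cols].to_numpy(float)
    X2 = matrix[c_cols].to_numpy(float)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    diff = m1 - m2
    d = n1 + n2 - 2
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    d0, s0_sq = _fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
    degenerate = se == 0
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.warning("%d genes have zero variance in both groups; p set to 1", n_degenerate)
    tstat = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, se))
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2 * stats.t.sf(np.abs(tstat), df=df_total)
    p = np.where(degenerate, 1.0, p)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    sig = q < config.fdr_alpha
    direction = np.where(~sig, Direction.NS.value, np.where(diff > 0, Direction.UP.value, Direction.DOWN.value))
    table = pd.DataFrame(
        {
            "log_fc": diff,
            "t": tstat,
            "p_value": p,
            "fdr_q": q,
            "direction": direction,
        },
        index=matrix.index,
    )
    return DEResult(table, float(d0), float(s0_sq))


@dataclass
class TagLists:
    food_id: str
    up_tags: list[str]  # ordered by significance (most significant first)
    down_tags: list[str]
    n_unmapped: int = 0


def build_tag_lists(
    de: DEResult,
    id_map: dict[str, str] | None = None,
    food_id: str = "",
    max_size: int | None = None,
) -> TagLists:
    """Split significant genes into up/down tag lists in reference id space.

    ``id_map`` translates gene ids to the reference profile's probe ids;
    unmapped tags are dropped and counted. Raises if both lists come out
    empty (there is nothing to score).
    """
    tab = de.table.sort_values("p_value", kind="mergesort")
    up_genes = [g for g in tab.index if tab.at[g, "direction"] == Direction.UP.value]
    down_genes = [g for g in tab.index if tab.at[g, "direction"] == Direction.DOWN.value]

    n_unmapped = 0

    def _convert(genes: list[str]) -> list[str]:
        nonlocal n_unmapped
        if id_map is None:
            return list(genes)
        out = []
        for g in genes:
            if g in id_map:
                out.append(id_map[g])
            else:
                n_unmapped += 1
        return out

    up, down = _convert(up_genes), _convert(down_genes)
    if max_size is not None:
        up, down = up[:max_size], down[:max_size]
    if not up and not down:
        raise ValueError("no significant genes map into the reference id space; nothing to score")
    if n_unmapped:
        logger.info("dropped %d unmapped tag ids", n_unmapped)
    return TagLists(food_id=food_id, up_tags=up, down_tags=down, n_unmapped=n_unmapped)


def ks_enrichment(tag_positions: np.ndarray, n_total: int) -> float:
    """Two-sided KS statistic of tag positions within a ranking of n_total.

    ``tag_positions`` are 1-based ranks. Returns a when a > b else -b,
    where a measures enrichment toward the top of the list and b toward
    the bottom; 0 tags give 0.
    """
    t = len(tag_positions)
    if t == 0:
        return 0.0
    v = np.sort(tag_positions)
    j = np.arange(1, t + 1)
    a = float(np.max(j / t - v / n_total))
    b = float(np.max(v / n_total - (j - 1) / t))
    return a if a > b else -b


@dataclass
class ConnectivityResult:
    food_id: str
    reference_id: str
    enrichment_score: float  # mean of scaled instance scores, in [-1, 1]
    permutation_p: float
    nonnull_pct: float
    classification: str  # 'correlated' | 'anticorrelated' | 'null'
    n_instances: int


def _instance_raw_scores(
    up_pos: list[np.ndarray], down_pos: list[np.ndarray], n_total: int
) -> np.ndarray:
    """Raw (unscaled) connectivity score per instance: 0 on sign agreement."""
    out = np.empty(len(up_pos))
    for i, (u, d) in enumerate(zip(up_pos, down_pos)):
        ks_u = ks_enrichment(u, n_total)
        ks_d = ks_enrichment(d, n_total)
        out[i] = 0.0 if np.sign(ks_u) == np.sign(ks_d) else ks_u - ks_d
    return out


def _scale_scores(raw: np.ndarray) -> np.ndarray:
    """Max-scale positive scores by the max, negative by |min| (to [-1, 1])."""
    scaled = raw.astype(float).copy()
    pos = raw > 0
    neg = raw < 0
    if pos.any():
        scaled[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        scaled[neg] = raw[neg] / abs(raw[neg].min())
    return scaled


def connectivity_score(
    tags: TagLists,
    reference: pd.DataFrame,
    instance_sets: dict[str, list[str]],
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[ConnectivityResult]:
    """Score a tag-list pair against every reference set of rank instances.

    ``reference`` is probe_id x instance with values = rank (1 = most
    up-regulated by the reference perturbation); ``instance_sets`` groups
    instance columns by reference compound. Scaling to [-1, 1] is done
    across all instances of the query, the set score is the mean over the
    set's scaled instances, the permutation p resamples tag id sets of the
    same sizes from the profile universe (two-sided on the set mean), and
    the non-null percentage counts instances with a nonzero score whose
    sign agrees with the set mean.
    """
    config = config or PipelineConfig()
    rng = rng or np.random.default_rng(config.seed)
    n_total = len(reference.index)
    if len(tags.up_tags) > n_total or len(tags.down_tags) > n_total:
        raise ValueError("tag list longer than the reference ranking")
    missing = (set(tags.up_tags) | set(tags.down_tags)) - set(reference.index)
    if missing:
        raise ValueError(f"{len(missing)} tag ids absent from the reference ranking")

    instances = [c for cols in instance_sets.values() for c in cols]
    ranks = reference[instances].to_numpy(float)  # probes x instances
    row_of = {pid: i for i, pid in enumerate(reference.index)}
    up_rows = np.array([row_of[t] for t in tags.up_tags], dtype=int)
    down_rows = np.array([row_of[t] for t in tags.down_tags], dtype=int)

    up_pos = [ranks[up_rows, j] for j in range(ranks.shape[1])]
    down_pos = [ranks[down_rows, j] for j in range(ranks.shape[1])]
    raw = _instance_raw_scores(up_pos, down_pos, n_total)
    scaled = _scale_scores(raw)
    col_idx = {c: j for j, c in enumerate(instances)}

    set_scores = {
        ref: float(np.mean([scaled[col_idx[c]] for c in cols]))
        for ref, cols in instance_sets.items()
    }
    raw_set_means = {
        ref: float(np.mean([raw[col_idx[c]] for c in cols]))
        for ref, cols in instance_sets.items()
    }

    # permutation null: resample tag sets of the same sizes and compare the
    # *raw* set means (cross-instance max-scaling is a display normalization;
    # under it any nonzero permuted set would rescale toward +-1 whenever its
    # instances dominate the query, which would destroy the test's power)
    n_perm = config.n_permutations
    nu, nd = len(up_rows), len(down_rows)
    perm_means = {ref: np.empty(n_perm) for ref in instance_sets}
    for b in range(n_perm):
        sel = rng.choice(n_total, size=nu + nd, replace=False)
        pu = [ranks[sel[:nu], j] for j in range(ranks.shape[1])]
        pdn = [ranks[sel[nu:], j] for j in range(ranks.shape[1])]
        praw = _instance_raw_scores(pu, pdn, n_total)
        for ref, cols in instance_sets.items():
            perm_means[ref][b] = np.mean([praw[col_idx[c]] for c in cols])

    results = []
    for ref, cols in sorted(instance_sets.items()):
        score = set_scores[ref]
        pm = perm_means[ref]
        p = float((1 + np.sum(np.abs(pm) >= abs(raw_set_means[ref]))) / (n_perm + 1))
        inst_scaled = np.array([scaled[col_idx[c]] for c in cols])
        if score != 0:
            nonnull = float(
                100 * np.mean((inst_scaled != 0) & (np.sign(inst_scaled) == np.sign(score)))
            )
        else:
            nonnull = 0.0
        if abs(score) > config.es_min and p < config.perm_p_max and nonnull > config.nonnull_min_pct:
            cls = "correlated" if score > 0 else "anticorrelated"
        else:
            cls = "null"
        results.append(
            ConnectivityResult(
                food_id=tags.food_id,
                reference_id=ref,
                enrichment_score=score,
                permutation_p=p,
                nonnull_pct=nonnull,
                classification=cls,
                n_instances=len(cols),
            )
        )
    return results


def classify_connections(
    results: list[ConnectivityResult],
    drug_disease_classes: dict[str, frozenset[str]] | None = None,
):
    """Food-drug network of non-null connectivity calls.

    Edge weight is |enrichment score|; edges carry the classification and
    the drug nodes their disease classes. Returns (graph, per-class drug
    counts).
    """
    import networkx as nx

    g = nx.Graph()
    class_counts: dict[str, int] = {}
    counted: set[str] = set()
    for r in results:
        if r.classification == "null":
            continue
        g.add_node(r.food_id, kind="food")
        classes = (drug_disease_classes or {}).get(r.reference_id, frozenset())
        g.add_node(r.reference_id, kind="drug", disease_classes="|".join(sorted(classes)))
        g.add_edge(
            r.food_id,
            r.reference_id,
            weight=abs(r.enrichment_score),
            classification=r.classification,
        )
        if r.reference_id not in counted:
            counted.add(r.reference_id)
            for c in classes:
                class_counts[c] = class_counts.get(c, 0) + 1
    return g, class_counts


@dataclass
class DeVsNonDeResult:
    statistic: float
    p_value: float
    n_compounds: int
    de_affinities: list[float]
    nonde_affinities: list[float]
    per_compound: pd.DataFrame  # compound, n_de, n_nonde, geo-mean affinities


def de_vs_nonde_affinity(
    links: pd.DataFrame,  # columns: compound_id, protein_id (gene-mapped), affinity_nM
    de_genes: set[str],
) -> DeVsNonDeResult:
    """Compare binding affinities toward DE vs non-DE target genes.

    Restricted to compounds with >=1 target in each group; reports the
    pooled two-sample Wilcoxon rank-sum test (exact for small samples via
    the Mann-Whitney implementation) plus a per-compound summary.
    """
    from .bioactivity import geometric_mean

    de_vals: list[float] = []
    nonde_vals: list[float] = []
    rows = []
    for cid, sub in links.groupby("compound_id"):
        de_mask = sub["protein_id"].isin(de_genes)
        a_de = sub.loc[de_mask, "affinity_nM"].tolist()
        a_non = sub.loc[~de_mask, "affinity_nM"].tolist()
        if not a_de or not a_non:
            continue
        de_vals.extend(a_de)
        nonde_vals.extend(a_non)
        rows.append(
            {
                "compound_id": cid,
                "n_de": len(a_de),
                "n_nonde": len(a_non),
                "geo_mean_de_nM": geometric_mean(a_de),
                "geo_mean_nonde_nM": geometric_mean(a_non),
            }
        )
    if not rows:
        raise ValueError(
            "no compound has targets in both the DE and non-DE groups; comparison undefined"
        )
    method = "exact" if max(len(de_vals), len(nonde_vals)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(de_vals, nonde_vals, alternative="two-sided", method=method)
    return DeVsNonDeResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_compounds=len(rows),
        de_affinities=de_vals,
        nonde_affinities=nonde_vals,
        per_compound=pd.DataFrame(rows),
    )
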