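"""Statistical comparisons for repertoire overlap analyses.

Fisher odds ratios with Woolf logit confidence intervals, seeded uniform
down-sampling of unique junctions, an equivalence-line slope test for
match-count curves across mismatch thresholds, hypergeometric set-overlap
probabilities, two-sample Kolmogorov-Smirnov feature comparisons, per-gene
usage enrichment with Benjamini-Hochberg correction, and disease-group /
donor-level match-fraction analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

from pitmatch.errors import ContractError
from pitmatch.repertoire_io import Repertoire, normalize_gene


@dataclass
class ContingencyResult:
    """A 2x2 Fisher comparison with log2 odds ratio and Woolf 95% CI."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    log2_odds_ratio: float
    ci95: tuple[float, float]  # on the log2 scale
    p_value: float
    corrected: bool = False    # Haldane-Anscombe 0.5 applied
    undefined: bool = False    # a row or column is all zero


def fisher_or(table, zero_correction: bool = True) -> ContingencyResult:
    """Sample odds ratio, Woolf logit 95% CI and exact two-sided p.

    ``table`` is 2x2 non-negative counts [[a, b], [c, d]]; the odds ratio
    is (a*d)/(b*c).  When any cell is zero and ``zero_correction`` is set,
    0.5 is added to every cell for the estimate and CI (Haldane-Anscombe);
    the exact p-value always uses the raw counts.
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ContractError("negative cell count")
    undefined = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = False
    aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if 0 in (a, b, c, d) and zero_correction:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    if bb * cc == 0:
        or_, log2_or = math.inf, math.inf
        ci = (math.inf, math.inf)
    else:
        or_ = (aa * dd) / (bb * cc)
        log2_or = math.log2(or_)
        se_ln = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        half = 1.959963984540054 * se_ln / math.log(2)
        ci = (log2_or - half, log2_or + half)
    return ContingencyResult(table=((a, b), (c, d)), odds_ratio=or_,
                             log2_odds_ratio=log2_or, ci95=ci, p_value=p,
                             corrected=corrected, undefined=undefined)


def downsample(rep: Repertoire, n: int, seed: int) -> Repertoire:
    """Uniform sample of ``n`` unique junctions, without replacement.

    Keeps every record whose junction was drawn, so tallies stay
    consistent.  Deterministic for a given seed.
    """
    junctions = sorted(rep.unique_junctions)
    if n > len(junctions):
        raise ContractError(
            f"cannot sample {n} from {len(junctions)} unique junctions")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(junctions), size=n, replace=False))
    keep = {junctions[i] for i in chosen}
    return rep.subset(lambda r: r.junction_aa in keep)


@dataclass
class SlopeResult:
    slope: float
    intercept: float
    p_vs_1: float
    stderr: float


def threshold_curve_regression(counts_query, counts_reference) -> SlopeResult:
    """OLS of reference match counts on query match counts, testing the
    slope against the equivalence line (slope 1).

    Both vectors hold cumulative match counts at the same ascending
    mismatch thresholds.
    """
    x = np.asarray(counts_query, dtype=float)
    y = np.asarray(counts_reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ContractError("need >= 3 paired threshold counts")
    model = OLS(y, add_constant(x)).fit()
    slope = model.params[1]
    stderr = model.bse[1]
    if model.ssr <= 1e-12 * max(float(y @ y), 1.0):
        # numerically exact fit: the t statistic is 0/0 noise
        p = 1.0 if abs(slope - 1.0) < 1e-9 else 0.0
    else:
        t = (slope - 1.0) / stderr
        p = 2 * stats.t.sf(abs(t), df=model.df_resid)
    return SlopeResult(slope=float(slope), intercept=float(model.params[0]),
                       p_vs_1=float(p), stderr=float(stderr))


def overlap_hypergeom(set_a, set_b, universe_size: int) -> float:
    """Upper-tail probability of observing >= |A intersect B| shared
    junctions when both sets are random draws from the universe."""
    set_a, set_b = set(set_a), set(set_b)
    if max(len(set_a), len(set_b)) > universe_size:
        raise ContractError("set larger than universe")
    k = len(set_a & set_b)
    # P(X >= k), X ~ Hypergeom(N=universe, K=|A|, n=|B|)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(set_a),
                                    len(set_b)))


def ks_compare(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on feature values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ContractError("each sample needs >= 2 values")
    alt = {"two_sided": "two-sided", "less": "less",
           "greater": "greater"}.get(alternative)
    if alt is None:
        raise ContractError(f"unknown alternative {alternative!r}")
    res = stats.ks_2samp(x, y, alternative=alt, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GeneEnrichment:
    gene: str
    result: ContingencyResult
    p_adj: float = float("nan")
    direction: str = "none"  # over- or under-represented in matched set


def vgene_enrichment(matched: Repertoire,
                     nonmatched: Repertoire) -> list[GeneEnrichment]:
    """Per-V-gene 2x2 Fisher tests (gene vs rest x matched vs nonmatched)
    with Benjamini-Hochberg correction across genes."""
    m_counts: dict[str, int] = {}
    n_counts: dict[str, int] = {}
    for rep, counts in ((matched, m_counts), (nonmatched, n_counts)):
        seen = set()
        for r in rep.records:
            if r.junction_aa in seen:
                continue
            seen.add(r.junction_aa)
            g = normalize_gene(r.v_gene)
            counts[g] = counts.get(g, 0) + 1
    m_total = sum(m_counts.values())
    n_total = sum(n_counts.values())
    genes = sorted(set(m_counts) | set(n_counts))
    out = []
    for g in genes:
        a = m_counts.get(g, 0)
        c = n_counts.get(g, 0)
        res = fisher_or([[a, m_total - a], [c, n_total - c]])
        direction = "none"
        if res.log2_odds_ratio > 0:
            direction = "over"
        elif res.log2_odds_ratio < 0:
            direction = "under"
        out.append(GeneEnrichment(gene=g, result=res, direction=direction))
    if out:
        padj = multipletests([e.result.p_value for e in out],
                             method="fdr_bh")[1]
        for e, p in zip(out, padj):
            e.p_adj = float(p)
    return out


@dataclass
class GroupFractionResult:
    """Matched fractions per disease_group x expansion stratum, with all
    pairwise Fisher comparisons (BH-adjusted) within each stratum."""

    fractions: pd.DataFrame     # group, stratum, matched, total, fraction
    pairwise: pd.DataFrame      # stratum, group_a, group_b, p, p_adj
    excluded_groups: list[str] = field(default_factory=list)
    seed: int | None = None


def group_match_fractions(rep: Repertoire, match_flags: dict[str, bool],
                          strata: dict[str, bool] | None = None,
                          equalize: bool = False,
                          seed: int | None = None) -> GroupFractionResult:
    """Matched-junction fractions per disease group.

    ``match_flags`` maps junction -> tissue-match flag; ``strata`` maps
    junction -> expanded flag (optional).  With ``equalize`` the groups are
    down-sampled (seeded) to the smallest group's unique-junction count
    before testing.
    """
    if equalize and seed is None:
        raise ContractError("equalize requires a seed")
    per_group: dict[str, list[str]] = {}
    seen = set()
    for r in rep.records:
        if r.junction_aa in seen:
            continue
        seen.add(r.junction_aa)
        per_group.setdefault(r.disease_group, []).append(r.junction_aa)
    excluded = [g for g, js in per_group.items() if not js]
    per_group = {g: js for g, js in per_group.items() if js}
    if equalize:
        n_min = min(len(js) for js in per_group.values())
        rng = np.random.default_rng(seed)
        per_group = {
            g: [js[i] for i in sorted(rng.choice(len(js), size=n_min,
                                                 replace=False))]
            for g, js in sorted(per_group.items())
        }

    def stratum_of(j: str) -> str:
        if strata is None:
            return "all"
        return "expanded" if strata.get(j, False) else "non_expanded"

    rows = []
    cells: dict[tuple[str, str], tuple[int, int]] = {}
    for g, js in sorted(per_group.items()):
        by_stratum: dict[str, list[str]] = {}
        for j in js:
            by_stratum.setdefault(stratum_of(j), []).append(j)
        for s, sj in sorted(by_stratum.items()):
            matched = sum(bool(match_flags.get(j, False)) for j in sj)
            rows.append({"group": g, "stratum": s, "matched": matched,
                         "total": len(sj),
                         "fraction": matched / len(sj)})
            cells[(g, s)] = (matched, len(sj))
    fractions = pd.DataFrame(rows)

    pw_rows = []
    strata_names = sorted({s for (_, s) in cells})
    for s in strata_names:
        groups = sorted(g for (g, s2) in cells if s2 == s)
        for ga, gb in combinations(groups, 2):
            ma, ta = cells[(ga, s)]
            mb, tb = cells[(gb, s)]
            res = fisher_or([[ma, ta - ma], [mb, tb - mb]])
            pw_rows.append({"stratum": s, "group_a": ga, "group_b": gb,
                            "p": res.p_value})
    pairwise = pd.DataFrame(pw_rows)
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    else:
        pairwise["p_adj"] = []
    return GroupFractionResult(fractions=fractions, pairwise=pairwise,
                               excluded_groups=excluded, seed=seed)


@dataclass
class DonorFractionResult:
    per_donor: pd.DataFrame     # donor, group, matched, total, fraction
    pairwise: pd.DataFrame      # group_a, group_b, p, p_adj (NaN if skipped)
    skipped: list[tuple[str, str]] = field(default_factory=list)


def donor_level_fractions(rep: Repertoire,
                          match_flags: dict[str, bool]) -> DonorFractionResult:
    """Per-donor matched fractions with pairwise Wilcoxon rank-sum tests
    between disease groups (BH-adjusted).  Donors without junctions are
    excluded; group pairs where either side has < 2 donors are skipped."""
    per_donor: dict[str, tuple[str, set[str]]] = {}
    for r in rep.records:
        g, js = per_donor.setdefault(r.donor_id, (r.disease_group, set()))
        js.add(r.junction_aa)
    rows = []
    for donor, (group, js) in sorted(per_donor.items()):
        if not js:
            continue
        matched = sum(bool(match_flags.get(j, False)) for j in js)
        rows.append({"donor": donor, "group": group, "matched": matched,
                     "total": len(js), "fraction": matched / len(js)})
    per_donor_df = pd.DataFrame(rows)
    skipped: list[tuple[str, str]] = []
    pw = []
    groups = sorted(per_donor_df["group"].unique()) if len(per_donor_df) else []
    for ga, gb in combinations(groups, 2):
        fa = per_donor_df.loc[per_donor_df["group"] == ga, "fraction"]
        fb = per_donor_df.loc[per_donor_df["group"] == gb, "fraction"]
        if len(fa) < 2 or len(fb) < 2:
            skipped.append((ga, gb))
            continue
        stat = stats.mannwhitneyu(fa, fb, alternative="two-sided")
        pw.append({"group_a": ga, "group_b": gb, "p": float(stat.pvalue),
                   "delta": float(fa.mean() - fb.mean())})
    pairwise = pd.DataFrame(pw)
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    else:
        pairwise["p_adj"] = []
    return DonorFractionResult(per_donor=per_donor_df, pairwise=pairwise,
                               skipped=skipped)
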