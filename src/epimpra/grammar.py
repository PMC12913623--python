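"""Statistical dissection of motif grammar and per-variant effects.

Four analyses operate on the synthetic-enhancer classes:

* :func:`homotypic_trend` — Spearman correlation between motif copy number
  (1/2/4) and log2 activity, per motif and assay (Class 1).
* :func:`fit_pairwise_synergy` — per TF pair, OLS of
  ``log2(activity) ~ count_tf1 + count_tf2 + k`` where the interaction
  term k is the per-motif copy number of the heterotypic element
  (0 for homotypic elements); a significant positive k coefficient is
  synergy, negative is repression.
* :func:`order_anova` — one-way ANOVA over the 24 slot-order permutations
  of each 4-motif combination (Class 3).
* :func:`positional_enrichment` — hypergeometric enrichment of each motif
  at each slot among the top/bottom-ranked Class 3 elements.

Variant effects (saturation-substitution libraries) are estimated with
:func:`fit_variant_effects`:
``log2(enriched) ~ log2(inserted) + N + offset`` with one binary indicator
per variant, the wild type as baseline, fitted per CRE and assay.

Multiple-testing families are per assay within each analysis and adjusted
with Benjamini-Hochberg (:func:`bh_adjust`); variant effects use raw
p < 0.01 by default.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignedElement, LibraryDesign
from .quantify import DEFAULT_PSEUDOCOUNT, cpm_normalize

DEFAULT_VARIANT_P = 0.01


# ---------------------------------------------------------------------------
# shared helpers


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate unchanged."""
    p = np.asarray(p_values, dtype=float)
    adj = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return adj
    pm = p[mask]
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = pm.size
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    adj[mask] = out
    return adj


def spearman_test(x: Sequence[float], y: Sequence[float], exact_max_n: int = 9) -> tuple[float, float]:
    """Two-sided Spearman test; exact permutation null for small samples.

    For n <= ``exact_max_n`` the p-value is computed by enumerating every
    permutation of the (mid-)ranks of y; larger samples use the asymptotic
    t approximation.  Returns (rho, p); (nan, nan) when either input is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
        perms = np.array(list(itertools.permutations(cy)))
        rho_null = perms @ cx / denom
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return (rho, p)


def _ols_fit(y: np.ndarray, X: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    """OLS with intercept-included design; returns coef/se/t/p per column.

    Zero-residual (noise-free) fits get the limiting p-values: 1 for a
    zero coefficient, 0 otherwise.
    """
    model = sm.OLS(y, X)
    res = model.fit()
    params = np.asarray(res.params, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    if res.df_resid > 0 and (res.ssr <= 1e-16 * max(1.0, float(np.abs(y).max()) ** 2)):
        pvals = np.where(np.abs(params) <= 1e-8, 1.0, 0.0)
    return pd.DataFrame(
        {"term": list(names), "coef": params, "se": np.asarray(res.bse), "p_value": pvals}
    )


# ---------------------------------------------------------------------------
# Class 1: homotypic copy-number trend


def _class1_info(element: DesignedElement) -> tuple[str, int]:
    name = element.motif_layout[0][0]
    copies = element.motif_layout[0][1]
    return name, copies


def homotypic_trend(
    activities: pd.DataFrame,
    design: LibraryDesign,
    exclude_motifs: Iterable[str] = (),
    fdr: float = 0.05,
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """Spearman trend of log2 activity vs motif copy number, per motif/assay.

    ``activities`` is the per-replicate activity table (columns
    ``element_id, assay, sample, log2_activity``).  Observations pool the
    templates and replicates.  Results carry columns ``motif, assay,
    spearman_rho, p_value, adj_p, n_obs, flag`` with BH adjustment across
    motifs within each assay.
    """
    excluded = set(exclude_motifs)
    copies_of = {
        e.id: _class1_info(e) for e in design.by_class("class1") if _class1_info(e)[0] not in excluded
    }
    sub = activities[activities["element_id"].isin(copies_of)].dropna(subset=["log2_activity"])
    rows = []
    for (assay, motif), grp in sub.assign(
        motif=sub["element_id"].map(lambda i: copies_of[i][0]),
        copies=sub["element_id"].map(lambda i: copies_of[i][1]),
    ).groupby(["assay", "motif"]):
        x = grp["copies"].to_numpy(dtype=float)
        y = grp["log2_activity"].to_numpy(dtype=float)
        flag = ""
        if np.unique(x).size < 2:
            rho, p, flag = float("nan"), float("nan"), "single_copy_level"
        else:
            rho, p = spearman_test(x, y, exact_max_n=exact_max_n)
            if math.isnan(rho):
                flag = "constant_activity"
        rows.append(
            {
                "motif": motif,
                "assay": assay,
                "spearman_rho": rho,
                "p_value": p,
                "n_obs": int(len(grp)),
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adj_p"] = np.nan
    for assay, idx in out.groupby("assay").groups.items():
        out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p_value"])
    out["significant"] = out["adj_p"] < fdr
    return out[["motif", "assay", "spearman_rho", "p_value", "adj_p", "significant", "n_obs", "flag"]]


# ---------------------------------------------------------------------------
# Class 1 + 2: pairwise synergy regression


def _pair_rows(
    design: LibraryDesign, tf1: str, tf2: str
) -> dict[str, tuple[float, float, float]]:
    """Map element id -> (count_tf1, count_tf2, k) for one TF pair."""
    rows: dict[str, tuple[float, float, float]] = {}
    for e in design.by_class("class1"):
        name, copies = _class1_info(e)
        if name == tf1:
            rows[e.id] = (float(copies), 0.0, 0.0)
        elif name == tf2:
            rows[e.id] = (0.0, float(copies), 0.0)
    for e in design.by_class("class2"):
        counts: dict[str, int] = {}
        for name, copies, _slot in e.motif_layout:
            counts[name] = copies
        if set(counts) == {tf1, tf2}:
            k = float(min(counts.values()))
            rows[e.id] = (float(counts[tf1]), float(counts[tf2]), k)
    return rows


def fit_pairwise_synergy(
    activities: pd.DataFrame,
    design: LibraryDesign,
    fdr: float = 0.01,
    exclude_motifs: Iterable[str] = (),
) -> pd.DataFrame:
    """OLS synergy screen over all TF pairs, per assay.

    For each unordered pair the homotypic (Class 1) elements of both
    motifs and the heterotypic (Class 2) elements of the pair enter as
    per-replicate observations of
    ``log2(activity) ~ count_tf1 + count_tf2 + k`` with intercept.
    The k coefficient is BH-adjusted across pairs within each assay;
    ``direction`` is "synergy"/"repression" for significant positive/
    negative coefficients, else "none".
    """
    excluded = set(exclude_motifs)
    motif_names = [m.name for m in design.motif_set if m.name not in excluded]
    act = activities.dropna(subset=["log2_activity"])
    rows = []
    for tf1, tf2 in itertools.combinations(sorted(motif_names), 2):
        covariates = _pair_rows(design, tf1, tf2)
        sub = act[act["element_id"].isin(covariates)]
        for assay, grp in sub.groupby("assay"):
            cov = np.array([covariates[i] for i in grp["element_id"]])
            y = grp["log2_activity"].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(grp)), cov])
            flag = ""
            if len(grp) < 5 or np.linalg.matrix_rank(X) < X.shape[1]:
                coef1 = coef2 = coef_k = p_k = float("nan")
                flag = "rank_deficient"
            else:
                fit = _ols_fit(y, X, ["intercept", "count_tf1", "count_tf2", "k"])
                coef1 = float(fit.loc[1, "coef"])
                coef2 = float(fit.loc[2, "coef"])
                coef_k = float(fit.loc[3, "coef"])
                p_k = float(fit.loc[3, "p_value"])
            rows.append(
                {
                    "tf1": tf1,
                    "tf2": tf2,
                    "assay": assay,
                    "coef_count_tf1": coef1,
                    "coef_count_tf2": coef2,
                    "coef_k": coef_k,
                    "p_k": p_k,
                    "n_obs": int(len(grp)),
                    "flag": flag,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adj_p_k"] = np.nan
    for assay, idx in out.groupby("assay").groups.items():
        out.loc[idx, "adj_p_k"] = bh_adjust(out.loc[idx, "p_k"])
    significant = out["adj_p_k"] < fdr
    out["direction"] = np.select(
        [significant & (out["coef_k"] > 0), significant & (out["coef_k"] < 0)],
        ["synergy", "repression"],
        default="none",
    )
    return out[
        [
            "tf1",
            "tf2",
            "assay",
            "coef_count_tf1",
            "coef_count_tf2",
            "coef_k",
            "p_k",
            "adj_p_k",
            "direction",
            "n_obs",
            "flag",
        ]
    ]


# ---------------------------------------------------------------------------
# Class 3: motif-order ANOVA


def order_anova(
    activities: pd.DataFrame,
    design: LibraryDesign,
    exclude_motifs: Iterable[str] = (),
    min_groups: int = 3,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """One-way ANOVA of activity across the slot-order permutations.

    Elements sharing a 4-motif combination form up to 24 permutation
    groups (each pooling templates x replicates).  Combinations with fewer
    than ``min_groups`` groups holding >= 2 observations, or with zero
    variance everywhere, are reported NA with a flag.  BH adjustment runs
    across combinations within each assay.  ``delta_max_min`` is the
    difference between the highest and lowest permutation group means.
    """
    excluded = set(exclude_motifs)
    meta: dict[str, tuple[frozenset[str], tuple[str, ...]]] = {}
    for e in design.by_class("class3"):
        order = tuple(name for name, _c, _s in sorted(e.motif_layout, key=lambda t: t[2]))
        if excluded.intersection(order):
            continue
        meta[e.id] = (frozenset(order), order)
    act = activities[activities["element_id"].isin(meta)].dropna(subset=["log2_activity"])
    rows = []
    grouped = act.assign(
        combo=act["element_id"].map(lambda i: meta[i][0]),
        order=act["element_id"].map(lambda i: meta[i][1]),
    )
    for (assay, combo), grp in grouped.groupby(["assay", "combo"]):
        groups = [g["log2_activity"].to_numpy() for _o, g in grp.groupby("order")]
        usable = [g for g in groups if g.size >= 2]
        means = [float(g.mean()) for g in groups]
        delta = float(max(means) - min(means)) if means else float("nan")
        flag = ""
        if len(usable) < min_groups:
            f_stat = p = float("nan")
            flag = "too_few_groups"
        elif all(np.ptp(g) == 0 for g in usable) and np.ptp(means) == 0:
            f_stat = p = float("nan")
            flag = "degenerate_constant"
        else:
            f_stat, p = (float(v) for v in stats.f_oneway(*usable))
        rows.append(
            {
                "combination": "+".join(sorted(combo)),
                "assay": assay,
                "f_stat": f_stat,
                "p_value": p,
                "delta_max_min": delta,
                "n_groups": len(groups),
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adj_p"] = np.nan
    for assay, idx in out.groupby("assay").groups.items():
        out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p_value"])
    out["significant"] = out["adj_p"] < fdr
    return out[
        ["combination", "assay", "f_stat", "p_value", "adj_p", "significant", "delta_max_min", "n_groups", "flag"]
    ]


# ---------------------------------------------------------------------------
# Class 3: positional enrichment


def positional_enrichment(
    activity: pd.Series,
    design: LibraryDesign,
    n_extreme: int = 200,
    exclude_motifs: Iterable[str] = (),
    assay: str = "mpra",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric motif-by-slot enrichment in the activity extremes.

    ``activity`` is the combined (across-replicate) activity indexed by
    element id.  Class 3 elements are ranked and the top/bottom
    ``n_extreme`` form the draw sets; rank-boundary ties break
    deterministically by element id.  For each (motif, slot, group) the
    one-sided hypergeometric tail in the direction of the observed odds
    ratio is reported, BH-adjusted across all rows.
    """
    excluded = set(exclude_motifs)
    slot_of: dict[str, dict[tuple[str, int], bool]] = {}
    keep_ids = []
    for e in design.by_class("class3"):
        names = {name for name, _c, _s in e.motif_layout}
        if excluded & names:
            continue
        slot_of[e.id] = {(name, slot): True for name, _c, slot in e.motif_layout}
        keep_ids.append(e.id)
    scores = activity.reindex(keep_ids).dropna()
    N = len(scores)
    if n_extreme > N:
        raise ValueError(f"n_extreme={n_extreme} exceeds the {N}-element population")
    ranked = scores.sort_values(ascending=False, kind="stable")
    ranked = ranked.iloc[np.lexsort((ranked.index, -ranked.to_numpy()))]
    top = set(ranked.index[:n_extreme])
    bottom = set(ranked.index[-n_extreme:])
    motifs = sorted({name for m in slot_of.values() for (name, _s) in m})
    rows = []
    for motif in motifs:
        for slot in (1, 2, 3, 4):
            K = sum((motif, slot) in slot_of[i] for i in scores.index)
            for group, members in (("top", top), ("bottom", bottom)):
                k = sum((motif, slot) in slot_of[i] for i in members)
                n = len(members)
                table = np.array([[k, n - k], [K - k, (N - n) - (K - k)]], dtype=float)
                flag = ""
                if table[0, 1] == 0 or table[1, 0] == 0:
                    odds_ratio = float("inf")
                    flag = "boundary"
                elif table[0, 0] == 0 or table[1, 1] == 0:
                    odds_ratio = 0.0
                    flag = "boundary" if table[0, 0] == 0 and table[1, 1] == 0 else flag
                else:
                    odds_ratio = float(
                        (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
                    )
                enriched = (k / n) > (K / N) if N else False
                if enriched:
                    p = float(stats.hypergeom.sf(k - 1, N, K, n))
                    direction = "enriched"
                else:
                    p = float(stats.hypergeom.cdf(k, N, K, n))
                    direction = "depleted"
                rows.append(
                    {
                        "motif": motif,
                        "slot": slot,
                        "group": group,
                        "assay": assay,
                        "odds_ratio": odds_ratio,
                        "direction": direction,
                        "p_value": p,
                        "k": k,
                        "K": K,
                        "n": n,
                        "N": N,
                        "flag": flag,
                    }
                )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p_value"])
    out["significant"] = out["adj_p"] < fdr
    return out


# ---------------------------------------------------------------------------
# variant-effect regression (saturation substitution / window libraries)


def fit_variant_effects(
    counts: pd.DataFrame,
    elements: Sequence[DesignedElement],
    enriched_assay: str,
    inserted_assay: str = "inserted",
    cre_id: str = "",
    p_threshold: float = DEFAULT_VARIANT_P,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-variant effect regression for one CRE and one enriched assay.

    ``elements`` is the CRE's perturbation design (one wild-type element
    plus variants); ``counts`` a tidy count table covering at least the
    ``enriched_assay`` and ``inserted_assay`` rows of those elements.
    Replicates enter as independent observations of
    ``log2(enriched CPM) ~ log2(inserted CPM) + N + offset`` where N is a
    binary indicator per variant (wild type = baseline).  Variants with no
    counts in any replicate are omitted (flagged in the ``omitted``
    attribute of the returned frame).  Significance is raw ``p <
    p_threshold`` unless ``adjust`` requests BH.
    """
    wild_type = [e for e in elements if e.class_label == "wild_type"]
    if len(wild_type) != 1:
        raise ValueError(f"expected exactly one wild-type element, got {len(wild_type)}")
    wt_id = wild_type[0].id
    variants = [e for e in elements if e.class_label in {"snv", "window"}]
    variant_ids = [e.id for e in variants]
    ids = [wt_id] + variant_ids

    sub = counts[
        counts["element_id"].isin(ids) & counts["assay"].isin([enriched_assay, inserted_assay])
    ].copy()
    # pseudocount in count space (half the smallest observable molecule),
    # applied before CPM so zeros land just below one UMI, not at 0.5 CPM
    sub["count"] = sub["count"].astype(float).where(sub["count"] > 0, pseudocount)
    cpm = cpm_normalize(sub)
    wide = cpm.pivot_table(index=["element_id", "sample"], columns="assay", values="cpm").reset_index()
    wide = wide.dropna(subset=[inserted_assay])
    observed = set(wide["element_id"])
    omitted = [v for v in variant_ids if v not in observed]
    used_variants = [v for v in variant_ids if v in observed]
    if wt_id not in observed:
        raise ValueError(f"wild-type element {wt_id!r} has no usable counts")

    # rows absent from the enriched library entirely behave like a zero
    # count: half the smallest observed enriched CPM
    floor = float(wide[enriched_assay].min()) / 2 if wide[enriched_assay].notna().any() else pseudocount
    enr = wide[enriched_assay].fillna(floor).to_numpy(dtype=float)
    ins = wide[inserted_assay].to_numpy(dtype=float)
    y = np.log2(enr)
    x_ins = np.log2(ins)
    index_of = {v: j for j, v in enumerate(used_variants)}
    N = np.zeros((len(wide), len(used_variants)))
    for row, element_id in enumerate(wide["element_id"]):
        j = index_of.get(element_id)
        if j is not None:
            N[row, j] = 1.0
    X = np.column_stack([np.ones(len(wide)), x_ins, N])
    fit = _ols_fit(y, X, ["offset", "log2_inserted", *used_variants])

    info = {e.id: (e.variant_info or {}) for e in variants}
    records = []
    for term, coef, p in fit.iloc[2:][["term", "coef", "p_value"]].itertuples(index=False):
        vi = info[term]
        records.append(
            {
                "cre_id": cre_id,
                "assay": enriched_assay,
                "variant_id": term,
                "position": vi.get("position", vi.get("window_start")),
                "alt": vi.get("alt_base"),
                "coef": float(coef),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(records)
    if adjust and not out.empty:
        out["adj_p"] = bh_adjust(out["p_value"])
        out["significant"] = out["adj_p"] < p_threshold
    elif not out.empty:
        out["significant"] = out["p_value"] < p_threshold
    out.attrs["omitted"] = omitted
    out.attrs["inserted_slope"] = float(fit.loc[1, "coef"])
    return out
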