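"""UMI-based quantification and negative-control-anchored normalization.

Activity of an element is the ratio of its assay-captured ("enriched")
UMI count to its genomic integration frequency ("inserted" UMI count);
for the reporter assay it is the ratio of RNA to DNA barcode counts,
averaged over barcodes.  Counts are CPM-normalized within each
(sample, assay), then anchored with a trimmed-mean-of-M-values (TMM)
scaling factor computed over negative-control elements so that the
expected log2 activity of negatives is 0 in every sample.

Tidy table layouts used throughout:

* UMI tag table   — columns ``element_id, umi, sample, assay``
* count table     — columns ``element_id, sample, assay, count``
* barcode counts  — columns ``element_id, barcode, sample, dna_count, rna_count``
* activity table  — columns ``element_id, assay, sample, log2_activity, qc_flag``
  (``sample == "combined"`` for the across-replicate summary)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["element_id", "sample", "assay", "count"]
TAG_COLUMNS = ["element_id", "umi", "sample", "assay"]
BARCODE_COLUMNS = ["element_id", "barcode", "sample", "dna_count", "rna_count"]

DEFAULT_MIN_BARCODES = 5
DEFAULT_MIN_INSERTED = 5
DEFAULT_PSEUDOCOUNT = 0.5


class NormalizationError(ValueError):
    """Raised for empty libraries or unusable negative-control sets."""


# ---------------------------------------------------------------------------
# UMI deduplication


def dedup_umis(tags: pd.DataFrame) -> pd.DataFrame:
    """Collapse a UMI tag table to unique-UMI counts.

    The count for (element, sample, assay) is the number of *distinct* UMI
    strings observed, i.e. PCR duplicates sharing a UMI collapse to one
    molecule.
    """
    if tags.empty:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    missing = [c for c in TAG_COLUMNS if c not in tags.columns]
    if missing:
        raise ValueError(f"tag table missing columns: {missing}")
    counts = (
        tags.groupby(["element_id", "sample", "assay"], sort=True)["umi"]
        .nunique()
        .rename("count")
        .reset_index()
    )
    return counts[COUNT_COLUMNS]


# ---------------------------------------------------------------------------
# CPM + TMM


def cpm_normalize(counts: pd.DataFrame, value_col: str = "count") -> pd.DataFrame:
    """Counts-per-million within each (sample, assay); adds a ``cpm`` column."""
    out = counts.copy()
    totals = out.groupby(["sample", "assay"])[value_col].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, ["sample", "assay"]].drop_duplicates()
        raise NormalizationError(f"zero library size for {bad.to_dict('records')}")
    out["cpm"] = out[value_col] / totals * 1e6
    return out


def tmm_factor(
    enriched: pd.Series,
    inserted: pd.Series,
    negative_ids: Iterable[str],
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_negatives: int = 8,
    weighted: bool = False,
) -> float:
    """TMM scaling factor anchored on negative-control elements.

    ``enriched`` and ``inserted`` are CPM values indexed by element id.
    Over negatives with positive counts on both sides, M = log2(E/I) and
    A = 0.5*log2(E*I) are doubly trimmed (``trim_m`` per tail by M,
    ``trim_a`` per tail by A) and their mean M-bar taken.  Returns
    f = 2**M-bar; dividing all enriched values by f centers the negatives'
    doubly-trimmed mean log2 activity at exactly 0 (both the trim windows
    and the unit-weight mean are invariant under the common shift).
    ``weighted=True`` uses inverse-asymptotic-variance weights
    w = 1/(1/E + 1/I) instead; the anchoring is then exact only up to the
    weight recomputation.
    """
    negatives = pd.Index(sorted(set(negative_ids)))
    e = enriched.reindex(negatives).astype(float)
    i = inserted.reindex(negatives).astype(float)
    usable = (e > 0) & (i > 0)
    e, i = e[usable], i[usable]
    if len(e) < min_negatives:
        raise NormalizationError(
            f"only {len(e)} negative controls with positive counts on both "
            f"sides; need >= {min_negatives} (lower min_negatives or add controls)"
        )
    m = np.log2(e / i)
    a = 0.5 * np.log2(e * i)
    keep = _double_trim_mask(m.to_numpy(), a.to_numpy(), trim_m, trim_a)
    if keep.sum() == 0:
        raise NormalizationError("trimming removed every negative control")
    w = 1.0 / (1.0 / e + 1.0 / i) if weighted else pd.Series(1.0, index=e.index)
    m_bar = float(np.average(m.to_numpy()[keep], weights=w.to_numpy()[keep]))
    return float(2.0**m_bar)


def _double_trim_mask(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Keep values inside both the M-rank and A-rank trim windows."""
    n = m.size
    keep = np.ones(n, dtype=bool)
    for values, frac in ((m, trim_m), (a, trim_a)):
        cut = int(np.floor(n * frac))
        if cut == 0:
            continue
        order = np.argsort(values, kind="stable")
        keep[order[:cut]] = False
        keep[order[n - cut :]] = False
    return keep


def tmm_trimmed_mean(
    enriched: pd.Series,
    inserted: pd.Series,
    negative_ids: Iterable[str],
    **kwargs: object,
) -> float:
    """Trimmed weighted mean of negatives' log2(E/I) (log2 of the TMM factor)."""
    return float(np.log2(tmm_factor(enriched, inserted, negative_ids, **kwargs)))


# ---------------------------------------------------------------------------
# epigenetic (enriched / inserted) activity


def epigenetic_activity(
    enriched: pd.Series,
    inserted: pd.Series,
    f: float = 1.0,
    raw_inserted: pd.Series | None = None,
    min_inserted: int = DEFAULT_MIN_INSERTED,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-element log2((enriched / f) / inserted) with QC flags.

    ``enriched``/``inserted`` are CPM series indexed by element.  Elements
    whose *raw* inserted UMI count (``raw_inserted``, same index) falls
    below ``min_inserted`` are flagged ``low_inserted`` and left NaN —
    the poly-C-type dropout failure mode is an exclusion, not an error.
    A ``pseudocount`` (in the units of the series; callers working in CPM
    should pass half a UMI converted to CPM) is added to both sides only
    when either is zero.
    """
    if f <= 0:
        raise NormalizationError(f"TMM factor must be positive, got {f}")
    idx = enriched.index.union(inserted.index)
    e = enriched.reindex(idx).fillna(0.0).astype(float) / f
    i = inserted.reindex(idx).fillna(0.0).astype(float)
    needs_pc = (e == 0) | (i == 0)
    e = e.where(~needs_pc, e + pseudocount)
    i = i.where(~needs_pc, i + pseudocount)
    log2_activity = np.log2(e / i)
    qc = pd.Series("", index=idx, dtype=object)
    if raw_inserted is not None:
        low = raw_inserted.reindex(idx).fillna(0) < min_inserted
        qc[low] = "low_inserted"
        log2_activity[low] = np.nan
    return pd.DataFrame({"log2_activity": log2_activity, "qc_flag": qc}).rename_axis("element_id")


def combine_replicates(
    per_replicate: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Ratio-of-totals activity across replicates.

    ``per_replicate`` has columns ``element_id, sample, enriched, inserted``
    holding TMM-anchored CPM enriched and CPM inserted values.  Counts are
    summed per element across replicates first and the activity is the
    ratio of those totals (not the mean of per-replicate ratios).  Elements
    missing from some replicate use the replicates that observed them and
    are flagged ``missing_in_replicate``.
    """
    n_samples = per_replicate["sample"].nunique()
    grouped = per_replicate.groupby("element_id").agg(
        enriched=("enriched", "sum"),
        inserted=("inserted", "sum"),
        n_obs=("sample", "nunique"),
    )
    needs_pc = (grouped["enriched"] == 0) | (grouped["inserted"] == 0)
    e = grouped["enriched"].where(~needs_pc, grouped["enriched"] + pseudocount)
    i = grouped["inserted"].where(~needs_pc, grouped["inserted"] + pseudocount)
    out = pd.DataFrame(
        {
            "log2_activity": np.log2(e / i),
            "qc_flag": np.where(grouped["n_obs"] < n_samples, "missing_in_replicate", ""),
        },
        index=grouped.index,
    )
    return out


# ---------------------------------------------------------------------------
# reporter (barcode) side


def filter_mpra_elements(
    barcodes: pd.DataFrame, min_barcodes: int = DEFAULT_MIN_BARCODES
) -> tuple[pd.DataFrame, list[dict[str, object]]]:
    """Apply the reporter-assay barcode filters.

    Within each sample, barcodes must be observed in both the DNA and RNA
    libraries (both counts positive); elements then need at least
    ``min_barcodes`` surviving barcodes.  Returns the filtered table plus a
    log of exclusions (one record per dropped element with its reason).
    """
    exclusions: list[dict[str, object]] = []
    surviving = barcodes[(barcodes["dna_count"] > 0) & (barcodes["rna_count"] > 0)].copy()
    if min_barcodes <= 0:
        return surviving, exclusions
    n_bc = surviving.groupby(["element_id", "sample"])["barcode"].transform("nunique")
    keep = n_bc >= min_barcodes
    dropped = surviving.loc[~keep, ["element_id", "sample"]].drop_duplicates()
    for rec in dropped.to_dict("records"):
        n = int(
            surviving[
                (surviving["element_id"] == rec["element_id"])
                & (surviving["sample"] == rec["sample"])
            ]["barcode"].nunique()
        )
        exclusions.append({**rec, "reason": "low_barcodes", "n_barcodes": n})
    return surviving[keep], exclusions


def mpra_activity(
    barcodes: pd.DataFrame,
    negative_ids: Iterable[str] = (),
    aggregate: str = "mean",
    **tmm_kwargs: object,
) -> pd.DataFrame:
    """Per-element reporter activity: mean of barcode RNA/DNA CPM ratios.

    DNA and RNA counts are CPM-normalized separately within each sample,
    per-barcode ratios taken, and barcodes aggregated per element by
    ``aggregate`` ("mean", the default, or "median").  When negatives are
    given, the log2 activities are anchored by a TMM-style factor computed
    on the *same statistic being anchored*: the doubly trimmed mean of the
    negatives' log2 aggregated ratios (trimmed by that M and by the
    summed-CPM abundance A), so the negatives' trimmed mean is exactly 0
    after anchoring.  Returns columns ``element_id, sample, ratio,
    log2_activity, n_barcodes``.
    """
    if aggregate not in {"mean", "median"}:
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    negative_ids = list(negative_ids)
    frames = []
    for sample, group in barcodes.groupby("sample"):
        dna_tot, rna_tot = group["dna_count"].sum(), group["rna_count"].sum()
        if dna_tot <= 0 or rna_tot <= 0:
            raise NormalizationError(f"sample {sample!r}: zero DNA or RNA library size")
        g = group.assign(
            dna_cpm=group["dna_count"] / dna_tot * 1e6,
            rna_cpm=group["rna_count"] / rna_tot * 1e6,
        )
        g["ratio"] = g["rna_cpm"] / g["dna_cpm"]
        per_element = g.groupby("element_id").agg(
            ratio=("ratio", aggregate), n_barcodes=("barcode", "nunique")
        )
        f = 1.0
        if negative_ids:
            sums = g.groupby("element_id")[["rna_cpm", "dna_cpm"]].sum()
            negs = per_element.index.intersection(negative_ids).intersection(sums.index)
            usable = negs[(per_element.loc[negs, "ratio"] > 0)]
            min_negatives = int(tmm_kwargs.get("min_negatives", 8))
            if len(usable) < min_negatives:
                raise NormalizationError(
                    f"sample {sample!r}: only {len(usable)} usable negative controls"
                )
            m = np.log2(per_element.loc[usable, "ratio"].to_numpy())
            a = 0.5 * np.log2(
                (sums.loc[usable, "rna_cpm"] * sums.loc[usable, "dna_cpm"]).to_numpy()
            )
            keep = _double_trim_mask(
                m, a, float(tmm_kwargs.get("trim_m", 0.30)), float(tmm_kwargs.get("trim_a", 0.05))
            )
            f = float(2.0 ** np.mean(m[keep]))
        per_element["log2_activity"] = np.log2(per_element["ratio"] / f)
        per_element["sample"] = sample
        frames.append(per_element.reset_index())
    out = pd.concat(frames, ignore_index=True)
    return out[["element_id", "sample", "ratio", "log2_activity", "n_barcodes"]]


# ---------------------------------------------------------------------------
# full pipeline convenience


@dataclass
class QuantificationResult:
    """Activity tables plus the QC bookkeeping of a quantification run."""

    per_replicate: pd.DataFrame  # element_id, assay, sample, log2_activity, qc_flag
    combined: pd.DataFrame  # element_id, assay, log2_activity, qc_flag
    tmm_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    exclusions: list[dict[str, object]] = field(default_factory=list)

    def activity(self, assay: str) -> pd.Series:
        """Combined log2 activity for one assay, indexed by element id."""
        sub = self.combined[self.combined["assay"] == assay]
        return sub.set_index("element_id")["log2_activity"]

    def qc_report(self) -> dict[str, object]:
        return {
            "tmm_factors": {f"{s}/{a}": f for (s, a), f in self.tmm_factors.items()},
            "n_excluded": len(self.exclusions),
            "exclusions": self.exclusions,
        }


def quantify_epigenetic(
    counts: pd.DataFrame,
    negative_ids: Iterable[str],
    enriched_assays: Sequence[str] = ("atac", "cuttag"),
    inserted_assay: str = "inserted",
    min_inserted: int = DEFAULT_MIN_INSERTED,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tmm_per_replicate: bool = True,
    **tmm_kwargs: object,
) -> QuantificationResult:
    """CPM -> TMM anchoring -> activity, per replicate and combined.

    ``counts`` is a tidy UMI count table; each enriched assay is paired
    with the ``inserted_assay`` of the same sample.  TMM anchoring is
    applied within each replicate by default (``tmm_per_replicate=False``
    computes a single factor from pooled counts instead).
    """
    negative_ids = list(negative_ids)
    cpm = cpm_normalize(counts)
    # half a UMI on the CPM scale, per (sample, assay) library
    totals = counts.groupby(["sample", "assay"])["count"].sum()
    pc_cpm = pseudocount * 1e6 / totals
    samples = sorted(counts["sample"].unique())
    per_rep_frames = []
    combine_frames: dict[str, list[pd.DataFrame]] = {a: [] for a in enriched_assays}
    factors: dict[tuple[str, str], float] = {}
    exclusions: list[dict[str, object]] = []

    pooled_f: dict[str, float] = {}
    if not tmm_per_replicate:
        pooled = counts.groupby(["element_id", "assay"])["count"].sum().reset_index()
        pooled["sample"] = "pooled"
        pooled_cpm = cpm_normalize(pooled)
        ins = pooled_cpm[pooled_cpm["assay"] == inserted_assay].set_index("element_id")["cpm"]
        for assay in enriched_assays:
            enr = pooled_cpm[pooled_cpm["assay"] == assay].set_index("element_id")["cpm"]
            pooled_f[assay] = tmm_factor(enr, ins, negative_ids, **tmm_kwargs)

    for sample in samples:
        sub = cpm[cpm["sample"] == sample]
        inserted = sub[sub["assay"] == inserted_assay].set_index("element_id")["cpm"]
        raw_inserted = sub[sub["assay"] == inserted_assay].set_index("element_id")["count"]
        for assay in enriched_assays:
            enriched = sub[sub["assay"] == assay].set_index("element_id")["cpm"]
            if tmm_per_replicate:
                f = tmm_factor(enriched, inserted, negative_ids, **tmm_kwargs)
            else:
                f = pooled_f[assay]
            factors[(sample, assay)] = f
            act = epigenetic_activity(
                enriched,
                inserted,
                f,
                raw_inserted=raw_inserted,
                min_inserted=min_inserted,
                pseudocount=float(pc_cpm[(sample, assay)]),
            ).reset_index()
            act["sample"] = sample
            act["assay"] = assay
            per_rep_frames.append(act)
            for rec in act.loc[act["qc_flag"] == "low_inserted"].itertuples():
                exclusions.append(
                    {
                        "element_id": rec.element_id,
                        "sample": sample,
                        "assay": assay,
                        "reason": "low_inserted",
                    }
                )
            idx = enriched.index.union(inserted.index)
            combine_frames[assay].append(
                pd.DataFrame(
                    {
                        "element_id": idx,
                        "sample": sample,
                        "enriched": enriched.reindex(idx).fillna(0.0) / f,
                        "inserted": inserted.reindex(idx).fillna(0.0),
                    }
                )
            )

    per_replicate = pd.concat(per_rep_frames, ignore_index=True)[
        ["element_id", "assay", "sample", "log2_activity", "qc_flag"]
    ]
    combined_frames = []
    for assay in enriched_assays:
        pc = float(np.mean([pc_cpm[(s, assay)] for s in samples]))
        comb = combine_replicates(pd.concat(combine_frames[assay], ignore_index=True), pseudocount=pc)
        comb = comb.reset_index()
        comb["assay"] = assay
        # propagate the low_inserted exclusion to the combined table when an
        # element was flagged in every replicate
        flagged = (
            per_replicate[(per_replicate["assay"] == assay)]
            .groupby("element_id")["qc_flag"]
            .apply(lambda s: (s == "low_inserted").all())
        )
        always_low = flagged[flagged].index
        comb.loc[comb["element_id"].isin(always_low), "log2_activity"] = np.nan
        comb.loc[comb["element_id"].isin(always_low), "qc_flag"] = "low_inserted"
        combined_frames.append(comb)
    combined = pd.concat(combined_frames, ignore_index=True)[
        ["element_id", "assay", "log2_activity", "qc_flag"]
    ]
    return QuantificationResult(per_replicate, combined, factors, exclusions)


def quantify_mpra(
    barcodes: pd.DataFrame,
    negative_ids: Iterable[str],
    min_barcodes: int = DEFAULT_MIN_BARCODES,
    aggregate: str = "mean",
    assay_name: str = "mpra",
    **tmm_kwargs: object,
) -> QuantificationResult:
    """Barcode filtering + per-element reporter activity, anchored on negatives.

    Combined activity is the across-replicate mean of per-replicate log2
    activities (reporter activities are already barcode averages).
    """
    filtered, exclusions = filter_mpra_elements(barcodes, min_barcodes=min_barcodes)
    act = mpra_activity(filtered, negative_ids=negative_ids, aggregate=aggregate, **tmm_kwargs)
    per_replicate = act.assign(assay=assay_name, qc_flag="")[
        ["element_id", "assay", "sample", "log2_activity", "qc_flag"]
    ]
    n_samples = act["sample"].nunique()
    comb = act.groupby("element_id").agg(
        log2_activity=("log2_activity", "mean"), n_obs=("sample", "nunique")
    )
    combined = pd.DataFrame(
        {
            "element_id": comb.index,
            "assay": assay_name,
            "log2_activity": comb["log2_activity"].to_numpy(),
            "qc_flag": np.where(comb["n_obs"] < n_samples, "missing_in_replicate", ""),
        }
    )
    return QuantificationResult(per_replicate, combined, {}, exclusions)
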