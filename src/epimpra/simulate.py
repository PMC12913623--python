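"""Seeded synthetic libraries and count tables with known ground truth.

The generator composes a true log2 activity for every designed element
from additive per-motif effects, pairwise synergy terms, optional
slot-position modifiers and template effects (negative controls are fixed
at 0), then emits UMI count tables with negative-binomial noise whose
means follow the enrichment model: inserted counts track an
element-specific lentiviral integration frequency, enriched counts track
integration frequency times 2**activity.  Reporter barcode tables pair
DNA and RNA counts per barcode.

Default depths emulate the reported sequencing scales: a few hundred
inserted UMIs and a few dozen enriched UMIs per element, and on the order
of 80 barcodes per element for the reporter assay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    DesignedElement,
    LibraryDesign,
    build_snv_library,
    build_window_library,
    _random_sequence,
)
from .motifs import MotifDef

DEFAULT_ASSAYS = ("mpra", "atac", "cuttag")
DEFAULT_INSERTED_DEPTH = 400.0
DEFAULT_ENRICHED_DEPTH = 50.0
DEFAULT_DISPERSION = 0.1


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EffectConfig:
    """Planted effect sizes (log2 units) for truth construction.

    ``motif_effects`` is per copy; ``synergy`` applies per unit of the
    pair's interaction term k (the minimum copy number of the two motifs
    in an element); ``position_effects`` maps (motif, slot) to an additive
    modifier; ``assay_scale`` multiplies the whole truth per assay
    (default 1 everywhere).
    """

    motif_effects: dict[str, float] = field(default_factory=dict)
    synergy: dict[tuple[str, str], float] = field(default_factory=dict)
    position_effects: dict[tuple[str, int], float] = field(default_factory=dict)
    template_effects: dict[str, float] = field(default_factory=dict)
    assay_scale: dict[str, float] = field(default_factory=dict)

    def known_motifs(self) -> set[str]:
        names = set(self.motif_effects)
        for a, b in self.synergy:
            names.update((a, b))
        for m, _slot in self.position_effects:
            names.add(m)
        return names


@dataclass
class GroundTruth:
    """True activities and the provenance needed to reproduce them."""

    truth: pd.DataFrame  # index element_id, one column per assay
    negative_ids: list[str] = field(default_factory=list)
    functional_windows: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int | None = None

    def activity(self, assay: str) -> pd.Series:
        return self.truth[assay]

    def to_json(self) -> str:
        return json.dumps(
            {
                "truth": {a: self.truth[a].to_dict() for a in self.truth.columns},
                "negative_ids": self.negative_ids,
                "functional_windows": self.functional_windows,
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "GroundTruth":
        data = json.loads(payload)
        truth = pd.DataFrame(data["truth"])
        truth.index.name = "element_id"
        return cls(
            truth=truth,
            negative_ids=list(data["negative_ids"]),
            functional_windows=[tuple(w) for w in data["functional_windows"]],
            seed=data["seed"],
        )


# ---------------------------------------------------------------------------
# truth construction


def _element_truth(element: DesignedElement, config: EffectConfig) -> float:
    if element.class_label in {"control", "pilot_category"}:
        return 0.0
    value = config.template_effects.get(element.template_id or "", 0.0)
    counts: dict[str, int] = {}
    for name, copies, slot in element.motif_layout:
        value += config.motif_effects.get(name, 0.0)
        value += config.position_effects.get((name, slot), 0.0)
        counts[name] = copies
    for (a, b), delta in config.synergy.items():
        if a in counts and b in counts and a != b:
            value += delta * min(counts[a], counts[b])
    return value


def simulate_design_truth(
    design: LibraryDesign,
    config: EffectConfig,
    assays: Sequence[str] = DEFAULT_ASSAYS,
    seed: int | None = None,
) -> GroundTruth:
    """True log2 activity per element and assay from planted effects.

    Truth is additive: per-copy motif effects + synergy * k + slot
    modifiers + template effect, scaled per assay by
    ``config.assay_scale``; control elements are exactly 0.  Raises when
    the config names motifs absent from the design.
    """
    design_names = {m.name for m in design.motif_set}
    unknown = config.known_motifs() - design_names
    if unknown:
        raise ValueError(f"effect config references unknown motifs: {sorted(unknown)}")
    base = pd.Series({e.id: _element_truth(e, config) for e in design.elements})
    truth = pd.DataFrame(
        {assay: base * config.assay_scale.get(assay, 1.0) for assay in assays}
    )
    truth.index.name = "element_id"
    return GroundTruth(truth=truth, negative_ids=design.negative_control_ids, seed=seed)


# ---------------------------------------------------------------------------
# count emission


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws parameterized by mean and dispersion.

    Var = mean + dispersion * mean**2; dispersion 0 is the Poisson limit.
    """
    mean = np.clip(np.asarray(mean, dtype=float), 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    truth: GroundTruth,
    n_replicates: int = 3,
    inserted_depth: float = DEFAULT_INSERTED_DEPTH,
    enriched_depth: float = DEFAULT_ENRICHED_DEPTH,
    dispersion: float = DEFAULT_DISPERSION,
    integration_sd: float = 0.5,
    enriched_assays: Sequence[str] | None = None,
    seed: int = 0,
    barcode_assay: str = "mpra",
    barcodes_per_element: tuple[int, int] = (40, 120),
    dna_per_barcode: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit UMI count tables (and barcode counts) for the planted truth.

    Inserted counts are NB around ``inserted_depth`` times an
    element-specific log-normal integration frequency (sd
    ``integration_sd`` in log space).  Replicates model independent
    library infections, so integration frequencies are redrawn per
    replicate.  Enriched counts for each assay are NB around
    integration * 2**truth scaled to ``enriched_depth``.  When ``barcode_assay`` is in the truth table a
    reporter barcode table is also produced (DNA ~ NB, RNA ~ NB around
    DNA mean * 2**truth).  Returns (count_table, barcode_table).
    """
    rng = np.random.default_rng(seed)
    if enriched_assays is None:
        enriched_assays = tuple(
            a for a in truth.truth.columns if a not in (barcode_assay, "inserted")
        )
    elements = list(truth.truth.index)
    n = len(elements)
    samples = [f"rep{r}" for r in range(1, n_replicates + 1)]

    count_rows = []
    for sample in samples:
        # independent infection per replicate: fresh integration frequencies
        integration = np.exp(rng.normal(0.0, integration_sd, size=n))
        integration /= integration.mean()
        inserted = _nb_draw(rng, inserted_depth * integration, dispersion)
        count_rows.append(
            pd.DataFrame(
                {"element_id": elements, "sample": sample, "assay": "inserted", "count": inserted}
            )
        )
        for assay in enriched_assays:
            fold = np.power(2.0, truth.truth[assay].to_numpy())
            mean = enriched_depth * integration * fold / np.mean(fold)
            enriched = _nb_draw(rng, mean, dispersion)
            count_rows.append(
                pd.DataFrame(
                    {"element_id": elements, "sample": sample, "assay": assay, "count": enriched}
                )
            )
    counts = pd.concat(count_rows, ignore_index=True)

    barcode_rows = []
    if barcode_assay in truth.truth.columns:
        lo, hi = barcodes_per_element
        n_bc = rng.integers(lo, hi + 1, size=n)
        fold = np.power(2.0, truth.truth[barcode_assay].to_numpy())
        elem_idx = np.repeat(np.arange(n), n_bc)
        element_col = np.asarray(elements, dtype=object)[elem_idx]
        bc_num = np.concatenate([np.arange(k) for k in n_bc]) if n else np.empty(0, int)
        barcode_col = np.array([f"bc{j}_{b}" for j, b in zip(elem_idx, bc_num)], dtype=object)
        bc_freq = np.exp(rng.normal(0.0, 0.3, size=elem_idx.size))
        dna_mean = dna_per_barcode * bc_freq
        rna_mean = dna_mean * fold[elem_idx]
        for sample in samples:
            barcode_rows.append(
                pd.DataFrame(
                    {
                        "element_id": element_col,
                        "barcode": barcode_col,
                        "sample": sample,
                        "dna_count": _nb_draw(rng, dna_mean, dispersion),
                        "rna_count": _nb_draw(rng, rna_mean, dispersion),
                    }
                )
            )
    barcodes = (
        pd.concat(barcode_rows, ignore_index=True)
        if barcode_rows
        else pd.DataFrame(columns=["element_id", "barcode", "sample", "dna_count", "rna_count"])
    )
    return counts, barcodes


def simulate_activities(
    truth: GroundTruth,
    noise_sd: float,
    n_replicates: int = 3,
    assays: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate activity table: truth + iid Gaussian noise.

    A lighter-weight alternative to full count simulation for analyses
    whose noise model is specified directly on the activity scale.
    """
    rng = np.random.default_rng(seed)
    assays = list(assays) if assays is not None else list(truth.truth.columns)
    rows = []
    for r in range(1, n_replicates + 1):
        for assay in assays:
            values = truth.truth[assay].to_numpy()
            rows.append(
                pd.DataFrame(
                    {
                        "element_id": truth.truth.index,
                        "assay": assay,
                        "sample": f"rep{r}",
                        "log2_activity": values + rng.normal(0.0, noise_sd, size=values.size),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# perturbation datasets


@dataclass
class SimulatedPerturbation:
    """A perturbation study with planted functional windows."""

    cre_id: str
    sequence: str
    elements: list[DesignedElement]
    truth: GroundTruth
    activities: pd.DataFrame  # per-replicate truth + noise, tidy
    counts: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)


def _variant_span(element: DesignedElement) -> tuple[int, int] | None:
    vi = element.variant_info or {}
    if "position" in vi:
        return (int(vi["position"]), int(vi["position"]))
    if "window_start" in vi:
        start = int(vi["window_start"])
        return (start, start + int(vi.get("window_length", 6)) - 1)
    return None


def simulate_perturbation_dataset(
    cre_length: int = 100,
    functional_windows: Sequence[tuple[int, int, float]] = (),
    noise_sd: float = 0.15,
    n_replicates: int = 3,
    assays: Sequence[str] = ("atac",),
    motif_set: Sequence[MotifDef] = (),
    window_replicates: int = 2,
    include_snv: bool = True,
    seed: int = 0,
    cre_id: str = "cre1",
    with_counts: bool = False,
    **count_kwargs: object,
) -> SimulatedPerturbation:
    """Design + truth + noisy activities for one perturbed CRE.

    A random CRE sequence is drawn, its SNV and 6-bp window libraries
    built, and every variant whose mutated span overlaps a planted
    functional window ``(start, end, effect)`` carries that window's
    additive effect; all other variants and the wild type are 0.
    Overlapping planted windows are allowed (their effects add) but
    flagged.  ``with_counts`` additionally emits NB count tables via
    :func:`simulate_counts`.
    """
    for start, end, _effect in functional_windows:
        if not (1 <= start <= end <= cre_length):
            raise ValueError(f"functional window ({start}, {end}) outside 1..{cre_length}")
    rng = np.random.default_rng(seed)
    sequence = _random_sequence(rng, cre_length)
    elements: list[DesignedElement] = []
    if include_snv:
        elements += build_snv_library(cre_id, sequence, include_wild_type=True)
    else:
        elements.append(
            DesignedElement(id=f"{cre_id}_wt", class_label="wild_type", sequence=sequence)
        )
    elements += build_window_library(
        cre_id,
        sequence,
        motif_set=motif_set,
        replicates=window_replicates,
        seed=int(rng.integers(2**31)),
    )

    windows = sorted(functional_windows)
    overlap_flag = any(
        w1[1] >= w2[0] for w1, w2 in zip(windows, windows[1:])
    )
    truth_values = {}
    for e in elements:
        span = _variant_span(e)
        value = 0.0
        if span is not None:
            for start, end, effect in windows:
                if span[0] <= end and start <= span[1]:
                    value += effect
        truth_values[e.id] = value
    truth_df = pd.DataFrame({assay: pd.Series(truth_values) for assay in assays})
    truth_df.index.name = "element_id"
    truth = GroundTruth(
        truth=truth_df,
        functional_windows=[tuple(w) for w in windows],
        seed=seed,
    )
    activities = simulate_activities(
        truth, noise_sd=noise_sd, n_replicates=n_replicates, seed=int(rng.integers(2**31))
    )
    counts = None
    if with_counts:
        counts, _ = simulate_counts(
            truth,
            n_replicates=n_replicates,
            enriched_assays=tuple(assays),
            seed=int(rng.integers(2**31)),
            barcode_assay="__none__",
            **count_kwargs,
        )
    return SimulatedPerturbation(
        cre_id=cre_id,
        sequence=sequence,
        elements=elements,
        truth=truth,
        activities=activities,
        counts=counts,
        flags=["overlapping_planted_windows"] if overlap_flag else [],
    )
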