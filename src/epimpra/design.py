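"""Combinatorial design of 100-bp synthetic-enhancer and perturbation libraries.

The designer produces four families of elements:

* **Class 1** — homotypic arrangements: 1, 2 or 4 evenly spaced copies of a
  single TF motif on a neutral template.
* **Class 2** — heterotypic pairs: for every ordered pair (A, B) of distinct
  motifs, a 1:1 arrangement (one copy each) and a 2:2 block arrangement
  (two copies each).
* **Class 3** — heterotypic quadruples: every 4-motif subset in all 4! slot
  orders, one copy per slot.
* **Perturbation libraries** — single-nucleotide substitutions (every
  position to each of the three alternative bases) and randomized 6-bp
  sliding windows with a motif-emergence rejection step.

Motifs are substituted into the template at four fixed, evenly spaced slot
anchors.  Slot 1 is the most distal from the minimal promoter and slot 4
the most proximal.  Coordinates are 1-based closed intervals throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motifs import BASES, MotifDef, scan_motifs

TEMPLATE_LENGTH = 100

#: 1-based start positions of the four motif slots on a 100-bp template.
DEFAULT_SLOT_ANCHORS: tuple[int, int, int, int] = (8, 30, 52, 74)

#: Slots occupied by Class 1 arrangements, keyed by copy number.
CLASS1_SLOTS: dict[int, tuple[int, ...]] = {1: (2,), 2: (2, 3), 4: (1, 2, 3, 4)}

CLASS_LABELS = frozenset(
    {"pilot_category", "class1", "class2", "class3", "snv", "window", "control", "wild_type"}
)


class DesignError(ValueError):
    """Raised when a requested layout cannot be placed on a template."""


@dataclass(frozen=True)
class TemplateSeq:
    """A neutral 100-bp backbone sequence with genomic provenance."""

    id: str
    sequence: str
    source_coords: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != TEMPLATE_LENGTH:
            raise ValueError(
                f"template {self.id!r}: length {len(seq)}, expected {TEMPLATE_LENGTH}"
            )
        if any(b not in BASES for b in seq):
            raise ValueError(f"template {self.id!r}: alphabet must be A/C/G/T")


@dataclass(frozen=True)
class DesignedElement:
    """One library member: sequence, class, motif layout and provenance.

    ``motif_layout`` is an ordered tuple of ``(motif_name, copy_count,
    slot_index)`` placements; ``copy_count`` is the total number of copies
    of that motif in the element (so a 2-copy homotypic element carries two
    entries, each with copy_count 2).  ``variant_info`` holds either
    ``{"position", "ref_base", "alt_base"}`` for SNVs or ``{"window_start",
    "window_length", "replicate_index"}`` for window perturbations.
    ``category`` is the pilot/control sequence category where applicable.
    """

    id: str
    class_label: str
    sequence: str
    motif_layout: tuple[tuple[str, int, int], ...] = ()
    template_id: str | None = None
    variant_info: Mapping[str, object] | None = None
    adapters: tuple[str, str] = ("", "")
    category: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "motif_layout", tuple(tuple(p) for p in self.motif_layout))
        if self.variant_info is not None:
            object.__setattr__(self, "variant_info", dict(self.variant_info))

    @property
    def full_sequence(self) -> str:
        """Element sequence with 5'/3' adapters attached."""
        return self.adapters[0] + self.sequence + self.adapters[1]


@dataclass
class LibraryDesign:
    """A complete designed library plus the motif/template context."""

    elements: list[DesignedElement]
    motif_set: list[MotifDef] = field(default_factory=list)
    templates: list[TemplateSeq] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [e.id for e in self.elements]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate element ids: {dupes[:5]}")
        template_ids = {t.id for t in self.templates}
        for e in self.elements:
            if e.class_label in {"class1", "class2", "class3"} and e.template_id not in template_ids:
                raise ValueError(f"element {e.id!r} references unknown template {e.template_id!r}")

    def by_class(self, class_label: str) -> list[DesignedElement]:
        return [e for e in self.elements if e.class_label == class_label]

    def element(self, element_id: str) -> DesignedElement:
        for e in self.elements:
            if e.id == element_id:
                return e
        raise KeyError(element_id)

    @property
    def negative_control_ids(self) -> list[str]:
        """Random-genomic control elements (the TMM anchoring set)."""
        return [
            e.id
            for e in self.elements
            if e.category == "random_genomic" and e.class_label in {"control", "pilot_category"}
        ]


# ---------------------------------------------------------------------------
# motif placement


def place_motifs(
    template: TemplateSeq,
    placements: Sequence[tuple[MotifDef, int]],
    anchors: Sequence[int] = DEFAULT_SLOT_ANCHORS,
) -> str:
    """Substitute motifs into ``template`` at fixed slot anchors.

    ``placements`` is a sequence of (motif, slot_index) with slots in 1..4,
    slot 1 most distal from the minimal promoter.  An empty placement list
    returns the template sequence unchanged.  Raises :class:`DesignError`
    when a motif overruns the template or two placements overlap.
    """
    seq = list(template.sequence)
    spans: list[tuple[int, int, str]] = []
    occupied: set[int] = set()
    for motif, slot in placements:
        if not 1 <= slot <= len(anchors):
            raise DesignError(f"slot {slot} outside 1..{len(anchors)}")
        if slot in occupied:
            raise DesignError(f"slot {slot} assigned twice in layout {placements!r}")
        occupied.add(slot)
        start = anchors[slot - 1]  # 1-based
        end = start + motif.length - 1
        if end > len(seq):
            raise DesignError(
                f"motif {motif.name!r} (len {motif.length}) at slot {slot} "
                f"overruns the {len(seq)}-bp template"
            )
        spans.append((start, end, motif.name))
    spans.sort()
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise DesignError(f"motifs {n1!r} and {n2!r} overlap at positions {s2}..{e1}")
    for motif, slot in placements:
        start = anchors[slot - 1]
        instance = motif.consensus_sequence()
        seq[start - 1 : start - 1 + motif.length] = instance
    return "".join(seq)


# ---------------------------------------------------------------------------
# class builders


def build_class1(
    motifs: Sequence[MotifDef],
    templates: Sequence[TemplateSeq],
    copy_numbers: Sequence[int] = (1, 2, 4),
    anchors: Sequence[int] = DEFAULT_SLOT_ANCHORS,
    class1_slots: Mapping[int, tuple[int, ...]] | None = None,
) -> list[DesignedElement]:
    """Homotypic arrangements: one element per (motif, copy number, template)."""
    if not motifs or not templates:
        raise DesignError("build_class1 requires at least one motif and one template")
    slots_map = dict(CLASS1_SLOTS if class1_slots is None else class1_slots)
    elements = []
    for template in templates:
        for motif in motifs:
            for copies in copy_numbers:
                slots = slots_map[copies]
                seq = place_motifs(template, [(motif, s) for s in slots], anchors)
                elements.append(
                    DesignedElement(
                        id=f"class1_{motif.name}_x{copies}_{template.id}",
                        class_label="class1",
                        sequence=seq,
                        motif_layout=tuple((motif.name, copies, s) for s in slots),
                        template_id=template.id,
                    )
                )
    return elements


def build_class2(
    motifs: Sequence[MotifDef],
    templates: Sequence[TemplateSeq],
    anchors: Sequence[int] = DEFAULT_SLOT_ANCHORS,
) -> list[DesignedElement]:
    """Heterotypic pairs: every ordered pair in a 1:1 and a 2:2 arrangement.

    The 1:1 arrangement places A in slot 2 and B in slot 3; the 2:2
    arrangement places A in slots 1-2 and B in slots 3-4 (block layout).
    For M motifs and T templates this yields M*(M-1)*2*T elements.
    """
    if len(motifs) < 2:
        return []
    elements = []
    for template in templates:
        for a, b in itertools.permutations(motifs, 2):
            seq = place_motifs(template, [(a, 2), (b, 3)], anchors)
            elements.append(
                DesignedElement(
                    id=f"class2_{a.name}_{b.name}_1to1_{template.id}",
                    class_label="class2",
                    sequence=seq,
                    motif_layout=((a.name, 1, 2), (b.name, 1, 3)),
                    template_id=template.id,
                )
            )
            seq = place_motifs(template, [(a, 1), (a, 2), (b, 3), (b, 4)], anchors)
            elements.append(
                DesignedElement(
                    id=f"class2_{a.name}_{b.name}_2to2_{template.id}",
                    class_label="class2",
                    sequence=seq,
                    motif_layout=(
                        (a.name, 2, 1),
                        (a.name, 2, 2),
                        (b.name, 2, 3),
                        (b.name, 2, 4),
                    ),
                    template_id=template.id,
                )
            )
    return elements


def build_class3(
    motifs: Sequence[MotifDef],
    templates: Sequence[TemplateSeq],
    anchors: Sequence[int] = DEFAULT_SLOT_ANCHORS,
) -> list[DesignedElement]:
    """Heterotypic quadruples: each 4-subset in all 24 slot orders.

    Yields C(M, 4) * 24 * T elements for M motifs and T templates.
    """
    if len(motifs) < 4:
        raise DesignError("build_class3 requires at least four motifs")
    elements = []
    for template in templates:
        for subset in itertools.combinations(motifs, 4):
            for order in itertools.permutations(subset):
                seq = place_motifs(
                    template, [(m, slot) for slot, m in enumerate(order, start=1)], anchors
                )
                name = "-".join(m.name for m in order)
                elements.append(
                    DesignedElement(
                        id=f"class3_{name}_{template.id}",
                        class_label="class3",
                        sequence=seq,
                        motif_layout=tuple(
                            (m.name, 1, slot) for slot, m in enumerate(order, start=1)
                        ),
                        template_id=template.id,
                    )
                )
    return elements


# ---------------------------------------------------------------------------
# perturbation libraries


def build_snv_library(
    cre_id: str,
    sequence: str,
    include_wild_type: bool = True,
) -> list[DesignedElement]:
    """Saturation substitution: every position to each alternative base.

    Returns 3 * len(sequence) variant elements (class ``snv``), preceded by
    the wild-type element when ``include_wild_type``.
    """
    sequence = sequence.upper()
    if any(b not in BASES for b in sequence):
        raise DesignError(f"CRE {cre_id!r}: ambiguity codes are not allowed")
    elements: list[DesignedElement] = []
    if include_wild_type:
        elements.append(
            DesignedElement(id=f"{cre_id}_wt", class_label="wild_type", sequence=sequence)
        )
    for pos, ref in enumerate(sequence, start=1):
        for alt in BASES:
            if alt == ref:
                continue
            variant = sequence[: pos - 1] + alt + sequence[pos:]
            elements.append(
                DesignedElement(
                    id=f"{cre_id}_snv_p{pos}_{ref}to{alt}",
                    class_label="snv",
                    sequence=variant,
                    variant_info={"position": pos, "ref_base": ref, "alt_base": alt},
                )
            )
    return elements


def _randomize_window(window_seq: str, rng: np.random.Generator) -> str:
    """Redraw each base uniformly from the three non-reference bases."""
    out = []
    for ref in window_seq:
        choices = [b for b in BASES if b != ref]
        out.append(choices[rng.integers(3)])
    return "".join(out)


def build_window_library(
    cre_id: str,
    sequence: str,
    motif_set: Sequence[MotifDef] = (),
    window: int = 6,
    step: int = 1,
    replicates: int = 2,
    seed: int = 0,
    flank: int = 6,
    max_retries: int = 100,
    score_frac: float = 0.8,
) -> list[DesignedElement]:
    """Randomized sliding-window perturbation variants with motif rejection.

    Each ``window``-bp window (shifting by ``step``) is randomized
    independently ``replicates`` times.  A draw is rejected and redrawn when
    the mutated window together with its ``flank``-bp upstream and
    downstream context (18 bp total for the defaults) contains any motif
    match (:func:`~epimpra.motifs.scan_motifs`); rejection re-randomizes up
    to ``max_retries`` times before raising :class:`DesignError`.
    Deterministic for fixed (seed, sequence, motif_set).
    """
    sequence = sequence.upper()
    L = len(sequence)
    if L < window:
        raise DesignError(f"CRE {cre_id!r}: shorter than the {window}-bp window")
    if any(b not in BASES for b in sequence):
        raise DesignError(f"CRE {cre_id!r}: ambiguity codes are not allowed")
    rng = np.random.default_rng(seed)
    motifs = list(motif_set)
    elements = []
    for rep in range(1, replicates + 1):
        for start in range(1, L - window + 2, step):
            wt_window = sequence[start - 1 : start - 1 + window]
            accepted = None
            for _ in range(max_retries):
                mutated = _randomize_window(wt_window, rng)
                candidate = sequence[: start - 1] + mutated + sequence[start - 1 + window :]
                lo = max(0, start - 1 - flank)
                hi = min(L, start - 1 + window + flank)
                if motifs and scan_motifs(candidate[lo:hi], motifs, score_frac=score_frac):
                    continue
                accepted = candidate
                break
            if accepted is None:
                raise DesignError(
                    f"CRE {cre_id!r}: window at position {start} exhausted "
                    f"{max_retries} randomization attempts (motif rejection)"
                )
            elements.append(
                DesignedElement(
                    id=f"{cre_id}_win_p{start}_r{rep}",
                    class_label="window",
                    sequence=accepted,
                    variant_info={
                        "window_start": start,
                        "window_length": window,
                        "replicate_index": rep,
                    },
                )
            )
    return elements


# ---------------------------------------------------------------------------
# pilot / control sequences

PILOT_CATEGORIES: dict[str, int] = {
    "random_genomic": 50,
    "scrambled": 100,
    "active_genomic": 100,
    "inactive_genomic": 50,
    "synthetic_top": 50,
    "synthetic_bottom": 50,
}

CONTROL_CATEGORIES: dict[str, int] = {
    "random_genomic": 50,
    "scrambled": 50,
    "active_genomic": 50,
    "inactive_genomic": 50,
}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(4, size=length))


def build_pilot_library(
    seed: int = 0,
    categories: Mapping[str, int] | None = None,
    length: int = TEMPLATE_LENGTH,
    class_label: str = "pilot_category",
) -> list[DesignedElement]:
    """Pilot library: six sequence categories totalling 400 elements.

    The default category sizes are 50 random genomic, 100 scrambled, 100
    active genomic, 50 inactive genomic, and the top/bottom 50 synthetic
    sequences.  Sequences here are seeded random stand-ins (scrambled
    sequences are per-element shuffles of the active set), since the design
    step only needs category labels and distinct sequences.
    """
    sizes = dict(PILOT_CATEGORIES if categories is None else categories)
    rng = np.random.default_rng(seed)
    # non-scrambled categories first: scrambles are shuffles of the actives
    sequences: dict[str, list[str]] = {}
    for category, n in sizes.items():
        if category != "scrambled":
            sequences[category] = [_random_sequence(rng, length) for _ in range(n)]
    if "scrambled" in sizes:
        active = sequences.get("active_genomic", [])
        scrambled = []
        for i in range(sizes["scrambled"]):
            if active:
                base = list(active[i % len(active)])
                rng.shuffle(base)
                scrambled.append("".join(base))
            else:
                scrambled.append(_random_sequence(rng, length))
        sequences["scrambled"] = scrambled
    elements: list[DesignedElement] = []
    for category in sizes:
        for i, seq in enumerate(sequences[category], start=1):
            elements.append(
                DesignedElement(
                    id=f"{category}_{i:03d}",
                    class_label=class_label,
                    sequence=seq,
                    category=category,
                )
            )
    return elements


def build_control_set(seed: int = 0, categories: Mapping[str, int] | None = None) -> list[DesignedElement]:
    """200 control sequences (50 per category) used only for normalization."""
    return build_pilot_library(
        seed=seed,
        categories=CONTROL_CATEGORIES if categories is None else categories,
        class_label="control",
    )


def default_templates(seed: int = 20) -> list[TemplateSeq]:
    """Two neutral 100-bp templates (seeded stand-ins for the hg19 backbones)."""
    rng = np.random.default_rng(seed)
    return [
        TemplateSeq("tmplA", _random_sequence(rng, TEMPLATE_LENGTH), "chr9:83712634-83712733 (hg19)"),
        TemplateSeq("tmplB", _random_sequence(rng, TEMPLATE_LENGTH), "chr2:211153273-211153372 (hg19)"),
    ]


def build_synthetic_enhancer_library(
    motifs: Sequence[MotifDef],
    templates: Sequence[TemplateSeq],
    seed: int = 0,
    include_controls: bool = True,
    anchors: Sequence[int] = DEFAULT_SLOT_ANCHORS,
) -> LibraryDesign:
    """Full Class 1 + 2 + 3 library with the 200-sequence control set."""
    elements = (
        build_class1(motifs, templates, anchors=anchors)
        + build_class2(motifs, templates, anchors=anchors)
        + build_class3(motifs, templates, anchors=anchors)
    )
    if include_controls:
        elements += build_control_set(seed=seed)
    return LibraryDesign(
        elements=elements, motif_set=list(motifs), templates=list(templates), seed=seed
    )
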