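"""Synthetic data generation for the Se-locus pipeline.

Everything the downstream modules consume can be generated here with known
truth labels: locus sequences (a scaled reference with the PAV insert and
its variant haplotypes), accession panels with per-taxon type frequencies,
multinomially sampled cross progeny, and beta-binomial pollen-fertility
measurements that reproduce the bimodal fertile/semi-sterile pattern of a
segregating population.

The reference locus emulates the mapped region: two flanking genes (a
250-aa ORF1 analogue and a 466-aa ORF2 analogue) separated by the PAV
insert, which carries the 1791-nt killer CDS (596 aa + stop), the protector
promoter containing a 369-nt marker segment, and the 1572-nt protector CDS
(523 aa + stop).  Spacer DNA between features is shrunk ~10x by default so
tests run on kilobase-scale sequences; every feature length that downstream
logic measures (CDS lengths, the 369-nt marker) is preserved exactly.
Background sequence is i.i.d. uniform over {A,C,G,T}, which keeps the
exact-match primers and anchors unique with overwhelming probability (and
uniqueness is verified at build time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fertility import FertilityRecord
from .setyping import Lineage, LocusAnnotation, SeType
from .transmission import OffspringDistribution

__all__ = [
    "LocusTemplate",
    "ReferenceLocus",
    "VariantLocus",
    "PavAbsence",
    "Orf3StopAt",
    "Orf4PromoterDeletion",
    "TaxonSpec",
    "PanelSpec",
    "build_reference_locus",
    "apply_variants",
    "sequence_for_type",
    "default_panel_spec",
    "simulate_panel",
    "simulate_cross_counts",
    "simulate_fertility",
    "DEFAULT_TYPE_VARIANTS",
]

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# real-scale spacer budget (nt), shrunk by ``scale``
_REAL_SPACERS = {
    "left": 3000,       # upstream of ORF1
    "orf1_to_insert": 4000,
    "ins_left": 9000,   # insert start to killer CDS
    "ins_mid": 6000,    # killer CDS to protector promoter
    "ins_right": 9000,  # protector CDS to insert end
    "insert_to_orf2": 2000,
    "right": 2000,      # downstream of ORF2
}
_PROMOTER_UP = 120   # promoter bases upstream of the marker
_PROMOTER_DOWN = 80  # promoter bases between marker and protector ATG


@dataclass(frozen=True)
class LocusTemplate:
    """Parameters of the synthetic reference locus.

    ``scale`` multiplies all spacer (non-feature) segment lengths; feature
    lengths are absolute.  The same seed always yields the same locus.
    """

    scale: float = 0.1
    orf3_cds_len: int = 1791  # 596 aa + stop
    orf4_cds_len: int = 1572  # 523 aa + stop
    orf1_cds_len: int = 753   # 250 aa + stop
    orf2_cds_len: int = 1401  # 466 aa + stop
    promoter_marker_len: int = 369
    anchor_len: int = 24
    primer_len: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("orf3_cds_len", "orf4_cds_len", "orf1_cds_len", "orf2_cds_len"):
            if getattr(self, name) % 3:
                raise ValueError(f"{name} must be a multiple of 3")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass(frozen=True)
class ReferenceLocus:
    """The annotated Type-1 reference sequence (PAV present, all intact)."""

    seq: str
    annotation: LocusAnnotation
    features: Mapping[str, tuple[int, int]]
    template: LocusTemplate


@dataclass(frozen=True)
class VariantLocus:
    seq: str
    truth: dict


@dataclass(frozen=True)
class PavAbsence:
    """Remove the whole insert and join the flanking sequence."""


@dataclass(frozen=True)
class Orf3StopAt:
    """Substitute a stop codon at 1-based codon ``codon`` of the killer CDS.

    The translated product then has ``codon - 1`` residues, emulating the
    truncated killer haplotypes (e.g. a stop at codon 101 leaves the
    100-aa N-terminal fragment).
    """

    codon: int

    def __post_init__(self) -> None:
        if self.codon < 2:
            raise ValueError("stop codon position must be >= 2")


@dataclass(frozen=True)
class Orf4PromoterDeletion:
    """Excise exactly the promoter marker segment (369 nt by default)."""


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def build_reference_locus(template: LocusTemplate = LocusTemplate()) -> ReferenceLocus:
    """Deterministically build the annotated synthetic reference locus.

    Raises ``ValueError`` when ``scale`` shrinks a spacer below the room
    needed for unique anchors and primers.
    """
    spacers = {k: int(round(v * template.scale)) for k, v in _REAL_SPACERS.items()}
    min_spacer = 2 * template.anchor_len + template.primer_len
    too_small = [k for k, v in spacers.items() if v < min_spacer]
    if too_small:
        raise ValueError(
            f"scale {template.scale} leaves spacers {too_small} shorter than "
            f"{min_spacer} nt; features would collide"
        )

    for attempt in range(16):
        rng = np.random.default_rng(np.random.SeedSequence([template.seed, attempt]))
        locus = _assemble(template, spacers, rng)
        if locus is not None:
            return locus
    raise RuntimeError("could not build a locus with unique anchors")  # pragma: no cover


def _assemble(
    template: LocusTemplate, spacers: Mapping[str, int], rng: np.random.Generator
) -> ReferenceLocus | None:
    parts: list[str] = []
    features: dict[str, tuple[int, int]] = {}
    pos = 0

    def add(name: str | None, seq: str) -> None:
        nonlocal pos
        if name is not None:
            features[name] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)

    add(None, _random_seq(rng, spacers["left"]))
    add("orf1_cds", _random_cds(rng, template.orf1_cds_len))
    add(None, _random_seq(rng, spacers["orf1_to_insert"]))

    insert_start = pos
    add(None, _random_seq(rng, spacers["ins_left"]))
    add("orf3_cds", _random_cds(rng, template.orf3_cds_len))
    add(None, _random_seq(rng, spacers["ins_mid"]))
    add(None, _random_seq(rng, _PROMOTER_UP))
    add("promoter_marker", _random_seq(rng, template.promoter_marker_len))
    add(None, _random_seq(rng, _PROMOTER_DOWN))
    add("orf4_cds", _random_cds(rng, template.orf4_cds_len))
    add(None, _random_seq(rng, spacers["ins_right"]))
    features["insert"] = (insert_start, pos)

    add(None, _random_seq(rng, spacers["insert_to_orf2"]))
    add("orf2_cds", _random_cds(rng, template.orf2_cds_len))
    add(None, _random_seq(rng, spacers["right"]))

    seq = "".join(parts)
    a = template.anchor_len
    p = template.primer_len
    orf3 = features["orf3_cds"]
    orf4 = features["orf4_cds"]
    marker = features["promoter_marker"]

    # presence-assay primers spanning part of the killer CDS and the
    # protector promoter/CDS, so no product forms without the insert
    fwd_start = orf3[1] - 150
    fwd = seq[fwd_start : fwd_start + p]
    rev_bind_start = orf4[0] + 100
    rev_site = seq[rev_bind_start : rev_bind_start + p]
    rev = _revcomp(rev_site)
    product_len = (rev_bind_start + p) - fwd_start

    annotation = LocusAnnotation(
        pav_fwd_primer=fwd,
        pav_rev_primer=rev,
        pav_max_product=product_len + 200,
        orf3_anchor=seq[orf3[0] - a : orf3[0]],
        orf3_cds_len=template.orf3_cds_len,
        orf3_ref_aa=template.orf3_cds_len // 3 - 1,
        orf4_anchor=seq[orf4[0] - a : orf4[0]],
        orf4_cds_len=template.orf4_cds_len,
        orf4_ref_aa=template.orf4_cds_len // 3 - 1,
        promoter_left_flank=seq[marker[0] - a : marker[0]],
        promoter_right_flank=seq[marker[1] : marker[1] + a],
        promoter_marker_len=template.promoter_marker_len,
    )

    probes = [
        annotation.pav_fwd_primer,
        rev_site,
        annotation.orf3_anchor,
        annotation.orf4_anchor,
        annotation.promoter_left_flank,
        annotation.promoter_right_flank,
    ]
    no_pav = seq[: features["insert"][0]] + seq[features["insert"][1] :]
    for probe in probes:
        if seq.count(probe) != 1 or _revcomp(seq).count(probe) > (
            1 if probe == rev_site else 0
        ):
            return None
        if probe not in (annotation.pav_fwd_primer, rev_site) and no_pav.count(probe):
            return None
    return ReferenceLocus(seq=seq, annotation=annotation, features=features, template=template)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def apply_variants(
    reference: ReferenceLocus,
    variants: Sequence[PavAbsence | Orf3StopAt | Orf4PromoterDeletion],
) -> VariantLocus:
    """Apply structural variants to the reference; returns seq + truth labels.

    ``PavAbsence`` is exclusive of the other variants (there is nothing left
    to mutate once the insert is gone).
    """
    truth = {
        "pav_present": True,
        "orf3_status": "full_length",
        "orf4_status": "intact",
    }
    if any(isinstance(v, PavAbsence) for v in variants):
        if len(variants) > 1:
            raise ValueError("PavAbsence cannot be combined with other variants")
        start, end = reference.features["insert"]
        seq = reference.seq[:start] + reference.seq[end:]
        truth.update(pav_present=False, orf3_status="absent", orf4_status="absent")
        return VariantLocus(seq=seq, truth=truth)

    # edits ordered right-to-left so earlier coordinates stay valid
    seq = reference.seq
    edits: list[tuple[int, int, str]] = []
    for variant in variants:
        if isinstance(variant, Orf3StopAt):
            cds_start, cds_end = reference.features["orf3_cds"]
            offset = cds_start + (variant.codon - 1) * 3
            if offset + 3 > cds_end:
                raise ValueError(
                    f"stop position {variant.codon} beyond the killer CDS"
                )
            edits.append((offset, offset + 3, "TAA"))
            truth["orf3_status"] = "truncated"
            truth["orf3_stop_codon"] = variant.codon
        elif isinstance(variant, Orf4PromoterDeletion):
            start, end = reference.features["promoter_marker"]
            edits.append((start, end, ""))
            truth["orf4_status"] = "promoter_deleted"
        else:  # pragma: no cover
            raise TypeError(f"unknown variant {variant!r}")
    for start, end, repl in sorted(edits, reverse=True):
        seq = seq[:start] + repl + seq[end:]
    return VariantLocus(seq=seq, truth=truth)


#: Default variant recipe per Se type; stop positions differ between types
#: to mimic independent truncation haplotypes.
DEFAULT_TYPE_VARIANTS: dict[SeType, tuple] = {
    SeType.TYPE1: (),
    SeType.TYPE2: (Orf3StopAt(101), Orf4PromoterDeletion()),
    SeType.TYPE3: (Orf3StopAt(150),),
    SeType.TYPE4: (Orf3StopAt(220),),
    SeType.TYPE5: (Orf3StopAt(310),),
    SeType.NO_PAV: (PavAbsence(),),
}


def sequence_for_type(reference: ReferenceLocus, se_type: SeType) -> VariantLocus:
    """The representative variant sequence of an Se type."""
    return apply_variants(reference, DEFAULT_TYPE_VARIANTS[SeType(se_type)])


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon of an accession panel.

    Either ``counts`` (exact per-type composition) or ``freqs`` (per-type
    probabilities, sampled multinomially) must be given.
    """

    taxon: str
    lineage: Lineage
    n: int = 0
    freqs: Mapping[SeType, float] | None = None
    counts: Mapping[SeType, int] | None = None

    def __post_init__(self) -> None:
        if (self.freqs is None) == (self.counts is None):
            raise ValueError("specify exactly one of freqs or counts")
        if self.freqs is not None:
            if self.n < 1:
                raise ValueError("n must be >= 1 when sampling from freqs")
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"type frequencies sum to {total}, expected 1")

    @property
    def size(self) -> int:
        if self.counts is not None:
            return sum(self.counts.values())
        return self.n


@dataclass(frozen=True)
class PanelSpec:
    taxa: tuple[TaxonSpec, ...]
    seed: int = 0


def default_panel_spec(seed: int = 0) -> PanelSpec:
    """A panel emulating the published Oryza survey composition.

    Exact per-taxon counts reproduce the headline figures (132/148 japonica
    lacking the PAV, 74/236 indica with the full-length killer, all African-
    complex and *O. meridionalis* accessions PAV-positive); the remaining
    splits are plausible round numbers, not reported values.
    """
    A, F, M = Lineage.ASIAN_COMPLEX, Lineage.AFRICAN_COMPLEX, Lineage.MERIDIONALIS
    t = SeType
    taxa = (
        TaxonSpec("japonica", A, counts={t.NO_PAV: 132, t.TYPE1: 6, t.TYPE2: 10}),
        TaxonSpec("indica", A, counts={t.NO_PAV: 22, t.TYPE1: 74, t.TYPE2: 140}),
        TaxonSpec(
            "O_rufipogon",
            A,
            counts={t.NO_PAV: 235, t.TYPE1: 14, t.TYPE2: 66, t.TYPE3: 27},
        ),
        TaxonSpec(
            "O_nivara", A, counts={t.NO_PAV: 34, t.TYPE1: 2, t.TYPE2: 7, t.TYPE3: 1}
        ),
        TaxonSpec("O_glaberrima", F, counts={t.TYPE4: 7}),
        TaxonSpec("O_barthii", F, counts={t.TYPE4: 4}),
        TaxonSpec("O_meridionalis", M, counts={t.TYPE5: 5}),
    )
    return PanelSpec(taxa=taxa, seed=seed)


def simulate_panel(
    spec: PanelSpec, reference: ReferenceLocus
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate an accession panel: (id, sequence) pairs plus a truth table.

    Types are drawn per accession from the taxon's frequency vector (or laid
    out exactly from its counts, shuffled); each accession receives the
    representative variant sequence of its type.  The truth table columns
    are accession_id, taxon, lineage, se_type and the underlying
    pav/orf3/orf4 status labels.
    """
    rng = np.random.default_rng(spec.seed)
    cache = {st: sequence_for_type(reference, st) for st in SeType}

    records: list[tuple[str, str]] = []
    truth_rows = []
    for taxon_spec in spec.taxa:
        if taxon_spec.counts is not None:
            types = [st for st, k in taxon_spec.counts.items() for _ in range(k)]
        else:
            names = list(taxon_spec.freqs)
            probs = np.array([taxon_spec.freqs[st] for st in names])
            draws = rng.choice(len(names), size=taxon_spec.n, p=probs)
            types = [names[i] for i in draws]
        rng.shuffle(types)
        for i, se_type in enumerate(types):
            accession = f"{taxon_spec.taxon}_{i + 1:04d}"
            var = cache[SeType(se_type)]
            records.append((accession, var.seq))
            truth_rows.append(
                {
                    "accession_id": accession,
                    "taxon": taxon_spec.taxon,
                    "lineage": taxon_spec.lineage.value,
                    "se_type": SeType(se_type).value,
                    **{k: v for k, v in var.truth.items() if k != "orf3_stop_codon"},
                }
            )
    return records, pd.DataFrame(truth_rows)


def simulate_cross_counts(
    dist: OffspringDistribution, n: int, seed: int
) -> dict[str, int]:
    """One multinomial draw of ``n`` progeny from an offspring distribution."""
    if n < 1:
        raise ValueError(f"progeny size must be >= 1, got {n}")
    keys = sorted(dist.classes)
    probs = np.array([dist.classes[k] for k in keys])
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs / probs.sum())
    return {k: int(c) for k, c in zip(keys, draws)}


def simulate_fertility(
    genotype_means: Mapping[str, float] | None = None,
    dispersion: float = 0.02,
    n_plants: int = 279,
    n_pollen: int = 200,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
) -> list[FertilityRecord]:
    """Beta-binomial pollen-fertility measurements for a mixed population.

    Each plant draws a genotype class (default fertile/semi-sterile at 1:1),
    a true fertility from a Beta with the class mean and concentration
    ``1/dispersion`` (``dispersion`` -> 0 degenerates to the mean), and an
    observed stained fraction as Binomial(``n_pollen``, true)/``n_pollen``
    — pollen counts are bounded fractions of a few hundred grains, which is
    exactly the beta-binomial regime.  The defaults (means 0.95 and 0.50,
    dispersion 0.02) put the histogram valley of a 1:1 population inside
    the 70-80% cut-off band.
    """
    if genotype_means is None:
        genotype_means = {"fertile": 0.95, "semi_sterile": 0.50}
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    for cls, m in genotype_means.items():
        if not 0.0 < m < 1.0:
            raise ValueError(f"mean for {cls!r} must lie in (0, 1), got {m}")
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")

    classes = sorted(genotype_means)
    if weights is None:
        w = np.full(len(classes), 1.0 / len(classes))
    else:
        w = np.array([weights[c] for c in classes], dtype=float)
        w = w / w.sum()

    rng = np.random.default_rng(seed)
    records = []
    assignments = rng.choice(len(classes), size=n_plants, p=w)
    for i, ci in enumerate(assignments):
        mean = genotype_means[classes[ci]]
        if dispersion == 0.0:
            true_fert = mean
        else:
            conc = 1.0 / dispersion
            true_fert = rng.beta(mean * conc, (1.0 - mean) * conc)
        stained = rng.binomial(n_pollen, true_fert) / n_pollen
        records.append(
            FertilityRecord(
                plant_id=f"plant_{i + 1:04d}",
                stained_fraction=float(stained),
                n_pollen=n_pollen,
            )
        )
    return records
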