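"""Killer-protector transmission genetics for the rice *Se* hybrid-sterility locus.

The *Se* locus of Asian rice sits inside a large presence-absence variation
(PAV) carrying two adjacent genes: a sporophytic pollen killer (*ORF3*) and a
gametophytic protector (*ORF4*).  In an ``indica x japonica`` heterozygote the
killer, expressed by the diploid plant, attacks *every* gamete; only gametes
that themselves carry a functional protector allele (or an unlinked protector
transgene copy) survive.  The japonica-type haplotype ("T") lacks the PAV and
hence both genes, so T-bearing pollen of a T/E heterozygote is aborted and the
T allele is not transmitted through the male side.

This module implements that model as a small deterministic calculus:

* enumerate the Mendelian gamete classes of an arbitrary genotype
  (two Se alleles plus any number of unlinked transgene loci),
* apply sex-specific killing to unprotected gametes
  (``km`` for pollen, ``kf`` for ovules),
* combine the surviving male and female gamete pools into an offspring
  genotype-class distribution with canonical string keys (``"T/E;G/-"``).

The surviving-viability mass of the male pool is the model's prediction of
pollen fertility, e.g. 50% for a plain T/E heterozygote under complete
killing and 75% when one hemizygous protector transgene is added.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Sex",
    "TransgeneGene",
    "AlleleProfile",
    "TransgeneLocus",
    "PlantGenotype",
    "TransmissionParams",
    "Gamete",
    "GametePool",
    "OffspringDistribution",
    "CompleteSterilityError",
    "ALLELE_T",
    "ALLELE_E",
    "DEFAULT_ALLELES",
    "killer_active",
    "gamete_pool",
    "pollen_viability",
    "cross",
    "expected_counts",
    "parse_genotype",
    "canonical_se_key",
]

_SUM_TOL = 1e-12


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class TransgeneGene(str, Enum):
    KILLER = "killer"
    PROTECTOR = "protector"


class CompleteSterilityError(RuntimeError):
    """Raised when every gamete of the requested sex is aborted.

    A zero surviving-viability mass means the plant cannot serve as a parent
    on that side; callers must not silently renormalise an empty pool.
    """


@dataclass(frozen=True)
class AlleleProfile:
    """Functional status of one Se-locus haplotype.

    ``label`` is the symbol used in genotype keys ("T", "E", "Type3", ...).
    The two booleans are independent: a haplotype may carry a functional
    killer, a functional protector, both (the canonical indica "E" allele)
    or neither (the PAV-absent japonica "T" allele).
    """

    label: str
    has_functional_killer: bool = False
    has_functional_protector: bool = False

    def __post_init__(self) -> None:
        if not self.label or "/" in self.label or ";" in self.label:
            raise ValueError(f"invalid allele label {self.label!r}")


#: PAV-absent japonica haplotype: no killer, no protector.
ALLELE_T = AlleleProfile("T", has_functional_killer=False, has_functional_protector=False)
#: PAV-present indica haplotype with full-length ORF3 and intact ORF4.
ALLELE_E = AlleleProfile("E", has_functional_killer=True, has_functional_protector=True)

DEFAULT_ALLELES: Mapping[str, AlleleProfile] = {"T": ALLELE_T, "E": ALLELE_E}


@dataclass(frozen=True)
class TransgeneLocus:
    """An unlinked transgene insertion carrying the killer or the protector.

    ``dosage`` counts copies in the sporophyte (1 = hemizygous T0-style
    plant, 2 = homozygous).  ``penetrance`` is the probability that the
    transgene product is functionally expressed; 1 models full activity,
    while values below 1 represent silencing of the kind seen when the
    killer is reintroduced without its native regulation.
    """

    gene: TransgeneGene
    dosage: int = 1
    penetrance: float = 1.0
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1 or 2, got {self.dosage}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must lie in [0, 1], got {self.penetrance}")
        if not self.symbol:
            default = "G" if self.gene is TransgeneGene.PROTECTOR else "K"
            object.__setattr__(self, "symbol", default)


@dataclass(frozen=True)
class PlantGenotype:
    """Diploid genotype: an ordered pair of Se alleles plus transgene loci."""

    se_alleles: tuple[AlleleProfile, AlleleProfile]
    transgenes: tuple[TransgeneLocus, ...] = ()

    def __post_init__(self) -> None:
        if len(self.se_alleles) != 2:
            raise ValueError("a PlantGenotype carries exactly two Se alleles")
        a, b = self.se_alleles
        if a.label == b.label and a != b:
            raise ValueError(f"conflicting profiles share the label {a.label!r}")
        genes = [t.gene for t in self.transgenes]
        if len(genes) != len(set(genes)):
            raise ValueError("at most one transgene locus per gene")

    @property
    def se_key(self) -> str:
        return canonical_se_key(self.se_alleles[0].label, self.se_alleles[1].label)


@dataclass(frozen=True)
class TransmissionParams:
    """Sex-specific killing efficiencies of the sporophytic killer.

    ``km`` acts on unprotected pollen, ``kf`` on unprotected ovules.  The
    defaults (km=1, kf=0) encode the headline observation: male T-gametes of
    a T/E heterozygote are fully aborted, while female transmission is only
    mildly distorted and is therefore left to be fitted from data.
    """

    km: float = 1.0
    kf: float = 0.0

    def __post_init__(self) -> None:
        for name in ("km", "kf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def rate_for(self, sex: Sex) -> float:
        return self.km if sex is Sex.MALE else self.kf


@dataclass(frozen=True)
class Gamete:
    """A haploid gamete class: one Se allele plus carried transgene copies."""

    se: AlleleProfile
    transgenes: frozenset[TransgeneLocus] = frozenset()

    @property
    def key(self) -> str:
        symbols = sorted(t.symbol for t in self.transgenes)
        return "|".join([self.se.label] + symbols)

    def protection(self) -> float:
        """Probability the gamete is shielded from the killer."""
        if self.se.has_functional_protector:
            return 1.0
        unprotected = 1.0
        for t in self.transgenes:
            if t.gene is TransgeneGene.PROTECTOR:
                unprotected *= 1.0 - t.penetrance
        return 1.0 - unprotected


@dataclass(frozen=True)
class GametePool:
    """Post-selection gamete class frequencies and surviving-viability mass."""

    classes: Mapping[Gamete, float]
    viability_mass: float

    def __post_init__(self) -> None:
        total = sum(self.classes.values())
        if self.classes and abs(total - 1.0) > 1e-9:
            raise ValueError(f"gamete frequencies sum to {total}, expected 1")

    def frequency(self, key: str) -> float:
        for g, f in self.classes.items():
            if g.key == key:
                return f
        return 0.0


@dataclass(frozen=True)
class OffspringDistribution:
    """Canonical genotype-class -> probability map for one cross."""

    classes: Mapping[str, float]
    genotypes: Mapping[str, PlantGenotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.classes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"offspring probabilities sum to {total}, expected 1")
        if any(p < 0 for p in self.classes.values()):
            raise ValueError("negative offspring probability")


def canonical_se_key(label_a: str, label_b: str) -> str:
    """Join an unordered Se allele pair into its canonical string.

    Labels are ordered reverse-lexicographically so the pair renders in the
    conventional orientation ("T/E", never "E/T").
    """
    hi, lo = sorted((label_a, label_b), reverse=True)
    return f"{hi}/{lo}"


def killer_active(plant: PlantGenotype) -> bool:
    """True when the sporophyte expresses any pollen-killer activity."""
    return _killer_activity(plant) > 0.0


def _killer_activity(plant: PlantGenotype) -> float:
    if any(a.has_functional_killer for a in plant.se_alleles):
        return 1.0
    activity = 0.0
    for t in plant.transgenes:
        if t.gene is TransgeneGene.KILLER and t.dosage >= 1:
            activity = max(activity, t.penetrance)
    return activity


def _enumerate_gametes(plant: PlantGenotype) -> list[tuple[Gamete, float]]:
    """Mendelian (pre-selection) gamete classes with their prior frequencies."""
    a, b = plant.se_alleles
    se_options: list[tuple[AlleleProfile, float]]
    if a == b:
        se_options = [(a, 1.0)]
    else:
        se_options = [(a, 0.5), (b, 0.5)]

    locus_options: list[list[tuple[TransgeneLocus | None, float]]] = []
    for locus in plant.transgenes:
        copy = replace(locus, dosage=1)
        if locus.dosage == 2:
            locus_options.append([(copy, 1.0)])
        elif locus.dosage == 1:
            locus_options.append([(copy, 0.5), (None, 0.5)])
        else:
            locus_options.append([(None, 1.0)])

    gametes: dict[Gamete, float] = {}
    for (se, f_se), combo in itertools.product(se_options, itertools.product(*locus_options)):
        carried = frozenset(c for c, _ in combo if c is not None)
        freq = f_se
        for _, f in combo:
            freq *= f
        g = Gamete(se=se, transgenes=carried)
        gametes[g] = gametes.get(g, 0.0) + freq
    return list(gametes.items())


def gamete_pool(plant: PlantGenotype, sex: Sex, params: TransmissionParams) -> GametePool:
    """Surviving gamete classes of ``plant`` for the given sex.

    The killer acts sporophytically: when the parent plant expresses it,
    every gamete lacking protection keeps only viability ``1 - km`` (male)
    or ``1 - kf`` (female), regardless of which Se allele the gamete itself
    carries.  Protection is gametophytic: a gamete is shielded iff it carries
    a functional protector Se allele or a protector transgene copy.

    Raises
    ------
    CompleteSterilityError
        If no gamete survives (viability mass 0).
    """
    sex = Sex(sex)
    classes, mass = _select(plant, sex, params)
    if mass <= 0.0:
        raise CompleteSterilityError(
            f"complete {sex.value} sterility for genotype {plant.se_key}"
        )
    return GametePool(
        classes={g: w / mass for g, w in classes.items() if w > 0.0},
        viability_mass=mass,
    )


def _select(
    plant: PlantGenotype, sex: Sex, params: TransmissionParams
) -> tuple[dict[Gamete, float], float]:
    activity = _killer_activity(plant)
    rate = params.rate_for(sex)
    out: dict[Gamete, float] = {}
    mass = 0.0
    for gamete, freq in _enumerate_gametes(plant):
        viability = 1.0 - rate * activity * (1.0 - gamete.protection())
        w = freq * viability
        out[gamete] = w
        mass += w
    return out, mass


def pollen_viability(plant: PlantGenotype, params: TransmissionParams) -> float:
    """Predicted pollen fertility: surviving-viability mass of the male pool."""
    _, mass = _select(plant, Sex.MALE, params)
    return mass


def cross(
    female: PlantGenotype, male: PlantGenotype, params: TransmissionParams
) -> OffspringDistribution:
    """Offspring genotype-class distribution of ``female x male``.

    The female pool (ovule selection at rate ``kf``) and male pool (pollen
    selection at ``km``) are combined as an outer product; zygote classes are
    merged under canonical keys such as ``"T/E;G/-"``.  Transgene dosage in
    the offspring is the number of copies inherited from the two gametes.

    Raises :class:`CompleteSterilityError` if either parent's pool is empty.
    """
    fpool = gamete_pool(female, Sex.FEMALE, params)
    mpool = gamete_pool(male, Sex.MALE, params)

    # transgene loci whose genotype segment appears in offspring keys
    symbols = sorted({t.symbol for t in (*female.transgenes, *male.transgenes)})

    classes: dict[str, float] = {}
    genotypes: dict[str, PlantGenotype] = {}
    for (fg, ff), (mg, mf) in itertools.product(fpool.classes.items(), mpool.classes.items()):
        key, genotype = _zygote(fg, mg, symbols)
        classes[key] = classes.get(key, 0.0) + ff * mf
        genotypes.setdefault(key, genotype)
    return OffspringDistribution(classes=classes, genotypes=genotypes)


def _zygote(fg: Gamete, mg: Gamete, symbols: list[str]) -> tuple[str, PlantGenotype]:
    key = canonical_se_key(fg.se.label, mg.se.label)
    loci: list[TransgeneLocus] = []
    for symbol in symbols:
        copies = [t for t in (*fg.transgenes, *mg.transgenes) if t.symbol == symbol]
        dosage = len(copies)
        if dosage == 2:
            key += f";{symbol}/{symbol}"
        elif dosage == 1:
            key += f";{symbol}/-"
        else:
            key += ";-/-"
        if copies:
            loci.append(replace(copies[0], dosage=dosage))
    genotype = PlantGenotype(
        se_alleles=tuple(sorted((fg.se, mg.se), key=lambda a: a.label, reverse=True)),
        transgenes=tuple(loci),
    )
    return key, genotype


def expected_counts(dist: OffspringDistribution, n: int) -> dict[str, float]:
    """Expected class counts ``n * p`` for a progeny of size ``n``."""
    if n < 1:
        raise ValueError(f"progeny size must be >= 1, got {n}")
    return {key: n * p for key, p in dist.classes.items()}


def parse_genotype(
    text: str,
    alleles: Mapping[str, AlleleProfile] = DEFAULT_ALLELES,
    penetrance: float = 1.0,
) -> PlantGenotype:
    """Parse a genotype string like ``"T/E"`` or ``"T/E;G/-"``.

    The first ``/``-pair names Se alleles from the ``alleles`` table; each
    further ``;``-separated pair is a transgene genotype written with the
    locus symbol ("G" protector, "K" killer) and ``-`` for the null allele.
    """
    parts = text.strip().split(";")
    se_part = parts[0].split("/")
    if len(se_part) != 2:
        raise ValueError(f"expected two Se alleles in {text!r}")
    try:
        pair = tuple(alleles[label] for label in se_part)
    except KeyError as exc:
        raise ValueError(f"unknown Se allele {exc.args[0]!r} in {text!r}") from None

    loci: list[TransgeneLocus] = []
    for segment in parts[1:]:
        symbols = segment.split("/")
        if len(symbols) != 2:
            raise ValueError(f"malformed transgene segment {segment!r}")
        carried = [s for s in symbols if s != "-"]
        if not carried:
            continue
        if len(set(carried)) != 1:
            raise ValueError(f"mixed symbols in transgene segment {segment!r}")
        symbol = carried[0]
        gene = TransgeneGene.KILLER if symbol.upper() == "K" else TransgeneGene.PROTECTOR
        loci.append(
            TransgeneLocus(gene=gene, dosage=len(carried), penetrance=penetrance, symbol=symbol)
        )
    return PlantGenotype(se_alleles=pair, transgenes=tuple(loci))
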