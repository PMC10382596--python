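"""Independent brute-force oracles, kept separate from the library code.

``punnett_cross`` enumerates zygote classes of a cross by exhaustive
Mendelian bookkeeping with exact rational arithmetic and no gamete
selection; it shares no code with the transmission module beyond the
canonical key grammar, which it re-implements inline.

``chi2_sf_bisect`` inverts an independently coded chi-square survival
function (regularized upper incomplete gamma) by bisection.
"""

from __future__ import annotations

from fractions import Fraction

from scipy.special import gammaincc


def _oracle_gametes(plant) -> list[tuple[str, tuple[str, ...], Fraction]]:
    """(se label, carried transgene symbols, frequency) without selection."""
    out = []
    for se in plant.se_alleles:
        combos: list[tuple[tuple[str, ...], Fraction]] = [((), Fraction(1))]
        for locus in plant.transgenes:
            nxt = []
            for carried, f in combos:
                if locus.dosage == 2:
                    nxt.append((carried + (locus.symbol,), f))
                elif locus.dosage == 1:
                    nxt.append((carried + (locus.symbol,), f / 2))
                    nxt.append((carried, f / 2))
                else:
                    nxt.append((carried, f))
            combos = nxt
        for carried, f in combos:
            out.append((se.label, carried, f / 2))
    return out


def punnett_cross(female, male) -> dict[str, Fraction]:
    """Exhaustive no-selection Punnett enumeration with exact fractions."""
    symbols = sorted(
        {t.symbol for t in female.transgenes} | {t.symbol for t in male.transgenes}
    )
    dist: dict[str, Fraction] = {}
    for f_se, f_carried, f_freq in _oracle_gametes(female):
        for m_se, m_carried, m_freq in _oracle_gametes(male):
            hi, lo = sorted((f_se, m_se), reverse=True)
            key = f"{hi}/{lo}"
            for symbol in symbols:
                dosage = (symbol in f_carried) + (symbol in m_carried)
                if dosage == 2:
                    key += f";{symbol}/{symbol}"
                elif dosage == 1:
                    key += f";{symbol}/-"
                else:
                    key += ";-/-"
            dist[key] = dist.get(key, Fraction(0)) + f_freq * m_freq
    return dist


def chi2_sf(x: float, df: int) -> float:
    """Chi-square survival function via the regularized incomplete gamma."""
    return float(gammaincc(df / 2.0, x / 2.0))


def chi2_sf_bisect(df: int, alpha: float, tol: float = 1e-12) -> float:
    """Invert ``chi2_sf`` by bisection: the upper-tail critical value."""
    lo, hi = 0.0, 1.0
    while chi2_sf(hi, df) > alpha:
        hi *= 2.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if chi2_sf(mid, df) > alpha:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
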