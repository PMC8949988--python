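"""ESI polarity allocation from per-group pKa values.

A soft-ionization (ESI) source can only see a metabolite if it can carry a
charge, so the acid/base character of its functional groups decides the
polarity in which to monitor it.  The classification works on per-group
predicted pKa values: the strongest acidic group (minimum acidic pKa) and
the strongest basic group (maximum basic pKa) govern the molecule.

Rule table, with a = min(acidic pKa), b = max(basic pKa), and the default
cut-offs acid_cut = 6.5, base_cut = 8.5:

===============================  ===========
condition                        class
===============================  ===========
no pKa data                      unclassified
a < 6.5, no basic group          acid
a < 6.5 and b < 8.5              acid        (e.g. ATP: strong overall acid)
b > 8.5, no acidic group         base
b > 8.5 and a > 6.5              base        (e.g. kanamycin)
a < 6.5 and b > 8.5              amphoteric  (e.g. amino acids)
everything else (weak groups)    neutral
===============================  ===========

Acids are monitored in negative mode, bases in positive mode, amphoterics in
both (final mode deferred to transition selection), weak-group neutrals get
the mode(s) their weak groups allow.  Unclassified metabolites cannot be
allocated and are excluded from method building.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compound_db import PkaSet
from .errors import InputError, MetaboliteExcluded

POSITIVE = "positive"
NEGATIVE = "negative"


class SpeciesClass(enum.Enum):
    ACID = "acid"
    BASE = "base"
    AMPHOTERIC = "amphoteric"
    NEUTRAL = "neutral"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifierThresholds:
    acid_cut: float = 6.5
    base_cut: float = 8.5

    def __post_init__(self):
        if not self.acid_cut < self.base_cut:
            raise InputError("acid_cut must be below base_cut")


DEFAULT_THRESHOLDS = ClassifierThresholds()


@dataclass(frozen=True)
class ModeAllocation:
    modes: frozenset[str]
    deferred: bool = False

    def __post_init__(self):
        if not self.modes:
            raise InputError("mode allocation must not be empty")


def classify_species(
    pka: PkaSet | None, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS
) -> SpeciesClass:
    """Classify one metabolite from its per-group pKa values.

    The strongest group governs: min over acidic values, max over basic
    values.  Boundary equality counts as "weak" (not beyond the cut).
    """
    if pka is None:
        return SpeciesClass.UNCLASSIFIED
    a = min(pka.acidic) if pka.acidic else None
    b = max(pka.basic) if pka.basic else None

    strong_acid = a is not None and a < thresholds.acid_cut
    strong_base = b is not None and b > thresholds.base_cut

    if strong_acid and strong_base:
        return SpeciesClass.AMPHOTERIC
    if strong_acid:  # no basic group, or only a weak one
        return SpeciesClass.ACID
    if strong_base:
        return SpeciesClass.BASE
    return SpeciesClass.NEUTRAL


def allocate_mode(
    cls: SpeciesClass, pka: PkaSet | None = None
) -> ModeAllocation:
    """Map a species class to ESI polarity(s).

    For neutral metabolites the weak groups decide, so the PkaSet must be
    supplied in that case.  Unclassified input raises
    :class:`MetaboliteExcluded` — without a single ionizable group the
    metabolite cannot be monitored at all.
    """
    if cls is SpeciesClass.UNCLASSIFIED:
        raise MetaboliteExcluded("no pKa data: metabolite dropped from method building")
    if cls is SpeciesClass.ACID:
        return ModeAllocation(frozenset({NEGATIVE}))
    if cls is SpeciesClass.BASE:
        return ModeAllocation(frozenset({POSITIVE}))
    if cls is SpeciesClass.AMPHOTERIC:
        return ModeAllocation(frozenset({POSITIVE, NEGATIVE}), deferred=True)
    # neutral: weak groups decide
    if pka is None:
        raise InputError("neutral classification needs the PkaSet to pick a mode")
    if pka.acidic and pka.basic:
        return ModeAllocation(frozenset({POSITIVE, NEGATIVE}), deferred=True)
    if pka.acidic:
        return ModeAllocation(frozenset({NEGATIVE}))
    return ModeAllocation(frozenset({POSITIVE}))


@dataclass(frozen=True)
class PkaValidationResult:
    """Predicted-vs-experimental pKa comparison.

    ``slope``/``intercept``/``r2`` describe the OLS fit of experimental on
    predicted values (absent when fewer than 3 pairs were supplied);
    ``deviations`` holds the per-pair signed deviation predicted − experimental
    and ``max_abs_dev_by_category`` the worst absolute deviation per
    compound category.
    """

    slope: float | None
    intercept: float | None
    r2: float | None
    deviations: pd.DataFrame
    max_abs_dev_by_category: dict[str, float]


_CATEGORIES = {"acid", "base", "amphoteric"}


def validate_pka(pairs: list[tuple[float, float, str]]) -> PkaValidationResult:
    """Validate predicted pKa values against experimental references.

    Parameters
    ----------
    pairs:
        (predicted, experimental, category) triples with category in
        {"acid", "base", "amphoteric"}.
    """
    if not pairs:
        raise InputError("no pKa pairs supplied")
    for p, e, cat in pairs:
        if cat not in _CATEGORIES:
            raise InputError(f"unknown pKa category: {cat!r}")
        if not np.isfinite(p) or not np.isfinite(e):
            raise InputError("non-finite pKa pair")

    df = pd.DataFrame(pairs, columns=["predicted", "experimental", "category"])
    df["deviation"] = df["predicted"] - df["experimental"]

    slope = intercept = r2 = None
    if len(df) >= 3:
        fit = stats.linregress(df["predicted"], df["experimental"])
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue) ** 2

    max_abs = (
        df.groupby("category")["deviation"].apply(lambda s: float(s.abs().max())).to_dict()
    )
    return PkaValidationResult(slope, intercept, r2, df, max_abs)
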