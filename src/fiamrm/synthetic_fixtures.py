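"""Seeded synthetic inputs for the whole workflow.

Every input the tool consumes — the resolved compound library, the organism
model, CFM-ID-style predicted-spectrum documents, in-house/literature
transition tables, and MRM peak-area batches — can be generated here
deterministically from a :class:`FixtureSpec`, so the complete pipeline is
exercisable without any database or instrument access.

The batch generator states a world modelled on a three-product yeast-extract
comparison: three classes with six replicates each, multiplicative lognormal
peak-area noise (typical for MS intensities), a smooth intra-batch drift,
pooled-mean QC injections, planted fold-change discriminators, and the two
missingness mechanisms the pipeline distinguishes (random dropouts and
whole-class knockouts below detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compound_db import CompoundLibrary, CompoundRecord, OrganismModel, PkaSet
from .errors import InputError
from .ionization import NEGATIVE, POSITIVE
from .spectra import Spectrum, make_spectrum


@dataclass(frozen=True)
class FixtureSpec:
    """Stated world of the synthetic data.

    Defaults follow the screening workflow's own conditions where it states
    them (3 classes x 6 replicates, QC every 6 sample injections, 5%-straddling
    predicted peaks, 10 planted discriminators among 100 variables at a
    2-fold change, ~10% multiplicative noise); the rest are chosen once as
    realistic for an MS peak-area table.
    """

    seed: int = 0
    # library
    n_metabolites: int = 50
    # batch design
    n_classes: int = 3
    n_replicates: int = 6
    n_planted: int = 10
    fold_change: float = 2.0
    noise_cv: float = 0.10
    drift_model: str = "linear"       # "linear" | "sinusoid" | "none"
    drift_amplitude: float = 0.20     # fraction of the mean
    mar_rate: float = 0.03
    mnar_knockouts: int = 2
    qc_every: int = 6
    sn_median: float = 50.0
    sn_sigma: float = 0.6
    low_sn_rate: float = 0.02

    def __post_init__(self):
        for r in (self.mar_rate, self.low_sn_rate):
            if not 0 <= r <= 1:
                raise InputError("rates must be within [0, 1]")


# --------------------------------------------------------------------------
# compound library


@dataclass(frozen=True)
class LibraryFixture:
    library: CompoundLibrary
    model: OrganismModel
    enantiomer_pair: tuple[str, str]
    isobaric_pairs: dict[str, tuple[str, str]]  # mode -> pair of kegg_ids
    model_misses: tuple[str, ...]  # model IDs intentionally absent from library


_PKA_CYCLE = (
    ("acid", PkaSet(acidic=(3.2,))),
    ("base", PkaSet(basic=(9.9,))),
    ("amphoteric", PkaSet(acidic=(2.3,), basic=(9.7,))),
    ("neutral", PkaSet(acidic=(7.2,))),
    ("unclassified", None),
)


def _kegg(i: int) -> str:
    return f"C{i:05d}"


def gen_library(spec: FixtureSpec) -> LibraryFixture:
    """Generate a resolved compound library plus organism model.

    The library covers all five ionization classes, straddles the 30 and
    1500 g/mol bounds, contains one enantiomer pair and one planted isobaric
    pair per polarity, and reserves a couple of organism-model IDs that are
    absent from the library (exercising the miss report).
    """
    rng = np.random.default_rng(spec.seed)
    n = max(spec.n_metabolites, 12)
    records: list[CompoundRecord] = []

    def make(i, name, mw, pka, smiles=None, formula=None, chembl=True):
        kegg = _kegg(i)
        has_chembl = chembl and pka is not None
        return CompoundRecord(
            kegg_id=kegg,
            pubchem_sid=f"SID{i}",
            pubchem_cid=f"CID{i}",
            chembl_id=f"CHEMBL{i}" if has_chembl else None,
            name=name,
            smiles=smiles or f"C{'C' * (i % 5)}O",
            formula=formula or f"C{2 + i % 9}H{5 + i % 11}NO{1 + i % 4}",
            mw=mw,
            has_stereo=smiles is not None and ("@" in smiles),
            pka=pka if has_chembl else None,
        )

    # 1-2: enantiomer pair (same formula/mw, mirrored stereo marks)
    records.append(make(1, "D-alanine-like", 89.09, PkaSet(acidic=(2.3,), basic=(9.7,)),
                        smiles="N[C@@H](C)C(=O)O", formula="C3H7NO2"))
    records.append(make(2, "L-alanine-like", 89.09, PkaSet(acidic=(2.3,), basic=(9.7,)),
                        smiles="N[C@H](C)C(=O)O", formula="C3H7NO2"))
    # 3-4: isobaric pair, negative mode (hexose-phosphate-like acids)
    records.append(make(3, "hexose-6-phosphate-A", 260.14, PkaSet(acidic=(1.5,)),
                        formula="C6H13O9P"))
    records.append(make(4, "hexose-1-phosphate-B", 260.14, PkaSet(acidic=(1.6,)),
                        formula="C6H13O9P"))
    # 5-6: isobaric pair, positive mode (amine isomers)
    records.append(make(5, "amine-isomer-A", 146.19, PkaSet(basic=(10.1,)),
                        formula="C6H14N2O2"))
    records.append(make(6, "amine-isomer-B", 146.19, PkaSet(basic=(10.2,)),
                        formula="C6H14N2O2"))
    # 7-8: molecular-weight window edges
    records.append(make(7, "water-like", 18.02, PkaSet(acidic=(14.0,))))
    records.append(make(8, "polymer-like", 1600.0, PkaSet(acidic=(3.0,))))

    for i in range(9, n + 1):
        label, pka = _PKA_CYCLE[i % len(_PKA_CYCLE)]
        mw = float(np.round(rng.uniform(60, 800), 2))
        records.append(make(i, f"met-{label}-{i:03d}", mw, pka))

    library = CompoundLibrary(records)

    misses = (_kegg(99998), _kegg(99999))
    in_model = frozenset(r.kegg_id for r in records if r.kegg_id not in
                         {_kegg(n), _kegg(n - 1)}) | frozenset(misses)
    model = OrganismModel(org_code="sce", metabolite_ids=in_model)
    return LibraryFixture(
        library=library,
        model=model,
        enantiomer_pair=(_kegg(1), _kegg(2)),
        isobaric_pairs={NEGATIVE: (_kegg(3), _kegg(4)),
                        POSITIVE: (_kegg(5), _kegg(6))},
        model_misses=misses,
    )


# --------------------------------------------------------------------------
# predicted spectra


def gen_predicted_spectra(
    spec: FixtureSpec, fixture: LibraryFixture
) -> dict[tuple[str, str], str]:
    """CFM-ID-dialect documents per (kegg_id, mode) for every classified record.

    Every document has three energy blocks; each block carries a 100% base
    peak, mid-intensity fragments, and one planted 3% peak (below the 5%
    relative-signal threshold, exercising the filter).  The planted isobaric
    pairs share their top fragment m/z so a unit-resolution instrument
    cannot tell them apart.
    """
    from .ionization import SpeciesClass, allocate_mode, classify_species
    from .method_builder import precursor_mz

    rng = np.random.default_rng(spec.seed + 1)
    docs: dict[tuple[str, str], str] = {}
    iso_frag = {m: 97.0 + 10 * i for i, m in enumerate((NEGATIVE, POSITIVE))}
    iso_members = {kid: m for m, pair in fixture.isobaric_pairs.items() for kid in pair}

    for rec in fixture.library:
        cls = classify_species(rec.pka)
        if cls is SpeciesClass.UNCLASSIFIED or rec.mw is None:
            continue
        for mode in sorted(allocate_mode(cls, rec.pka).modes):
            q1 = precursor_mz(rec.mw, mode)
            lines = []
            for block in range(3):
                lines.append(f"energy{block}")
                n_frag = 3 + int(rng.integers(0, 3))
                mzs = np.round(np.sort(rng.uniform(50, max(60.0, q1 - 5), n_frag)), 3)
                rels = np.round(rng.uniform(20, 90, n_frag), 1)
                rels[int(rng.integers(0, n_frag))] = 100.0
                if iso_members.get(rec.kegg_id) == mode and block == 1:
                    # planted convolution: shared, dominant fragment
                    mzs[0], rels[0] = iso_frag[mode], 100.0
                    rels[1:] = np.minimum(rels[1:], 90.0)
                for mz, rel in zip(mzs, rels):
                    lines.append(f"{mz:.3f} {rel:.1f}")
                lines.append(f"{min(49.0, q1 / 3):.3f} 3.0")  # sub-threshold peak
            docs[(rec.kegg_id, mode)] = "\n".join(lines) + "\n"
    return docs


def tyrosine_example() -> tuple[Spectrum, Spectrum]:
    """A tyrosine-style measured/predicted spectrum pair (+20 V, positive).

    8 measured signals, 18 predicted signals, exactly 6 shared m/z values —
    the worked example behind the R = 75%, P = 33.3%, J = 30% scores.
    """
    shared = [91.054, 95.049, 119.049, 123.044, 136.076, 165.055]
    measured_only = [51.023, 77.039]
    predicted_only = [53.002, 55.018, 65.039, 69.034, 81.034, 93.070,
                      103.054, 107.049, 113.060, 147.044, 152.070, 182.081]

    measured = make_spectrum(
        "C00082", "positive", 20.0, "measured",
        [(mz, 100.0 if mz == 136.076 else 20.0 + i) for i, mz in
         enumerate(sorted(shared + measured_only))],
    )
    predicted = make_spectrum(
        "C00082", "positive", 20.0, "predicted",
        [(mz, 100.0 if mz == 136.076 else 10.0 + i) for i, mz in
         enumerate(sorted(shared + predicted_only))],
    )
    return measured, predicted


# --------------------------------------------------------------------------
# transition tables


def gen_transition_tables(
    spec: FixtureSpec, fixture: LibraryFixture
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Small in-house and literature transition tables.

    A handful of metabolites get an in-house entry (complete parameters), a
    few others a literature entry with EP/CXP/DP left blank — exercising the
    defaulting and DP-regression paths.
    """
    rng = np.random.default_rng(spec.seed + 2)
    from .ionization import SpeciesClass, allocate_mode, classify_species
    from .method_builder import precursor_mz

    special = {*fixture.enantiomer_pair,
               *(k for pair in fixture.isobaric_pairs.values() for k in pair)}
    classified = [r for r in fixture.library
                  if classify_species(r.pka) is not SpeciesClass.UNCLASSIFIED
                  and r.mw is not None and r.kegg_id not in special]
    inhouse_rows, lit_rows = [], []
    for i, rec in enumerate(classified[:10]):
        mode = sorted(allocate_mode(classify_species(rec.pka), rec.pka).modes)[0]
        q1 = precursor_mz(rec.mw, mode)
        q3 = float(np.round(rng.uniform(50, max(60.0, q1 - 10)), 3))
        ce = 20.0 if mode == POSITIVE else -20.0
        dp = float(np.round(20.0 + 0.2 * q1 + rng.normal(0, 2), 1))
        row = dict(kegg_id=rec.kegg_id, mode=mode, q1=round(q1, 3), q3=q3,
                   ce=ce, dp=dp, ep=10.0, cxp=4.0)
        if i % 2 == 0:
            inhouse_rows.append(row)
        else:
            lit_rows.append({**row, "ep": np.nan, "cxp": np.nan})
    return pd.DataFrame(inhouse_rows), pd.DataFrame(lit_rows)


# --------------------------------------------------------------------------
# peak-area batches


@dataclass(frozen=True)
class BatchFixture:
    table: pd.DataFrame          # long layout (sample_id, injection_order, ...)
    planted: tuple[str, ...]     # analytes with a true class effect
    high_class: Mapping[str, str]  # planted analyte -> boosted class
    mnar: tuple[str, ...]        # analytes with a whole-class knockout


def _drift(spec: FixtureSpec, t: np.ndarray) -> np.ndarray:
    if spec.drift_model == "none" or spec.drift_amplitude == 0:
        return np.ones_like(t)
    u = (t - t.min()) / max(t.max() - t.min(), 1)
    if spec.drift_model == "linear":
        return 1.0 + spec.drift_amplitude * (u - 0.5) * 2
    if spec.drift_model == "sinusoid":
        return 1.0 + spec.drift_amplitude * np.sin(2 * np.pi * u)
    raise InputError(f"unknown drift model {spec.drift_model!r}")


def gen_batch(spec: FixtureSpec, analytes: Sequence[str]) -> BatchFixture:
    """Generate a long-form MRM peak-area table with planted structure.

    areas = class mean x drift(injection order) x lognormal noise; QC rows
    are the pooled mean of the class means.  The first ``n_planted``
    positions (chosen by the seeded RNG) carry a ``fold_change`` boost in
    one class; ``mnar_knockouts`` non-planted analytes lose one entire
    class (below detection).  S/N values are lognormal with a small forced
    low-S/N fraction.
    """
    analytes = list(analytes)
    rng = np.random.default_rng(spec.seed + 3)
    classes = [f"YE{k + 1}" for k in range(spec.n_classes)]

    planted_idx = rng.choice(len(analytes), size=min(spec.n_planted, len(analytes)),
                             replace=False)
    planted = [analytes[i] for i in sorted(planted_idx)]
    high_class = {a: classes[i % len(classes)] for i, a in enumerate(planted)}
    non_planted = [a for a in analytes if a not in set(planted)]
    mnar = tuple(non_planted[: spec.mnar_knockouts])
    mnar_class = {a: classes[i % len(classes)] for i, a in enumerate(mnar)}

    # injection plan: blank, QC, then shuffled samples with QC bracketing
    sample_ids = [f"{c}_r{r + 1}" for c in classes for r in range(spec.n_replicates)]
    order = list(sample_ids)
    rng.shuffle(order)
    plan: list[tuple[str, str, str]] = [("B1", "blank", ""), ("QC1", "qc", "")]
    qc_i, since = 1, 0
    for s in order:
        plan.append((s, "sample", s.rsplit("_", 1)[0]))
        since += 1
        if since == spec.qc_every:
            qc_i += 1
            plan.append((f"QC{qc_i}", "qc", ""))
            since = 0
    if since:
        qc_i += 1
        plan.append((f"QC{qc_i}", "qc", ""))

    inj_order = np.arange(1, len(plan) + 1, dtype=float)
    drift = _drift(spec, inj_order)
    sigma = float(np.sqrt(np.log(1 + spec.noise_cv ** 2)))

    base = rng.lognormal(mean=np.log(1e5), sigma=0.8, size=len(analytes))
    rows = []
    for j, analyte in enumerate(analytes):
        class_mean = {c: base[j] for c in classes}
        if analyte in high_class:
            class_mean[high_class[analyte]] *= spec.fold_change
        pooled = float(np.mean(list(class_mean.values())))
        for i, (sid, typ, cls) in enumerate(plan):
            if typ == "blank":
                area, sn = np.nan, 1.0
            else:
                mu = pooled if typ == "qc" else class_mean[cls]
                area = mu * drift[i] * rng.lognormal(mean=0.0, sigma=sigma)
                sn = float(rng.lognormal(np.log(spec.sn_median), spec.sn_sigma))
                if typ == "sample":
                    if analyte in mnar and cls == mnar_class[analyte]:
                        area, sn = np.nan, 1.0
                    elif rng.random() < spec.mar_rate:
                        area = np.nan
                    elif rng.random() < spec.low_sn_rate:
                        sn = float(rng.uniform(1.0, 5.0))
            rows.append(dict(sample_id=sid, injection_order=int(inj_order[i]),
                             type=typ, **{"class": cls}, analyte=analyte,
                             area=area, sn=sn))
    table = pd.DataFrame(rows)
    return BatchFixture(table=table, planted=tuple(planted),
                        high_class=high_class, mnar=mnar)


def write_batch_csv(batch: BatchFixture, path) -> None:
    """Write the long table with a fixed float encoding (byte-stable)."""
    batch.table.to_csv(path, index=False, float_format="%.6g")
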