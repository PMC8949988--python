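"""Assembly of packaged FIA-MRM screening methods.

Starting from an organism-filtered compound library, this module

1. drops metabolites outside the ionizable mass range (30–1500 g/mol) or
   without pKa data,
2. collapses enantiomers (indistinguishable without chromatography),
3. gathers candidate mass transitions per metabolite and allowed polarity —
   in-house tables first, literature second, predicted fragment spectra last,
4. fills instrument parameters (EP 10 V, CXP 4 V defaults, 50 ms dwell,
   missing DP interpolated from a linear DP-vs-precursor-mass regression),
5. flags isobaric convolutions (same polarity, precursor and product m/z),
6. selects one transition and final polarity per metabolite, avoiding
   convolved signals where any alternative exists,
7. distributes the selections into ≤40-transition single-polarity packages
   (one 1-min flow-injection method each), and
8. emits instrument-format CSV tables plus randomized injection sequences
   with QC bracketing.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compound_db import CompoundRecord
from .errors import InputError
from .ionization import (
    NEGATIVE,
    POSITIVE,
    ClassifierThresholds,
    DEFAULT_THRESHOLDS,
    SpeciesClass,
    allocate_mode,
    classify_species,
)
from .spectra import Spectrum

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276  # Th; [M+H]+ / [M−H]− precursor offset

METHOD_COLUMNS = ("Q1", "Q3", "Time(msec)", "ID", "DP", "EP", "CE", "CXP")


@dataclass(frozen=True)
class BuilderConfig:
    """Tunables of the method builder (defaults = the screening workflow's)."""

    mw_min: float = 30.0      # g/mol, strict lower precursor bound
    mw_max: float = 1500.0    # g/mol, strict upper precursor bound
    min_rel_signal: float = 5.0   # % relative-intensity floor for predicted fragments
    default_ep: float = 10.0  # V, entrance potential when absent
    default_cxp: float = 4.0  # V, cell exit potential when absent
    dwell: float = 50.0       # ms per transition
    max_per_package: int = 40
    iso_tol: float = 0.5      # Th, unit-resolution QqQ convolution tolerance
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)

    def __post_init__(self):
        if not self.mw_min < self.mw_max:
            raise InputError("mw_min must be below mw_max")
        if self.max_per_package < 1:
            raise InputError("max_per_package must be >= 1")


@dataclass(frozen=True)
class TransitionCandidate:
    kegg_id: str
    mode: str                # "positive" | "negative"
    q1: float                # precursor m/z, Th
    q3: float                # product m/z, Th
    ce: float                # collision energy, V (signed with mode)
    dp: float | None         # declustering potential, V (None until filled)
    ep: float                # entrance potential, V
    cxp: float               # cell exit potential, V
    dwell: float             # ms
    origin: str              # "inhouse" | "literature" | "predicted"
    intensity_rank: int      # 1 = most intense fragment for this metabolite/mode
    intensity: float | None = None  # relative intensity (%) when known

    def __post_init__(self):
        if not (self.q1 > 0 and self.q3 > 0):
            raise InputError("Q1 and Q3 must be > 0")
        if not self.dwell > 0:
            raise InputError("dwell must be > 0")
        if self.mode not in (POSITIVE, NEGATIVE):
            raise InputError(f"unknown mode {self.mode!r}")
        if (self.mode == POSITIVE) != (self.ce > 0):
            raise InputError("CE sign inconsistent with ionization mode")


# --------------------------------------------------------------------------
# metabolite-level filters


def filter_metabolites(
    records: Iterable[CompoundRecord], config: BuilderConfig
) -> list[CompoundRecord]:
    """Keep classifiable metabolites inside the (mw_min, mw_max) window."""
    kept = []
    for r in records:
        if r.mw is None or not (config.mw_min < r.mw < config.mw_max):
            continue
        if classify_species(r.pka, config.thresholds) is SpeciesClass.UNCLASSIFIED:
            continue
        kept.append(r)
    return kept


_STEREO_CHARS = str.maketrans("", "", "@/\\")


def _stereo_stripped(smiles: str | None) -> str | None:
    return None if smiles is None else smiles.translate(_STEREO_CHARS)


def dedup_enantiomers(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse enantiomer sets to a single survivor (smallest KEGG id).

    Records count as enantiomers when they share molecular formula and
    weight, carry stereo descriptors, and their structure strings agree once
    stereo marks are stripped.  Structural isomers (distinct stripped
    structures) are all kept.
    """
    groups: dict[tuple, list[CompoundRecord]] = {}
    for r in records:
        mw_key = None if r.mw is None else round(r.mw, 4)
        key = (r.formula, mw_key, _stereo_stripped(r.smiles))
        groups.setdefault(key, []).append(r)

    out = []
    for members in groups.values():
        stereo = sorted((m for m in members if m.has_stereo), key=lambda m: m.kegg_id)
        plain = [m for m in members if not m.has_stereo]
        if stereo:
            out.append(stereo[0])
            if len(stereo) > 1:
                logger.info("enantiomer set %s collapsed to %s",
                            [m.kegg_id for m in stereo], stereo[0].kegg_id)
        out.extend(plain)
    out.sort(key=lambda m: m.kegg_id)
    return out


# --------------------------------------------------------------------------
# candidate assembly


def precursor_mz(mw: float, mode: str) -> float:
    """[M+H]+ or [M−H]− precursor m/z for a neutral mass."""
    return mw + PROTON_MASS if mode == POSITIVE else mw - PROTON_MASS


def _ce_signed(ce: float, mode: str) -> float:
    return abs(ce) if mode == POSITIVE else -abs(ce)


def _candidates_from_table(
    table: pd.DataFrame, kegg_id: str, mode: str, origin: str, config: BuilderConfig
) -> list[TransitionCandidate]:
    rows = table[(table["kegg_id"] == kegg_id) & (table["mode"] == mode)]
    out = []
    for rank, (_, row) in enumerate(rows.iterrows(), start=1):
        dp = row.get("dp")
        dp = None if dp is None or (isinstance(dp, float) and math.isnan(dp)) else float(dp)

        def _pot(key, default):
            v = row.get(key)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return default
            return float(v)

        out.append(TransitionCandidate(
            kegg_id=kegg_id, mode=mode,
            q1=float(row["q1"]), q3=float(row["q3"]),
            ce=_ce_signed(float(row["ce"]), mode),
            dp=dp,
            ep=_pot("ep", config.default_ep),
            cxp=_pot("cxp", config.default_cxp),
            dwell=config.dwell, origin=origin, intensity_rank=rank,
        ))
    return out


def _candidates_from_prediction(
    record: CompoundRecord, mode: str, spectra: Sequence[Spectrum],
    config: BuilderConfig,
) -> list[TransitionCandidate]:
    """Pool predicted fragments across the three collision energies,
    ranked by relative intensity (rank 1 = most intense)."""
    q1 = precursor_mz(record.mw, mode)
    frags = []
    for s in spectra:
        for p in s.peaks:
            frags.append((p.rel_intensity, p.mz, s.collision_energy))
    frags.sort(key=lambda t: (-t[0], t[1]))
    out = []
    for rank, (rel, mz, ce) in enumerate(frags, start=1):
        out.append(TransitionCandidate(
            kegg_id=record.kegg_id, mode=mode, q1=q1, q3=mz,
            ce=_ce_signed(ce, mode), dp=None,
            ep=config.default_ep, cxp=config.default_cxp,
            dwell=config.dwell, origin="predicted",
            intensity_rank=rank, intensity=rel,
        ))
    return out


_EMPTY_TABLE = pd.DataFrame(columns=["kegg_id", "mode", "q1", "q3", "ce",
                                     "dp", "ep", "cxp"])


def assemble_candidates(
    records: Sequence[CompoundRecord],
    inhouse: pd.DataFrame | None,
    literature: pd.DataFrame | None,
    predicted: Mapping[tuple[str, str], Sequence[Spectrum]] | None,
    config: BuilderConfig,
) -> tuple[dict[str, list[TransitionCandidate]], list[str]]:
    """Gather candidate transitions per metabolite with origin priority.

    Per metabolite and allowed polarity, in-house entries win over
    literature entries, which win over predicted fragments (spectra are
    expected pre-thresholded at ``min_rel_signal``).  Returns the candidate
    map plus the IDs dropped for lack of any candidate.
    """
    inhouse = _EMPTY_TABLE if inhouse is None or inhouse.empty else inhouse
    literature = _EMPTY_TABLE if literature is None or literature.empty else literature
    predicted = predicted or {}

    candidates: dict[str, list[TransitionCandidate]] = {}
    dropped: list[str] = []
    for r in records:
        cls = classify_species(r.pka, config.thresholds)
        if cls is SpeciesClass.UNCLASSIFIED:
            dropped.append(r.kegg_id)
            continue
        modes = allocate_mode(cls, r.pka).modes
        found: list[TransitionCandidate] = []
        for mode in sorted(modes):
            cands = _candidates_from_table(inhouse, r.kegg_id, mode, "inhouse", config)
            if not cands:
                cands = _candidates_from_table(literature, r.kegg_id, mode,
                                               "literature", config)
            if not cands and (r.kegg_id, mode) in predicted and r.mw is not None:
                cands = _candidates_from_prediction(
                    r, mode, predicted[(r.kegg_id, mode)], config)
            found.extend(cands)
        if found:
            candidates[r.kegg_id] = found
        else:
            dropped.append(r.kegg_id)
    if dropped:
        logger.info("%d metabolites dropped without any transition candidate", len(dropped))
    return candidates, dropped


# --------------------------------------------------------------------------
# declustering-potential regression


@dataclass(frozen=True)
class DpModel:
    """Per-mode linear DP(precursor mass) fit, with a pooled fallback."""

    coefs: dict[str, tuple[float, float]]  # mode -> (slope, intercept)
    pooled: tuple[float, float]

    def predict(self, mw: float, mode: str) -> float:
        slope, intercept = self.coefs.get(mode, self.pooled)
        return slope * mw + intercept


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:  # constant predictor: constant model
        return 0.0, float(np.mean(y))
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_dp_model(known: Sequence[tuple[float, float, str]]) -> DpModel:
    """OLS of declustering potential on precursor mass.

    ``known`` holds (precursor mw, dp, mode) triples from in-house and
    literature transitions.  A mode with fewer than 2 points falls back to
    the pooled fit; fewer than 2 points overall is a configuration error.
    """
    if len(known) < 2:
        raise InputError("DP regression needs at least 2 known (mw, dp) points")
    arr = pd.DataFrame(known, columns=["mw", "dp", "mode"])
    pooled = _ols_line(arr["mw"].to_numpy(float), arr["dp"].to_numpy(float))
    coefs = {}
    for mode, sub in arr.groupby("mode"):
        if len(sub) >= 2:
            coefs[mode] = _ols_line(sub["mw"].to_numpy(float), sub["dp"].to_numpy(float))
    return DpModel(coefs=coefs, pooled=pooled)


def fill_missing_dp(
    candidates: dict[str, list[TransitionCandidate]], model: DpModel
) -> dict[str, list[TransitionCandidate]]:
    """Replace absent DP values with the regression prediction at Q1."""
    out = {}
    for kegg, cands in candidates.items():
        out[kegg] = [
            c if c.dp is not None else replace(c, dp=model.predict(c.q1, c.mode))
            for c in cands
        ]
    return out


# --------------------------------------------------------------------------
# isobaric convolutions


@dataclass(frozen=True)
class ConvolutionGroup:
    mode: str
    q1: float  # group key (mean of members)
    q3: float
    member_ids: frozenset[str]
    members: tuple[tuple[str, float, float], ...]  # (kegg_id, q1, q3)
    tol: float


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def detect_convolutions(
    candidates: dict[str, list[TransitionCandidate]], iso_tol: float
) -> list[ConvolutionGroup]:
    """Group candidate transitions of distinct metabolites that collide.

    Two transitions collide when they share polarity and agree on both Q1
    and Q3 within ``iso_tol``.  Opposite-mode coincidences are not
    convolutions — the instrument never sees them together.
    """
    flat = [c for cands in candidates.values() for c in cands]
    groups: list[ConvolutionGroup] = []
    for mode in (POSITIVE, NEGATIVE):
        cs = sorted((c for c in flat if c.mode == mode), key=lambda c: c.q1)
        n = len(cs)
        uf = _UnionFind(n)
        for i in range(n):
            for j in range(i + 1, n):
                if cs[j].q1 - cs[i].q1 > iso_tol:
                    break
                if abs(cs[j].q3 - cs[i].q3) <= iso_tol:
                    uf.union(i, j)
        comp: dict[int, list[int]] = {}
        for i in range(n):
            comp.setdefault(uf.find(i), []).append(i)
        for idxs in comp.values():
            ids = {cs[i].kegg_id for i in idxs}
            if len(ids) < 2:
                continue
            groups.append(ConvolutionGroup(
                mode=mode,
                q1=float(np.mean([cs[i].q1 for i in idxs])),
                q3=float(np.mean([cs[i].q3 for i in idxs])),
                member_ids=frozenset(ids),
                members=tuple(sorted((cs[i].kegg_id, cs[i].q1, cs[i].q3) for i in idxs)),
                tol=iso_tol,
            ))
    return groups


def _is_convolved(c: TransitionCandidate, groups: Sequence[ConvolutionGroup]) -> bool:
    for g in groups:
        if g.mode != c.mode:
            continue
        for kegg, q1, q3 in g.members:
            if kegg != c.kegg_id and abs(q1 - c.q1) <= g.tol and abs(q3 - c.q3) <= g.tol:
                return True
    return False


# --------------------------------------------------------------------------
# transition selection


@dataclass(frozen=True)
class Selection:
    kegg_id: str
    candidate: TransitionCandidate
    convolved: bool

    @property
    def mode(self):
        return self.candidate.mode


def select_transitions(
    candidates: dict[str, list[TransitionCandidate]],
    convolutions: Sequence[ConvolutionGroup],
) -> dict[str, Selection]:
    """Pick one transition (and thereby one final polarity) per metabolite.

    The most intense convolution-free candidate wins.  Metabolites allocated
    to both polarities choose whichever mode offers a convolution-free
    candidate (tie: higher relative intensity of the best candidate, then
    negative mode).  If every candidate is convolved, the top-ranked one is
    taken and flagged.
    """
    selections: dict[str, Selection] = {}
    for kegg, cands in candidates.items():
        if not cands:
            raise InputError(f"metabolite {kegg} has no candidates")
        per_mode: dict[str, list[TransitionCandidate]] = {}
        for c in sorted(cands, key=lambda c: c.intensity_rank):
            per_mode.setdefault(c.mode, []).append(c)

        free_best: dict[str, TransitionCandidate] = {}
        for mode, cs in per_mode.items():
            for c in cs:
                if not _is_convolved(c, convolutions):
                    free_best[mode] = c
                    break

        if free_best:
            chosen = _pick_mode(free_best)
            selections[kegg] = Selection(kegg, chosen, convolved=False)
        else:
            top = {mode: cs[0] for mode, cs in per_mode.items()}
            chosen = _pick_mode(top)
            selections[kegg] = Selection(kegg, chosen, convolved=True)
    return selections


def _pick_mode(best: dict[str, TransitionCandidate]) -> TransitionCandidate:
    """Deferred-mode tie-break: higher relative intensity where known, then
    better intensity rank, then negative polarity."""
    def key(c: TransitionCandidate):
        inten = c.intensity if c.intensity is not None else float("inf")
        return (-inten, c.intensity_rank, 0 if c.mode == NEGATIVE else 1)

    return min(best.values(), key=key)


# --------------------------------------------------------------------------
# packaging


@dataclass(frozen=True)
class MrmMethodPackage:
    mode: str
    index: int  # 1-based within its mode
    transitions: tuple[TransitionCandidate, ...]

    def __post_init__(self):
        if any(t.mode != self.mode for t in self.transitions):
            raise InputError("package must be single-polarity")

    def __len__(self):
        return len(self.transitions)


def package_methods(
    selected: Mapping[str, Selection] | Sequence[Selection], config: BuilderConfig
) -> list[MrmMethodPackage]:
    """Distribute selections into balanced ≤max_per_package packages.

    Per mode: package count = ceil(n / max_per_package); transitions are
    sorted by Q1 and dealt round-robin, so package sizes differ by at most
    one and each package spans the m/z axis.
    """
    sels = list(selected.values()) if isinstance(selected, Mapping) else list(selected)
    packages: list[MrmMethodPackage] = []
    for mode in (POSITIVE, NEGATIVE):
        chosen = sorted((s.candidate for s in sels if s.mode == mode),
                        key=lambda c: (c.q1, c.q3, c.kegg_id))
        if not chosen:
            continue
        n_pkg = math.ceil(len(chosen) / config.max_per_package)
        for i in range(n_pkg):
            packages.append(MrmMethodPackage(
                mode=mode, index=i + 1, transitions=tuple(chosen[i::n_pkg])))
    return packages


@dataclass(frozen=True)
class MethodSet:
    """A complete screening method: packages plus the per-metabolite ledger."""

    packages: tuple[MrmMethodPackage, ...]
    selection: pd.DataFrame  # kegg_id, mode, q1, q3, ce, dp, ep, cxp, dwell,
    #                          origin, intensity_rank, convolved
    convolutions: tuple[ConvolutionGroup, ...]
    dropped: tuple[str, ...]

    @property
    def analysis_time_min(self) -> int:
        """Total acquisition time per sample: 1 min of flow injection per package."""
        return len(self.packages)


def _selection_frame(selections: Mapping[str, Selection]) -> pd.DataFrame:
    rows = []
    for s in selections.values():
        c = s.candidate
        rows.append({
            "kegg_id": s.kegg_id, "mode": c.mode, "q1": c.q1, "q3": c.q3,
            "ce": c.ce, "dp": c.dp, "ep": c.ep, "cxp": c.cxp, "dwell": c.dwell,
            "origin": c.origin, "intensity_rank": c.intensity_rank,
            "convolved": s.convolved,
        })
    return pd.DataFrame(rows).sort_values("kegg_id").reset_index(drop=True)


def build_method_set(
    records: Sequence[CompoundRecord],
    inhouse: pd.DataFrame | None,
    literature: pd.DataFrame | None,
    predicted: Mapping[tuple[str, str], Sequence[Spectrum]] | None,
    config: BuilderConfig = BuilderConfig(),
) -> MethodSet:
    """End-to-end method assembly for an organism-filtered record set."""
    retained = dedup_enantiomers(filter_metabolites(records, config))
    candidates, dropped = assemble_candidates(
        retained, inhouse, literature, predicted, config)

    known_dp = []
    for table in (inhouse, literature):
        if table is None or table.empty or "dp" not in table.columns:
            continue
        for _, row in table.dropna(subset=["dp"]).iterrows():
            known_dp.append((float(row["q1"]), float(row["dp"]), str(row["mode"])))
    if len(known_dp) >= 2:
        candidates = fill_missing_dp(candidates, fit_dp_model(known_dp))
    else:
        # no DP evidence at all: leave a neutral mid-range default
        candidates = {
            k: [c if c.dp is not None else replace(c, dp=60.0) for c in cs]
            for k, cs in candidates.items()
        }
        logger.warning("no known DP values; defaulting missing DP to 60 V")

    convolutions = detect_convolutions(candidates, config.iso_tol)
    selections = select_transitions(candidates, convolutions)
    packages = package_methods(selections, config)
    return MethodSet(
        packages=tuple(packages),
        selection=_selection_frame(selections),
        convolutions=tuple(convolutions),
        dropped=tuple(dropped),
    )


# --------------------------------------------------------------------------
# instrument tables


def _fmt(x: float) -> str:
    return repr(float(x))


def method_table(pkg: MrmMethodPackage, names: Mapping[str, str] | None = None
                 ) -> pd.DataFrame:
    """Instrument MRM-format table for one package."""
    names = names or {}
    rows = []
    for t in pkg.transitions:
        if t.dp is None:
            raise InputError(f"transition {t.kegg_id} has no DP; fill DP first")
        label = f"{t.kegg_id} {names.get(t.kegg_id, '')}".strip()
        rows.append({
            "Q1": t.q1, "Q3": t.q3, "Time(msec)": t.dwell, "ID": label,
            "DP": t.dp, "EP": t.ep, "CE": t.ce, "CXP": t.cxp,
        })
    return pd.DataFrame(rows, columns=list(METHOD_COLUMNS))


def write_method_csv(pkg: MrmMethodPackage, path: str | Path,
                     names: Mapping[str, str] | None = None) -> None:
    """Write one package as an instrument CSV (byte-stable float encoding)."""
    names = names or {}
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(METHOD_COLUMNS)
    for t in pkg.transitions:
        if t.dp is None:
            raise InputError(f"transition {t.kegg_id} has no DP; fill DP first")
        label = f"{t.kegg_id} {names.get(t.kegg_id, '')}".strip()
        w.writerow([_fmt(t.q1), _fmt(t.q3), _fmt(t.dwell), label,
                    _fmt(t.dp), _fmt(t.ep), _fmt(t.ce), _fmt(t.cxp)])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


_FNAME_RE = re.compile(r"method_(positive|negative)_(\d+)\.csv$")


def read_method_csv(path: str | Path, mode: str | None = None,
                    index: int | None = None) -> MrmMethodPackage:
    """Read a package back from an instrument CSV.

    Mode and index default to what the canonical file name
    ``method_<mode>_<index>.csv`` encodes; the CE sign is cross-checked.
    """
    path = Path(path)
    m = _FNAME_RE.search(path.name)
    if mode is None or index is None:
        if not m:
            raise InputError(f"cannot infer mode/index from file name {path.name!r}")
        mode, index = m.group(1), int(m.group(2))
    with path.open(encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    if tuple(rows[0]) != METHOD_COLUMNS:
        raise InputError(f"unexpected method CSV header: {rows[0]}")
    transitions = []
    for r in rows[1:]:
        d = dict(zip(METHOD_COLUMNS, r))
        kegg_id = d["ID"].split(" ", 1)[0]
        transitions.append(TransitionCandidate(
            kegg_id=kegg_id, mode=mode,
            q1=float(d["Q1"]), q3=float(d["Q3"]), ce=float(d["CE"]),
            dp=float(d["DP"]), ep=float(d["EP"]), cxp=float(d["CXP"]),
            dwell=float(d["Time(msec)"]), origin="inhouse", intensity_rank=1,
        ))
    return MrmMethodPackage(mode=mode, index=index, transitions=tuple(transitions))


def write_method_set(method_set: MethodSet, out_dir: str | Path,
                     names: Mapping[str, str] | None = None) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pkg in method_set.packages:
        p = out_dir / f"method_{pkg.mode}_{pkg.index}.csv"
        write_method_csv(pkg, p, names)
        paths.append(p)
    method_set.selection.to_csv(out_dir / "selection.tsv", sep="\t", index=False)
    return paths


# --------------------------------------------------------------------------
# injection sequences


def build_injection_sequence(
    samples: Sequence[str],
    replicates: int,
    packages: Sequence[MrmMethodPackage],
    seed: int,
) -> pd.DataFrame:
    """Randomized QC-bracketed injection sequence, one plate per polarity.

    Each plate opens with a blank and a QC; samples are shuffled (seeded),
    injected ``replicates`` times back-to-back, and a QC is inserted after
    every 6 sample injections (plus a closing QC).  Columns: position, type,
    sample_id, plate, polarity.
    """
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(samples)
    rng.shuffle(order)

    polarities = sorted({p.mode for p in packages}, reverse=True) or [POSITIVE]
    rows = []
    for plate, polarity in enumerate(polarities, start=1):
        pos = 0

        def push(kind, sample_id=None):
            nonlocal pos
            pos += 1
            rows.append({"position": pos, "type": kind,
                         "sample_id": sample_id or "",
                         "plate": plate, "polarity": polarity})

        push("blank")
        push("qc")
        since_qc = 0
        for s in order:
            for r in range(1, replicates + 1):
                push("sample", f"{s}_r{r}")
                since_qc += 1
                if since_qc == 6:
                    push("qc")
                    since_qc = 0
        if since_qc:
            push("qc")
    return pd.DataFrame(rows, columns=["position", "type", "sample_id",
                                       "plate", "polarity"])
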