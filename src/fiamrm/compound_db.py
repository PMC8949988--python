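"""Compound library built from the KEGG -> PubChem -> ChEMBL identifier chain.

Each metabolite of interest starts as a KEGG compound identifier.  A KEGG ID
links to a PubChem substance (SID), the SID to the neutral-form compound
(CID) carrying the SMILES structure, formula and molecular weight, the CID to
a ChEMBL entry, and the ChEMBL entry to predicted per-group pKa values.  Any
link may be absent, in which case everything downstream of it stays absent —
the chain is never back-filled or invented.

Network access, where used at all, happens behind the :class:`Fetcher`
contract; the library itself only ever sees resolved records and persists
them as a plain UTF-8 TSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol

from .errors import FetchError, InputError

logger = logging.getLogger(__name__)

_KEGG_RE = re.compile(r"^C\d{5}$")

LIBRARY_COLUMNS = (
    "kegg_id",
    "pubchem_sid",
    "pubchem_cid",
    "chembl_id",
    "name",
    "smiles",
    "formula",
    "mw",
    "has_stereo",
    "pka_acidic",
    "pka_basic",
)


@dataclass(frozen=True)
class PkaSet:
    """Predicted pKa values, one per acidic / basic functional group.

    These are per-group constants (log10 units), not whole-molecule
    constants: a molecule with two carboxyl groups carries two acidic values.
    """

    acidic: tuple[float, ...] = ()
    basic: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.acidic and not self.basic:
            raise InputError("PkaSet needs at least one acidic or basic value")
        for v in (*self.acidic, *self.basic):
            if not _finite(v):
                raise InputError(f"non-finite pKa value: {v!r}")


def _finite(v) -> bool:
    try:
        return abs(float(v)) < float("inf") and float(v) == float(v)
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class CompoundRecord:
    """One metabolite's resolved identifiers, structure and pKa set."""

    kegg_id: str
    pubchem_sid: str | None = None
    pubchem_cid: str | None = None
    chembl_id: str | None = None
    name: str = ""
    smiles: str | None = None
    formula: str | None = None
    mw: float | None = None
    has_stereo: bool = False
    pka: PkaSet | None = None

    def __post_init__(self):
        if not _KEGG_RE.match(self.kegg_id):
            raise InputError(f"malformed KEGG compound id: {self.kegg_id!r}")
        if self.mw is not None and not self.mw > 0:
            raise InputError(f"molecular weight must be > 0, got {self.mw}")
        if self.pka is not None and self.chembl_id is None:
            raise InputError("pKa present requires a ChEMBL id (chain order)")


@dataclass(frozen=True)
class OrganismModel:
    """Genome-scale view of one organism: which metabolites it can touch."""

    org_code: str
    metabolite_ids: frozenset[str]
    pathways: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    enzymes: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.metabolite_ids:
            raise InputError("organism model has no metabolites")
        for m in self.metabolite_ids:
            if not _KEGG_RE.match(m):
                raise InputError(f"malformed metabolite id in model: {m!r}")

    def save(self, path: str | Path) -> None:
        lines = ["org_code\tkegg_id"]
        lines += [f"{self.org_code}\t{m}" for m in sorted(self.metabolite_ids)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "OrganismModel":
        rows = Path(path).read_text(encoding="utf-8").splitlines()[1:]
        org, ids = None, set()
        for r in rows:
            if not r.strip():
                continue
            org_code, kegg_id = r.split("\t")
            org = org_code
            ids.add(kegg_id)
        if org is None:
            raise InputError(f"empty organism model file: {path}")
        return cls(org_code=org, metabolite_ids=frozenset(ids))


@dataclass(frozen=True)
class LibraryStats:
    """Survivor counts along the identifier chain (Fig-style funnel).

    A record counts at a stage only if every upstream link resolved too, so
    the counts are non-increasing by construction.
    """

    n_total: int
    n_sid: int
    n_cid: int
    n_chembl: int
    n_pka: int

    def __post_init__(self):
        chain = (self.n_total, self.n_sid, self.n_cid, self.n_chembl, self.n_pka)
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise AssertionError(f"filter-chain counts must be non-increasing: {chain}")


class Fetcher(Protocol):
    """Identifier-resolution contract.

    Every method returns the resolved value or ``None`` for a definitive
    "absent" answer; transport failures raise :class:`FetchError`.
    """

    def sid_for_kegg(self, kegg_id: str) -> str | None: ...

    def cid_for_sid(self, sid: str) -> str | None: ...

    def structure_for_cid(self, cid: str) -> dict | None:
        """Return {'smiles', 'formula', 'mw', 'name'} for the neutral form."""
        ...

    def chembl_for_cid(self, cid: str) -> str | None: ...

    def pka_for_chembl(self, chembl_id: str) -> PkaSet | None: ...


class TabularFetcher:
    """Fetcher backed by in-memory mappings (or local tabular dumps)."""

    def __init__(self, sid_map=None, cid_map=None, structure_map=None,
                 chembl_map=None, pka_map=None):
        self._sid = dict(sid_map or {})
        self._cid = dict(cid_map or {})
        self._structure = dict(structure_map or {})
        self._chembl = dict(chembl_map or {})
        self._pka = dict(pka_map or {})

    def sid_for_kegg(self, kegg_id):
        return self._sid.get(kegg_id)

    def cid_for_sid(self, sid):
        return self._cid.get(sid)

    def structure_for_cid(self, cid):
        return self._structure.get(cid)

    def chembl_for_cid(self, cid):
        return self._chembl.get(cid)

    def pka_for_chembl(self, chembl_id):
        return self._pka.get(chembl_id)


def smiles_has_stereo(smiles: str | None) -> bool:
    """Whether a SMILES string carries stereo descriptors (@, / or \\)."""
    if not smiles:
        return False
    return any(c in smiles for c in ("@", "/", "\\"))


def resolve_chain(kegg_id: str, fetcher: Fetcher) -> CompoundRecord:
    """Walk the identifier chain for one KEGG compound.

    Unresolvable links leave every downstream field absent.  A transport
    failure propagates as :class:`FetchError` and no partial record is
    returned.
    """
    if not isinstance(kegg_id, str) or not _KEGG_RE.match(kegg_id):
        raise InputError(f"malformed KEGG compound id: {kegg_id!r}")

    sid = fetcher.sid_for_kegg(kegg_id)
    rec = CompoundRecord(kegg_id=kegg_id, pubchem_sid=sid)
    if sid is None:
        return rec

    cid = fetcher.cid_for_sid(sid)
    if cid is None:
        return rec
    rec = replace(rec, pubchem_cid=cid)

    structure = fetcher.structure_for_cid(cid)
    if structure is not None:
        smiles = structure.get("smiles")
        rec = replace(
            rec,
            smiles=smiles,
            formula=structure.get("formula"),
            mw=structure.get("mw"),
            name=structure.get("name", ""),
            has_stereo=smiles_has_stereo(smiles),
        )

    chembl = fetcher.chembl_for_cid(cid)
    if chembl is None:
        return rec
    rec = replace(rec, chembl_id=chembl)

    pka = fetcher.pka_for_chembl(chembl)
    if pka is not None:
        rec = replace(rec, pka=pka)
    return rec


class CompoundLibrary:
    """Deduplicated, persistable collection of :class:`CompoundRecord`."""

    def __init__(self, records: Iterable[CompoundRecord] = ()):
        self._records: dict[str, CompoundRecord] = {}
        for r in records:
            if r.kegg_id in self._records:
                logger.warning("duplicate kegg_id %s: first occurrence wins", r.kegg_id)
                continue
            self._records[r.kegg_id] = r

    def __len__(self):
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, kegg_id):
        return kegg_id in self._records

    def __getitem__(self, kegg_id) -> CompoundRecord:
        return self._records[kegg_id]

    def __eq__(self, other):
        return isinstance(other, CompoundLibrary) and self._records == other._records

    @property
    def stats(self) -> LibraryStats:
        recs = list(self)
        with_sid = [r for r in recs if r.pubchem_sid is not None]
        with_cid = [r for r in with_sid if r.pubchem_cid is not None]
        with_chembl = [r for r in with_cid if r.chembl_id is not None]
        with_pka = [r for r in with_chembl if r.pka is not None]
        return LibraryStats(len(recs), len(with_sid), len(with_cid),
                            len(with_chembl), len(with_pka))

    # --- persistence: UTF-8 TSV, absent values as empty fields --------------

    def save(self, path: str | Path) -> None:
        lines = ["\t".join(LIBRARY_COLUMNS)]
        for r in self:
            lines.append("\t".join(_record_to_row(r)))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CompoundLibrary":
        text = Path(path).read_text(encoding="utf-8")
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = tuple(lines[0].split("\t"))
        if header != LIBRARY_COLUMNS:
            raise InputError(f"unexpected library header: {header}")
        return cls(_row_to_record(ln.split("\t")) for ln in lines[1:])


def _record_to_row(r: CompoundRecord) -> list[str]:
    def opt(v):
        return "" if v is None else str(v)

    return [
        r.kegg_id,
        opt(r.pubchem_sid),
        opt(r.pubchem_cid),
        opt(r.chembl_id),
        r.name,
        opt(r.smiles),
        opt(r.formula),
        "" if r.mw is None else repr(float(r.mw)),
        "1" if r.has_stereo else "0",
        "" if r.pka is None else ";".join(repr(v) for v in r.pka.acidic),
        "" if r.pka is None else ";".join(repr(v) for v in r.pka.basic),
    ]


def _row_to_record(row: list[str]) -> CompoundRecord:
    if len(row) != len(LIBRARY_COLUMNS):
        raise InputError(f"library row has {len(row)} fields, expected {len(LIBRARY_COLUMNS)}")
    d = dict(zip(LIBRARY_COLUMNS, row))
    pka = None
    if d["chembl_id"] and (d["pka_acidic"] or d["pka_basic"]):
        pka = PkaSet(
            acidic=tuple(float(v) for v in d["pka_acidic"].split(";") if v),
            basic=tuple(float(v) for v in d["pka_basic"].split(";") if v),
        )
    return CompoundRecord(
        kegg_id=d["kegg_id"],
        pubchem_sid=d["pubchem_sid"] or None,
        pubchem_cid=d["pubchem_cid"] or None,
        chembl_id=d["chembl_id"] or None,
        name=d["name"],
        smiles=d["smiles"] or None,
        formula=d["formula"] or None,
        mw=float(d["mw"]) if d["mw"] else None,
        has_stereo=d["has_stereo"] == "1",
        pka=pka,
    )


def build_library(records: Iterable[CompoundRecord]) -> tuple[CompoundLibrary, LibraryStats]:
    """Collapse duplicates (first wins) and count the identifier funnel."""
    lib = CompoundLibrary(records)
    return lib, lib.stats


def organism_metabolome(
    model: OrganismModel, library: CompoundLibrary
) -> tuple[list[CompoundRecord], list[str]]:
    """Restrict a library to one organism's metabolome.

    Returns the matching records plus the model metabolite IDs absent from
    the library (reported, not fatal).
    """
    hits = [r for r in library if r.kegg_id in model.metabolite_ids]
    misses = sorted(m for m in model.metabolite_ids if m not in library)
    if misses:
        logger.info("%d organism metabolites not in library: %s",
                    len(misses), ", ".join(misses[:10]))
    return hits, misses
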