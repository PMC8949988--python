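"""Fragment-spectrum handling: CFM-ID parsing, thresholding, matching, metrics.

Predicted MS/MS spectra arrive as plain-text documents with three
collision-energy blocks (low / medium / high, corresponding to ±10, ±20 and
±40 V).  A predicted spectrum is compared with a measured one by greedy
nearest-m/z peak pairing within a tolerance, and the agreement is summarized
with five scores:

    R  (recall)              matched / measured peaks
    P  (precision)           matched / predicted peaks
    WR (weighted recall)     matched measured intensity / total measured
    WP (weighted precision)  matched predicted intensity / total predicted
    J  (Jaccard)             matched / (measured + predicted − matched)

R and P weight every signal equally (noise included); WR and WP favour the
intense signals a screening assay actually rides on.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InputError, SpectrumParseError, UndefinedMetricError

ENERGY_LEVELS = (10.0, 20.0, 40.0)  # |CE| in V for low / medium / high blocks


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    rel_intensity: float  # % of block base peak

    def __post_init__(self):
        if not self.mz > 0:
            raise InputError(f"peak m/z must be > 0, got {self.mz}")
        if not 0 < self.rel_intensity <= 100:
            raise InputError(f"rel_intensity out of (0, 100]: {self.rel_intensity}")


@dataclass(frozen=True)
class Spectrum:
    compound_id: str
    polarity: str  # "positive" | "negative"
    collision_energy: float  # signed, V
    source: str  # "measured" | "predicted"
    peaks: tuple[Peak, ...]

    def __post_init__(self):
        if self.peaks:
            mzs = [p.mz for p in self.peaks]
            if mzs != sorted(mzs):
                raise InputError("peaks must be sorted by m/z")
            base = max(p.rel_intensity for p in self.peaks)
            if not math.isclose(base, 100.0):
                raise InputError("non-empty spectrum needs a 100% base peak")

    def __len__(self):
        return len(self.peaks)


def make_spectrum(compound_id, polarity, collision_energy, source, peaks):
    """Build a Spectrum from raw (mz, intensity) pairs; computes rel_intensity."""
    pairs = sorted(peaks)
    if not pairs:
        return Spectrum(compound_id, polarity, collision_energy, source, ())
    base = max(i for _, i in pairs)
    if base <= 0:
        raise InputError("all peak intensities are <= 0")
    return Spectrum(
        compound_id, polarity, collision_energy, source,
        tuple(Peak(mz, inten, min(100.0, 100.0 * inten / base))
              for mz, inten in pairs),
    )


_BLOCK_RE = re.compile(r"^\s*(?:energy(?P<idx>[012])|(?P<word>low|medium|high))\s*$",
                       re.IGNORECASE)
_WORD_IDX = {"low": 0, "medium": 1, "high": 2}


def parse_cfmid(text: str, compound_id: str = "", polarity: str = "positive"
                ) -> list[Spectrum]:
    """Parse a CFM-ID-dialect predicted-spectrum document.

    The document holds up to three blocks headed ``energy0``/``energy1``/
    ``energy2`` (or ``low``/``medium``/``high``), each a list of
    ``mz intensity`` lines.  Blocks map to |CE| = 10, 20, 40 V, signed by
    polarity.  A missing block yields a warning and a partial result; an
    unparsable line raises :class:`SpectrumParseError` with its line number.
    """
    sign = 1.0 if polarity == "positive" else -1.0
    blocks: dict[int, list[tuple[float, float]]] = {}
    current: list[tuple[float, float]] | None = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _BLOCK_RE.match(line)
        if m:
            idx = int(m["idx"]) if m["idx"] is not None else _WORD_IDX[m["word"].lower()]
            current = blocks.setdefault(idx, [])
            continue
        if current is None:
            raise SpectrumParseError("peak line before any energy block header", line_no)
        fields = line.split()
        if len(fields) < 2:
            raise SpectrumParseError(f"expected 'mz intensity', got {raw!r}", line_no)
        try:
            mz, inten = float(fields[0]), float(fields[1])
        except ValueError:
            raise SpectrumParseError(f"non-numeric peak line {raw!r}", line_no) from None
        current.append((mz, inten))

    if not blocks:
        raise SpectrumParseError("document contains no energy blocks")
    missing = [i for i in range(3) if i not in blocks or not blocks[i]]
    if missing:
        warnings.warn(
            f"{compound_id or 'document'}: missing energy block(s) {missing}",
            stacklevel=2,
        )
    return [
        make_spectrum(compound_id, polarity, sign * ENERGY_LEVELS[i], "predicted",
                      blocks[i])
        for i in sorted(blocks)
        if blocks[i]
    ]


def apply_threshold(s: Spectrum, min_rel: float) -> Spectrum:
    """Drop peaks below ``min_rel`` % of the base peak (base always survives)."""
    if not 0 <= min_rel < 100:
        raise InputError(f"min_rel must be in [0, 100), got {min_rel}")
    kept = tuple(p for p in s.peaks if p.rel_intensity >= min_rel)
    return replace(s, peaks=kept)


@dataclass(frozen=True)
class MatchResult:
    matched: tuple[tuple[Peak, Peak], ...]  # (measured, predicted) pairs
    unmatched_measured: tuple[Peak, ...]
    unmatched_predicted: tuple[Peak, ...]
    tolerance: float

    @property
    def n_measured(self):
        return len(self.matched) + len(self.unmatched_measured)

    @property
    def n_predicted(self):
        return len(self.matched) + len(self.unmatched_predicted)


def match_spectra(measured: Spectrum, predicted: Spectrum, tol: float = 0.01
                  ) -> MatchResult:
    """Greedy nearest-m/z peak pairing within ±tol.

    Candidate pairs are taken in order of |Δm/z| (ties toward the more
    intense predicted peak); each peak is used at most once.
    """
    if measured.polarity != predicted.polarity:
        raise InputError("polarity mismatch between spectra")
    if measured.collision_energy != predicted.collision_energy:
        raise InputError("collision-energy mismatch between spectra")

    candidates = []
    for i, pm in enumerate(measured.peaks):
        for j, pp in enumerate(predicted.peaks):
            d = abs(pm.mz - pp.mz)
            if d <= tol:
                candidates.append((d, -pp.intensity, i, j))
    candidates.sort()

    used_m: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for _, _, i, j in candidates:
        if i in used_m or j in used_p:
            continue
        used_m.add(i)
        used_p.add(j)
        pairs.append((measured.peaks[i], predicted.peaks[j]))

    return MatchResult(
        matched=tuple(pairs),
        unmatched_measured=tuple(p for i, p in enumerate(measured.peaks)
                                 if i not in used_m),
        unmatched_predicted=tuple(p for j, p in enumerate(predicted.peaks)
                                  if j not in used_p),
        tolerance=tol,
    )


@dataclass(frozen=True)
class SpectrumMetrics:
    r: float
    p: float
    wr: float
    wp: float
    j: float

    def as_dict(self):
        return {"R": self.r, "P": self.p, "WR": self.wr, "WP": self.wp, "J": self.j}


def spectrum_metrics(m: MatchResult) -> SpectrumMetrics:
    """The five prediction-validation scores for one match result."""
    n_match = len(m.matched)
    n_meas, n_pred = m.n_measured, m.n_predicted
    if n_meas == 0 or n_pred == 0:
        raise UndefinedMetricError("metrics undefined for an empty spectrum")

    int_meas_matched = sum(pm.intensity for pm, _ in m.matched)
    int_pred_matched = sum(pp.intensity for _, pp in m.matched)
    int_meas_total = int_meas_matched + sum(p.intensity for p in m.unmatched_measured)
    int_pred_total = int_pred_matched + sum(p.intensity for p in m.unmatched_predicted)

    return SpectrumMetrics(
        r=n_match / n_meas,
        p=n_match / n_pred,
        wr=int_meas_matched / int_meas_total,
        wp=int_pred_matched / int_pred_total,
        j=n_match / (n_meas + n_pred - n_match),
    )


def summarize_metrics(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mean ± standard error of the five scores, overall / per mode / per |CE|.

    ``results`` needs columns polarity, ce and R, P, WR, WP, J (one row per
    compared spectrum pair).  SE uses the sample standard deviation; a group
    of one reports SE = 0.
    """
    cols = ["R", "P", "WR", "WP", "J"]
    missing = [c for c in cols + ["polarity", "ce"] if c not in results.columns]
    if missing:
        raise InputError(f"results table missing columns: {missing}")
    if results.empty:
        raise InputError("no metric results to summarize")

    def agg(df: pd.DataFrame, by=None) -> pd.DataFrame:
        if by is None:
            mean = df[cols].mean().to_frame().T
            se = (df[cols].sem(ddof=1).fillna(0.0)).to_frame().T
        else:
            g = df.groupby(by, sort=True)
            mean = g[cols].mean()
            se = g[cols].sem(ddof=1).fillna(0.0)
        se.columns = [f"{c}_se" for c in cols]
        return pd.concat([mean, se], axis=1)

    by_energy = results.assign(abs_ce=results["ce"].abs())
    return {
        "overall": agg(results),
        "by_mode": agg(results, by="polarity"),
        "by_energy": agg(by_energy, by="abs_ce"),
    }
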