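"""QC and statistics pipeline for MRM peak-area tables.

The mandatory order mirrors how a flow-injection screening batch is
processed:

1. **S/N filter** — areas with signal-to-noise ≤ 5 become missing.
2. **LOESS drift correction** — per metabolite, a degree-1 LOESS of QC area
   vs injection order (span picked by leave-one-out CV on the QCs) models
   intra-batch drift; every injection is rescaled by QC-median / trend.
3. **QC acceptance** — keep metabolites with QC RSD < 20% and < 30% missing
   QC values.
4. **Imputation** — within a metabolite × class block, partially missing
   values get the class mean (missing at random); a wholly missing class
   gets half the metabolite's global minimum (missing not at random,
   i.e. below detection).
5. **Modelling** — range scaling *inside* each cross-validation fold, PCA
   for overview, multiclass PLSDA with stratified double 5-fold CV,
   bootstrap percentile confidence intervals for coefficients and VIP
   scores, Kruskal–Wallis omnibus tests, and the three-criterion variable
   selection (p < α, β CI excluding 0, VIP > 1 for at least one class).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from statsmodels.nonparametric.smoothers_lowess import lowess

from .chemometrics import PlsdaClassifier, RangeScaler
from .errors import InputError, PipelineOrderError

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("blank", "qc", "sample")
LONG_COLUMNS = ("sample_id", "injection_order", "type", "class", "analyte",
                "area", "sn")


@dataclass(frozen=True)
class QcConfig:
    """Thresholds and model settings of the QC/statistics pipeline."""

    sn_min: float = 5.0          # keep signals with S/N strictly above this
    rsd_max: float = 20.0        # % QC relative standard deviation ceiling
    qc_missing_max: float = 30.0  # % missing QC values ceiling
    alpha: float = 0.05
    n_boot: int = 1000
    cv_folds: int = 5
    q2_gain: float = 0.05        # stop adding components below this Q2 gain
    vip_cut: float = 1.0
    max_components: int = 8
    loess_span_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    min_qc_for_loess: int = 4
    beta_criterion: str = "ci"   # "ci" (CI excludes 0) or "point" (estimate != 0)
    bh_adjust: bool = False      # optional Benjamini-Hochberg on KW p-values

    def __post_init__(self):
        if self.cv_folds < 2:
            raise InputError("cv_folds must be >= 2")
        for name in ("sn_min", "rsd_max", "qc_missing_max", "alpha", "vip_cut"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")


class FeatureTable:
    """Samples x metabolites peak areas with injection metadata.

    Wraps a metadata frame (sample_id, injection_order, type, class) indexed
    by injection, plus aligned wide ``area`` and ``sn`` frames (columns =
    analytes).  Loadable from / convertible to the long CSV layout.
    """

    def __init__(self, meta: pd.DataFrame, area: pd.DataFrame, sn: pd.DataFrame):
        if not (meta.index.equals(area.index) and meta.index.equals(sn.index)):
            raise InputError("meta/area/sn row indices must align")
        if not meta["injection_order"].is_monotonic_increasing or \
                meta["injection_order"].duplicated().any():
            raise InputError("injection_order must be strictly increasing")
        bad = set(meta["type"]) - set(SAMPLE_TYPES)
        if bad:
            raise InputError(f"unknown sample types: {bad}")
        self.meta = meta
        self.area = area
        self.sn = sn

    @property
    def analytes(self) -> list[str]:
        return list(self.area.columns)

    @property
    def qc_mask(self) -> pd.Series:
        return self.meta["type"] == "qc"

    @property
    def sample_mask(self) -> pd.Series:
        return self.meta["type"] == "sample"

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.meta.copy(), self.area.copy(), self.sn.copy())

    def drop_analytes(self, analytes) -> "FeatureTable":
        keep = [a for a in self.area.columns if a not in set(analytes)]
        return FeatureTable(self.meta, self.area[keep], self.sn[keep])

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "FeatureTable":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"long table missing columns: {missing}")
        meta = (df[["sample_id", "injection_order", "type", "class"]]
                .drop_duplicates("sample_id")
                .sort_values("injection_order")
                .set_index("sample_id", drop=False))
        area = df.pivot(index="sample_id", columns="analyte", values="area")
        sn = df.pivot(index="sample_id", columns="analyte", values="sn")
        area = area.loc[meta.index]
        sn = sn.loc[meta.index]
        return cls(meta, area, sn)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for col in self.area.columns:
            sub = self.meta[["sample_id", "injection_order", "type", "class"]].copy()
            sub["analyte"] = col
            sub["area"] = self.area[col].to_numpy()
            sub["sn"] = self.sn[col].to_numpy()
            rows.append(sub)
        return pd.concat(rows, ignore_index=True)[list(LONG_COLUMNS)]


# --------------------------------------------------------------------------
# 1. signal/noise filter


def filter_sn(table: FeatureTable, config: QcConfig = QcConfig()) -> FeatureTable:
    """Blank out areas whose signal-to-noise is not strictly above sn_min."""
    out = table.copy()
    low = ~(out.sn > config.sn_min)
    out.area = out.area.mask(low)
    return out


# --------------------------------------------------------------------------
# 2. LOESS drift correction


@dataclass
class LoessCorrection:
    """Per-metabolite record of the drift correction."""

    report: pd.DataFrame  # analyte, span, corrected, reason, rsd_before, rsd_after
    factors: pd.DataFrame  # injections x analytes multiplicative correction


def _qc_rsd(values: np.ndarray) -> float:
    v = values[~np.isnan(values)]
    if len(v) < 2 or v.mean() == 0:
        return np.nan
    return 100.0 * v.std(ddof=1) / v.mean()


def _loo_cv_error(x: np.ndarray, y: np.ndarray, span: float) -> float:
    err = 0.0
    for i in range(len(x)):
        mask = np.ones(len(x), bool)
        mask[i] = False
        pred = lowess(y[mask], x[mask], frac=span, it=0, xvals=np.array([x[i]]))
        if np.isnan(pred[0]):
            return np.inf
        err += (y[i] - pred[0]) ** 2
    return err


def loess_correct(
    table: FeatureTable, config: QcConfig = QcConfig()
) -> tuple[FeatureTable, LoessCorrection]:
    """Remove intra-batch drift using QC injections.

    For each metabolite with at least ``min_qc_for_loess`` non-missing QC
    values, a degree-1 LOESS (tricube weights) of QC area on injection order
    is fitted; the span comes from a leave-one-out CV over the grid in the
    config.  Corrected area = raw x (QC median / trend at that injection).
    A metabolite is left uncorrected (and flagged) when the trend
    interpolates to <= 0 anywhere or the correction fails to reduce the QC
    RSD.
    """
    out = table.copy()
    order = table.meta["injection_order"].to_numpy(float)
    qc = table.qc_mask.to_numpy()
    factors = pd.DataFrame(1.0, index=table.area.index, columns=table.area.columns)
    rows = []

    for analyte in table.analytes:
        y_all = table.area[analyte].to_numpy(float)
        qc_ok = qc & ~np.isnan(y_all)
        x_qc, y_qc = order[qc_ok], y_all[qc_ok]
        rsd_before = _qc_rsd(y_all[qc])

        if qc_ok.sum() < config.min_qc_for_loess:
            warnings.warn(f"{analyte}: <{config.min_qc_for_loess} QC values, "
                          "drift correction skipped", stacklevel=2)
            rows.append(dict(analyte=analyte, span=np.nan, corrected=False,
                             reason="too_few_qc", rsd_before=rsd_before,
                             rsd_after=rsd_before))
            continue

        errors = [_loo_cv_error(x_qc, y_qc, s) for s in config.loess_span_grid]
        span = config.loess_span_grid[int(np.argmin(errors))]
        trend = lowess(y_qc, x_qc, frac=span, it=0, xvals=order)
        # outside the QC range lowess extrapolates NaN: hold the edge value
        trend = pd.Series(trend).ffill().bfill().to_numpy()

        if np.any(trend <= 0) or np.any(np.isnan(trend)):
            rows.append(dict(analyte=analyte, span=span, corrected=False,
                             reason="nonpositive_trend", rsd_before=rsd_before,
                             rsd_after=rsd_before))
            continue

        f = np.median(y_qc) / trend
        corrected = y_all * f
        rsd_after = _qc_rsd(corrected[qc])
        if not np.isnan(rsd_before) and rsd_after > rsd_before:
            rows.append(dict(analyte=analyte, span=span, corrected=False,
                             reason="no_improvement", rsd_before=rsd_before,
                             rsd_after=rsd_before))
            continue

        out.area[analyte] = corrected
        factors[analyte] = f
        rows.append(dict(analyte=analyte, span=span, corrected=True, reason="",
                         rsd_before=rsd_before, rsd_after=rsd_after))

    return out, LoessCorrection(report=pd.DataFrame(rows), factors=factors)


# --------------------------------------------------------------------------
# 3. QC acceptance


def qc_accept(table: FeatureTable, config: QcConfig = QcConfig()) -> pd.DataFrame:
    """Per-metabolite QC precision report.

    pass <=> QC RSD < rsd_max (%) and QC missing fraction < qc_missing_max (%).
    RSD uses the sample standard deviation (n − 1).
    """
    qc_area = table.area[table.qc_mask.to_numpy()]
    if qc_area.shape[0] < 2:
        raise InputError("QC acceptance needs at least 2 QC injections")
    rows = []
    for analyte in table.analytes:
        v = qc_area[analyte].to_numpy(float)
        missing_pct = 100.0 * np.isnan(v).mean()
        rsd = _qc_rsd(v)
        passed = (not np.isnan(rsd)) and rsd < config.rsd_max \
            and missing_pct < config.qc_missing_max
        rows.append(dict(analyte=analyte, qc_rsd=rsd, qc_missing_pct=missing_pct,
                         passed=passed))
    return pd.DataFrame(rows)


def apply_qc_filter(table: FeatureTable, report: pd.DataFrame) -> FeatureTable:
    failed = report.loc[~report["passed"], "analyte"].tolist()
    return table.drop_analytes(failed)


# --------------------------------------------------------------------------
# 4. imputation


def impute(table: FeatureTable) -> FeatureTable:
    """MAR/MNAR imputation on the sample rows.

    Within a metabolite x class block: partially missing -> class mean
    (treated as missing at random); a wholly missing class -> half of the
    metabolite's global minimum (treated as below-detection, missing not at
    random).  Metabolites missing everywhere are dropped with a warning.
    """
    out = table.copy()
    smask = table.sample_mask.to_numpy()
    classes = table.meta.loc[smask, "class"]
    dropped = []
    for analyte in table.analytes:
        v = out.area[analyte].to_numpy(float).copy()
        sample_vals = v[smask]
        if np.all(np.isnan(sample_vals)):
            dropped.append(analyte)
            continue
        global_min = np.nanmin(sample_vals)
        for cls in classes.unique():
            cmask = smask & (table.meta["class"] == cls).to_numpy()
            block = v[cmask]
            if np.all(np.isnan(block)):
                v[cmask] = global_min / 2.0
            elif np.any(np.isnan(block)):
                block[np.isnan(block)] = np.nanmean(block)
                v[cmask] = block
        out.area[analyte] = v
    if dropped:
        warnings.warn(f"{len(dropped)} metabolite(s) missing everywhere, dropped",
                      stacklevel=2)
        out = out.drop_analytes(dropped)
    return out


# --------------------------------------------------------------------------
# 5a. range scaling (thin functional wrapper over the estimator)


def range_scale(train: pd.DataFrame, test: pd.DataFrame | None = None):
    """Range-scale train (fit) and test (transform with train's min/max)."""
    scaler = RangeScaler().fit(train.to_numpy(float))
    train_s = pd.DataFrame(scaler.transform(train.to_numpy(float)),
                           index=train.index, columns=train.columns)
    if test is None:
        return train_s, None, scaler
    test_s = pd.DataFrame(scaler.transform(test.to_numpy(float)),
                          index=test.index, columns=test.columns)
    return train_s, test_s, scaler


# --------------------------------------------------------------------------
# 5b. PCA with cross-validated component count


@dataclass(frozen=True)
class PcaResult:
    n_components: int
    r2x_per_component: np.ndarray
    r2x_cum: np.ndarray
    q2x: np.ndarray  # cumulative, per candidate component count
    scores: np.ndarray
    loadings: np.ndarray
    mean_: np.ndarray


def fit_pca(X: np.ndarray | pd.DataFrame, config: QcConfig = QcConfig(),
            seed: int = 0) -> PcaResult:
    """PCA with the Q2-gain rule for the component count.

    R2X is the cumulative explained variance; Q2X comes from K-fold
    row-held-out reconstruction (train loadings applied to test rows).  The
    component count stops growing when the Q2X gain falls below
    ``q2_gain``.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    max_comp = min(config.max_components, p, n - 1)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    ss_tot = float((Xc ** 2).sum())
    r2x_per = (S[:max_comp] ** 2) / ss_tot
    r2x_cum = np.cumsum(r2x_per)

    press = np.zeros(max_comp)
    tss = 0.0
    folds = KFold(n_splits=min(config.cv_folds, n), shuffle=True, random_state=seed)
    for tr, te in folds.split(X):
        mu = X[tr].mean(axis=0)
        _, _, Vt_tr = np.linalg.svd(X[tr] - mu, full_matrices=False)
        Xte = X[te] - mu
        tss += float((Xte ** 2).sum())
        for a in range(1, max_comp + 1):
            V = Vt_tr[:a].T
            recon = Xte @ V @ V.T
            press[a - 1] += float(((Xte - recon) ** 2).sum())
    q2x = 1.0 - press / tss

    n_comp = max_comp
    for a in range(1, max_comp):
        if q2x[a] - q2x[a - 1] < config.q2_gain:
            n_comp = a
            break

    return PcaResult(
        n_components=n_comp,
        r2x_per_component=r2x_per,
        r2x_cum=r2x_cum,
        q2x=q2x,
        scores=Xc @ Vt[:n_comp].T,
        loadings=Vt[:n_comp].T,
        mean_=mean,
    )


# --------------------------------------------------------------------------
# 5c. PLSDA with stratified double cross-validation


@dataclass(frozen=True)
class PlsdaCvResult:
    model: PlsdaClassifier
    scaler: RangeScaler
    n_lv: int
    r2y: float
    q2y: float
    accuracy: float
    inner_q2: np.ndarray  # inner-CV Q2Y per candidate LV count (full data)


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    return np.eye(len(classes))[idx]


def _cv_press(X, y, classes, n_lv, folds) -> tuple[float, float, int, int]:
    """Pooled PRESS/TSS and classification hits over given folds,
    with range scaling refit inside every fold."""
    press = tss = 0.0
    hits = total = 0
    for tr, te in folds:
        scaler = RangeScaler().fit(X[tr])
        model = PlsdaClassifier(n_components=n_lv).fit(scaler.transform(X[tr]), y[tr])
        Yte = _one_hot(y[te], classes)
        pred = model.decision_function(scaler.transform(X[te]))
        # align predicted columns with the global class order
        col = np.searchsorted(classes, model.classes_)
        full = np.zeros_like(Yte)
        full[:, col] = pred
        press += float(((Yte - full) ** 2).sum())
        Ytr_mean = _one_hot(y[tr], classes).mean(axis=0)
        tss += float(((Yte - Ytr_mean) ** 2).sum())
        hits += int((model.predict(scaler.transform(X[te])) == y[te]).sum())
        total += len(te)
    return press, tss, hits, total


def _select_n_lv(X, y, classes, config, seed) -> tuple[int, np.ndarray]:
    """Inner stratified CV: grow LVs until the Q2Y gain drops below q2_gain."""
    max_lv = min(config.max_components, X.shape[1], X.shape[0] - 1)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    q2 = []
    for n_lv in range(1, max_lv + 1):
        press, tss, _, _ = _cv_press(X, y, classes, n_lv, folds)
        q2.append(1.0 - press / tss)
        if len(q2) >= 2 and q2[-1] - q2[-2] < config.q2_gain:
            return len(q2) - 1, np.array(q2)
    return max_lv, np.array(q2)


def fit_plsda_cv(
    X: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    config: QcConfig = QcConfig(),
    seed: int = 0,
) -> PlsdaCvResult:
    """Stratified double 5-fold cross-validated PLSDA.

    The inner loop (on each outer training set) selects the latent-variable
    count with the Q2-gain stop rule; the outer loop pools the held-out
    PRESS into Q2Y and the classification accuracy.  The returned model is
    refit on all data at the LV count selected by an inner CV on the full
    data set, together with its range scaler.
    """
    X = np.asarray(X, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("PLSDA needs at least 2 classes")
    if counts.min() < config.cv_folds:
        raise InputError(
            f"smallest class ({counts.min()}) below cv_folds={config.cv_folds}; "
            "stratification impossible")

    outer = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                            random_state=seed + 1)
    press = tss = 0.0
    hits = total = 0
    for tr, te in outer.split(X, y):
        n_lv_tr, _ = _select_n_lv(X[tr], y[tr], classes, config, seed)
        p, t, h, m = _cv_press(X, y, classes, n_lv_tr, [(tr, te)])
        press += p
        tss += t
        hits += h
        total += m
    q2y = 1.0 - press / tss

    n_lv, inner_q2 = _select_n_lv(X, y, classes, config, seed)
    scaler = RangeScaler().fit(X)
    model = PlsdaClassifier(n_components=n_lv).fit(scaler.transform(X), y)
    return PlsdaCvResult(model=model, scaler=scaler, n_lv=n_lv,
                         r2y=model.r2y_, q2y=q2y,
                         accuracy=hits / total, inner_q2=inner_q2)


def permutation_q2y(
    X, labels, n_lv: int, config: QcConfig = QcConfig(),
    n_perm: int = 20, seed: int = 0,
) -> np.ndarray:
    """Q2Y under label permutation (a no-information reference)."""
    X = np.asarray(X, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_perm):
        yp = rng.permutation(y)
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=seed + k)
        press, tss, _, _ = _cv_press(X, yp, classes, n_lv, list(skf.split(X, yp)))
        out.append(1.0 - press / tss)
    return np.array(out)


# --------------------------------------------------------------------------
# 5d. bootstrap confidence intervals


@dataclass(frozen=True)
class BootstrapResult:
    classes: np.ndarray
    beta_point: np.ndarray   # (p, k)
    vip_point: np.ndarray    # (p, k)
    beta_lo: np.ndarray
    beta_hi: np.ndarray
    vip_lo: np.ndarray
    vip_hi: np.ndarray


def bootstrap_plsda(
    X: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    n_lv: int,
    config: QcConfig = QcConfig(),
    seed: int = 0,
) -> BootstrapResult:
    """Class-stratified bootstrap of PLSDA coefficients and VIP scores.

    ``n_boot`` resamples with replacement are drawn within each class (so no
    class can vanish), the scaling + PLSDA pipeline is refit on each, and
    2.5/97.5 percentile confidence intervals are reported for every
    coefficient and class-specific VIP.
    """
    X = np.asarray(X, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    idx_by_class = [np.flatnonzero(y == c) for c in classes]

    scaler = RangeScaler().fit(X)
    point = PlsdaClassifier(n_components=n_lv).fit(scaler.transform(X), y)

    betas = np.empty((config.n_boot, *point.coef_.shape))
    vips = np.empty_like(betas)
    for b in range(config.n_boot):
        idx = np.concatenate([rng.choice(ix, size=len(ix), replace=True)
                              for ix in idx_by_class])
        sc = RangeScaler().fit(X[idx])
        m = PlsdaClassifier(n_components=n_lv).fit(sc.transform(X[idx]), y[idx])
        betas[b] = m.coef_
        vips[b] = m.vip_

    return BootstrapResult(
        classes=classes,
        beta_point=point.coef_, vip_point=point.vip_,
        beta_lo=np.percentile(betas, 2.5, axis=0),
        beta_hi=np.percentile(betas, 97.5, axis=0),
        vip_lo=np.percentile(vips, 2.5, axis=0),
        vip_hi=np.percentile(vips, 97.5, axis=0),
    )


# --------------------------------------------------------------------------
# 5e. univariate testing and variable selection


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected mid-ranks) and chi-square p-value.

    All-identical values are a degenerate no-signal case: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise InputError("Kruskal-Wallis needs at least 2 groups")
    if sum(len(g) for g in groups) < 2:
        raise InputError("Kruskal-Wallis needs at least 2 observations")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kruskal_table(table: FeatureTable) -> pd.DataFrame:
    """Kruskal-Wallis test per metabolite across the sample classes."""
    smask = table.sample_mask.to_numpy()
    classes = table.meta.loc[smask, "class"]
    rows = []
    for analyte in table.analytes:
        v = table.area[analyte].to_numpy(float)[smask]
        groups = [v[(classes == c).to_numpy()] for c in classes.unique()]
        groups = [g[~np.isnan(g)] for g in groups if np.any(~np.isnan(g))]
        if len(groups) < 2:
            h, p = 0.0, 1.0  # degenerate: fewer than two observed groups
        else:
            h, p = kruskal_wallis(groups)
        rows.append(dict(analyte=analyte, H=h, p=p))
    return pd.DataFrame(rows)


def select_variables(
    kw: pd.DataFrame,
    boot: BootstrapResult,
    analytes: list[str],
    config: QcConfig = QcConfig(),
) -> pd.DataFrame:
    """Three-criterion discriminating-metabolite call.

    selected <=> KW p < alpha AND for at least one class the bootstrap CI of
    the regression coefficient excludes 0 AND the VIP point estimate exceeds
    vip_cut (strictly) for that same class.
    """
    kw = kw.set_index("analyte").loc[analytes]
    pvals = kw["p"].to_numpy(float)
    if config.bh_adjust:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]

    if config.beta_criterion == "ci":
        beta_nonzero = (boot.beta_lo > 0) | (boot.beta_hi < 0)
    elif config.beta_criterion == "point":
        beta_nonzero = boot.beta_point != 0
    else:
        raise InputError(f"unknown beta_criterion {config.beta_criterion!r}")
    vip_high = boot.vip_point > config.vip_cut
    class_hit = beta_nonzero & vip_high  # (p, k)

    rows = []
    for i, analyte in enumerate(analytes):
        hit_classes = [str(boot.classes[c]) for c in np.flatnonzero(class_hit[i])]
        rows.append({
            "analyte": analyte,
            "H": kw.loc[analyte, "H"],
            "p": pvals[i],
            "selected": bool(pvals[i] < config.alpha and hit_classes),
            "classes": ";".join(hit_classes),
            **{f"beta_lo_{c}": boot.beta_lo[i, j] for j, c in enumerate(boot.classes)},
            **{f"beta_hi_{c}": boot.beta_hi[i, j] for j, c in enumerate(boot.classes)},
            **{f"vip_{c}": boot.vip_point[i, j] for j, c in enumerate(boot.classes)},
            **{f"vip_lo_{c}": boot.vip_lo[i, j] for j, c in enumerate(boot.classes)},
            **{f"vip_hi_{c}": boot.vip_hi[i, j] for j, c in enumerate(boot.classes)},
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pipeline driver


@dataclass
class PipelineResult:
    table: FeatureTable            # filtered, corrected, imputed
    loess: LoessCorrection
    qc_report: pd.DataFrame
    pca: PcaResult
    plsda: PlsdaCvResult
    bootstrap: BootstrapResult
    kw: pd.DataFrame
    selection: pd.DataFrame


def run_pipeline(
    table: FeatureTable | pd.DataFrame,
    config: QcConfig = QcConfig(),
    seed: int = 0,
) -> PipelineResult:
    """Run the full fixed-order QC/statistics pipeline on a feature table."""
    if isinstance(table, pd.DataFrame):
        table = FeatureTable.from_long(table)

    t1 = filter_sn(table, config)
    t2, loess = loess_correct(t1, config)
    qc_report = qc_accept(t2, config)
    t3 = apply_qc_filter(t2, qc_report)
    if not t3.analytes:
        raise PipelineOrderError("no metabolite passed QC acceptance")
    # univariate testing runs on observed values; imputation feeds only the
    # multivariate models
    kw = kruskal_table(t3)
    t4 = impute(t3)

    smask = t4.sample_mask.to_numpy()
    X = t4.area.to_numpy(float)[smask]
    y = t4.meta.loc[smask, "class"].to_numpy()

    # PCA overview on range-scaled sample data (QCs excluded from modelling)
    pca = fit_pca(RangeScaler().fit_transform(X), config, seed=seed)
    plsda = fit_plsda_cv(X, y, config, seed=seed)
    boot = bootstrap_plsda(X, y, plsda.n_lv, config, seed=seed)
    selection = select_variables(kw, boot, t4.analytes, config)

    return PipelineResult(table=t4, loess=loess, qc_report=qc_report, pca=pca,
                          plsda=plsda, bootstrap=boot, kw=kw, selection=selection)
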