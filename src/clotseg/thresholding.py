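"""Per-patient ROC-optimal HU thresholds and threshold-prediction regressions.

The labeled-voxel protocol samples 36 thrombus voxels (four 3x3 axial ROIs
along the clot centerline), 36 contralateral-vessel voxels (four 3x3 ROIs)
and 100 normal-parenchyma voxels (one 10x10 ROI); vessel and parenchyma are
pooled into a single non-thrombus class. The per-patient optimal threshold
T* maximizes Youden's J = sensitivity + specificity - 1 over an integer HU
grid, with the classifier "thrombus iff HU >= t". Linear models then predict
T* from a single contralateral tissue measurement; the published cohort
models are

    T* = 0.45 x contralateral artery HU + 31
    T* = 0.62 x parenchyma HU + 30.0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume_core import Centerline, ROISpec, Volume, extract_roi_values

__all__ = [
    "VoxelSampleSet",
    "ROCResult",
    "ThresholdModel",
    "CorrelationReport",
    "ModelComparison",
    "PUBLISHED_MODELS",
    "PUBLISHED_ARTERY_MODEL",
    "PUBLISHED_PARENCHYMA_MODEL",
    "assemble_samples",
    "equidistant_centerline_rois",
    "roc_optimal_threshold",
    "fit_threshold_model",
    "predict_threshold",
    "compare_models",
    "correlation_report",
]

PROTOCOL = {"n_thrombus_rois": 4, "n_vessel_rois": 4, "small_roi": 3, "parenchyma_roi": 10}

_PREDICTOR_COLUMNS = {"artery": "artery_hu", "parenchyma": "parenchyma_hu"}
_TARGET_COLUMN = "optimal_threshold_hu"


@dataclass
class VoxelSampleSet:
    """Labeled HU samples feeding the per-patient ROC analysis."""

    thrombus: np.ndarray
    vessel: np.ndarray
    parenchyma: np.ndarray
    rois: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thrombus = np.asarray(self.thrombus, dtype=float).ravel()
        self.vessel = np.asarray(self.vessel, dtype=float).ravel()
        self.parenchyma = np.asarray(self.parenchyma, dtype=float).ravel()
        for name in ("thrombus", "vessel", "parenchyma"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} samples must be finite")

    @property
    def non_thrombus(self) -> np.ndarray:
        """Vessel and parenchyma voxels pooled into one class."""
        return np.concatenate([self.vessel, self.parenchyma])

    def validate_protocol(self) -> None:
        if len(self.thrombus) != 36 or len(self.vessel) != 36 or len(self.parenchyma) != 100:
            raise ValueError(
                "protocol violation: expected 36 thrombus / 36 vessel / 100 parenchyma "
                f"voxels, got {len(self.thrombus)}/{len(self.vessel)}/{len(self.parenchyma)}"
            )


@dataclass
class ROCResult:
    """Integer-grid ROC scan with the Youden-optimal threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    optimal_threshold: int
    sensitivity_at_optimum: float
    specificity_at_optimum: float


@dataclass
class ThresholdModel:
    """Linear threshold predictor T* = intercept + slope * tissue HU."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float | None = None
    f_statistic: float | None = None
    f_pvalue: float | None = None
    df: tuple[int, int] | None = None
    aic: float | None = None
    bic: float | None = None
    n: int | None = None
    published: bool = False

    def predict(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = self.intercept + self.slope * x
        return float(out) if out.ndim == 0 else out


# Published cohort models (70-patient thin-slice NCCT cohort).
PUBLISHED_ARTERY_MODEL = ThresholdModel("artery", slope=0.45, intercept=31.0, published=True)
PUBLISHED_PARENCHYMA_MODEL = ThresholdModel("parenchyma", slope=0.62, intercept=30.0, published=True)
PUBLISHED_MODELS = {"artery": PUBLISHED_ARTERY_MODEL, "parenchyma": PUBLISHED_PARENCHYMA_MODEL}


@dataclass
class CorrelationReport:
    """Pairwise association matrix with the per-pair method used."""

    coefficients: pd.DataFrame
    methods: pd.DataFrame
    alpha: float


@dataclass
class ModelComparison:
    records: pd.DataFrame  # one row per model: aic, bic, pearson_r


def assemble_samples(
    ncct: Volume,
    thrombus_rois: Sequence[ROISpec],
    vessel_rois: Sequence[ROISpec],
    parenchyma_roi: ROISpec,
) -> VoxelSampleSet:
    """Extract the protocol's 36/36/100 labeled voxel samples from NCCT."""
    if len(thrombus_rois) != PROTOCOL["n_thrombus_rois"]:
        raise ValueError(f"protocol requires 4 thrombus ROIs, got {len(thrombus_rois)}")
    if len(vessel_rois) != PROTOCOL["n_vessel_rois"]:
        raise ValueError(f"protocol requires 4 contralateral-vessel ROIs, got {len(vessel_rois)}")
    for roi in thrombus_rois:
        if roi.in_plane_shape != (3, 3) or roi.tissue_class != "thrombus":
            raise ValueError("thrombus ROIs must be 3x3 patches of class 'thrombus'")
    for roi in vessel_rois:
        if roi.in_plane_shape != (3, 3) or roi.tissue_class != "contralateral_vessel":
            raise ValueError("vessel ROIs must be 3x3 patches of class 'contralateral_vessel'")
    if parenchyma_roi.in_plane_shape != (10, 10) or parenchyma_roi.tissue_class != "parenchyma":
        raise ValueError("parenchyma ROI must be a 10x10 patch of class 'parenchyma'")

    thrombus = np.concatenate([extract_roi_values(ncct, r) for r in thrombus_rois])
    vessel = np.concatenate([extract_roi_values(ncct, r) for r in vessel_rois])
    parenchyma = extract_roi_values(ncct, parenchyma_roi)
    samples = VoxelSampleSet(
        thrombus,
        vessel,
        parenchyma,
        rois={
            "thrombus": [r.to_dict() for r in thrombus_rois],
            "vessel": [r.to_dict() for r in vessel_rois],
            "parenchyma": parenchyma_roi.to_dict(),
        },
    )
    samples.validate_protocol()
    return samples


def equidistant_centerline_rois(
    centerline: Centerline,
    vol: Volume,
    k: int = 4,
    size: int = 3,
    tissue_class: str = "thrombus",
) -> list[ROISpec]:
    """Place ``k`` ROIs at arc-length fractions (i + 0.5)/k along a centerline.

    Centres are mapped to the nearest voxel. Raises if the centerline (or an
    ROI patch) exits the volume.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = centerline.arc_length
    if L <= 0:
        raise ValueError("centerline arc length must be positive")
    nx, ny, nz = vol.shape
    rois = []
    for i in range(k):
        p = centerline.point_at_arclength((i + 0.5) / k * L)
        idx = np.rint(vol.physical_to_index(p)).astype(int)
        roi = ROISpec(center=tuple(int(v) for v in idx), size=size, tissue_class=tissue_class)
        (i0, i1), (j0, j1) = roi.bounds()
        if i0 < 0 or j0 < 0 or idx[2] < 0 or i1 > nx or j1 > ny or idx[2] >= nz:
            raise ValueError("centerline exits volume: ROI out of bounds")
        rois.append(roi)
    return rois


def roc_optimal_threshold(
    samples: VoxelSampleSet, grid: tuple[int, int] = (0, 100)
) -> ROCResult:
    """Scan an integer HU grid for the Youden-optimal threshold.

    A voxel is classified thrombus iff HU >= t. ``sens(t)`` is the fraction
    of thrombus voxels >= t, ``spec(t)`` the fraction of non-thrombus voxels
    < t; T* maximizes J(t) = sens + spec - 1. Ties are resolved by the
    midpoint of the longest contiguous run of optimal integers, rounded
    toward the lower integer, which centres the cut in the separating gap.
    """
    thrombus = samples.thrombus
    non = samples.non_thrombus
    if len(thrombus) == 0 or len(non) == 0:
        raise ValueError("both classes must be non-empty for ROC analysis")
    pooled = np.concatenate([thrombus, non])
    if np.ptp(pooled) == 0:
        raise ValueError("classes inseparable: all HU values identical (max J = 0)")

    lo, hi = int(grid[0]), int(grid[1])
    if hi <= lo:
        raise ValueError("grid upper bound must exceed lower bound")
    t = np.arange(lo, hi + 1)
    thr_sorted = np.sort(thrombus)
    non_sorted = np.sort(non)
    # sens(t): fraction of thrombus >= t; spec(t): fraction of non-thrombus < t
    sens = 1.0 - np.searchsorted(thr_sorted, t, side="left") / len(thrombus)
    spec = np.searchsorted(non_sorted, t, side="left") / len(non)
    youden = sens + spec - 1.0

    jmax = youden.max()
    optimal = np.isclose(youden, jmax, rtol=0.0, atol=1e-12)
    # longest contiguous run of optimal integers (first run wins ties)
    best_start = best_len = cur_start = cur_len = 0
    for i, flag in enumerate(optimal):
        if flag:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    run_lo = t[best_start]
    run_hi = t[best_start + best_len - 1]
    t_star = int(np.floor((run_lo + run_hi) / 2.0))
    at = t_star - lo
    return ROCResult(
        thresholds=t,
        sensitivity=sens,
        specificity=spec,
        youden=youden,
        optimal_threshold=t_star,
        sensitivity_at_optimum=float(sens[at]),
        specificity_at_optimum=float(spec[at]),
    )


def _predictor_column(predictor: str) -> str:
    key = predictor.replace("contralateral_", "")
    if key not in _PREDICTOR_COLUMNS:
        raise ValueError(f"predictor must be one of {sorted(_PREDICTOR_COLUMNS)}, got {predictor!r}")
    return _PREDICTOR_COLUMNS[key]


def fit_threshold_model(table: pd.DataFrame, predictor: str) -> ThresholdModel:
    """OLS fit of the ROC-optimal threshold on one tissue-HU predictor.

    Returns slope/intercept with R^2, F(1, n-2), and Gaussian-likelihood
    AIC/BIC from the statsmodels fit.
    """
    import statsmodels.api as sm

    col = _predictor_column(predictor)
    if len(table) < 3:
        raise ValueError("need at least 3 rows to fit a threshold model")
    x = np.asarray(table[col], dtype=float)
    y = np.asarray(table[_TARGET_COLUMN], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"zero variance predictor: column {col!r} is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ThresholdModel(
        predictor=predictor.replace("contralateral_", ""),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df=(int(res.df_model), int(res.df_resid)),
        aic=float(res.aic),
        bic=float(res.bic),
        n=len(table),
    )


def predict_threshold(model: ThresholdModel, predictor_value: float) -> float:
    """Predicted optimal threshold (HU), unrounded.

    Rounding to integer HU is applied only where the value feeds volume
    growing (see the segmentation pipeline).
    """
    value = float(predictor_value)
    if not np.isfinite(value):
        raise ValueError("predictor value must be finite")
    return model.intercept + model.slope * value


def compare_models(
    m1: ThresholdModel, m2: ThresholdModel, table: pd.DataFrame
) -> ModelComparison:
    """Per-model AIC/BIC and Pearson r between predictions and ROC thresholds."""
    for m in (m1, m2):
        if m.n is not None and m.n != len(table):
            raise ValueError(
                f"mismatched tables: model fit on n={m.n}, comparison table has n={len(table)}"
            )
    y = np.asarray(table[_TARGET_COLUMN], dtype=float)
    rows = []
    for name, m in (("m1", m1), ("m2", m2)):
        x = np.asarray(table[_predictor_column(m.predictor)], dtype=float)
        pred = m.predict(x)
        r = float(stats.pearsonr(pred, y).statistic) if np.ptp(pred) > 0 else np.nan
        rows.append(
            {
                "model": name,
                "predictor": m.predictor,
                "slope": m.slope,
                "intercept": m.intercept,
                "aic": m.aic,
                "bic": m.bic,
                "pearson_r": r,
            }
        )
    return ModelComparison(records=pd.DataFrame(rows).set_index("model"))


def correlation_report(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> CorrelationReport:
    """Symmetric pairwise association matrix over cohort covariates.

    Pearson's r is used when both margins pass a Shapiro normality screen at
    ``alpha``, otherwise Spearman's rho. Constant columns yield NaN with
    method "undefined".
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation report")
    if columns is None:
        columns = [
            c
            for c in (
                "age",
                "hematocrit",
                "slice_thickness_mm",
                "thrombus_hu",
                "artery_hu",
                "parenchyma_hu",
                "optimal_threshold_hu",
            )
            if c in table.columns
        ]
    cols = list(columns)
    normal = {}
    constant = {}
    for c in cols:
        x = np.asarray(table[c], dtype=float)
        constant[c] = np.ptp(x) == 0
        normal[c] = (not constant[c]) and stats.shapiro(x).pvalue > alpha

    coef = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    meth = pd.DataFrame("", index=cols, columns=cols)
    for i, a in enumerate(cols):
        meth.loc[a, a] = "identity"
        for b in cols[i + 1 :]:
            if constant[a] or constant[b]:
                r, method = np.nan, "undefined"
            elif normal[a] and normal[b]:
                r = stats.pearsonr(table[a], table[b]).statistic
                method = "pearson"
            else:
                r = stats.spearmanr(table[a], table[b]).statistic
                method = "spearman"
            coef.loc[a, b] = coef.loc[b, a] = r
            meth.loc[a, b] = meth.loc[b, a] = method
    return CorrelationReport(coefficients=coef, methods=meth, alpha=alpha)
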