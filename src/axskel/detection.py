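"""PET quantification over VOIs and threshold-based lesion detection.

For every VOI the SUVmax, SUVpeak and SUVmean are extracted from the PET
volume.  Background activity is summarised as the median SUV of the
cervical / thoracic / lumbar spine (plus whole spine, femur, liver and
aortic blood pool; femur and aorta are eroded by one voxel first to shed
cortical bone and vascular lumen).  The target-to-background ratio (TBR)
divides a VOI metric by the spine background matched to the VOI's own
level.  Detection classifies a VOI positive when the chosen metric meets
its cut-off: by default TBR-SUVmax >= 1.8 for posterior joints and SIJs
and >= 2.25 for DVUs; the raw-SUVmax rule uses 10.4 and 13.0.  Thresholds
are closed (>=), so the printed cut-offs act as minimal positive values.

SUVpeak uses a 6 mm-radius spherical neighbourhood (~1 mL, 19 voxels on
the 4 mm grid), an EANM-style convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from . import taxonomy as tax
from .core import ImageVolume, LabelVolume, StructuringElement, erode_one_voxel
from .errors import EmptyMaskError, InvalidArgumentError, UndefinedMetricError
from .voi import VoiRecord

SUVPEAK_RADIUS_MM = 6.0

#: default cut-offs per rule and VOI family (DVUs vs joints/SIJs)
TBR_CUTOFFS = {"joint": 1.8, "dvu": 2.25}
RAW_SUVMAX_CUTOFFS = {"joint": 10.4, "dvu": 13.0}

SPINE_REGIONS = ("cervical", "thoracic", "lumbar")


@dataclass
class SuvMetrics:
    suv_max: float
    suv_peak: float
    suv_mean: float


@dataclass
class BackgroundSet:
    """SUVmedian per reference region."""

    medians: dict = field(default_factory=dict)

    def __getitem__(self, region: str) -> float:
        return self.medians[region]

    def __contains__(self, region: str) -> bool:
        return region in self.medians


@dataclass
class VoiMeasurement:
    voi: VoiRecord
    metrics: SuvMetrics
    background_region: str
    background: float
    tbr: float


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray  # ascending candidate thresholds
    tpr: np.ndarray
    fpr: np.ndarray
    ks_threshold: float
    confusion: tuple  # (tp, fp, tn, fn) at ks_threshold


def extract_suv_metrics(
    pet: ImageVolume, voi: VoiRecord | np.ndarray, peak_radius_mm=SUVPEAK_RADIUS_MM
) -> SuvMetrics:
    """SUVmax/SUVpeak/SUVmean of one VOI.

    SUVpeak is the maximum, over VOI voxels, of the mean PET value in the
    spherical peak neighbourhood centred on that voxel (neighbourhood
    clipped at the grid boundary).
    """
    mask = voi.mask if isinstance(voi, VoiRecord) else np.asarray(voi, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot extract SUV metrics from an empty VOI")
    vals = pet.voxels[mask]
    fp = StructuringElement("sphere", peak_radius_mm).footprint(pet.spacing)
    # mean over the in-grid part of the neighbourhood at each voxel
    ssum = ndimage.correlate(pet.voxels.astype(float), fp.astype(float), mode="constant")
    cnt = ndimage.correlate(np.ones(pet.shape), fp.astype(float), mode="constant")
    peak_map = ssum / cnt
    return SuvMetrics(
        suv_max=float(vals.max()),
        suv_peak=float(peak_map[mask].max()),
        suv_mean=float(vals.mean()),
    )


def background_medians(pet: ImageVolume, labels: LabelVolume) -> BackgroundSet:
    """SUVmedian of the spine segments, whole spine, femur, liver and aorta.

    Femur and aorta masks are eroded by one voxel first; absent regions are
    simply missing from the result.
    """
    out = BackgroundSet()
    spine_all = np.zeros(labels.shape, dtype=bool)
    groups = {"cervical": tax.CERVICAL, "thoracic": tax.THORACIC, "lumbar": tax.LUMBAR}
    for region, names in groups.items():
        m = np.zeros(labels.shape, dtype=bool)
        for n in names:
            if labels.present(n):
                m |= labels.mask(n)
        if m.any():
            out.medians[region] = float(np.median(pet.voxels[m]))
            spine_all |= m
    if spine_all.any():
        out.medians["spine"] = float(np.median(pet.voxels[spine_all]))
    for region, names in (
        ("femur", ("femur_left", "femur_right")),
        ("aorta", ("aorta",)),
        ("liver", ("liver",)),
    ):
        m = np.zeros(labels.shape, dtype=bool)
        for n in names:
            if labels.present(n):
                m |= labels.mask(n)
        if region in ("femur", "aorta"):
            m = erode_one_voxel(m)
        if m.any():
            out.medians[region] = float(np.median(pet.voxels[m]))
    return out


def tbr(metric: float, background: float) -> float:
    """Target-to-background ratio."""
    if background <= 0:
        raise InvalidArgumentError("background must be positive")
    return float(metric) / float(background)


def measure_vois(
    pet: ImageVolume, vois: list[VoiRecord], backgrounds: BackgroundSet
) -> list[VoiMeasurement]:
    """Extract SUV metrics and the level-matched spine TBR for every VOI.

    SIJ VOIs use the lumbar spine background (the anatomically adjacent
    spine segment); VOIs whose background region is unavailable are
    skipped.
    """
    out = []
    for voi in vois:
        region = voi.region
        if region not in backgrounds:
            continue
        m = extract_suv_metrics(pet, voi)
        bg = backgrounds[region]
        out.append(VoiMeasurement(voi, m, region, bg, tbr(m.suv_max, bg)))
    return out


# ---------------------------------------------------------------------------
# ROC / threshold analysis
# ---------------------------------------------------------------------------


def _check_two_class(truth) -> np.ndarray:
    y = np.asarray(truth, dtype=bool)
    if y.all() or not y.any():
        raise UndefinedMetricError("ROC analysis needs both classes present")
    return y


def roc_auc(scores, truth) -> RocResult:
    """ROC analysis of scores against binary truth.

    AUC uses the rank (Mann-Whitney) formulation so ties contribute 1/2;
    the operating threshold maximises the Kolmogorov-Smirnov statistic
    |F+ - F-| = TPR - FPR over observed scores (ties broken towards the
    lower threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = _check_two_class(truth)
    if s.shape != y.shape:
        raise InvalidArgumentError("scores and truth must have equal length")
    auc = float(roc_auc_score(y, s))
    thr = np.unique(s)
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    cp = pos.size - np.searchsorted(pos, thr, side="left")  # positives >= t
    cn = neg.size - np.searchsorted(neg, thr, side="left")  # negatives >= t
    tpr = cp / pos.size
    fpr = cn / neg.size
    # maximise J = TPR - FPR in integer arithmetic (common denominator) so
    # mathematically tied thresholds compare equal; first argmax = lowest t
    j_int = cp.astype(np.int64) * neg.size - cn.astype(np.int64) * pos.size
    ks = float(thr[np.argmax(j_int)])
    t_pred = s >= ks
    tp = int(np.sum(t_pred & y))
    fp = int(np.sum(t_pred & ~y))
    tn = int(np.sum(~t_pred & ~y))
    fn = int(np.sum(~t_pred & y))
    return RocResult(auc, thr, tpr, fpr, ks, (tp, fp, tn, fn))


def ks_optimal_threshold(scores, truth) -> float:
    """Threshold maximising TPR - FPR over the observed scores."""
    return roc_auc(scores, truth).ks_threshold


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_structural(scores: np.ndarray, y: np.ndarray):
    """AUC plus the DeLong structural components V10 (positives) and V01
    (negatives) for one score vector."""
    pos = scores[y]
    neg = scores[~y]
    m, n = pos.size, neg.size
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def delong_test(scores_a, scores_b, truth):
    """DeLong comparison of two correlated AUCs on identical truth.

    Returns ``(auc_a, auc_b, delta, variance, p_value)`` with a two-sided
    normal p-value; identical score vectors give delta 0 and p 1.
    """
    y = _check_two_class(truth)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise InvalidArgumentError("paired scores must match the truth length")
    auc_a, v10_a, v01_a = _delong_structural(a, y)
    auc_b, v10_b, v01_b = _delong_structural(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    delta = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return float(auc_a), float(auc_b), float(delta), float(var), p


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _family(kind: str) -> str:
    return "dvu" if kind == "DVU" else "joint"


def classify_vois(
    measurements: list[VoiMeasurement], rule="tbr-suvmax", cutoffs=None
) -> dict:
    """Per-VOI binary classification: metric >= family cut-off -> positive.

    ``rule`` is ``tbr-suvmax`` (default cut-offs 1.8 for joints/SIJs and
    2.25 for DVUs) or ``raw-suvmax`` (10.4 and 13.0).
    """
    if rule == "tbr-suvmax":
        cutoffs = dict(TBR_CUTOFFS if cutoffs is None else cutoffs)
        value = lambda m: m.tbr
    elif rule == "raw-suvmax":
        cutoffs = dict(RAW_SUVMAX_CUTOFFS if cutoffs is None else cutoffs)
        value = lambda m: m.metrics.suv_max
    else:
        raise InvalidArgumentError(f"unknown detection rule {rule!r}")
    return {m.voi.key: bool(value(m) >= cutoffs[_family(m.voi.kind)]) for m in measurements}


def sensitivity_specificity(predictions, truth):
    """Lesion-level sensitivity and specificity in percent.

    Accepts aligned boolean sequences, or two dicts keyed by VOI id.
    """
    if isinstance(predictions, dict):
        keys = sorted(set(predictions) & set(truth))
        p = np.asarray([predictions[k] for k in keys], dtype=bool)
        t = np.asarray([truth[k] for k in keys], dtype=bool)
    else:
        p = np.asarray(predictions, dtype=bool)
        t = np.asarray(truth, dtype=bool)
        if p.shape != t.shape:
            raise InvalidArgumentError("predictions and truth must have equal length")
    sens = 100.0 * np.sum(p & t) / t.sum() if t.any() else None
    spec = 100.0 * np.sum(~p & ~t) / (~t).sum() if (~t).any() else None
    return (
        None if sens is None else float(sens),
        None if spec is None else float(spec),
    )
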